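"""Signed upstream-regulator activation scoring.

Given a differential selection with up/down directions and a catalog of
signed regulator -> target edges, each regulator receives

* an overlap p-value: the right-tail hypergeometric probability of drawing
  at least the observed number of its targets in the selection, given the
  measured gene universe; and
* an activation Z-score: over the N targets present in the selection,
  z = (sum of concordance terms) / sqrt(N), where a term is +1 when the
  observed direction matches the edge sign under an activated regulator
  (activating edge & up, or inhibiting edge & down) and -1 otherwise.

|z| >= 2 is conventionally read as activated (z positive) or inhibited
(z negative).  All edges carry unit weight: no edge-confidence weighting is
applied, making this the unweighted special case of published causal
analytics scoring.  Unsigned gene-set catalogs (pathways, disease and
bio-function categories) can be scored with the same machinery; sets whose
edges all carry sign +1 simply measure net direction, and the overlap
p-value is sign-free.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core_data import RegulatorNetwork
from .differential_testing import ComparisonResult, FeatureSelection, bh_fdr, select_features

__all__ = [
    "ActivationScore",
    "overlap_pvalue",
    "activation_zscore",
    "score_all_regulators",
]

Z_ACTIVATED = 2.0


@dataclass
class ActivationScore:
    """Overlap p-value and activation Z for one regulator."""

    regulator_id: str
    regulator_class: str
    n_targets: int  # targets inside the measured universe
    n_overlap: int  # targets inside the differential selection
    overlap_p: float
    z: float | None  # None when no target overlaps the selection

    @property
    def predicted_state(self) -> str:
        if self.z is None:
            return "undetermined"
        if self.z >= Z_ACTIVATED:
            return "activated"
        if self.z <= -Z_ACTIVATED:
            return "inhibited"
        return "undetermined"


def overlap_pvalue(de_genes: set, targets: set, universe: set) -> float:
    """Right-tail hypergeometric P(X >= |targets & de_genes|).

    Targets outside the universe are dropped before the draw is evaluated;
    ``de_genes`` must be a subset of the universe.
    """
    if not universe:
        raise ValueError("empty gene universe")
    stray = set(de_genes) - set(universe)
    if stray:
        raise ValueError(f"selection contains genes outside the universe: {sorted(stray)[:5]}")
    targets_in = set(targets) & set(universe)
    M = len(universe)
    n = len(targets_in)
    K = len(de_genes)
    k = len(targets_in & set(de_genes))
    # P(X >= k) with X ~ Hypergeom(M, n, K)
    return float(stats.hypergeom.sf(k - 1, M, n, K))


def activation_zscore(selection: FeatureSelection, edges: pd.DataFrame) -> float | None:
    """Signed concordance Z over the targets present in the selection.

    ``edges`` needs columns ``target_gene`` and ``sign``.  Returns None when
    no target overlaps the selection (the Z is undefined there).
    """
    direction = selection.direction_of()
    concordance = []
    for target, sign in zip(edges["target_gene"], edges["sign"]):
        obs = direction.get(target)
        if obs is None:
            continue
        concordance.append(1 if obs == sign else -1)
    if not concordance:
        return None
    return float(sum(concordance) / np.sqrt(len(concordance)))


def score_all_regulators(
    de: ComparisonResult | FeatureSelection,
    net: RegulatorNetwork,
    universe: set,
    min_overlap: int = 4,
    de_alpha: float = 0.05,
    de_rule: str = "p",
) -> pd.DataFrame:
    """Score every regulator of a network against a differential result.

    ``de`` may be a ready :class:`FeatureSelection` or a raw
    :class:`ComparisonResult` (then thresholded at ``de_rule``/``de_alpha``,
    default p < 0.05).  Regulators with fewer than ``min_overlap`` selected
    targets are omitted (small overlaps give unstable Z-scores).  The table
    is sorted by overlap p-value and carries a BH ``overlap_q`` column.
    """
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    if isinstance(de, ComparisonResult):
        selection = select_features(de, rule=de_rule, alpha=de_alpha)
    else:
        selection = de
    de_genes = selection.features & set(universe)

    rows = []
    for reg in net.regulator_ids:
        edges = net.edges_of(reg)
        in_universe = edges[edges["target_gene"].isin(universe)]
        n_overlap = int(in_universe["target_gene"].isin(de_genes).sum())
        if n_overlap < min_overlap:
            continue
        p = overlap_pvalue(de_genes, set(in_universe["target_gene"]), set(universe))
        z = activation_zscore(selection, in_universe)
        score = ActivationScore(
            regulator_id=reg,
            regulator_class=str(edges["regulator_class"].iloc[0]),
            n_targets=len(in_universe),
            n_overlap=n_overlap,
            overlap_p=p,
            z=z,
        )
        rows.append(
            {
                "regulator_id": score.regulator_id,
                "regulator_class": score.regulator_class,
                "n_targets": score.n_targets,
                "n_overlap": score.n_overlap,
                "overlap_p": score.overlap_p,
                "z": np.nan if score.z is None else score.z,
                "predicted_state": score.predicted_state,
            }
        )
    cols = [
        "regulator_id",
        "regulator_class",
        "n_targets",
        "n_overlap",
        "overlap_p",
        "z",
        "predicted_state",
    ]
    if not rows:
        return pd.DataFrame(columns=cols + ["overlap_q"])
    out = pd.DataFrame(rows, columns=cols)
    out["overlap_q"] = bh_fdr(out["overlap_p"].to_numpy())
    return out.sort_values(["overlap_p", "regulator_id"], kind="mergesort").reset_index(drop=True)
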