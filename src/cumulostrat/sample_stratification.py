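"""Relative classification of analysis units by pairwise activation Z-scores.

An *analysis unit* is one donor-treatment cycle represented by its >= 2
non-pooled cumulus-cell clusters.  For every (reference, comparator) unit
pair the pipeline runs a cluster-level differential test, thresholds it,
and scores a regulator catalog, yielding one activation Z per regulator
per pair.  Comparator units are then classified *relative to the
references* (typically the pregnancy-positive units) by the sign of their
mean Z for a chosen regulator: above +z_cut -> "high" responder, below
-z_cut -> "low", otherwise "middle"; references are "middle" by
construction.  Per-regulator group differences in Z between two sets of
pairs are assessed with a pooled t-test under Holm correction, and the
resulting three groups can be checked for molecular separability with a
per-feature ANOVA.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core_data import OmicsMatrix, RegulatorNetwork, SampleSheet
from .differential_testing import (
    ComparisonResult,
    holm_adjust,
    multi_group_anova,
    select_features,
    two_group_test,
)
from .regulator_scoring import score_all_regulators

__all__ = [
    "PairwiseZ",
    "StratificationResult",
    "pairwise_z_matrix",
    "classify_units",
    "zscore_group_test",
    "three_group_separation",
]


@dataclass
class PairwiseZ:
    """Long table of activation Z-scores, one row per (reference, comparator, regulator)."""

    table: pd.DataFrame  # reference_unit, comparator_unit, regulator_id, n_overlap, overlap_p, z
    de_alpha: float
    min_overlap: int

    def z_of(self, regulator_id: str) -> pd.DataFrame:
        sel = self.table[self.table["regulator_id"] == regulator_id]
        if sel.empty:
            raise KeyError(f"regulator {regulator_id!r} absent from pairwise table")
        return sel

    @property
    def reference_units(self) -> list[str]:
        return list(dict.fromkeys(self.table["reference_unit"]))

    @property
    def comparator_units(self) -> list[str]:
        return list(dict.fromkeys(self.table["comparator_unit"]))


@dataclass
class StratificationResult:
    """Unit -> group assignment plus the per-regulator group tests."""

    assignments: pd.DataFrame  # unit, role (reference|comparator), mean_z, group
    regulator_id: str
    z_cut: float
    group_tests: pd.DataFrame | None = None  # regulator_id, t, p, p_holm, significant

    def group_of(self) -> dict[str, str]:
        return dict(zip(self.assignments["unit"], self.assignments["group"]))

    def units_in(self, group: str) -> list[str]:
        sel = self.assignments[self.assignments["group"] == group]
        return list(sel["unit"])


def _unit_clusters(sheet: SampleSheet, units: list[str]) -> dict[str, list[str]]:
    out = {}
    for u in units:
        members = sheet.clusters_of_cycle(u)
        if len(members) < 2:
            raise ValueError(
                f"analysis unit {u!r} has {len(members)} cluster(s); >=2 required for unit-vs-unit testing"
            )
        out[u] = members
    return out


def pairwise_z_matrix(
    expr: OmicsMatrix,
    sheet: SampleSheet,
    net: RegulatorNetwork,
    reference_units: list[str],
    comparator_units: list[str],
    de_alpha: float = 0.05,
    min_overlap: int = 4,
) -> PairwiseZ:
    """Compute activation Z-scores for every (reference, comparator) unit pair.

    For each pair, the comparator's clusters are tested against the
    reference's clusters (effect = comparator - reference), the result is
    thresholded at p < ``de_alpha``, and every regulator of ``net`` with at
    least ``min_overlap`` selected targets is Z-scored.  Pairs whose
    selection is empty (or whose regulators fall below the overlap floor)
    contribute no rows for those regulators.
    """
    if not reference_units or not comparator_units:
        raise ValueError("need at least one reference and one comparator unit")
    ref_members = _unit_clusters(sheet, list(reference_units))
    cmp_members = _unit_clusters(sheet, list(comparator_units))
    universe = set(expr.feature_ids)

    rows = []
    for ref, ref_cl in ref_members.items():
        for cmp_, cmp_cl in cmp_members.items():
            cols = ref_cl + cmp_cl
            sub = expr.subset_samples(cols)
            labels = {c: "reference" for c in ref_cl}
            labels.update({c: "comparator" for c in cmp_cl})
            de = two_group_test(sub, labels, reference="reference")
            selection = select_features(de, rule="p", alpha=de_alpha)
            scores = score_all_regulators(
                selection, net, universe, min_overlap=min_overlap
            )
            for _, r in scores.iterrows():
                rows.append(
                    (
                        ref,
                        cmp_,
                        r["regulator_id"],
                        int(r["n_overlap"]),
                        float(r["overlap_p"]),
                        float(r["z"]) if pd.notna(r["z"]) else np.nan,
                    )
                )
    table = pd.DataFrame(
        rows,
        columns=["reference_unit", "comparator_unit", "regulator_id", "n_overlap", "overlap_p", "z"],
    )
    return PairwiseZ(table=table, de_alpha=de_alpha, min_overlap=min_overlap)


def classify_units(
    pz: PairwiseZ,
    regulator_id: str,
    z_cut: float = 0.0,
    reference_units: list[str] | None = None,
    comparator_units: list[str] | None = None,
) -> StratificationResult:
    """Three-group classification by mean pairwise Z for one regulator.

    A comparator's score is its mean Z across all reference pairs; scores
    above ``+z_cut`` go to "high", below ``-z_cut`` to "low", anything else
    (ties included) to "middle".  Reference units are "middle" by
    construction.  |mean z| >= 2 marks a conventionally confident call.
    """
    if z_cut < 0:
        raise ValueError("z_cut must be >= 0")
    if reference_units is None:
        reference_units = pz.reference_units
    if comparator_units is None:
        comparator_units = pz.comparator_units
    sel = pz.table[pz.table["regulator_id"] == regulator_id]
    if sel.empty or sel["z"].isna().all():
        raise ValueError(f"no usable Z-scores for regulator {regulator_id!r}")

    rows = [(u, "reference", np.nan, "middle") for u in reference_units]
    for u in comparator_units:
        zs = sel.loc[sel["comparator_unit"] == u, "z"].dropna()
        if zs.empty:
            raise ValueError(
                f"comparator unit {u!r} has no Z-score for regulator {regulator_id!r}"
            )
        mean_z = float(zs.mean())
        if mean_z > z_cut:
            group = "high"
        elif mean_z < -z_cut:
            group = "low"
        else:
            group = "middle"
        rows.append((u, "comparator", mean_z, group))
    assignments = pd.DataFrame(rows, columns=["unit", "role", "mean_z", "group"])
    return StratificationResult(assignments=assignments, regulator_id=regulator_id, z_cut=z_cut)


def zscore_group_test(
    pz: PairwiseZ,
    group_a_pairs: list[tuple[str, str]],
    group_b_pairs: list[tuple[str, str]],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-regulator pooled t-test between two sets of pairwise Z-scores.

    ``group_a_pairs``/``group_b_pairs`` are (reference, comparator) tuples.
    The t statistic is oriented B - A.  P-values are Holm-adjusted across
    the regulators tested; regulators with fewer than two Z values in
    either group are skipped.
    """
    if len(group_a_pairs) < 2 or len(group_b_pairs) < 2:
        raise ValueError("each group needs >=2 pairs")

    def _pick(pairs):
        keys = pd.DataFrame(pairs, columns=["reference_unit", "comparator_unit"])
        return pz.table.merge(keys, on=["reference_unit", "comparator_unit"])

    t_a, t_b = _pick(group_a_pairs), _pick(group_b_pairs)
    rows = []
    for reg in sorted(set(t_a["regulator_id"]) & set(t_b["regulator_id"])):
        za = t_a.loc[t_a["regulator_id"] == reg, "z"].dropna().to_numpy()
        zb = t_b.loc[t_b["regulator_id"] == reg, "z"].dropna().to_numpy()
        if len(za) < 2 or len(zb) < 2:
            continue
        n1, n2 = len(za), len(zb)
        df = n1 + n2 - 2
        pooled = ((n1 - 1) * za.var(ddof=1) + (n2 - 1) * zb.var(ddof=1)) / df
        diff = zb.mean() - za.mean()
        if pooled == 0:
            t = 0.0 if diff == 0 else np.inf * np.sign(diff)
            p = 1.0 if diff == 0 else np.nextafter(0.0, 1.0)
        else:
            t = diff / np.sqrt(pooled * (1 / n1 + 1 / n2))
            p = 2.0 * stats.t.sf(abs(t), df)
        rows.append((reg, float(t), float(p)))
    out = pd.DataFrame(rows, columns=["regulator_id", "t", "p"])
    if not out.empty:
        out["p_holm"] = holm_adjust(out["p"].to_numpy())
        out["significant"] = out["p_holm"] < alpha
    else:
        out["p_holm"] = pd.Series(dtype=float)
        out["significant"] = pd.Series(dtype=bool)
    return out.sort_values("p", kind="mergesort").reset_index(drop=True)


def three_group_separation(
    m: OmicsMatrix,
    strat: StratificationResult,
    sheet: SampleSheet,
    fdr: float = 0.05,
) -> tuple[ComparisonResult, set[str]]:
    """ANOVA across the high/middle/low cluster sets; features at q < fdr.

    Cluster-level group labels are inherited from each cluster's unit
    assignment.  All three groups must be non-empty.
    """
    if not 0 < fdr <= 1:
        raise ValueError("fdr must lie in (0, 1]")
    group_of = strat.group_of()
    labels = {}
    for unit, group in group_of.items():
        for cl in sheet.clusters_of_cycle(unit):
            labels[cl] = group
    present = set(labels.values())
    missing = {"high", "middle", "low"} - present
    if missing:
        raise ValueError(f"empty stratification group(s): {sorted(missing)}")
    cols = [c for c in m.sample_ids if c in labels]
    sub = m.subset_samples(cols)
    res = multi_group_anova(sub, {c: labels[c] for c in cols})
    if fdr == 1.0:
        selected = set(res.feature_ids)
    else:
        selected = set(res.table.index[res.table["q_value"] < fdr])
    return res, selected
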