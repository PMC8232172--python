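"""Core data containers and tabular IO.

The pipeline operates on four tabular objects, all carried as pandas
DataFrames behind thin validating wrappers:

* :class:`OmicsMatrix` -- a dense features x samples matrix, tagged with a
  modality.  Expression values are log2-scale intensities; methylation
  values are beta fractions bounded in [0, 1].
* :class:`SampleSheet` -- maps each cumulus-cluster column of a matrix to
  its donor, treatment cycle, stimulation protocol and pregnancy outcome.
* :class:`FeatureAnnotation` -- probe-to-gene mapping for expression
  features and CpG-to-gene mapping with a signed, strand-aware distance to
  the transcription start site (TSS) for methylation features.
* :class:`RegulatorNetwork` -- signed regulator -> target edges used by the
  activation scorer.

All files are plain TSV with mandated header names, matching the matrix
exports of common array platforms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

__all__ = [
    "OmicsMatrix",
    "SampleSheet",
    "FeatureAnnotation",
    "RegulatorNetwork",
    "AnalysisUnit",
    "read_omics_matrix",
    "write_omics_matrix",
    "read_sample_sheet",
    "write_sample_sheet",
    "read_annotation",
    "write_annotation",
    "read_network",
    "write_network",
    "collapse_probes_to_genes",
    "pca_embed",
]

Modality = Literal["expression", "methylation"]

PROTOCOLS = ("short", "long")
OUTCOMES = ("positive", "negative")

SHEET_COLUMNS = ["cluster_id", "donor_id", "cycle_id", "protocol", "outcome", "oocyte_index"]
ANNOTATION_COLUMNS = ["feature_id", "gene_symbol", "chromosome", "strand", "tss_offset_bp"]
NETWORK_COLUMNS = ["regulator_id", "regulator_class", "target_gene", "sign"]


class FormatError(ValueError):
    """A file or table violates the structural contract of its type."""


def _check_unique(values: Iterable[str], what: str) -> None:
    values = list(values)
    if len(set(values)) != len(values):
        seen, dupes = set(), []
        for v in values:
            if v in seen:
                dupes.append(v)
            seen.add(v)
        raise FormatError(f"duplicate {what}: {sorted(set(dupes))[:5]}")


@dataclass
class OmicsMatrix:
    """Dense features x samples matrix tagged with a modality.

    ``values`` is indexed by feature id with one column per sample cluster.
    Methylation values must lie in [0, 1]; expression values must be finite.
    """

    values: pd.DataFrame
    modality: Modality

    def __post_init__(self) -> None:
        if self.modality not in ("expression", "methylation"):
            raise FormatError(f"unknown modality {self.modality!r}")
        _check_unique(self.values.index, "feature_ids")
        _check_unique(self.values.columns, "sample_ids")
        arr = self.values.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise FormatError("matrix body must be numeric")
        if not np.all(np.isfinite(arr)):
            r, c = np.argwhere(~np.isfinite(arr))[0]
            raise FormatError(
                f"non-finite value at feature {self.values.index[r]!r}, "
                f"sample {self.values.columns[c]!r}"
            )
        if self.modality == "methylation":
            bad = (arr < 0) | (arr > 1)
            if bad.any():
                r, c = np.argwhere(bad)[0]
                raise FormatError(
                    f"beta value {arr[r, c]} outside [0, 1] at feature "
                    f"{self.values.index[r]!r}, sample {self.values.columns[c]!r}"
                )

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_samples(self, sample_ids: Iterable[str]) -> "OmicsMatrix":
        sample_ids = list(sample_ids)
        missing = set(sample_ids) - set(self.values.columns)
        if missing:
            raise KeyError(f"unknown samples: {sorted(missing)}")
        return OmicsMatrix(self.values[sample_ids].copy(), self.modality)


@dataclass
class AnalysisUnit:
    """One donor-treatment cycle with its non-pooled cumulus-cell clusters.

    Unit-vs-unit testing uses the clusters as replicates, so a unit needs at
    least two members.
    """

    cycle_id: str
    cluster_ids: list[str]

    def require_testable(self) -> None:
        if len(self.cluster_ids) < 2:
            raise ValueError(
                f"analysis unit {self.cycle_id!r} has {len(self.cluster_ids)} "
                "cluster(s); >=2 required"
            )


@dataclass
class SampleSheet:
    """Cluster-level metadata: donor, cycle, protocol, outcome, oocyte index."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = set(SHEET_COLUMNS) - set(self.table.columns)
        if missing:
            raise FormatError(f"sample sheet missing columns: {sorted(missing)}")
        self.table = self.table[SHEET_COLUMNS].reset_index(drop=True)
        _check_unique(self.table["cluster_id"], "cluster_id")
        bad_proto = set(self.table["protocol"]) - set(PROTOCOLS)
        if bad_proto:
            raise FormatError(f"unknown protocol values: {sorted(bad_proto)}")
        bad_out = set(self.table["outcome"]) - set(OUTCOMES)
        if bad_out:
            raise FormatError(f"unknown outcome values: {sorted(bad_out)}")
        if (self.table["oocyte_index"].astype(int) < 1).any():
            raise FormatError("oocyte_index must be >= 1")
        # each cycle maps to exactly one donor / protocol / outcome
        for col in ("donor_id", "protocol", "outcome"):
            per_cycle = self.table.groupby("cycle_id")[col].nunique()
            if (per_cycle > 1).any():
                bad = per_cycle[per_cycle > 1].index.tolist()
                raise FormatError(f"cycle(s) {bad} map to more than one {col}")

    @property
    def cluster_ids(self) -> list[str]:
        return list(self.table["cluster_id"])

    def clusters_of_cycle(self, cycle_id: str) -> list[str]:
        sel = self.table[self.table["cycle_id"] == cycle_id]
        if sel.empty:
            raise KeyError(f"unknown cycle {cycle_id!r}")
        return list(sel["cluster_id"])

    def analysis_units(self) -> list[AnalysisUnit]:
        return [
            AnalysisUnit(cycle, list(grp["cluster_id"]))
            for cycle, grp in self.table.groupby("cycle_id", sort=False)
        ]

    def cycle_table(self) -> pd.DataFrame:
        """One row per cycle with donor, protocol and outcome."""
        return (
            self.table.groupby("cycle_id", sort=False)[["donor_id", "protocol", "outcome"]]
            .first()
            .reset_index()
        )

    def labels(self, column: str) -> pd.Series:
        """Per-cluster label vector indexed by cluster_id."""
        return self.table.set_index("cluster_id")[column]


@dataclass
class FeatureAnnotation:
    """Feature-to-gene mapping; methylation features carry a signed TSS offset.

    ``tss_offset_bp`` is strand-aware, in base pairs, 0 at the TSS and
    negative upstream.  Expression probes leave it empty.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = set(ANNOTATION_COLUMNS) - set(self.table.columns)
        if missing:
            raise FormatError(f"annotation missing columns: {sorted(missing)}")
        self.table = self.table[ANNOTATION_COLUMNS].reset_index(drop=True)
        _check_unique(self.table["feature_id"], "feature_id")
        bad_strand = set(self.table["strand"].dropna()) - {"+", "-"}
        if bad_strand:
            raise FormatError(f"strand must be '+' or '-', got {sorted(bad_strand)}")

    def gene_of(self) -> pd.Series:
        return self.table.set_index("feature_id")["gene_symbol"]

    def tss_offsets(self) -> pd.Series:
        return self.table.set_index("feature_id")["tss_offset_bp"]


@dataclass
class RegulatorNetwork:
    """Signed regulator -> target edges (sign +1 activating, -1 inhibiting)."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = set(NETWORK_COLUMNS) - set(self.table.columns)
        if missing:
            raise FormatError(f"network missing columns: {sorted(missing)}")
        self.table = self.table[NETWORK_COLUMNS].reset_index(drop=True)
        signs = set(self.table["sign"].astype(int))
        if signs - {1, -1}:
            raise FormatError(f"edge sign must be +1 or -1, got {sorted(signs - {1, -1})}")
        pairs = self.table[["regulator_id", "target_gene"]]
        if pairs.duplicated().any():
            dupes = pairs[pairs.duplicated()].to_records(index=False).tolist()
            raise FormatError(f"duplicate (regulator, target) pairs: {dupes[:5]}")
        self.table["sign"] = self.table["sign"].astype(int)

    @property
    def regulator_ids(self) -> list[str]:
        return list(dict.fromkeys(self.table["regulator_id"]))

    def edges_of(self, regulator_id: str) -> pd.DataFrame:
        return self.table[self.table["regulator_id"] == regulator_id]

    def flipped(self) -> "RegulatorNetwork":
        t = self.table.copy()
        t["sign"] = -t["sign"]
        return RegulatorNetwork(t)


# ---------------------------------------------------------------------------
# IO


def read_omics_matrix(path: str | Path, modality: Modality) -> OmicsMatrix:
    """Read a TSV matrix (first column feature_id, header row of sample ids)."""
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    try:
        df = df.astype(float)
    except (TypeError, ValueError):
        for col in df.columns:
            coerced = pd.to_numeric(df[col], errors="coerce")
            if coerced.isna().any():
                row = df.index[coerced.isna().to_numpy().nonzero()[0][0]]
                raise FormatError(
                    f"non-numeric cell at feature {row!r}, sample {col!r} in {path}"
                ) from None
        raise
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return OmicsMatrix(df, modality)


def write_omics_matrix(m: OmicsMatrix, path: str | Path) -> None:
    out = m.values.copy()
    out.index.name = "feature_id"
    out.to_csv(path, sep="\t", float_format="%.17g")


def read_sample_sheet(path: str | Path) -> SampleSheet:
    return SampleSheet(pd.read_csv(path, sep="\t", dtype={"cluster_id": str, "donor_id": str, "cycle_id": str}))


def write_sample_sheet(s: SampleSheet, path: str | Path) -> None:
    s.table.to_csv(path, sep="\t", index=False)


def read_annotation(path: str | Path) -> FeatureAnnotation:
    df = pd.read_csv(path, sep="\t", dtype={"feature_id": str, "gene_symbol": str})
    return FeatureAnnotation(df)


def write_annotation(a: FeatureAnnotation, path: str | Path) -> None:
    out = a.table.copy()
    out["tss_offset_bp"] = out["tss_offset_bp"].astype("Int64")
    out.to_csv(path, sep="\t", index=False)


def read_network(path: str | Path) -> RegulatorNetwork:
    return RegulatorNetwork(pd.read_csv(path, sep="\t"))


def write_network(n: RegulatorNetwork, path: str | Path) -> None:
    n.table.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Operations


def collapse_probes_to_genes(
    m: OmicsMatrix, ann: FeatureAnnotation
) -> tuple[OmicsMatrix, pd.DataFrame]:
    """Collapse an expression probe matrix to one row per gene.

    For each gene the probe with the largest variance across samples is
    retained (a deterministic, standard collapse rule; ties broken by probe
    id order).  Probes without a gene annotation are dropped.

    Returns the gene-level matrix and a mapping table with columns
    ``gene_symbol``, ``feature_id`` (the retained probe) and ``n_probes``.
    """
    if m.modality != "expression":
        raise ValueError("probe collapse applies to expression matrices")
    gene_of = ann.gene_of()
    annotated = [f for f in m.feature_ids if f in gene_of.index and pd.notna(gene_of[f])]
    if not annotated:
        raise FormatError("no matrix feature has a gene annotation")
    sub = m.values.loc[annotated]
    variances = sub.var(axis=1, ddof=1)
    tbl = pd.DataFrame(
        {
            "feature_id": sub.index,
            "gene_symbol": gene_of[sub.index].to_numpy(),
            "variance": variances.to_numpy(),
        }
    )
    # stable sort keeps probe-id order among equal variances
    tbl = tbl.sort_values(["gene_symbol", "variance", "feature_id"], ascending=[True, False, True], kind="mergesort")
    winners = tbl.groupby("gene_symbol", sort=True).first()
    mapping = winners.reset_index()[["gene_symbol", "feature_id"]]
    mapping["n_probes"] = tbl.groupby("gene_symbol", sort=True)["feature_id"].count().to_numpy()
    collapsed = m.values.loc[mapping["feature_id"]].copy()
    collapsed.index = mapping["gene_symbol"].to_numpy()
    return OmicsMatrix(collapsed, "expression"), mapping


def pca_embed(m: OmicsMatrix, n_components: int) -> tuple[pd.DataFrame, np.ndarray]:
    """Embed samples by PCA of the feature space.

    Features are centered internally.  Returns per-sample coordinates
    (columns ``PC1..PCk``, ordered by decreasing explained variance) and
    the explained-variance fractions.
    """
    max_k = min(m.n_features, m.n_samples - 1)
    if not 1 <= n_components <= max_k:
        raise ValueError(
            f"n_components={n_components} outside [1, {max_k}] for a "
            f"{m.n_features}x{m.n_samples} matrix"
        )
    X = m.values.to_numpy().T  # samples x features; PCA centers features
    pca = PCA(n_components=n_components, svd_solver="full")
    coords = pca.fit_transform(X)
    out = pd.DataFrame(
        coords,
        index=m.sample_ids,
        columns=[f"PC{i + 1}" for i in range(n_components)],
    )
    return out, pca.explained_variance_ratio_.copy()
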