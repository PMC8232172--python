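"""Expression-methylation correlation around the TSS and clinical screens.

CpGs are paired to genes through the feature annotation; only CpGs within
the +-window (default 10 kb, closed interval) of the TSS are considered.
Per (gene, CpG) pair a Spearman rank correlation is computed across the
shared samples, with a two-sided p from the t approximation (average ranks
for ties; an exact permutation p is available for very small n).  Records
can be summarised into a 1-kb positional profile around the TSS, split by
correlation sign -- the cohort-level readout for promoter-coupled
repressive methylation is an excess of significant negative over positive
correlations in the central bins.

Clinical screens correlate every matrix feature (Pearson) against a
per-cycle clinical scalar broadcast to that cycle's cluster columns.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core_data import FeatureAnnotation, OmicsMatrix, SampleSheet

__all__ = [
    "CorrelationRecord",
    "TssProfile",
    "expr_meth_correlation",
    "tss_profile",
    "clinical_feature_correlation",
    "parameter_overlap",
    "count_correlation",
    "spearman_rho",
]


@dataclass
class TssProfile:
    """Per-1-kb-bin counts of significant correlations around the TSS."""

    bins: pd.DataFrame  # bin_left, bin_right, n_negative, n_positive, neglog10p_negative, neglog10p_positive
    alpha: float
    n_records: int
    n_significant_negative: int
    n_significant_positive: int

    @property
    def negative_positive_ratio(self) -> float:
        """Global significant negative:positive ratio (inf when no positives)."""
        if self.n_significant_positive == 0:
            return float("inf") if self.n_significant_negative > 0 else float("nan")
        return self.n_significant_negative / self.n_significant_positive

    def central_ratio(self, n_central_bins: int = 2) -> float:
        """Negative:positive ratio restricted to the bins flanking the TSS."""
        half = n_central_bins // 2 * 1000
        sel = self.bins[(self.bins["bin_left"] >= -half) & (self.bins["bin_right"] <= half)]
        neg, pos = int(sel["n_negative"].sum()), int(sel["n_positive"].sum())
        if pos == 0:
            return float("inf") if neg > 0 else float("nan")
        return neg / pos


def _rank_rows(X: np.ndarray) -> np.ndarray:
    return np.apply_along_axis(stats.rankdata, 1, X)


def _pearson_rows(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Row-wise Pearson correlation of two aligned matrices."""
    A = A - A.mean(axis=1, keepdims=True)
    B = B - B.mean(axis=1, keepdims=True)
    denom = np.sqrt((A**2).sum(axis=1) * (B**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (A * B).sum(axis=1) / denom
    return np.clip(r, -1.0, 1.0)


def _t_pvalue(r: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p for a correlation coefficient via the t approximation."""
    r = np.asarray(r, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(t), n - 2)
    p = np.where(np.abs(r) >= 1.0, 0.0, p)
    return p


def spearman_rho(x, y, exact: bool = False) -> tuple[float, float]:
    """Spearman rho with average ranks for ties, plus a two-sided p.

    ``exact=True`` computes the permutation p by full enumeration and is
    meant for very small vectors (n <= 8).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and of equal length")
    n = len(x)
    if n < 4:
        raise ValueError("need >=4 observations for a rank correlation")
    rx, ry = stats.rankdata(x), stats.rankdata(y)
    rho = float(_pearson_rows(rx[None, :], ry[None, :])[0])
    if exact:
        if n > 8:
            raise ValueError("exact permutation p supported for n <= 8 only")
        count = 0
        total = 0
        for perm in itertools.permutations(range(n)):
            r_perm = float(_pearson_rows(rx[None, :], ry[np.array(perm)][None, :])[0])
            total += 1
            if abs(r_perm) >= abs(rho) - 1e-12:
                count += 1
        return rho, count / total
    return rho, float(_t_pvalue(np.array([rho]), n)[0])


def expr_meth_correlation(
    expr: OmicsMatrix,
    meth: OmicsMatrix,
    ann: FeatureAnnotation,
    window_bp: int = 10000,
) -> pd.DataFrame:
    """Spearman correlation per (gene, CpG) pair within the TSS window.

    Returns records with columns ``gene_symbol``, ``cpg_id``,
    ``tss_offset_bp``, ``rho``, ``p_value``, ``q_value`` (BH across all
    pairs) and ``sign``.
    """
    shared = [s for s in expr.sample_ids if s in set(meth.sample_ids)]
    if len(shared) < 4:
        raise ValueError(f"only {len(shared)} shared samples; >=4 required")
    atab = ann.table
    cpg_rows = atab[atab["feature_id"].isin(meth.feature_ids) & atab["tss_offset_bp"].notna()]
    cpg_rows = cpg_rows[np.abs(cpg_rows["tss_offset_bp"].astype(int)) <= window_bp]
    cpg_rows = cpg_rows[cpg_rows["gene_symbol"].isin(set(expr.feature_ids))]
    if cpg_rows.empty:
        return pd.DataFrame(
            columns=["gene_symbol", "cpg_id", "tss_offset_bp", "rho", "p_value", "q_value", "sign"]
        )

    E = expr.values.loc[cpg_rows["gene_symbol"], shared].to_numpy(dtype=float)
    M = meth.values.loc[cpg_rows["feature_id"], shared].to_numpy(dtype=float)
    rho = _pearson_rows(_rank_rows(E), _rank_rows(M))
    p = _t_pvalue(rho, len(shared))
    from .differential_testing import bh_fdr

    q = bh_fdr(np.clip(p, np.nextafter(0.0, 1.0), 1.0))
    out = pd.DataFrame(
        {
            "gene_symbol": cpg_rows["gene_symbol"].to_numpy(),
            "cpg_id": cpg_rows["feature_id"].to_numpy(),
            "tss_offset_bp": cpg_rows["tss_offset_bp"].astype(int).to_numpy(),
            "rho": rho,
            "p_value": p,
            "q_value": q,
            "sign": np.where(rho >= 0, "positive", "negative"),
        }
    )
    return out.reset_index(drop=True)


def tss_profile(records: pd.DataFrame, alpha: float = 0.01) -> TssProfile:
    """Bin correlation records into 1-kb windows around the TSS.

    Bins are [-10000, -9000), ..., [9000, 10000]; counts cover records
    significant at ``p < alpha`` split by correlation sign, with the mean
    -log10(p) per bin and sign.
    """
    edges = np.arange(-10000, 10001, 1000)
    rows = []
    if len(records):
        sig = records[records["p_value"] < alpha]
    else:
        sig = records
    for left, right in zip(edges[:-1], edges[1:]):
        if right == 10000:
            mask_all = lambda df: (df["tss_offset_bp"] >= left) & (df["tss_offset_bp"] <= right)
        else:
            mask_all = lambda df: (df["tss_offset_bp"] >= left) & (df["tss_offset_bp"] < right)
        if len(records):
            in_bin = sig[mask_all(sig)]
            neg = in_bin[in_bin["sign"] == "negative"]
            pos = in_bin[in_bin["sign"] == "positive"]
            nlp = lambda df: float(-np.log10(df["p_value"]).mean()) if len(df) else 0.0
            rows.append((left, right, len(neg), len(pos), nlp(neg), nlp(pos)))
        else:
            rows.append((left, right, 0, 0, 0.0, 0.0))
    bins = pd.DataFrame(
        rows,
        columns=[
            "bin_left",
            "bin_right",
            "n_negative",
            "n_positive",
            "neglog10p_negative",
            "neglog10p_positive",
        ],
    )
    n_neg = int(bins["n_negative"].sum())
    n_pos = int(bins["n_positive"].sum())
    return TssProfile(
        bins=bins,
        alpha=alpha,
        n_records=len(records),
        n_significant_negative=n_neg,
        n_significant_positive=n_pos,
    )


def clinical_feature_correlation(
    m: OmicsMatrix,
    clinical_scalar: pd.Series | dict,
    sheet: SampleSheet | None = None,
    alpha: float = 0.01,
) -> pd.DataFrame:
    """Pearson screen of every feature against one clinical scalar.

    ``clinical_scalar`` maps cycle ids (with ``sheet`` supplied, broadcast
    to that cycle's clusters) or sample ids directly to a value.  Returns a
    table of selected features at ``p < alpha`` with columns ``feature_id``,
    ``r``, ``p_value`` and ``direction``.
    """
    scalar = pd.Series(clinical_scalar, dtype=float)
    if sheet is not None:
        cycle_of = sheet.labels("cycle_id")
        scalar = pd.Series({c: scalar[cycle_of[c]] for c in m.sample_ids if cycle_of.get(c) in scalar.index})
    cols = [s for s in m.sample_ids if s in scalar.index]
    if len(cols) < 4:
        raise ValueError(f"only {len(cols)} samples carry a clinical value; >=4 required")
    y = scalar[cols].to_numpy(dtype=float)
    if np.allclose(y, y[0]):
        raise ValueError("clinical vector is constant; correlation undefined")
    distinct_cycles = len(set(np.round(y, 12)))
    if distinct_cycles < 2:
        raise ValueError("clinical vector is constant; correlation undefined")
    X = m.values[cols].to_numpy(dtype=float)
    r = _pearson_rows(X, np.tile(y, (X.shape[0], 1)))
    r = np.where(np.isnan(r), 0.0, r)  # zero-variance features carry no signal
    p = _t_pvalue(r, len(cols))
    p = np.where(r == 0.0, 1.0, p)
    if alpha >= 1.0:
        mask = np.ones_like(p, dtype=bool)
    else:
        mask = p < alpha
    out = pd.DataFrame(
        {
            "feature_id": np.asarray(m.feature_ids)[mask],
            "r": r[mask],
            "p_value": p[mask],
            "direction": np.where(r[mask] >= 0, "positive", "negative"),
        }
    )
    return out.reset_index(drop=True)


def parameter_overlap(sets: dict[str, set]) -> pd.DataFrame:
    """Symmetric pairwise intersection-count matrix; diagonal = set sizes."""
    if len(sets) < 2:
        raise ValueError("need >=2 named sets")
    names = list(sets)
    mat = pd.DataFrame(0, index=names, columns=names, dtype=int)
    for a in names:
        for b in names:
            mat.loc[a, b] = len(set(sets[a]) & set(sets[b]))
    return mat


def count_correlation(counts_expr, counts_meth) -> tuple[float, float]:
    """Pearson r and two-sided p between per-parameter selection counts."""
    a = np.asarray(counts_expr, dtype=float)
    b = np.asarray(counts_meth, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    if len(a) < 3:
        raise ValueError("need >=3 parameters")
    r, p = stats.pearsonr(a, b)
    return float(r), float(p)
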