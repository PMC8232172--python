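"""Synthetic ICSI-cohort generator with planted ground truth.

The generator emulates the statistical structure the downstream analyses
assume, so every stage of the pipeline can be exercised and validated
against known truth without access to patient data:

* **Donor effects** -- each donor contributes a per-gene offset (Gaussian by
  default, or bimodal +-sigma_d to mimic a strongly heterogeneous cohort),
  shared by all cumulus clusters of that donor across treatment cycles.
* **Protocol effects** -- a random subset of genes shifts in long-protocol
  (GnRH agonist) samples relative to short-protocol (antagonist) ones.
* **Outcome-linked regulator modules** -- treatment cycles carry a latent
  response-group label (high / middle / low); the planted regulators of a
  group shift their network targets by beta * edge_sign * direction, so an
  activated regulator pushes its activating targets up and its inhibiting
  targets down.  Pregnancy-positive cycles are the middle group, mirroring
  a positive cohort flanked by over- and under-stimulated negative groups.
* **Expression-methylation coupling** -- CpG beta values follow a logistic
  model on the logit scale; CpGs within the coupling window of a gene's TSS
  receive a negative coefficient on that gene's expression deviation, CpGs
  outside the window are uncoupled.
* **Clinical growth curves** -- estrogen, endometrium thickness and lead
  follicle size grow linearly in day with group-specific slopes plus noise.

Expression is simulated at the gene level (one feature per gene symbol);
probe-to-gene collapse is exercised separately with explicit multi-probe
fixtures.  A single global seed fans out to per-component child generators,
so e.g. the network is reproducible independently of the matrices.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit

from .core_data import (
    FeatureAnnotation,
    OmicsMatrix,
    RegulatorNetwork,
    SampleSheet,
    write_annotation,
    write_network,
    write_omics_matrix,
    write_sample_sheet,
)

__all__ = [
    "CohortConfig",
    "GroundTruth",
    "Cohort",
    "generate_cohort",
    "generate_regulator_network",
    "null_config",
    "two_group_config",
    "heterogeneous_config",
    "homogeneous_control_config",
]

GROUPS = ("high", "middle", "low")
CLINICAL_PARAMETERS = ("estrogen", "endometrium", "lead_follicle")

_BETA_EPS = 1e-12  # keep generated betas strictly inside (0, 1)


def _default_active_regulators() -> dict:
    return {"high": {"REG01": +1}, "low": {"REG01": -1}}


def _default_group_proportions() -> dict:
    return {"high": 1 / 3, "middle": 1 / 3, "low": 1 / 3}


def _default_clinical_slopes() -> dict:
    # units per day: estrogen pg/mL, endometrium mm, lead follicle mm
    return {
        "estrogen": {"high": 220.0, "middle": 180.0, "low": 140.0},
        "endometrium": {"high": 0.75, "middle": 0.60, "low": 0.45},
        "lead_follicle": {"high": 1.50, "middle": 1.25, "low": 1.00},
    }


def _default_clinical_intercepts() -> dict:
    return {"estrogen": 50.0, "endometrium": 4.0, "lead_follicle": 5.0}


def _default_clinical_noise() -> dict:
    return {"estrogen": 60.0, "endometrium": 0.4, "lead_follicle": 0.8}


@dataclass
class CohortConfig:
    """All knobs of the generator; defaults emulate the study conditions.

    Sample-size defaults follow the source cohort scale (eight donors, one
    cycle each, a few non-pooled cumulus clusters per cycle, ~70% long
    protocol).  Effect sizes default to values at which planted structure
    is recoverable by the pipeline's own statistics at this cohort size.
    """

    n_donors: int = 8
    cycles_per_donor: int = 1  # 1 or 2
    clusters_per_cycle: int = 3  # 2..4
    n_genes: int = 2000
    n_cpgs: int = 1000
    n_regulators: int = 10
    targets_per_regulator: int = 40
    activating_fraction: float = 0.7
    baseline_mean: float = 8.0  # log2-scale intensity
    baseline_sd: float = 1.5
    donor_sd: float = 0.3  # sigma_d
    cluster_sd: float = 0.5  # sigma_e
    donor_effect: str = "normal"  # "normal" | "bimodal"
    protocol_effect_size: float = 1.0
    n_protocol_genes: int = 100
    long_fraction: float = 0.7
    outcome_effect_size: float = 1.5  # beta applied to regulator targets
    active_regulators: dict = field(default_factory=_default_active_regulators)
    group_proportions: dict = field(default_factory=_default_group_proportions)
    meth_coupling: float = -2.0  # logit units per log2 expression deviation
    coupling_window_bp: int = 1000
    meth_baseline_sd: float = 1.5
    meth_noise_sd: float = 0.3
    clinical_slopes: dict = field(default_factory=_default_clinical_slopes)
    clinical_intercepts: dict = field(default_factory=_default_clinical_intercepts)
    clinical_noise_sd: dict = field(default_factory=_default_clinical_noise)
    clinical_days: tuple = (5, 7, 9, 11)
    mean_age: float = 33.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_donors < 1:
            raise ValueError("n_donors must be >= 1")
        if not 1 <= self.cycles_per_donor <= 2:
            raise ValueError("cycles_per_donor must be 1 or 2")
        if not 2 <= self.clusters_per_cycle <= 4:
            raise ValueError("clusters_per_cycle must be in [2, 4]")
        for name in ("baseline_sd", "donor_sd", "cluster_sd", "meth_baseline_sd", "meth_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.donor_effect not in ("normal", "bimodal"):
            raise ValueError("donor_effect must be 'normal' or 'bimodal'")
        if not 0 <= self.coupling_window_bp <= 10000:
            raise ValueError("coupling_window_bp must lie in [0, 10000]")
        if not 0 <= self.long_fraction <= 1:
            raise ValueError("long_fraction must lie in [0, 1]")
        if not 0 <= self.activating_fraction <= 1:
            raise ValueError("activating_fraction must lie in [0, 1]")
        if set(self.group_proportions) - set(GROUPS):
            raise ValueError(f"group labels must be among {GROUPS}")
        if abs(sum(self.group_proportions.values()) - 1.0) > 1e-9:
            raise ValueError("group_proportions must sum to 1")
        if set(self.active_regulators) - set(GROUPS):
            raise ValueError(f"active_regulators keys must be among {GROUPS}")
        if self.n_protocol_genes > self.n_genes:
            raise ValueError("n_protocol_genes exceeds gene universe")
        if len(self.clinical_days) < 2:
            raise ValueError("need >=2 clinical observation days")

    @classmethod
    def from_dict(cls, d: dict) -> "CohortConfig":
        d = dict(d)
        if "clinical_days" in d:
            d["clinical_days"] = tuple(d["clinical_days"])
        return cls(**d)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["clinical_days"] = list(self.clinical_days)
        return d


@dataclass
class GroundTruth:
    """Every planted effect, for parameter-recovery testing."""

    donor_offsets: pd.DataFrame  # genes x donors
    protocol_effects: dict  # gene -> delta applied in long-protocol samples
    group_effects: dict  # group -> {gene -> delta}
    regulator_truth: dict  # group -> {regulator_id -> direction}
    cpg_coupling: pd.DataFrame  # cpg_id, gene_symbol, tss_offset_bp, coupling
    cycle_truth: pd.DataFrame  # cycle_id, group, outcome + one slope column per parameter

    def to_json(self, path: str | Path) -> None:
        payload = {
            "donor_offsets": {
                d: self.donor_offsets[d].round(10).to_dict() for d in self.donor_offsets.columns
            },
            "protocol_effects": self.protocol_effects,
            "group_effects": self.group_effects,
            "regulator_truth": self.regulator_truth,
            "cpg_coupling": self.cpg_coupling.to_dict(orient="records"),
            "cycle_truth": self.cycle_truth.to_dict(orient="records"),
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


@dataclass
class Cohort:
    """Everything one simulated study yields."""

    expression: OmicsMatrix
    methylation: OmicsMatrix
    sheet: SampleSheet
    annotation: FeatureAnnotation
    network: RegulatorNetwork
    clinical: pd.DataFrame  # long: cycle_id, parameter, day, value
    clinical_static: pd.DataFrame  # cycle_id, spindle_presence, zona_birefringence, pronuclear_pattern, age
    truth: GroundTruth

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_omics_matrix(self.expression, outdir / "expression.tsv")
        write_omics_matrix(self.methylation, outdir / "methylation.tsv")
        write_sample_sheet(self.sheet, outdir / "samples.tsv")
        write_annotation(self.annotation, outdir / "annotation.tsv")
        write_network(self.network, outdir / "network.tsv")
        self.clinical.to_csv(outdir / "clinical.tsv", sep="\t", index=False, float_format="%.10g")
        self.clinical_static.to_csv(
            outdir / "clinical_static.tsv", sep="\t", index=False, float_format="%.10g"
        )
        self.truth.to_json(outdir / "ground_truth.json")


def generate_regulator_network(
    n_regulators: int,
    targets_per_regulator: int,
    activating_fraction: float,
    genes: list[str],
    seed: int | np.random.Generator = 0,
) -> RegulatorNetwork:
    """Draw a signed regulator -> target catalog over a gene universe.

    Each regulator samples its targets without replacement (overlap between
    regulators is allowed); edge signs are +1 with ``activating_fraction``.
    """
    if n_regulators < 0:
        raise ValueError("n_regulators must be >= 0")
    if n_regulators > 0 and targets_per_regulator < 1:
        raise ValueError("targets_per_regulator must be >= 1")
    if targets_per_regulator > len(genes) and n_regulators > 0:
        raise ValueError(
            f"targets_per_regulator={targets_per_regulator} exceeds the "
            f"gene universe of {len(genes)}"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    classes = ("hormone", "transcription regulator", "kinase")
    rows = []
    for i in range(n_regulators):
        reg = f"REG{i + 1:02d}"
        targets = rng.choice(genes, size=targets_per_regulator, replace=False)
        signs = np.where(rng.random(targets_per_regulator) < activating_fraction, 1, -1)
        for t, s in zip(targets, signs):
            rows.append((reg, classes[i % len(classes)], str(t), int(s)))
    return RegulatorNetwork(
        pd.DataFrame(rows, columns=["regulator_id", "regulator_class", "target_gene", "sign"])
    )


def _assign_groups(n_cycles: int, proportions: dict) -> list[str]:
    """Deterministic largest-remaining-quota assignment over cycle order."""
    quotas = {g: proportions.get(g, 0.0) * n_cycles for g in GROUPS}
    assigned: list[str] = []
    counts = {g: 0 for g in GROUPS}
    for _ in range(n_cycles):
        deficit = {g: quotas[g] - counts[g] for g in GROUPS}
        pick = max(GROUPS, key=lambda g: deficit[g])
        assigned.append(pick)
        counts[pick] += 1
    return assigned


def generate_cohort(cfg: CohortConfig) -> Cohort:
    """Simulate one full cohort with ground truth; same seed, same bits."""
    ss = np.random.SeedSequence(cfg.seed)
    rng_sheet, rng_net, rng_expr, rng_meth, rng_clin = (
        np.random.default_rng(s) for s in ss.spawn(5)
    )

    genes = [f"G{i:04d}" for i in range(cfg.n_genes)]
    n_cycles = cfg.n_donors * cfg.cycles_per_donor

    # --- sample sheet -------------------------------------------------
    groups = _assign_groups(n_cycles, cfg.group_proportions)
    n_short = int(round((1 - cfg.long_fraction) * n_cycles))
    short_cycles = set(rng_sheet.choice(n_cycles, size=n_short, replace=False).tolist())
    rows = []
    cycle_meta = []
    ci = 0
    for d in range(cfg.n_donors):
        donor = f"D{d + 1:02d}"
        for _ in range(cfg.cycles_per_donor):
            cycle = f"VS{ci + 1}"
            protocol = "short" if ci in short_cycles else "long"
            group = groups[ci]
            outcome = "positive" if group == "middle" else "negative"
            for k in range(cfg.clusters_per_cycle):
                rows.append((f"{cycle}c{k + 1}", donor, cycle, protocol, outcome, k + 1))
            cycle_meta.append((cycle, donor, protocol, outcome, group))
            ci += 1
    sheet = SampleSheet(pd.DataFrame(rows, columns=["cluster_id", "donor_id", "cycle_id", "protocol", "outcome", "oocyte_index"]))
    meta = pd.DataFrame(cycle_meta, columns=["cycle_id", "donor_id", "protocol", "outcome", "group"])

    # --- network ------------------------------------------------------
    network = generate_regulator_network(
        cfg.n_regulators, cfg.targets_per_regulator, cfg.activating_fraction, genes, rng_net
    )
    known = set(network.regulator_ids)
    for group, regs in cfg.active_regulators.items():
        missing = set(regs) - known
        if missing:
            raise ValueError(f"active regulator(s) {sorted(missing)} not in the generated network")

    # --- expression ---------------------------------------------------
    mu = rng_expr.normal(cfg.baseline_mean, cfg.baseline_sd, size=cfg.n_genes)
    donors = sorted(sheet.table["donor_id"].unique())
    if cfg.donor_effect == "normal":
        donor_off = rng_expr.normal(0.0, cfg.donor_sd, size=(cfg.n_genes, len(donors)))
    else:  # bimodal: +-sigma_d, a strongly heterogeneous cohort
        donor_off = cfg.donor_sd * rng_expr.choice([-1.0, 1.0], size=(cfg.n_genes, len(donors)))
    donor_off_df = pd.DataFrame(donor_off, index=genes, columns=donors)

    proto_idx = rng_expr.choice(cfg.n_genes, size=cfg.n_protocol_genes, replace=False)
    proto_sign = rng_expr.choice([-1.0, 1.0], size=cfg.n_protocol_genes)
    protocol_delta = np.zeros(cfg.n_genes)
    protocol_delta[proto_idx] = cfg.protocol_effect_size * proto_sign
    protocol_effects = {genes[i]: float(protocol_delta[i]) for i in proto_idx}

    gene_index = {g: i for i, g in enumerate(genes)}
    group_delta = {g: np.zeros(cfg.n_genes) for g in GROUPS}
    for group, regs in cfg.active_regulators.items():
        for reg, direction in regs.items():
            edges = network.edges_of(reg)
            for t, s in zip(edges["target_gene"], edges["sign"]):
                group_delta[group][gene_index[t]] += cfg.outcome_effect_size * direction * s
    group_effects = {
        g: {genes[i]: float(v) for i, v in enumerate(group_delta[g]) if v != 0.0} for g in GROUPS
    }

    donor_of = sheet.labels("donor_id")
    cycle_of = sheet.labels("cycle_id")
    group_of_cycle = meta.set_index("cycle_id")["group"]
    clusters = sheet.cluster_ids
    X = np.empty((cfg.n_genes, len(clusters)))
    for j, cl in enumerate(clusters):
        cyc = cycle_of[cl]
        col = mu + donor_off_df[donor_of[cl]].to_numpy()
        if meta.set_index("cycle_id")["protocol"][cyc] == "long":
            col = col + protocol_delta
        col = col + group_delta[group_of_cycle[cyc]]
        X[:, j] = col
    X = X + rng_expr.normal(0.0, cfg.cluster_sd, size=X.shape)
    expression = OmicsMatrix(pd.DataFrame(X, index=genes, columns=clusters), "expression")

    # --- methylation --------------------------------------------------
    cpg_gene_idx = rng_meth.integers(0, cfg.n_genes, size=cfg.n_cpgs)
    offsets = rng_meth.integers(-10000, 10001, size=cfg.n_cpgs)
    cpg_ids = [f"cg{i:06d}" for i in range(cfg.n_cpgs)]
    coupling = np.where(np.abs(offsets) <= cfg.coupling_window_bp, cfg.meth_coupling, 0.0)
    b0 = rng_meth.normal(0.0, cfg.meth_baseline_sd, size=cfg.n_cpgs)
    deviation = X - mu[:, None]  # latent expression deviation per gene x sample
    logit = b0[:, None] + coupling[:, None] * deviation[cpg_gene_idx, :]
    logit = logit + rng_meth.normal(0.0, cfg.meth_noise_sd, size=logit.shape)
    betas = np.clip(expit(logit), _BETA_EPS, 1.0 - _BETA_EPS)
    methylation = OmicsMatrix(pd.DataFrame(betas, index=cpg_ids, columns=clusters), "methylation")

    strands = rng_meth.choice(["+", "-"], size=cfg.n_cpgs)
    annotation = FeatureAnnotation(
        pd.concat(
            [
                pd.DataFrame(
                    {
                        "feature_id": genes,
                        "gene_symbol": genes,
                        "chromosome": "chr1",
                        "strand": "+",
                        "tss_offset_bp": pd.array([pd.NA] * cfg.n_genes, dtype="Int64"),
                    }
                ),
                pd.DataFrame(
                    {
                        "feature_id": cpg_ids,
                        "gene_symbol": [genes[i] for i in cpg_gene_idx],
                        "chromosome": "chr1",
                        "strand": strands,
                        "tss_offset_bp": pd.array(offsets, dtype="Int64"),
                    }
                ),
            ],
            ignore_index=True,
        )
    )
    cpg_coupling = pd.DataFrame(
        {
            "cpg_id": cpg_ids,
            "gene_symbol": [genes[i] for i in cpg_gene_idx],
            "tss_offset_bp": offsets,
            "coupling": coupling,
        }
    )

    # --- clinical -----------------------------------------------------
    days = list(cfg.clinical_days)
    clin_rows = []
    slope_cols = {p: [] for p in CLINICAL_PARAMETERS}
    for cyc, group in zip(meta["cycle_id"], meta["group"]):
        for param in CLINICAL_PARAMETERS:
            slope = cfg.clinical_slopes[param][group]
            intercept = cfg.clinical_intercepts[param]
            noise = rng_clin.normal(0.0, cfg.clinical_noise_sd[param], size=len(days))
            for day, eps in zip(days, noise):
                clin_rows.append((cyc, param, int(day), float(intercept + slope * day + eps)))
            slope_cols[param].append(slope)
    clinical = pd.DataFrame(clin_rows, columns=["cycle_id", "parameter", "day", "value"])
    clinical_static = pd.DataFrame(
        {
            "cycle_id": meta["cycle_id"],
            "spindle_presence": rng_clin.integers(0, 2, size=n_cycles),
            "zona_birefringence": rng_clin.integers(1, 4, size=n_cycles),
            "pronuclear_pattern": rng_clin.integers(1, 4, size=n_cycles),
            "age": np.round(rng_clin.normal(cfg.mean_age, 3.0, size=n_cycles), 1),
        }
    )

    cycle_truth = meta[["cycle_id", "group", "outcome"]].copy()
    for param in CLINICAL_PARAMETERS:
        cycle_truth[f"slope_{param}"] = slope_cols[param]

    truth = GroundTruth(
        donor_offsets=donor_off_df,
        protocol_effects=protocol_effects,
        group_effects=group_effects,
        regulator_truth={g: dict(r) for g, r in cfg.active_regulators.items()},
        cpg_coupling=cpg_coupling,
        cycle_truth=cycle_truth,
    )
    return Cohort(
        expression=expression,
        methylation=methylation,
        sheet=sheet,
        annotation=annotation,
        network=network,
        clinical=clinical,
        clinical_static=clinical_static,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# Named study conditions
#
# These presets pin down the cohort designs used for calibration and
# recovery benchmarking, so tests, scripts and documentation all reference
# one definition.


def null_config(seed: int = 0, **overrides) -> CohortConfig:
    """A cohort with no planted effects: pure cluster noise.

    10 donors x 2 clusters give 20 samples split evenly into two outcome
    groups; every systematic effect (donor, protocol, outcome) is zeroed,
    so any differential signal is a false positive.
    """
    base = dict(
        n_donors=10,
        clusters_per_cycle=2,
        donor_sd=0.0,
        protocol_effect_size=0.0,
        outcome_effect_size=0.0,
        group_proportions={"high": 0.5, "middle": 0.5, "low": 0.0},
        active_regulators={},
        seed=seed,
    )
    base.update(overrides)
    return CohortConfig(**base)


def two_group_config(seed: int = 0, **overrides) -> CohortConfig:
    """A clean two-group design: one regulator activated in the negative group.

    Half the cycles are "middle" (pregnancy positive), half "high"
    (negative) with regulator REG01 activated, so a positive-vs-negative
    test carries one signed planted module and no other structure.
    """
    base = dict(
        group_proportions={"high": 0.5, "middle": 0.5, "low": 0.0},
        active_regulators={"high": {"REG01": +1}},
        long_fraction=1.0,
        protocol_effect_size=0.0,
        seed=seed,
    )
    base.update(overrides)
    return CohortConfig(**base)


def heterogeneous_config(seed: int = 0, **overrides) -> CohortConfig:
    """Strongly heterogeneous cohort: bimodal donor effects, modest outcome effect.

    Every gene carries a +-sigma_d offset per donor, so the differential
    signature between outcome groups rides on which donors survive a
    subsample -- the regime the resampling heterogeneity statistic is
    designed to flag.
    """
    base = dict(donor_effect="bimodal", donor_sd=1.2, outcome_effect_size=0.8)
    base.update(overrides)
    return two_group_config(seed, **base)


def homogeneous_control_config(seed: int = 0, **overrides) -> CohortConfig:
    """Homogeneous control: no donor structure, one strong clean signature.

    Mirrors a benchmark contrast with a large reproducible signal (such as
    a male-vs-female blood comparison): the selected feature set barely
    moves under subsampling.
    """
    base = dict(donor_effect="normal", donor_sd=0.0, outcome_effect_size=2.0)
    base.update(overrides)
    return two_group_config(seed, **base)
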