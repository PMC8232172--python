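"""Pairwise Z stratification: classification, group tests, ANOVA separation."""

import numpy as np
import pandas as pd
import pytest

from cumulostrat import (
    CohortConfig,
    PairwiseZ,
    classify_units,
    generate_cohort,
    pairwise_z_matrix,
    three_group_separation,
    zscore_group_test,
)

from conftest import make_matrix, make_network


@pytest.fixture(scope="module")
def planted_cohort():
    cfg = CohortConfig(seed=67, long_fraction=1.0, protocol_effect_size=0.0)
    return generate_cohort(cfg)


def _split_units(cohort):
    cyc = cohort.sheet.cycle_table()
    refs = list(cyc.loc[cyc["outcome"] == "positive", "cycle_id"])
    cmps = list(cyc.loc[cyc["outcome"] == "negative", "cycle_id"])
    return refs, cmps


def _pz(records):
    return PairwiseZ(
        table=pd.DataFrame(
            records,
            columns=["reference_unit", "comparator_unit", "regulator_id", "n_overlap", "overlap_p", "z"],
        ),
        de_alpha=0.05,
        min_overlap=4,
    )


class TestPairwiseZMatrix:
    def test_self_comparison_yields_no_scores(self, tiny_sheet):
        rng = np.random.default_rng(71)
        m = make_matrix(
            rng.normal(size=(30, 6)),
            feature_ids=[f"g{i}" for i in range(30)],
            sample_ids=list(tiny_sheet.cluster_ids),
        )
        # comparator has the same values as the reference: empty DE selection
        m.values.loc[:, ["VS2c1", "VS2c2"]] = m.values[["VS1c1", "VS1c2"]].to_numpy()
        net = make_network([("R", f"g{i}", 1) for i in range(10)])
        pz = pairwise_z_matrix(m, tiny_sheet, net, ["VS1"], ["VS2"], de_alpha=1e-6)
        assert pz.table.empty

    def test_record_cardinality_bound(self, planted_cohort):
        refs, cmps = _split_units(planted_cohort)
        pz = pairwise_z_matrix(
            planted_cohort.expression, planted_cohort.sheet, planted_cohort.network,
            refs[:1], cmps[:4],
        )
        n_regs = len(planted_cohort.network.regulator_ids)
        assert len(pz.table) <= 1 * 4 * n_regs

    def test_single_cluster_unit_rejected(self, tiny_sheet):
        sheet_df = tiny_sheet.table.drop(index=[5]).reset_index(drop=True)  # VS3 loses a cluster
        from cumulostrat import SampleSheet

        sheet = SampleSheet(sheet_df)
        m = make_matrix(
            np.random.default_rng(73).normal(size=(10, 5)),
            sample_ids=list(sheet.cluster_ids),
        )
        net = make_network([("R", "f0", 1)])
        with pytest.raises(ValueError, match="VS3"):
            pairwise_z_matrix(m, sheet, net, ["VS1"], ["VS3"])

    def test_planted_sign_recovered_per_pair(self, planted_cohort):
        refs, cmps = _split_units(planted_cohort)
        pz = pairwise_z_matrix(
            planted_cohort.expression, planted_cohort.sheet, planted_cohort.network, refs, cmps
        )
        truth = planted_cohort.truth.cycle_truth.set_index("cycle_id")["group"]
        sel = pz.table[pz.table["regulator_id"] == "REG01"].dropna(subset=["z"])
        signs_ok = [
            (z > 0) == (truth[cmp_] == "high")
            for cmp_, z in zip(sel["comparator_unit"], sel["z"])
        ]
        assert np.mean(signs_ok) >= 0.9


class TestClassifyUnits:
    def test_positive_mean_z_is_high(self):
        pz = _pz([("r", "c1", "R", 10, 0.01, 1.3)])
        strat = classify_units(pz, "R", z_cut=0.0, reference_units=["r"], comparator_units=["c1"])
        assert strat.group_of()["c1"] == "high"
        assert strat.group_of()["r"] == "middle"

    def test_zero_mean_z_ties_to_middle(self):
        pz = _pz([("r", "c1", "R", 10, 0.01, 0.0)])
        strat = classify_units(pz, "R", z_cut=0.0, reference_units=["r"], comparator_units=["c1"])
        assert strat.group_of()["c1"] == "middle"

    def test_comparator_order_invariant(self):
        recs = [("r", f"c{i}", "R", 10, 0.01, z) for i, z in enumerate([2.0, -1.0, 0.5])]
        a = classify_units(_pz(recs), "R", reference_units=["r"], comparator_units=["c0", "c1", "c2"])
        b = classify_units(_pz(recs[::-1]), "R", reference_units=["r"], comparator_units=["c2", "c1", "c0"])
        assert a.group_of() == b.group_of()

    def test_missing_regulator_is_error(self):
        pz = _pz([("r", "c1", "R", 10, 0.01, 1.0)])
        with pytest.raises(ValueError):
            classify_units(pz, "OTHER", reference_units=["r"], comparator_units=["c1"])


class TestZscoreGroupTest:
    def test_identical_distributions_null(self):
        recs = [("r", f"a{i}", "R", 10, 0.01, 1.0) for i in range(3)]
        recs += [("r", f"b{i}", "R", 10, 0.01, 1.0) for i in range(3)]
        pz = _pz(recs)
        out = zscore_group_test(
            pz, [("r", f"a{i}") for i in range(3)], [("r", f"b{i}") for i in range(3)]
        )
        assert out.iloc[0]["t"] == 0 and out.iloc[0]["p"] == 1

    def test_label_swap_negates_t_keeps_p(self):
        rng = np.random.default_rng(79)
        recs = [("r", f"a{i}", "R", 10, 0.01, float(rng.normal())) for i in range(4)]
        recs += [("r", f"b{i}", "R", 10, 0.01, float(rng.normal(1.0))) for i in range(4)]
        pz = _pz(recs)
        pa = [("r", f"a{i}") for i in range(4)]
        pb = [("r", f"b{i}") for i in range(4)]
        fwd = zscore_group_test(pz, pa, pb)
        rev = zscore_group_test(pz, pb, pa)
        assert fwd.iloc[0]["t"] == pytest.approx(-rev.iloc[0]["t"])
        assert fwd.iloc[0]["p"] == pytest.approx(rev.iloc[0]["p"])

    def test_too_few_pairs_rejected(self):
        pz = _pz([("r", "c1", "R", 10, 0.01, 1.0)])
        with pytest.raises(ValueError, match=">=2"):
            zscore_group_test(pz, [("r", "c1")], [("r", "c1"), ("r", "c2")])

    def test_planted_regulator_survives_holm(self, planted_cohort):
        refs, cmps = _split_units(planted_cohort)
        pz = pairwise_z_matrix(
            planted_cohort.expression, planted_cohort.sheet, planted_cohort.network, refs, cmps
        )
        strat = classify_units(pz, "REG01", reference_units=refs, comparator_units=cmps)
        high = strat.units_in("high")
        low = [u for u in strat.units_in("low") if u in cmps]
        pairs_h = [(r, c) for r in refs for c in high if c in cmps]
        pairs_l = [(r, c) for r in refs for c in low]
        out = zscore_group_test(pz, pairs_h, pairs_l)
        row = out[out["regulator_id"] == "REG01"].iloc[0]
        assert row["p_holm"] < 0.05


class TestThreeGroupSeparation:
    def test_planted_features_recovered(self, planted_cohort):
        refs, cmps = _split_units(planted_cohort)
        pz = pairwise_z_matrix(
            planted_cohort.expression, planted_cohort.sheet, planted_cohort.network, refs, cmps
        )
        strat = classify_units(pz, "REG01", reference_units=refs, comparator_units=cmps)
        res, selected = three_group_separation(
            planted_cohort.expression, strat, planted_cohort.sheet, fdr=0.05
        )
        planted = set(planted_cohort.truth.group_effects["high"]) | set(
            planted_cohort.truth.group_effects["low"]
        )
        sensitivity = len(selected & planted) / len(planted)
        assert sensitivity >= 0.8

    def test_fdr_one_selects_everything(self, planted_cohort):
        refs, cmps = _split_units(planted_cohort)
        pz = pairwise_z_matrix(
            planted_cohort.expression, planted_cohort.sheet, planted_cohort.network, refs, cmps
        )
        strat = classify_units(pz, "REG01", reference_units=refs, comparator_units=cmps)
        _, selected = three_group_separation(
            planted_cohort.expression, strat, planted_cohort.sheet, fdr=1.0
        )
        assert selected == set(planted_cohort.expression.feature_ids)

    def test_empty_group_is_error(self, planted_cohort):
        refs, cmps = _split_units(planted_cohort)
        pz = pairwise_z_matrix(
            planted_cohort.expression, planted_cohort.sheet, planted_cohort.network, refs, cmps
        )
        # force every comparator into "high"/"middle" only by a huge z_cut
        strat = classify_units(pz, "REG01", z_cut=1e9, reference_units=refs, comparator_units=cmps)
        with pytest.raises(ValueError, match="empty"):
            three_group_separation(planted_cohort.expression, strat, planted_cohort.sheet)
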