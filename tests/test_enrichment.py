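"""Label-free AP-MS enrichment statistics and the paraspeckle overlap."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ireskit import (
    CANONICAL_COMPARISONS,
    ComparisonSpec,
    LfqMatrix,
    aggregate_peptides,
    annotate_paraspeckle,
    apply_confidence_filters,
    average_technical,
    impute_quantile,
    load_paraspeckle_table,
    log2_transform,
    normalize_median,
    run_enrichment_pipeline,
    test_enrichment as differential_test,
    volcano_data,
)


def _ann(runs, condition="normoxia", compartment="nucleus"):
    rows = []
    for i, r in enumerate(runs):
        rows.append(
            {"run": r, "condition": condition, "compartment": compartment, "bio_rep": f"b{i}", "tech_rep": 1}
        )
    return pd.DataFrame(rows).set_index("run")


class TestAggregatePeptides:
    def test_unique_peptides_summed(self):
        peps = pd.DataFrame({"peptide": ["p1", "p2"], "protein": ["A", "A"], "r1": [100.0, 200.0]})
        m = aggregate_peptides(peps, _ann(["r1"]))
        assert m.intensities.loc["A", "r1"] == 300.0

    def test_shared_peptides_dropped(self):
        peps = pd.DataFrame(
            {"peptide": ["p1", "p2"], "protein": ["A", "A;B"], "r1": [100.0, 200.0]}
        )
        m = aggregate_peptides(peps, _ann(["r1"]))
        assert m.intensities.loc["A", "r1"] == 100.0
        assert "B" not in m.intensities.index

    def test_matches_brute_force_group_and_sum(self):
        rng = np.random.default_rng(0)
        prots = rng.choice(list("ABCD"), 30)
        runs = ["r1", "r2"]
        peps = pd.DataFrame(
            {"peptide": [f"p{i}" for i in range(30)], "protein": prots}
            | {r: rng.uniform(1, 100, 30) for r in runs}
        )
        m = aggregate_peptides(peps, _ann(runs))
        for prot in "ABCD":
            for r in runs:
                expected = sum(v for p, v in zip(prots, peps[r]) if p == prot)
                assert m.intensities.loc[prot, r] == pytest.approx(expected)


class TestNormalizeMedian:
    def test_two_runs_scale_to_median_of_medians(self):
        # run medians 10 and 20 -> reference 15 -> factors 1.5 and 0.75
        m = LfqMatrix(
            pd.DataFrame({"r1": [5.0, 10.0, 15.0], "r2": [10.0, 20.0, 30.0]}, index=list("ABC")),
            _ann(["r1", "r2"]),
        )
        out = normalize_median(m)
        assert out.intensities["r1"].median() == pytest.approx(15.0)
        assert out.intensities["r2"].median() == pytest.approx(15.0)
        np.testing.assert_allclose(out.intensities["r1"], [7.5, 15.0, 22.5])
        np.testing.assert_allclose(out.intensities["r2"], [7.5, 15.0, 22.5])

    def test_equal_medians_identity(self):
        m = LfqMatrix(
            pd.DataFrame({"r1": [1.0, 2.0, 3.0], "r2": [1.5, 2.0, 2.5]}, index=list("ABC")),
            _ann(["r1", "r2"]),
        )
        out = normalize_median(m)
        np.testing.assert_allclose(out.intensities, m.intensities)

    def test_ranks_preserved_and_missing_untouched(self, tiny_matrix):
        out = normalize_median(tiny_matrix)
        assert out.intensities["r1"].rank().equals(tiny_matrix.intensities["r1"].rank())
        assert out.intensities.isna().equals(tiny_matrix.intensities.isna())


class TestImputeQuantile:
    def test_five_percent_quantile_linear_interpolation(self):
        # observed 1..100: 5% quantile with linear interpolation = 5.95
        vals = list(range(1, 101)) + [np.nan]
        m = LfqMatrix(pd.DataFrame({"r1": vals}, index=[f"P{i}" for i in range(101)]), _ann(["r1"]))
        out = impute_quantile(normalize_median(m))
        assert out.intensities["r1"].iloc[-1] == pytest.approx(5.95)

    def test_no_missing_values_unchanged_and_idempotent(self):
        m = normalize_median(
            LfqMatrix(pd.DataFrame({"r1": [1.0, 2.0, 3.0]}, index=list("ABC")), _ann(["r1"]))
        )
        once = impute_quantile(m)
        twice = impute_quantile(once)
        np.testing.assert_allclose(once.intensities, m.intensities)
        np.testing.assert_allclose(twice.intensities, once.intensities)

    def test_observed_mask_survives_imputation(self, tiny_matrix):
        out = impute_quantile(normalize_median(tiny_matrix))
        assert out.intensities.notna().all().all()
        assert out.observed.equals(tiny_matrix.intensities.notna())

    def test_rejects_bad_quantile(self, tiny_matrix):
        with pytest.raises(ValueError):
            impute_quantile(normalize_median(tiny_matrix), q=1.5)


class TestAverageTechnical:
    def test_log2_means_per_biological_replicate(self):
        log2_int = pd.DataFrame({"r1": [10.0], "r2": [12.0], "r3": [20.0]}, index=["A"])
        ann = pd.DataFrame(
            {
                "condition": ["normoxia"] * 3,
                "compartment": ["nucleus"] * 3,
                "bio_rep": ["b1", "b1", "b2"],
                "tech_rep": [1, 2, 1],
            },
            index=pd.Index(["r1", "r2", "r3"], name="run"),
        )
        m = LfqMatrix(log2_int, ann, stage="log2")
        out = average_technical(m)
        assert out.intensities.loc["A", "normoxia|nucleus|b1"] == pytest.approx(11.0)
        assert out.intensities.loc["A", "normoxia|nucleus|b2"] == pytest.approx(20.0)


def _averaged_matrix(g1_values, g2_values):
    """Build an already-averaged log2 matrix: one protein, two groups."""
    cols1 = [f"hypoxia|nucleus|b{i}" for i in range(len(g1_values))]
    cols2 = [f"normoxia|nucleus|b{i}" for i in range(len(g2_values))]
    intensities = pd.DataFrame([list(g1_values) + list(g2_values)], index=["A"], columns=cols1 + cols2)
    ann = pd.DataFrame(
        {
            "condition": ["hypoxia"] * len(g1_values) + ["normoxia"] * len(g2_values),
            "compartment": "nucleus",
            "bio_rep": [c.split("|")[-1] for c in cols1 + cols2],
        },
        index=pd.Index(cols1 + cols2, name="sample"),
    )
    psm = pd.DataFrame(10.0, index=["A"], columns=cols1 + cols2)
    return LfqMatrix(intensities, ann, psm=psm, observed=intensities.notna(), stage="averaged")


SPEC = CANONICAL_COMPARISONS[0]  # hypoxia vs normoxia, nucleus


class TestTestEnrichment:
    def test_pooled_t_matches_closed_form(self):
        # groups (1,2,3) vs (2,3,4): pooled s2 = 1, t = -1/sqrt(2/3), df = 4
        tab = differential_test(_averaged_matrix([1, 2, 3], [2, 3, 4]), SPEC)
        t_expected = -1.0 / np.sqrt(2.0 / 3.0)
        p_expected = 2 * stats.t.sf(abs(t_expected), df=4)
        assert tab.loc["A", "t"] == pytest.approx(t_expected)  # -1.2247
        assert tab.loc["A", "p"] == pytest.approx(p_expected)  # 0.2879
        assert tab.loc["A", "log2fc"] == pytest.approx(-1.0)

    def test_identical_groups_null(self):
        tab = differential_test(_averaged_matrix([5, 6, 7], [5, 6, 7]), SPEC)
        assert tab.loc["A", "log2fc"] == 0
        assert tab.loc["A", "p"] == pytest.approx(1.0)
        assert not tab.loc["A", "enriched"]

    def test_swapping_groups_flips_sign_not_p(self):
        m = _averaged_matrix([1, 2, 3], [4, 5, 7])
        fwd = differential_test(m, SPEC)
        rev = differential_test(m, ComparisonSpec("rev", SPEC.group2, SPEC.group1))
        # same data, groups exchanged via the comparison definition
        assert fwd.loc["A", "log2fc"] == pytest.approx(-rev.loc["A", "log2fc"])
        assert fwd.loc["A", "p"] == pytest.approx(rev.loc["A", "p"])

    def test_single_replicate_group_untestable(self):
        tab = differential_test(_averaged_matrix([1.0], [2.0, 3.0]), SPEC)
        assert tab["untestable"].all()
        assert np.isnan(tab.loc["A", "p"])


class TestConfidenceFilters:
    @pytest.mark.parametrize(
        "psm_total,n1,n2,enriched,expected",
        [
            (4.0, 3, 3, True, False),  # PSM > 4 is strict: 4 is excluded
            (10.0, 1, 1, True, False),  # quantified in only one replicate per group
            (10.0, 3, 3, True, True),
            (10.0, 3, 0, True, True),  # >= 2 replicates needed in one group only
            (10.0, 3, 3, False, False),  # filters never rescue a non-enriched protein
        ],
    )
    def test_filter_rules(self, psm_total, n1, n2, enriched, expected):
        tab = pd.DataFrame(
            {
                "log2fc": [1.5],
                "p": [0.01],
                "psm_total": [psm_total],
                "n_quant_group1": [n1],
                "n_quant_group2": [n2],
                "enriched": [enriched],
            },
            index=["A"],
        )
        out = apply_confidence_filters(tab)
        assert bool(out.loc["A", "significant_after_filters"]) is expected


class TestVolcano:
    def test_neglog10_values(self):
        tab = pd.DataFrame(
            {"log2fc": [2.0, 0.0], "p": [0.05, 1.0], "enriched": [True, False]}, index=["A", "B"]
        )
        vol = volcano_data(tab)
        assert vol.loc["A", "neg_log10_p"] == pytest.approx(1.30103, abs=1e-5)
        assert vol.loc["B", "neg_log10_p"] == 0.0

    def test_p_zero_capped_with_warning(self):
        tab = pd.DataFrame({"log2fc": [3.0], "p": [0.0], "enriched": [True]}, index=["A"])
        with pytest.warns(UserWarning):
            vol = volcano_data(tab)
        assert np.isfinite(vol.loc["A", "neg_log10_p"])

    def test_flags_consistent_with_filters(self, lfq_sim):
        _, sim = lfq_sim
        results = run_enrichment_pipeline(LfqMatrix(sim.proteins, sim.annotation, psm=sim.psm))
        tab = results["nucleus_hypoxia_vs_normoxia"]
        vol = volcano_data(tab)
        assert vol["significant_after_filters"].equals(tab["significant_after_filters"])


class TestPipelineOrder:
    def test_wrong_order_is_rejected(self, tiny_matrix):
        with pytest.raises(ValueError, match="pipeline order"):
            impute_quantile(tiny_matrix)  # skipping normalization
        with pytest.raises(ValueError, match="pipeline order"):
            log2_transform(normalize_median(tiny_matrix))  # skipping imputation

    def test_run_permutation_equivariance(self, lfq_sim):
        # normalize+impute commute with relabeling of runs
        _, sim = lfq_sim
        m = LfqMatrix(sim.proteins, sim.annotation, psm=sim.psm)
        out = impute_quantile(normalize_median(m)).intensities
        perm = list(sim.proteins.columns[::-1])
        m2 = LfqMatrix(sim.proteins[perm], sim.annotation, psm=sim.psm)
        out2 = impute_quantile(normalize_median(m2)).intensities
        np.testing.assert_allclose(out[perm].to_numpy(), out2.to_numpy())


class TestParaspeckleOverlap:
    def test_packaged_table_counts(self):
        table = load_paraspeckle_table()
        summary = annotate_paraspeckle(table)
        assert summary == {"n_total": 40, "n_present": 22, "n_present_itaf": 6, "mode": "fixture"}

    def test_empty_annotation(self):
        empty = load_paraspeckle_table().iloc[0:0]
        assert annotate_paraspeckle(empty)["n_total"] == 0

    def test_all_present(self):
        table = load_paraspeckle_table().copy()
        table["presence_in_ms"] = "Yes"
        assert annotate_paraspeckle(table)["n_present"] == len(table)

    def test_analysis_mode_honours_alternative_names(self):
        table = load_paraspeckle_table()
        summary = annotate_paraspeckle(table, identified={"NONO", "psf", "FUS"})
        assert summary["mode"] == "analysis"
        assert summary["n_present"] == 3  # p54nrb via NONO, SFPQ via PSF, FUS directly

    def test_duplicate_names_rejected(self):
        table = pd.concat([load_paraspeckle_table()] * 2)
        with pytest.raises(ValueError):
            annotate_paraspeckle(table)


class TestEstimatorBias:
    def test_spiked_log2fc_unbiased_without_censoring(self):
        """With all values observed, the estimated log2FC of spiked proteins
        is unbiased within Monte-Carlo error (|mean bias| < 0.1 over 50
        seeds at biological sd 0.3)."""
        from ireskit import Spike, SimLfqConfig, simulate_lfq

        biases = []
        for seed in range(50):
            spikes = tuple(
                Spike(f"P{i:05d}", "nucleus_hypoxia_vs_normoxia", 2.0) for i in range(5)
            )
            sim = simulate_lfq(
                SimLfqConfig(
                    n_proteins=200,
                    n_bio_replicates=4,
                    bio_sd=0.3,
                    missing_model=None,
                    seed=seed,
                    spiked=spikes,
                )
            )
            tab = run_enrichment_pipeline(LfqMatrix(sim.proteins, sim.annotation, psm=sim.psm))[
                "nucleus_hypoxia_vs_normoxia"
            ]
            biases.extend(tab.loc[[s.protein for s in spikes], "log2fc"] - 2.0)
        assert abs(np.mean(biases)) < 0.1
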