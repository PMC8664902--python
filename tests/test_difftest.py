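"""TMM, dispersion estimation, exact test and BH FDR."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import medipdmr as m
from medipdmr.difftest import adjust_fdr, estimate_dispersion, exact_test, tmm_factors
from medipdmr.windowing import CountMatrix, tile_genome


def _matrix(counts, samples=None, library_sizes=None):
    counts = np.asarray(counts, dtype=np.int64)
    ws = tile_genome({"chr1": 1000 * counts.shape[0]})
    samples = samples or [f"s{i}" for i in range(counts.shape[1])]
    return CountMatrix(ws, samples, counts, library_sizes=library_sizes)


class TestTMM:
    def test_identical_columns_give_unit_factors(self):
        rng = np.random.default_rng(0)
        col = rng.poisson(50, size=100)
        cm = _matrix(np.tile(col[:, None], (1, 4)))
        norm = tmm_factors(cm)
        np.testing.assert_allclose(norm.tmm_factors, 1.0, atol=1e-9)

    def test_doubled_column_normalizes_out(self):
        """Doubling a column doubles its library size; composition is
        unchanged, so factors stay 1 and normalized CPMs agree within 1%."""
        rng = np.random.default_rng(1)
        col = rng.poisson(100, size=200)
        counts = np.tile(col[:, None], (1, 3))
        counts[:, 2] *= 2
        cm = _matrix(counts)
        norm = tmm_factors(cm)
        np.testing.assert_allclose(norm.tmm_factors, 1.0, atol=1e-6)
        cpm = counts / norm.effective_lib_sizes[None, :]
        np.testing.assert_allclose(cpm[:, 2], cpm[:, 0], rtol=0.01)

    def test_sample_permutation_equivariance(self):
        rng = np.random.default_rng(2)
        counts = rng.poisson(rng.gamma(2, 25, size=(150, 1)), size=(150, 5))
        perm = [3, 0, 4, 1, 2]
        f = tmm_factors(_matrix(counts)).tmm_factors
        f_perm = tmm_factors(_matrix(counts[:, perm])).tmm_factors
        np.testing.assert_allclose(f_perm, f[perm], rtol=1e-9)

    def test_zero_library_rejected_by_name(self):
        counts = np.array([[1, 0], [2, 0]])
        with pytest.raises(ValueError, match="s1"):
            tmm_factors(_matrix(counts))


class TestDispersion:
    def test_poisson_data_estimates_near_zero(self, poisson_run):
        assert poisson_run.disp.common_phi <= 0.01

    def test_nb_dispersion_recovered(self, null_run):
        assert 0.07 <= null_run.disp.common_phi <= 0.13

    def test_window_order_invariance(self):
        rng = np.random.default_rng(3)
        mu = rng.gamma(3, 30, size=300)
        counts = rng.negative_binomial(10, 10 / (10 + mu[:, None]), size=(300, 8))
        groups = ["control"] * 4 + ["case"] * 4
        cm = _matrix(counts)
        norm = tmm_factors(cm)
        d1 = estimate_dispersion(cm, groups, norm, tagwise=False)
        perm = rng.permutation(300)
        cm2 = CountMatrix(cm.windows, cm.samples, counts[perm], library_sizes=cm.library_sizes)
        d2 = estimate_dispersion(cm2, groups, tmm_factors(cm2), tagwise=False)
        assert d1.common_phi == pytest.approx(d2.common_phi, rel=1e-6)

    def test_singleton_group_rejected(self):
        cm = _matrix(np.ones((10, 3), dtype=int))
        norm = tmm_factors(cm)
        with pytest.raises(ValueError, match="fewer than 2"):
            estimate_dispersion(cm, ["control", "control", "case"], norm)

    def test_tagwise_shrinks_toward_common(self, null_run):
        disp = null_run.disp
        assert disp.tagwise_phi is not None
        # under a common-dispersion generator, tagwise mass concentrates
        # around the common value
        within = np.abs(np.log2(disp.tagwise_phi / disp.common_phi)) <= 1.5
        assert within.mean() > 0.95


@pytest.fixture(scope="module")
def small_case():
    rng = np.random.default_rng(4)
    mu = rng.gamma(3, 40, size=120)
    counts = rng.negative_binomial(10, 10 / (10 + mu[:, None]), size=(120, 8))
    cm = _matrix(counts)
    groups = ["control"] * 4 + ["case"] * 4
    norm = tmm_factors(cm)
    disp = estimate_dispersion(cm, groups, norm)
    return cm, groups, norm, disp


class TestExactTest:
    def test_label_swap_negates_lfc_keeps_p(self, small_case):
        cm, groups, norm, disp = small_case
        res = exact_test(cm, groups, norm, disp)
        flipped = ["case" if g == "control" else "control" for g in groups]
        res_swap = exact_test(cm, flipped, norm, disp)
        np.testing.assert_allclose(res_swap["p_value"], res["p_value"], rtol=1e-12)
        np.testing.assert_allclose(res_swap["log_fc"], -res["log_fc"], atol=1e-12)

    def test_balanced_equal_sums_give_p_one_and_zero_lfc(self):
        counts = np.tile(np.array([[30, 30, 30, 30]]), (20, 1)).astype(np.int64)
        cm = _matrix(counts)
        groups = ["control", "control", "case", "case"]
        norm = tmm_factors(cm)
        disp = m.DispersionEstimate(common_phi=0.1)
        res = exact_test(cm, groups, norm, disp)
        np.testing.assert_allclose(res["log_fc"], 0.0, atol=1e-9)
        np.testing.assert_allclose(res["p_value"], 1.0)

    def test_library_scale_invariance(self, small_case):
        """Post-normalization, scaling all library sizes by a constant
        leaves p-values unchanged (same TMM factors, scaled depths)."""
        from medipdmr.difftest import NormalizationState

        cm, groups, norm, disp = small_case
        res = exact_test(cm, groups, norm, disp)
        scaled = CountMatrix(
            cm.windows, cm.samples, cm.counts, library_sizes=cm.library_sizes * 7.0
        )
        norm2 = NormalizationState(
            norm.samples, norm.tmm_factors, norm.effective_lib_sizes * 7.0
        )
        res2 = exact_test(scaled, groups, norm2, disp)
        np.testing.assert_allclose(res2["p_value"], res["p_value"], rtol=1e-12)

    def test_power_monotone_in_effect_size(self):
        """Window-level rejection rate is non-decreasing in |true_lfc|."""
        from medipdmr.synthetic import ChromSpec

        genome = m.generate_genome([ChromSpec("chr1", 200_000)], seed=20)
        windows = m.tile_genome(genome.chrom_sizes())
        cohort = m.simulate_cohort(13, 13, seed=21)
        groups = [s.group for s in cohort]
        rates = []
        for lfc in [None, 0.5, 1.0, 2.0]:
            regions = [] if lfc is None else [("chr1", 10_000, 60_000, lfc, 50)]
            truth = m.GroundTruth(regions=regions, dispersion=0.1)
            counts = m.simulate_window_counts(genome, windows, cohort, truth, seed=22)
            kept = m.filter_windows(counts)
            norm = tmm_factors(kept)
            disp = estimate_dispersion(kept, groups, norm, tagwise=False)
            res = exact_test(kept, groups, norm, disp)
            idx = (
                np.arange(10, 60)
                if lfc is not None
                else res["window_index"].to_numpy()[:50]
            )
            sub = res[res["window_index"].isin(idx)]
            rates.append((sub["p_value"] < 1e-3).mean())
        assert all(a <= b + 1e-12 for a, b in zip(rates, rates[1:]))
        assert rates[0] < 0.05 and rates[-1] > 0.9

    def test_fdr_control_on_mixed_simulation(self):
        """BH at q<0.1 keeps empirical FDR <= 0.15 with 5% true effects."""
        from medipdmr.synthetic import ChromSpec

        genome = m.generate_genome(
            [ChromSpec("chr1", 1_000_000), ChromSpec("chr2", 1_000_000)], seed=23
        )
        windows = m.tile_genome(genome.chrom_sizes())
        cohort = m.simulate_cohort(13, 13, seed=24)
        groups = [s.group for s in cohort]
        # 25 four-window regions = 100 of 2000 windows carry |lfc| = 2
        regions = []
        for i in range(25):
            chrom = "chr1" if i % 2 == 0 else "chr2"
            start = 20_000 + (i // 2) * 40_000
            regions.append((chrom, start, start + 4_000, 2.0 if i % 4 < 2 else -2.0, 4))
        truth = m.GroundTruth(regions=regions, dispersion=0.1)
        counts = m.simulate_window_counts(genome, windows, cohort, truth, seed=25)
        kept = m.filter_windows(counts)
        norm = tmm_factors(kept)
        disp = estimate_dispersion(kept, groups, norm, tagwise=False)
        res = exact_test(kept, groups, norm, disp)
        true_windows = set(truth.window_indices(windows).tolist())
        hits = res[res["q_value"] < 0.1]
        false = (~hits["window_index"].isin(true_windows)).sum()
        assert len(hits) > 0
        assert false / len(hits) <= 0.15
        # essentially all injected windows should be found at this effect size
        assert hits["window_index"].isin(true_windows).sum() >= 0.9 * len(true_windows)


class TestBH:
    def test_hand_example(self):
        np.testing.assert_allclose(
            adjust_fdr([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03], atol=1e-15
        )

    def test_degenerate_inputs(self):
        assert adjust_fdr([0.2]) == pytest.approx([0.2])
        np.testing.assert_allclose(adjust_fdr([1.0, 1.0, 1.0]), 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            adjust_fdr([0.5, 1.5])

    @given(
        st.lists(st.floats(min_value=0, max_value=1, allow_nan=False), min_size=1, max_size=200)
    )
    @settings(max_examples=100, deadline=None)
    def test_matches_statsmodels(self, pvals):
        """BH step-up agrees with the statsmodels implementation exactly."""
        from statsmodels.stats.multitest import multipletests

        expected = multipletests(pvals, method="fdr_bh")[1]
        np.testing.assert_allclose(adjust_fdr(pvals), expected, atol=1e-12)

    def test_q_at_least_p(self, null_run):
        res = null_run.results
        assert (res["q_value"] >= res["p_value"] - 1e-12).all()
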