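"""Distance estimator tests: independent scalar oracles, hand arithmetic,
null behaviour, aggregation and invariance properties."""

import numpy as np
import pytest

from refmatch.distance import (AlleleCountSummary, allele_count_summary,
                               compare_measures, fst_mwc, fst_reich, fst_wc,
                               gst, pairwise_matrix)
from refmatch.genodata import GenotypePanel, HaplotypePanel
from refmatch.synthetic import SimulationConfig, simulate_independent_snp_panels
from .conftest import make_markers, random_genotype_panel


def summary_from_counts(n, a, name="pop"):
    """AlleleCountSummary with hets assigned greedily (v = a mod 2 parity
    kept valid: use u = a // 2, v = a % 2)."""
    n, a = np.asarray(n, float), np.asarray(a, float)
    u = np.floor(a / 2)
    v = a - 2 * u
    return AlleleCountSummary(name, [f"rs{k + 1}" for k in range(len(n))],
                              n, a, u, v)


# ---------------------------------------------------------------------------
# Naive per-marker scalar oracles (independent re-implementations)
# ---------------------------------------------------------------------------

def oracle(measure, n1, a1, n2, a2, mwc_squared=False):
    """Scalar per-marker (numerator, denominator) by direct transcription."""
    m1, m2 = 2 * n1, 2 * n2
    p1, p2 = a1 / m1, a2 / m2
    if measure == "gst":
        p_avg = (p1 + p2) / 2
        return (p1 - p2) ** 2, 2 * p_avg * (1 - p_avg)
    if measure == "fst_r":
        h1 = a1 * (m1 - a1) / (m1 * (m1 - 1))
        h2 = a2 * (m2 - a2) / (m2 * (m2 - 1))
        N = (a1 / m1 - a2 / m2) ** 2 - h1 / m1 - h2 / m2
        return N, N + h1 + h2
    if measure == "fst_wc":
        p_bar = (p1 + p2) / 2
        n_bar = (n1 + n2) / 2
        s2 = (n1 * (p1 - p_bar) ** 2 + n2 * (p2 - p_bar) ** 2) / n_bar
        h_bar = (2 * n1 * p1 * (1 - p1) + 2 * n2 * p2 * (1 - p2)) / (2 * n_bar)
        N = s2 - (p_bar * (1 - p_bar) - s2 / 2 - h_bar / 4) / (2 * n_bar - 1)
        return N, p_bar * (1 - p_bar) + s2 / 2
    if measure == "fst_mwc":
        N = (p1 - p2) ** 2
        first = (p1 - p2) ** 2 if mwc_squared else (p1 - p2)
        D = first + 2 / (n1 + n2) * (n1 * p1 * (1 - p1) + n2 * p2 * (1 - p2))
        return N, D
    raise ValueError(measure)


def oracle_ratio(measure, s1, s2, **kw):
    nums, dens = [], []
    for k in range(len(s1.n)):
        N, D = oracle(measure, s1.n[k], s1.a[k], s2.n[k], s2.a[k], **kw)
        if D == 0:
            continue
        nums.append(N)
        dens.append(D)
    return sum(nums) / sum(dens)


ESTIMATORS = {"gst": gst, "fst_r": fst_reich, "fst_wc": fst_wc,
              "fst_mwc": fst_mwc}


class TestScalarOracles:
    @pytest.mark.parametrize("measure", list(ESTIMATORS))
    def test_ratio_of_sums_equals_naive_loop(self, measure):
        rng = np.random.default_rng(17)
        for _ in range(5):
            n = rng.integers(10, 80)
            K = 40
            s1 = summary_from_counts(np.full(K, n), rng.integers(0, 2 * n + 1, K), "a")
            s2 = summary_from_counts(np.full(K, n), rng.integers(0, 2 * n + 1, K), "b")
            est = ESTIMATORS[measure](s1, s2)
            assert est.value == pytest.approx(oracle_ratio(measure, s1, s2),
                                              abs=1e-12)

    def test_gst_hand_values(self):
        # single marker p1=0.2, p2=0.4 -> 0.04 / 0.42
        s1 = summary_from_counts([50], [20])
        s2 = summary_from_counts([50], [40])
        assert gst(s1, s2).value == pytest.approx(0.04 / 0.42)
        # fixed opposite alleles reach the printed-scale maximum 2.0
        s1 = summary_from_counts([50], [0])
        s2 = summary_from_counts([50], [100])
        assert gst(s1, s2).value == pytest.approx(2.0)

    def test_gst_zero_when_frequencies_equal(self):
        s = summary_from_counts([50, 50, 50], [10, 50, 77])
        assert gst(s, s).value == 0.0

    def test_reich_hand_single_marker(self):
        s1 = summary_from_counts([50], [20])  # a1=20, m1=100
        s2 = summary_from_counts([50], [40])
        N, D = oracle("fst_r", 50, 20, 50, 40)
        assert fst_reich(s1, s2).value == pytest.approx(N / D, abs=1e-12)

    def test_wc_hand_arithmetic(self):
        # p1=0.2, p2=0.4, n1=n2=50: s2=0.02, h_bar=0.4,
        # N = 0.02 - (0.21-0.01-0.1)/99, D = 0.22
        s1 = summary_from_counts([50], [20])
        s2 = summary_from_counts([50], [40])
        est = fst_wc(s1, s2)
        assert est.value == pytest.approx(0.0189899 / 0.22, abs=1e-6)
        assert est.value == pytest.approx(0.08632, abs=1e-5)

    def test_mwc_both_conventions(self):
        s1 = summary_from_counts([50], [20])
        s2 = summary_from_counts([50], [40])
        for conv, sq in (("as_printed", False), ("squared", True)):
            est = fst_mwc(s1, s2, convention=conv)
            N, D = oracle("fst_mwc", 50, 20, 50, 40, mwc_squared=sq)
            assert est.value == pytest.approx(N / D, abs=1e-12)
            assert est.meta["convention"] == conv

    def test_mwc_conventions_rank_identically(self):
        rng = np.random.default_rng(23)
        vals_p, vals_s = [], []
        for _ in range(10):
            K, n = 200, 50
            base = rng.integers(10, 90, K)
            shift = rng.integers(0, 15, K) * rng.integers(1, 4)
            s1 = summary_from_counts(np.full(K, n), base, "a")
            s2 = summary_from_counts(np.full(K, n), np.clip(base + shift, 0, 2 * n), "b")
            vals_p.append(fst_mwc(s1, s2, "as_printed").value)
            vals_s.append(fst_mwc(s1, s2, "squared").value)
        from scipy.stats import spearmanr
        assert spearmanr(vals_p, vals_s).statistic == pytest.approx(1.0)


class TestNullBehaviour:
    @pytest.mark.parametrize("estimator", [fst_reich, fst_wc])
    def test_corrected_estimators_center_on_zero(self, estimator):
        vals = []
        for seed in range(20):
            cfg = SimulationConfig(n_snps=2000, n_pops=2, n_per_pop=500,
                                   divergence=0.0, seed=seed)
            panels, _ = simulate_independent_snp_panels(cfg)
            s1, s2 = (allele_count_summary(p) for p in panels)
            vals.append(estimator(s1, s2).value)
        assert abs(np.mean(vals)) < 0.002


class TestJackknife:
    def test_single_block_gives_zero_se(self):
        rng = np.random.default_rng(1)
        s1 = summary_from_counts(np.full(30, 50), rng.integers(0, 101, 30), "a")
        s2 = summary_from_counts(np.full(30, 50), rng.integers(0, 101, 30), "b")
        assert fst_reich(s1, s2, n_blocks=1).se == 0.0

    def test_se_positive_and_stable_scale(self):
        rng = np.random.default_rng(2)
        s1 = summary_from_counts(np.full(400, 50), rng.integers(0, 101, 400), "a")
        s2 = summary_from_counts(np.full(400, 50), rng.integers(0, 101, 400), "b")
        est = fst_reich(s1, s2)
        assert est.meta["n_blocks"] == 20
        assert 0 < est.se < abs(est.value)


class TestAggregationProperties:
    def test_zero_component_marker_is_inert(self):
        rng = np.random.default_rng(3)
        s1 = summary_from_counts(np.full(20, 40), rng.integers(0, 81, 20), "a")
        s2 = summary_from_counts(np.full(20, 40), rng.integers(0, 81, 20), "b")
        # append a marker fixed for the same allele in both: N = D = 0 for all
        s1x = summary_from_counts(np.append(s1.n, 40), np.append(s1.a, 80), "a")
        s2x = summary_from_counts(np.append(s2.n, 40), np.append(s2.a, 80), "b")
        for est in (gst, fst_wc):
            assert est(s1x, s2x).value == pytest.approx(est(s1, s2).value,
                                                        abs=1e-15)

    @pytest.mark.parametrize("measure", ["gst", "fst_r", "fst_wc"])
    def test_counted_allele_swap_invariance(self, measure):
        rng = np.random.default_rng(4)
        n = np.full(50, 60)
        a1, a2 = rng.integers(0, 121, 50), rng.integers(0, 121, 50)
        s1, s2 = summary_from_counts(n, a1, "a"), summary_from_counts(n, a2, "b")
        f1, f2 = summary_from_counts(n, 120 - a1, "a"), summary_from_counts(n, 120 - a2, "b")
        est = ESTIMATORS[measure]
        assert est(f1, f2).value == pytest.approx(est(s1, s2).value, abs=1e-12)

    def test_mwc_squared_convention_is_swap_invariant(self):
        rng = np.random.default_rng(5)
        n = np.full(50, 60)
        a1, a2 = rng.integers(0, 121, 50), rng.integers(0, 121, 50)
        s1, s2 = summary_from_counts(n, a1, "a"), summary_from_counts(n, a2, "b")
        f1, f2 = summary_from_counts(n, 120 - a1, "a"), summary_from_counts(n, 120 - a2, "b")
        assert fst_mwc(f1, f2, "squared").value == pytest.approx(
            fst_mwc(s1, s2, "squared").value, abs=1e-12)

    def test_empty_marker_set_rejected(self):
        s = summary_from_counts([], [])
        with pytest.raises(ValueError):
            gst(s, s)


class TestLowMafRobustness:
    def test_gst_less_perturbed_by_rare_markers_than_reich(self):
        """Appending 20 % rare markers (ancestral MAF 0.02) shifts G_ST less
        than it shifts F_ST^R on the same panels (paired over seeds)."""
        from refmatch.genodata import GenotypePanel
        from .conftest import make_markers

        def panel(name, freqs, n, rng):
            markers = make_markers(len(freqs))
            calls = rng.binomial(2, freqs, size=(n, len(freqs))).astype(np.int8)
            return GenotypePanel(name, markers,
                                 [f"{name}{i}" for i in range(n)], calls)

        wins = 0
        for seed in range(8):
            rng = np.random.default_rng(seed)
            K, Kr, n, F = 500, 100, 40, 0.05
            scale = (1 - F) / F

            def drift(p):
                return rng.beta(p * scale, (1 - p) * scale)

            p_anc = rng.uniform(0.1, 0.9, K)
            p1, p2 = drift(p_anc), drift(p_anc)
            rare = np.full(Kr, 0.02)
            r1, r2 = drift(rare), drift(rare)
            a = panel("a", np.concatenate([p1, r1]), n, rng)
            b = panel("b", np.concatenate([p2, r2]), n, rng)
            sa, sb = allele_count_summary(a), allele_count_summary(b)
            common = np.arange(K)
            g_c = gst(sa.subset(common), sb.subset(common)).value
            r_c = fst_reich(sa.subset(common), sb.subset(common)).value
            g_shift = abs(gst(sa, sb).value - g_c) / g_c
            r_shift = abs(fst_reich(sa, sb).value - r_c) / r_c
            wins += g_shift <= r_shift
        assert wins >= 7


class TestParameterRecovery:
    def test_estimators_track_balding_nichols(self):
        # 3 drift levels x 10 seeds; G_ST expectation 2F/(2-F)
        for F in (0.01, 0.05, 0.1):
            gsts, wcs = [], []
            for seed in range(10):
                cfg = SimulationConfig(n_snps=5000, n_pops=2, n_per_pop=500,
                                       divergence=F, seed=seed)
                panels, _ = simulate_independent_snp_panels(cfg)
                s1, s2 = (allele_count_summary(p) for p in panels)
                gsts.append(gst(s1, s2).value)
                wcs.append(fst_wc(s1, s2).value)
            expect = 2 * F / (2 - F)
            assert abs(np.mean(gsts) - expect) < 0.15 * expect
            # the corrected WC estimator tracks the classical scale F
            assert abs(np.mean(wcs) - F) < 0.15 * F + 0.002


class TestPairwiseMatrix:
    def test_pair_count_and_symmetry(self):
        rng = np.random.default_rng(6)
        panels = [random_genotype_panel(rng, name=f"p{i}") for i in range(3)]
        table = pairwise_matrix(panels)
        # 3 unordered pairs x 4 measures x 2 orientations
        assert len(table) == 3 * 4 * 2
        piv = table.pivot_table(index=["pop1", "pop2"], columns="measure",
                                values="value")
        for (i, j) in (("p0", "p1"), ("p0", "p2"), ("p1", "p2")):
            np.testing.assert_array_equal(piv.loc[(i, j)].to_numpy(),
                                          piv.loc[(j, i)].to_numpy())

    def test_self_pair_gst_is_zero(self, toy_genotypes):
        s = allele_count_summary(toy_genotypes)
        assert gst(s, s).value == 0.0

    def test_haplotype_panels_accepted(self, toy_haplotypes):
        rng = np.random.default_rng(7)
        g = random_genotype_panel(rng, n_markers=3, name="g")
        table = pairwise_matrix([g, toy_haplotypes], measures=("gst",))
        assert len(table) == 2


class TestCompareMeasures:
    def _matrix(self, values_by_measure, pairs):
        import pandas as pd
        rows = []
        for meas, vals in values_by_measure.items():
            for (a, b), v in zip(pairs, vals):
                rows.append({"pop1": a, "pop2": b, "measure": meas, "value": v})
                rows.append({"pop1": b, "pop2": a, "measure": meas, "value": v})
        return pd.DataFrame(rows)

    PAIRS = [("a", "b"), ("a", "c"), ("a", "d"), ("b", "c")]

    def test_identical_and_reversed_rankings(self):
        m = self._matrix({"gst": [1, 2, 3, 4], "fst_r": [10, 20, 30, 40],
                          "fst_wc": [4, 3, 2, 1]}, self.PAIRS)
        out = compare_measures(m).set_index(["measure_1", "measure_2"])
        assert out.loc[("fst_r", "gst"), "tau"] == pytest.approx(1.0)
        assert out.loc[("fst_wc", "gst"), "tau"] == pytest.approx(-1.0)

    def test_single_swap_matches_enumeration(self):
        x, y = [1, 2, 3, 4], [1, 2, 4, 3]
        conc = disc = 0
        for i in range(4):
            for j in range(i + 1, 4):
                s = (x[i] - x[j]) * (y[i] - y[j])
                conc += s > 0
                disc += s < 0
        expected = (conc - disc) / 6
        m = self._matrix({"gst": x, "fst_r": y}, self.PAIRS)
        out = compare_measures(m)
        assert out.tau.iloc[0] == pytest.approx(expected)
        assert out.max_rank_dev.iloc[0] == 1.0

    def test_constant_measure_reported_missing(self):
        m = self._matrix({"gst": [1, 2, 3, 4], "fst_r": [5, 5, 5, 5]}, self.PAIRS)
        out = compare_measures(m)
        assert np.isnan(out.tau.iloc[0])
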