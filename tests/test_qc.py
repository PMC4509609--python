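"""QC tests: allele alignment, filter statistics, the stratified exact HWE
test against brute-force enumeration, GQ selection and sample equalization."""

import itertools

import numpy as np
import pytest

from refmatch.genodata import MISSING, GenotypePanel, HaplotypePanel, Marker
from refmatch.qc import (QCThresholds, align_alleles, equalize_sample_sizes,
                         exact_hwe_pvalue, levene_haldane_pmf, mean_call_rate,
                         mean_maf, select_gq_snps, stratified_exact_hwe)
from .conftest import make_markers


def _panel(markers, calls, name="pop"):
    calls = np.asarray(calls, dtype=np.int8)
    return GenotypePanel(name, markers, [f"{name}{i}" for i in range(calls.shape[0])],
                         calls)


class TestAlignAlleles:
    def _target(self, markers):
        return _panel(markers, np.zeros((2, len(markers)), dtype=np.int8), "t")

    def test_dispositions(self):
        t_markers = [Marker("rs1", "1", 100, "A", "G"),   # complement match
                     Marker("rs2", "1", 200, "A", "T"),   # ambiguous
                     Marker("rs3", "1", 300, "C", "T"),   # unmatched id
                     Marker("rs4", "1", 400, "A", "C")]   # irreconcilable
        r_markers = [Marker("rs1", "1", 100, "T", "C"),
                     Marker("rs2", "1", 200, "A", "T"),
                     Marker("rs4", "1", 400, "A", "G")]
        target = self._target(t_markers)
        ref = HaplotypePanel("r", r_markers,
                             np.ones((2, 3), dtype=np.uint8))
        at, ar, report = align_alleles(target, ref)
        assert at.marker_ids() == ar.marker_ids() == ["rs1"]
        assert ar.markers[0].alleleA == "A"  # relabelled to target strand
        dispo = dict(zip(report.marker, report.disposition))
        assert dispo == {"rs1": "kept", "rs2": "ambiguous",
                         "rs3": "unmatched", "rs4": "unmatched"}

    def test_swapped_alleles_flip_haplotype_codes(self):
        t = self._target([Marker("rs1", "1", 100, "A", "G")])
        ref = HaplotypePanel("r", [Marker("rs1", "1", 100, "G", "A")],
                             np.array([[1], [0]], dtype=np.uint8))
        _, ar, _ = align_alleles(t, ref)
        # ref's 1 counted G; after alignment 1 must count the target's A
        np.testing.assert_array_equal(ar.haplotypes, [[0], [1]])

    def test_every_marker_has_exactly_one_disposition(self):
        rng = np.random.default_rng(0)
        markers = make_markers(20)
        t = self._target(markers)
        keep = rng.random(20) < 0.6
        ref = HaplotypePanel("r", [m for m, k in zip(markers, keep) if k],
                             np.zeros((2, int(keep.sum())), dtype=np.uint8))
        _, _, report = align_alleles(t, ref)
        assert sorted(report.marker) == sorted(t.marker_ids())
        assert report.disposition.isin(["kept", "unmatched", "ambiguous"]).all()


class TestFilterStatistics:
    def test_call_rate_mean_over_populations(self):
        markers = make_markers(1)
        full = _panel(markers, [[0], [1]], "a")                    # CR 1.0
        half = _panel(markers, [[MISSING], [1], [2], [MISSING]], "b")  # CR 0.5
        np.testing.assert_allclose(mean_call_rate([full, half]), [0.75])
        empty = _panel(markers, [[MISSING], [MISSING]], "c")       # CR 0
        np.testing.assert_allclose(mean_call_rate([full, empty]), [0.5])
        with pytest.raises(ValueError):
            mean_call_rate([])

    def test_maf_mean_over_populations(self):
        markers = make_markers(1)
        # p = 0.2 and p = 0.6 -> MAFs 0.2 and 0.4 -> mean 0.3
        a = _panel(markers, [[1], [1], [0], [0], [0]], "a")
        b = _panel(markers, [[2], [1], [1], [2], [0]], "b")
        np.testing.assert_allclose(mean_maf([a, b]), [0.3])

    def test_maf_skips_population_with_no_calls(self):
        markers = make_markers(1)
        a = _panel(markers, [[1], [1]], "a")              # p = 0.5 -> MAF 0.5
        b = _panel(markers, [[MISSING], [MISSING]], "b")
        np.testing.assert_allclose(mean_maf([a, b]), [0.5])

    def test_monomorphic_maf_is_zero(self):
        markers = make_markers(1)
        a = _panel(markers, [[2], [2], [2]], "a")
        np.testing.assert_allclose(mean_maf([a]), [0.0])


def brute_force_hwe_pmf(n, a):
    """Independent oracle: place `a` counted alleles into 2n slots, pair
    consecutive slots into individuals, tally heterozygote counts."""
    from collections import Counter

    counts = Counter()
    total = 0
    for positions in itertools.combinations(range(2 * n), a):
        alleles = np.zeros(2 * n, dtype=int)
        alleles[list(positions)] = 1
        hets = sum(alleles[2 * i] != alleles[2 * i + 1] for i in range(n))
        counts[hets] += 1
        total += 1
    return {v: c / total for v, c in counts.items()}


class TestExactHWE:
    @pytest.mark.parametrize("n,a", [(2, 2), (3, 3), (4, 2), (5, 5), (5, 8)])
    def test_levene_haldane_matches_enumeration(self, n, a):
        support, probs = levene_haldane_pmf(n, a)
        oracle = brute_force_hwe_pmf(n, a)
        assert set(support.tolist()) == set(oracle)
        for v, p in zip(support, probs):
            assert p == pytest.approx(oracle[int(v)], abs=1e-12)

    def test_two_het_two_individuals_example(self):
        # genotype counts (hom, het, hom) = (0, 2, 0): n=2, a=2, v_obs=2
        oracle = brute_force_hwe_pmf(2, 2)
        p_obs = oracle[2]
        expected = sum(p for p in oracle.values() if p <= p_obs + 1e-15)
        assert exact_hwe_pvalue(2, 2, 2) == pytest.approx(expected, abs=1e-12)

    def test_single_stratum_reduces_to_plain_exact_test(self):
        rng = np.random.default_rng(4)
        markers = make_markers(1)
        for _ in range(200):
            n = int(rng.integers(2, 30))
            calls = rng.integers(0, 3, size=(n, 1)).astype(np.int8)
            panel = _panel(markers, calls)
            a = int(2 * (calls == 2).sum() + (calls == 1).sum())
            v = int((calls == 1).sum())
            strat = stratified_exact_hwe([panel])[0]
            assert strat == pytest.approx(exact_hwe_pvalue(n, a, v), abs=1e-12)

    def test_hwe_proportions_give_large_p(self):
        rng = np.random.default_rng(11)
        markers = make_markers(1)
        panels = []
        for i in range(3):
            haps = rng.random((400, 1)) < 0.4
            calls = (haps[0::2].astype(int) + haps[1::2]).astype(np.int8)
            panels.append(_panel(markers, calls, f"p{i}"))
        assert stratified_exact_hwe(panels)[0] > 0.5

    def test_monomorphic_everywhere_gives_p_one(self):
        markers = make_markers(1)
        panels = [_panel(markers, [[2], [2], [2]], "a"),
                  _panel(markers, [[2], [2]], "b")]
        assert stratified_exact_hwe(panels)[0] == 1.0

    def test_fisher_alternative_agrees_qualitatively(self):
        rng = np.random.default_rng(5)
        markers = make_markers(1)
        # grossly het-deficient in both strata
        calls = np.array([[0], [0], [2], [2], [0], [2], [2], [0]], dtype=np.int8)
        panels = [_panel(markers, calls, "a"), _panel(markers, calls, "b")]
        p_conv = stratified_exact_hwe(panels)[0]
        p_fish = stratified_exact_hwe(panels, method="fisher")[0]
        assert p_conv < 0.2 and p_fish < 0.2


class TestSelectGq:
    def _three_marker_toy(self):
        markers = make_markers(3)
        rng = np.random.default_rng(2)
        # marker 0: low CR; marker 1: low MAF; marker 2: HWE violation
        n = 60
        calls = np.zeros((n, 3), dtype=np.int8)
        calls[:, 0] = rng.binomial(2, 0.5, n)
        calls[rng.random(n) < 0.2, 0] = MISSING
        calls[:, 1] = rng.binomial(2, 0.02, n)
        calls[:, 2] = np.where(rng.random(n) < 0.5, 0, 2)  # no hets, p ~ 0.5
        return [_panel(markers, calls)]

    def test_each_rule_fires_once(self):
        kept, report = select_gq_snps(self._three_marker_toy())
        assert kept == []
        assert report.reason.tolist() == ["cr", "maf", "hwe"]
        assert (~report["pass"]).all()

    def test_zero_thresholds_keep_everything(self):
        kept, report = select_gq_snps(self._three_marker_toy(),
                                      QCThresholds(0.0, 0.0, 0.0))
        assert len(kept) == 3
        assert report["pass"].all()

    def test_default_profile_is_the_stringent_one(self):
        t = QCThresholds()
        assert (t.cr_min, t.maf_min, t.hwe_p_min) == (0.95, 0.1, 0.01)

    def test_monotone_in_thresholds(self):
        rng = np.random.default_rng(9)
        markers = make_markers(30)
        panels = [_panel(markers, rng.integers(0, 3, size=(50, 30)), f"p{i}")
                  for i in range(2)]
        kept_loose, _ = select_gq_snps(panels, QCThresholds(0.5, 0.05, 0.001))
        kept_tight, _ = select_gq_snps(panels, QCThresholds(0.9, 0.2, 0.05))
        assert set(kept_tight) <= set(kept_loose)


class TestEqualizeSampleSizes:
    def test_subsample_is_deterministic_under_seed(self):
        rng = np.random.default_rng(3)
        markers = make_markers(5)
        big = _panel(markers, rng.integers(0, 3, size=(252, 5)), "big")
        a = equalize_sample_sizes([big], 40, rng=123)[0]
        b = equalize_sample_sizes([big], 40, rng=123)[0]
        assert a.n_samples == 40
        assert a.samples == b.samples

    def test_exact_size_unchanged_and_small_dropped(self):
        rng = np.random.default_rng(3)
        markers = make_markers(2)
        exact = _panel(markers, rng.integers(0, 3, size=(40, 2)), "exact")
        small = _panel(markers, rng.integers(0, 3, size=(39, 2)), "small")
        with pytest.warns(UserWarning, match="small"):
            out = equalize_sample_sizes([exact, small], 40)
        assert [p.population for p in out] == ["exact"]
        assert out[0] is exact
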