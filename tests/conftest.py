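"""Shared fixtures: tiny hand-built panels and the session-scoped benchmark runs."""

import numpy as np
import pytest

from refmatch import analysis
from refmatch.genodata import GenotypePanel, HaplotypePanel, Marker
from refmatch.synthetic import SimulationConfig, simulate_mosaic_panels


def make_markers(n, alleles=("A", "G"), chrom="1"):
    return [Marker(f"rs{k + 1}", chrom, (k + 1) * 100, *alleles) for k in range(n)]


@pytest.fixture
def markers3():
    return make_markers(3)


@pytest.fixture
def toy_genotypes(markers3):
    calls = np.array([[2, 1, 0], [1, 1, 2]], dtype=np.int8)
    return GenotypePanel("toy", markers3, ["s1", "s2"], calls)


@pytest.fixture
def toy_haplotypes(markers3):
    haps = np.array([[1, 1, 0], [0, 1, 1], [1, 0, 0], [0, 0, 1]], dtype=np.uint8)
    return HaplotypePanel("toyref", markers3, haps)


def random_genotype_panel(rng, n_samples=30, n_markers=25, name="pop",
                          missing_rate=0.0):
    markers = make_markers(n_markers)
    calls = rng.integers(0, 3, size=(n_samples, n_markers)).astype(np.int8)
    if missing_rate:
        calls[rng.random(calls.shape) < missing_rate] = -1
    return GenotypePanel(name, markers, [f"{name}_s{i}" for i in range(n_samples)],
                         calls)


# --------------------------------------------------------------------------
# Session-scoped benchmark runs (shared across the heavier analysis tests)
# --------------------------------------------------------------------------

from refmatch import study  # noqa: E402


def study_panels(seed, n_targets=study.N_TARGETS, n_snps=2000,
                 ref_divergence=study.REF_DIVERGENCE):
    """The synthetic study conditions: homogeneous targets, references at
    graded divergence, the most distant in complex-haplotype mode."""
    return study.simulate_study(seed, n_targets=n_targets, n_snps=n_snps,
                                ref_divergence=ref_divergence)


@pytest.fixture(scope="session")
def full_factorial():
    """The 12 x 4 single-missingness benchmark (the distance-accuracy law)."""
    return study.distance_accuracy_benchmark(seed=1)


@pytest.fixture(scope="session")
def missingness_factorials():
    """Three seeds of a reduced grid with nested 50 % / 100 % masking."""
    out = []
    for seed in (11, 12, 13):
        refs, targets = study_panels(seed=seed, n_targets=4, n_snps=600)
        design = analysis.FactorialDesign(
            targets=targets, references=refs, fractions=(0.5, 1.0), seed=seed)
        out.append(analysis.run_factorial(design))
    return out
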