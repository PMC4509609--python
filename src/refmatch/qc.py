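"""Allele alignment, good-quality (GQ) SNP selection and sample-size
equalization.

The GQ filter keeps markers whose mean call rate across populations is at
least ``cr_min`` (default 0.95), whose mean minor-allele frequency is at
least ``maf_min`` (default 0.1) and whose stratified exact
Hardy-Weinberg-equilibrium p-value is at least ``hwe_p_min`` (default 0.01).
GQ SNPs are treated as true genotypes by the masking benchmark.

The stratified HWE test conditions on the allele counts within each
population; its statistic is the total heterozygote count across
populations, its null distribution the convolution of the per-population
Levene-Haldane conditional distributions, and the two-sided p-value sums
the probabilities of all outcomes no more probable than the observed one.
With a single population this is exactly the standard exact HWE test. A
Fisher combination of per-population exact p-values is available as an
alternative (``method="fisher"``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from .genodata import MISSING, GenotypePanel, HaplotypePanel, Marker

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass
class QCThresholds:
    """GQ-SNP filter thresholds (all in [0, 1])."""

    cr_min: float = 0.95
    maf_min: float = 0.1
    hwe_p_min: float = 0.01

    def __post_init__(self) -> None:
        for name in ("cr_min", "maf_min", "hwe_p_min"):
            if not (0.0 <= getattr(self, name) <= 1.0):
                raise ValueError(f"{name} must lie in [0,1]")


# ---------------------------------------------------------------------------
# Allele alignment
# ---------------------------------------------------------------------------

def align_alleles(target: GenotypePanel, ref: HaplotypePanel
                  ) -> tuple[GenotypePanel, HaplotypePanel, pd.DataFrame]:
    """Match target and reference markers by id and reconcile allele labels.

    Per target marker the disposition is one of: ``kept`` (alleles equal,
    possibly after strand complement of the reference labels), ``ambiguous``
    (A/T or C/G pair, strand unverifiable, removed) or ``unmatched`` (id
    absent from the reference, or alleles irreconcilable). When the
    reference lists the same pair in swapped order its haplotype codes are
    flipped so that 1 keeps meaning the target's counted allele. The two
    returned panels carry identical marker lists.
    """
    ref_index = {m.id: k for k, m in enumerate(ref.markers)}
    keep_t: list[int] = []
    keep_r: list[int] = []
    flip: list[bool] = []
    new_ref_markers: list[Marker] = []
    rows = []
    for k, mk in enumerate(target.markers):
        if mk.ambiguous:
            rows.append({"marker": mk.id, "disposition": "ambiguous"})
            continue
        rk = ref_index.get(mk.id)
        if rk is None:
            rows.append({"marker": mk.id, "disposition": "unmatched"})
            continue
        rm = ref.markers[rk]
        pair_t = (mk.alleleA, mk.alleleB)
        resolved = None
        for cand, swapped in ((rm, False), (rm.swapped(), True),
                              (rm.complemented(), False),
                              (rm.complemented().swapped(), True)):
            if (cand.alleleA, cand.alleleB) == pair_t:
                resolved = (cand, swapped)
                break
        if resolved is None:
            rows.append({"marker": mk.id, "disposition": "unmatched"})
            continue
        cand, swapped = resolved
        keep_t.append(k)
        keep_r.append(rk)
        flip.append(swapped)
        new_ref_markers.append(cand)
        rows.append({"marker": mk.id, "disposition": "kept"})
    aligned_t = target.subset_markers(np.asarray(keep_t, dtype=int))
    haps = ref.haplotypes[:, keep_r].copy() if keep_r else \
        np.zeros((ref.n_haplotypes, 0), dtype=np.uint8)
    for j, fl in enumerate(flip):
        if fl:
            haps[:, j] = 1 - haps[:, j]
    aligned_r = HaplotypePanel(ref.panel_name, new_ref_markers, haps)
    return aligned_t, aligned_r, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Per-marker filter statistics
# ---------------------------------------------------------------------------

def _shared_map(panels: list[GenotypePanel]) -> list[str]:
    if not panels:
        raise ValueError("empty population list")
    ids = panels[0].marker_ids()
    for p in panels[1:]:
        if p.marker_ids() != ids:
            raise ValueError("panels do not share a marker map")
    return ids


def mean_call_rate(panels: list[GenotypePanel]) -> np.ndarray:
    """Unweighted mean over populations of the per-marker call rate."""
    _shared_map(panels)
    return np.mean([p.call_rate() for p in panels], axis=0)


def mean_maf(panels: list[GenotypePanel]) -> np.ndarray:
    """Unweighted mean over populations of min(p-hat, 1-p-hat); populations
    with zero calls at a marker are skipped for that marker."""
    _shared_map(panels)
    mafs = []
    for p in panels:
        freq = p.allele_freq()
        mafs.append(np.minimum(freq, 1.0 - freq))
    stacked = np.array(mafs)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        out = np.nanmean(stacked, axis=0)
    return np.where(np.isnan(out), 0.0, out)


def levene_haldane_pmf(n: int, a: int) -> tuple[np.ndarray, np.ndarray]:
    """Exact conditional distribution of the heterozygote count given
    ``a`` counted alleles among ``n`` diploid individuals.

    Returns (support, probabilities). Support is every feasible het count
    v with v = a (mod 2), (a - v)/2 >= 0 hom-counted and n - (a+v)/2 >= 0
    other-homozygote individuals.
    """
    m = 2 * n
    if not (0 <= a <= m):
        raise ValueError("allele count out of range")
    v = np.arange(a % 2, min(a, m - a) + 1, 2)
    u = (a - v) // 2
    w = n - u - v
    ok = w >= 0
    v, u, w = v[ok], u[ok], w[ok]
    logp = (v * np.log(2.0) + gammaln(n + 1)
            - gammaln(u + 1) - gammaln(v + 1) - gammaln(w + 1)
            + gammaln(a + 1) + gammaln(m - a + 1) - gammaln(m + 1))
    p = np.exp(logp - logp.max())
    return v, p / p.sum()


def exact_hwe_pvalue(n: int, a: int, v_obs: int) -> float:
    """Single-population exact HWE p (probability-ordering two-sided rule)."""
    support, probs = levene_haldane_pmf(n, a)
    p_obs = probs[support == v_obs]
    if p_obs.size == 0:
        raise ValueError(f"het count {v_obs} infeasible for n={n}, a={a}")
    return float(probs[probs <= p_obs[0] * (1 + 1e-12)].sum())


def stratified_exact_hwe(panels: list[GenotypePanel],
                         method: str = "convolution") -> np.ndarray:
    """Per-marker stratified exact HWE p-values across populations.

    ``method="convolution"`` (default): null distribution of the total het
    count is the convolution of per-population Levene-Haldane conditionals;
    two-sided p by probability ordering. ``method="fisher"`` combines
    per-population exact p-values with Fisher's method instead. Markers
    with no informative population (fewer than 2 genotyped individuals
    everywhere, or monomorphic in every population) get p = 1.
    """
    if method not in ("convolution", "fisher"):
        raise ValueError(f"unknown HWE method {method!r}")
    _shared_map(panels)
    n_markers = panels[0].n_markers
    obs = [(p.calls != MISSING) for p in panels]
    ns = [o.sum(axis=0) for o in obs]
    a_counts = [np.where(o, p.calls, 0).sum(axis=0)
                for o, p in zip(obs, panels)]
    v_counts = [(p.calls == 1).sum(axis=0) for p in panels]
    out = np.ones(n_markers)
    warned = False
    for k in range(n_markers):
        strata = [(int(ns[i][k]), int(a_counts[i][k]), int(v_counts[i][k]))
                  for i in range(len(panels)) if ns[i][k] >= 2]
        if not strata:
            if not warned:
                warnings.warn("marker(s) with no genotyped stratum: p = 1")
                warned = True
            continue
        if method == "fisher":
            pvals = [exact_hwe_pvalue(n, a, v) for n, a, v in strata]
            out[k] = stats.combine_pvalues(np.clip(pvals, 1e-300, 1.0),
                                           method="fisher").pvalue
            continue
        dist = np.array([1.0])
        offset = 0
        t_obs = 0
        for n, a, v in strata:
            support, probs = levene_haldane_pmf(n, a)
            vec = np.zeros(support[-1] - support[0] + 1)
            vec[support - support[0]] = probs
            dist = np.convolve(dist, vec)
            offset += int(support[0])
            t_obs += v
        p_obs = dist[t_obs - offset]
        out[k] = min(1.0, float(dist[dist <= p_obs * (1 + 1e-12)].sum()))
    return out


# ---------------------------------------------------------------------------
# GQ selection and sample-size equalization
# ---------------------------------------------------------------------------

def select_gq_snps(panels: list[GenotypePanel],
                   thresholds: QCThresholds | None = None,
                   hwe_method: str = "convolution"
                   ) -> tuple[list[str], pd.DataFrame]:
    """Good-quality SNPs: mean CR >= cr_min, mean MAF >= maf_min and
    stratified HWE p >= hwe_p_min.

    Returns (kept marker ids, report). The report lists every marker once
    with its statistics, pass flag and first failed rule (cr | maf | hwe).
    """
    thresholds = thresholds or QCThresholds()
    ids = _shared_map(panels)
    cr = mean_call_rate(panels)
    maf = mean_maf(panels)
    hwe = stratified_exact_hwe(panels, method=hwe_method)
    reason = np.where(cr < thresholds.cr_min, "cr",
                      np.where(maf < thresholds.maf_min, "maf",
                               np.where(hwe < thresholds.hwe_p_min, "hwe", "")))
    passed = reason == ""
    report = pd.DataFrame({"marker": ids, "mean_cr": cr, "mean_maf": maf,
                           "hwe_p": hwe, "pass": passed,
                           "reason": reason})
    kept = [mid for mid, ok in zip(ids, passed) if ok]
    return kept, report


def equalize_sample_sizes(panels: list[GenotypePanel], n: int,
                          rng: np.random.Generator | int = 0
                          ) -> list[GenotypePanel]:
    """Subsample every population to exactly ``n`` individuals (without
    replacement, seeded); populations with fewer than ``n`` are dropped with
    a warning."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    out = []
    for p in panels:
        if p.n_samples < n:
            warnings.warn(f"population {p.population} has {p.n_samples} < {n} "
                          "members and is discarded")
            continue
        if p.n_samples == n:
            out.append(p)
        else:
            idx = np.sort(rng.choice(p.n_samples, size=n, replace=False))
            out.append(p.subset_samples(idx))
    return out
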