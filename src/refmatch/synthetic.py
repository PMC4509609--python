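"""Synthetic structured populations for distance/imputation benchmarking.

Two generators are provided:

* **independent-SNP mode** (:func:`simulate_independent_snp_panels`) -- each
  population's allele frequencies drift from a shared ancestral frequency
  under the Balding-Nichols Beta model; genotypes are Binomial(2, p) with no
  LD. This mode has closed-form expectations and is the oracle for the
  distance estimators (for the printed two-population G_ST the
  Balding-Nichols expectation is 2F/(2-F)).

* **founder-mosaic mode** (:func:`simulate_mosaic_panels`) -- a shared pool
  of founder haplotypes is drawn site-wise from ancestral frequencies; every
  population's haplotypes are mosaics of that pool, switching founders
  between adjacent markers with a small probability, which induces the long-
  range haplotype sharing that reference-based imputation exploits.
  Population divergence is controlled by a single parameter ``d``: founder
  usage weights are drawn from a symmetric Dirichlet with total
  concentration (1-d)/d (uniform exactly at d=0), so a divergent population
  both shifts its allele frequencies and loses founders from its effective
  haplotype pool -- a distant reference panel is a genuinely poorer
  template library. An optional second channel (``drift_flip_scale`` > 0)
  adds population-private founder drift by flipping founder alleles at
  rate ``drift_flip_scale * d``; it is off by default.

  Target panels additionally emulate array-quality variation: a fraction
  of markers (``lowcr_marker_frac``, shared across populations, as on a
  shared genotyping platform) receives a per-marker missing-call rate
  drawn from ``lowcr_missing_range``. These markers fail the call-rate
  filter downstream, so the good-quality (maskable) SNPs are a minority
  and the typed scaffold available to the imputer stays dense and common --
  the situation the masking benchmark is designed around. Reference panels
  are complete, like curated phased reference sets.

A "complex" population mode doubles the founder count and the switch
probability, depressing LD -- a qualitative analog of populations with high
haplotype diversity (e.g. African-ancestry panels), for which genetic
distance under-predicts imputation difficulty.

All draws derive from ``numpy`` Generators spawned per population from the
config seed, so identical configs are bit-reproducible and populations have
independent streams.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .genodata import GenotypePanel, HaplotypePanel, Marker


@dataclass
class SimulationConfig:
    """Parameters of both simulation modes.

    ``divergence`` is the per-population drift parameter: the Balding-
    Nichols F in independent-SNP mode, the Dirichlet/drift parameter ``d``
    in mosaic mode. It may be a scalar (shared) or a sequence giving one
    value per population (targets first, then references, in mosaic mode).
    """

    n_snps: int = 2000
    n_founders: int = 16
    n_pops: int = 2
    n_per_pop: int = 40
    divergence: float | tuple = 0.05
    recomb_per_interval: float = 0.003
    maf_floor: float = 0.1
    seed: int = 0
    # mosaic-mode extras
    n_ref_pops: int = 0
    n_ref_haplotypes: int = 120
    complex_pops: tuple = ()          # indices (targets then refs) in complex mode
    drift_flip_scale: float = 0.0
    lowcr_marker_frac: float = 0.75   # markers with platform-quality missingness
    lowcr_missing_range: tuple = (0.06, 0.5)

    def __post_init__(self) -> None:
        for name in ("n_snps", "n_founders", "n_pops", "n_per_pop"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for d in np.atleast_1d(np.asarray(self.divergence, dtype=float)):
            if not (0.0 <= d < 1.0):
                raise ValueError(f"divergence must lie in [0,1), got {d}")
        if not (0.0 <= self.recomb_per_interval <= 1.0):
            raise ValueError("recomb_per_interval must lie in [0,1]")
        if not (0.0 < self.maf_floor < 0.5):
            raise ValueError("maf_floor must lie in (0, 0.5)")
        if not (0.0 <= self.lowcr_marker_frac <= 1.0):
            raise ValueError("lowcr_marker_frac must lie in [0,1]")
        lo, hi = self.lowcr_missing_range
        if not (0.0 <= lo <= hi < 1.0):
            raise ValueError("lowcr_missing_range must satisfy 0 <= lo <= hi < 1")

    def divergence_for(self, pop_index: int, n_total: int) -> float:
        div = np.atleast_1d(np.asarray(self.divergence, dtype=float))
        if div.size == 1:
            return float(div[0])
        if div.size != n_total:
            raise ValueError(
                f"divergence sequence length {div.size} != {n_total} populations")
        return float(div[pop_index])


def _pop_rngs(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def default_markers(n_snps: int, chrom: str = "1", spacing: int = 1000) -> list[Marker]:
    """Evenly spaced non-ambiguous A/G markers (positions carry no map)."""
    return [Marker(f"rs{k + 1}", chrom, (k + 1) * spacing, "A", "G")
            for k in range(n_snps)]


def draw_ancestral_freqs(cfg: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    return rng.uniform(cfg.maf_floor, 1.0 - cfg.maf_floor, size=cfg.n_snps)


def draw_balding_nichols_freqs(p_anc: np.ndarray, F: float,
                               rng: np.random.Generator) -> np.ndarray:
    """Per-population frequencies Beta(p(1-F)/F, (1-p)(1-F)/F); identity at F=0."""
    p_anc = np.asarray(p_anc, dtype=float)
    if ((p_anc <= 0) | (p_anc >= 1)).any():
        raise ValueError("ancestral frequencies must lie in (0,1)")
    if not (0.0 <= F < 1.0):
        raise ValueError("F must lie in [0,1)")
    if F == 0.0:
        return p_anc.copy()
    scale = (1.0 - F) / F
    return rng.beta(p_anc * scale, (1.0 - p_anc) * scale)


def simulate_independent_snp_panels(
        cfg: SimulationConfig) -> tuple[list[GenotypePanel], np.ndarray]:
    """LD-free panels with known truth: returns (panels, true freqs pops x snps)."""
    master = np.random.default_rng(cfg.seed)
    p_anc = draw_ancestral_freqs(cfg, master)
    rngs = _pop_rngs(cfg.seed + 1, cfg.n_pops)
    markers = default_markers(cfg.n_snps)
    panels: list[GenotypePanel] = []
    freqs = np.empty((cfg.n_pops, cfg.n_snps))
    for i, rng in enumerate(rngs):
        F = cfg.divergence_for(i, cfg.n_pops)
        p = draw_balding_nichols_freqs(p_anc, F, rng)
        freqs[i] = p
        calls = rng.binomial(2, p, size=(cfg.n_per_pop, cfg.n_snps)).astype(np.int8)
        panels.append(GenotypePanel(
            f"pop{i}", list(markers),
            [f"pop{i}_ind{j}" for j in range(cfg.n_per_pop)], calls))
    return panels, freqs


def mosaic_haplotypes(founders: np.ndarray, weights: np.ndarray, n_haplotypes: int,
                      recomb_per_interval: float,
                      rng: np.random.Generator) -> np.ndarray:
    """Draw haplotypes as founder mosaics with per-interval switch probability."""
    n_founders, n_snps = founders.shape
    if n_founders < 2:
        raise ValueError("need at least 2 founders")
    # candidate founder at every site; kept from the last switch point on
    proposals = rng.choice(n_founders, size=(n_haplotypes, n_snps), p=weights)
    switch = rng.random((n_haplotypes, n_snps)) < recomb_per_interval
    switch[:, 0] = True
    cols = np.broadcast_to(np.arange(n_snps), switch.shape)
    last_switch = np.maximum.accumulate(np.where(switch, cols, 0), axis=1)
    founder_idx = proposals[np.arange(n_haplotypes)[:, None], last_switch]
    return founders[founder_idx, cols].astype(np.uint8)


def _population_founders(founders: np.ndarray, d: float, flip_scale: float,
                         rng: np.random.Generator) -> np.ndarray:
    delta = flip_scale * d
    if delta <= 0:
        return founders
    flips = rng.random(founders.shape) < delta
    return np.where(flips, 1 - founders, founders).astype(np.uint8)


def _founder_weights(n_founders: int, d: float,
                     rng: np.random.Generator) -> np.ndarray:
    if d == 0.0:
        return np.full(n_founders, 1.0 / n_founders)
    concentration = (1.0 - d) / d
    return rng.dirichlet(np.full(n_founders, concentration / n_founders))


def simulate_mosaic_panels(
        cfg: SimulationConfig
) -> tuple[list[HaplotypePanel], list[GenotypePanel]]:
    """Founder-mosaic populations: (reference panels, target panels).

    ``cfg.n_pops`` target populations of ``n_per_pop`` diploid individuals
    and ``cfg.n_ref_pops`` reference panels of ``n_ref_haplotypes`` phased
    haplotypes, all drawn from one shared founder pool. Population order for
    per-population divergence/complex flags is targets first, then
    references.
    """
    if cfg.n_founders < 2:
        raise ValueError("n_founders must be >= 2")
    master = np.random.default_rng(cfg.seed)
    p_anc = draw_ancestral_freqs(cfg, master)
    founders = (master.random((cfg.n_founders, cfg.n_snps)) < p_anc).astype(np.uint8)
    # platform-quality profile: shared across target populations
    lowcr = master.random(cfg.n_snps) < cfg.lowcr_marker_frac
    lo, hi = cfg.lowcr_missing_range
    miss_rate = np.where(lowcr, master.uniform(lo, hi, cfg.n_snps), 0.0)
    n_total = cfg.n_pops + cfg.n_ref_pops
    rngs = _pop_rngs(cfg.seed + 1, n_total)
    markers = default_markers(cfg.n_snps)
    complex_set = set(cfg.complex_pops)

    def draw_pop(i: int, n_hap: int) -> np.ndarray:
        rng = rngs[i]
        d = cfg.divergence_for(i, n_total)
        pool, recomb = founders, cfg.recomb_per_interval
        if i in complex_set:
            # complex-haplotype mode: more founders, shorter segments
            extra = (master.random((cfg.n_founders, cfg.n_snps)) < p_anc)
            pool = np.vstack([founders, extra.astype(np.uint8)])
            recomb = min(1.0, 2.0 * recomb)
        pool = _population_founders(pool, d, cfg.drift_flip_scale, rng)
        weights = _founder_weights(pool.shape[0], d, rng)
        return mosaic_haplotypes(pool, weights, n_hap, recomb, rng)

    targets: list[GenotypePanel] = []
    for i in range(cfg.n_pops):
        haps = draw_pop(i, 2 * cfg.n_per_pop)
        calls = (haps[0::2] + haps[1::2]).astype(np.int8)
        if miss_rate.any():
            miss = rngs[i].random(calls.shape) < miss_rate
            calls[miss] = -1
        targets.append(GenotypePanel(
            f"target{i}", list(markers),
            [f"target{i}_ind{j}" for j in range(cfg.n_per_pop)], calls))
    refs: list[HaplotypePanel] = []
    for j in range(cfg.n_ref_pops):
        haps = draw_pop(cfg.n_pops + j, cfg.n_ref_haplotypes)
        refs.append(HaplotypePanel(f"ref{j}", list(markers), haps))
    return refs, targets


def realized_gst(panel_a, panel_b, maf_min: float = 0.0) -> float:
    """Printed-scale pairwise G_ST between two panels on markers whose mean
    MAF across the pair is >= ``maf_min``."""
    from .distance import allele_count_summary, gst

    s1 = allele_count_summary(panel_a)
    s2 = allele_count_summary(panel_b)
    if maf_min > 0.0:
        maf = 0.5 * (np.minimum(s1.p, 1 - s1.p) + np.minimum(s2.p, 1 - s2.p))
        keep = np.flatnonzero(maf >= maf_min)
        s1, s2 = s1.subset(keep), s2.subset(keep)
    return gst(s1, s2).value


def calibrate_divergence(target_gst: float, cfg: SimulationConfig,
                         lo: float = 1e-4, hi: float = 0.6,
                         n_seeds: int = 3, rel_tol: float = 0.1,
                         max_iter: int = 30, maf_min: float = 0.1
                         ) -> tuple[float, list[float]]:
    """Bisection on the reference-population divergence until the realized
    pairwise G_ST (median over ``n_seeds`` seeds) is within ``rel_tol`` of
    ``target_gst``.

    The pair measured is target population 0 (divergence taken from
    ``cfg.divergence``) against a reference panel whose divergence is the
    search variable. Returns ``(divergence, realized G_ST per seed)``.
    Raises if the search range does not bracket the target.
    """
    if not (0.0 < target_gst < 0.3):
        raise ValueError("target_gst must lie in (0, 0.3)")

    d_target = cfg.divergence_for(0, max(cfg.n_pops, 1))

    def realize(d: float) -> list[float]:
        vals = []
        for s in range(n_seeds):
            c = replace(cfg, n_pops=1, n_ref_pops=1,
                        divergence=(d_target, d), seed=cfg.seed + s,
                        complex_pops=())
            refs, targets = simulate_mosaic_panels(c)
            vals.append(realized_gst(targets[0], refs[0], maf_min=maf_min))
        return vals

    g_lo, g_hi = np.median(realize(lo)), np.median(realize(hi))
    if not (g_lo <= target_gst <= g_hi):
        raise ValueError(
            f"search range [{lo}, {hi}] does not bracket target G_ST "
            f"{target_gst:.4g} (realized {g_lo:.4g} .. {g_hi:.4g})")
    a, b = lo, hi
    for _ in range(max_iter):
        mid = 0.5 * (a + b)
        vals = realize(mid)
        g_mid = float(np.median(vals))
        if abs(g_mid - target_gst) <= rel_tol * target_gst:
            return mid, vals
        if g_mid < target_gst:
            a = mid
        else:
            b = mid
    warnings.warn("calibrate_divergence: tolerance not reached, returning midpoint")
    return 0.5 * (a + b), realize(0.5 * (a + b))
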