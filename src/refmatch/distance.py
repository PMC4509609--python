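"""Pairwise population genetic distances: G_ST and three F_ST estimators.

All four measures are aggregated **ratio-of-averages** style: per-marker
numerator and denominator components are summed over markers first and the
distance is the single ratio of those sums. This is the haplotype-wise
aggregation that reduces bias and standard error relative to averaging
per-marker ratios.

Measures (two populations, counted-allele frequencies p1, p2, sample sizes
n1, n2 individuals, allele counts a_i out of m_i = 2 n_i):

* ``gst`` -- Nei's coefficient of gene differentiation in its printed
  two-population per-marker form N = (p1-p2)^2, D = 2 p_avg (1-p_avg) with
  p_avg = (p1+p2)/2. Note this is twice the classical Nei value and can
  reach 2.0 for fixed opposite alleles; all thresholds in this package
  (0.01 "excellent", 0.04 "satisfactory") are on this scale.
* ``fst_reich`` -- the Reich/Hudson-style unbiased estimator
  N = (a1/m1 - a2/m2)^2 - h1/m1 - h2/m2, D = N + h1 + h2 with
  h_i = a_i (m_i - a_i) / (m_i (m_i - 1)); optional block-jackknife SE.
* ``fst_wc`` -- Weir & Cockerham's estimator with an unweighted mean
  frequency p-bar = (p1+p2)/2.
* ``fst_mwc`` -- a modified WC form N = (p1-p2)^2,
  D = first_term + (2/(n1+n2)) [n1 p1(1-p1) + n2 p2(1-p2)]; the first
  denominator term is ``(p1-p2)`` in the "as_printed" convention (default)
  or ``(p1-p2)^2`` in the "squared" convention. Only the squared convention
  is symmetric in the two populations and invariant to relabelling the
  counted allele; the two conventions are rank-equivalent in practice and
  the convention used is recorded on the estimate.

Markers whose denominator is exactly 0 for a measure contribute (0, 0) to
the sums, so every measure sees the same marker set.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genodata import MISSING, GenotypePanel, HaplotypePanel

MEASURES = ("gst", "fst_r", "fst_wc", "fst_mwc")


@dataclass
class AlleleCountSummary:
    """Per-marker allele bookkeeping for one population.

    ``n`` genotyped individuals, ``m = 2n`` alleles, ``a = 2u + v`` counted
    alleles (u hom-counted, v het), ``p = a/m``, and ``h`` the within-
    population heterozygosity term a(m-a)/(m(m-1)) of the Reich estimator.
    """

    population: str
    marker_ids: list[str]
    n: np.ndarray
    a: np.ndarray
    u: np.ndarray
    v: np.ndarray

    def __post_init__(self) -> None:
        for name in ("n", "a", "u", "v"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if not np.array_equal(self.a, 2 * self.u + self.v):
            raise ValueError("a = 2u + v violated")
        if ((self.a < 0) | (self.a > self.m)).any():
            raise ValueError("allele counts out of range")

    @property
    def m(self) -> np.ndarray:
        return 2.0 * self.n

    @property
    def p(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(self.m > 0, self.a / self.m, np.nan)

    @property
    def h(self) -> np.ndarray:
        m = self.m
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(m > 1, self.a * (m - self.a) / (m * (m - 1)), np.nan)

    def subset(self, index: np.ndarray) -> "AlleleCountSummary":
        index = np.asarray(index)
        return AlleleCountSummary(
            self.population, [self.marker_ids[i] for i in index],
            self.n[index], self.a[index], self.u[index], self.v[index])


def allele_count_summary(panel) -> AlleleCountSummary:
    """Summarize a GenotypePanel or HaplotypePanel (consecutive haplotype
    pairs treated as diploid individuals)."""
    if isinstance(panel, HaplotypePanel):
        panel = panel.as_genotypes()
    if not isinstance(panel, GenotypePanel):
        raise TypeError("expected GenotypePanel or HaplotypePanel")
    obs = panel.calls != MISSING
    n = obs.sum(axis=0).astype(float)
    u = (panel.calls == 2).sum(axis=0).astype(float)
    v = (panel.calls == 1).sum(axis=0).astype(float)
    return AlleleCountSummary(panel.population, panel.marker_ids(),
                              n, 2 * u + v, u, v)


@dataclass
class DistanceEstimate:
    """One pairwise distance with its per-marker components.

    ``value`` equals the exact ratio of the component sums. ``components``
    is a DataFrame with columns (marker, N_k, D_k) and measure-specific
    auxiliaries.
    """

    measure: str
    value: float
    se: float | None
    n_markers: int
    components: pd.DataFrame
    meta: dict = field(default_factory=dict)


def _check_pair(s1: AlleleCountSummary, s2: AlleleCountSummary) -> None:
    if len(s1.marker_ids) == 0:
        raise ValueError("empty marker set")
    if s1.marker_ids != s2.marker_ids:
        raise ValueError("marker sets differ between populations")


def _aggregate(measure: str, N: np.ndarray, D: np.ndarray,
               marker_ids: list[str], aux: dict, se: float | None = None,
               meta: dict | None = None) -> DistanceEstimate:
    # markers with zero denominator contribute (0, 0) to both sums
    zero = D == 0.0
    N = np.where(zero, 0.0, N)
    D = np.where(zero, 0.0, D)
    total_d = D.sum()
    if total_d == 0.0:
        value = 0.0
    else:
        value = float(N.sum() / total_d)
    comp = pd.DataFrame({"marker": marker_ids, "N_k": N, "D_k": D, **aux})
    return DistanceEstimate(measure, value, se, len(marker_ids), comp,
                            meta or {})


def gst(s1: AlleleCountSummary, s2: AlleleCountSummary) -> DistanceEstimate:
    """Printed-scale Nei G_ST: sum (p1-p2)^2 / sum 2 p_avg (1 - p_avg)."""
    _check_pair(s1, s2)
    p1, p2 = s1.p, s2.p
    D = (p1 - p2) ** 2
    p_avg = 0.5 * (p1 + p2)
    H_T = 2.0 * p_avg * (1.0 - p_avg)
    valid = np.isfinite(p1) & np.isfinite(p2)
    D, H_T = np.where(valid, D, 0.0), np.where(valid, H_T, 0.0)
    return _aggregate("gst", D, H_T, s1.marker_ids,
                      {"p1": p1, "p2": p2, "p_avg": p_avg})


def _reich_components(s1, s2):
    m1, m2 = s1.m, s2.m
    usable = (m1 > 1) & (m2 > 1)
    if not usable.all():
        warnings.warn(f"{(~usable).sum()} markers skipped (fewer than 2 "
                      "alleles in a population)")
    with np.errstate(invalid="ignore", divide="ignore"):
        h1, h2 = s1.h, s2.h
        N = (s1.p - s2.p) ** 2 - h1 / m1 - h2 / m2
        D = N + h1 + h2
    N = np.where(usable, N, 0.0)
    D = np.where(usable, D, 0.0)
    return N, D, h1, h2


def fst_reich(s1: AlleleCountSummary, s2: AlleleCountSummary,
              n_blocks: int = 20) -> DistanceEstimate:
    """Reich-style unbiased F_ST with delete-one-block jackknife SE over
    ``n_blocks`` contiguous, equally sized marker blocks (SE = 0 when
    ``n_blocks`` <= 1)."""
    _check_pair(s1, s2)
    N, D, h1, h2 = _reich_components(s1, s2)
    zero = D == 0.0
    N, D = np.where(zero, 0.0, N), np.where(zero, 0.0, D)
    se = _block_jackknife_se(N, D, n_blocks)
    return _aggregate("fst_r", N, D, s1.marker_ids, {"h1": h1, "h2": h2},
                      se=se, meta={"n_blocks": n_blocks})


def _block_jackknife_se(N: np.ndarray, D: np.ndarray, n_blocks: int) -> float:
    B = min(n_blocks, len(N))
    if B <= 1 or D.sum() == 0.0:
        return 0.0
    bounds = np.linspace(0, len(N), B + 1).astype(int)
    tot_n, tot_d = N.sum(), D.sum()
    thetas = []
    for b in range(B):
        sl = slice(bounds[b], bounds[b + 1])
        dd = tot_d - D[sl].sum()
        thetas.append((tot_n - N[sl].sum()) / dd if dd != 0.0 else 0.0)
    thetas = np.asarray(thetas)
    return float(np.sqrt((B - 1) / B * ((thetas - thetas.mean()) ** 2).sum()))


def fst_wc(s1: AlleleCountSummary, s2: AlleleCountSummary) -> DistanceEstimate:
    """Weir-Cockerham F_ST with unweighted mean frequency p-bar."""
    _check_pair(s1, s2)
    p1, p2, n1, n2 = s1.p, s2.p, s1.n, s2.n
    n_bar = 0.5 * (n1 + n2)
    usable = (2 * n_bar > 1) & np.isfinite(p1) & np.isfinite(p2)
    with np.errstate(invalid="ignore", divide="ignore"):
        p_bar = 0.5 * (p1 + p2)
        s2_var = (n1 * (p1 - p_bar) ** 2 + n2 * (p2 - p_bar) ** 2) / n_bar
        h_bar = (2 * n1 * p1 * (1 - p1) + 2 * n2 * p2 * (1 - p2)) / (2 * n_bar)
        N = s2_var - (p_bar * (1 - p_bar) - s2_var / 2 - h_bar / 4) / (2 * n_bar - 1)
        D = p_bar * (1 - p_bar) + s2_var / 2
    N = np.where(usable, N, 0.0)
    D = np.where(usable, D, 0.0)
    return _aggregate("fst_wc", N, D, s1.marker_ids,
                      {"s2": s2_var, "p_bar": p_bar, "h_bar": h_bar,
                       "n_bar": n_bar})


def fst_mwc(s1: AlleleCountSummary, s2: AlleleCountSummary,
            convention: str = "as_printed") -> DistanceEstimate:
    """Modified Weir-Cockerham F_ST.

    ``convention="as_printed"`` uses ``(p1 - p2)`` as the first denominator
    term; ``"squared"`` uses ``(p1 - p2)^2`` (symmetric, allele-swap
    invariant). The convention is recorded in ``meta``.
    """
    if convention not in ("as_printed", "squared"):
        raise ValueError(f"unknown mWC convention {convention!r}")
    _check_pair(s1, s2)
    p1, p2, n1, n2 = s1.p, s2.p, s1.n, s2.n
    usable = (n1 + n2 > 0) & np.isfinite(p1) & np.isfinite(p2)
    with np.errstate(invalid="ignore", divide="ignore"):
        N = (p1 - p2) ** 2
        first = (p1 - p2) if convention == "as_printed" else (p1 - p2) ** 2
        D = first + (2.0 / (n1 + n2)) * (n1 * p1 * (1 - p1) + n2 * p2 * (1 - p2))
    N = np.where(usable, N, 0.0)
    D = np.where(usable, D, 0.0)
    return _aggregate("fst_mwc", N, D, s1.marker_ids, {"p1": p1, "p2": p2},
                      meta={"convention": convention})


_ESTIMATORS = {"gst": gst, "fst_r": fst_reich, "fst_wc": fst_wc,
               "fst_mwc": fst_mwc}


def pairwise_matrix(panels: list, measures=MEASURES,
                    **kwargs) -> pd.DataFrame:
    """All pairwise distances between >= 2 panels on their (identical)
    marker set.

    Each unordered pair is computed once with the panels in list order and
    mirrored, so the matrix is symmetric by construction. Returns a long
    DataFrame (pop1, pop2, measure, value, se, n_markers).
    """
    if len(panels) < 2:
        raise ValueError("need at least 2 panels")
    summaries = [allele_count_summary(p) for p in panels]
    names = [s.population for s in summaries]
    rows = []
    for i, j in itertools.combinations(range(len(panels)), 2):
        for meas in measures:
            est = _ESTIMATORS[meas](summaries[i], summaries[j],
                                    **({k: v for k, v in kwargs.items()
                                        if meas == "fst_mwc" and k == "convention"}))
            for a, b in ((i, j), (j, i)):
                rows.append({"pop1": names[a], "pop2": names[b],
                             "measure": meas, "value": est.value,
                             "se": est.se, "n_markers": est.n_markers})
    return pd.DataFrame(rows)


def compare_measures(matrix: pd.DataFrame) -> pd.DataFrame:
    """Kendall tau-b concordance between distance measures over all pairs.

    For each measure pair, also flags the population pair with the largest
    absolute rank deviation between the two rankings (the outlier report).
    Tau is reported as NaN when a measure is constant over the pairs.
    """
    wide = (matrix[matrix.pop1 < matrix.pop2]
            .pivot_table(index=["pop1", "pop2"], columns="measure",
                         values="value"))
    if len(wide) < 3:
        raise ValueError("need at least 3 population pairs")
    rows = []
    for m1, m2 in itertools.combinations(wide.columns, 2):
        x, y = wide[m1].to_numpy(), wide[m2].to_numpy()
        if np.allclose(x, x[0]) or np.allclose(y, y[0]):
            tau, pval, outlier, dev = np.nan, np.nan, None, np.nan
        else:
            tau, pval = stats.kendalltau(x, y)
            rdev = np.abs(stats.rankdata(x) - stats.rankdata(y))
            k = int(np.argmax(rdev))
            outlier, dev = "{}|{}".format(*wide.index[k]), float(rdev[k])
        rows.append({"measure_1": m1, "measure_2": m2, "tau": tau,
                     "p": pval, "max_rank_dev_pair": outlier,
                     "max_rank_dev": dev})
    return pd.DataFrame(rows)
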