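"""Reference-based genotype imputation with a diploid haplotype-copying HMM.

Each unphased target individual is modelled as copying an ordered pair of
reference haplotypes along the chromosome (the Li-Stephens mosaic). Hidden
state at marker m is the template pair (j, k); each chromosome switches
independently to a template drawn uniformly at random with per-interval
probability rho, so the pair transition factorizes and a forward-backward
sweep costs O(markers * H^2). Emissions at typed markers allow an
independent per-allele error epsilon; missing markers emit 1. The posterior
genotype triple at a masked marker sums, over template pairs, the pair
posterior times P(dose | template alleles, epsilon).

This imputer is a scientific stand-in for production software (MaCH,
minimac, IMPUTE2): it reproduces their posterior-probability contract so
that accuracy scoring and the factorial benchmark are exercised end to end,
but it estimates no genetic map and performs no pre-phasing. "Software"
configurations in the benchmark are distinct parameterizations of this
model (or externally produced posterior files read via
:mod:`refmatch.genodata`).

Reference panels larger than ``max_ref_haplotypes`` are subsampled per
individual, keeping the haplotypes with the highest allele-sharing score
against the individual's typed genotypes (ties to the lower index), which
keeps the H^2 state space tractable without discarding the templates that
matter.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .genodata import (MISSING, GenotypePanel, HaplotypePanel, Marker,
                       PosteriorPanel)


@dataclass
class HMMParams:
    """Copying-model parameters.

    epsilon (``error_rate``) is the per-allele emission error, rho
    (``switch_rate``) the per-interval template switch probability and
    ``max_ref_haplotypes`` the per-individual reference subsample cap H.
    """

    error_rate: float = 0.01
    switch_rate: float = 0.05
    max_ref_haplotypes: int = 40
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.error_rate < 0.5):
            raise ValueError("error_rate must lie in (0, 0.5)")
        if not (0.0 < self.switch_rate < 1.0):
            raise ValueError("switch_rate must lie in (0, 1)")
        if self.max_ref_haplotypes < 2:
            raise ValueError("max_ref_haplotypes must be >= 2")


def subsample_reference(ref: HaplotypePanel, H: int,
                        target_calls: np.ndarray,
                        window: slice | None = None) -> np.ndarray:
    """Indices of the <= H reference haplotypes best matching one
    individual's typed genotypes.

    The sharing score of haplotype a against genotype g sums, over typed
    markers in ``window``, ``a * g/2 + (1 - a) * (1 - g/2)`` -- the expected
    agreement with a random allele of the genotype. Ties resolve to the
    lower haplotype index; if the panel has <= H haplotypes all are
    returned.
    """
    if H < 2:
        raise ValueError("H must be >= 2")
    if ref.n_haplotypes <= H:
        return np.arange(ref.n_haplotypes)
    sl = window if window is not None else slice(None)
    g = np.asarray(target_calls, dtype=float)[sl]
    a = ref.haplotypes[:, sl].astype(float)
    typed = g != MISSING
    gt = np.where(typed, g / 2.0, 0.0)
    score = a[:, typed] @ gt[typed] + (1.0 - a[:, typed]) @ (1.0 - gt[typed])
    order = np.argsort(-score, kind="stable")
    return np.sort(order[:H])


def _check_alignment(target: GenotypePanel, ref: HaplotypePanel) -> None:
    if target.marker_ids() != ref.marker_ids():
        raise ValueError("target and reference marker maps differ")
    for mt, mr in zip(target.markers, ref.markers):
        if (mt.alleleA, mt.alleleB) != (mr.alleleA, mr.alleleB):
            raise ValueError(f"allele mismatch at {mt.id}; run qc.align_alleles")


def _emission(g_col: np.ndarray, x_col: np.ndarray) -> np.ndarray:
    """Emission matrix (batch, H, H) for observed doses g (batch,) given
    per-haplotype counted-allele probabilities x (batch, H)."""
    xj = x_col[:, :, None]
    xk = x_col[:, None, :]
    out = np.empty((x_col.shape[0],) + (x_col.shape[1],) * 2)
    g0 = g_col == 0
    g1 = g_col == 1
    g2 = g_col == 2
    if g0.any():
        out[g0] = (1 - xj[g0]) * (1 - xk[g0])
    if g1.any():
        out[g1] = xj[g1] * (1 - xk[g1]) + (1 - xj[g1]) * xk[g1]
    if g2.any():
        out[g2] = xj[g2] * xk[g2]
    miss = g_col == MISSING
    if miss.any():
        out[miss] = 1.0
    return out


def _transition(A: np.ndarray, rho: float) -> np.ndarray:
    """Apply the factorized pair transition to (batch, H, H) mass."""
    H = A.shape[-1]
    stay = 1.0 - rho
    A = stay * A + (rho / H) * A.sum(axis=-2, keepdims=True)
    A = stay * A + (rho / H) * A.sum(axis=-1, keepdims=True)
    return A


def _triple_from_pair_posterior(post: np.ndarray, x_col: np.ndarray) -> np.ndarray:
    """Genotype triple (batch, 3) from pair posteriors (batch, H, H) and
    per-haplotype counted-allele probabilities x (batch, H)."""
    row = post.sum(axis=-1)            # marginal over k
    col = post.sum(axis=-2)            # marginal over j
    u = np.einsum("bh,bh->b", row, x_col)
    v = np.einsum("bh,bh->b", col, x_col)
    t = np.einsum("bjk,bj,bk->b", post, x_col, x_col)
    p2 = t
    p1 = u + v - 2.0 * t
    p0 = 1.0 - u - v + t
    return np.clip(np.stack([p0, p1, p2], axis=-1), 0.0, None)


def _forward_backward(calls: np.ndarray, alleles: np.ndarray,
                      params: HMMParams) -> np.ndarray:
    """Posterior genotype triples for a batch of individuals.

    calls: (batch, M) doses with MISSING at untyped markers;
    alleles: (batch, H, M) subsampled reference haplotypes per individual.
    Returns (batch, M, 3).
    """
    eps, rho = params.error_rate, params.switch_rate
    batch, M = calls.shape
    H = alleles.shape[1]
    x = np.where(alleles == 1, 1.0 - eps, eps)  # (batch, H, M)
    fwd = np.empty((M, batch, H, H))
    A = np.full((batch, H, H), 1.0 / (H * H))
    for m in range(M):
        if m > 0:
            A = _transition(A, rho)
        A = A * _emission(calls[:, m], x[:, :, m])
        norm = A.sum(axis=(-2, -1), keepdims=True)
        A = A / norm
        fwd[m] = A
    post = np.empty((batch, M, 3))
    B = np.ones((batch, H, H))
    for m in range(M - 1, -1, -1):
        pair = fwd[m] * B
        pair /= pair.sum(axis=(-2, -1), keepdims=True)
        post[:, m, :] = _triple_from_pair_posterior(pair, x[:, :, m])
        if m > 0:
            B = _transition(B * _emission(calls[:, m], x[:, :, m]), rho)
            B /= B.sum(axis=(-2, -1), keepdims=True)
    post /= post.sum(axis=-1, keepdims=True)
    return post


def impute(target: GenotypePanel, ref: HaplotypePanel,
           params: HMMParams | None = None,
           batch_memory_bytes: int = 300_000_000) -> PosteriorPanel:
    """Posterior genotype triples for every marker of every target
    individual (typed markers included).

    The target and reference must already be aligned on an identical marker
    map. Individuals are processed in batches sized to keep the stored
    forward lattice under ``batch_memory_bytes``.
    """
    params = params or HMMParams()
    _check_alignment(target, ref)
    if ref.n_haplotypes < 2:
        raise ValueError("reference must contain at least 2 haplotypes")
    M = target.n_markers
    H = min(params.max_ref_haplotypes, ref.n_haplotypes)
    sel = np.stack([
        subsample_reference(ref, params.max_ref_haplotypes, target.calls[i])
        for i in range(target.n_samples)
    ])  # (n, H)
    alleles = ref.haplotypes[sel, :]  # (n, H, M)
    probs = np.empty((target.n_samples, M, 3))
    chunk = max(1, int(batch_memory_bytes // max(1, M * H * H * 8)))
    for start in range(0, target.n_samples, chunk):
        stop = min(start + chunk, target.n_samples)
        probs[start:stop] = _forward_backward(
            target.calls[start:stop].astype(np.int64),
            alleles[start:stop], params)
    return PosteriorPanel(list(target.markers), list(target.samples), probs)


def estimate_params(target: GenotypePanel, ref: HaplotypePanel,
                    n_rounds: int = 0,
                    params: HMMParams | None = None) -> HMMParams:
    """EM-style refinement of the emission error epsilon (rho held fixed).

    Each round runs the forward-backward sweep and re-estimates epsilon as
    the expected per-allele mismatch rate between the observed doses and
    the leave-one-marker-out posterior template dose at typed markers.
    ``n_rounds = 0`` returns the input (or default) parameters unchanged.
    """
    params = params or HMMParams()
    if n_rounds == 0:
        return params
    _check_alignment(target, ref)
    typed_any = (target.calls != MISSING).any(axis=0)
    if not typed_any.any():
        return params
    rho = params.switch_rate
    for _ in range(n_rounds):
        eps = params.error_rate
        num = 0.0
        den = 0.0
        for i in range(target.n_samples):
            calls = target.calls[i].astype(np.int64)
            sel = subsample_reference(ref, params.max_ref_haplotypes, calls)
            al = ref.haplotypes[sel, :][None, :, :]  # (1, H, M)
            x = np.where(al == 1, 1.0 - eps, eps)
            M = calls.size
            H = al.shape[1]
            fwd = np.empty((M, 1, H, H))
            pred = np.empty((M, 1, H, H))
            A = np.full((1, H, H), 1.0 / (H * H))
            for m in range(M):
                if m > 0:
                    A = _transition(A, rho)
                pred[m] = A
                A = A * _emission(calls[None, m], x[:, :, m])
                A /= A.sum(axis=(-2, -1), keepdims=True)
                fwd[m] = A
            B = np.ones((1, H, H))
            for m in range(M - 1, -1, -1):
                if calls[m] != MISSING:
                    loo = pred[m] * B  # excludes marker m's own emission
                    loo /= loo.sum(axis=(-2, -1), keepdims=True)
                    dose_probs = _triple_from_pair_posterior(
                        loo, al[:, :, m].astype(float))
                    mism = np.abs(np.arange(3) - calls[m])
                    num += float((dose_probs * mism).sum())
                    den += 2.0
                if m > 0:
                    B = _transition(B * _emission(calls[None, m], x[:, :, m]), rho)
                    B /= B.sum(axis=(-2, -1), keepdims=True)
        if den == 0.0:
            break
        params = replace(params, error_rate=float(np.clip(num / den, 1e-4, 0.49)))
    return params
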