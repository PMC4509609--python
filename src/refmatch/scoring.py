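"""Genotype-level and SNP-level imputation accuracy measures.

Genotype-level (truth g against posterior triple P):

* Hellinger score = 1 - H(delta_g, P) = 1 - sqrt(1 - sqrt(P_g)), one minus
  the Hellinger distance between the point mass at the true genotype and
  the posterior. It is 1 iff the posterior is degenerate at g and strictly
  increasing in P_g; the 0.45 cut-off marks well-imputed genotypes and
  corresponds to P_g >= (1 - 0.55^2)^2 ~= 0.4865.
* SEN score = 1 - |g - dose| / 2 with dose = P1 + 2 P2: maximal iff the
  posterior expectation equals the true dose; the 0.95 cut-off equals
  |dose error| <= 0.1.
* correct = best-guess (argmax, ties to the smaller dose) equals g.

SNP-level (no truth needed):

* MaCH-style Rsq = population variance of the dosages over the expected
  binomial variance 2 p (1-p) under Hardy-Weinberg, p = mean dosage / 2;
  0 (flagged monomorphic) when p is 0 or 1.
* IMPUTE-style info = 1 - sum(f_i - e_i^2) / (2 N theta (1-theta)) with
  e_i = P1 + 2 P2, f_i = P1 + 4 P2 and theta = sum(e_i) / 2N; equal to 1
  on degenerate posteriors and when theta is 0 or 1. The value is reported
  unclamped -- worse-than-null posteriors yield negative info -- since
  summary thresholds at 0.8 are unaffected.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genodata import MISSING, PosteriorPanel, dosage_and_bestguess

LOW_MAF_MAX = 0.05  # "low-frequency" class boundary


@dataclass
class ScoreCutoffs:
    """Thresholds for the summary percentages."""

    hellinger: float = 0.45
    sen: float = 0.95
    snp_quality: float = 0.8


def hellinger_score(g, P) -> np.ndarray:
    """1 - sqrt(1 - sqrt(P_g)); elementwise over matching shapes."""
    g = np.asarray(g)
    P = np.asarray(P, dtype=float)
    pg = np.take_along_axis(P, g[..., None].astype(int), axis=-1)[..., 0]
    return 1.0 - np.sqrt(np.clip(1.0 - np.sqrt(pg), 0.0, None))


def sen_score(g, P) -> np.ndarray:
    """1 - |g - (P1 + 2 P2)| / 2."""
    g = np.asarray(g, dtype=float)
    P = np.asarray(P, dtype=float)
    dose = P[..., 1] + 2.0 * P[..., 2]
    return 1.0 - np.abs(g - dose) / 2.0


def mach_rsq(dosages) -> tuple[float, bool]:
    """(Rsq, monomorphic flag) from per-sample dosages in [0, 2].

    Rsq is the plug-in (1/n) variance of the dosages over 2 p (1-p);
    monomorphic SNPs (p in {0, 1}) report Rsq = 0.
    """
    d = np.asarray(dosages, dtype=float)
    if d.size == 0:
        raise ValueError("empty dosage vector")
    p = d.mean() / 2.0
    if p in (0.0, 1.0):
        return 0.0, True
    return float(d.var() / (2.0 * p * (1.0 - p))), False


def impute_info(posteriors) -> float:
    """IMPUTE-style information from per-sample triples (N x 3)."""
    P = np.asarray(posteriors, dtype=float)
    if P.size == 0:
        raise ValueError("empty posterior set")
    e = P[:, 1] + 2.0 * P[:, 2]
    f = P[:, 1] + 4.0 * P[:, 2]
    n = P.shape[0]
    theta = e.sum() / (2.0 * n)
    if theta in (0.0, 1.0):
        return 1.0
    return float(1.0 - (f - e ** 2).sum() / (2.0 * n * theta * (1.0 - theta)))


def score_genotypes(truth: pd.DataFrame, posteriors: PosteriorPanel
                    ) -> pd.DataFrame:
    """Per-genotype scores for the masked entries.

    ``truth`` is a samples x markers table of hidden calls (missing truth
    entries are skipped). Returns long format: sample, marker, g,
    hellinger, sen, correct.
    """
    mk_index = {m: k for k, m in enumerate(posteriors.marker_ids())}
    sm_index = {s: i for i, s in enumerate(posteriors.samples)}
    cols = [mk_index[m] for m in truth.columns]
    rows = [sm_index[s] for s in truth.index]
    P = posteriors.probs[np.ix_(rows, cols)]
    g = truth.to_numpy()
    _, best = dosage_and_bestguess(posteriors)
    best = best[np.ix_(rows, cols)]
    ok = g != MISSING
    sam, mar = np.nonzero(ok)
    gg = g[ok].astype(int)
    pp = P[ok]
    return pd.DataFrame({
        "sample": np.asarray(truth.index)[sam],
        "marker": np.asarray(truth.columns)[mar],
        "g": gg,
        "hellinger": hellinger_score(gg, pp),
        "sen": sen_score(gg, pp),
        "correct": best[ok] == gg,
    })


def snp_quality(posteriors: PosteriorPanel, markers: list[str],
                maf: dict | pd.Series | None = None) -> pd.DataFrame:
    """Per-SNP MaCH-Rsq and IMPUTE-info for the given markers.

    ``maf`` maps marker id to the SNP's minor-allele frequency in the truth
    data, used for the low/common class (low: MAF <= 0.05); without it the
    class is derived from the posterior dosages.
    """
    mk_index = {m: k for k, m in enumerate(posteriors.marker_ids())}
    dosage, _ = dosage_and_bestguess(posteriors)
    rows = []
    for mid in markers:
        k = mk_index[mid]
        rsq, mono = mach_rsq(dosage[:, k])
        info = impute_info(posteriors.probs[:, k, :])
        if maf is not None:
            m = float(maf[mid])
        else:
            p = dosage[:, k].mean() / 2.0
            m = min(p, 1.0 - p)
        rows.append({"marker": mid, "rsq": rsq, "info": info,
                     "monomorphic": mono, "maf": m,
                     "maf_class": "low" if m <= LOW_MAF_MAX else "common"})
    return pd.DataFrame(rows)


def _pct(x) -> float:
    return float(np.mean(x) * 100.0) if len(x) else np.nan


def summarize(scores: pd.DataFrame, quality: pd.DataFrame,
              cutoffs: ScoreCutoffs | None = None) -> dict:
    """Benchmark-row accuracy summary.

    Percentages of genotypes with Hellinger >= cut-off, SEN >= cut-off and
    correct best guess; mean Rsq / info and percentage of SNPs at >= the
    SNP-quality cut-off -- overall and stratified by MAF class.
    """
    cutoffs = cutoffs or ScoreCutoffs()
    if len(scores) == 0 or len(quality) == 0:
        raise ValueError("empty score or quality set")
    klass = quality.set_index("marker")["maf_class"]
    out = {}

    def geno_block(sub: pd.DataFrame, suffix: str) -> None:
        out[f"pct_hellinger{suffix}"] = _pct(sub.hellinger >= cutoffs.hellinger)
        out[f"pct_sen{suffix}"] = _pct(sub.sen >= cutoffs.sen)
        out[f"pct_correct{suffix}"] = _pct(sub.correct)
        out[f"n_genotypes{suffix}"] = int(len(sub))

    def snp_block(sub: pd.DataFrame, suffix: str) -> None:
        out[f"mean_rsq{suffix}"] = float(sub.rsq.mean()) if len(sub) else np.nan
        out[f"mean_info{suffix}"] = float(sub["info"].mean()) if len(sub) else np.nan
        out[f"pct_rsq{suffix}"] = _pct(sub.rsq >= cutoffs.snp_quality)
        out[f"pct_info{suffix}"] = _pct(sub["info"] >= cutoffs.snp_quality)
        out[f"n_snps{suffix}"] = int(len(sub))

    geno_block(scores, "")
    snp_block(quality, "")
    marker_class = scores.marker.map(klass)
    for cls in ("low", "common"):
        geno_block(scores[marker_class == cls], f"_{cls}")
        snp_block(quality[quality.maf_class == cls], f"_{cls}")
    return out


def reliability_check(quality: pd.DataFrame, scores: pd.DataFrame,
                      positions: dict | pd.Series | None = None
                      ) -> pd.DataFrame:
    """Per-SNP table joining software quality (Rsq/info) with the mean
    Hellinger score, for the matched-reference regression.

    SNPs present in only one of the inputs are excluded. Output is sorted
    by position when ``positions`` is given, else by marker id.
    """
    if len(quality) < 2:
        raise ValueError("need at least 2 SNPs")
    mean_h = scores.groupby("marker")["hellinger"].mean().rename("mean_hellinger")
    joined = quality.set_index("marker").join(mean_h, how="inner").reset_index()
    if positions is not None:
        joined["pos"] = joined.marker.map(positions)
        joined = joined.sort_values("pos", kind="stable")
    else:
        joined = joined.sort_values("marker", kind="stable")
    return joined.reset_index(drop=True)
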