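"""Full-factorial benchmark driver and distance-vs-accuracy statistics.

:func:`run_factorial` executes, for every cell of the
(target x reference x imputer-configuration x missingness) grid:
GQ-SNP selection -> pairwise distances -> nested masking -> imputation ->
accuracy scoring, and emits one long-format row per cell carrying all four
distance measures and all accuracy summaries. Accuracy columns are computed
twice: over the cell's own masked set, and (suffix ``_shared``) over the
markers masked at the smallest fraction, which is the only set on which
missingness levels are comparable.

The statistics mirror the benchmark's standard analyses: Pearson
correlation of distance against accuracy with a plain two-sided t-test of
zero correlation (t = r sqrt((n-2)/(1-r^2))), OLS of per-SNP mean Hellinger
score on the software quality score plus a matched-reference indicator, and
correlations restricted by missingness level or MAF class. Outliers
(studentized residual > 3) are flagged, never removed; correlations are
reported with and without flagged rows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import masking, qc, scoring
from .distance import allele_count_summary, fst_mwc, fst_reich, fst_wc, gst
from .genodata import GenotypePanel, HaplotypePanel
from .imputer import HMMParams, impute


@dataclass
class FactorialDesign:
    """The benchmark grid.

    ``imputer_configs`` maps a label (the "software" axis) to an
    :class:`HMMParams`; ``fractions`` are the nested missingness levels.
    ``distance_markers`` chooses the SNP set for the distance estimates:
    the GQ set (default) or all aligned markers.
    """

    targets: list
    references: list
    imputer_configs: dict = field(default_factory=lambda: {"hmm": HMMParams()})
    fractions: tuple = (1.0,)
    thresholds: qc.QCThresholds = field(default_factory=qc.QCThresholds)
    distance_markers: str = "gq"  # or "all"
    seed: int = 0


def _distances(target: GenotypePanel, ref: HaplotypePanel,
               marker_ids: list[str] | None) -> dict:
    st, sr = allele_count_summary(target), allele_count_summary(ref)
    if marker_ids is not None:
        wanted = set(marker_ids)
        keep = np.flatnonzero([m in wanted for m in st.marker_ids])
        st, sr = st.subset(keep), sr.subset(keep)
    return {
        "gst": gst(st, sr).value,
        "fst_r": fst_reich(st, sr).value,
        "fst_wc": fst_wc(st, sr).value,
        "fst_mwc": fst_mwc(st, sr).value,
    }


def run_factorial(design: FactorialDesign, impute_fn=impute,
                  keep_details: bool = False
                  ) -> pd.DataFrame | tuple[pd.DataFrame, dict]:
    """Execute the full grid; one row per cell, failures recorded inline.

    ``impute_fn(target, ref, params) -> PosteriorPanel`` may be replaced
    (e.g. by a reader of externally produced posterior files). With
    ``keep_details`` the per-cell genotype scores and SNP-quality tables are
    returned as a dict keyed by (target, reference, imputer, fraction).
    """
    gq, _report = qc.select_gq_snps(design.targets, design.thresholds)
    if not gq:
        raise ValueError("no GQ SNPs passed the filters")
    plan = masking.build_mask_plan(gq, design.fractions, seed=design.seed)
    shared = set(plan.mask(design.fractions[0]))
    dist_set = gq if design.distance_markers == "gq" else None
    rows = []
    details: dict = {}
    target_maf = {}
    for t in design.targets:
        freq = t.allele_freq()
        target_maf[t.population] = pd.Series(
            np.minimum(freq, 1.0 - freq), index=t.marker_ids())
    for t in design.targets:
        for r in design.references:
            dists = _distances(t, r, dist_set)
            for label, params in design.imputer_configs.items():
                for frac in design.fractions:
                    key = (t.population, r.panel_name, label, frac)
                    row = {"target": t.population, "reference": r.panel_name,
                           "imputer": label, "missingness": frac,
                           "seed": design.seed, **dists}
                    try:
                        masked, truth = masking.apply_mask(t, plan, frac)
                        post = impute_fn(masked, r, params)
                        scores = scoring.score_genotypes(truth, post)
                        quality = scoring.snp_quality(
                            post, list(truth.columns),
                            maf=target_maf[t.population])
                        row.update(scoring.summarize(scores, quality))
                        sh_scores = scores[scores.marker.isin(shared)]
                        sh_quality = quality[quality.marker.isin(shared)]
                        for k, v in scoring.summarize(sh_scores,
                                                      sh_quality).items():
                            row[f"{k}_shared"] = v
                        row["n_markers"] = len(truth.columns)
                        row["error"] = ""
                        if keep_details:
                            details[key] = (scores, quality)
                    except Exception as exc:  # cell failure: record, continue
                        row["error"] = f"{type(exc).__name__}: {exc}"
                        warnings.warn(f"cell {key} failed: {row['error']}")
                    rows.append(row)
    result = pd.DataFrame(rows)
    return (result, details) if keep_details else result


# ---------------------------------------------------------------------------
# Correlation statistics
# ---------------------------------------------------------------------------

def _pearson_report(x: np.ndarray, y: np.ndarray) -> dict:
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = x.size
    if n < 3 or np.allclose(x, x[0]) or np.allclose(y, y[0]):
        return {"r": np.nan, "p": np.nan, "n": n, "outliers": "",
                "r_wo_outliers": np.nan}
    r, p = stats.pearsonr(x, y)  # p from t = r sqrt((n-2)/(1-r^2))
    # studentized residuals of y on x (diagnostics need a few df)
    import statsmodels.api as sm

    if n >= 5:
        fit = sm.OLS(y, sm.add_constant(x)).fit()
        stud = fit.get_influence().resid_studentized_external
        out_idx = np.flatnonzero(np.abs(stud) > 3)
    else:
        out_idx = np.array([], dtype=int)
    if out_idx.size and n - out_idx.size >= 3:
        keep = np.setdiff1d(np.arange(n), out_idx)
        r_wo = stats.pearsonr(x[keep], y[keep])[0]
    else:
        r_wo = r
    return {"r": float(r), "p": float(p), "n": int(n),
            "outliers": ",".join(map(str, out_idx)), "r_wo_outliers": float(r_wo)}


def accuracy_vs_distance(result: pd.DataFrame,
                         accuracy_col: str = "pct_hellinger",
                         distance_col: str = "gst",
                         groupby: str | list | None = None,
                         row_filter=None) -> pd.DataFrame:
    """Pearson r (with zero-correlation t-test) between a distance column
    and an accuracy column, optionally per group and/or on a row subset."""
    df = result[result.get("error", "") == ""] if "error" in result else result
    if row_filter is not None:
        df = df[row_filter(df)]
    groups = [("overall", df)] if groupby is None else list(df.groupby(groupby))
    rows = []
    for name, sub in groups:
        rep = _pearson_report(sub[distance_col].to_numpy(dtype=float),
                              sub[accuracy_col].to_numpy(dtype=float))
        rows.append({"group": name, "accuracy_col": accuracy_col,
                     "distance_col": distance_col, **rep})
    return pd.DataFrame(rows)


def matched_reference_regression(table: pd.DataFrame, match_col: str = "matched",
                                 score_col: str = "rsq",
                                 response_col: str = "mean_hellinger"
                                 ) -> dict:
    """OLS of per-SNP mean Hellinger on (software score, matched indicator).

    Returns the indicator's coefficient, standard error and two-sided p.
    Raises on a collinear design (e.g. a constant covariate).
    """
    import statsmodels.api as sm

    if not (table[match_col].astype(bool).any()
            and (~table[match_col].astype(bool)).any()):
        raise ValueError("need both matched and mismatched rows")
    X = np.column_stack([table[score_col].to_numpy(dtype=float),
                         table[match_col].to_numpy(dtype=float)])
    X = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("collinear design")
    fit = sm.OLS(table[response_col].to_numpy(dtype=float), X).fit()
    return {"coef": float(fit.params[2]), "se": float(fit.bse[2]),
            "p": float(fit.pvalues[2]), "n": int(fit.nobs)}


def missingness_comparison(result: pd.DataFrame,
                           accuracy_col: str = "pct_hellinger",
                           distance_col: str = "gst") -> pd.DataFrame:
    """Distance-accuracy correlation per missingness level, restricted to
    the markers masked at every level (the ``_shared`` columns)."""
    fractions = sorted(result.missingness.unique())
    if len(fractions) < 2:
        raise ValueError("need at least 2 missingness fractions")
    col = f"{accuracy_col}_shared"
    if col not in result.columns:
        raise ValueError(f"result lacks shared-subset column {col}")
    rep = accuracy_vs_distance(result, accuracy_col=col,
                               distance_col=distance_col,
                               groupby="missingness")
    means = result.groupby("missingness")[col].mean().rename("mean_accuracy")
    return rep.merge(means, left_on="group", right_index=True)


def maf_stratified_correlation(result: pd.DataFrame,
                               accuracy_stem: str = "mean_rsq",
                               distance_col: str = "gst") -> pd.DataFrame:
    """Distance-accuracy correlation per MAF class (low: MAF <= 0.05),
    with the mean accuracy per class; classes without data report NaN.

    The default accuracy measure is the SNP-level mean Rsq: genotype-level
    percentages are dominated by easy major-homozygote calls at rare
    variants, whereas the dosage-variance ratio exposes how poorly the
    minor allele is recovered.
    """
    rows = []
    for cls in ("low", "common"):
        col = f"{accuracy_stem}_{cls}"
        sub = result[np.isfinite(result[col])]
        rep = (_pearson_report(sub[distance_col].to_numpy(dtype=float),
                               sub[col].to_numpy(dtype=float))
               if len(sub) else
               {"r": np.nan, "p": np.nan, "n": 0, "outliers": "",
                "r_wo_outliers": np.nan})
        rows.append({"maf_class": cls,
                     "mean_accuracy": float(sub[col].mean()) if len(sub) else np.nan,
                     **rep})
    return pd.DataFrame(rows)
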