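"""Per-feature discrimination battery for the two maturity stages.

For each feature: a linear mixed-effects test of the stage effect with the
biological sample as random grouping factor (technical replicates share a
random intercept), Benjamini–Hochberg FDR control across features, the
fold change of stage medians, and the ROC AUC with a stratified-bootstrap
confidence interval.  Results are summarised one row per feature in the
``median [p5–p95]`` layout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize_scalar

from .design import STAGES

__all__ = [
    "LmeResult",
    "AucResult",
    "lme_stage_test",
    "benjamini_hochberg",
    "fold_change",
    "roc_auc",
    "auc_ci",
    "table_summary",
    "format_results_table",
]


@dataclass(frozen=True)
class LmeResult:
    """Stage-effect test from the random-intercept model."""

    estimate: float  # fixed-effect contrast (positive stage minus reference)
    se: float
    df: int  # between-sample degrees of freedom
    p: float
    sigma2_sample: float  # random-intercept variance
    sigma2_resid: float  # replicate residual variance


def _group_arrays(values, stage, sample):
    values = np.asarray(values, float)
    stage = np.asarray(stage)
    sample = np.asarray(sample)
    if not (len(values) == len(stage) == len(sample)):
        raise ValueError("values, stage and sample must have equal length")
    if np.ptp(values) == 0:
        raise ValueError("zero total variance: all values identical")
    uniq_samples, inv = np.unique(sample, return_inverse=True)
    sample_stage = []
    for i, s in enumerate(uniq_samples):
        st = np.unique(stage[inv == i])
        if len(st) != 1:
            raise ValueError(f"sample {s!r} spans more than one stage")
        sample_stage.append(st[0])
    sample_stage = np.asarray(sample_stage)
    stages = np.unique(stage)
    if len(stages) != 2:
        raise ValueError("exactly two stages required")
    for st in stages:
        if (sample_stage == st).sum() < 2:
            raise ValueError(f"stage {st!r} has fewer than 2 samples")
    return values, stage, inv, uniq_samples, sample_stage, stages


def lme_stage_test(values, stage, sample, positive_stage: str | None = None) -> LmeResult:
    """Test the maturity-stage effect with a random sample intercept.

    Model: y_sr = mu + beta * stage_s + a_s + e_sr, a_s ~ N(0, sigma_a^2),
    e_sr ~ N(0, sigma_e^2).  Balanced designs (equal replicates per sample)
    use the closed-form REML components from the within/between mean
    squares — in which case the Wald t statistic on the stage contrast
    with between-sample degrees of freedom (S - 2) is exactly the
    two-sample t-test on the per-sample replicate means.  Unbalanced
    designs profile the REML criterion over the variance ratio.
    """
    values, stage, inv, uniq_samples, sample_stage, stages = _group_arrays(
        values, stage, sample
    )
    if positive_stage is None:
        positive_stage = STAGES[1] if STAGES[1] in stages else stages[-1]
    ref_stage = [s for s in stages if s != positive_stage][0]
    S = len(uniq_samples)
    n_g = np.bincount(inv, minlength=S)
    sums = np.bincount(inv, weights=values, minlength=S)
    means = sums / n_g
    df_between = S - 2

    if np.all(n_g == n_g[0]):
        r = int(n_g[0])
        N = len(values)
        # within-sample mean square
        ssw = float(np.sum((values - means[inv]) ** 2))
        msw = ssw / (N - S) if N > S else 0.0
        pos = sample_stage == positive_stage
        est = float(means[pos].mean() - means[~pos].mean())
        stage_mean = np.where(pos, means[pos].mean(), means[~pos].mean())
        msb = r * float(np.sum((means - stage_mean) ** 2)) / df_between
        if msb == 0:
            raise ValueError("zero between-sample variance; test degenerate")
        sigma2_e = msw if N > S else msb
        sigma2_a = max(0.0, (msb - msw) / r) if N > S else 0.0
        se = float(np.sqrt(msb / r * (1.0 / pos.sum() + 1.0 / (~pos).sum())))
    else:
        est, se, sigma2_a, sigma2_e = _reml_profile(
            values, inv, n_g, sample_stage == positive_stage
        )
    t = est / se
    p = 2.0 * stats.t.sf(abs(t), df_between)
    return LmeResult(est, se, df_between, float(p), sigma2_a, sigma2_e)


def _reml_profile(values, inv, n_g, pos_sample):
    """Profiled REML for the unbalanced random-intercept model.

    The variance ratio lambda = sigma_a^2 / sigma_e^2 is profiled: for
    each lambda the GLS fit is closed-form through the Woodbury identity
    on the block-diagonal marginal covariance.
    """
    S = len(n_g)
    N = len(values)
    sums = np.bincount(inv, weights=values, minlength=S)
    sumsq = np.bincount(inv, weights=values**2, minlength=S)
    x_g = pos_sample.astype(float)  # stage indicator per sample

    def gls(lam):
        d = 1.0 + lam * n_g
        # X = [1, stage]; columns constant within sample
        xtvx = np.empty((2, 2))
        xtvx[0, 0] = np.sum(n_g / d)
        xtvx[0, 1] = xtvx[1, 0] = np.sum(x_g * n_g / d)
        xtvx[1, 1] = np.sum(x_g * n_g / d)
        xtvy = np.array([np.sum(sums / d), np.sum(x_g * sums / d)])
        ytvy = np.sum(sumsq) - np.sum(lam / d * sums**2)
        beta = np.linalg.solve(xtvx, xtvy)
        rss = float(ytvy - beta @ xtvy)
        return beta, rss, xtvx, d

    def neg2_reml(u):
        lam = np.exp(u)
        beta, rss, xtvx, d = gls(lam)
        sigma2 = max(rss / (N - 2), 1e-300)
        sign, logdet = np.linalg.slogdet(xtvx)
        return (N - 2) * np.log(sigma2) + np.sum(np.log(d)) + logdet

    res = minimize_scalar(neg2_reml, bounds=(-15.0, 15.0), method="bounded")
    lam = float(np.exp(res.x))
    if neg2_reml(-np.inf if False else -40.0) < res.fun:  # lambda -> 0 boundary
        lam = 0.0
    beta, rss, xtvx, d = gls(lam)
    sigma2_e = rss / (N - 2)
    cov = sigma2_e * np.linalg.inv(xtvx)
    return float(beta[1]), float(np.sqrt(cov[1, 1])), lam * sigma2_e, sigma2_e


def benjamini_hochberg(pvalues, delta: float = 0.05):
    """Benjamini–Hochberg step-up FDR control at level delta.

    Returns ``(adjusted, reject)``: adjusted p-values by the step-up
    max-min construction (monotone non-decreasing in the raw p) and
    rejection flags ``adjusted <= delta``.
    """
    p = np.asarray(pvalues, float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("pvalues must be a non-empty 1-D array")
    if np.any(p < 0) or np.any(p > 1) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    adj_sorted = np.minimum(adj_sorted, 1.0)
    adjusted = np.empty(m)
    adjusted[order] = adj_sorted
    return adjusted, adjusted <= delta


def fold_change(red_values, half_red_values) -> float:
    """Ratio of stage medians: median(red) / median(half-red)."""
    red = np.asarray(red_values, float)
    half = np.asarray(half_red_values, float)
    if red.size == 0 or half.size == 0:
        raise ValueError("both stage groups must be non-empty")
    denom = float(np.median(half))
    if denom == 0:
        raise ValueError("half-red median is zero; fold change undefined")
    return float(np.median(red)) / denom


@dataclass(frozen=True)
class AucResult:
    """Rank-based ROC AUC with orientation folding."""

    raw: float  # P(positive value > negative value) + half ties
    auc: float  # folded so auc >= 0.5
    direction: int  # +1 if the positive stage tends higher, else -1


def roc_auc(values, labels, positive: str = "red") -> AucResult:
    """Rank-based (Mann–Whitney) ROC AUC with tie correction.

    ``raw`` is the probability that a random positive-class value exceeds
    a random negative-class value (ties counted half); ``auc`` is folded
    to >= 0.5 with the effect direction retained separately.
    """
    values = np.asarray(values, float)
    labels = np.asarray(labels)
    pos = labels == positive
    n1, n0 = int(pos.sum()), int((~pos).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    ranks = stats.rankdata(values)
    u = ranks[pos].sum() - n1 * (n1 + 1) / 2.0
    raw = float(u / (n1 * n0))
    return AucResult(raw=raw, auc=max(raw, 1.0 - raw), direction=1 if raw >= 0.5 else -1)


def auc_ci(
    values,
    labels,
    B: int = 2000,
    level: float = 0.95,
    seed: int = 0,
    positive: str = "red",
) -> tuple[float, float]:
    """Stratified-bootstrap percentile CI of the folded ROC AUC.

    Each class is resampled with replacement independently; the percentile
    interval of the folded AUC is returned.  Perfectly separated data give
    the degenerate interval (1.0, 1.0).
    """
    values = np.asarray(values, float)
    labels = np.asarray(labels)
    pos_vals = values[labels == positive]
    neg_vals = values[labels != positive]
    if pos_vals.size == 0 or neg_vals.size == 0:
        raise ValueError("both classes must be present")
    rng = np.random.default_rng(seed)
    boots = np.empty(B)
    lab = np.concatenate([np.ones(pos_vals.size, bool), np.zeros(neg_vals.size, bool)])
    for b in range(B):
        v = np.concatenate(
            [rng.choice(pos_vals, pos_vals.size), rng.choice(neg_vals, neg_vals.size)]
        )
        ranks = stats.rankdata(v)
        u = ranks[lab].sum() - pos_vals.size * (pos_vals.size + 1) / 2.0
        raw = u / (pos_vals.size * neg_vals.size)
        boots[b] = max(raw, 1.0 - raw)
    alpha = 1.0 - level
    lo, hi = np.percentile(boots, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return float(lo), float(hi)


def table_summary(
    table: pd.DataFrame,
    feature_cols=None,
    stage_col: str = "stage",
    sample_col: str = "sample_id",
    stages: tuple[str, str] = STAGES,
    delta: float = 0.05,
    B: int = 2000,
    seed: int = 0,
) -> pd.DataFrame:
    """Univariate battery over every feature column, one result row each.

    Columns per feature: stage medians and 5th/95th percentiles (linear
    interpolation), LME p-value, BH-adjusted p and significance flag at
    ``delta``, fold change in both ratio directions, folded AUC with
    bootstrap CI.
    """
    ref, pos = stages
    if feature_cols is None:
        meta = {stage_col, sample_col, "harvest", "replicate"}
        feature_cols = [c for c in table.columns if c not in meta]
    if len(feature_cols) == 0:
        return pd.DataFrame()
    rows = []
    pvals = []
    for feat in feature_cols:
        v = table[feat].to_numpy(float)
        lab = table[stage_col].to_numpy()
        v_pos, v_ref = v[lab == pos], v[lab == ref]
        res = lme_stage_test(v, lab, table[sample_col].to_numpy(), positive_stage=pos)
        auc = roc_auc(v, lab, positive=pos)
        ci = auc_ci(v, lab, B=B, seed=seed, positive=pos)
        fc = fold_change(v_pos, v_ref)
        rows.append(
            {
                "feature": feat,
                f"median_{ref}": float(np.median(v_ref)),
                f"p5_{ref}": float(np.percentile(v_ref, 5)),
                f"p95_{ref}": float(np.percentile(v_ref, 95)),
                f"median_{pos}": float(np.median(v_pos)),
                f"p5_{pos}": float(np.percentile(v_pos, 5)),
                f"p95_{pos}": float(np.percentile(v_pos, 95)),
                "p": res.p,
                "estimate": res.estimate,
                "FC": fc,
                "FC_reciprocal": 1.0 / fc,
                "AUC": auc.auc,
                "AUC_raw": auc.raw,
                "direction": auc.direction,
                "CI95_low": ci[0],
                "CI95_high": ci[1],
            }
        )
        pvals.append(res.p)
    out = pd.DataFrame(rows)
    adjusted, reject = benjamini_hochberg(np.array(pvals), delta=delta)
    out["p_adjusted"] = adjusted
    out["fdr_significant"] = reject
    return out


def format_results_table(res: pd.DataFrame, stages: tuple[str, str] = STAGES, dp: int = 3) -> pd.DataFrame:
    """Render results in the published layout: ``median [p5–p95]`` strings."""
    ref, pos = stages

    def cell(row, st):
        return (
            f"{row[f'median_{st}']:.{dp}f} "
            f"[{row[f'p5_{st}']:.{dp}f}–{row[f'p95_{st}']:.{dp}f}]"
        )

    return pd.DataFrame(
        {
            "ID": res["feature"],
            ref: [cell(r, ref) for _, r in res.iterrows()],
            pos: [cell(r, pos) for _, r in res.iterrows()],
            "p": res["p"].map(lambda p: "<0.001" if p < 0.001 else f"{p:.3f}"),
            "FC": res["FC"].round(dp),
            "AUC": res["AUC"].round(dp),
            "CI 95%": [
                f"{r['CI95_low']:.{dp}f}–{r['CI95_high']:.{dp}f}"
                for _, r in res.iterrows()
            ],
        }
    )
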