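"""The five-method causal-estimate battery plus multivariable IVW and BH-FDR.

Estimators operate on a :class:`~mrpipe.harmonization.HarmonizedSet` (or any
DataFrame with beta_exp/se_exp/beta_out/se_out columns):

* ``ivw`` — inverse-variance-weighted mean of per-variant Wald ratios, the
  primary estimator; default multiplicative random effects (SE scaled by
  max(1, √(Q/(k−1)))).
* ``egger`` — weighted regression of beta_out on beta_exp with a free
  intercept; the slope is the pleiotropy-robust estimate under InSIDE, the
  intercept tests directional pleiotropy.
* ``weighted_median`` — interpolated weighted median of the ratios;
  consistent when valid instruments carry >50% of the weight.
* ``mode_estimate`` — simple/weighted mode via a normal-kernel density over
  the ratios.
* ``mvmr_ivw`` — multivariable weighted regression through the origin for
  direct effects adjusted for co-exposures.

Odds ratios and 95% CIs are exp-transforms with a 1.96 normal multiplier.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "MRResult",
    "ivw",
    "egger",
    "weighted_median",
    "mode_estimate",
    "mvmr_ivw",
    "bh_fdr",
    "run_all_methods",
]

Z95 = 1.96


@dataclass
class MRResult:
    """One estimator's causal estimate on the log-odds (or SD) scale."""

    method: str
    nsnp: int
    beta: float
    se: float
    pval: float
    q_stat: float | None = None
    q_pval: float | None = None
    egger_intercept: float | None = None
    intercept_pval: float | None = None
    fdr_q: float | None = None
    exposure_id: str = ""
    outcome_id: str = ""
    extra: dict = field(default_factory=dict)

    @property
    def or_(self) -> float:
        return float(np.exp(self.beta))

    @property
    def ci_low(self) -> float:
        return float(np.exp(self.beta - Z95 * self.se))

    @property
    def ci_high(self) -> float:
        return float(np.exp(self.beta + Z95 * self.se))


def _arrays(hset):
    """Extract aligned effect arrays from a HarmonizedSet or DataFrame."""
    df = hset.retained if hasattr(hset, "retained") else hset
    bx = df["beta_exp"].to_numpy(dtype=float)
    sx = df["se_exp"].to_numpy(dtype=float)
    by = df["beta_out"].to_numpy(dtype=float)
    sy = df["se_out"].to_numpy(dtype=float)
    ids = df["variant_id"].to_numpy()
    return ids, bx, sx, by, sy


def _ids(hset):
    meta = {}
    if hasattr(hset, "exposure_id"):
        meta = {"exposure_id": hset.exposure_id, "outcome_id": hset.outcome_id}
    return meta


def _ratios_weights(bx, sx, by, sy):
    ratios = by / bx
    wald_se = sy / np.abs(bx)
    weights = 1.0 / wald_se**2
    return ratios, weights


def ivw(hset, effects_model: str = "multiplicative_random") -> MRResult:
    """Inverse-variance-weighted estimate across Wald ratios.

    ``effects_model``: "fixed" or "multiplicative_random" (default). The
    random-effects SE is the fixed SE scaled by max(1, √(Q/(k−1))), so it
    never undercuts the fixed model.
    """
    ids, bx, sx, by, sy = _arrays(hset)
    k = len(bx)
    if k < 2:
        raise ValueError("IVW requires at least 2 instruments")
    ratios, w = _ratios_weights(bx, sx, by, sy)
    beta = float(np.sum(w * ratios) / np.sum(w))
    se_fixed = float(1.0 / np.sqrt(np.sum(w)))
    q = float(np.sum(w * (ratios - beta) ** 2))
    scale = 1.0
    if effects_model == "multiplicative_random" and k > 1:
        scale = max(1.0, np.sqrt(q / (k - 1)))
    elif effects_model not in ("fixed", "multiplicative_random"):
        raise ValueError(f"unknown effects model {effects_model!r}")
    se = se_fixed * scale
    pval = float(2 * stats.norm.sf(abs(beta / se)))
    return MRResult("ivw", k, beta, se, pval,
                    q_stat=q, q_pval=float(stats.chi2.sf(q, k - 1)), **_ids(hset))


def egger(hset) -> MRResult:
    """MR-Egger weighted regression with intercept (pleiotropy test).

    Pairs are sign-oriented so beta_exp >= 0 before fitting; weights are
    1/se_out². Slope and intercept p-values use the t distribution on k−2 df
    with multiplicative residual scaling bounded below at 1.
    """
    ids, bx, sx, by, sy = _arrays(hset)
    k = len(bx)
    if k < 3:
        raise ValueError("MR-Egger requires at least 3 instruments")
    flip = np.sign(bx)
    flip[flip == 0] = 1
    x = bx * flip
    y = by * flip
    if np.allclose(x.var(), 0):
        raise ValueError("zero variance in exposure effects; Egger unidentified")
    w = 1.0 / sy**2
    X = np.column_stack([np.ones(k), x])
    WX = X * w[:, None]
    xtwx = X.T @ WX
    coef = np.linalg.solve(xtwx, WX.T @ y)
    resid = y - X @ coef
    sigma2 = float(np.sum(w * resid**2) / (k - 2))
    scale = max(1.0, sigma2)
    cov = np.linalg.inv(xtwx) * scale
    se_int, se_slope = np.sqrt(np.diag(cov))
    intercept, slope = coef
    p_slope = float(2 * stats.t.sf(abs(slope / se_slope), k - 2))
    p_int = float(2 * stats.t.sf(abs(intercept / se_int), k - 2))
    q = float(np.sum(w * resid**2))
    return MRResult("egger", k, float(slope), float(se_slope), p_slope,
                    q_stat=q, q_pval=float(stats.chi2.sf(q, k - 2)),
                    egger_intercept=float(intercept), intercept_pval=p_int, **_ids(hset))


def _weighted_median_point(ratios: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(ratios, kind="mergesort")
    r = ratios[order]
    w = weights[order] / weights.sum()
    # cumulative mid-point positions
    p = np.cumsum(w) - w / 2
    if 0.5 <= p[0]:
        return float(r[0])
    if 0.5 >= p[-1]:
        return float(r[-1])
    return float(np.interp(0.5, p, r))


def weighted_median(hset, n_boot: int = 1000, seed: int = 0) -> MRResult:
    """Weighted median of Wald ratios with parametric-bootstrap SE.

    With ``n_boot=0`` the SE (and p-value) are NaN — useful inside large
    simulations where only the point estimate matters.
    """
    ids, bx, sx, by, sy = _arrays(hset)
    k = len(bx)
    if k < 3:
        raise ValueError("weighted median requires at least 3 instruments")
    ratios, w = _ratios_weights(bx, sx, by, sy)
    beta = _weighted_median_point(ratios, w)
    se = pval = float("nan")
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        bxs = rng.normal(bx, sx, size=(n_boot, k))
        bys = rng.normal(by, sy, size=(n_boot, k))
        est = np.empty(n_boot)
        for i in range(n_boot):
            r_i = bys[i] / bxs[i]
            w_i = (bxs[i] / sy) ** 2
            est[i] = _weighted_median_point(r_i, w_i)
        se = float(est.std(ddof=1))
        pval = float(2 * stats.norm.sf(abs(beta / se))) if se > 0 else float(beta == 0)
    return MRResult("weighted_median", k, beta, se, pval, **_ids(hset))


def _mode_point(ratios, weights, bandwidth_factor=1.0, grid_points=2048):
    """Density-argmax of a normal-kernel KDE over the ratios.

    Bandwidth = factor × 1.4826·MAD(ratios); argmax ties break toward the
    median ratio.
    """
    mad = np.median(np.abs(ratios - np.median(ratios)))
    h = bandwidth_factor * 1.4826 * mad
    if h <= 0:
        return float(np.median(ratios))
    grid = np.linspace(ratios.min() - 3 * h, ratios.max() + 3 * h, grid_points)
    u = (grid[:, None] - ratios[None, :]) / h
    dens = (np.exp(-0.5 * u**2) * weights[None, :]).sum(axis=1)
    best = np.flatnonzero(dens == dens.max())
    if len(best) > 1:
        med = np.median(ratios)
        best = best[np.argmin(np.abs(grid[best] - med))]
    else:
        best = best[0]
    return float(grid[best])


def mode_estimate(
    hset,
    variant: str = "simple",
    bandwidth_factor: float = 1.0,
    n_boot: int = 1000,
    seed: int = 0,
) -> MRResult:
    """Simple or weighted mode-based estimate with bootstrap SE."""
    if variant not in ("simple", "weighted"):
        raise ValueError("variant must be simple|weighted")
    ids, bx, sx, by, sy = _arrays(hset)
    k = len(bx)
    if k < 3:
        raise ValueError("mode estimators require at least 3 instruments")
    ratios, w = _ratios_weights(bx, sx, by, sy)
    kw = w if variant == "weighted" else np.ones(k)
    if np.allclose(ratios, ratios[0]):
        return MRResult(f"{variant}_mode", k, float(ratios[0]), 0.0, 0.0, **_ids(hset))
    beta = _mode_point(ratios, kw, bandwidth_factor)
    se = pval = float("nan")
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        est = np.empty(n_boot)
        for i in range(n_boot):
            bxi = rng.normal(bx, sx)
            byi = rng.normal(by, sy)
            r_i = byi / bxi
            kw_i = (bxi / sy) ** 2 if variant == "weighted" else np.ones(k)
            est[i] = _mode_point(r_i, kw_i, bandwidth_factor, grid_points=512)
        se = float(est.std(ddof=1))
        pval = float(2 * stats.norm.sf(abs(beta / se))) if se > 0 else float("nan")
    return MRResult(f"{variant}_mode", k, beta, se, pval, **_ids(hset))


def wald_single(hset) -> MRResult:
    """Single-instrument Wald-ratio result (the k=1 fallback)."""
    ids, bx, sx, by, sy = _arrays(hset)
    if len(bx) != 1:
        raise ValueError("wald_single expects exactly one instrument")
    beta = float(by[0] / bx[0])
    se = float(sy[0] / abs(bx[0]))
    pval = float(2 * stats.norm.sf(abs(beta / se)))
    return MRResult("wald", 1, beta, se, pval, **_ids(hset))


def mvmr_ivw(multi_set: pd.DataFrame, exposure_cols: list | None = None) -> list:
    """Multivariable IVW: weighted regression of beta_out on exposure betas.

    ``multi_set`` comes from :func:`mrpipe.harmonization.harmonize_multi`.
    No intercept; weights 1/se_out². Returns one MRResult per exposure.
    """
    if exposure_cols is None:
        exposure_cols = [c for c in multi_set.columns
                         if c.startswith("beta_") and c != "beta_out"]
    k = len(multi_set)
    p = len(exposure_cols)
    if k < p + 2:
        raise ValueError(f"MVMR needs >= {p + 2} joint instruments, got {k}")
    X = multi_set[exposure_cols].to_numpy(dtype=float)
    y = multi_set["beta_out"].to_numpy(dtype=float)
    w = 1.0 / multi_set["se_out"].to_numpy(dtype=float) ** 2
    WX = X * w[:, None]
    xtwx = X.T @ WX
    if np.linalg.matrix_rank(xtwx) < p:
        raise ValueError("collinear exposures: rank-deficient MVMR design")
    coef = np.linalg.solve(xtwx, WX.T @ y)
    resid = y - X @ coef
    scale = max(1.0, float(np.sum(w * resid**2) / (k - p))) if k > p else 1.0
    cov = np.linalg.inv(xtwx) * scale
    ses = np.sqrt(np.diag(cov))
    results = []
    for col, b, s in zip(exposure_cols, coef, ses):
        pv = float(2 * stats.norm.sf(abs(b / s)))
        results.append(MRResult("mvmr_ivw", k, float(b), float(s), pv,
                                exposure_id=col.removeprefix("beta_")))
    return results


def bh_fdr(pvals) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, returned in input order."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    out = np.empty(m)
    out[order] = q_sorted
    return out


def run_all_methods(hset, n_boot: int = 1000, seed: int = 0) -> list:
    """Run the five-estimator battery, skipping methods the set is too small for.

    A 1-instrument set yields only the Wald ratio; 2 instruments only IVW.
    The returned list carries an ``extra['skipped']`` entry on a sentinel
    result when a method could not run, and a direction-agreement flag
    (all betas share a sign) on the IVW result.
    """
    df = hset.retained if hasattr(hset, "retained") else hset
    k = len(df)
    results = []
    if k == 1:
        return [wald_single(hset)]
    specs = [
        ("ivw", lambda: ivw(hset), 2),
        ("egger", lambda: egger(hset), 3),
        ("weighted_median", lambda: weighted_median(hset, n_boot, seed), 3),
        ("simple_mode", lambda: mode_estimate(hset, "simple", 1.0, n_boot, seed + 1), 3),
        ("weighted_mode", lambda: mode_estimate(hset, "weighted", 1.0, n_boot, seed + 2), 3),
    ]
    for name, fn, kmin in specs:
        if k < kmin:
            r = MRResult(name, k, float("nan"), float("nan"), float("nan"), **_ids(hset))
            r.extra["skipped"] = f"needs >= {kmin} instruments, have {k}"
            results.append(r)
        else:
            try:
                results.append(fn())
            except ValueError as exc:  # degenerate input for this method only
                r = MRResult(name, k, float("nan"), float("nan"), float("nan"), **_ids(hset))
                r.extra["skipped"] = str(exc)
                results.append(r)
    betas = [r.beta for r in results if np.isfinite(r.beta)]
    agree = len(betas) > 0 and (all(b > 0 for b in betas) or all(b < 0 for b in betas))
    results[0].extra["direction_agreement"] = bool(agree)
    return results


def results_table(results: list) -> pd.DataFrame:
    """Flatten MRResults into the reporting layout (OR, CI, p, FDR, Q, intercept)."""
    rows = []
    for r in results:
        rows.append({
            "exposure": r.exposure_id, "outcome": r.outcome_id, "method": r.method,
            "nsnp": r.nsnp, "beta": r.beta, "se": r.se,
            "or": r.or_ if np.isfinite(r.beta) else np.nan,
            "ci_low": r.ci_low if np.isfinite(r.beta) else np.nan,
            "ci_high": r.ci_high if np.isfinite(r.beta) else np.nan,
            "pval": r.pval, "fdr_q": r.fdr_q,
            "q_stat": r.q_stat, "q_pval": r.q_pval,
            "egger_intercept": r.egger_intercept, "intercept_pval": r.intercept_pval,
        })
    return pd.DataFrame(rows)
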