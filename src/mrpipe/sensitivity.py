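"""Heterogeneity, pleiotropy, direction and power diagnostics.

Cochran's Q, MR-PRESSO (global / outlier / distortion tests), radial MR,
leave-one-out, the Steiger directionality test, and a closed-form power
approximation for binary outcomes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .mr_estimators import MRResult, ivw, _arrays, _ratios_weights

__all__ = [
    "SensitivityReport",
    "cochran_q",
    "mr_presso",
    "radial_mr",
    "leave_one_out",
    "steiger_test",
    "power_binary",
    "run_sensitivity",
]


@dataclass
class SensitivityReport:
    q_stat: float | None = None
    q_df: int | None = None
    q_pval: float | None = None
    egger_intercept: float | None = None
    intercept_pval: float | None = None
    presso_global_pval: float | None = None
    presso_outliers: list = field(default_factory=list)
    presso_distortion_pval: float | None = None
    radial_beta: float | None = None
    radial_q_contributions: dict = field(default_factory=dict)
    radial_outliers: list = field(default_factory=list)
    loo_estimates: list = field(default_factory=list)
    loo_influential: list = field(default_factory=list)
    steiger_direction: bool | None = None
    steiger_pval: float | None = None
    power: float | None = None
    notes: dict = field(default_factory=dict)


def cochran_q(hset, ivw_beta: float | None = None) -> tuple:
    """Cochran's Q about the fixed-effects IVW estimate: (Q, df, p)."""
    ids, bx, sx, by, sy = _arrays(hset)
    k = len(bx)
    if k < 2:
        raise ValueError("Cochran Q requires at least 2 instruments")
    ratios, w = _ratios_weights(bx, sx, by, sy)
    if ivw_beta is None:
        ivw_beta = float(np.sum(w * ratios) / np.sum(w))
    q = float(np.sum(w * (ratios - ivw_beta) ** 2))
    df = k - 1
    return q, df, float(stats.chi2.sf(q, df))


def _loo_slopes(bx, by, w):
    """Leave-one-out IVW slopes (regression through the origin form)."""
    sxy = np.sum(w * bx * by)
    sxx = np.sum(w * bx**2)
    return (sxy - w * bx * by) / (sxx - w * bx**2)


def mr_presso(
    hset,
    n_sim: int = 1000,
    seed: int = 0,
    outlier_alpha: float = 0.05,
):
    """MR-PRESSO: global heterogeneity test, outlier flags, distortion test.

    The observed statistic is the weighted residual sum of squares of
    beta_out about leave-one-out IVW fits; the null distribution is built by
    redrawing beta_out,j ~ Normal(LOO fit_j, se_out,j) ``n_sim`` times.
    Per-variant outlier p-values are Bonferroni-compared to ``outlier_alpha``;
    the distortion p-value compares the with/without-outliers estimate shift
    against random same-size subsets.

    Returns ``(global_pval, outliers, distortion_pval, corrected_result)``.
    """
    ids, bx, sx, by, sy = _arrays(hset)
    k = len(bx)
    if k < 4:
        raise ValueError("MR-PRESSO requires at least 4 instruments")
    if n_sim < 100:
        raise ValueError("n_sim must be >= 100")
    rng = np.random.default_rng(seed)
    w = 1.0 / sy**2
    loo = _loo_slopes(bx, by, w)
    obs_contrib = w * (by - loo * bx) ** 2
    rss_obs = float(obs_contrib.sum())

    # simulated null: redraw outcome effects about the LOO fits
    by_sim = rng.normal(loo * bx, sy, size=(n_sim, k))
    sxy = by_sim @ (w * bx)
    sxx = float(np.sum(w * bx**2))
    loo_sim = (sxy[:, None] - w * bx * by_sim) / (sxx - w * bx**2)
    contrib_sim = w * (by_sim - loo_sim * bx) ** 2
    rss_sim = contrib_sim.sum(axis=1)
    global_pval = float((1 + np.sum(rss_sim >= rss_obs)) / (n_sim + 1))

    # per-variant outlier test against each variant's own simulated residuals;
    # empirical proportion (can reach 0) so Bonferroni keeps power at modest n_sim
    p_out = np.sum(contrib_sim >= obs_contrib[None, :], axis=0) / n_sim
    outliers = [ids[j] for j in range(k) if p_out[j] * k < outlier_alpha]

    distortion_pval = None
    corrected = None
    if outliers and len(outliers) < k - 1:
        mask = ~np.isin(ids, outliers)
        sub = _subframe(hset, mask)
        corrected = ivw(sub)
        full = ivw(hset)
        d_obs = abs(full.beta - corrected.beta)
        n_out = len(outliers)
        d_null = np.empty(min(n_sim, 500))
        for i in range(len(d_null)):
            drop = rng.choice(k, size=n_out, replace=False)
            msk = np.ones(k, dtype=bool)
            msk[drop] = False
            d_null[i] = abs(full.beta - ivw(_subframe(hset, msk)).beta)
        distortion_pval = float((1 + np.sum(d_null >= d_obs)) / (len(d_null) + 1))
    return global_pval, outliers, distortion_pval, corrected


def _subframe(hset, mask):
    df = hset.retained if hasattr(hset, "retained") else hset
    return df[np.asarray(mask, dtype=bool)]


def radial_mr(hset, alpha: float = 0.05):
    """Radial (modified second-order free) IVW with per-variant Q contributions.

    With first-order weights w_j, regress β_j·√w_j on √w_j through the
    origin; the slope is the radial IVW estimate and Q_j = w_j(β_j − slope)²
    decomposes Cochran's Q exactly. A variant is an outlier when its Q_j
    exceeds the upper-α χ²(1) point.
    """
    ids, bx, sx, by, sy = _arrays(hset)
    if len(bx) < 2:
        raise ValueError("radial MR requires at least 2 instruments")
    ratios, w = _ratios_weights(bx, sx, by, sy)
    sw = np.sqrt(w)
    slope = float(np.sum(sw * ratios * sw) / np.sum(sw * sw))  # == IVW fixed
    qj = w * (ratios - slope) ** 2
    pj = stats.chi2.sf(qj, 1)
    outliers = [ids[j] for j in range(len(ids)) if pj[j] < alpha]
    return slope, dict(zip(ids, qj)), outliers


def leave_one_out(hset) -> list:
    """IVW re-fit omitting each instrument in turn.

    Returns ``[(left_out_id, MRResult, influential), ...]`` where a variant
    is influential if its omission flips the sign of the estimate or moves
    it outside the full-set 95% CI.
    """
    ids, bx, sx, by, sy = _arrays(hset)
    k = len(bx)
    if k < 3:
        raise ValueError("leave-one-out requires at least 3 instruments")
    full = ivw(hset)
    lo = full.beta - 1.96 * full.se
    hi = full.beta + 1.96 * full.se
    out = []
    for j in range(k):
        mask = np.ones(k, dtype=bool)
        mask[j] = False
        r = ivw(_subframe(hset, mask))
        influential = (np.sign(r.beta) != np.sign(full.beta)) or not (lo <= r.beta <= hi)
        out.append((ids[j], r, bool(influential)))
    return out


def steiger_test(hset, exposure_n=None, outcome_n=None) -> tuple:
    """Directionality check: variance explained in exposure vs outcome.

    R² per side is Σ z²/(z²+n) over instruments; direction is correct when
    the instruments explain more of the exposure than of the outcome. The
    p-value is a two-sample z-test on the difference of Fisher-transformed
    correlations √R².
    """
    df = hset.retained if hasattr(hset, "retained") else hset
    if exposure_n is None:
        exposure_n = df["n_exp"].to_numpy(dtype=float)
    if outcome_n is None:
        outcome_n = df["n_out"].to_numpy(dtype=float)
    exposure_n = np.broadcast_to(np.asarray(exposure_n, dtype=float), (len(df),))
    outcome_n = np.broadcast_to(np.asarray(outcome_n, dtype=float), (len(df),))
    if np.any(~np.isfinite(exposure_n)) or np.any(~np.isfinite(outcome_n)):
        raise ValueError("Steiger test requires per-variant sample sizes")
    zx = (df["beta_exp"] / df["se_exp"]).to_numpy()
    zy = (df["beta_out"] / df["se_out"]).to_numpy()
    r2_exp = float(np.sum(zx**2 / (zx**2 + exposure_n)))
    r2_out = float(np.sum(zy**2 / (zy**2 + outcome_n)))
    r2_exp = min(r2_exp, 1 - 1e-12)
    r2_out = min(r2_out, 1 - 1e-12)
    nx = float(np.mean(exposure_n))
    ny = float(np.mean(outcome_n))
    fz = np.arctanh(np.sqrt(r2_exp)) - np.arctanh(np.sqrt(r2_out))
    se = np.sqrt(1.0 / (nx - 3) + 1.0 / (ny - 3))
    p = float(2 * stats.norm.sf(abs(fz / se)))
    return r2_exp > r2_out, p, r2_exp, r2_out


def power_binary(
    n_total: float,
    case_fraction: float,
    r2_sum: float,
    or_alt: float,
    alpha: float = 0.05,
) -> float:
    """Normal-approximation power for a binary-outcome MR estimate.

    Non-centrality z* = |ln OR|·√(n·r²·cf·(1−cf));
    power = Φ(z*−z_{1−α/2}) + Φ(−z*−z_{1−α/2}).
    """
    if r2_sum <= 0:
        raise ValueError("r2_sum must be positive")
    if not 0 < case_fraction < 1:
        raise ValueError("case_fraction must be in (0,1)")
    zc = stats.norm.isf(alpha / 2)
    zstar = abs(np.log(or_alt)) * np.sqrt(n_total * r2_sum * case_fraction * (1 - case_fraction))
    return float(stats.norm.cdf(zstar - zc) + stats.norm.cdf(-zstar - zc))


def run_sensitivity(
    hset,
    egger_result: MRResult | None = None,
    presso_nsim: int = 1000,
    presso_seed: int = 0,
    radial_alpha: float = 0.05,
    power_args: dict | None = None,
) -> SensitivityReport:
    """Assemble the full diagnostic report for one exposure-outcome pair."""
    rep = SensitivityReport()
    df = hset.retained if hasattr(hset, "retained") else hset
    k = len(df)
    if k >= 2:
        rep.q_stat, rep.q_df, rep.q_pval = cochran_q(hset)
        rep.radial_beta, rep.radial_q_contributions, rep.radial_outliers = radial_mr(
            hset, radial_alpha
        )
    if egger_result is not None:
        rep.egger_intercept = egger_result.egger_intercept
        rep.intercept_pval = egger_result.intercept_pval
    if k >= 4:
        g, out, dist, _ = mr_presso(hset, presso_nsim, presso_seed)
        rep.presso_global_pval, rep.presso_outliers, rep.presso_distortion_pval = g, out, dist
    else:
        rep.notes["presso"] = f"skipped: needs >= 4 instruments, have {k}"
    if k >= 3:
        loo = leave_one_out(hset)
        rep.loo_estimates = [(vid, r) for vid, r, _ in loo]
        rep.loo_influential = [vid for vid, _, infl in loo if infl]
    try:
        rep.steiger_direction, rep.steiger_pval, *_ = steiger_test(hset)
    except (ValueError, KeyError):
        rep.notes["steiger"] = "skipped: per-variant sample sizes unavailable"
    if power_args:
        rep.power = power_binary(**power_args)
    return rep
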