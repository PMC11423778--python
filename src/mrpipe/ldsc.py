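"""Lightweight LD-score regression: SNP-heritability and genetic correlation.

Univariate model: E[χ²_j] = 1 + n·h²·ℓ_j/M, fit by weighted regression of
χ² on ℓ with a free intercept (the intercept absorbs confounding/stratification;
1 under the null). Cross-trait model: E[z_1j·z_2j] = √(n1·n2)·ρg·ℓ_j/M plus a
free intercept that absorbs sample overlap; rg = ρg/√(h²_1·h²_2).

Weights follow the variance of the regressand — 1/(2·(1+n·ĥ²·ℓ/M)²) for χ²,
the product form for z-score products — starting from an unweighted fit and
iterating twice. Standard errors come from a delete-one-block jackknife over
contiguous variant blocks (default 50).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .harmonization import _match_orientation
from .sumstats_io import LDScores, SummaryStatsTable

__all__ = ["LdscResult", "ldsc_h2", "ldsc_rg"]

MIN_VARIANTS = 200


@dataclass
class LdscResult:
    h2_1: float | None = None
    h2_1_se: float | None = None
    h2_2: float | None = None
    h2_2_se: float | None = None
    intercept_1: float | None = None
    intercept_2: float | None = None
    cross_intercept: float | None = None
    rg: float | None = None
    rg_se: float | None = None
    rg_pval: float | None = None
    blocks_used: int = 0
    flags: list = field(default_factory=list)


def _block_sums(x, y, w, n_blocks):
    """Per-block cross-products for a weighted regression of y on [1, x]."""
    m = len(x)
    idx = np.array_split(np.arange(m), n_blocks)
    A = np.zeros((len(idx), 2, 2))
    b = np.zeros((len(idx), 2))
    for i, block in enumerate(idx):
        xb, yb, wb = x[block], y[block], w[block]
        A[i, 0, 0] = wb.sum()
        A[i, 0, 1] = A[i, 1, 0] = (wb * xb).sum()
        A[i, 1, 1] = (wb * xb**2).sum()
        b[i, 0] = (wb * yb).sum()
        b[i, 1] = (wb * xb * yb).sum()
    return A, b


def _solve(A, b):
    return np.linalg.solve(A, b)  # coef = (intercept, slope)


def _jackknife(A, b, transform):
    """Delete-one-block jackknife of ``transform(coef)`` (returns est array + SE)."""
    A_tot = A.sum(axis=0)
    b_tot = b.sum(axis=0)
    full = transform(_solve(A_tot, b_tot))
    B = len(A)
    deletes = np.array([transform(_solve(A_tot - A[i], b_tot - b[i])) for i in range(B)])
    se = np.sqrt((B - 1) / B * np.sum((deletes - deletes.mean()) ** 2))
    return full, float(se)


def _chi2_fit(ell, chi2, n, M, n_blocks):
    """Two-step weighted fit of χ² on ℓ. Returns (h2, intercept, A, b, weights)."""
    x = ell
    w = np.ones_like(x)
    coef = None
    for _ in range(3):  # unweighted init + two variance-weighted refits
        A, b = _block_sums(x, chi2, w, n_blocks)
        coef = _solve(A.sum(axis=0), b.sum(axis=0))
        h2_hat = max(coef[1] * M / n, 0.0)
        w = 1.0 / (2.0 * (1 + n * h2_hat * x / M) ** 2)
    A, b = _block_sums(x, chi2, w, n_blocks)
    coef = _solve(A.sum(axis=0), b.sum(axis=0))
    return coef[1] * M / n, coef[0], A, b, w


def ldsc_h2(
    table: SummaryStatsTable,
    ld_scores: LDScores,
    n: float | None = None,
    n_blocks: int = 50,
) -> LdscResult:
    """SNP-heritability and intercept for one trait."""
    df = table.records
    if len(df) < MIN_VARIANTS:
        raise ValueError(f"insufficient variants for LDSC ({len(df)} < {MIN_VARIANTS})")
    ell = ld_scores.for_variants(df["variant_id"])
    if np.any(~np.isfinite(ell)):
        raise ValueError("LD scores missing for some variants")
    if n is None:
        n = float(df["n"].median())
    M = ld_scores.M
    chi2 = (df["beta"] / df["se"]).to_numpy() ** 2
    _, _, A, b, _ = _chi2_fit(ell, chi2, n, M, n_blocks)
    h2, h2_se = _jackknife(A, b, lambda c: c[1] * M / n)
    intercept, int_se = _jackknife(A, b, lambda c: c[0])
    res = LdscResult(h2_1=float(h2), h2_1_se=h2_se, intercept_1=float(intercept),
                     blocks_used=n_blocks)
    res.flags.append(f"intercept_se={int_se:.4g}")
    return res


def _aligned_z(table1: SummaryStatsTable, table2: SummaryStatsTable):
    """Merge two tables and align trait-2 z-score signs to trait 1's alleles."""
    m = table1.records.merge(table2.records, on="variant_id", suffixes=("_1", "_2"))
    z1 = (m["beta_1"] / m["se_1"]).to_numpy()
    z2 = (m["beta_2"] / m["se_2"]).to_numpy()
    keep = np.ones(len(m), dtype=bool)
    for i, rec in enumerate(m.itertuples()):
        orient = _match_orientation(
            rec.effect_allele_1, rec.other_allele_1,
            rec.effect_allele_2, rec.other_allele_2,
        )
        if orient is None:
            keep[i] = False
        elif orient == "swapped":
            z2[i] = -z2[i]
    return m[keep], z1[keep], z2[keep]


def ldsc_rg(
    table1: SummaryStatsTable,
    table2: SummaryStatsTable,
    ld_scores: LDScores,
    n1: float | None = None,
    n2: float | None = None,
    n_blocks: int = 50,
) -> LdscResult:
    """Cross-trait genetic correlation with delete-one-block jackknife inference."""
    merged, z1, z2 = _aligned_z(table1, table2)
    if len(merged) < MIN_VARIANTS:
        raise ValueError(f"insufficient overlapping variants for LDSC ({len(merged)})")
    if n1 is None:
        n1 = float(merged["n_1"].median())
    if n2 is None:
        n2 = float(merged["n_2"].median())
    ell = ld_scores.for_variants(merged["variant_id"])
    if np.any(~np.isfinite(ell)):
        raise ValueError("LD scores missing for some variants")
    M = ld_scores.M

    h2_1, int_1, A1, b1, _ = _chi2_fit(ell, z1**2, n1, M, n_blocks)
    h2_2, int_2, A2, b2, _ = _chi2_fit(ell, z2**2, n2, M, n_blocks)
    res = LdscResult(h2_1=float(h2_1), h2_2=float(h2_2),
                     intercept_1=float(int_1), intercept_2=float(int_2),
                     blocks_used=n_blocks)
    res.h2_1_se = _jackknife(A1, b1, lambda c: c[1] * M / n1)[1]
    res.h2_2_se = _jackknife(A2, b2, lambda c: c[1] * M / n2)[1]
    if h2_1 <= 0 or h2_2 <= 0:
        res.flags.append("not evaluable: non-positive heritability estimate")
        return res

    # cross-trait regression of z1·z2 on ℓ, product-form variance weights
    y = z1 * z2
    v1 = 1 + n1 * max(h2_1, 0) * ell / M
    v2 = 1 + n2 * max(h2_2, 0) * ell / M
    w = np.ones_like(ell)
    for _ in range(2):
        Ac, bc = _block_sums(ell, y, w, n_blocks)
        coef = _solve(Ac.sum(axis=0), bc.sum(axis=0))
        cov_hat = coef[0] + coef[1] * ell
        w = 1.0 / (v1 * v2 + cov_hat**2)
    Ac, bc = _block_sums(ell, y, w, n_blocks)

    denom = np.sqrt(n1 * n2)

    def _rg_of(coefs):
        c1, c2, cc = coefs
        h1 = c1[1] * M / n1
        h2 = c2[1] * M / n2
        if h1 <= 0 or h2 <= 0:
            return np.nan
        rho_g = cc[1] * M / denom
        return rho_g / np.sqrt(h1 * h2)

    A1t, b1t = A1.sum(axis=0), b1.sum(axis=0)
    A2t, b2t = A2.sum(axis=0), b2.sum(axis=0)
    Act, bct = Ac.sum(axis=0), bc.sum(axis=0)
    rg_full = _rg_of((_solve(A1t, b1t), _solve(A2t, b2t), _solve(Act, bct)))
    B = n_blocks
    deletes = np.empty(B)
    for i in range(B):
        deletes[i] = _rg_of((
            _solve(A1t - A1[i], b1t - b1[i]),
            _solve(A2t - A2[i], b2t - b2[i]),
            _solve(Act - Ac[i], bct - bc[i]),
        ))
    good = np.isfinite(deletes)
    rg_se = float(np.sqrt((good.sum() - 1) / good.sum()
                          * np.sum((deletes[good] - deletes[good].mean()) ** 2)))
    res.cross_intercept = float(_solve(Act, bct)[0])
    res.rg = float(rg_full)
    res.rg_se = rg_se
    res.rg_pval = float(2 * stats.norm.sf(abs(rg_full / rg_se))) if rg_se > 0 else 0.0
    if not -1.25 <= rg_full <= 1.25:
        res.flags.append("rg outside numeric tolerance [-1.25, 1.25]")
    elif abs(rg_full) > 1:
        res.flags.append("rg outside [-1, 1]")
    return res
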