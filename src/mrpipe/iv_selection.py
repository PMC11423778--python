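"""Instrumental-variable selection: significance filter, LD clumping,
instrument-strength statistics, weak-instrument and confounder removal.

The five-step procedure: (1) keep variants with p < 1e-5 (locus-wide
significance); (2) greedy LD clumping at r² < 0.001 within a 10,000 kb
window; (3) palindrome/mismatch exclusion happens at harmonization;
(4) drop instruments with F < 10; (5) remove variants listed in a local
confounder blocklist (smoking, alcohol, air pollution). An exposure is
analyzable only if at least two instruments survive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .sumstats_io import LDMatrix, SummaryStatsTable

logger = logging.getLogger(__name__)

__all__ = [
    "IVStats",
    "filter_pvalue",
    "greedy_clump",
    "instrument_strength",
    "filter_weak",
    "filter_confounders",
    "require_min_instruments",
    "select_instruments",
]


@dataclass
class IVStats:
    variant_id: str
    r2_variant: float
    f_stat: float
    selected: bool = True
    rejection_reason: str = "none"


def filter_pvalue(table: SummaryStatsTable, threshold: float = 1e-5) -> SummaryStatsTable:
    """Keep rows with pval strictly below ``threshold``; stable input order."""
    mask = table.records["pval"] < threshold
    return table.subset(mask.to_numpy())


def greedy_clump(
    table: SummaryStatsTable,
    ld: LDMatrix | None,
    r2_max: float = 0.001,
    window_kb: float = 10_000,
) -> SummaryStatsTable:
    """Greedy p-value-ordered LD clumping.

    Variants are visited by ascending p-value (ties broken by chrom, pos,
    variant_id so output is independent of input row order); a variant is
    kept unless it lies within ``window_kb`` of an already-kept variant on
    the same chromosome AND has r² with it above ``r2_max``. Variants absent
    from the LD matrix are treated as unlinked (logged).
    """
    df = table.records
    if df.empty:
        return table.subset([])
    order = df.sort_values(
        ["pval", "chrom", "pos", "variant_id"], kind="mergesort"
    ).index
    if ld is not None:
        n_missing = sum(v not in ld for v in df["variant_id"])
        if n_missing:
            logger.info("%d variants absent from LD matrix; treated as unlinked", n_missing)
    kept: list = []  # (variant_id, chrom, pos)
    window_bp = window_kb * 1000
    for i in order:
        vid = df.at[i, "variant_id"]
        chrom, pos = df.at[i, "chrom"], df.at[i, "pos"]
        clumped = False
        for kvid, kchrom, kpos in kept:
            if chrom == kchrom and abs(pos - kpos) <= window_bp:
                r2 = ld.get(vid, kvid, 0.0) if ld is not None else 0.0
                if r2 > r2_max:
                    clumped = True
                    break
        if not clumped:
            kept.append((vid, chrom, pos))
    kept_ids = {v for v, _, _ in kept}
    return table.subset(df["variant_id"].isin(kept_ids).to_numpy())


def instrument_strength(
    beta: float, se: float, n: float, eaf: float | None = None, mode: str = "z_based"
) -> tuple:
    """Per-variant variance explained (r²) and F statistic.

    ``z_based``: r² = z²/(z²+n) with z = beta/se — robust when EAF is
    missing. ``eaf_based``: r² = 2·eaf·(1−eaf)·beta², the standardized-trait
    approximation. Either way F = r²·(n−2)/(1−r²).
    """
    if n <= 2:
        raise ValueError("instrument F undefined for n <= 2")
    if mode == "z_based":
        z = beta / se
        r2 = z**2 / (z**2 + n)
    elif mode == "eaf_based":
        if eaf is None or not 0 < eaf < 1:
            raise ValueError("eaf_based mode requires EAF in (0,1)")
        r2 = 2 * eaf * (1 - eaf) * beta**2
    else:
        raise ValueError(f"unknown mode {mode!r}")
    f = r2 * (n - 2) / (1 - r2)
    return float(r2), float(f)


def compute_iv_stats(table: SummaryStatsTable, mode: str = "z_based") -> pd.DataFrame:
    rows = []
    for rec in table.records.itertuples():
        eaf = rec.eaf if np.isfinite(rec.eaf) else None
        r2, f = instrument_strength(rec.beta, rec.se, rec.n, eaf, mode)
        rows.append((rec.variant_id, r2, f))
    return pd.DataFrame(rows, columns=["variant_id", "r2_variant", "f_stat"])


def filter_weak(
    table: SummaryStatsTable, f_min: float = 10.0, mode: str = "z_based"
) -> SummaryStatsTable:
    """Drop instruments with F strictly below ``f_min`` (reason: weak)."""
    if table.records.empty:
        return table
    stats_df = compute_iv_stats(table, mode)
    keep = stats_df["f_stat"] >= f_min
    for vid in stats_df.loc[~keep, "variant_id"]:
        logger.info("dropped %s: weak (F < %g)", vid, f_min)
    return table.subset(keep.to_numpy())


def filter_confounders(
    table: SummaryStatsTable, blocklist: pd.DataFrame | None
) -> SummaryStatsTable:
    """Remove variants associated with known confounder traits."""
    if blocklist is None or blocklist.empty:
        return table
    listed = table.records["variant_id"].isin(set(blocklist["variant_id"]))
    if listed.any():
        by_trait = blocklist.set_index("variant_id")["confounder_trait"]
        for vid in table.records.loc[listed, "variant_id"]:
            logger.info("dropped %s: confounder (%s)", vid, by_trait.get(vid, "?"))
    return table.subset((~listed).to_numpy())


def require_min_instruments(table: SummaryStatsTable, k_min: int = 2):
    """Pass the table through iff it has at least ``k_min`` instruments, else None."""
    if len(table) < k_min:
        logger.warning(
            "exposure %s unanalyzable: fewer than %d instruments (%d)",
            table.trait_id, k_min, len(table),
        )
        return None
    return table


def select_instruments(
    table: SummaryStatsTable,
    ld: LDMatrix | None = None,
    blocklist: pd.DataFrame | None = None,
    pval_threshold: float = 1e-5,
    clump_r2: float = 0.001,
    clump_window_kb: float = 10_000,
    f_min: float = 10.0,
    f_mode: str = "z_based",
    k_min: int = 2,
):
    """Run the full selection cascade; returns the instrument table or None."""
    out = filter_pvalue(table, pval_threshold)
    out = greedy_clump(out, ld, clump_r2, clump_window_kb)
    out = filter_weak(out, f_min, f_mode)
    out = filter_confounders(out, blocklist)
    return require_min_instruments(out, k_min)
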