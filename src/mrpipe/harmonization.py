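"""Align exposure and outcome effects to a shared effect allele.

For each variant present in both studies the outcome record is matched to the
exposure's allele coding: identical coding is kept as-is; swapped alleles
flip the sign of the outcome beta (and EAF → 1−EAF); a strand-complemented
match (A↔T, C↔G) is accepted before declaring a mismatch. Palindromic (A/T,
C/G) variants are strand-ambiguous: the default policy drops them all; an
EAF-inference policy keeps those whose allele frequencies on both sides are
far from 0.5 and orient the pair unambiguously.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .sumstats_io import SummaryStatsTable, is_palindromic

logger = logging.getLogger(__name__)

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: EAF window around 0.5 inside which palindromic orientation is not inferable
EAF_AMBIGUOUS = (0.42, 0.58)


@dataclass
class HarmonizedSet:
    """Analysis-ready exposure/outcome pairs sharing an effect allele.

    ``pairs`` columns: variant_id, beta_exp, se_exp, beta_out, se_out,
    eaf_exp, eaf_out, action_taken, wald_ratio, wald_se. Wald fields are set
    only for retained pairs with beta_exp != 0.
    """

    exposure_id: str
    outcome_id: str
    pairs: pd.DataFrame
    meta: dict = field(default_factory=dict)

    @property
    def retained(self) -> pd.DataFrame:
        mask = self.pairs["action_taken"].isin(["kept", "sign_flipped"])
        mask &= self.pairs["beta_exp"] != 0
        return self.pairs[mask]

    @property
    def n_retained(self) -> int:
        return len(self.retained)


def wald_ratio(beta_exp: float, beta_out: float, se_out: float) -> tuple:
    """Per-variant causal estimate beta_out/beta_exp with first-order SE."""
    if beta_exp == 0:
        raise ZeroDivisionError("Wald ratio undefined for beta_exp = 0")
    return beta_out / beta_exp, se_out / abs(beta_exp)


def _match_orientation(ea_x, oa_x, ea_y, oa_y):
    """How the outcome coding relates to the exposure coding.

    Returns 'same', 'swapped', or None (mismatch). Strand complements are
    tried before giving up.
    """
    if (ea_y, oa_y) == (ea_x, oa_x):
        return "same"
    if (ea_y, oa_y) == (oa_x, ea_x):
        return "swapped"
    cea, coa = _COMPLEMENT[ea_y], _COMPLEMENT[oa_y]
    if (cea, coa) == (ea_x, oa_x):
        return "same"
    if (cea, coa) == (oa_x, ea_x):
        return "swapped"
    return None


def harmonize(
    exposure: SummaryStatsTable,
    outcome: SummaryStatsTable,
    palindrome_policy: str = "drop_all",
) -> HarmonizedSet:
    """Inner-join the two studies on variant_id and align allele coding.

    ``palindrome_policy``: "drop_all" (default) removes every strand-ambiguous
    pair; "eaf_infer" keeps palindromic pairs whose EAFs on both sides fall
    outside (0.42, 0.58) and agree on orientation.
    """
    if palindrome_policy not in ("drop_all", "eaf_infer"):
        raise ValueError(f"unknown palindrome policy {palindrome_policy!r}")
    merged = exposure.records.merge(
        outcome.records, on="variant_id", suffixes=("_exp", "_out")
    )
    if merged.empty:
        logger.warning("harmonize: no shared variants between %s and %s",
                       exposure.trait_id, outcome.trait_id)
    rows = []
    for rec in merged.itertuples():
        ea_x, oa_x = rec.effect_allele_exp, rec.other_allele_exp
        ea_y, oa_y = rec.effect_allele_out, rec.other_allele_out
        beta_out, eaf_out = rec.beta_out, rec.eaf_out
        orient = _match_orientation(ea_x, oa_x, ea_y, oa_y)
        if orient is None:
            action = "removed_mismatch"
        elif is_palindromic(ea_x, oa_x):
            # any complemented "match" on a palindrome is inherently ambiguous
            if palindrome_policy == "drop_all":
                action = "removed_palindrome"
            else:
                lo, hi = EAF_AMBIGUOUS
                ex, ey = rec.eaf_exp, rec.eaf_out
                if pd.isna(ex) or pd.isna(ey) or lo < ex < hi or lo < ey < hi:
                    action = "removed_palindrome"
                else:
                    # orient by frequency: minor/major allele must agree
                    same_side = (ex < 0.5) == (ey < 0.5)
                    if same_side:
                        action = "kept"
                    else:
                        action = "sign_flipped"
                        beta_out = -beta_out
                        eaf_out = 1 - eaf_out
        elif orient == "same":
            action = "kept"
        else:
            action = "sign_flipped"
            beta_out = -beta_out
            eaf_out = 1 - eaf_out if pd.notna(eaf_out) else eaf_out
        wr = wse = float("nan")
        if action in ("kept", "sign_flipped") and rec.beta_exp != 0:
            wr, wse = wald_ratio(rec.beta_exp, beta_out, rec.se_out)
        rows.append(
            (rec.variant_id, rec.beta_exp, rec.se_exp, beta_out, rec.se_out,
             rec.eaf_exp, eaf_out, rec.pval_exp, rec.pval_out,
             rec.n_exp, rec.n_out, action, wr, wse)
        )
    pairs = pd.DataFrame(
        rows,
        columns=["variant_id", "beta_exp", "se_exp", "beta_out", "se_out",
                 "eaf_exp", "eaf_out", "pval_exp", "pval_out", "n_exp", "n_out",
                 "action_taken", "wald_ratio", "wald_se"],
    )
    return HarmonizedSet(exposure.trait_id, outcome.trait_id, pairs,
                         meta={"palindrome_policy": palindrome_policy})


def harmonize_multi(exposures: list, outcome: SummaryStatsTable) -> pd.DataFrame:
    """Joint harmonization of several exposures against one outcome (for MVMR).

    Every study is aligned to the first exposure's effect alleles; only
    variants present in all studies survive. Returns a frame with one
    beta/se column pair per exposure plus the outcome columns.
    """
    if len(exposures) == 1:
        hs = harmonize(exposures[0], outcome)
        ret = hs.retained
        out = ret[["variant_id", "beta_out", "se_out"]].copy()
        out[f"beta_{exposures[0].trait_id}"] = ret["beta_exp"].to_numpy()
        out[f"se_{exposures[0].trait_id}"] = ret["se_exp"].to_numpy()
        return out
    if len(exposures) < 1:
        raise ValueError("harmonize_multi needs at least one exposure")
    ref = exposures[0]
    frames = []
    for other in exposures[1:] + [outcome]:
        hs = harmonize(ref, other)
        ret = hs.retained.set_index("variant_id")
        frames.append(ret)
    common = frames[0].index
    for f in frames[1:]:
        common = common.intersection(f.index)
    k_needed = len(exposures) + 2
    if len(common) < k_needed:
        raise ValueError(
            f"insufficient joint instruments: {len(common)} shared variants, "
            f"need >= {k_needed}"
        )
    common = ref.records.set_index("variant_id").index.intersection(common)
    out = pd.DataFrame(index=common)
    ref_idx = ref.records.set_index("variant_id")
    out[f"beta_{ref.trait_id}"] = ref_idx.loc[common, "beta"]
    out[f"se_{ref.trait_id}"] = ref_idx.loc[common, "se"]
    for exp, frame in zip(exposures[1:], frames[:-1]):
        out[f"beta_{exp.trait_id}"] = frame.loc[common, "beta_out"]
        out[f"se_{exp.trait_id}"] = frame.loc[common, "se_out"]
    out["beta_out"] = frames[-1].loc[common, "beta_out"]
    out["se_out"] = frames[-1].loc[common, "se_out"]
    return out.reset_index().rename(columns={"index": "variant_id"})
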