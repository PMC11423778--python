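"""Readers, writers and validation for GWAS summary-statistic tables.

The canonical on-disk format is a tab-separated table with header columns

    variant_id chrom pos effect_allele other_allele eaf beta se pval n n_case n_control

Positions are 1-based and inclusive (GWAS-catalog convention). Alleles are
upper-cased on read; only single-nucleotide alleles (A/C/G/T) are accepted —
the pipeline is SNP-only. Auxiliary tables (LD matrix, LD scores, confounder
blocklist, variant→gene map, pathway library) are plain TSV as well.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

VALID_ALLELES = frozenset("ACGT")
PALINDROMIC_PAIRS = frozenset({("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")})

#: minimum p-value after underflow clamping
PVAL_FLOOR = 1e-300

CANONICAL_COLUMNS = [
    "variant_id",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "pval",
    "n",
    "n_case",
    "n_control",
]

REQUIRED_COLUMNS = ["variant_id", "effect_allele", "other_allele", "beta", "se", "pval", "n"]

#: column-name synonyms found in the wild; extend via the ``dialect`` argument
DEFAULT_DIALECT = {
    "SNP": "variant_id",
    "rsid": "variant_id",
    "rs_id": "variant_id",
    "MarkerName": "variant_id",
    "CHR": "chrom",
    "chr": "chrom",
    "chromosome": "chrom",
    "BP": "pos",
    "position": "pos",
    "base_pair_location": "pos",
    "A1": "effect_allele",
    "A2": "other_allele",
    "ALT": "effect_allele",
    "REF": "other_allele",
    "EA": "effect_allele",
    "NEA": "other_allele",
    "freq": "eaf",
    "FRQ": "eaf",
    "effect_allele_frequency": "eaf",
    "b": "beta",
    "BETA": "beta",
    "Effect": "beta",
    "SE": "se",
    "standard_error": "se",
    "p": "pval",
    "P": "pval",
    "p_value": "pval",
    "pvalue": "pval",
    "N": "n",
    "sample_size": "n",
    "Ncases": "n_case",
    "Ncontrols": "n_control",
}


def is_palindromic(effect_allele: str, other_allele: str) -> bool:
    """True for strand-ambiguous (A/T or C/G) allele pairs."""
    return (effect_allele, other_allele) in PALINDROMIC_PAIRS


@dataclass
class SummaryStatsTable:
    """One trait's per-variant GWAS associations.

    ``records`` is a DataFrame with the canonical columns. ``beta`` is on the
    log-odds scale for binary traits and in SD units for continuous traits.
    """

    trait_id: str
    records: pd.DataFrame
    trait_type: str = "continuous"  # continuous | binary
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.trait_type not in ("continuous", "binary"):
            raise ValueError(f"trait_type must be continuous|binary, got {self.trait_type!r}")
        dup = self.records["variant_id"].duplicated()
        if dup.any():
            dups = sorted(self.records.loc[dup, "variant_id"].unique().tolist())
            raise ValueError(f"duplicate variant_id in table {self.trait_id!r}: {dups}")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def n_variants(self) -> int:
        return len(self.records)

    def zscores(self) -> np.ndarray:
        return (self.records["beta"] / self.records["se"]).to_numpy()

    def subset(self, mask_or_ids) -> "SummaryStatsTable":
        """New table restricted to a boolean mask or an iterable of variant ids."""
        if isinstance(mask_or_ids, (pd.Series, np.ndarray, list)) and len(mask_or_ids) and isinstance(
            next(iter(mask_or_ids)), (bool, np.bool_)
        ):
            sub = self.records[np.asarray(mask_or_ids, dtype=bool)]
        else:
            ids = set(mask_or_ids)
            sub = self.records[self.records["variant_id"].isin(ids)]
        return SummaryStatsTable(self.trait_id, sub.reset_index(drop=True), self.trait_type, dict(self.meta))


@dataclass
class LDMatrix:
    """Squared-correlation (r²) matrix over an ordered list of variants."""

    variant_ids: list
    r2: np.ndarray

    def __post_init__(self) -> None:
        self.r2 = np.asarray(self.r2, dtype=float)
        k = len(self.variant_ids)
        if self.r2.shape != (k, k):
            raise ValueError("r2 matrix shape does not match variant list")
        if not np.allclose(self.r2, self.r2.T, atol=1e-10):
            raise ValueError("r2 matrix must be symmetric")
        if not np.allclose(np.diag(self.r2), 1.0, atol=1e-10):
            raise ValueError("r2 diagonal must be 1")
        if self.r2.min() < -1e-12 or self.r2.max() > 1 + 1e-12:
            raise ValueError("r2 values must lie in [0, 1]")
        self._index = {v: i for i, v in enumerate(self.variant_ids)}

    def get(self, id_a: str, id_b: str, default: float = 0.0) -> float:
        """r² between two variants; ``default`` if either is absent (treated as unlinked)."""
        ia = self._index.get(id_a)
        ib = self._index.get(id_b)
        if ia is None or ib is None:
            return default
        return float(self.r2[ia, ib])

    def __contains__(self, variant_id: str) -> bool:
        return variant_id in self._index


@dataclass
class LDScores:
    """Per-variant LD scores ℓ_j (≥ 1) and the reference panel size M."""

    scores: pd.DataFrame  # columns: variant_id, ld_score
    M: int

    def __post_init__(self) -> None:
        if (self.scores["ld_score"] < 1 - 1e-9).any():
            raise ValueError("LD scores must be >= 1 (a variant is in LD with itself)")
        if self.M <= 0:
            raise ValueError("reference size M must be positive")

    def for_variants(self, variant_ids) -> np.ndarray:
        s = self.scores.set_index("variant_id")["ld_score"]
        return s.reindex(variant_ids).to_numpy()


@dataclass
class PathwayLibrary:
    """Pathway sizes K against a library-wide background of N compounds."""

    pathways: pd.DataFrame  # columns: pathway_name, member_count
    background_size: int

    def __post_init__(self) -> None:
        if (self.pathways["member_count"] <= 0).any():
            raise ValueError("pathway member counts must be positive")
        if (self.pathways["member_count"] > self.background_size).any():
            raise ValueError("pathway larger than background")


class FormatError(ValueError):
    """A file does not conform to the expected tabular layout."""


def _apply_dialect(df: pd.DataFrame, dialect: dict | None) -> pd.DataFrame:
    mapping = dict(DEFAULT_DIALECT)
    if dialect:
        mapping.update(dialect)
    return df.rename(columns={c: mapping.get(c, c) for c in df.columns})


def read_sumstats(
    path,
    trait_id: str | None = None,
    trait_type: str = "continuous",
    dialect: dict | None = None,
) -> SummaryStatsTable:
    """Read and validate a summary-statistics TSV.

    Rows violating hard invariants (bad alleles, non-positive SE, EAF or p-value
    out of range) are rejected; every rejection is logged with a reason so that
    count(input) = count(accepted) + count(rejected).
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    df = _apply_dialect(df, dialect)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    for col in CANONICAL_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    df = df[CANONICAL_COLUMNS].copy()
    if df.empty:
        warnings.warn(f"{path}: header-only file, empty table", stacklevel=2)
        return SummaryStatsTable(trait_id or str(path), df, trait_type)

    df["effect_allele"] = df["effect_allele"].astype(str).str.upper()
    df["other_allele"] = df["other_allele"].astype(str).str.upper()

    # p = 0 underflow: clamp rather than reject
    df["pval"] = df["pval"].astype(float)
    underflow = df["pval"] == 0
    if underflow.any():
        warnings.warn(f"{int(underflow.sum())} p-values of 0 clamped to {PVAL_FLOOR}", stacklevel=2)
        df.loc[underflow, "pval"] = PVAL_FLOOR

    reasons = pd.Series("", index=df.index)

    def reject(mask, reason):
        fresh = mask & (reasons == "")
        reasons[fresh] = reason

    reject(~df["effect_allele"].isin(VALID_ALLELES) | ~df["other_allele"].isin(VALID_ALLELES),
           "non-SNP or invalid allele")
    reject(df["effect_allele"] == df["other_allele"], "identical alleles")
    reject(~(df["se"] > 0), "non-positive SE")
    reject(df["eaf"].notna() & ~((df["eaf"] > 0) & (df["eaf"] < 1)), "EAF outside (0,1)")
    reject(~((df["pval"] > 0) & (df["pval"] <= 1)), "p-value outside (0,1]")
    both = df["n_case"].notna() & df["n_control"].notna()
    reject(both & (df.loc[both, "n_case"] + df.loc[both, "n_control"] != df.loc[both, "n"]).reindex(df.index, fill_value=False),
           "n_case + n_control != n")

    rejected = df[reasons != ""]
    for vid, reason in zip(rejected["variant_id"], reasons[reasons != ""]):
        logger.warning("rejected %s: %s", vid, reason)
    accepted = df[reasons == ""].reset_index(drop=True)
    table = SummaryStatsTable(trait_id or str(path), accepted, trait_type)
    table.meta["n_rejected"] = int(len(rejected))
    table.meta["rejection_reasons"] = dict(zip(rejected["variant_id"], reasons[reasons != ""]))
    return table


def write_sumstats(table: SummaryStatsTable, path) -> None:
    """Write a table in the canonical column order (round-trips with read_sumstats)."""
    table.records[CANONICAL_COLUMNS].to_csv(path, sep="\t", index=False)


def validate_pz_consistency(table: SummaryStatsTable, tolerance: float = 0.5) -> pd.DataFrame:
    """Flag rows where the stated p-value disagrees with 2·Φ(−|beta/se|).

    ``tolerance`` is in −log10 units. Report-only: never mutates the table.
    """
    z = np.abs(table.records["beta"] / table.records["se"])
    p_expected = 2 * stats.norm.sf(z)
    p_expected = np.clip(p_expected, PVAL_FLOOR, 1.0)
    p_stated = np.clip(table.records["pval"].to_numpy(), PVAL_FLOOR, 1.0)
    dlog = np.abs(np.log10(p_expected) - np.log10(p_stated))
    return pd.DataFrame(
        {
            "variant_id": table.records["variant_id"],
            "pval_stated": p_stated,
            "pval_from_z": p_expected,
            "log10_discrepancy": dlog,
            "consistent": dlog <= tolerance,
        }
    )


def read_ld_matrix(path) -> LDMatrix:
    """Read a long-format LD table ``id_a id_b r2`` into a symmetric matrix."""
    df = pd.read_csv(path, sep="\t")
    ids = pd.unique(pd.concat([df["id_a"], df["id_b"]], ignore_index=True)).tolist()
    index = {v: i for i, v in enumerate(ids)}
    r2 = np.eye(len(ids))
    for a, b, v in zip(df["id_a"], df["id_b"], df["r2"]):
        r2[index[a], index[b]] = v
        r2[index[b], index[a]] = v
    return LDMatrix(ids, r2)


def write_ld_matrix(ld: LDMatrix, path) -> None:
    rows = []
    k = len(ld.variant_ids)
    for i in range(k):
        for j in range(i, k):
            if i == j or ld.r2[i, j] != 0:
                rows.append((ld.variant_ids[i], ld.variant_ids[j], ld.r2[i, j]))
    pd.DataFrame(rows, columns=["id_a", "id_b", "r2"]).to_csv(path, sep="\t", index=False)


def read_ld_scores(path, M: int | None = None) -> LDScores:
    """Read per-variant LD scores; ``M`` defaults to the number of rows."""
    df = pd.read_csv(path, sep="\t")
    return LDScores(df[["variant_id", "ld_score"]], M if M is not None else len(df))


def write_ld_scores(scores: LDScores, path) -> None:
    scores.scores.to_csv(path, sep="\t", index=False)


def read_blocklist(path) -> pd.DataFrame:
    """Confounder blocklist: ``variant_id  confounder_trait`` rows."""
    df = pd.read_csv(path, sep="\t")
    return df[["variant_id", "confounder_trait"]].drop_duplicates()


def read_gene_map(path) -> pd.DataFrame:
    """Variant→gene map: variant_id, gene_id, gene_name, chrom, start, end, strand."""
    return pd.read_csv(path, sep="\t", dtype={"chrom": str})


def read_pathway_library(path, background_size: int) -> PathwayLibrary:
    df = pd.read_csv(path, sep="\t")
    return PathwayLibrary(df[["pathway_name", "member_count"]], background_size)


def annotate_variants(table: SummaryStatsTable, gene_map: pd.DataFrame) -> pd.DataFrame:
    """Left-join variants onto a local variant→gene map.

    Unmapped variants carry gene_name="unmapped" and −1 coordinates, mirroring
    how annotation services leave non-genic variants blank.
    """
    cols = ["variant_id", "gene_id", "gene_name", "chrom", "start", "end", "strand"]
    if gene_map.empty:
        gene_map = pd.DataFrame(columns=cols)
    out = table.records[["variant_id"]].merge(
        gene_map[[c for c in cols if c in gene_map.columns]], on="variant_id", how="left"
    )
    for c in ("gene_id", "gene_name", "strand"):
        if c in out.columns:
            out[c] = out[c].fillna("unmapped")
        else:
            out[c] = "unmapped"
    for c in ("start", "end"):
        if c in out.columns:
            out[c] = pd.to_numeric(out[c], errors="coerce").fillna(-1).astype(int)
        else:
            out[c] = -1
    return out
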