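"""Synthetic GWAS summary-statistic generator with known ground truth.

Emulates three non-overlapping summary-statistic studies — a continuous
exposure (e.g. a gut-microbiome trait), a continuous mediator (e.g. a blood
metabolite) and a binary outcome on the log-odds scale (e.g. lung cancer) —
so that instrument selection, harmonization, the MR estimator battery,
mediation and LD-score regression can all be exercised against generating
parameters instead of downloaded accessions.

Generative model, per variant j with effect-allele frequency p_j:

* exposure instruments carry true effects b_j (half-normal, effect alleles
  oriented to the exposure-increasing allele) scaled so Σ 2p_j(1−p_j)b_j² =
  h2_exposure;
* the mediator owns its instruments c_j (scaled to h2_mediator) and inherits
  β1·b_j from the exposure;
* outcome log-odds effects are θ·b_j + β2·c_j + α_j·1[j invalid], with
  θ = δ + β1·β2 and direct pleiotropy α_j ~ N(μα, σα²) independent of b_j
  (InSIDE satisfied) unless correlated pleiotropy is switched on;
* each study's estimate is the true effect plus noise with SE =
  1/√(2p(1−p)·n); the binary outcome uses the effective size
  4/(1/n_case + 1/n_control);
* LD blocks of ``ld_block_size`` share noise correlation √(ld_block_r2), so
  within-block z-scores have squared correlation ld_block_r2, and the LD
  score of a variant is 1 + (block_size−1)·ld_block_r2;
* a ``palindromic_fraction`` of variants get A/T or C/G allele pairs with
  EAF drawn in (0.4, 0.6) so the strand ambiguity is real.

The three studies use independent noise substreams (no sample overlap); all
randomness derives from one master seed via deterministic child streams.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .sumstats_io import LDMatrix, LDScores, SummaryStatsTable

__all__ = [
    "SimulationConfig",
    "SimulationTruth",
    "StudySet",
    "simulate_study_set",
    "simulate_null_pair",
    "make_varied_ld_scores",
]

_NONPALINDROMIC = [("A", "C"), ("A", "G"), ("T", "C"), ("T", "G"), ("C", "A"), ("G", "A")]
_PALINDROMIC = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]


@dataclass
class SimulationConfig:
    """Generating parameters for one exposure/mediator/outcome study triplet.

    Sample sizes default to the source studies this generator stands in for:
    7,738 (microbiome), 8,299 (metabolites), 29,266 cases / 56,450 controls
    (lung cancer).
    """

    m_variants: int = 50          # exposure instruments
    m_mediator: int = 0           # mediator-specific instruments
    m_null: int = 0               # variants with no true effect anywhere
    n_exposure: int = 7738
    n_mediator: int = 8299
    n_case: int = 29266
    n_control: int = 56450
    theta: float = 0.1            # total exposure→outcome effect (log-odds per SD)
    beta1: float = 0.0            # exposure→mediator
    beta2: float = 0.0            # mediator→outcome (log-odds per SD)
    delta: float | None = None    # direct effect; defaults to theta − beta1·beta2
    pleio_mean: float = 0.0       # μα of the direct-pleiotropy law
    pleio_sd: float = 0.0         # σα
    invalid_fraction: float = 0.0
    correlated_pleiotropy: bool = False
    maf_range: tuple = (0.05, 0.5)
    h2_exposure: float = 0.2
    h2_mediator: float = 0.2
    ld_block_size: int = 1
    ld_block_r2: float = 0.0
    palindromic_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.invalid_fraction <= 1:
            raise ValueError("invalid_fraction must be in [0,1]")
        if not 0 <= self.palindromic_fraction <= 1:
            raise ValueError("palindromic_fraction must be in [0,1]")
        for name in ("n_exposure", "n_mediator", "n_case", "n_control"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.delta is None:
            self.delta = self.theta - self.beta1 * self.beta2
        elif abs(self.theta - (self.delta + self.beta1 * self.beta2)) > 1e-9:
            raise ValueError("inconsistent effects: theta must equal delta + beta1*beta2")

    @property
    def m_total(self) -> int:
        return self.m_variants + self.m_mediator + self.m_null

    @property
    def n_outcome_effective(self) -> float:
        return 4.0 / (1.0 / self.n_case + 1.0 / self.n_control)


@dataclass
class SimulationTruth:
    """Realized generating quantities, serialized alongside simulated outputs."""

    b_exposure: np.ndarray
    c_mediator: np.ndarray
    alpha: np.ndarray
    invalid: np.ndarray
    theta: float
    beta1: float
    beta2: float
    delta: float
    pleio_mean: float
    h2_exposure: float
    h2_mediator: float
    proportion_mediated: float
    seed: int

    def to_json(self, path) -> None:
        d = {k: (v.tolist() if isinstance(v, np.ndarray) else v) for k, v in asdict(self).items()}
        with open(path, "w") as fh:
            json.dump(d, fh, indent=1)


@dataclass
class StudySet:
    exposure: SummaryStatsTable
    mediator: SummaryStatsTable
    outcome: SummaryStatsTable
    ld: LDMatrix
    ld_scores: LDScores
    truth: SimulationTruth


def _block_sizes(m: int, block_size: int) -> list:
    sizes = [block_size] * (m // block_size)
    if m % block_size:
        sizes.append(m % block_size)
    return sizes


def _block_noise(rng: np.random.Generator, sizes: list, rho: float) -> np.ndarray:
    """Standard-normal noise, equicorrelated at ``rho`` within each block."""
    out = []
    for s in sizes:
        own = rng.standard_normal(s)
        if rho > 0 and s > 1:
            shared = rng.standard_normal()
            out.append(np.sqrt(rho) * shared + np.sqrt(1 - rho) * own)
        else:
            out.append(own)
    return np.concatenate(out) if out else np.array([])


def _sumstats_frame(ids, chrom, pos, ea, oa, eaf, beta, se, n, n_case=None, n_control=None):
    z = beta / se
    pval = np.clip(2 * stats.norm.sf(np.abs(z)), 1e-300, 1.0)
    return pd.DataFrame(
        {
            "variant_id": ids,
            "chrom": chrom,
            "pos": pos,
            "effect_allele": ea,
            "other_allele": oa,
            "eaf": eaf,
            "beta": beta,
            "se": se,
            "pval": pval,
            "n": n,
            "n_case": np.nan if n_case is None else n_case,
            "n_control": np.nan if n_control is None else n_control,
        }
    )


def simulate_study_set(config: SimulationConfig) -> StudySet:
    """Generate one exposure/mediator/outcome triplet plus LD structure and truth."""
    cfg = config
    m = cfg.m_total
    ss = np.random.SeedSequence(cfg.seed)
    rng_var, rng_exp, rng_med, rng_out, rng_pleio = (
        np.random.default_rng(c) for c in ss.spawn(5)
    )

    # --- variant scaffold -------------------------------------------------
    ids = np.array([f"rs{100000 + j}" for j in range(m)])
    sizes = _block_sizes(m, cfg.ld_block_size)
    block_of = np.repeat(np.arange(len(sizes)), sizes)
    # blocks 50 Mb apart (outside any clumping window), 10 kb spacing inside
    chrom = ((block_of % 22) + 1).astype(str)
    within = np.concatenate([np.arange(s) for s in sizes])
    pos = (block_of // 22 + 1) * 50_000_000 + within * 10_000 + 1

    n_pal = int(round(cfg.palindromic_fraction * m))
    pal_idx = rng_var.choice(m, size=n_pal, replace=False) if n_pal else np.array([], dtype=int)
    is_pal = np.zeros(m, dtype=bool)
    is_pal[pal_idx] = True
    ea = np.empty(m, dtype=object)
    oa = np.empty(m, dtype=object)
    for j in range(m):
        pool = _PALINDROMIC if is_pal[j] else _NONPALINDROMIC
        a, b = pool[rng_var.integers(len(pool))]
        ea[j], oa[j] = a, b
    eaf = rng_var.uniform(*cfg.maf_range, size=m)
    eaf[is_pal] = rng_var.uniform(0.4, 0.6, size=is_pal.sum())
    het = 2 * eaf * (1 - eaf)  # variance of the standardized genotype

    # --- true effects -----------------------------------------------------
    exp_idx = np.arange(cfg.m_variants)
    med_idx = np.arange(cfg.m_variants, cfg.m_variants + cfg.m_mediator)
    b = np.zeros(m)
    if cfg.m_variants:
        raw = np.abs(rng_var.standard_normal(cfg.m_variants))
        scale = np.sqrt(cfg.h2_exposure / np.sum(het[exp_idx] * raw**2))
        b[exp_idx] = raw * scale
    c = np.zeros(m)
    if cfg.m_mediator:
        raw = np.abs(rng_var.standard_normal(cfg.m_mediator))
        scale = np.sqrt(cfg.h2_mediator / np.sum(het[med_idx] * raw**2))
        c[med_idx] = raw * scale

    invalid = np.zeros(m, dtype=bool)
    alpha = np.zeros(m)
    n_invalid = int(round(cfg.invalid_fraction * cfg.m_variants))
    if n_invalid:
        chosen = rng_pleio.choice(exp_idx, size=n_invalid, replace=False)
        invalid[chosen] = True
        alpha[chosen] = rng_pleio.normal(cfg.pleio_mean, cfg.pleio_sd, size=n_invalid)
        if cfg.correlated_pleiotropy and cfg.m_variants > 1:
            bz = (b[chosen] - b[exp_idx].mean()) / (b[exp_idx].std() + 1e-12)
            alpha[chosen] += 0.5 * cfg.pleio_sd * bz  # stress-test switch; violates InSIDE

    # --- per-study noisy estimates ---------------------------------------
    rho = np.sqrt(cfg.ld_block_r2)
    se_exp = 1.0 / np.sqrt(het * cfg.n_exposure)
    se_med = 1.0 / np.sqrt(het * cfg.n_mediator)
    n_eff = cfg.n_outcome_effective
    se_out = 1.0 / np.sqrt(het * n_eff)

    beta_exp = b + se_exp * _block_noise(rng_exp, sizes, rho)
    beta_med = cfg.beta1 * b + c + se_med * _block_noise(rng_med, sizes, rho)
    beta_out = cfg.theta * b + cfg.beta2 * c + alpha + se_out * _block_noise(rng_out, sizes, rho)

    exposure = SummaryStatsTable(
        "sim_exposure",
        _sumstats_frame(ids, chrom, pos, ea, oa, eaf, beta_exp, se_exp, cfg.n_exposure),
        "continuous",
    )
    mediator = SummaryStatsTable(
        "sim_mediator",
        _sumstats_frame(ids, chrom, pos, ea, oa, eaf, beta_med, se_med, cfg.n_mediator),
        "continuous",
    )
    outcome = SummaryStatsTable(
        "sim_outcome",
        _sumstats_frame(
            ids, chrom, pos, ea, oa, eaf, beta_out, se_out,
            cfg.n_case + cfg.n_control, cfg.n_case, cfg.n_control,
        ),
        "binary",
    )

    # --- LD structure -----------------------------------------------------
    r2 = np.eye(m)
    start = 0
    for s in sizes:
        blk = slice(start, start + s)
        r2[blk, blk] = cfg.ld_block_r2
        start += s
    np.fill_diagonal(r2, 1.0)
    ld = LDMatrix(ids.tolist(), r2)
    ell = 1 + (np.asarray(sizes)[block_of] - 1) * cfg.ld_block_r2
    ld_scores = LDScores(pd.DataFrame({"variant_id": ids, "ld_score": ell}), M=m)

    prop = cfg.beta1 * cfg.beta2 / cfg.theta if cfg.theta != 0 else float("nan")
    truth = SimulationTruth(
        b_exposure=b, c_mediator=c, alpha=alpha, invalid=invalid,
        theta=cfg.theta, beta1=cfg.beta1, beta2=cfg.beta2, delta=cfg.delta,
        pleio_mean=cfg.pleio_mean, h2_exposure=cfg.h2_exposure,
        h2_mediator=cfg.h2_mediator, proportion_mediated=prop, seed=cfg.seed,
    )
    return StudySet(exposure, mediator, outcome, ld, ld_scores, truth)


def make_varied_ld_scores(m: int, max_block: int = 10, block_r2: float = 0.8) -> LDScores:
    """Deterministic LD-score reference with block sizes cycling 1..max_block.

    The spread in ℓ_j (from 1 up to 1 + (max_block−1)·r²) is what gives
    LD-score regression its leverage; uniform blocks would make the design
    nearly collinear with the intercept.
    """
    sizes = []
    total = 0
    k = 1
    while total < m:
        s = min(k, m - total)
        sizes.append(s)
        total += s
        k = k % max_block + 1
    block_of = np.repeat(np.arange(len(sizes)), sizes)
    ell = 1 + (np.asarray(sizes)[block_of] - 1) * block_r2
    ids = [f"rs{200000 + j}" for j in range(m)]
    return LDScores(pd.DataFrame({"variant_id": ids, "ld_score": ell}), M=m)


def simulate_null_pair(
    ld_scores: LDScores,
    n1: int,
    n2: int,
    h2_1: float,
    h2_2: float,
    rg: float,
    seed: int = 0,
    maf_range: tuple = (0.05, 0.5),
) -> tuple:
    """Two trait tables drawn from the LD-score regression moment conditions.

    Per variant j: Var(z_kj) = 1 + n_k·h²_k·ℓ_j/M and, with no sample overlap,
    E[z_1j·z_2j] = √(n1·n2)·ρg·ℓ_j/M where ρg = rg·√(h²_1·h²_2).
    """
    if not -1 <= rg <= 1:
        raise ValueError("rg must lie in [-1, 1]")
    rng = np.random.default_rng(seed)
    ell = ld_scores.scores["ld_score"].to_numpy()
    ids = ld_scores.scores["variant_id"].to_numpy()
    M = ld_scores.M
    m = len(ell)
    v1 = 1 + n1 * h2_1 * ell / M
    v2 = 1 + n2 * h2_2 * ell / M
    cov = np.sqrt(n1 * n2 * h2_1 * h2_2) * rg * ell / M
    u1 = rng.standard_normal(m)
    u2 = rng.standard_normal(m)
    z1 = np.sqrt(v1) * u1
    # conditional draw preserving the target covariance
    rho = cov / np.sqrt(v1 * v2)
    z2 = np.sqrt(v2) * (rho * u1 + np.sqrt(1 - rho**2) * u2)

    eaf = rng.uniform(*maf_range, size=m)
    het = 2 * eaf * (1 - eaf)
    alleles = [_NONPALINDROMIC[i] for i in rng.integers(len(_NONPALINDROMIC), size=m)]
    ea = np.array([a for a, _ in alleles])
    oa = np.array([o for _, o in alleles])
    chrom = np.repeat("1", m)
    pos = np.arange(1, m + 1) * 10_000

    tables = []
    for z, n in ((z1, n1), (z2, n2)):
        se = 1.0 / np.sqrt(het * n)
        tables.append(
            SummaryStatsTable(
                f"sim_trait{len(tables) + 1}",
                _sumstats_frame(ids, chrom, pos, ea, oa, eaf, z * se, se, n),
                "continuous",
            )
        )
    return tables[0], tables[1]
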