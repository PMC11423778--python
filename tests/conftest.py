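import numpy as np
import pandas as pd
import pytest

from mrpipe.harmonization import HarmonizedSet
from mrpipe.sumstats_io import SummaryStatsTable


def make_harmonized(ratios=None, wald_ses=None, beta_exp=None, se_exp=None,
                    beta_out=None, se_out=None, n_exp=10_000, n_out=50_000):
    """Build a HarmonizedSet directly from effect arrays.

    Either give per-variant (ratio, wald_se) pairs — realised with beta_exp=1 —
    or the four raw effect/SE arrays.
    """
    if ratios is not None:
        ratios = np.asarray(ratios, dtype=float)
        wald_ses = np.asarray(wald_ses, dtype=float)
        beta_exp = np.ones_like(ratios)
        se_exp = np.full_like(ratios, 1e-6)
        beta_out = ratios.copy()
        se_out = wald_ses.copy()
    beta_exp = np.asarray(beta_exp, dtype=float)
    k = len(beta_exp)
    df = pd.DataFrame({
        "variant_id": [f"rs{i}" for i in range(k)],
        "beta_exp": beta_exp,
        "se_exp": np.asarray(se_exp, dtype=float),
        "beta_out": np.asarray(beta_out, dtype=float),
        "se_out": np.asarray(se_out, dtype=float),
        "eaf_exp": 0.3, "eaf_out": 0.3,
        "pval_exp": 1e-8, "pval_out": 0.5,
        "n_exp": float(n_exp), "n_out": float(n_out),
        "action_taken": "kept",
    })
    df["wald_ratio"] = df["beta_out"] / df["beta_exp"]
    df["wald_se"] = df["se_out"] / df["beta_exp"].abs()
    return HarmonizedSet("exp", "out", df)


def make_table(rows, trait_id="trait", trait_type="continuous"):
    """SummaryStatsTable from a list of dicts with sensible column defaults."""
    defaults = {"chrom": "1", "pos": 1000, "effect_allele": "A", "other_allele": "G",
                "eaf": 0.3, "beta": 0.1, "se": 0.02, "pval": 1e-7, "n": 10_000,
                "n_case": np.nan, "n_control": np.nan}
    recs = []
    for i, row in enumerate(rows):
        r = dict(defaults)
        r.setdefault("variant_id", f"rs{i + 1}")
        r.update(row)
        recs.append(r)
    cols = ["variant_id", "chrom", "pos", "effect_allele", "other_allele",
            "eaf", "beta", "se", "pval", "n", "n_case", "n_control"]
    df = pd.DataFrame(recs, columns=cols) if recs else pd.DataFrame(columns=cols)
    return SummaryStatsTable(trait_id, df, trait_type)


@pytest.fixture
def simple_harmonized():
    """The worked three-instrument example: ratios (0.2, 0.15, 0.1), SEs (0.1, 0.05, 0.04)."""
    return make_harmonized(ratios=[0.2, 0.15, 0.1], wald_ses=[0.1, 0.05, 0.04])
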