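import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from mrpipe.iv_selection import (
    filter_confounders,
    filter_pvalue,
    filter_weak,
    greedy_clump,
    instrument_strength,
    require_min_instruments,
    select_instruments,
)
from mrpipe.sumstats_io import LDMatrix

from conftest import make_table


def clump_oracle(df, ld, r2_max, window_bp):
    """Recursive definition of the p-ordered maximal independent set.

    Take the best remaining variant, discard everything conflicting with it,
    recurse. Conflict = same chromosome, within window, r2 above threshold.
    """
    remaining = df.sort_values(["pval", "chrom", "pos", "variant_id"]).to_dict("records")
    kept = []
    while remaining:
        best = remaining.pop(0)
        kept.append(best["variant_id"])
        remaining = [
            r for r in remaining
            if not (
                r["chrom"] == best["chrom"]
                and abs(r["pos"] - best["pos"]) <= window_bp
                and ld.get(r["variant_id"], best["variant_id"], 0.0) > r2_max
            )
        ]
    return set(kept)


class TestFilterPvalue:
    def test_strict_threshold_boundary(self):
        t = make_table([{"pval": 1e-6}, {"pval": 1e-5}, {"pval": 1e-4}])
        kept = filter_pvalue(t, 1e-5)
        assert kept.records["variant_id"].tolist() == ["rs1"]

    def test_empty_table(self):
        t = make_table([])
        assert len(filter_pvalue(t)) == 0

    def test_genomewide_threshold_keeps_none(self):
        t = make_table([{"pval": 1e-6}, {"pval": 1e-5}, {"pval": 1e-4}])
        assert len(filter_pvalue(t, 5e-8)) == 0


class TestGreedyClump:
    def _ld(self, ids, pairs):
        k = len(ids)
        r2 = np.eye(k)
        idx = {v: i for i, v in enumerate(ids)}
        for a, b, v in pairs:
            r2[idx[a], idx[b]] = r2[idx[b], idx[a]] = v
        return LDMatrix(ids, r2)

    def test_linked_pair_keeps_best(self):
        t = make_table([
            {"variant_id": "v1", "pos": 1000, "pval": 1e-8},
            {"variant_id": "v2", "pos": 2000, "pval": 1e-7},
            {"variant_id": "v3", "pos": 3000, "pval": 1e-6},
        ])
        ld = self._ld(["v1", "v2", "v3"], [("v1", "v2", 0.5)])
        kept = greedy_clump(t, ld, r2_max=0.001, window_kb=10_000)
        assert set(kept.records["variant_id"]) == {"v1", "v3"}

    def test_unlinked_all_kept(self):
        t = make_table([{"variant_id": f"v{i}", "pos": i * 1000, "pval": 10.0**-(8 - i)}
                        for i in range(5)])
        ld = self._ld([f"v{i}" for i in range(5)], [])
        assert len(greedy_clump(t, ld)) == 5

    def test_window_gates_ld_test(self):
        """High r2 outside the window does not clump."""
        t = make_table([
            {"variant_id": "v1", "pos": 1_000, "pval": 1e-8},
            {"variant_id": "v2", "pos": 20_001_000, "pval": 1e-7},
        ])
        ld = self._ld(["v1", "v2"], [("v1", "v2", 0.9)])
        kept = greedy_clump(t, ld, r2_max=0.001, window_kb=10_000)
        assert len(kept) == 2

    def test_matches_exhaustive_oracle_random_instances(self):
        """Greedy clumping equals the p-ordered maximal independent set (<=15 variants)."""
        rng = np.random.default_rng(42)
        for trial in range(30):
            k = int(rng.integers(2, 16))
            ids = [f"v{i}" for i in range(k)]
            rows = [{"variant_id": ids[i],
                     "chrom": str(rng.integers(1, 3)),
                     "pos": int(rng.integers(1, 30_000_000)),
                     "pval": float(rng.uniform(1e-10, 1e-5))} for i in range(k)]
            r2 = np.eye(k)
            for i in range(k):
                for j in range(i + 1, k):
                    if rng.random() < 0.4:
                        r2[i, j] = r2[j, i] = rng.random()
            ld = LDMatrix(ids, r2)
            t = make_table(rows)
            kept = set(greedy_clump(t, ld).records["variant_id"])
            expected = clump_oracle(t.records, ld, 0.001, 10_000 * 1000)
            assert kept == expected, f"trial {trial}"

    def test_order_invariance(self):
        rng = np.random.default_rng(7)
        rows = [{"variant_id": f"v{i}", "chrom": "1", "pos": int(rng.integers(1, 5_000_000)),
                 "pval": float(rng.uniform(1e-9, 1e-5))} for i in range(10)]
        ids = [r["variant_id"] for r in rows]
        r2 = np.eye(10)
        r2[0, 1] = r2[1, 0] = 0.8
        r2[2, 5] = r2[5, 2] = 0.9
        ld = LDMatrix(ids, r2)
        ref = set(greedy_clump(make_table(rows), ld).records["variant_id"])
        perm = [rows[i] for i in rng.permutation(10)]
        assert set(greedy_clump(make_table(perm), ld).records["variant_id"]) == ref

    def test_no_kept_pair_violates_threshold(self):
        rng = np.random.default_rng(3)
        k = 12
        ids = [f"v{i}" for i in range(k)]
        rows = [{"variant_id": ids[i], "chrom": "1", "pos": int(rng.integers(1, 2_000_000)),
                 "pval": float(rng.uniform(1e-9, 1e-5))} for i in range(k)]
        r2 = np.eye(k)
        for i in range(k):
            for j in range(i + 1, k):
                r2[i, j] = r2[j, i] = rng.random() * 0.5
        ld = LDMatrix(ids, r2)
        t = make_table(rows)
        kept = greedy_clump(t, ld).records
        for i in range(len(kept)):
            for j in range(i + 1, len(kept)):
                a, b = kept.iloc[i], kept.iloc[j]
                if a["chrom"] == b["chrom"] and abs(a["pos"] - b["pos"]) <= 10_000_000:
                    assert ld.get(a["variant_id"], b["variant_id"]) <= 0.001


class TestInstrumentStrength:
    def test_eaf_based_hand_value(self):
        r2, _ = instrument_strength(beta=0.1, se=0.02, n=1000, eaf=0.5, mode="eaf_based")
        assert r2 == pytest.approx(0.005)

    def test_f_from_r2_hand_value(self):
        # r2 = 0.01 via z: z^2/(z^2+n) = 0.01 with n=1000 -> z^2 = 1000/99
        z2 = 1000 / 99
        z = np.sqrt(z2)
        r2, f = instrument_strength(beta=z, se=1.0, n=1000, mode="z_based")
        assert r2 == pytest.approx(0.01)
        assert f == pytest.approx(0.01 * 998 / 0.99, rel=1e-6)  # ~10.08

    def test_zero_beta(self):
        r2, f = instrument_strength(beta=0.0, se=0.1, n=1000, eaf=0.3, mode="eaf_based")
        assert r2 == 0 and f == 0

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            instrument_strength(0.1, 0.02, n=2)


class TestFilterWeak:
    def _table_with_f(self, f_target, n=1000):
        # invert F -> r2 -> z for an exact boundary construction
        r2 = f_target / (f_target + n - 2)
        z = np.sqrt(r2 * n / (1 - r2))
        return make_table([{"beta": z, "se": 1.0, "n": n}])

    def test_f_below_10_dropped(self):
        assert len(filter_weak(self._table_with_f(9.99))) == 0

    def test_f_at_10_kept(self):
        # removal is strictly F < 10; nudge above the boundary to dodge
        # floating-point round-off in the construction
        assert len(filter_weak(self._table_with_f(10.000001))) == 1

    def test_empty(self):
        assert len(filter_weak(make_table([]))) == 0


class TestConfounders:
    def test_blocklisted_removed(self):
        t = make_table([{"variant_id": "rs1"}, {"variant_id": "rs2"}])
        bl = pd.DataFrame({"variant_id": ["rs1"], "confounder_trait": ["smoking"]})
        assert filter_confounders(t, bl).records["variant_id"].tolist() == ["rs2"]

    def test_empty_blocklist_identity(self):
        t = make_table([{"variant_id": "rs1"}])
        assert len(filter_confounders(t, pd.DataFrame(columns=["variant_id", "confounder_trait"]))) == 1

    def test_all_listed_leaves_too_few(self):
        t = make_table([{"variant_id": "rs1"}, {"variant_id": "rs2"}])
        bl = pd.DataFrame({"variant_id": ["rs1", "rs2"],
                           "confounder_trait": ["smoking", "alcohol"]})
        out = filter_confounders(t, bl)
        assert len(out) == 0
        assert require_min_instruments(out) is None


@pytest.mark.parametrize("k, expected", [(0, None), (1, None), (2, 2)])
def test_min_instruments(k, expected):
    t = make_table([{"variant_id": f"rs{i}"} for i in range(k)])
    res = require_min_instruments(t, 2)
    if expected is None:
        assert res is None
    else:
        assert len(res) == expected


@given(st.lists(st.floats(min_value=1e-12, max_value=1.0), min_size=0, max_size=20))
@settings(deadline=None, derandomize=True)
def test_pvalue_filter_never_reorders(pvals):
    rows = [{"variant_id": f"rs{i}", "pval": p} for i, p in enumerate(pvals)]
    t = make_table(rows)
    kept = filter_pvalue(t, 1e-5)
    ids = kept.records["variant_id"].tolist()
    assert ids == [f"rs{i}" for i, p in enumerate(pvals) if p < 1e-5]


def test_full_cascade_runs():
    rows = [{"variant_id": f"rs{i}", "pos": 1000 + i * 100_000_000,
             "beta": 0.3, "se": 0.02, "pval": 1e-8} for i in range(5)]
    t = make_table(rows)
    out = select_instruments(t)
    assert out is not None and len(out) == 5
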