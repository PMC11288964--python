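"""t-tests, BH adjustment, and the differential-ratio pipeline."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from riboratio import (
    QuantTable,
    RatioMatrix,
    bh_adjust,
    compute_ratios,
    differential_ratio,
    two_sample_t,
    volcano_table,
)


def pooled_t_oracle(a, b):
    """Textbook pooled-variance two-sample t."""
    na, nb = len(a), len(b)
    sp2 = ((na - 1) * np.var(a, ddof=1) + (nb - 1) * np.var(b, ddof=1)) / (
        na + nb - 2
    )
    t = (np.mean(a) - np.mean(b)) / math.sqrt(sp2 * (1 / na + 1 / nb))
    p = 2 * stats.t.sf(abs(t), na + nb - 2)
    return t, p


def welch_t_oracle(a, b):
    na, nb = len(a), len(b)
    va, vb = np.var(a, ddof=1) / na, np.var(b, ddof=1) / nb
    t = (np.mean(a) - np.mean(b)) / math.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (na - 1) + vb**2 / (nb - 1))
    p = 2 * stats.t.sf(abs(t), df)
    return t, p


def bh_oracle(p):
    """Step-up BH by direct enumeration of the definition."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    for rank_i, idx in enumerate(order):
        candidates = [
            m * p[order[j]] / (j + 1) for j in range(rank_i, m)
        ]
        adj[idx] = min(1.0, min(candidates))
    return adj


class TestTwoSampleT:
    def test_textbook_example_student(self):
        t, p = two_sample_t([1, 2, 3], [4, 5, 6], "student")
        t_ref, p_ref = pooled_t_oracle([1, 2, 3], [4, 5, 6])
        assert t == pytest.approx(t_ref, abs=1e-10)
        assert t == pytest.approx(-3.6742346141747673, abs=1e-9)
        assert p == pytest.approx(p_ref, abs=1e-10)
        assert p == pytest.approx(0.021311641128756727, abs=1e-6)

    def test_identical_groups_null(self):
        t, p = two_sample_t([2, 3, 4], [2, 3, 4])
        assert t == 0.0 and p == 1.0

    def test_degenerate_variance_flagged(self):
        t, p = two_sample_t([1, 1, 1], [2, 2, 2])
        assert math.isnan(t) and math.isnan(p)

    def test_too_few_observations_error(self):
        with pytest.raises(ValueError, match=">= 2 observations"):
            two_sample_t([1.0], [2.0, 3.0])

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 2**31 - 1))
    def test_matches_closed_form_random(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(size=rng.integers(2, 8))
        b = rng.normal(loc=0.3, size=rng.integers(2, 8))
        for variant, oracle in (
            ("student", pooled_t_oracle), ("welch", welch_t_oracle)
        ):
            t, p = two_sample_t(a, b, variant)
            t_ref, p_ref = oracle(a, b)
            assert t == pytest.approx(t_ref, abs=1e-10)
            assert p == pytest.approx(p_ref, abs=1e-10)


class TestBHAdjust:
    def test_enumerated_example(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_p_unchanged(self):
        assert bh_adjust([0.03])[0] == pytest.approx(0.03)

    def test_equal_ps_monotone_cap(self):
        np.testing.assert_allclose(bh_adjust([0.2] * 5), [0.2] * 5)

    def test_missing_entries_excluded_from_family(self):
        p = np.array([0.01, np.nan, 0.02])
        adj = bh_adjust(p)
        assert np.isnan(adj[1])
        np.testing.assert_allclose(adj[[0, 2]], bh_oracle([0.01, 0.02]))

    def test_out_of_range_errors(self):
        for bad in ([0.0, 0.5], [0.5, 1.5]):
            with pytest.raises(ValueError, match="p-values"):
                bh_adjust(bad)

    @settings(max_examples=150, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 2**31 - 1))
    def test_matches_bruteforce_random(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.uniform(1e-12, 1.0, size=rng.integers(1, 40))
        np.testing.assert_allclose(bh_adjust(p), bh_oracle(p), rtol=1e-12)

    def test_adjusted_at_least_raw(self):
        rng = np.random.default_rng(9)
        p = rng.uniform(1e-6, 1, size=30)
        assert (bh_adjust(p) >= p - 1e-15).all()


def _ratio_fixture(rng, n_rp=20, na=4, nb=4, shift_idx=(), fold=2.0):
    base = rng.dirichlet(np.full(n_rp, 5.0))
    cols = {}
    groups = {}
    for i in range(na):
        cols[f"a{i}"] = base * rng.lognormal(0, 0.1, n_rp)
        groups[f"a{i}"] = "A"
    shifted = base.copy()
    for idx in shift_idx:
        shifted[idx] *= fold
    shifted /= shifted.sum()
    for i in range(nb):
        cols[f"b{i}"] = shifted * rng.lognormal(0, 0.1, n_rp)
        groups[f"b{i}"] = "B"
    frame = pd.DataFrame(cols, index=[f"RP{i}" for i in range(n_rp)])
    quant = QuantTable(frame, groups)
    return compute_ratios(quant)


class TestDifferentialRatio:
    def test_exact_null_all_ns(self):
        rng = np.random.default_rng(10)
        ratios = _ratio_fixture(rng)
        # group B = copy of group A samples
        frame = ratios.ratios
        copied = frame[["a0", "a1", "a2", "a3"]].copy()
        copied.columns = ["b0", "b1", "b2", "b3"]
        both = pd.concat([frame[["a0", "a1", "a2", "a3"]], copied], axis=1)
        groups = {c: ("A" if c.startswith("a") else "B") for c in both.columns}
        diff = differential_ratio(RatioMatrix(both, groups), "A", "B")
        assert (diff.table["direction"] == "ns").all()

    def test_unknown_group_errors(self):
        rng = np.random.default_rng(11)
        ratios = _ratio_fixture(rng)
        with pytest.raises(ValueError, match="group label"):
            differential_ratio(ratios, "A", "nope")

    def test_min_detection_rule(self):
        rng = np.random.default_rng(12)
        ratios = _ratio_fixture(rng)
        frame = ratios.ratios.copy()
        frame.iloc[0, [0, 1, 2]] = np.nan  # one A value left for RP0
        diff = differential_ratio(
            RatioMatrix(frame, ratios.sample_groups), "A", "B"
        )
        assert not diff.table.loc["RP0", "tested"]
        assert diff.table.loc["RP0", "direction"] == ""

    def test_permutation_invariance_within_groups(self):
        rng = np.random.default_rng(13)
        ratios = _ratio_fixture(rng, shift_idx=(2, 5), fold=3.0)
        perm = ["a2", "a0", "a3", "a1", "b1", "b3", "b0", "b2"]
        shuffled = RatioMatrix(
            ratios.ratios[perm], dict(ratios.sample_groups)
        )
        d1 = differential_ratio(ratios, "A", "B")
        d2 = differential_ratio(shuffled, "A", "B")
        pd.testing.assert_series_equal(
            d1.table["direction"], d2.table["direction"]
        )

    def test_direction_semantics_and_log2fc_sign(self):
        rng = np.random.default_rng(14)
        ratios = _ratio_fixture(rng, na=6, nb=6, shift_idx=(3,), fold=4.0)
        diff = differential_ratio(ratios, "A", "B")
        # RP3 is higher in B, so A-vs-B is "down"
        assert diff.table.loc["RP3", "direction"] == "down"
        assert diff.table.loc["RP3", "log2fc"] < 0

    def test_monotone_direction_path_through_ns(self):
        """Scaling one RP's group-B values up along a grid can change its
        call from up to down only by passing through ns."""
        rng = np.random.default_rng(15)
        path = []
        for factor in [0.2, 0.5, 0.8, 1.0, 1.25, 2.0, 5.0]:
            ratios = _ratio_fixture(rng=np.random.default_rng(15),
                                    na=5, nb=5)
            frame = ratios.ratios.copy()
            bcols = [c for c in frame.columns if c.startswith("b")]
            frame.loc["RP0", bcols] *= factor
            diff = differential_ratio(
                RatioMatrix(frame, ratios.sample_groups), "A", "B"
            )
            path.append(diff.table.loc["RP0", "direction"])
        coded = [{"up": 1, "ns": 0, "down": -1}[c] for c in path]
        for a, b in zip(coded, coded[1:]):
            assert abs(a - b) <= 1  # no direct up<->down flip

    def test_level_mode_detects_global_downshift(self):
        """A uniform 3-fold intensity drop in one group is invisible to
        ratio mode but called on every RP by level mode."""
        rng = np.random.default_rng(16)
        n_rp = 15
        base = rng.dirichlet(np.full(n_rp, 5.0)) * 1e9
        cols, groups = {}, {}
        for i in range(4):
            cols[f"a{i}"] = base * rng.lognormal(0, 0.05, n_rp)
            groups[f"a{i}"] = "spleen"
        for i in range(4):
            cols[f"b{i}"] = base / 3.0 * rng.lognormal(0, 0.05, n_rp)
            groups[f"b{i}"] = "fat"
        quant = QuantTable(
            pd.DataFrame(cols, index=[f"RP{i}" for i in range(n_rp)]), groups
        )
        level = differential_ratio(quant, "fat", "spleen", mode="level")
        assert (level.table["direction"] == "down").all()
        ratio = differential_ratio(
            compute_ratios(quant), "fat", "spleen", mode="ratio"
        )
        assert (ratio.table["direction"] == "ns").all()

    def test_mode_type_guards(self):
        rng = np.random.default_rng(17)
        ratios = _ratio_fixture(rng)
        with pytest.raises(ValueError, match="level mode"):
            differential_ratio(ratios, "A", "B", mode="level")


class TestVolcano:
    def test_boundary_and_zero_fc_are_ns(self):
        rng = np.random.default_rng(18)
        ratios = _ratio_fixture(rng)
        diff = differential_ratio(ratios, "A", "B")
        # exact threshold: p_adj == alpha must not be significant
        t = diff.table.copy()
        t.loc[t.index[0], "p_adj"] = diff.alpha
        t.loc[t.index[0], "direction"] = "ns"
        vt = volcano_table(diff)
        assert set(vt.columns) == {"log2fc", "neg_log10_p_adj", "direction"}
        assert len(vt) == len(diff.table)

    def test_planted_paralog_rises_in_testis_design(self):
        from riboratio import generate_dataset, preset

        quant, _ = generate_dataset(preset("testis4", seed=2))
        ratios = compute_ratios(quant)
        diff = differential_ratio(ratios, "day28", "day14")
        vt = volcano_table(diff)
        assert vt.loc["RPL10L", "direction"] == "up"
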