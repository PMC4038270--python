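"""Non-compensatory group indices, GPI, classes and the enumeration oracle."""

import math
from itertools import islice

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from riverpress.harmonize import HarmonizedSite
from riverpress.schema import (
    AGGREGATED_CODE,
    MORPH_INSTREAM,
    VARIABLE_ORDER,
    PressureValueError,
    schema_map,
)
from riverpress.scoring import (
    UndefinedIndexError,
    combination_category,
    enumerate_all_configurations,
    gpi,
    gpi_class,
    group_index,
    oracle_summary,
    score_frame,
    score_values,
    theoretical_gpi_max,
)

values_in_range = st.lists(
    st.floats(min_value=1.0, max_value=5.0, allow_nan=False), min_size=1, max_size=6
)


def site_values(**overrides):
    """Harmonised value mapping with every variable at 1 unless overridden.

    Instream-morphology raw values may be given; the aggregate is derived.
    """
    raw = {c: 1.0 for c in VARIABLE_ORDER}
    raw.update(overrides)
    values = {c: raw[c] for c in VARIABLE_ORDER if c not in MORPH_INSTREAM}
    instream = [raw[c] for c in MORPH_INSTREAM if raw[c] is not None]
    values[AGGREGATED_CODE] = sum(instream) / len(instream) if instream else None
    return values


class TestGroupIndex:
    @pytest.mark.parametrize("vals,expected", [
        ((1, 3, 5), 4.0),        # printed worked example
        ((1, 1, 1), 1.0),
        ((1, 2, 5), 5.0),
        ((3, 3, 3), 3.0),
        ((1, 2), 1.5),
        ((5,), 5.0),
    ])
    def test_conditional_mean(self, vals, expected):
        assert group_index(vals) == pytest.approx(expected)

    def test_empty_set_is_undefined(self):
        with pytest.raises(UndefinedIndexError):
            group_index([])

    def test_out_of_range_rejected(self):
        with pytest.raises(PressureValueError):
            group_index([0.5, 3])

    @settings(max_examples=200, derandomize=True)
    @given(values_in_range)
    def test_bounds_and_threshold_biconditional(self, vals):
        idx = group_index(vals)
        assert 1.0 <= idx <= 5.0
        assert (idx >= 3.0) == any(v >= 3.0 for v in vals)

    @settings(max_examples=200, derandomize=True)
    @given(values_in_range)
    def test_non_compensation(self, vals):
        # a nearly-undisturbed value never changes an impacted group's index
        idx = group_index(vals)
        if idx >= 3.0:
            assert group_index(list(vals) + [1.0]) == pytest.approx(idx)

    @settings(max_examples=100, derandomize=True)
    @given(values_in_range, st.randoms(use_true_random=False))
    def test_permutation_invariance(self, vals, rnd):
        shuffled = list(vals)
        rnd.shuffle(shuffled)
        assert group_index(shuffled) == pytest.approx(group_index(vals))


class TestGpi:
    @pytest.mark.parametrize("indices,expected", [
        ((1, 1, 4, 1), 4.0),
        ((5, 5, 5, 5), 20.0),
        ((3, 3, 3, 3), 12.0),
        ((2.9, 2.9, 2.9, 2.9), 0.0),
        ((float("nan"), 4, 1, 1), 4.0),
    ])
    def test_sum_of_impacted_indices(self, indices, expected):
        assert gpi(indices) == pytest.approx(expected)

    def test_all_missing_is_missing(self):
        assert math.isnan(gpi([float("nan")] * 4))

    @pytest.mark.parametrize("g,expected", [
        (0.0, 0), (3.0, 1), (5.0, 1), (5.999, 1), (6.0, 2), (7.0, 2),
        (8.5, 2), (9.0, 3), (10.3, 3), (12.0, 4), (15.9667, 4), (20.0, 4),
    ])
    def test_class_bins(self, g, expected):
        assert gpi_class(g) == expected

    @pytest.mark.parametrize("bad", [-0.1, 20.5, float("nan")])
    def test_class_range_errors(self, bad):
        with pytest.raises(PressureValueError):
            gpi_class(bad)

    def test_class_non_decreasing_in_gpi(self):
        grid = np.r_[0.0, np.linspace(3, 20, 200)]
        classes = [gpi_class(g) for g in grid]
        assert classes == sorted(classes)


class TestCombination:
    @pytest.mark.parametrize("hmwc,expected", [
        ((1, 1, 4, 1), "W"),
        ((1, 1, 2, 3), "HMC"),
        ((1, 3, 3, 1), "W+HMC"),
        ((1, 1, 1, 1), "NoP"),
        ((float("nan"), float("nan"), 3, float("nan")), "W"),
    ])
    def test_split(self, hmwc, expected):
        assert combination_category(*hmwc) == expected


class TestScoreSite:
    def test_undisturbed_site(self):
        s = score_values(site_values(), site_id="u")
        assert (s.hpi, s.mpi, s.wqpi, s.cpi) == (1.0, 1.0, 1.0, 1.0)
        assert s.affected_groups == 0 and s.gpi == 0.0
        assert s.gpi_class == 0 and s.combination == "NoP"

    def test_water_quality_worked_example(self):
        s = score_values(site_values(W_acid=1, W_eutroph=3, W_opoll=5))
        assert s.wqpi == pytest.approx(4.0)
        assert s.affected_groups == 1
        assert s.gpi == pytest.approx(4.0)
        assert s.gpi_class == 1 and s.combination == "W"

    def test_every_variable_at_maximum(self, schema):
        s = score_values(site_values(**{c: float(sp.max_value)
                                        for c, sp in schema.items()}))
        assert s.hpi == pytest.approx(3.8)          # mean(5, 3, 5, 3, 3)
        assert s.mpi == pytest.approx(13 / 3)       # mean(5, 5, 3)
        assert s.wqpi == pytest.approx(13 / 3)      # mean(3, 5, 5)
        assert s.cpi == pytest.approx(3.5)          # mean(3, 4)
        assert s.gpi == pytest.approx(479 / 30)     # 15.9667
        assert s.gpi_class == 4

    def test_missing_group_contributes_nothing(self):
        vals = site_values(W_opoll=5.0)
        vals["C_B_s_up"] = vals["C_B_s_do"] = None
        s = score_values(vals)
        assert math.isnan(s.cpi)
        assert s.gpi == pytest.approx(5.0)
        assert s.n_groups_scored == 3 and not s.complete

    def test_fully_missing_site_is_unscorable(self):
        vals = {c: None for c in site_values()}
        s = score_values(vals, site_id="void")
        assert s.combination == "unscorable" and s.n_groups_scored == 0
        assert math.isnan(s.gpi)

    def test_score_site_matches_score_values(self):
        h = HarmonizedSite(
            site_id="h1",
            values={c: 1 for c in VARIABLE_ORDER if c not in MORPH_INSTREAM},
            m_morph_instr=11 / 3,
        )
        from riverpress.scoring import score_site
        s = score_site(h)
        assert s.mpi == pytest.approx(11 / 3)
        assert s.combination == "HMC"


class TestRestrictedMonotonicity:
    """Monotonicity holds away from threshold-crossing dilution.

    Raising a value that is already impacted, raising within a fully
    sub-threshold group, or crossing the threshold first in a group are
    all non-decreasing for the group index.
    """

    def test_raising_an_impacted_value(self):
        rng = np.random.default_rng(11)
        for _ in range(300):
            vals = list(rng.uniform(1, 5, size=rng.integers(1, 6)))
            impacted = [i for i, v in enumerate(vals) if v >= 3]
            if not impacted:
                continue
            i = impacted[0]
            before = group_index(vals)
            vals[i] = min(vals[i] + rng.uniform(0, 5 - vals[i]), 5.0)
            assert group_index(vals) >= before - 1e-12

    def test_raising_within_sub_threshold_group(self):
        rng = np.random.default_rng(12)
        for _ in range(300):
            vals = list(rng.uniform(1, 2.99, size=rng.integers(1, 6)))
            before = group_index(vals)
            i = rng.integers(len(vals))
            vals[i] = min(vals[i] + rng.uniform(0, 0.5), 2.99)
            assert group_index(vals) >= before - 1e-12

    def test_first_threshold_crossing_increases_index(self):
        rng = np.random.default_rng(13)
        for _ in range(300):
            vals = list(rng.uniform(1, 2.99, size=rng.integers(1, 6)))
            before = group_index(vals)
            i = rng.integers(len(vals))
            vals[i] = rng.uniform(3, 5)
            assert group_index(vals) >= before


class TestEnumerationOracle:
    def test_summary_statistics(self):
        osum = oracle_summary()
        assert osum.n_configurations == 1_492_992
        assert osum.gpi_min_positive == pytest.approx(3.0)
        assert osum.gpi_max == pytest.approx(theoretical_gpi_max())
        assert not osum.has_gap_values

    def test_gpi_zero_count_matches_combinatorial_count(self):
        # all-sub-threshold combinations per group: hydrology 1 (all vars 1);
        # morphology: 10 instream triples with sum < 9, x2 embankment in {1,2},
        # x1 flood protection; connectivity 1; water quality 1 -> 20 total
        assert oracle_summary().n_gpi_zero == 1 * (10 * 2 * 1) * 1 * 1

    def test_class_zero_is_exactly_gpi_zero(self):
        osum = oracle_summary()
        assert osum.class_counts[0] == osum.n_gpi_zero
        assert sum(osum.class_counts) == osum.n_configurations
        assert sum(osum.affected_counts) == osum.n_configurations

    def test_streamed_scores_agree_with_vectorised_summary(self):
        """Dual route: the scalar per-configuration scorer, streamed over the
        full Cartesian product, reproduces the vectorised summary exactly."""
        osum = oracle_summary()
        gmax = gmin_pos = None
        n_zero = 0
        class_counts = [0] * 5
        n = 0
        for _, s in enumerate_all_configurations():
            n += 1
            class_counts[s.gpi_class] += 1
            if s.gpi == 0:
                n_zero += 1
            elif gmin_pos is None or s.gpi < gmin_pos:
                gmin_pos = s.gpi
            if gmax is None or s.gpi > gmax:
                gmax = s.gpi
        assert n == osum.n_configurations
        assert gmax == pytest.approx(osum.gpi_max)
        assert gmin_pos == pytest.approx(osum.gpi_min_positive)
        assert n_zero == osum.n_gpi_zero
        assert tuple(class_counts) == osum.class_counts

    def test_stream_yields_valid_configurations(self, schema):
        for cfg, s in islice(enumerate_all_configurations(), 0, 5000, 97):
            for code, v in cfg.items():
                assert v in schema[code].allowed_values
            assert 3 * s.affected_groups <= s.gpi <= 5 * s.affected_groups \
                or s.affected_groups == 0


class TestScoreFrame:
    def test_matches_scalar_scorer_on_random_sites(self):
        import pandas as pd
        rng = np.random.default_rng(5)
        schema = schema_map()
        rows = []
        for i in range(200):
            row = {"site_id": f"r{i}"}
            for c in VARIABLE_ORDER:
                allowed = schema[c].allowed_values
                row[c] = float(allowed[rng.integers(len(allowed))])
                if rng.random() < 0.1:
                    row[c] = np.nan
            rows.append(row)
        raw = pd.DataFrame(rows)
        from riverpress.harmonize import harmonize_frame
        h = harmonize_frame(raw)
        vec = score_frame(h)
        for i in range(len(raw)):
            vals = {c: (None if np.isnan(raw.loc[i, c]) else raw.loc[i, c])
                    for c in VARIABLE_ORDER}
            s = score_values(site_values(**vals) if all(
                vals[c] is not None for c in MORPH_INSTREAM) else _values_with_missing(vals))
            for col, attr in [("HPI", "hpi"), ("MPI", "mpi"), ("WQPI", "wqpi"),
                              ("CPI", "cpi"), ("GPI", "gpi")]:
                got, want = vec.loc[i, col], getattr(s, attr)
                assert (math.isnan(got) and math.isnan(want)) or got == pytest.approx(want)
            assert vec.loc[i, "combination"] == s.combination


def _values_with_missing(raw_vals):
    values = {c: raw_vals[c] for c in VARIABLE_ORDER if c not in MORPH_INSTREAM}
    instream = [raw_vals[c] for c in MORPH_INSTREAM if raw_vals[c] is not None]
    values[AGGREGATED_CODE] = sum(instream) / len(instream) if instream else None
    return values
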