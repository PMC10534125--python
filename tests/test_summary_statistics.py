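"""Descriptive statistics, aggregate indices, compliance flags, rank test."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from pahrisk import (
    ConcentrationTable,
    eu_compliance,
    load_fixture,
    pah4,
    rank_sum_test,
    summarize,
    total_pah,
)
from pahrisk.summary_statistics import holm_adjust


def _mono_table(values, analyte="BaP"):
    rows = [
        {
            "sample_id": f"s{i}", "species": "carp", "cooking": "raw",
            "replicate": i + 1, "analyte": analyte, "concentration": v,
        }
        for i, v in enumerate(values)
    ]
    return ConcentrationTable(pd.DataFrame(rows))


class TestSummarize:
    def test_hand_computed_cell(self):
        out = summarize(_mono_table([1, 2, 3, 4]), include_aggregates=False)
        row = out.iloc[0]
        assert row["mean"] == 2.5
        assert row["median"] == 2.5
        assert row["min"] == 1 and row["max"] == 4
        assert row["sd"] == pytest.approx(1.29099, abs=1e-5)
        assert row["n"] == 4

    def test_constant_values_zero_sd(self):
        out = summarize(_mono_table([5, 5, 5]), include_aggregates=False)
        assert out.iloc[0]["mean"] == 5 and out.iloc[0]["sd"] == 0

    def test_single_record_sd_undefined(self):
        with pytest.warns(UserWarning, match="single record"):
            out = summarize(_mono_table([2.0]), include_aggregates=False)
        assert np.isnan(out.iloc[0]["sd"])

    def test_record_order_invariance(self, tiny_table):
        shuffled = ConcentrationTable(
            tiny_table.data.sample(frac=1, random_state=3).reset_index(drop=True)
        )
        a = summarize(tiny_table, include_aggregates=False)
        b = summarize(shuffled, include_aggregates=False)
        pd.testing.assert_frame_equal(
            a.sort_values("analyte").reset_index(drop=True),
            b.sort_values("analyte").reset_index(drop=True),
        )

    def test_large_sample_recovers_generator_target(self, table2):
        # method-of-moments recovery: generator calibrated to the pooled
        # BaP row, 10,000 draws, sample mean within 1% of the target
        from pahrisk import fit_distribution
        from pahrisk._rng import substream

        row = table2[table2["analyte"] == "BaP"].iloc[0]
        spec = fit_distribution(row)
        x = spec.sample(substream(11, "recovery"), 10_000)
        table = _mono_table(x)
        out = summarize(table, include_aggregates=False)
        assert out.iloc[0]["mean"] == pytest.approx(row["mean"], rel=0.01)


class TestAggregates:
    def test_table2_means_sum_to_printed_total(self, table2_means):
        assert total_pah(table2_means) == pytest.approx(20.31, abs=1e-9)

    def test_all_zeros(self):
        zeros = {a: 0.0 for a in table_analytes()}
        assert total_pah(zeros) == 0.0
        assert pah4(zeros) == 0.0

    def test_raw_fish_means_sum(self):
        t4 = load_fixture("table4_by_cooking")
        raw = t4[t4["cooking"] == "raw"]
        vals = {r["analyte"]: r["mean"] for _, r in raw.iterrows()
                if r["analyte"] in table_analytes()}
        assert total_pah(vals) == pytest.approx(16.44, abs=0.02)

    def test_pah4_raw_fish_exact(self):
        assert pah4({"BaA": 1.09, "Chr": 0.92, "BbF": 1.07, "BaP": 0.88}) == (
            pytest.approx(3.96, abs=1e-12)
        )

    def test_pah4_charcoal_within_rounding(self):
        val = pah4({"BaA": 1.63, "Chr": 1.37, "BbF": 1.66, "BaP": 1.31})
        assert val == pytest.approx(5.98, abs=0.02)

    def test_missing_member_named(self):
        with pytest.raises(KeyError, match="BbF"):
            pah4({"BaA": 1.0, "Chr": 1.0, "BaP": 1.0})

    def test_missing_analyte_policy(self):
        with pytest.raises(KeyError):
            total_pah({"BaP": 1.0})
        assert total_pah({"BaP": 1.0}, missing_as_zero=True) == 1.0

    @given(
        st.lists(st.floats(0, 100), min_size=16, max_size=16),
        st.floats(0.01, 10),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_linearity_and_permutation_invariance(self, values, alpha):
        analytes = table_analytes()
        base = dict(zip(analytes, values))
        scaled = {a: alpha * v for a, v in base.items()}
        assert total_pah(scaled) == pytest.approx(alpha * total_pah(base), rel=1e-9)
        shuffled = dict(reversed(list(base.items())))
        assert total_pah(shuffled) == total_pah(base)


class TestEUCompliance:
    def test_pooled_fixture_passes_both_limits(self, table2):
        flags = eu_compliance(table2)
        assert flags["compliant"].all()
        bap = flags[flags["analyte"] == "BaP"].iloc[0]
        assert bap["mean"] == 1.08 and bap["limit"] == 2.0

    def test_hypothetical_exceedance_fails(self, table2):
        hot = table2.copy()
        hot.loc[hot["analyte"] == "BaP", "mean"] = 2.5
        flags = eu_compliance(hot)
        assert not flags[flags["analyte"] == "BaP"]["compliant"].iloc[0]

    def test_missing_rows_error(self, table2):
        with pytest.raises(KeyError):
            eu_compliance(table2[table2["analyte"] != "PAH4"])


class TestRankSum:
    def test_separated_pairs_exact(self):
        res = rank_sum_test([1, 2], [3, 4])
        assert res.statistic == 0
        assert res.p_value == pytest.approx(1 / 3)
        assert res.method == "exact_enumeration"

    def test_separated_triples_exact(self):
        res = rank_sum_test([1, 2, 3], [4, 5, 6])
        assert res.statistic == 0
        assert res.p_value == pytest.approx(0.1)

    def test_identical_multisets_symmetric_u(self):
        a = [1.0, 2.0, 3.0, 4.0]
        res = rank_sum_test(a, a)
        assert res.statistic == len(a) * len(a) / 2
        assert res.method == "normal_approx_tie_corrected"

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            rank_sum_test([], [1.0])

    def test_large_samples_use_normal_approximation(self):
        rng = np.random.default_rng(5)
        res = rank_sum_test(rng.normal(size=20), rng.normal(1, 1, size=20))
        assert res.method == "normal_approx_tie_corrected"
        assert 0 <= res.p_value <= 1

    @given(
        pooled=st.lists(
            st.integers(-1000, 1000), min_size=2, max_size=10, unique=True
        ),
        split=st.data(),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_exact_path_matches_independent_oracle(self, pooled, split):
        """Enumeration p-value equals scipy's exact distribution for all
        tie-free inputs with combined n <= 10; U_A + U_B = nA*nB."""
        k = split.draw(st.integers(1, len(pooled) - 1))
        a, b = pooled[:k], pooled[k:]
        res = rank_sum_test(a, b)
        assert res.method == "exact_enumeration"
        oracle = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
        assert res.statistic == oracle.statistic
        assert res.p_value == pytest.approx(float(oracle.pvalue), rel=1e-12)
        u_b = rank_sum_test(b, a).statistic
        assert res.statistic + u_b == len(a) * len(b)


def table_analytes():
    from pahrisk.analytes import CANONICAL

    return CANONICAL


def test_holm_adjustment_monotone_and_bounded():
    p = [0.001, 0.04, 0.03, 0.5]
    adj = holm_adjust(p)
    assert (adj >= np.asarray(p)).all()
    assert (adj <= 1).all()
    # smallest p multiplied by the family size
    assert adj[0] == pytest.approx(0.004)
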