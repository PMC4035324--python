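"""Exact count test, BH adjustment, DEG screening, transition summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import gammaln

from tagdge.degs import (
    bh_adjust,
    classify_fold,
    count_test,
    screen,
    summarize_transition,
)
from tagdge.errors import InputError
from tests.conftest import make_profile


def log_pmf(y: np.ndarray, x: int, n1: float, n2: float) -> np.ndarray:
    """log P(y|x) = log[(N2/N1)^y (x+y)!/(x!y!) / (1+N2/N1)^(x+y+1)]."""
    r = n2 / n1
    return (
        y * np.log(r)
        + gammaln(x + y + 1)
        - gammaln(x + 1)
        - gammaln(y + 1)
        - (x + y + 1) * np.log1p(r)
    )


def oracle_p(x: int, y: int, n1: float, n2: float, y_max: int = 10_000) -> float:
    """Brute-force tail summation in both library orientations."""
    tails = []
    for a, b, na, nb in ((x, y, n1, n2), (y, x, n2, n1)):
        grid = np.arange(0, y_max + 1)
        pmf = np.exp(log_pmf(grid, a, na, nb))
        tails.append(pmf[: b + 1].sum())          # P(Y <= b | a)
        tails.append(pmf[b:].sum())               # P(Y >= b | a)
    return min(1.0, 2.0 * min(tails))


class TestCountTest:
    def test_identical_observations_give_p_one(self):
        assert count_test(0, 0, 1e6, 1e6) == 1.0
        assert count_test(5, 5, 1e6, 1e6) == 1.0

    def test_matches_tail_summation_oracle(self):
        for x, y in [(5, 5), (0, 12), (3, 30), (50, 120), (200, 100)]:
            for n1, n2 in [(1e6, 1e6), (1e6, 2e6), (2e6, 1e6)]:
                assert count_test(x, y, n1, n2) == pytest.approx(
                    oracle_p(x, y, n1, n2), abs=1e-10
                )

    def test_swap_symmetry(self):
        p1 = count_test(3, 9, 1e6, 2e6)
        p2 = count_test(9, 3, 2e6, 1e6)
        assert abs(p1 - p2) < 1e-12

    def test_more_extreme_difference_smaller_p(self):
        p_small = count_test(10, 20, 1e6, 1e6)
        p_large = count_test(10, 100, 1e6, 1e6)
        assert p_large < p_small

    def test_invalid_inputs_rejected(self):
        with pytest.raises(InputError):
            count_test(-1, 0, 1e6, 1e6)
        with pytest.raises(InputError):
            count_test(0, 0, 0, 1e6)

    @settings(max_examples=200, deadline=None)
    @given(
        st.integers(0, 500),
        st.integers(0, 500),
        st.sampled_from([5e5, 1e6, 2e6]),
        st.sampled_from([5e5, 1e6, 2e6]),
    )
    def test_p_in_unit_interval_and_symmetric(self, x, y, n1, n2):
        p = count_test(x, y, n1, n2)
        assert 0 < p <= 1
        assert p == pytest.approx(count_test(y, x, n2, n1), abs=1e-12)


class TestBHAdjust:
    def test_single_p(self):
        assert bh_adjust([0.04])[0] == pytest.approx(0.04)

    def test_stepup_by_hand(self):
        # m=3: q3 = 0.03; q2 = min(3*0.02/2, 0.03) = 0.03; q1 = min(3*0.01/1, 0.03) = 0.03
        q = bh_adjust([0.01, 0.02, 0.03])
        assert np.allclose(q, [0.03, 0.03, 0.03])

    def test_matches_manual_stepup_on_random_vectors(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            p = rng.uniform(size=rng.integers(1, 60))
            q = bh_adjust(p)
            # manual step-up: q_(i) = min_{j>=i} m p_(j) / j, restore order
            order = np.argsort(p, kind="stable")
            m = len(p)
            scaled = p[order] * m / np.arange(1, m + 1)
            manual_sorted = np.minimum.accumulate(scaled[::-1])[::-1]
            manual = np.empty(m)
            manual[order] = np.minimum(manual_sorted, 1.0)
            assert np.allclose(q, manual, atol=1e-12)

    @settings(max_examples=100, deadline=None)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
    def test_q_geq_p_elementwise(self, p):
        q = bh_adjust(p)
        assert np.all(q >= np.asarray(p) - 1e-15)
        assert np.all(q <= 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(InputError):
            bh_adjust([0.5, 1.5])


class TestScreen:
    def test_threefold_change_is_up_2_4(self):
        # tpm 10 vs 30 with counts large enough to clear FDR
        earlier = make_profile({"G": 1000, "H": 100_000}, total_clean=100_000_000, library_id="A")
        later = make_profile({"G": 3000, "H": 100_000}, total_clean=100_000_000, library_id="B")
        result = screen(earlier, later, transition="T1")
        row = result.loc["G"]
        assert row["tpm_x"] == pytest.approx(10.0)
        assert row["tpm_y"] == pytest.approx(30.0)
        assert row["direction"] == "up"
        assert row["fc_class"] == "2-4"
        assert row["is_deg"]

    def test_zero_to_fifty_is_on(self):
        earlier = make_profile({"G": 0, "H": 1000}, total_clean=1_000_000, library_id="A")
        later = make_profile({"G": 50, "H": 1000}, total_clean=1_000_000, library_id="B")
        result = screen(earlier, later, transition="T1")
        row = result.loc["G"]
        assert row["fc_class"] == "on"
        assert row["direction"] == "up"
        assert np.isinf(row["log2fc"])
        assert row["is_deg"]  # on/off passes the fold criterion; p is tiny

    def test_gene_absent_in_both_not_tested(self):
        earlier = make_profile({"G": 0, "H": 10}, total_clean=1000, library_id="A")
        later = make_profile({"G": 0, "H": 12}, total_clean=1000, library_id="B")
        result = screen(earlier, later)
        assert "G" not in result.index
        assert "H" in result.index

    def test_mismatched_universe_rejected(self):
        earlier = make_profile({"G": 1}, total_clean=100, library_id="A")
        later = make_profile({"H": 1}, total_clean=100, library_id="B")
        with pytest.raises(InputError):
            screen(earlier, later)

    def test_fold_passing_but_insignificant_not_deg(self):
        earlier = make_profile({"G": 1, "H": 1000}, total_clean=10_000, library_id="A")
        later = make_profile({"G": 3, "H": 1000}, total_clean=10_000, library_id="B")
        result = screen(earlier, later)
        row = result.loc["G"]
        assert abs(row["log2fc"]) >= 1
        assert not row["is_deg"]  # q-value nowhere near 0.001

    def test_q_geq_p_in_output(self):
        rng = np.random.default_rng(4)
        counts_a = {f"g{i}": int(c) for i, c in enumerate(rng.integers(0, 200, size=80))}
        counts_b = {f"g{i}": int(c) for i, c in enumerate(rng.integers(0, 200, size=80))}
        result = screen(
            make_profile(counts_a, 10_000, "A"), make_profile(counts_b, 10_000, "B")
        )
        assert np.all(result["q_value"] >= result["p_value"] - 1e-15)


class TestClassifyFold:
    @pytest.mark.parametrize(
        "log2fc,cx,cy,expected",
        [
            (0.5, 10, 15, "lt2"),
            (1.0, 10, 20, "2-4"),
            (1.99, 10, 39, "2-4"),
            (2.0, 10, 40, "4-8"),   # boundary 4 belongs to 4-8
            (2.9, 10, 75, "4-8"),
            (3.0, 10, 80, "8plus"),  # boundary 8 belongs to 8plus
            (-3.5, 80, 7, "8plus"),
            (np.inf, 0, 50, "on"),
            (-np.inf, 50, 0, "off"),
        ],
    )
    def test_half_open_bins(self, log2fc, cx, cy, expected):
        assert classify_fold(log2fc, cx, cy) == expected


class TestSummarizeTransition:
    def _records(self, rows):
        df = pd.DataFrame(rows)
        df["transition"] = "T1"
        df["is_deg"] = True
        return df

    def test_fig2_style_arithmetic(self):
        """723+200+94 up and 235 down tally to 1,252 DEGs, 81.2% up."""
        rows = []
        for cls, n in (("2-4", 723), ("4-8", 200), ("8plus", 94)):
            rows += [{"direction": "up", "fc_class": cls}] * n
        rows += [{"direction": "down", "fc_class": "2-4"}] * 235
        s = summarize_transition(self._records(rows))
        assert s.n_up == 1017
        assert s.n_down == 235
        assert s.n_total == 1252
        assert s.pct_up == pytest.approx(81.2, abs=0.05)
        assert s.class_counts[("up", "2-4")] == 723

    def test_empty_records_all_zero(self):
        empty = pd.DataFrame(columns=["transition", "direction", "fc_class", "is_deg"])
        s = summarize_transition(empty)
        assert s.n_total == 0 and s.n_on == 0 and s.n_off == 0

    def test_on_off_counted_in_direction_and_onoff(self):
        rows = [
            {"direction": "up", "fc_class": "on"},
            {"direction": "down", "fc_class": "off"},
            {"direction": "up", "fc_class": "8plus"},
        ]
        s = summarize_transition(self._records(rows))
        assert s.n_up == 2 and s.n_down == 1
        assert s.n_on == 1 and s.n_off == 1

    def test_mixed_transitions_rejected(self):
        df = pd.DataFrame(
            {
                "transition": ["T1", "T2"],
                "direction": ["up", "up"],
                "fc_class": ["2-4", "2-4"],
                "is_deg": [True, True],
            }
        )
        with pytest.raises(InputError):
            summarize_transition(df)
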