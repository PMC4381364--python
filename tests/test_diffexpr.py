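"""TPM normalization, exact two-library count test, regulation calls."""

import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import saltmir as sm
from saltmir.diffexpr import build_records, call_regulation


def exact_conditional_pvalue(x, y, n1, n2):
    """Oracle: exact Binomial(x+y, N2/(N1+N2)) tails in rational arithmetic."""
    n = x + y
    if n == 0:
        return Fraction(1)
    p2 = Fraction(n2, n1 + n2)
    p1 = 1 - p2

    def pmf(k):
        return Fraction(math.comb(n, k)) * p2**k * p1 ** (n - k)

    lower = sum(pmf(k) for k in range(0, y + 1))
    upper = sum(pmf(k) for k in range(y, n + 1))
    return min(Fraction(1), 2 * min(lower, upper))


class TestNormalize:
    def test_zero_count_maps_to_floor(self):
        assert sm.normalize(0, 123456) == 0.01

    def test_full_library_is_one_million(self):
        assert sm.normalize(1000, 1000) == 1_000_000

    def test_unit_definition(self):
        assert sm.normalize(5, 1_000_000) == 5.0

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            sm.normalize(1, 0)

    def test_tpm_conservation_before_floor(self):
        counts = [3, 0, 7, 90]
        total = sum(counts)
        tpm = [c / total * 1e6 for c in counts]  # pre-floor values
        assert abs(sum(tpm) - 1e6) < 1e-6


class TestCountPvalue:
    def test_worked_example_five_vs_zero(self):
        # one-sided tail 1/32, doubled
        assert sm.count_pvalue(5, 0, 1000, 1000) == pytest.approx(0.0625, abs=1e-12)

    def test_symmetric_center_capped_at_one(self):
        assert sm.count_pvalue(7, 7, 5000, 5000) == 1.0

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            sm.count_pvalue(-1, 2, 10, 10)

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(
        x=st.integers(0, 200),
        y=st.integers(0, 200),
        n1=st.integers(1, 10**7),
        n2=st.integers(1, 10**7),
    )
    def test_symmetry(self, x, y, n1, n2):
        a = sm.count_pvalue(x, y, n1, n2)
        b = sm.count_pvalue(y, x, n2, n1)
        assert a == pytest.approx(b, rel=1e-9, abs=1e-300)

    def test_ac_series_matches_binomial_pointwise(self):
        """The Audic-Claverie series term equals the conditional-binomial pmf
        at the observed pair; only the tail convention differs."""
        from scipy.stats import binom, nbinom

        for x, y, n1, n2 in ((3, 7, 1000, 2000), (0, 5, 500, 500)):
            ac_term = nbinom.pmf(y, x + 1, n1 / (n1 + n2))
            conditional = binom.pmf(y, x + y, n2 / (n1 + n2))
            # AC normalizes over y with an extra 1/(1+N2/N1) factor
            assert ac_term == pytest.approx(conditional * n1 / (n1 + n2), rel=1e-12)

    def test_monotone_tail_beyond_x(self):
        """For equal totals the upper tail is non-increasing in y beyond x."""
        x, n = 20, 100_000
        prev = None
        for y in range(20, 120):
            from scipy.stats import binom

            tail = float(binom.sf(y - 1, x + y, 0.5))
            if prev is not None:
                assert tail <= prev + 1e-12
            prev = tail

    def test_small_grid_matches_exact_oracle(self):
        for n1, n2 in ((1000, 1000), (3000, 2000)):
            for x in range(0, 13):
                for y in range(0, 13):
                    got = sm.count_pvalue(x, y, n1, n2)
                    want = float(exact_conditional_pvalue(x, y, n1, n2))
                    assert got == pytest.approx(want, rel=1e-9, abs=1e-15)


class TestCallRegulation:
    def _records(self, entries, n1=1_000_000, n2=1_000_000):
        return build_records({k: v for k, v in entries.items()}, n1, n2)

    def test_threshold_is_strict(self):
        # log2fc of exactly 0.5 must not be called up even at p ~ 0
        rec = sm.ExpressionRecord("m", 100, 142, 10**6, 10**6,
                                  tpm_ck=100.0, tpm_na=100.0 * 2**0.5,
                                  log2fc=0.5, pvalue=1e-10)
        called, _ = call_regulation([rec])
        assert called[0].call == "unchanged"

    def test_pvalue_gates_large_fold_changes(self):
        recs = self._records({"m": (1, 4)})  # log2fc = 2 but tiny counts
        assert recs[0].log2fc == pytest.approx(2.0)
        assert recs[0].pvalue > 0.05
        called, _ = call_regulation(recs)
        assert called[0].call == "unchanged"

    def test_up_and_down_calls(self):
        recs = self._records({"up": (100, 1000), "down": (1000, 100), "flat": (500, 500)})
        called, summary = call_regulation(recs)
        assert summary == {"up": 1, "down": 1}
        by_name = {r.mirna: r.call for r in called}
        assert by_name == {"up": "up", "down": "down", "flat": "unchanged"}

    def test_sorted_by_absolute_fold_change(self):
        recs = self._records({"a": (100, 200), "b": (100, 1600), "c": (100, 400)})
        called, _ = call_regulation(recs)
        assert [r.mirna for r in called] == ["b", "c", "a"]

    def test_planted_effects_recovered_with_correct_direction(self):
        """True log2 = +/-2 at mean 1000: across 3 generator replicates at
        dispersion 0.05 at least 80% of calls are correct and none flip sign."""
        rng = np.random.default_rng(31)
        n = 200_000
        correct = total = 0
        for _ in range(3):
            counts = {}
            truth = {}
            for i in range(10):
                lfc = 2.0 if i % 2 == 0 else -2.0
                mean_ck = 1000.0 if lfc > 0 else 4000.0
                mean_na = mean_ck * 2**lfc
                x = int(sm.draw_nb_counts(rng, mean_ck, 0.05)[0])
                y = int(sm.draw_nb_counts(rng, mean_na, 0.05)[0])
                counts[f"m{i}"] = (x, y)
                truth[f"m{i}"] = "up" if lfc > 0 else "down"
            called, _ = call_regulation(build_records(counts, n, n))
            for r in called:
                total += 1
                if r.call == truth[r.mirna]:
                    correct += 1
                else:
                    assert r.call == "unchanged", "sign error"
        assert correct / total >= 0.8
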