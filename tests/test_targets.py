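"""Target-site scoring rules and transcript scanning."""

import numpy as np
import pytest

import saltmir as sm
from saltmir._util import revcomp, to_rna

MIRNA = "UGGAGCUCCCUUCAUUCCAAU"  # 21 nt


def perfect_site(mirna):
    """Transcript window (5'->3') perfectly complementary to the miRNA."""
    return revcomp(mirna.replace("U", "T"))


def _mutate_window(mirna, positions, kind="mismatch"):
    """Force a mismatch or wobble at given miRNA positions (1-based)."""
    window = list(perfect_site(mirna))
    L = len(mirna)
    for pos in positions:
        i = pos - 1
        b = to_rna(mirna)[i]
        j = L - 1 - i
        if kind == "wobble":
            window[j] = {"G": "T", "U": "G"}[b]  # G:U / U:G pairs
        else:
            window[j] = {"A": "A", "C": "C", "G": "G", "U": "T"}[b]  # self = mismatch
    return "".join(window)


class TestScoreSite:
    def test_perfect_complement_passes_with_zero_counters(self):
        hit = sm.score_site(MIRNA, perfect_site(MIRNA))
        assert hit.passes
        assert (hit.mm_total, hit.mm_1to9, hit.mm_10to11, hit.mm_1to12) == (0, 0, 0, 0)
        assert hit.mm_adjacent_max == 0

    @pytest.mark.parametrize("pos", [10, 11])
    def test_central_mismatch_fails(self, pos):
        hit = sm.score_site(MIRNA, _mutate_window(MIRNA, [pos]))
        assert hit.mm_10to11 == 1.0 and not hit.passes

    def test_central_wobble_also_fails(self):
        # position 11 of this miRNA is U -> wobble possible
        assert to_rna(MIRNA)[10] == "U"
        hit = sm.score_site(MIRNA, _mutate_window(MIRNA, [11], kind="wobble"))
        assert hit.mm_10to11 == 0.5 and not hit.passes

    def test_five_scattered_mismatches_fail_total_rule(self):
        hit = sm.score_site(MIRNA, _mutate_window(MIRNA, [2, 5, 13, 16, 20]))
        assert hit.mm_total == 5.0 and not hit.passes

    def test_two_wobbles_in_seed_pass(self):
        # G:U at positions 3 and 5 -> mm_total 1.0, mm_1to9 = 1.0 <= 1
        assert to_rna(MIRNA)[2] == "G" and to_rna(MIRNA)[4] == "G"
        hit = sm.score_site(MIRNA, _mutate_window(MIRNA, [3, 5], kind="wobble"))
        assert hit.mm_total == 1.0 and hit.mm_1to9 == 1.0 and hit.passes

    def test_three_adjacent_mismatches_fail(self):
        hit = sm.score_site(MIRNA, _mutate_window(MIRNA, [14, 15, 16]))
        assert hit.mm_adjacent_max == 3 and not hit.passes

    def test_adjacent_wobbles_do_not_count_as_adjacent_mismatches(self):
        # positions 15 and 16 are both U -> adjacent wobbles, score < 1 each
        hit = sm.score_site(MIRNA, _mutate_window(MIRNA, [15, 16], kind="wobble"))
        assert hit.mm_adjacent_max == 0

    def test_half_point_budget_needs_wobble_scoring(self):
        """Five wobbles (2.5 points) pass with wobble scoring; without it
        they count 5 full mismatches and fail the total rule."""
        positions = [3, 5, 12, 15, 16]  # G/U positions of this miRNA
        window = _mutate_window(MIRNA, positions, kind="wobble")
        with_wobble = sm.score_site(MIRNA, window)
        assert with_wobble.mm_total == 2.5
        assert with_wobble.mm_1to9 == 1.0 and with_wobble.mm_1to12 == 1.5
        assert with_wobble.passes
        without = sm.score_site(MIRNA, window, no_wobble=True)
        assert without.mm_total == 5.0 and not without.passes

    def test_no_wobble_counters_are_integers(self):
        window = _mutate_window(MIRNA, [3, 12], kind="wobble")
        hit = sm.score_site(MIRNA, window, no_wobble=True)
        assert all(float(s).is_integer() for s in hit.scores)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            sm.score_site(MIRNA, "ACGU")


class TestScan:
    def test_planted_perfect_site_found_exactly(self, rng):
        bases = np.array(list("ACGT"))
        t = "".join(bases[rng.integers(0, 4, 500)])
        site = perfect_site(MIRNA)
        transcript = t[:200] + site + t[200 + len(site):]
        hits = sm.scan(MIRNA, {"t1": transcript})
        perfect = [h for h in hits if h.mm_total == 0]
        assert len(perfect) == 1
        assert perfect[0].site_start == 201
        assert perfect[0].site_end == 201 + len(MIRNA) - 1

    def test_invariant_under_transcript_order(self):
        t1 = perfect_site(MIRNA) + "ACGT" * 30
        t2 = "TTTT" * 30 + perfect_site(MIRNA)
        a = sm.scan(MIRNA, {"a": t1, "b": t2})
        b = sm.scan(MIRNA, {"b": t2, "a": t1})
        assert [(h.transcript, h.site_start) for h in a] == [
            (h.transcript, h.site_start) for h in b
        ]

    def test_matches_independent_bruteforce_scorer(self):
        """A 10-kb random transcript re-scanned with an independently coded
        complementarity scorer yields the identical hit list."""
        rng = np.random.default_rng(9)
        bases = np.array(list("ACGT"))
        transcript = "".join(bases[rng.integers(0, 4, 10_000)])
        # plant some passing sites to make the comparison non-trivial
        for pos, wob in ((1000, []), (5000, [15, 16])):
            w = _mutate_window(MIRNA, wob, kind="wobble")
            transcript = transcript[:pos] + w + transcript[pos + len(w):]
        got = [(h.transcript, h.site_start, h.mm_total) for h in sm.scan(MIRNA, {"t": transcript})]

        comp = {"A": "U", "U": "A", "G": "C", "C": "G"}
        mi = to_rna(MIRNA)
        L = len(mi)
        want = []
        rna_t = to_rna(transcript)
        for s in range(len(rna_t) - L + 1):
            window = rna_t[s : s + L][::-1]
            scores = []
            for a, b in zip(mi, window):
                if comp[a] == b:
                    scores.append(0.0)
                elif (a, b) in (("G", "U"), ("U", "G")):
                    scores.append(0.5)
                else:
                    scores.append(1.0)
            run = best = 0
            for v in scores:
                run = run + 1 if v >= 1 else 0
                best = max(best, run)
            if (
                sum(scores) <= 4
                and best <= 2
                and sum(scores[:9]) <= 1
                and sum(scores[9:11]) == 0
                and sum(scores[:12]) <= 2.5
            ):
                want.append(("t", s + 1, sum(scores)))
        assert got == want
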