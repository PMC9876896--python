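"""Hit filtering, overlap logic, scoring, and architecture resolution."""

import math
from itertools import combinations

import numpy as np
import pytest

from archminer.domarch import (
    FilterParams,
    best_architecture,
    filter_hits,
    hit_score,
    is_overlapping,
    overlap_fraction,
)
from archminer.errors import UsageError

from conftest import make_hit, random_hits


class TestFilterHits:
    def test_passing_hit_retained(self):
        h = make_hit(i_evalue=0.005, c_evalue=0.001, acc=0.8)
        assert filter_hits([h]) == [h]

    def test_i_evalue_cut_is_strict(self):
        bad = make_hit(i_evalue=0.02, c_evalue=0.001, acc=0.9)
        boundary = make_hit(i_evalue=0.01, c_evalue=0.001, acc=0.9)
        just_below = make_hit(i_evalue=0.0099, c_evalue=0.001, acc=0.9)
        assert filter_hits([bad]) == []
        assert filter_hits([boundary]) == []
        assert filter_hits([just_below]) == [just_below]

    def test_c_evalue_also_evaluated(self):
        h = make_hit(i_evalue=0.001, c_evalue=0.02, acc=0.9)
        assert filter_hits([h]) == []

    def test_acc_cut_is_inclusive(self):
        at = make_hit(i_evalue=0.005, c_evalue=0.001, acc=0.6)
        below = make_hit(i_evalue=0.005, c_evalue=0.001, acc=0.59)
        assert filter_hits([at]) == [at]
        assert filter_hits([below]) == []

    def test_idempotent_and_monotone(self, rng):
        hits = random_hits(rng, 40)
        once = filter_hits(hits)
        assert filter_hits(once) == once
        looser = filter_hits(hits, FilterParams(evalue_max=0.1))
        assert set(h.env_from for h in once) <= set(h.env_from for h in looser)
        assert all(h in looser for h in once)


class TestOverlap:
    def test_disjoint_is_zero(self):
        a, b = make_hit(env=(1, 100)), make_hit(env=(101, 200))
        assert overlap_fraction(a, b) == 0.0

    def test_shared_positions_over_shorter_envelope(self):
        a, b = make_hit(env=(1, 100)), make_hit(env=(50, 150))
        assert overlap_fraction(a, b) == pytest.approx(51 / 100)
        a, c = make_hit(env=(1, 100)), make_hit(env=(90, 200))
        assert overlap_fraction(a, c) == pytest.approx(11 / 100)

    def test_symmetry(self, rng):
        hits = random_hits(rng, 20)
        for a, b in combinations(hits, 2):
            assert overlap_fraction(a, b) == overlap_fraction(b, a)
            assert is_overlapping(a, b) == is_overlapping(b, a)

    def test_threshold_inclusive_at_040(self):
        # shorter envelope 1000 positions, shared 400 -> exactly 0.40
        a = make_hit(target_len=2000, env=(1, 1000))
        b = make_hit(target_len=2000, env=(601, 1700))
        assert overlap_fraction(a, b) == pytest.approx(0.400)
        assert is_overlapping(a, b)
        c = make_hit(target_len=2000, env=(602, 1701))  # shared 399
        assert overlap_fraction(a, c) == pytest.approx(0.399)
        assert not is_overlapping(a, c)

    def test_different_targets_rejected(self):
        a = make_hit(target_id="p1")
        b = make_hit(target_id="p2")
        with pytest.raises(UsageError):
            overlap_fraction(a, b)

    def test_alignment_coordinate_mode(self):
        a = make_hit(env=(1, 100), ali=(40, 60))
        b = make_hit(env=(50, 150), ali=(100, 150))
        assert is_overlapping(a, b)  # envelopes share 51%
        assert not is_overlapping(a, b, on="ali")  # alignments disjoint


class TestHitScore:
    def test_negative_log10_of_i_evalue(self):
        assert hit_score(make_hit(i_evalue=1e-5)) == pytest.approx(5.0)

    def test_clamped_at_zero(self):
        assert hit_score(make_hit(i_evalue=1.0)) == 0.0
        assert hit_score(make_hit(i_evalue=20.0)) == 0.0

    def test_bitscore_fallback_when_evalue_underflows(self):
        assert hit_score(make_hit(i_evalue=0.0, bitscore=123.4)) == 123.4


def brute_force_best(hits, threshold=0.4):
    """Independent oracle: exhaustive subset enumeration.

    Scores are summed in (env_from, query_name) order so float totals are
    comparable bit-for-bit with the solver's.
    """
    n = len(hits)
    pair = [[False] * n for _ in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            pair[i][j] = pair[j][i] = is_overlapping(hits[i], hits[j], threshold)
    best = 0.0
    for mask in range(1 << n):
        sel = [i for i in range(n) if mask >> i & 1]
        if any(pair[i][j] for i, j in combinations(sel, 2)):
            continue
        total = 0.0
        for i in sorted(sel, key=lambda k: (hits[k].env_from, hits[k].query_name)):
            total += hit_score(hits[i])
        best = max(best, total)
    return best


class TestBestArchitecture:
    def test_empty_and_single(self):
        arch = best_architecture([])
        assert arch.hits == () and arch.total_score == 0.0
        h = make_hit(i_evalue=1e-8)
        arch = best_architecture([h])
        assert arch.hits == (h,)
        assert arch.total_score == hit_score(h)

    def test_three_hit_worked_example(self):
        # A(1-100, 1e-10) conflicts with B(50-150, 1e-3); C(160-260, 1e-8)
        # is compatible with both: optimum is {A, C} with score 18
        a = make_hit(query_name="A", env=(1, 100), i_evalue=1e-10)
        b = make_hit(query_name="B", env=(50, 150), i_evalue=1e-3)
        c = make_hit(query_name="C", env=(160, 260), i_evalue=1e-8)
        arch = best_architecture([a, b, c])
        assert arch.domain_names == ("A", "C")
        assert arch.total_score == pytest.approx(18.0)
        assert arch.total_score == brute_force_best([a, b, c])

    def test_result_sorted_and_pairwise_compatible(self, rng):
        hits = random_hits(rng, 15)
        arch = best_architecture(hits)
        starts = [h.env_from for h in arch.hits]
        assert starts == sorted(starts)
        for x, y in combinations(arch.hits, 2):
            assert not is_overlapping(x, y)

    def test_total_score_is_sum_of_hit_scores(self, rng):
        hits = random_hits(rng, 12)
        arch = best_architecture(hits)
        assert arch.total_score == pytest.approx(
            sum(hit_score(h) for h in arch.hits), rel=1e-9
        )

    def test_oracle_equivalence_on_random_instances(self):
        rng = np.random.default_rng(424242)
        for _ in range(200):
            n = int(rng.integers(1, 13))
            hits = random_hits(rng, n)
            arch = best_architecture(hits)
            assert arch.total_score == brute_force_best(hits)

    def test_mixed_targets_rejected(self):
        with pytest.raises(UsageError):
            best_architecture([make_hit(target_id="p1"), make_hit(target_id="p2")])

    def test_input_order_does_not_matter(self, rng):
        hits = random_hits(rng, 10)
        a1 = best_architecture(hits)
        a2 = best_architecture(list(reversed(hits)))
        assert a1 == a2

    def test_scale_invariance_ln_vs_log10(self, rng):
        # replacing -log10 by -ln multiplies all scores by ln(10): the
        # selected subset must not change when no E-value is zero
        hits = [h for h in random_hits(rng, 12) if h.i_evalue > 0]
        arch = best_architecture(hits)
        scaled = brute_force_best(hits) * math.log(10)
        # recompute optimum under -ln scoring via the same oracle
        n = len(hits)
        pair = {
            (i, j): is_overlapping(hits[i], hits[j])
            for i in range(n)
            for j in range(i + 1, n)
        }
        best_ln, best_sel = 0.0, ()
        for mask in range(1 << n):
            sel = [i for i in range(n) if mask >> i & 1]
            if any(pair[(i, j)] for i, j in combinations(sel, 2)):
                continue
            tot = sum(max(0.0, -math.log(hits[i].i_evalue)) for i in sel)
            if tot > best_ln:
                best_ln, best_sel = tot, tuple(sel)
        chosen = tuple(sorted(hits.index(h) for h in arch.hits))
        assert chosen == tuple(sorted(best_sel))
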