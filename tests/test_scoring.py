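"""Unit and property tests for response-sheet scoring."""

import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from recallkit import (
    CORRECT,
    INS,
    NEAR_MISS,
    NULL,
    REM,
    Lexicon,
    MatchRecord,
    ResponseSheet,
    ScoringConfig,
    WordList,
    assign_entries,
    classify_match,
    count_removals,
    edit_distance,
    normalize_entry,
    position_errors,
    score_sheet,
    sequence_index,
)


def dp_levenshtein(a: str, b: str) -> int:
    """Independent dynamic-programming oracle for the edit distance."""
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        curr = [i]
        for j, cb in enumerate(b, 1):
            curr.append(
                min(prev[j] + 1, curr[j - 1] + 1, prev[j - 1] + (ca != cb))
            )
        prev = curr
    return prev[-1]


@pytest.mark.parametrize(
    "raw, expected",
    [
        (" Metalmark ", "metalmark"),
        ("angle-wing", "anglewing"),
        ("   ", ""),
        ("Great  Spangled\tFritillary", "greatspangledfritillary"),
        ("angle - wing", "anglewing"),
    ],
)
def test_normalize_entry(raw, expected):
    assert normalize_entry(raw) == expected


class TestEditDistance:
    @pytest.mark.parametrize(
        "a, b, d",
        [
            ("metalmark", "metalmark", 0),
            ("metalmark", "metalmask", 1),
            ("metalmark", "metalspot", 4),
            ("", "abc", 3),
            ("", "", 0),
        ],
    )
    def test_known_values(self, a, b, d):
        assert edit_distance(a, b) == d
        assert edit_distance(b, a) == d

    def test_exhaustive_small_alphabet(self):
        """Match the DP oracle on every token pair of length <= 3 over {a,b,c}."""
        tokens = [
            "".join(t)
            for n in range(4)
            for t in itertools.product("abc", repeat=n)
        ]
        for a in tokens:
            for b in tokens:
                assert edit_distance(a, b) == dp_levenshtein(a, b)

    @given(
        st.text(alphabet="abcdef", max_size=8),
        st.text(alphabet="abcdef", max_size=8),
    )
    def test_matches_oracle_and_metric_axioms(self, a, b):
        d = edit_distance(a, b)
        assert d == dp_levenshtein(a, b)
        assert d == edit_distance(b, a)
        assert (d == 0) == (a == b)


class TestAssignment:
    def test_identity_assignment(self, small_wordlist, butterfly_lexicon):
        records = assign_entries(
            list(small_wordlist.canonical), small_wordlist, lexicon=butterfly_lexicon
        )
        assigned = {m.target_index: m.entry_index for m in records}
        assert assigned == {i: i for i in range(1, 6)}
        assert all(m.category is None for m in records)

    def test_near_spelling_assigned_to_intended_target(
        self, small_wordlist, butterfly_lexicon
    ):
        records = assign_entries(["metalmask"], small_wordlist, lexicon=butterfly_lexicon)
        (match,) = [m for m in records if m.entry_index == 1]
        assert small_wordlist.canonical[match.target_index - 1] == "metalmark"
        assert match.distance == 1

    def test_dissimilar_entry_left_unassigned(self, small_wordlist, butterfly_lexicon):
        records = assign_entries(["zzzz"], small_wordlist, lexicon=butterfly_lexicon)
        (entry_rec,) = [m for m in records if m.entry_index == 1]
        assert entry_rec.target_index is None
        assert sum(m.category == NULL for m in records) == len(small_wordlist)

    def test_duplicate_entries_one_to_one(self, small_wordlist, butterfly_lexicon):
        records = assign_entries(
            ["metalmark", "metalmark"], small_wordlist, lexicon=butterfly_lexicon
        )
        hits = [m for m in records if m.target_index == 1 and m.entry_index]
        assert len(hits) == 1
        assert hits[0].entry_index == 1  # tie broken toward the earlier entry

    def test_tie_broken_toward_lower_target(self):
        targets = WordList.from_tokens(["abcd", "abce"])
        records = assign_entries(["abcf"], targets)
        (match,) = [m for m in records if m.entry_index == 1]
        assert match.target_index == 1

    def test_shared_morpheme_credit_rescues_assignment(self, butterfly_lexicon):
        # "metalspot" vs "metalmark": raw similarity 1 - 4/9 ~ 0.56, but the
        # shared modifier should hold the pair well above the floor even
        # under a stricter similarity threshold.
        targets = WordList.from_tokens(["metalmark"])
        cfg = ScoringConfig(assignment_min_similarity=0.7)
        records = assign_entries(["metalspot"], targets, cfg, butterfly_lexicon)
        (match,) = [m for m in records if m.entry_index == 1]
        assert match.target_index == 1


class TestClassification:
    @pytest.mark.parametrize(
        "entry, target, expected",
        [
            ("metalmask", "metalmark", NEAR_MISS),  # meaningful small error
            ("meselmark", "metalmark", CORRECT),  # pure spelling slip
            ("metalspot", "metalmark", INS),  # completely different word
            ("angelwing", "anglewing", NEAR_MISS),  # morpheme-level near miss
            ("metalmark", "metalmark", CORRECT),
        ],
    )
    def test_published_examples(self, entry, target, expected, butterfly_lexicon):
        assert classify_match(entry, target, butterfly_lexicon) == expected

    def test_order_independent_and_deterministic(self, butterfly_lexicon):
        pairs = [("metalmask", "metalmark"), ("meselmark", "metalmark")]
        results = [classify_match(e, t, butterfly_lexicon) for e, t in pairs]
        assert results == [
            classify_match(e, t, butterfly_lexicon) for e, t in pairs
        ]

    def test_spelling_distance_knob(self, butterfly_lexicon):
        # With a stricter distance bound, "meselmark" (distance 2) becomes
        # an insertion rather than a spelling slip.
        cfg = ScoringConfig(max_spelling_distance=1)
        assert classify_match("meselmark", "metalmark", butterfly_lexicon, cfg) == INS


def _matches_from_orders(target_order, entry_order):
    """Build CORRECT match records for recalled targets in a given order."""
    return [
        MatchRecord(entry_index=e + 1, target_index=t, category=CORRECT)
        for e, t in enumerate(entry_order)
        if t in target_order
    ]


class TestPositionErrors:
    @pytest.mark.parametrize("mode", ["rank_based", "literal_position"])
    def test_single_swap_worked_example(self, mode):
        """Recalling 1,2,3,4,5 as 1,3,2,4,5 gives two distance-1 errors."""
        matches = _matches_from_orders([1, 2, 3, 4, 5], [1, 3, 2, 4, 5])
        distances, total = position_errors(matches, mode)
        assert distances == {1: 0, 2: 1, 3: 1, 4: 0, 5: 0}
        assert total == 2

    @pytest.mark.parametrize("n", [1, 4, 9])
    @pytest.mark.parametrize("mode", ["rank_based", "literal_position"])
    def test_identity_order_is_zero(self, n, mode):
        matches = _matches_from_orders(list(range(1, n + 1)), list(range(1, n + 1)))
        assert position_errors(matches, mode)[1] == 0

    @pytest.mark.parametrize("mode", ["rank_based", "literal_position"])
    def test_full_reversal_of_five(self, mode):
        # sum over |sigma(i) - i| = 4 + 2 + 0 + 2 + 4; modes agree on
        # complete recalls.
        matches = _matches_from_orders([1, 2, 3, 4, 5], [5, 4, 3, 2, 1])
        assert position_errors(matches, mode)[1] == 12

    def test_rank_based_ignores_omissions(self):
        # Items 2 and 4 omitted, survivors in target-relative order.
        matches = _matches_from_orders([1, 3, 5], [1, 3, 5])
        assert position_errors(matches, "rank_based")[1] == 0
        # Literal positions would penalize the shift caused by omission.
        matches = _matches_from_orders([2, 3, 5], [3, 5])
        assert position_errors(matches, "rank_based")[1] == 0
        assert position_errors(matches, "literal_position")[1] > 0

    @given(st.permutations(list(range(1, 9))))
    def test_rank_based_sum_is_even(self, order):
        matches = _matches_from_orders(sorted(order), list(order))
        _, total = position_errors(matches, "rank_based")
        assert total % 2 == 0

    def test_near_miss_inclusion_flag(self):
        matches = [
            MatchRecord(entry_index=1, target_index=2, category=NEAR_MISS),
            MatchRecord(entry_index=2, target_index=1, category=CORRECT),
        ]
        assert position_errors(matches, "rank_based")[1] == 0
        assert position_errors(matches, "rank_based", include_near_miss=True)[1] == 2


class TestSequenceIndex:
    @pytest.mark.parametrize(
        "pos_sum, n_correct, expected",
        [(2, 5, 0.2), (0, 20, 0.0), (12, 5, 1.2)],
    )
    def test_values(self, pos_sum, n_correct, expected):
        assert sequence_index(pos_sum, n_correct) == pytest.approx(expected)

    def test_undefined_when_nothing_correct(self):
        assert sequence_index(0, 0) is None

    def test_rejects_negative_inputs(self):
        with pytest.raises(ValueError):
            sequence_index(-1, 5)


class TestScoreSheet:
    def _sheet(self, entries, pid="p1", tp="baseline"):
        return ResponseSheet(pid, "untrained", tp, tuple(entries))

    def test_perfect_sheet(self, small_wordlist, butterfly_lexicon):
        scored = score_sheet(
            self._sheet(small_wordlist.items), small_wordlist, butterfly_lexicon
        )
        assert scored.n_correct == len(small_wordlist)
        assert scored.n_near == scored.n_ins == scored.n_null == 0
        assert scored.position_sum == 0
        assert scored.seq_index == 0.0

    def test_near_miss_substitution(self, small_wordlist, butterfly_lexicon):
        entries = ["metalmask"] + list(small_wordlist.items[1:])
        scored = score_sheet(self._sheet(entries), small_wordlist, butterfly_lexicon)
        assert scored.n_correct == len(small_wordlist) - 1
        assert scored.n_near == 1

    def test_partition_invariant(self, small_wordlist, butterfly_lexicon):
        entries = ["metalmask", "anglewing", "zzzzzz", "pearlstreak"]
        scored = score_sheet(self._sheet(entries), small_wordlist, butterfly_lexicon)
        assert (
            scored.n_correct
            + scored.n_near
            + scored.n_null
            + scored.n_ins_assigned
            + scored.n_rem
            == len(small_wordlist)
        )

    def test_blank_entries_dropped(self, small_wordlist, butterfly_lexicon):
        entries = ["metalmark", "   ", "anglewing"]
        scored = score_sheet(self._sheet(entries), small_wordlist, butterfly_lexicon)
        assert scored.entries == ("metalmark", "anglewing")
        assert scored.n_correct == 2

    def test_empty_sheet_all_null(self, small_wordlist, butterfly_lexicon):
        scored = score_sheet(self._sheet([]), small_wordlist, butterfly_lexicon)
        assert scored.n_null == len(small_wordlist)
        assert scored.seq_index is None


class TestRemovals:
    def _score(self, entries, cfg=ScoringConfig(), prev=None, tp="baseline"):
        wl = WordList.from_tokens(["metalmark", "anglewing", "coppertail"])
        lex = Lexicon.from_tokens(
            ["metal", "mark", "mask", "angle", "wing", "copper", "tail"]
        )
        sheet = ResponseSheet("p1", "untrained", tp, tuple(entries))
        return score_sheet(sheet, wl, lex, cfg, prev=prev)

    def test_identical_sheets_no_removals(self):
        full = ["metalmark", "anglewing", "coppertail"]
        prev = self._score(full)
        for precedence in ("null_first", "removal_first"):
            cfg = ScoringConfig(removal_precedence=precedence)
            curr = self._score(full, cfg, prev=prev, tp="post_training")
            assert curr.n_rem == 0

    def test_null_first_keeps_omission_as_null(self):
        prev = self._score(["metalmark", "anglewing", "coppertail"])
        curr = self._score(["metalmark", "anglewing"], prev=prev, tp="post_training")
        assert curr.n_rem == 0
        assert curr.n_null == 1

    def test_removal_first_reclassifies(self):
        cfg = ScoringConfig(removal_precedence="removal_first")
        prev = self._score(["metalmark", "anglewing", "coppertail"], cfg)
        curr = self._score(["metalmark", "anglewing"], cfg, prev=prev, tp="post_training")
        assert curr.n_rem == 1
        assert curr.n_null == 0
        assert sum(m.category == REM for m in curr.matches) == 1

    def test_replacement_is_not_a_removal(self):
        # The omitted item's slot is occupied by a near miss, which is a
        # categorized replacement, so no removal even under removal-first.
        cfg = ScoringConfig(removal_precedence="removal_first")
        prev = self._score(["metalmark", "anglewing", "coppertail"], cfg)
        curr = self._score(
            ["metalmask", "anglewing", "coppertail"], cfg, prev=prev, tp="post_training"
        )
        assert curr.n_rem == 0
        assert curr.n_near == 1

    def test_mismatched_participants_rejected(self):
        import dataclasses

        prev = self._score(["metalmark"])
        other = dataclasses.replace(self._score(["metalmark"]), participant_id="p2")
        with pytest.raises(ValueError):
            count_removals(prev, other, "removal_first")


class TestDomainTypes:
    def test_wordlist_requires_distinct_canonicals(self):
        with pytest.raises(ValueError):
            WordList.from_tokens(["Metalmark", "metal mark"])

    def test_wordlist_nonempty(self):
        with pytest.raises(ValueError):
            WordList(items=())

    def test_scoring_config_validation(self):
        with pytest.raises(ValueError):
            ScoringConfig(max_spelling_distance=0)
        with pytest.raises(ValueError):
            ScoringConfig(assignment_min_similarity=1.5)
        with pytest.raises(ValueError):
            ScoringConfig(sequence_mode="bogus")

    def test_match_record_invariants(self):
        with pytest.raises(ValueError):
            MatchRecord(entry_index=None, target_index=None)
        with pytest.raises(ValueError):
            MatchRecord(entry_index=1, target_index=2, category=NULL)

    def test_response_sheet_from_raw_drops_blanks(self):
        sheet = ResponseSheet.from_raw("p", "untrained", "baseline", ["a", "  ", "B c"])
        assert sheet.entries == ("a", "bc")
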