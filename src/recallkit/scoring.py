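"""Scoring of free-recall response sheets against an ordered target list.

A participant studies an ordered list of compound words (e.g. butterfly
common names) and later writes down as many items as they can remember.
Scoring proceeds in stages:

1. each written entry is normalized and matched one-to-one against the
   target list by string similarity (:func:`assign_entries`);
2. each matched pair is classified as a correct reproduction, a *near
   miss* (a small error that lands on a semantically meaningful word,
   e.g. "metalmask" for "metalmark"), or an *insertion* of a completely
   different word ("metalspot" for "metalmark"); unmatched targets are
   *null* errors (:func:`classify_match`);
3. serial-order accuracy is measured by positional distances — how many
   places out of sequence each correctly recalled item fell — and
   summarized by the Sequence Index,

       SeqI = (sum of positional distances / 2) / (number correct),

   where the division by two corrects for the fact that a single
   displaced item necessarily produces two observed position errors
   (:func:`position_errors`, :func:`sequence_index`);
4. optionally, a *removal* error is recorded when an item that was
   correct at the previous timepoint disappears without a categorized
   replacement (:func:`count_removals`).

Pure spelling slips that do not produce a meaningful word ("meselmark")
count as correct: the writer clearly retrieved the right item.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Optional, Sequence

import edlib
import numpy as np
from scipy.optimize import linear_sum_assignment

__all__ = [
    "CORRECT",
    "NEAR_MISS",
    "INS",
    "NULL",
    "REM",
    "BLANK",
    "WordList",
    "Lexicon",
    "ResponseSheet",
    "MatchRecord",
    "ScoredSheet",
    "ScoringConfig",
    "normalize_entry",
    "edit_distance",
    "similarity",
    "assign_entries",
    "classify_match",
    "position_errors",
    "sequence_index",
    "count_removals",
    "score_sheet",
]

# Error taxonomy for a scored entry/target.
CORRECT = "CORRECT"
NEAR_MISS = "NEAR_MISS"
INS = "INS"
NULL = "NULL"
REM = "REM"

#: Marker returned by :func:`normalize_entry` for all-whitespace input.
BLANK = ""

GROUPS = ("memory_palace", "aboriginal_method", "untrained")
TIMEPOINTS = ("baseline", "post_training", "delayed")

_WS_OR_HYPHEN = re.compile(r"[\s\-]+")


def normalize_entry(raw: str) -> str:
    """Canonicalize a written entry.

    Lowercases, strips outer whitespace and removes internal whitespace
    and hyphens, so "Angle-Wing" and "anglewing" compare equal.
    All-whitespace input yields :data:`BLANK`.
    """
    return _WS_OR_HYPHEN.sub("", raw.strip().lower())


def edit_distance(a: str, b: str) -> int:
    """Levenshtein distance (unit-cost insert/delete/substitute)."""
    if a == b:
        return 0
    return edlib.align(a, b, task="distance")["editDistance"]


@dataclass(frozen=True)
class WordList:
    """Ordered target items with canonical (normalized) forms.

    Positions are 1-based throughout.
    """

    items: tuple[str, ...]
    canonical: tuple[str, ...] = ()

    def __post_init__(self):
        if not self.items:
            raise ValueError("word list must contain at least one item")
        if not self.canonical:
            object.__setattr__(
                self, "canonical", tuple(normalize_entry(i) for i in self.items)
            )
        if len(self.canonical) != len(self.items):
            raise ValueError("items and canonical forms differ in length")
        if len(set(self.canonical)) != len(self.canonical):
            raise ValueError("canonical forms must be pairwise distinct")

    def __len__(self) -> int:
        return len(self.items)

    @classmethod
    def from_tokens(cls, tokens: Iterable[str]) -> "WordList":
        return cls(items=tuple(tokens))


@dataclass(frozen=True)
class Lexicon:
    """Inventory of semantically meaningful words and compound morphemes.

    A token is *meaningful* if it is a known word outright or if it can
    be split into two known morphemes (modifier + head), which is how a
    near miss like "metalmask" is recognized without listing every
    possible compound.
    """

    words: frozenset[str] = frozenset()
    morphemes: frozenset[str] = frozenset()

    @classmethod
    def from_tokens(cls, tokens: Iterable[str]) -> "Lexicon":
        toks = frozenset(normalize_entry(t) for t in tokens if t.strip())
        return cls(words=toks, morphemes=toks)

    def splits(self, token: str) -> list[tuple[str, str]]:
        """All ways to split ``token`` into two known morphemes."""
        return [
            (token[:i], token[i:])
            for i in range(1, len(token))
            if token[:i] in self.morphemes and token[i:] in self.morphemes
        ]

    def is_meaningful(self, token: str) -> bool:
        return token in self.words or bool(self.splits(token))


SequenceMode = Literal["rank_based", "literal_position"]
RemovalPrecedence = Literal["null_first", "removal_first"]


@dataclass(frozen=True)
class ScoringConfig:
    """Knobs the scoring rules leave open.

    max_spelling_distance
        Largest edit distance still treated as a "small error" (spelling
        slip or near miss); 2 covers "meselmark" for "metalmark".
    assignment_min_similarity
        Similarity floor below which an entry/target pairing is rejected.
    sequence_mode
        ``rank_based`` measures displacement among the recalled items
        themselves (robust to omissions); ``literal_position`` uses raw
        sheet positions (the 4th item written 6th scores distance 2).
    near_miss_counts_toward_correct_responses
        Whether near misses join the sequence-scorable set and the SeqI
        denominator; off by default because a near miss is an error.
    removal_precedence
        ``null_first`` leaves an omitted previously-correct item as a
        NULL error; ``removal_first`` reclassifies it as a removal.
    """

    max_spelling_distance: int = 2
    assignment_min_similarity: float = 0.5
    sequence_mode: SequenceMode = "rank_based"
    near_miss_counts_toward_correct_responses: bool = False
    removal_precedence: RemovalPrecedence = "null_first"

    def __post_init__(self):
        if self.max_spelling_distance < 1:
            raise ValueError("max_spelling_distance must be >= 1")
        if not 0.0 <= self.assignment_min_similarity <= 1.0:
            raise ValueError("assignment_min_similarity must be in [0, 1]")
        if self.sequence_mode not in ("rank_based", "literal_position"):
            raise ValueError(f"unknown sequence_mode {self.sequence_mode!r}")
        if self.removal_precedence not in ("null_first", "removal_first"):
            raise ValueError(
                f"unknown removal_precedence {self.removal_precedence!r}"
            )


@dataclass(frozen=True)
class ResponseSheet:
    """One participant x timepoint list of written entries, in order."""

    participant_id: str
    group: str
    timepoint: str
    entries: tuple[str, ...]

    @classmethod
    def from_raw(cls, participant_id, group, timepoint, raw_entries) -> "ResponseSheet":
        """Normalize raw strings and drop blanks on ingest."""
        entries = tuple(
            e for e in (normalize_entry(r) for r in raw_entries) if e != BLANK
        )
        return cls(participant_id, group, timepoint, entries)


@dataclass(frozen=True)
class MatchRecord:
    """Assignment of one written entry to one target slot (1-based).

    ``entry_index`` is None for an unrecalled target (a NULL error);
    ``target_index`` is None for a written entry no target would accept
    (an unassigned insertion). ``distance`` is the edit distance for
    assigned pairs.
    """

    entry_index: Optional[int]
    target_index: Optional[int]
    category: Optional[str] = None
    distance: Optional[int] = None

    def __post_init__(self):
        if self.entry_index is None and self.target_index is None:
            raise ValueError("a match record must reference an entry or a target")
        if self.category == NULL and self.entry_index is not None:
            raise ValueError("NULL records correspond to unwritten targets")


def similarity(entry: str, target: str, lexicon: Optional[Lexicon] = None) -> float:
    """String similarity in [0, 1] used for entry-target assignment.

    Base similarity is 1 - d/max(|a|, |b|) with d the edit distance.
    If both tokens are two-morpheme compounds sharing their modifier or
    their head, similarity is floored at 0.75: half the compound is an
    exact match, so the pair should survive the assignment floor even
    when the other morpheme is completely different (the "metalspot"
    insertion pattern).
    """
    if entry == target:
        return 1.0
    d = edit_distance(entry, target)
    sim = 1.0 - d / max(len(entry), len(target))
    if lexicon is not None:
        for e_mod, e_head in lexicon.splits(entry):
            for t_mod, t_head in lexicon.splits(target):
                if e_mod == t_mod or e_head == t_head:
                    return max(sim, 0.75)
    return sim


def assign_entries(
    entries: Sequence[str],
    targets: WordList,
    cfg: ScoringConfig = ScoringConfig(),
    lexicon: Optional[Lexicon] = None,
) -> list[MatchRecord]:
    """One-to-one maximum-similarity assignment of entries to targets.

    Returns records without final categories: assigned pairs carry their
    edit distance, unmatched targets become NULL records and unassigned
    entries become target-less records. Deterministic; among equally
    similar assignments, lower target index then lower entry index wins.
    """
    if len(targets) == 0:  # pragma: no cover - WordList forbids this
        raise ValueError("empty target list")
    n_e, n_t = len(entries), len(targets)
    records: list[MatchRecord] = []
    assigned_entries: set[int] = set()
    assigned_targets: set[int] = set()
    if n_e:
        sim = np.empty((n_e, n_t))
        for i, e in enumerate(entries):
            for j, t in enumerate(targets.canonical):
                sim[i, j] = similarity(e, t, lexicon)
        # Tiny index-dependent terms steer tie-breaks without disturbing
        # genuinely different similarities (which differ by at least
        # ~1/L**2 for tokens of length <= L): prefer lower target index,
        # then lower entry index, and pair equal-similarity duplicates in
        # order (the rearrangement term -e*t is maximized by sorting).
        t_idx = np.arange(n_t)[None, :]
        e_idx = np.arange(n_e)[:, None]
        cost = -sim + 1e-7 * t_idx + 1e-8 * e_idx - 1e-10 * e_idx * t_idx
        rows, cols = linear_sum_assignment(cost)
        for i, j in zip(rows, cols):
            if sim[i, j] >= cfg.assignment_min_similarity:
                records.append(
                    MatchRecord(
                        entry_index=int(i) + 1,
                        target_index=int(j) + 1,
                        distance=edit_distance(entries[i], targets.canonical[j]),
                    )
                )
                assigned_entries.add(i)
                assigned_targets.add(j)
    for j in range(n_t):
        if j not in assigned_targets:
            records.append(
                MatchRecord(entry_index=None, target_index=j + 1, category=NULL)
            )
    for i in range(n_e):
        if i not in assigned_entries:
            records.append(MatchRecord(entry_index=i + 1, target_index=None))
    return records


def _single_morpheme_variant(
    entry: str, target: str, lexicon: Lexicon, max_dist: int
) -> bool:
    """True when entry and target are compounds differing in exactly one
    morpheme, and that morpheme changed by at most ``max_dist`` edits.

    Covers near misses where the token-level distance check would be
    blind to the compound structure ("angelwing" for "anglewing" alters
    only the modifier). A wholesale morpheme replacement ("metalspot"
    for "metalmark") fails the per-morpheme distance bound and is left
    to be classified as an insertion.
    """
    for e_mod, e_head in lexicon.splits(entry):
        for t_mod, t_head in lexicon.splits(target):
            if e_mod == t_mod and e_head != t_head:
                if edit_distance(e_head, t_head) <= max_dist:
                    return True
            elif e_head == t_head and e_mod != t_mod:
                if edit_distance(e_mod, t_mod) <= max_dist:
                    return True
    return False


def classify_match(
    entry: str,
    target: str,
    lexicon: Lexicon,
    cfg: ScoringConfig = ScoringConfig(),
) -> str:
    """Categorize an assigned entry/target pair.

    CORRECT: exact reproduction, or a small error (edit distance within
    ``max_spelling_distance``) that is not a meaningful word — a pure
    spelling slip like "meselmark".
    NEAR_MISS: a small error (token-level or confined to one compound
    morpheme) that *is* a meaningful word, like "metalmask".
    INS: anything else — a completely different word written in the
    target's place, like "metalspot".
    """
    if entry == target:
        return CORRECT
    d = edit_distance(entry, target)
    small = d <= cfg.max_spelling_distance or _single_morpheme_variant(
        entry, target, lexicon, cfg.max_spelling_distance
    )
    if small and lexicon.is_meaningful(entry):
        return NEAR_MISS
    if d <= cfg.max_spelling_distance:
        return CORRECT
    return INS


def _scorable(matches: Iterable[MatchRecord], include_near: bool) -> list[MatchRecord]:
    cats = {CORRECT, NEAR_MISS} if include_near else {CORRECT}
    return [
        m
        for m in matches
        if m.category in cats and m.entry_index is not None and m.target_index is not None
    ]


def position_errors(
    matches: Iterable[MatchRecord],
    mode: SequenceMode = "rank_based",
    include_near_miss: bool = False,
) -> tuple[dict[int, int], int]:
    """Positional distances of sequence-scorable items and their sum.

    Returns ``(distances, position_sum)`` with ``distances`` keyed by
    target index. In ``rank_based`` mode the distance is the difference
    between an item's rank among the written scorable entries and its
    rank among the recalled targets, so omissions do not shift every
    later item; the sum is then always even. ``literal_position`` uses
    raw 1-based sheet and list positions.
    """
    scorable = _scorable(matches, include_near_miss)
    distances: dict[int, int] = {}
    if mode == "literal_position":
        for m in scorable:
            distances[m.target_index] = abs(m.entry_index - m.target_index)
    else:
        by_entry = sorted(scorable, key=lambda m: m.entry_index)
        by_target = sorted(scorable, key=lambda m: m.target_index)
        entry_rank = {m.target_index: r for r, m in enumerate(by_entry, start=1)}
        target_rank = {m.target_index: r for r, m in enumerate(by_target, start=1)}
        for m in scorable:
            distances[m.target_index] = abs(
                entry_rank[m.target_index] - target_rank[m.target_index]
            )
    return distances, sum(distances.values())


def sequence_index(position_sum: int, n_correct: int) -> Optional[float]:
    """SeqI = (position_sum / 2) / n_correct; None when nothing was correct.

    An undefined index is reported as missing, never as 0 (0 means a
    perfectly ordered sheet).
    """
    if position_sum < 0 or n_correct < 0:
        raise ValueError("position_sum and n_correct must be non-negative")
    if n_correct == 0:
        return None
    return (position_sum / 2.0) / n_correct


@dataclass(frozen=True)
class ScoredSheet:
    """Scored summary of one response sheet.

    ``n_ins`` counts all insertions; ``n_ins_assigned`` only those that
    occupied a target's slot, which is the number entering the partition
    n_correct + n_near + n_null + n_ins_assigned + n_rem = list length.
    ``seq_index`` is None when no item was correct.
    """

    participant_id: str
    group: str
    timepoint: str
    n_correct: int
    n_near: int
    n_ins: int
    n_ins_assigned: int
    n_null: int
    n_rem: int
    position_sum: int
    seq_index: Optional[float]
    matches: tuple[MatchRecord, ...] = field(repr=False, default=())
    entries: tuple[str, ...] = field(repr=False, default=())


def count_removals(
    prev: ScoredSheet,
    curr: ScoredSheet,
    precedence: RemovalPrecedence = "null_first",
) -> list[int]:
    """Target indices whose omission at ``curr`` counts as a removal.

    A removal candidate is a target CORRECT at the previous timepoint
    for which the current sheet holds a NULL record (no replacement that
    fell into another category). Under the default ``null_first``
    precedence the omission stays a NULL error and no removals are
    returned; under ``removal_first`` every candidate is reclassified.
    """
    if prev.participant_id != curr.participant_id:
        raise ValueError(
            f"removal counting needs one participant, got "
            f"{prev.participant_id!r} and {curr.participant_id!r}"
        )
    if precedence == "null_first":
        return []
    prev_correct = {
        m.target_index for m in prev.matches if m.category == CORRECT
    }
    return sorted(
        m.target_index
        for m in curr.matches
        if m.category == NULL and m.target_index in prev_correct
    )


def score_sheet(
    sheet: ResponseSheet,
    targets: WordList,
    lexicon: Lexicon,
    cfg: ScoringConfig = ScoringConfig(),
    prev: Optional[ScoredSheet] = None,
) -> ScoredSheet:
    """Score one response sheet end to end.

    Composes normalization, assignment, classification, positional
    distances, the Sequence Index and (when ``prev`` is given) removal
    counting. Deterministic for fixed inputs and configuration.
    """
    entries = tuple(
        e for e in (normalize_entry(r) for r in sheet.entries) if e != BLANK
    )
    records = assign_entries(entries, targets, cfg, lexicon)
    classified: list[MatchRecord] = []
    for m in records:
        if m.category is not None:
            classified.append(m)
        elif m.target_index is None:
            classified.append(replace(m, category=INS))
        else:
            cat = classify_match(
                entries[m.entry_index - 1],
                targets.canonical[m.target_index - 1],
                lexicon,
                cfg,
            )
            classified.append(replace(m, category=cat))

    include_near = cfg.near_miss_counts_toward_correct_responses
    _, pos_sum = position_errors(classified, cfg.sequence_mode, include_near)

    n_correct = sum(m.category == CORRECT for m in classified)
    n_near = sum(m.category == NEAR_MISS for m in classified)
    n_ins = sum(m.category == INS for m in classified)
    n_ins_assigned = sum(
        m.category == INS and m.target_index is not None for m in classified
    )
    n_null = sum(m.category == NULL for m in classified)

    scored = ScoredSheet(
        participant_id=sheet.participant_id,
        group=sheet.group,
        timepoint=sheet.timepoint,
        n_correct=n_correct,
        n_near=n_near,
        n_ins=n_ins,
        n_ins_assigned=n_ins_assigned,
        n_null=n_null,
        n_rem=0,
        position_sum=pos_sum,
        seq_index=sequence_index(pos_sum, n_correct + n_near * include_near),
        matches=tuple(classified),
        entries=entries,
    )
    if prev is not None:
        removed = count_removals(prev, scored, cfg.removal_precedence)
        if removed:
            removed_set = set(removed)
            reclassified = tuple(
                replace(m, category=REM)
                if m.category == NULL and m.target_index in removed_set
                else m
                for m in scored.matches
            )
            scored = replace(
                scored,
                n_rem=len(removed),
                n_null=scored.n_null - len(removed),
                matches=reclassified,
            )
    return scored
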