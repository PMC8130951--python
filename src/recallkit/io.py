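"""File interfaces: word lists, lexicons, response CSVs, scored CSVs.

Word lists and lexicons are plain UTF-8 text, one token per line, with
``#`` comments. Responses travel as CSV with one row per written entry
(columns participant_id, group, timepoint, entry_order, entry_text);
a participant who wrote nothing at a timepoint appears as a single row
with empty entry_text.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Union

import pandas as pd

from .scoring import Lexicon, ScoredSheet, WordList

__all__ = [
    "read_wordlist",
    "write_wordlist",
    "read_lexicon",
    "write_lexicon",
    "read_responses",
    "write_responses",
    "scored_to_frame",
    "write_scored",
]

PathLike = Union[str, Path]

RESPONSE_COLUMNS = ["participant_id", "group", "timepoint", "entry_order", "entry_text"]

SCORED_COLUMNS = [
    "participant_id",
    "group",
    "timepoint",
    "n_correct",
    "n_near",
    "n_ins",
    "n_ins_assigned",
    "n_null",
    "n_rem",
    "position_sum",
    "seq_index",
]


def _read_tokens(path: PathLike) -> list[str]:
    tokens = []
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        token = line.split("#", 1)[0].strip()
        if token:
            tokens.append(token)
    return tokens


def read_wordlist(path: PathLike) -> WordList:
    return WordList.from_tokens(_read_tokens(path))


def write_wordlist(wordlist: WordList, path: PathLike) -> None:
    Path(path).write_text("\n".join(wordlist.items) + "\n", encoding="utf-8")


def read_lexicon(path: PathLike) -> Lexicon:
    return Lexicon.from_tokens(_read_tokens(path))


def write_lexicon(lexicon: Lexicon, path: PathLike) -> None:
    tokens = sorted(lexicon.words | lexicon.morphemes)
    Path(path).write_text("\n".join(tokens) + "\n", encoding="utf-8")


class ResponseFormatError(ValueError):
    """Raised when a response CSV violates the schema."""


def read_responses(path: PathLike) -> pd.DataFrame:
    """Read and validate a response CSV.

    Entries are ordered by entry_order within each participant x
    timepoint. Missing columns and duplicate (participant, timepoint,
    entry_order) keys raise :class:`ResponseFormatError` naming the
    offending rows (1-based, header excluded).
    """
    df = pd.read_csv(path, dtype={"entry_text": str}, keep_default_na=False)
    missing = [c for c in RESPONSE_COLUMNS if c not in df.columns]
    if missing:
        raise ResponseFormatError(f"missing required columns: {', '.join(missing)}")
    df = df[RESPONSE_COLUMNS].copy()
    try:
        df["entry_order"] = df["entry_order"].astype(int)
    except (TypeError, ValueError) as exc:
        raise ResponseFormatError(f"entry_order must be integer: {exc}") from None
    dup = df.duplicated(
        subset=["participant_id", "timepoint", "entry_order"], keep=False
    )
    if dup.any():
        rows = ", ".join(str(i + 1) for i in df.index[dup][:10])
        raise ResponseFormatError(
            f"duplicate (participant_id, timepoint, entry_order) at rows {rows}"
        )
    if (df["entry_order"] < 1).any():
        rows = ", ".join(str(i + 1) for i in df.index[df["entry_order"] < 1][:10])
        raise ResponseFormatError(f"entry_order must be >= 1 at rows {rows}")
    return df.sort_values(
        ["participant_id", "timepoint", "entry_order"], kind="stable"
    ).reset_index(drop=True)


def write_responses(responses: pd.DataFrame, path: PathLike) -> None:
    responses[RESPONSE_COLUMNS].to_csv(path, index=False)


def scored_to_frame(sheets: Iterable[ScoredSheet]) -> pd.DataFrame:
    rows = []
    for s in sheets:
        rows.append(
            {
                "participant_id": s.participant_id,
                "group": s.group,
                "timepoint": s.timepoint,
                "n_correct": s.n_correct,
                "n_near": s.n_near,
                "n_ins": s.n_ins,
                "n_ins_assigned": s.n_ins_assigned,
                "n_null": s.n_null,
                "n_rem": s.n_rem,
                "position_sum": s.position_sum,
                "seq_index": s.seq_index,
            }
        )
    return pd.DataFrame(rows, columns=SCORED_COLUMNS)


def write_scored(scored: pd.DataFrame, path: PathLike) -> None:
    scored[SCORED_COLUMNS].to_csv(path, index=False)
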