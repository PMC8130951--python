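"""End-to-end orchestration: score a study, then analyze it.

The analysis mirrors the reporting structure of a three-arm recall
trial: for each of five scored parameters (correct count, Sequence
Index, near-miss / NULL / insertion counts) and each training group, a
within-group Friedman test across the three timepoints with Kendall's W
and Nemenyi pairwise contrasts; plus, per group, the ratio of eligible
participants improving to a perfect score at the first post-training
test relative to the cohort's baseline-perfect proportion. Removal
errors are too rare to test and are reported only as a raw count.

Group sizes are equalized by random exclusion before each parameter's
repeated-measures run (re-drawn independently per parameter), and
participants with an undefined Sequence Index at any timepoint are
dropped listwise for that parameter only.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .io import scored_to_frame
from .scoring import (
    TIMEPOINTS,
    Lexicon,
    ResponseSheet,
    ScoredSheet,
    ScoringConfig,
    WordList,
    score_sheet,
)
from .stats import (
    FriedmanResult,
    ImprovementResult,
    PairwiseResult,
    RepeatedMeasures,
    equalize_group_sizes,
    friedman_test,
    improvement_ratio,
    nemenyi_posthoc,
)

__all__ = ["AnalysisConfig", "Report", "score_responses", "run_analysis"]

logger = logging.getLogger("recallkit")

PARAMETERS = ("n_correct", "seq_index", "n_near", "n_null", "n_ins")


@dataclass(frozen=True)
class AnalysisConfig:
    """Analysis-stage settings.

    ``improvement_threshold`` defaults to the word-list length (a
    perfect score); ``improvement_timepoint`` is the first post-training
    test. ``equalize`` drops randomly chosen subjects from oversized
    groups, independently per parameter, before each Friedman run.
    """

    alpha: float = 0.05
    seed: int = 0
    parameters: tuple[str, ...] = PARAMETERS
    equalize: bool = True
    improvement_threshold: Optional[int] = None
    improvement_timepoint: str = "post_training"
    baseline_timepoint: str = "baseline"
    ratio_method: str = "proportion_ratio"


@dataclass
class Report:
    """Collected analysis results plus provenance.

    ``summary`` is a long-format table (group x timepoint x parameter
    with mean/sd/median/quartiles/n) ready for violin-style plotting by
    external tools.
    """

    summary: pd.DataFrame
    friedman: dict[str, dict[str, FriedmanResult]]
    pairwise: dict[str, dict[str, list[PairwiseResult]]]
    improvements: list[ImprovementResult]
    rem_total: int
    provenance: dict

    def to_dict(self) -> dict:
        return {
            "provenance": self.provenance,
            "friedman": {
                param: {g: dataclasses.asdict(r) for g, r in by_group.items()}
                for param, by_group in self.friedman.items()
            },
            "pairwise": {
                param: {
                    g: [dataclasses.asdict(r) for r in results]
                    for g, results in by_group.items()
                }
                for param, by_group in self.pairwise.items()
            },
            "improvements": [dataclasses.asdict(r) for r in self.improvements],
            "rem_total": self.rem_total,
            "summary": self.summary.to_dict(orient="records"),
        }

    def to_json(self, path) -> None:
        Path(path).write_text(
            json.dumps(self.to_dict(), indent=2, sort_keys=True, default=_jsonify),
            encoding="utf-8",
        )


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def config_hash(*configs) -> str:
    """Stable short hash of one or more (data)class configurations."""
    payload = json.dumps(
        [
            dataclasses.asdict(c) if dataclasses.is_dataclass(c) else c
            for c in configs
        ],
        sort_keys=True,
        default=str,
    )
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def score_responses(
    responses: pd.DataFrame,
    wordlist: WordList,
    lexicon: Lexicon,
    cfg: ScoringConfig = ScoringConfig(),
) -> pd.DataFrame:
    """Score every participant x timepoint sheet in a response table.

    Timepoints are chained in study order so removal errors can be
    detected against the previous sheet.
    """
    known = [t for t in TIMEPOINTS if t in set(responses["timepoint"])]
    extra = sorted(set(responses["timepoint"]) - set(TIMEPOINTS))
    order = known + extra
    sheets: list[ScoredSheet] = []
    for pid, by_pid in responses.groupby("participant_id", sort=True):
        prev = None
        for tp in order:
            rows = by_pid[by_pid["timepoint"] == tp]
            if rows.empty:
                continue
            rows = rows.sort_values("entry_order")
            raw = [t for t in rows["entry_text"].tolist() if str(t).strip()]
            sheet = ResponseSheet.from_raw(
                str(pid), str(rows["group"].iloc[0]), tp, raw
            )
            scored = score_sheet(sheet, wordlist, lexicon, cfg, prev=prev)
            sheets.append(scored)
            prev = scored
    return scored_to_frame(sheets)


def _summaries(scored: pd.DataFrame, parameters) -> pd.DataFrame:
    rows = []
    for (grp, tp), chunk in scored.groupby(["group", "timepoint"], sort=True):
        for param in parameters:
            vals = chunk[param].dropna().astype(float)
            rows.append(
                {
                    "group": grp,
                    "timepoint": tp,
                    "parameter": param,
                    "n": int(vals.size),
                    "mean": float(vals.mean()) if vals.size else np.nan,
                    "sd": float(vals.std(ddof=1)) if vals.size > 1 else np.nan,
                    "median": float(vals.median()) if vals.size else np.nan,
                    "q1": float(vals.quantile(0.25)) if vals.size else np.nan,
                    "q3": float(vals.quantile(0.75)) if vals.size else np.nan,
                }
            )
    return pd.DataFrame(rows)


def _improvements(
    scored: pd.DataFrame, config: AnalysisConfig, threshold: int
) -> list[ImprovementResult]:
    base = scored[scored["timepoint"] == config.baseline_timepoint]
    post = scored[scored["timepoint"] == config.improvement_timepoint]
    base_perfect = set(
        base.loc[base["n_correct"] >= threshold, "participant_id"]
    )
    post_perfect = set(
        post.loc[post["n_correct"] >= threshold, "participant_id"]
    )
    cohort_total = base["participant_id"].nunique()
    results = []
    for grp, chunk in base.groupby("group", sort=True):
        members = set(chunk["participant_id"])
        eligible = members - base_perfect
        improved = eligible & post_perfect
        results.append(
            improvement_ratio(
                n_improved=len(improved),
                n_eligible=len(eligible),
                baseline_perfect_total=len(base_perfect),
                cohort_total=cohort_total,
                method=config.ratio_method,
                group=str(grp),
                n_baseline_perfect_group=len(members & base_perfect),
            )
        )
    return results


def run_analysis(
    scored: pd.DataFrame,
    config: AnalysisConfig = AnalysisConfig(),
    list_length: Optional[int] = None,
) -> Report:
    """Analyze a scored study table and assemble a :class:`Report`.

    ``list_length`` (or ``config.improvement_threshold``) defines the
    perfect score for the improvement analysis.
    """
    threshold = config.improvement_threshold
    if threshold is None:
        if list_length is None:
            raise ValueError("need list_length or improvement_threshold")
        threshold = list_length

    timepoints = [t for t in TIMEPOINTS if t in set(scored["timepoint"])]
    if len(timepoints) < 2:
        raise ValueError("analysis needs at least 2 timepoints")

    friedman: dict[str, dict[str, FriedmanResult]] = {}
    pairwise: dict[str, dict[str, list[PairwiseResult]]] = {}
    exclusions: dict[str, dict[str, list[str]]] = {}
    seed_root = np.random.SeedSequence(config.seed)
    param_seeds = seed_root.spawn(len(config.parameters))

    for param, param_ss in zip(config.parameters, param_seeds):
        wide = scored.pivot(
            index="participant_id", columns="timepoint", values=param
        )[timepoints]
        group_of = scored.drop_duplicates("participant_id").set_index(
            "participant_id"
        )["group"]
        complete = wide.dropna()
        n_dropped = len(wide) - len(complete)
        if n_dropped:
            logger.info(
                "%s: dropped %d participant(s) listwise (undefined values)",
                param,
                n_dropped,
            )
        members = {
            grp: [pid for pid in complete.index if group_of[pid] == grp]
            for grp in sorted(group_of.unique())
        }
        members = {g: m for g, m in members.items() if len(m) >= 2}
        if not members:
            continue
        if config.equalize:
            target_n = min(len(m) for m in members.values())
            kept, dropped = equalize_group_sizes(
                members, target_n, np.random.default_rng(param_ss)
            )
            exclusions[param] = {g: d for g, d in dropped.items() if d}
        else:
            kept = members
        friedman[param] = {}
        pairwise[param] = {}
        for grp, pids in kept.items():
            data = RepeatedMeasures(
                values=complete.loc[pids].to_numpy(dtype=float),
                subject_ids=tuple(pids),
                condition_labels=tuple(timepoints),
            )
            friedman[param][grp] = friedman_test(data)
            pairwise[param][grp] = nemenyi_posthoc(data)

    report = Report(
        summary=_summaries(scored, config.parameters),
        friedman=friedman,
        pairwise=pairwise,
        improvements=_improvements(scored, config, threshold),
        rem_total=int(scored["n_rem"].sum()),
        provenance={
            "version": __version__,
            "seed": config.seed,
            "alpha": config.alpha,
            "config_hash": config_hash(config),
            "improvement_threshold": threshold,
            "equalization_exclusions": exclusions,
        },
    )
    return report
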