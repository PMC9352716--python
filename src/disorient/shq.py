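"""Sea Hero Quest (SHQ) scoring.

Two level families are scored:

* **Wayfinding** (allocentric): the player studies a map, then sails to three
  numbered checkpoints from memory. Outcomes are total distance travelled and
  total duration, each divided by a per-level reference to give dimensionless
  scores where higher = worse. Only level 6 feeds the downstream analysis
  (harder wayfinding levels were not administered to patients).
* **Flare** (egocentric): after following a river with one or more 90-degree
  turns, the player fires a flare back toward the start and earns 1-3 stars.
  Accuracy is the star count averaged over levels with each level weighted by
  its number of turns, so the four-turn level counts four times as much as the
  single-turn levels.

Patients who never attempted the wayfinding level can be assigned the worst
observed patient score (`impute_worst`), the rule used to keep them in the
regression stage.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

WAYFINDING_LEVELS = (6, 8, 11)
ANALYSIS_WAYFINDING_LEVEL = 6
FLARE_LEVELS = (9, 14, 19, 49)
FLARE_TURNS = {9: 1, 14: 1, 19: 1, 49: 4}
CHECKPOINTS_PER_LEVEL = 3

__all__ = [
    "ShqWayfindingResult",
    "ShqFlareResult",
    "ShqScore",
    "IncompleteLevelError",
    "wayfinding_scores",
    "flare_accuracy",
    "impute_worst",
    "read_shq_csv",
    "score_shq_table",
]


class IncompleteLevelError(ValueError):
    """Raised when a wayfinding level was not completed; use impute_worst."""


@dataclass(frozen=True)
class ShqWayfindingResult:
    level_id: int
    distance_travelled: float
    duration_s: float
    map_view_duration_s: float
    checkpoints_visited: int

    def __post_init__(self) -> None:
        if min(self.distance_travelled, self.duration_s, self.map_view_duration_s) < 0:
            raise ValueError("distances and durations must be non-negative")
        if not 0 <= self.checkpoints_visited <= CHECKPOINTS_PER_LEVEL:
            raise ValueError(
                f"checkpoints_visited must be 0..{CHECKPOINTS_PER_LEVEL}"
            )


@dataclass(frozen=True)
class ShqFlareResult:
    level_id: int
    stars: int
    n_turns: int

    def __post_init__(self) -> None:
        if self.stars not in (1, 2, 3):
            raise ValueError("stars must be 1, 2 or 3")
        if self.n_turns < 1:
            raise ValueError("n_turns must be >= 1")


@dataclass(frozen=True)
class ShqScore:
    wf_distance_score: float
    wf_duration_score: float
    flare_accuracy: float
    imputed: bool = False


def wayfinding_scores(
    result: ShqWayfindingResult,
    reference_distance: float = 1.0,
    reference_duration: float = 1.0,
) -> tuple[float, float]:
    """Normalized (distance, duration) scores for one completed level.

    Scores are ratios to the per-level references; with the default references
    the raw values pass through unchanged. Higher = worse.
    """
    if reference_distance <= 0 or reference_duration <= 0:
        raise ValueError("reference distance/duration must be positive")
    if result.checkpoints_visited < CHECKPOINTS_PER_LEVEL:
        raise IncompleteLevelError(
            f"level {result.level_id}: only {result.checkpoints_visited}/"
            f"{CHECKPOINTS_PER_LEVEL} checkpoints visited; assign a score with "
            f"impute_worst instead of scoring the incomplete run"
        )
    return (
        result.distance_travelled / reference_distance,
        result.duration_s / reference_duration,
    )


def flare_accuracy(results: Sequence[ShqFlareResult]) -> float:
    """Turn-weighted mean star rating over the flare levels played.

    Each level contributes its star rating weighted by the level's number of
    turns: sum(stars_l * turns_l) / sum(turns_l). With equal turn counts this
    reduces to the plain mean.
    """
    if len(results) == 0:
        raise ValueError("at least one flare result required")
    ids = [r.level_id for r in results]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate level_id in flare results")
    total_turns = sum(r.n_turns for r in results)
    return sum(r.stars * r.n_turns for r in results) / total_turns


def impute_worst(
    observed: Mapping[str, float], missing: Iterable[str]
) -> dict[str, float]:
    """Assign non-attempters the worst (largest) observed score.

    Scores must be oriented so larger = worse (true for both wayfinding
    scores). Observed entries are never altered.
    """
    missing = set(missing)
    if not observed:
        raise ValueError("no observed scores to impute from")
    overlap = missing & set(observed)
    if overlap:
        raise ValueError(f"participants both observed and missing: {sorted(overlap)}")
    worst = max(observed.values())
    completed = dict(observed)
    completed.update({pid: worst for pid in missing})
    return completed


_CSV_COLUMNS = [
    "participant_id", "level_id", "level_type",
    "distance", "duration_s", "map_view_s", "checkpoints", "stars", "n_turns",
]


def read_shq_csv(path) -> pd.DataFrame:
    """Read per-level results; one row per (participant, level).

    ``level_type`` is ``wayfinding`` or ``flare``; fields not applying to the
    level type are left empty.
    """
    df = pd.read_csv(path, dtype={"participant_id": str})
    missing = [c for c in _CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    return df


def score_shq_table(
    df: pd.DataFrame,
    reference_distance: float = 1.0,
    reference_duration: float = 1.0,
) -> pd.DataFrame:
    """Score every participant from a long per-level table.

    Returns a frame indexed by participant_id with wf_distance, wf_duration,
    map_view_s (analysis level only), flare_accuracy, and wf_missing flag for
    participants with no completed analysis-level wayfinding run.
    """
    rows = []
    for pid, sub in df.groupby("participant_id", sort=True):
        rec: dict[str, object] = {"participant_id": str(pid)}
        wf = sub[(sub["level_type"] == "wayfinding")
                 & (sub["level_id"] == ANALYSIS_WAYFINDING_LEVEL)]
        rec["wf_missing"] = True
        rec["wf_distance"] = rec["wf_duration"] = rec["map_view_s"] = float("nan")
        if len(wf):
            r = wf.iloc[0]
            result = ShqWayfindingResult(
                level_id=int(r["level_id"]),
                distance_travelled=float(r["distance"]),
                duration_s=float(r["duration_s"]),
                map_view_duration_s=float(r["map_view_s"]),
                checkpoints_visited=int(r["checkpoints"]),
            )
            try:
                d, t = wayfinding_scores(result, reference_distance, reference_duration)
            except IncompleteLevelError:
                pass
            else:
                rec.update(wf_distance=d, wf_duration=t,
                           map_view_s=result.map_view_duration_s, wf_missing=False)
        fl = sub[sub["level_type"] == "flare"]
        rec["flare_accuracy"] = (
            flare_accuracy([
                ShqFlareResult(int(r["level_id"]), int(r["stars"]), int(r["n_turns"]))
                for r in fl.to_dict("records")
            ])
            if len(fl)
            else float("nan")
        )
        rows.append(rec)
    return pd.DataFrame(rows).set_index("participant_id")
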