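"""Virtual Supermarket Test (VST) scoring.

The VST shows 14 first-person videos of a trolley moving through a landmark-free
virtual supermarket. After each trial the participant answers three questions:

* **egocentric orientation** — point toward the start location relative to the
  current position (categorical direction choice);
* **allocentric map orientation** — mark the destination on a blank map of the
  supermarket; scored as the Euclidean displacement between the marked point
  and the true destination, expressed as a percentage of map size;
* **heading direction** — indicate the direction faced at the end of the trial
  (categorical direction choice).

Directional answers are scored by exact match (percent correct); displacement
is averaged over trials and normalized by the map diagonal by default, so 100
is the largest possible error. Lower displacement is better; higher percent
correct is better.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

MAX_TRIALS = 14

__all__ = [
    "VstTrialResponse",
    "VstScore",
    "score_vst",
    "read_vst_csv",
    "score_vst_table",
]


@dataclass(frozen=True)
class VstTrialResponse:
    """Answers for a single VST trial.

    Coordinates are in normalized map units: the map rectangle is
    ``[0, map_width] x [0, map_height]`` with width/height defaulting to 1.
    """

    trial_id: int
    egocentric_choice: str
    egocentric_truth: str
    allocentric_point: tuple[float, float]
    allocentric_truth: tuple[float, float]
    heading_choice: str
    heading_truth: str


@dataclass(frozen=True)
class VstScore:
    """Per-participant VST component scores."""

    egocentric_pct: float
    allocentric_displacement_pct: float
    heading_pct: float
    n_trials_scored: int


def _check_in_map(point: tuple[float, float], w: float, h: float,
                  trial_id: int, which: str) -> None:
    x, y = point
    if not (0.0 <= x <= w and 0.0 <= y <= h):
        raise ValueError(
            f"trial {trial_id}: {which} coordinate ({x}, {y}) outside the "
            f"map rectangle [0, {w}] x [0, {h}]"
        )


def score_vst(
    responses: Sequence[VstTrialResponse],
    map_width: float = 1.0,
    map_height: float = 1.0,
    normalizer: str = "diagonal",
) -> VstScore:
    """Score the three VST components over the trials present.

    Parameters
    ----------
    responses
        Between 1 and 14 trial responses with unique trial ids.
    map_width, map_height
        Map rectangle dimensions (same units as the coordinates).
    normalizer
        ``"diagonal"`` divides each displacement by the map diagonal (the
        maximum possible error, bounding the score in [0, 100]);
        ``"width"`` divides by the map width.
    """
    if len(responses) == 0:
        raise ValueError("no trials")
    if len(responses) > MAX_TRIALS:
        raise ValueError(f"at most {MAX_TRIALS} trials expected, got {len(responses)}")
    if map_width <= 0 or map_height <= 0:
        raise ValueError("map dimensions must be positive")
    ids = [r.trial_id for r in responses]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate trial_id in responses")
    if normalizer == "diagonal":
        norm = math.hypot(map_width, map_height)
    elif normalizer == "width":
        norm = map_width
    else:
        raise ValueError(f"unknown normalizer {normalizer!r}")

    n = len(responses)
    ego_correct = 0
    head_correct = 0
    disp_sum = 0.0
    for r in responses:
        _check_in_map(r.allocentric_point, map_width, map_height, r.trial_id, "response")
        _check_in_map(r.allocentric_truth, map_width, map_height, r.trial_id, "truth")
        ego_correct += r.egocentric_choice == r.egocentric_truth
        head_correct += r.heading_choice == r.heading_truth
        disp_sum += math.dist(r.allocentric_point, r.allocentric_truth) / norm
    return VstScore(
        egocentric_pct=100.0 * ego_correct / n,
        allocentric_displacement_pct=100.0 * disp_sum / n,
        heading_pct=100.0 * head_correct / n,
        n_trials_scored=n,
    )


_CSV_COLUMNS = [
    "participant_id", "trial_id", "ego_choice", "ego_truth",
    "allo_x", "allo_y", "allo_truth_x", "allo_truth_y",
    "head_choice", "head_truth",
]


def read_vst_csv(path) -> dict[str, list[VstTrialResponse]]:
    """Read per-trial responses, one row per (participant, trial)."""
    df = pd.read_csv(path, dtype={"participant_id": str})
    missing = [c for c in _CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    out: dict[str, list[VstTrialResponse]] = {}
    for rec in df.itertuples(index=False):
        out.setdefault(str(rec.participant_id), []).append(
            VstTrialResponse(
                trial_id=int(rec.trial_id),
                egocentric_choice=str(rec.ego_choice),
                egocentric_truth=str(rec.ego_truth),
                allocentric_point=(float(rec.allo_x), float(rec.allo_y)),
                allocentric_truth=(float(rec.allo_truth_x), float(rec.allo_truth_y)),
                heading_choice=str(rec.head_choice),
                heading_truth=str(rec.head_truth),
            )
        )
    return out


def score_vst_table(
    responses: dict[str, Iterable[VstTrialResponse]],
    map_width: float = 1.0,
    map_height: float = 1.0,
) -> pd.DataFrame:
    """Score every participant; returns a frame indexed by participant_id."""
    rows = []
    for pid in sorted(responses):
        s = score_vst(list(responses[pid]), map_width, map_height)
        rows.append(
            {
                "participant_id": pid,
                "egocentric_pct": s.egocentric_pct,
                "allocentric_displacement_pct": s.allocentric_displacement_pct,
                "heading_pct": s.heading_pct,
                "n_trials_scored": s.n_trials_scored,
            }
        )
    return pd.DataFrame(rows).set_index("participant_id")
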