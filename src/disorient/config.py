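"""Analysis configuration with JSON round-trip."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path


@dataclass
class AnalysisConfig:
    """Settings consumed by the scoring and analysis modules.

    Parameters
    ----------
    alpha_normality
        Per-group Shapiro-Wilk level gating the t-test vs rank-sum choice.
    dnt_normalization
        ``"split"`` divides wrong turns by the intersection count and
        hesitations by route length (the two components then sum to the route
        score); ``"combined"`` divides the summed event count by
        intersections x distance.
    dnt_risk_tolerance
        Half-width of the band around 1 inside which a composite
        disorientation score counts as "no differential disorientation"
        (low risk). Route scores are exact rationals of event counts, so the
        default is effectively an exact-equality test.
    shq_reference_distance, shq_reference_duration
        Per-level normalizers for the wayfinding distance/duration scores.
        The published normalization is not recoverable, so the default (1.0)
        passes raw values through; every downstream contrast is
        scale-invariant.
    impute_nonattempters
        Whether the regression stage fills wayfinding scores of patients who
        never attempted the level with the worst observed patient score.
    """

    alpha_normality: float = 0.05
    dnt_normalization: str = "split"
    dnt_risk_tolerance: float = 1e-9
    shq_reference_distance: float = 1.0
    shq_reference_duration: float = 1.0
    impute_nonattempters: bool = True
    seed: int = 0
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if self.dnt_normalization not in ("split", "combined"):
            raise ValueError(
                f"dnt_normalization must be 'split' or 'combined', "
                f"got {self.dnt_normalization!r}"
            )
        if not 0 < self.alpha_normality < 1:
            raise ValueError("alpha_normality must be in (0, 1)")
        if self.dnt_risk_tolerance <= 0:
            raise ValueError("dnt_risk_tolerance must be positive")

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "AnalysisConfig":
        p = Path(str(source))
        text = p.read_text() if p.is_file() else str(source)
        payload = json.loads(text)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**payload)
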