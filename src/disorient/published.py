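"""Published cohort summary statistics.

The study cohort (21 healthy controls, 16 community-dwelling Alzheimer's
patients) is described only by group-level summaries: per-variable means and
standard deviations, row-specific sample sizes, significance flags and pooled-SD
Cohen's d. Those summaries serve two roles here:

* defaults for the synthetic cohort generator (:mod:`disorient.simulate`), and
* inputs for the ``reproduce-table2`` check, which recomputes each printed
  effect size from the printed moments alone.

Sample-size bookkeeping is row specific: two patients never attempted the
wayfinding level (n=14 for the distance row), while the duration and
detour-route rows reproduce their printed d with the full n=16.
"""

from __future__ import annotations

from dataclasses import dataclass

N_CONTROLS = 21
N_PATIENTS = 16


@dataclass(frozen=True)
class GroupSummary:
    """Printed mean/SD/n for one group on one variable."""

    mean: float
    sd: float
    n: int


@dataclass(frozen=True)
class PublishedRow:
    """One row of the published group-difference table."""

    variable: str
    label: str
    control: GroupSummary
    patient: GroupSummary
    significant: bool
    cohens_d: float | None  # printed effect size; None where not reported
    lower: float  # support bounds used by the generator
    upper: float


# VR and community navigation variables (group-difference table).
NAVIGATION_ROWS: tuple[PublishedRow, ...] = (
    PublishedRow(
        "egocentric_pct", "Egocentric Orientation (% Correct)",
        GroupSummary(81.49, 21.67, 21), GroupSummary(30.35, 19.25, 16),
        True, 2.47, 0.0, 100.0,
    ),
    PublishedRow(
        "allocentric_displacement_pct",
        "Allocentric Map Orientation (Displacement; % of Map Size)",
        GroupSummary(18.57, 7.16, 21), GroupSummary(26.44, 8.07, 16),
        True, 1.04, 0.0, 100.0,
    ),
    PublishedRow(
        "heading_pct", "Heading Direction (% Correct)",
        GroupSummary(83.76, 16.37, 21), GroupSummary(34.37, 22.46, 16),
        True, 2.57, 0.0, 100.0,
    ),
    PublishedRow(
        "wf_distance", "Wayfinding Distance Score",
        GroupSummary(0.71, 0.27, 21), GroupSummary(1.21, 0.55, 14),
        True, 1.24, 0.2, 6.0,
    ),
    PublishedRow(
        "wf_duration", "Wayfinding Duration Score",
        GroupSummary(0.73, 0.27, 21), GroupSummary(1.25, 0.63, 16),
        True, 1.13, 0.2, 6.0,
    ),
    PublishedRow(
        "flare_accuracy", "Flare Accuracy Score",
        GroupSummary(2.30, 0.54, 21), GroupSummary(2.12, 0.54, 16),
        False, None, 1.0, 3.0,
    ),
    PublishedRow(
        "original_score", "Original Route Disorientation Score",
        GroupSummary(0.00, 0.00, 21), GroupSummary(0.01, 0.07, 16),
        False, None, 0.0, 20.0,
    ),
    PublishedRow(
        "detour_score", "Detour Route Disorientation Score",
        GroupSummary(0.001, 0.008, 21), GroupSummary(0.25, 0.50, 16),
        True, 0.76, 0.0, 20.0,
    ),
)

# Demographic / screening variables (participant table). The printed d for
# education and Mini-ACE do not reproduce from these rounded moments (they were
# presumably computed on unrounded data), so they are generator defaults only.
DEMOGRAPHIC_ROWS: tuple[PublishedRow, ...] = (
    PublishedRow(
        "age", "Age (Years)",
        GroupSummary(68.36, 7.57, 21), GroupSummary(70.25, 6.63, 16),
        False, None, 50.0, 80.0,
    ),
    PublishedRow(
        "education_years", "Education (Years)",
        GroupSummary(15.65, 2.96, 21), GroupSummary(12.81, 1.72, 16),
        True, None, 5.0, 25.0,
    ),
    PublishedRow(
        "mini_ace", "Mini-ACE Score",
        GroupSummary(28.59, 1.43, 21), GroupSummary(18.25, 5.47, 16),
        True, None, 0.0, 30.0,
    ),
)

# Rows whose printed Cohen's d is recomputed by ``reproduce-table2``
# (variable name -> printed d), in table order with duration last.
EFFECT_SIZE_ROWS: tuple[str, ...] = (
    "egocentric_pct",
    "allocentric_displacement_pct",
    "heading_pct",
    "wf_distance",
    "detour_score",
    "wf_duration",
)

# Published regression pairings of R-squared and Cohen's f-squared for the
# wayfinding -> composite-disorientation models (main and post-hoc fits).
R2_F2_PAIRS: tuple[tuple[float, tuple[float, ...]], ...] = (
    (0.29, (0.41, 0.42)),
    (0.27, (0.37,)),
    (0.26, (0.35, 0.36)),
    (0.22, (0.28, 0.29)),
)


def row(variable: str) -> PublishedRow:
    """Look up a published row by variable name."""
    for r in NAVIGATION_ROWS + DEMOGRAPHIC_ROWS:
        if r.variable == variable:
            return r
    raise KeyError(variable)
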