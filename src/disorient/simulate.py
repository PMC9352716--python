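"""Synthetic cohorts and walk event streams.

The patient-level data behind the published study are not deposited, so this
module generates cohorts with the statistical structure the analysis assumes:

* **Score-level cohorts** (:func:`gen_cohort_scores`): per-variable,
  per-group marginals are *censored (clipped) normals* whose latent (mu,
  sigma) are solved so the clipped draw reproduces the published group mean
  and SD exactly. Censoring — rather than renormalized truncation — is what
  the data demand: percent-correct scores pile up at the 100% ceiling, and
  disorientation scores pile up at exactly zero (which is what makes a
  composite score of exactly 1, i.e. "low risk", possible at all). Several
  published (mean, SD) pairs are unattainable by any renormalized truncated
  normal on the same support. An optional Gaussian copula couples selected
  variables (by default wayfinding distance/duration with the detour-route
  disorientation score) through the latent normals.
* **Event-level walks** (:func:`gen_dnt_walks` on
  :func:`make_neighborhood_graph`): Bernoulli wrong turns per intersection
  and Poisson hesitations per km on a synthetic street grid, built so planted
  events are re-detected exactly by :func:`disorient.dnt.detect_wrong_turns`.
* **Trial-level VST responses** (:func:`gen_vst_responses`).

A single study seed fans out to per-participant substreams, so adding a
participant never perturbs earlier draws.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.stats import norm

from . import published
from .dnt import RESET, NavEvent, RouteWalk, StreetGraph

__all__ = [
    "VariableSpec",
    "CohortParams",
    "WalkProfile",
    "gen_cohort_scores",
    "gen_vst_responses",
    "gen_dnt_walks",
    "make_neighborhood_graph",
    "censored_normal_params",
    "PATIENT_WALK_PROFILE",
    "CONTROL_WALK_PROFILE",
    "ORIGINAL_ROUTE_PROFILE",
]


@dataclass(frozen=True)
class VariableSpec:
    """Target moments and support for one variable in one group."""

    mean: float
    sd: float
    lower: float = -math.inf
    upper: float = math.inf

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be non-negative")
        if not self.lower <= self.upper:
            raise ValueError("inconsistent bounds")


@dataclass
class CohortParams:
    """Generator settings; defaults reproduce the published cohort tables."""

    variables: dict  # variable -> {"control": VariableSpec, "patient": VariableSpec}
    n_controls: int = published.N_CONTROLS
    n_patients: int = published.N_PATIENTS
    #: pairwise latent correlations, (var_a, var_b) -> rho
    latent_corr: dict = field(default_factory=dict)
    #: patients who never attempted the wayfinding level (scores set missing)
    n_wf_missing: int = 2
    #: patients unable to complete the detour route (DNT score set missing)
    n_dnt_missing: int = 1
    seed: int = 0

    @classmethod
    def default(cls, seed: int = 0) -> "CohortParams":
        variables: dict = {}
        for row in published.DEMOGRAPHIC_ROWS + published.NAVIGATION_ROWS:
            variables[row.variable] = {
                "control": VariableSpec(row.control.mean, row.control.sd,
                                        row.lower, row.upper),
                "patient": VariableSpec(row.patient.mean, row.patient.sd,
                                        row.lower, row.upper),
            }
        # Map-view duration is not published; plausible values for a study-map
        # phase (seconds), patients lingering longer, used only as the ANCOVA
        # covariate.
        variables["map_view_s"] = {
            "control": VariableSpec(45.0, 25.0, 5.0, 600.0),
            "patient": VariableSpec(75.0, 45.0, 5.0, 600.0),
        }
        # Latent coupling: the one published cross-test relation is wayfinding
        # -> composite disorientation (R2 ~ 0.29), emulated as rho = 0.55
        # between the wayfinding scores and the detour-route score; distance
        # and duration share most of their variance.
        corr = {
            ("wf_distance", "wf_duration"): 0.80,
            ("wf_distance", "detour_score"): 0.55,
            ("wf_duration", "detour_score"): 0.44,
        }
        return cls(variables=variables, latent_corr=corr, seed=seed)


_MOMENT_CACHE: dict[tuple, tuple[float, float]] = {}


def _censored_moments(mu: float, sigma: float, a: float, b: float) -> tuple[float, float]:
    """Mean and SD of clip(Normal(mu, sigma), a, b), in closed form."""
    alpha = (a - mu) / sigma if math.isfinite(a) else -math.inf
    beta = (b - mu) / sigma if math.isfinite(b) else math.inf
    Fa = norm.cdf(alpha) if math.isfinite(alpha) else 0.0
    Fb = norm.cdf(beta) if math.isfinite(beta) else 1.0
    fa = norm.pdf(alpha) if math.isfinite(alpha) else 0.0
    fb = norm.pdf(beta) if math.isfinite(beta) else 0.0
    afa = alpha * fa if math.isfinite(alpha) else 0.0
    bfb = beta * fb if math.isfinite(beta) else 0.0
    dF = Fb - Fa
    m = mu * dF + sigma * (fa - fb)
    if math.isfinite(a):
        m += a * Fa
    if math.isfinite(b):
        m += b * (1.0 - Fb)
    # E[Z^2 1{a<Z<b}] for Z = mu + sigma W
    ez2 = mu**2 * dF + 2 * mu * sigma * (fa - fb) + sigma**2 * (dF - (bfb - afa))
    e2 = ez2
    if math.isfinite(a):
        e2 += a**2 * Fa
    if math.isfinite(b):
        e2 += b**2 * (1.0 - Fb)
    var = max(e2 - m**2, 0.0)
    return m, math.sqrt(var)


def censored_normal_params(spec: VariableSpec) -> tuple[float, float]:
    """Latent (mu, sigma) whose censored draw has the requested mean and SD.

    Raises if the target mean lies outside the support or the two-moment
    system cannot be solved to working precision.
    """
    key = (spec.mean, spec.sd, spec.lower, spec.upper)
    if key in _MOMENT_CACHE:
        return _MOMENT_CACHE[key]
    if not spec.lower <= spec.mean <= spec.upper:
        raise ValueError(
            f"infeasible target: mean {spec.mean} outside support "
            f"[{spec.lower}, {spec.upper}]"
        )
    if spec.sd == 0:
        _MOMENT_CACHE[key] = (spec.mean, 0.0)
        return spec.mean, 0.0
    scale = max(spec.sd, abs(spec.mean), 1e-6)

    def resid(theta):
        mu, log_sigma = theta
        m, s = _censored_moments(mu, math.exp(log_sigma), spec.lower, spec.upper)
        return [(m - spec.mean) / scale, (s - spec.sd) / scale]

    sol = optimize.least_squares(
        resid, x0=[spec.mean, math.log(spec.sd)], xtol=1e-14, ftol=1e-14, gtol=1e-14
    )
    err = float(np.abs(sol.fun).max()) * scale
    if err > 1e-6 * scale + 1e-9:
        raise ValueError(
            f"could not match censored-normal moments for {spec}: residual {err:g}"
        )
    out = (float(sol.x[0]), float(math.exp(sol.x[1])))
    _MOMENT_CACHE[key] = out
    return out


def _latent_cholesky(order: Sequence[str], latent_corr: dict) -> np.ndarray:
    k = len(order)
    R = np.eye(k)
    idx = {v: i for i, v in enumerate(order)}
    for (a, b), rho in latent_corr.items():
        if a not in idx or b not in idx:
            raise KeyError(f"latent_corr names unknown variable in ({a}, {b})")
        if not -1 < rho < 1:
            raise ValueError("latent correlations must lie in (-1, 1)")
        R[idx[a], idx[b]] = R[idx[b], idx[a]] = rho
    if np.linalg.eigvalsh(R).min() < -1e-10:
        raise ValueError("latent correlation matrix is not positive semidefinite")
    return np.linalg.cholesky(R + 1e-12 * np.eye(k))


def gen_cohort_scores(
    params: CohortParams | None = None,
    seed: int | None = None,
    n_controls: int | None = None,
    n_patients: int | None = None,
) -> pd.DataFrame:
    """Draw a participant x variable cohort table.

    Deterministic given the seed; per-participant substreams keep draws stable
    when the cohort grows. The composite disorientation score and the
    missing-data flags consumed by the analysis pipeline are attached.
    """
    params = params if params is not None else CohortParams.default()
    seed = params.seed if seed is None else int(seed)
    n_by_group = {
        "control": params.n_controls if n_controls is None else int(n_controls),
        "patient": params.n_patients if n_patients is None else int(n_patients),
    }
    order = list(params.variables)
    L = _latent_cholesky(order, params.latent_corr)
    solved = {
        (v, g): censored_normal_params(params.variables[v][g])
        for v in order
        for g in ("control", "patient")
    }
    rows = []
    for g_i, group in enumerate(("control", "patient")):
        prefix = "C" if group == "control" else "P"
        for i in range(n_by_group[group]):
            rng = np.random.default_rng(np.random.SeedSequence([seed, g_i, i]))
            z = L @ rng.standard_normal(len(order))
            rec: dict[str, object] = {
                "participant_id": f"{prefix}{i + 1:03d}",
                "group": group,
            }
            for v, z_v in zip(order, z):
                mu, sigma = solved[(v, group)]
                spec = params.variables[v][group]
                rec[v] = float(np.clip(mu + sigma * z_v, spec.lower, spec.upper))
            rows.append(rec)
    df = pd.DataFrame(rows)

    df["wf_missing"] = False
    df["dnt_missing"] = False
    patients = df.index[df["group"] == "patient"].to_numpy()
    pick = np.random.default_rng(np.random.SeedSequence([seed, 7001]))
    chosen = pick.choice(patients, size=min(params.n_wf_missing + params.n_dnt_missing,
                                            len(patients)), replace=False)
    wf_lost = chosen[: params.n_wf_missing]
    dnt_lost = chosen[params.n_wf_missing:]
    df.loc[wf_lost, "wf_missing"] = True
    df.loc[wf_lost, ["wf_distance", "wf_duration", "map_view_s"]] = np.nan
    df.loc[dnt_lost, "dnt_missing"] = True
    df.loc[dnt_lost, ["original_score", "detour_score"]] = np.nan

    if {"original_score", "detour_score"} <= set(df.columns):
        with np.errstate(invalid="ignore"):
            df["composite"] = (df["detour_score"] + 1.0) / (df["original_score"] + 1.0)
    return df.sort_values("participant_id").reset_index(drop=True)


# --------------------------------------------------------------------------
# Trial-level VST responses

_DIRECTIONS = ("north", "east", "south", "west")


def gen_vst_responses(
    p_ego: float,
    disp_sigma: float,
    p_head: float,
    n_trials: int = 14,
    seed: int = 0,
    map_width: float = 1.0,
    map_height: float = 1.0,
):
    """Simulate one participant's trial responses.

    Directional answers are correct with the stated probabilities (errors drawn
    uniformly from the remaining options); the allocentric mark is the true
    location plus isotropic Gaussian noise with SD ``disp_sigma`` (map units),
    clipped to the map rectangle.
    """
    from .vst import MAX_TRIALS, VstTrialResponse

    if not (0 <= p_ego <= 1 and 0 <= p_head <= 1):
        raise ValueError("probabilities must lie in [0, 1]")
    if disp_sigma < 0:
        raise ValueError("disp_sigma must be non-negative")
    if not 1 <= n_trials <= MAX_TRIALS:
        raise ValueError(f"n_trials must be 1..{MAX_TRIALS}")
    rng = np.random.default_rng(seed)
    out = []
    for t in range(1, n_trials + 1):
        truths = rng.choice(_DIRECTIONS, size=2)
        choices = []
        for truth, p in zip(truths, (p_ego, p_head)):
            if rng.random() < p:
                choices.append(str(truth))
            else:
                choices.append(str(rng.choice([d for d in _DIRECTIONS if d != truth])))
        tx, ty = rng.uniform(0, map_width), rng.uniform(0, map_height)
        px = float(np.clip(tx + rng.normal(0, disp_sigma) if disp_sigma else tx,
                           0, map_width))
        py = float(np.clip(ty + rng.normal(0, disp_sigma) if disp_sigma else ty,
                           0, map_height))
        out.append(
            VstTrialResponse(
                trial_id=t,
                egocentric_choice=choices[0], egocentric_truth=str(truths[0]),
                allocentric_point=(px, py), allocentric_truth=(tx, ty),
                heading_choice=choices[1], heading_truth=str(truths[1]),
            )
        )
    return out


# --------------------------------------------------------------------------
# Event-level DNT walks

@dataclass(frozen=True)
class WalkProfile:
    """Event-rate profile for one walk."""

    p_wrong_turn: float  # per evaluated intersection
    hesitation_rate: float  # events per km
    route_length_km: float | None = None  # informational; geometry rules
    n_intersections: int | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.p_wrong_turn <= 1:
            raise ValueError("p_wrong_turn must lie in [0, 1]")
        if self.hesitation_rate < 0:
            raise ValueError("hesitation_rate must be non-negative")


#: Detour-route defaults calibrated to the published component means under the
#: per-intersection / per-km normalization (patients ~0.02 wrong turns per
#: intersection and ~0.23 hesitations per km; controls almost event-free).
PATIENT_WALK_PROFILE = WalkProfile(p_wrong_turn=0.02, hesitation_rate=0.23)
CONTROL_WALK_PROFILE = WalkProfile(p_wrong_turn=0.0, hesitation_rate=0.001)
#: Original (familiar) routes are essentially error-free for both groups.
ORIGINAL_ROUTE_PROFILE = WalkProfile(p_wrong_turn=0.0, hesitation_rate=0.005)


def make_neighborhood_graph(
    n_blocks: int = 5, block_km: float = 0.12
) -> tuple[StreetGraph, list[str], list[str]]:
    """Synthetic street grid admitting a home->landmark route and a
    non-overlapping detour home.

    The original route runs along one street (nodes ``A*``), the detour along
    a parallel street (nodes ``D*``). Every route intersection has an
    off-route branch (stubs ``T*`` on the original route; spur chains
    ``S*``/``W*`` on the detour, so a wrong turn can be followed by a second
    consecutive wrong turn before the positional reset). Returns
    ``(graph, original_route, detour_route)``; the routes are also stashed on
    the graph as ``original_route`` / ``detour_route`` attributes.
    """
    if n_blocks < 2:
        raise ValueError("need at least two blocks")
    g = StreetGraph()
    a_nodes = [f"A{i}" for i in range(n_blocks + 1)]  # A0 = home, last = landmark
    d_nodes = [f"D{i}" for i in range(1, n_blocks)]
    for i, n in enumerate(a_nodes):
        g.add_node(n, i * block_km, 0.0)
    for i, n in enumerate(d_nodes, start=1):
        g.add_node(n, i * block_km, block_km)
    for u, v in zip(a_nodes, a_nodes[1:]):
        g.add_edge(u, v, block_km)
    for u, v in zip(d_nodes, d_nodes[1:]):
        g.add_edge(u, v, block_km)
    g.add_edge(a_nodes[-1], d_nodes[-1], block_km)  # landmark joins detour street
    g.add_edge(d_nodes[0], a_nodes[0], block_km)  # detour street rejoins home
    for i in range(1, n_blocks):
        g.add_node(f"T{i}", i * block_km, -block_km)
        g.add_edge(a_nodes[i], f"T{i}", block_km)  # stub off the original route
        s, wa, wb = f"S{i}", f"Wa{i}", f"Wb{i}"
        g.add_node(s, i * block_km, 2 * block_km)
        g.add_node(wa, (i - 0.3) * block_km, 3 * block_km)
        g.add_node(wb, (i + 0.3) * block_km, 3 * block_km)
        g.add_edge(d_nodes[i - 1], s, block_km)  # spur off the detour route
        g.add_edge(s, wa, block_km)
        g.add_edge(s, wb, block_km)
    g.validate()
    original = list(a_nodes)
    detour = [a_nodes[-1]] + d_nodes[::-1] + [a_nodes[0]]
    g.original_route = original  # type: ignore[attr-defined]
    g.detour_route = detour  # type: ignore[attr-defined]
    return g, original, detour


def _walk_route(
    route: list[str],
    route_type: str,
    graph: StreetGraph,
    profile: WalkProfile,
    rng: np.random.Generator,
) -> RouteWalk:
    on_route = set(route)
    taken: list[str] = [route[0]]
    events: list[NavEvent] = []
    skip_wrong_at: str | None = None
    for prev, u, nxt in zip([None] + route[:-2], route[:-1], route[1:]):
        if graph.is_intersection(u) and u != skip_wrong_at:
            candidates = sorted(
                n for n in graph.g.neighbors(u)
                if n not in on_route and n != prev
            )
            if candidates and rng.random() < profile.p_wrong_turn:
                w1 = str(rng.choice(candidates))
                events.append(NavEvent("wrong_turn", u, 1))
                second = sorted(n for n in graph.g.neighbors(w1) if n != u)
                if (graph.is_intersection(w1) and second
                        and rng.random() < profile.p_wrong_turn):
                    w2 = str(rng.choice(second))
                    events.append(NavEvent("wrong_turn", w1, 2))
                    taken += [w1, w2, RESET, u]
                    skip_wrong_at = u  # encouraged to try again; next move succeeds
                else:
                    taken += [w1, u]  # single wrong turn, then retreat
        taken.append(nxt)
    distance = graph.path_length_km(route)
    n_hes = int(rng.poisson(profile.hesitation_rate * distance))
    hes_nodes = rng.choice(np.asarray(route, dtype=object), size=n_hes, replace=True)
    events += [NavEvent("hesitation", str(n)) for n in hes_nodes]
    return RouteWalk(route_type=route_type, planned_path=list(route),
                     taken_path=taken, events=events)


def gen_dnt_walks(
    graph: StreetGraph,
    profile: WalkProfile,
    seed: int = 0,
    original_profile: WalkProfile | None = None,
) -> tuple[RouteWalk, RouteWalk]:
    """Simulate one participant's (original, detour) walk pair.

    ``profile`` drives both walks unless ``original_profile`` overrides the
    familiar route. Planted wrong-turn events satisfy the round-trip property:
    re-running detection on the emitted walk recovers them exactly.
    """
    original_route = getattr(graph, "original_route", None)
    detour_route = getattr(graph, "detour_route", None)
    if original_route is None or detour_route is None:
        raise ValueError(
            "graph does not define an original route and a non-overlapping "
            "detour (use make_neighborhood_graph)"
        )
    rng = np.random.default_rng(seed)
    original = _walk_route(original_route, "original", graph,
                           original_profile or profile, rng)
    detour = _walk_route(detour_route, "detour", graph, profile, rng)
    return original, detour
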