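"""Study-level model object running the four-step disorientation analysis.

:class:`DisorientationStudy` wraps a participant x variable cohort table
(group labels plus VR and community navigation scores) and its ``fit()``
executes the full analysis:

1. group differences on the VR variables (normality-gated t / rank-sum tests
   with pooled-SD Cohen's d), plus ANCOVAs re-testing the wayfinding effects
   controlling for map-view duration on inverse-transformed outcomes;
2. group differences on the community (DNT) route disorientation scores;
3. patients only — standardized linear regressions of the composite
   disorientation score on each VR variable, with worst-score imputation for
   patients who never attempted the wayfinding level;
4. patients only — binomial logistic regression of the high/low risk label on
   every step-3-significant predictor.

Patients without detour data are excluded from steps 2-4. The fitted
:class:`DisorientationResults` carries the per-step estimates and renders a
text ``summary()`` and a markdown report mirroring the published table layout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import stats as st
from .config import AnalysisConfig
from .dnt import classify_risk
from .shq import impute_worst
from .simulate import CohortParams, gen_cohort_scores

VR_VARIABLES = (
    "egocentric_pct",
    "allocentric_displacement_pct",
    "heading_pct",
    "wf_distance",
    "wf_duration",
    "flare_accuracy",
)
DNT_VARIABLES = ("original_score", "detour_score")
ANCOVA_OUTCOMES = ("wf_distance", "wf_duration")

__all__ = ["DisorientationStudy", "DisorientationResults", "run_pipeline"]


def _stars(p: float) -> str:
    if np.isnan(p):
        return "-"
    for cut, mark in ((0.001, "***"), (0.01, "**"), (0.05, "*")):
        if p < cut:
            return mark
    return "ns"


@dataclass
class DisorientationResults:
    """Fitted four-step analysis."""

    group_comparisons: list = field(default_factory=list)
    degenerate_variables: list = field(default_factory=list)
    ancova: list = field(default_factory=list)
    regressions: list = field(default_factory=list)
    logistic: list = field(default_factory=list)
    logistic_failures: dict = field(default_factory=dict)
    imputed_participants: tuple = ()
    excluded_participants: tuple = ()
    n_high: int = 0
    n_low: int = 0
    config: AnalysisConfig = field(default_factory=AnalysisConfig)

    def comparisons_frame(self) -> pd.DataFrame:
        rows = [
            {
                "variable": c.variable,
                "control_mean": c.mean1, "control_sd": c.sd1, "n_controls": c.n1,
                "patient_mean": c.mean2, "patient_sd": c.sd2, "n_patients": c.n2,
                "test": c.test_used, "statistic": c.statistic,
                "p_value": c.p_value, "significance": _stars(c.p_value),
                "cohens_d": c.cohens_d,
            }
            for c in self.group_comparisons
        ]
        return pd.DataFrame(rows)

    def regressions_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "predictor": r.predictor, "beta": r.beta_standardized,
                    "p_value": r.p_value, "r_squared": r.r_squared,
                    "f_squared": r.f_squared,
                    "residuals_normal": r.residuals_normal, "n": r.n,
                }
                for r in self.regressions
            ]
        )

    def logistic_frame(self) -> pd.DataFrame:
        rows = [
            {"predictor": f.predictor, "odds_ratio": f.odds_ratio,
             "p_value": f.p_value, "n_high": f.n_high, "n_low": f.n_low}
            for f in self.logistic
        ]
        rows += [
            {"predictor": name, "odds_ratio": np.nan, "p_value": np.nan,
             "n_high": self.n_high, "n_low": self.n_low, "note": why}
            for name, why in self.logistic_failures.items()
        ]
        return pd.DataFrame(rows)

    def summary(self) -> str:
        lines = ["Disorientation study results", "=" * 60]
        lines.append("\nStep 1-2: group differences (controls vs patients)")
        cf = self.comparisons_frame()
        for _, r in cf.iterrows():
            lines.append(
                f"  {r['variable']:<28s} {r['control_mean']:8.2f} ({r['control_sd']:.2f})"
                f" vs {r['patient_mean']:8.2f} ({r['patient_sd']:.2f})"
                f"  {r['test']:<17s} p={r['p_value']:.4f} {r['significance']:<3s}"
                f" d={r['cohens_d']:.2f}"
            )
        for v in self.degenerate_variables:
            lines.append(f"  {v:<28s} (no variation; comparison degenerate)")
        for a in self.ancova:
            lines.append(
                f"  ANCOVA {a.outcome} | {a.covariate} ({a.transform_applied}):"
                f" F({a.df_between},{a.df_within}) = {a.F_statistic:.3f},"
                f" p = {a.p_value:.4f}"
            )
        lines.append("\nStep 3: composite disorientation score ~ VR variable (patients)")
        for r in self.regressions:
            lines.append(
                f"  {r.predictor:<28s} beta={r.beta_standardized:+.3f}"
                f" p={r.p_value:.4f} R2={r.r_squared:.3f} f2={r.f_squared:.3f}"
                f" n={r.n}"
            )
        if self.imputed_participants:
            lines.append(f"  worst-score imputation: {list(self.imputed_participants)}")
        lines.append(
            f"\nStep 4: risk classification (high n={self.n_high}, low n={self.n_low})"
        )
        for f in self.logistic:
            lines.append(
                f"  {f.predictor:<28s} OR={f.odds_ratio:.2f} p={f.p_value:.4f}"
            )
        for name, why in self.logistic_failures.items():
            lines.append(f"  {name:<28s} not estimable: {why}")
        if self.excluded_participants:
            lines.append(
                f"\nExcluded from steps 2-4 (no detour data): "
                f"{list(self.excluded_participants)}"
            )
        return "\n".join(lines)

    def to_markdown_report(self) -> str:
        cf = self.comparisons_frame()
        out = [
            "# Group differences in VR/community navigation",
            "",
            "| Variable | Controls (Mean; SD) | Patients (Mean; SD) | Test | "
            "Significance | Cohen's d |",
            "|---|---|---|---|---|---|",
        ]
        for _, r in cf.iterrows():
            out.append(
                f"| {r['variable']} | {r['control_mean']:.2f} ({r['control_sd']:.2f}) |"
                f" {r['patient_mean']:.2f} ({r['patient_sd']:.2f}) | {r['test']} |"
                f" {r['significance']} | {r['cohens_d']:.2f} |"
            )
        out += ["", "# Prediction of community navigation from VR navigation", ""]
        for r in self.regressions:
            out.append(
                f"- `{r.predictor}`: beta = {r.beta_standardized:.3f}, "
                f"p = {r.p_value:.3f}, R2 = {r.r_squared:.2f}, "
                f"f2 = {r.f_squared:.2f} (n = {r.n})"
            )
        out += ["", "# Risk classification", ""]
        for f in self.logistic:
            out.append(
                f"- `{f.predictor}`: OR = {f.odds_ratio:.2f}, p = {f.p_value:.3f} "
                f"(high n = {f.n_high}, low n = {f.n_low})"
            )
        for name, why in self.logistic_failures.items():
            out.append(f"- `{name}`: not estimable ({why})")
        return "\n".join(out) + "\n"


class DisorientationStudy:
    """Two-group navigation study built from a cohort table.

    The table needs ``participant_id``, ``group`` (``control``/``patient``),
    the VR score columns, the DNT route score columns, and optionally
    ``map_view_s``, ``wf_missing``, ``dnt_missing``. Missing values are NaN.
    """

    def __init__(self, cohort: pd.DataFrame, config: AnalysisConfig | None = None):
        cohort = cohort.copy()
        required = {"participant_id", "group"}
        missing = required - set(cohort.columns)
        if missing:
            raise ValueError(f"cohort table missing columns: {sorted(missing)}")
        bad = set(cohort["group"].unique()) - {"control", "patient"}
        if bad:
            raise ValueError(f"unknown group labels: {sorted(bad)}")
        for flag in ("wf_missing", "dnt_missing"):
            if flag not in cohort.columns:
                cohort[flag] = False
            cohort[flag] = cohort[flag].astype(bool)
        if "composite" not in cohort.columns and {
            "original_score", "detour_score"
        } <= set(cohort.columns):
            cohort["composite"] = (cohort["detour_score"] + 1.0) / (
                cohort["original_score"] + 1.0
            )
        self.cohort = cohort.sort_values("participant_id").reset_index(drop=True)
        self.config = config or AnalysisConfig()

    @classmethod
    def from_csv(cls, path, config: AnalysisConfig | None = None) -> "DisorientationStudy":
        return cls(pd.read_csv(path, dtype={"participant_id": str}), config)

    @classmethod
    def from_simulation(
        cls,
        params: CohortParams | None = None,
        seed: int | None = None,
        config: AnalysisConfig | None = None,
        n_controls: int | None = None,
        n_patients: int | None = None,
    ) -> "DisorientationStudy":
        table = gen_cohort_scores(params, seed=seed, n_controls=n_controls,
                                  n_patients=n_patients)
        return cls(table, config)

    # -- pipeline ----------------------------------------------------------

    def _observed(self, group: str, var: str) -> np.ndarray:
        vals = self.cohort.loc[self.cohort["group"] == group, var].to_numpy(float)
        return vals[~np.isnan(vals)]

    def fit(self) -> DisorientationResults:
        cfg = self.config
        res = DisorientationResults(config=cfg)

        # Steps 1-2: group differences on VR then community variables.
        for var in VR_VARIABLES + DNT_VARIABLES:
            if var not in self.cohort.columns:
                continue
            x = self._observed("control", var)
            y = self._observed("patient", var)
            try:
                res.group_comparisons.append(
                    st.compare_groups(x, y, cfg.alpha_normality, variable=var)
                )
            except st.DegenerateDataError:
                res.degenerate_variables.append(var)

        # Map-view time can drive wayfinding performance: re-test the group
        # effect by ANCOVA on the inverse-transformed outcome.
        if "map_view_s" in self.cohort.columns:
            for var in ANCOVA_OUTCOMES:
                if var not in self.cohort.columns:
                    continue
                sub = self.cohort.dropna(subset=[var, "map_view_s"])
                y_pair = tuple(
                    sub.loc[sub["group"] == g, var].to_numpy(float)
                    for g in ("control", "patient")
                )
                c_pair = tuple(
                    sub.loc[sub["group"] == g, "map_view_s"].to_numpy(float)
                    for g in ("control", "patient")
                )
                if min(len(a) for a in y_pair) < 3 or np.any(
                    np.concatenate(y_pair) == 0
                ):
                    continue
                res.ancova.append(
                    st.ancova_adjusted(y_pair, c_pair, transform="inverse",
                                       outcome_name=var, covariate_name="map_view_s")
                )

        # Steps 3-4 are patient-only: controls are not expected to become
        # disoriented in their own neighbourhoods.
        pats = self.cohort[self.cohort["group"] == "patient"].copy()
        if "composite" not in pats.columns:
            return res
        excluded = pats.loc[pats["dnt_missing"] | pats["composite"].isna(),
                            "participant_id"]
        res.excluded_participants = tuple(excluded)
        pats = pats[~pats["participant_id"].isin(excluded)]
        if len(pats) < 4:
            return res

        outcome = pats.set_index("participant_id")["composite"]
        significant: list[str] = []
        predictor_values: dict[str, pd.Series] = {}
        for var in VR_VARIABLES:
            if var not in pats.columns:
                continue
            series = pats.set_index("participant_id")[var]
            if var in ("wf_distance", "wf_duration") and cfg.impute_nonattempters:
                observed = series.dropna()
                missing = series.index[series.isna()]
                if len(missing) and len(observed):
                    series = pd.Series(
                        impute_worst(observed.to_dict(), set(missing))
                    ).reindex(series.index)
                    if var == "wf_distance":
                        res.imputed_participants = tuple(sorted(missing))
            keep = series.dropna().index
            if len(keep) < 4:
                continue
            try:
                fitres = st.linear_regression_standardized(
                    series.loc[keep].to_numpy(float),
                    outcome.loc[keep].to_numpy(float),
                    predictor=var,
                )
            except st.DegenerateDataError:
                continue
            res.regressions.append(fitres)
            predictor_values[var] = series.loc[keep]
            if fitres.p_value < 0.05:
                significant.append(var)

        labels = outcome.apply(lambda c: classify_risk(c, cfg.dnt_risk_tolerance))
        res.n_high = int((labels == "high").sum())
        res.n_low = int((labels == "low").sum())
        for var in significant:
            series = predictor_values[var]
            try:
                res.logistic.append(
                    st.logistic_risk(
                        series.to_numpy(float),
                        labels.loc[series.index].to_numpy(),
                        predictor=var,
                    )
                )
            except (st.SeparationError, st.DegenerateDataError) as err:
                res.logistic_failures[var] = str(err)
        return res


def run_pipeline(config: AnalysisConfig, cohort_csv, out_dir=None) -> DisorientationResults:
    """Run the four analysis steps on a cohort CSV and write per-step results.

    Writes ``step1_2_group_differences.csv``, ``step3_regressions.csv``,
    ``step4_logistic.csv`` and ``report.md`` into ``out_dir`` (or
    ``config.out_dir``); returns the fitted results.
    """
    study = DisorientationStudy.from_csv(cohort_csv, config)
    results = study.fit()
    target = out_dir or config.out_dir
    if target is not None:
        target = Path(target)
        target.mkdir(parents=True, exist_ok=True)
        results.comparisons_frame().to_csv(
            target / "step1_2_group_differences.csv", index=False)
        results.regressions_frame().to_csv(
            target / "step3_regressions.csv", index=False)
        results.logistic_frame().to_csv(target / "step4_logistic.csv", index=False)
        (target / "report.md").write_text(results.to_markdown_report())
        (target / "config.json").write_text(config.to_json() + "\n")
    return results
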