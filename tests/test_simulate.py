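"""Synthetic cohort and walk generation: moment matching, determinism,
substream stability, planted-event round trips."""

import numpy as np
import pytest

from disorient.dnt import RESET, NavEvent, detect_wrong_turns
from disorient.simulate import (
    CohortParams,
    VariableSpec,
    WalkProfile,
    _censored_moments,
    censored_normal_params,
    gen_cohort_scores,
    gen_dnt_walks,
    gen_vst_responses,
    make_neighborhood_graph,
)
from disorient.vst import score_vst


class TestCensoredNormalMatching:
    def test_all_default_marginals_match_published_moments(self):
        params = CohortParams.default()
        for var, groups in params.variables.items():
            for group, spec in groups.items():
                mu, sigma = censored_normal_params(spec)
                if sigma == 0:
                    continue
                m, s = _censored_moments(mu, sigma, spec.lower, spec.upper)
                assert m == pytest.approx(spec.mean, abs=1e-6), (var, group)
                assert s == pytest.approx(spec.sd, abs=1e-6), (var, group)

    def test_solved_moments_verified_by_simulation(self):
        spec = VariableSpec(mean=0.25, sd=0.50, lower=0.0, upper=20.0)
        mu, sigma = censored_normal_params(spec)
        rng = np.random.default_rng(0)
        draws = np.clip(rng.normal(mu, sigma, 400_000), spec.lower, spec.upper)
        assert draws.mean() == pytest.approx(0.25, abs=0.005)
        assert draws.std(ddof=1) == pytest.approx(0.50, abs=0.005)
        assert (draws == 0).mean() > 0.3  # exact zeros from floor censoring

    def test_mean_outside_support_rejected(self):
        with pytest.raises(ValueError, match="infeasible"):
            censored_normal_params(VariableSpec(mean=120, sd=5, lower=0, upper=100))


class TestCohortGeneration:
    def test_deterministic_given_seed(self):
        a = gen_cohort_scores(seed=42)
        b = gen_cohort_scores(seed=42)
        assert a.equals(b)
        assert not a.drop(columns="participant_id").equals(
            gen_cohort_scores(seed=43).drop(columns="participant_id")
        )

    def test_zero_sd_variable_is_constant_at_mean(self):
        df = gen_cohort_scores(seed=0)
        controls = df[df.group == "control"]
        assert (controls.original_score == 0.0).all()

    def test_group_sizes_and_missingness_flags(self):
        df = gen_cohort_scores(seed=1)
        assert (df.group == "control").sum() == 21
        assert (df.group == "patient").sum() == 16
        assert df.wf_missing.sum() == 2
        assert df.dnt_missing.sum() == 1
        assert df.loc[df.wf_missing, "wf_distance"].isna().all()
        assert df.loc[df.dnt_missing, "composite"].isna().all()
        assert not (df.wf_missing & df.dnt_missing).any()

    def test_large_sample_means_hit_published_targets(self):
        df = gen_cohort_scores(seed=9, n_controls=5000, n_patients=5000)
        ego = df[df.group == "control"].egocentric_pct
        assert ego.mean() == pytest.approx(81.49, abs=1.0)
        det = df[df.group == "patient"].detour_score.dropna()
        assert det.mean() == pytest.approx(0.25, abs=0.05)
        assert det.std(ddof=1) == pytest.approx(0.50, abs=0.05)

    def test_adding_participants_never_perturbs_earlier_draws(self):
        params = CohortParams.default()
        params.n_wf_missing = params.n_dnt_missing = 0  # isolate the raw draws
        small = gen_cohort_scores(params, seed=5, n_controls=10, n_patients=8)
        big = gen_cohort_scores(params, seed=5, n_controls=12, n_patients=9)
        cols = ["participant_id", "egocentric_pct", "wf_distance", "detour_score"]
        for group, n in (("control", 10), ("patient", 8)):
            a = small[small.group == group][cols].reset_index(drop=True)
            b = big[big.group == group][cols].head(n).reset_index(drop=True)
            assert a.equals(b)

    def test_ensemble_effect_sizes_match_published_rows(self):
        # Cohort-level fidelity: pooled-SD d estimated from synthetic cohorts
        # (20 cohorts of 200/group, averaged) lands near each published d.
        from disorient import compare_groups, published

        estimates = {v: [] for v in published.EFFECT_SIZE_ROWS}
        for seed in range(100, 110):
            df = gen_cohort_scores(seed=seed, n_controls=200, n_patients=200)
            for var in estimates:
                comp = compare_groups(
                    df[df.group == "control"][var].dropna(),
                    df[df.group == "patient"][var].dropna(),
                    variable=var,
                )
                estimates[var].append(comp.cohens_d)
        for var, vals in estimates.items():
            printed = published.row(var).cohens_d
            assert np.mean(vals) == pytest.approx(printed, abs=0.15), var

    def test_latent_coupling_induces_wayfinding_detour_correlation(self):
        df = gen_cohort_scores(seed=2, n_controls=0, n_patients=4000)
        sub = df.dropna(subset=["wf_distance", "detour_score"])
        r = np.corrcoef(sub.wf_distance, sub.detour_score)[0, 1]
        assert 0.25 < r < 0.55  # attenuated from the latent 0.55 by censoring
        assert (sub.composite == 1).mean() > 0.25  # low-risk patients exist


class TestVstGeneration:
    def test_certain_answers_and_zero_noise(self):
        responses = gen_vst_responses(1.0, 0.0, 1.0, seed=3)
        score = score_vst(responses)
        assert score.egocentric_pct == 100.0
        assert score.heading_pct == 100.0
        assert score.allocentric_displacement_pct == 0.0

    def test_binomial_mean_recovered_over_many_participants(self):
        means = [
            score_vst(gen_vst_responses(0.8, 0.1, 0.5, seed=s)).egocentric_pct
            for s in range(10_000)
        ]
        assert np.mean(means) == pytest.approx(80.0, abs=0.5)

    def test_deterministic_given_seed(self):
        assert gen_vst_responses(0.5, 0.2, 0.5, seed=8) == gen_vst_responses(
            0.5, 0.2, 0.5, seed=8
        )


class TestWalkGeneration:
    def test_event_free_profile_gives_clean_pair(self):
        graph, original, detour = make_neighborhood_graph()
        ow, dw = gen_dnt_walks(graph, WalkProfile(0.0, 0.0), seed=0)
        assert ow.taken_path == original
        assert dw.taken_path == detour
        assert ow.events == [] and dw.events == []

    def test_certain_wrong_turns_on_single_intersection_route(self):
        # p = 1 forces the full two-consecutive-wrong-turn reset sequence at
        # the detour's only intersection, then the retry succeeds.
        graph, _, detour = make_neighborhood_graph(n_blocks=2)
        assert graph.count_intersections(detour) == 1
        _, dw = gen_dnt_walks(graph, WalkProfile(1.0, 0.0), seed=0)
        kinds = [(e.kind, e.consecutive_index) for e in dw.events]
        assert kinds == [("wrong_turn", 1), ("wrong_turn", 2)]
        assert RESET in dw.taken_path

    @pytest.mark.parametrize("seed", range(8))
    def test_round_trip_planted_events_exactly_redetected(self, seed):
        graph, original, _ = make_neighborhood_graph()
        ow, dw = gen_dnt_walks(graph, WalkProfile(0.45, 1.5), seed=seed)
        for walk in (ow, dw):
            planted = [e for e in walk.events if e.kind == "wrong_turn"]
            found = detect_wrong_turns(
                walk, graph,
                original_path=original if walk.route_type == "detour" else None,
            )
            assert found == planted

    def test_poisson_hesitation_rate_recovered(self):
        graph, _, detour = make_neighborhood_graph()
        km = graph.path_length_km(detour)
        rate = 2.0
        counts = [
            sum(e.kind == "hesitation" for e in
                gen_dnt_walks(graph, WalkProfile(0.0, rate), seed=s)[1].events)
            for s in range(10_000)
        ]
        assert np.mean(counts) / km == pytest.approx(rate, rel=0.02)

    def test_graph_without_routes_rejected(self):
        from disorient.dnt import StreetGraph

        g = StreetGraph()
        g.add_node("a", 0, 0)
        g.add_node("b", 1, 0)
        g.add_edge("a", "b", 1.0)
        with pytest.raises(ValueError, match="detour"):
            gen_dnt_walks(g, WalkProfile(0.0, 0.0), seed=0)
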