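"""Visual search: scene generation, posterior composition, sequential test."""

import numpy as np
import pytest
from scipy.stats import poisson

from lowlight.search import (EMPTY, SearchSceneConfig, generate_scene,
                             global_llr, init_search_state, llr_from_counts,
                             local_log_posteriors, local_ratio, operating_point,
                             render_bar_window, sample_scene_streams,
                             scene_posterior, search_er_ppp,
                             simulate_llr_trajectories, sprt_search,
                             standard_search_config, update_search_state)
from lowlight.search import _hypothesis_rates
from lowlight.sensor import NoiseModel


def toy_config(L=2, M=1, y_t=90.0, y_d=0.0, window=3, **kw):
    return SearchSceneConfig(
        L=L, window=window, bar_length=3.0, bar_width=1.0,
        phi_support=((M, y_t, y_d),), phi_prior=(1.0,),
        noise=NoiseModel(3.0, 0.5), delta_t=0.2, **kw)


def oracle_llr(S, duration, cfg):
    """Exact Bayes log-odds of target presence by brute-force enumeration of
    the joint generative model (windows independent given scene properties
    and target placement)."""
    rates = _hypothesis_rates(cfg)
    like = np.array([poisson.pmf(S[l], rates * duration).prod(axis=1)
                     for l in range(cfg.L)])          # (L, H)
    p_absent, p_present = 0.0, 0.0
    for i, phi in enumerate(cfg.phi_support):
        win0 = like @ cfg.cond_no_target(phi)         # per-window, no target
        p_absent += cfg.phi_prior[i] * win0.prod()
        yt = cfg.hypothesis_index(phi[1])
        total = sum(
            like[lstar, yt] * np.prod([win0[l] for l in range(cfg.L)
                                       if l != lstar])
            for lstar in range(cfg.L))
        p_present += cfg.phi_prior[i] * total / cfg.L
    return np.log(p_present) - np.log(p_absent)


class TestConfig:
    def test_validation(self):
        with pytest.raises(ValueError):
            toy_config(L=2, M=3)
        with pytest.raises(ValueError):
            toy_config(y_t=45.0, y_d=45.0)
        with pytest.raises(ValueError):
            SearchSceneConfig(phi_support=((1, 90.0, 0.0),),
                              phi_prior=(0.5,))

    def test_hypothesis_space(self):
        cfg = standard_search_config(M=12, dy=20.0)
        assert cfg.hypotheses[0] is EMPTY
        assert set(cfg.hypotheses[1:]) == {70.0, 90.0}

    def test_conditionals_normalized(self):
        cfg = standard_search_config(known_m=False, known_dy=False)
        for phi in cfg.phi_support:
            assert cfg.cond_no_target(phi).sum() == pytest.approx(1.0)
            assert cfg.cond_target(phi).sum() == pytest.approx(1.0)
        assert cfg.marginal_hypothesis_prior().sum() == pytest.approx(1.0)


class TestSceneGeneration:
    def test_occupancy_and_target_placement(self, rng):
        cfg = standard_search_config(M=3, dy=90.0)
        for c_true in (0, 1):
            scene = generate_scene(cfg, c_true, rng)
            occupied = [y for y in scene.contents if y is not EMPTY]
            assert len(occupied) == 3
            n_targets = sum(y == 90.0 for y in scene.contents)
            assert n_targets == c_true
            assert scene.c == c_true

    def test_bar_covers_21_pixels(self):
        cfg = standard_search_config()
        for y in (0.0, 90.0):
            assert render_bar_window(cfg, y).sum() == pytest.approx(21.0)
        assert render_bar_window(cfg, EMPTY).sum() == 0.0


class TestLocalPosterior:
    def test_no_photons_returns_prior(self):
        cfg = toy_config()
        lf = local_log_posteriors(np.zeros((2, 9)), 0.0, cfg)
        np.testing.assert_allclose(np.exp(lf),
                                   np.tile(cfg.local_prior_vector(), (2, 1)),
                                   atol=1e-12)

    def test_matches_per_pixel_poisson(self, rng):
        cfg = toy_config()
        rates = _hypothesis_rates(cfg)
        S = rng.poisson(2.0, (2, 9)).astype(float)
        duration = 0.8
        lf = local_log_posteriors(S, duration, cfg)
        for l in range(2):
            logp = np.array([poisson.logpmf(S[l], rates[h] * duration).sum()
                             for h in range(len(cfg.hypotheses))])
            logp += np.log(cfg.local_prior_vector())
            expected = np.exp(logp - logp.max())
            expected /= expected.sum()
            np.testing.assert_allclose(np.exp(lf[l]), expected, atol=1e-10)

    def test_identifies_orientation_at_high_exposure(self, rng):
        cfg = toy_config(y_t=40.0, y_d=130.0, window=7)
        object.__setattr__(cfg, "bar_length", 7.0)
        object.__setattr__(cfg, "bar_width", 3.0)
        rates = _hypothesis_rates(cfg)
        idx = cfg.hypothesis_index(40.0)
        duration = 50.0 / 3.0                          # PPP 50
        hits = 0
        for _ in range(100):
            S = rng.poisson(rates[idx] * duration)
            lf = local_log_posteriors(S[None, :], duration, cfg)
            hits += int(np.argmax(lf[0]) == idx)
        assert hits >= 95


class TestScenePosterior:
    def test_single_phi_support(self, rng):
        cfg = toy_config()
        lf = local_log_posteriors(rng.poisson(1.0, (2, 9)).astype(float),
                                  0.4, cfg)
        np.testing.assert_allclose(scene_posterior(lf, cfg), [1.0])

    def test_prior_local_beliefs_recover_phi_prior(self):
        """When every local posterior equals the marginal hypothesis prior,
        the per-window terms telescope and the phi posterior is its prior."""
        cfg = SearchSceneConfig(
            L=3, window=3, bar_length=3.0, bar_width=1.0,
            phi_support=((1, 90.0, 0.0), (2, 90.0, 0.0)),
            phi_prior=(0.3, 0.7), noise=NoiseModel(3.0, 0.5), delta_t=0.2,
            local_prior="marginal")
        prior = cfg.local_prior_vector()
        lf = np.log(np.tile(prior, (3, 1)))
        np.testing.assert_allclose(scene_posterior(lf, cfg), [0.3, 0.7],
                                   atol=1e-12)

    def test_matches_enumeration_with_phi_uncertainty(self, rng):
        cfg = SearchSceneConfig(
            L=2, window=3, bar_length=3.0, bar_width=1.0,
            phi_support=((1, 90.0, 0.0), (2, 90.0, 45.0)),
            phi_prior=(0.4, 0.6), noise=NoiseModel(3.0, 0.5), delta_t=0.2)
        rates = _hypothesis_rates(cfg)
        S = rng.poisson(1.5, (2, 9)).astype(float)
        duration = 0.6
        # brute force: P(phi | X, C=0) by enumeration
        like = np.array([poisson.pmf(S[l], rates * duration).prod(axis=1)
                         for l in range(2)])
        post = np.array([
            w * np.prod(like @ cfg.cond_no_target(phi))
            for phi, w in zip(cfg.phi_support, cfg.phi_prior)])
        post /= post.sum()
        lf = local_log_posteriors(S, duration, cfg)
        np.testing.assert_allclose(scene_posterior(lf, cfg), post, atol=1e-10)


class TestRatioAndLLR:
    def test_uniform_beliefs_give_unit_ratio(self):
        cfg = toy_config(L=4, M=2)
        # uniform f with uniform conditionals: force both to uniform
        lf = np.log(np.full((4, 2), 0.5))
        phi = ("x", 90.0, 0.0)
        cond = np.full(2, 0.5)
        cfg2 = toy_config(L=4, M=2)
        object.__setattr__(cfg2, "cond_no_target", lambda p: cond)
        object.__setattr__(cfg2, "cond_target", lambda p: cond)
        object.__setattr__(cfg2, "hypothesis_index", lambda y: 1)
        assert local_ratio(0, phi, lf, cfg2) == pytest.approx(1.0)

    def test_concentrated_belief_plugin(self):
        cfg = toy_config(L=2, M=1)
        phi = cfg.phi_support[0]
        yt = cfg.hypothesis_index(phi[1])
        lf = np.full((2, len(cfg.hypotheses)), -np.inf)
        lf[:, yt] = 0.0
        expect = cfg.cond_target(phi)[yt] / cfg.cond_no_target(phi)[yt] \
            if cfg.cond_no_target(phi)[yt] > 0 else None
        if expect is None:
            with pytest.raises(ValueError):
                local_ratio(0, phi, lf, cfg)
        else:
            assert local_ratio(0, phi, lf, cfg) == pytest.approx(expect)

    def test_llr_zero_at_start(self):
        for cfg in (toy_config(), standard_search_config(known_m=False)):
            state = init_search_state(cfg)
            assert state.llr == pytest.approx(0.0, abs=1e-12)
            np.testing.assert_allclose(state.phi_post, cfg.phi_prior,
                                       atol=1e-12)

    def test_target_shaped_evidence_raises_llr(self, rng):
        cfg = toy_config(window=7)
        object.__setattr__(cfg, "bar_length", 7.0)
        object.__setattr__(cfg, "bar_width", 3.0)
        base = np.zeros((1, 2, 2, 7, 7))     # 1 trial, 2 frames, 2 windows
        with_target = base.copy()
        with_target[0, 0, 0] = 30.0 * render_bar_window(cfg, 90.0)
        s0 = llr_from_counts(cfg, base)[0, -1]
        s1 = llr_from_counts(cfg, with_target)[0, -1]
        assert s1 > s0


@pytest.mark.parametrize("L, M, orientations", [
    (1, 1, (90.0, 0.0)),
    (2, 1, (90.0, 0.0)),
    (2, 2, (90.0, 45.0)),
    (3, 2, (90.0, 30.0)),
])
def test_composition_equals_exhaustive_oracle(L, M, orientations, rng):
    """Eq-composition of local posteriors equals exhaustive joint-model Bayes
    at every frame of random streams (small L)."""
    cfg = toy_config(L=L, M=M, y_t=orientations[0], y_d=orientations[1])
    for c_true in (0, 1):
        scene = generate_scene(cfg, c_true, rng)
        state = init_search_state(cfg)
        S = np.zeros((L, 9))
        rates = _hypothesis_rates(cfg)
        scene_rates = np.stack([rates[cfg.hypothesis_index(y)]
                                for y in scene.contents])
        for t in range(5):
            frame = rng.poisson(scene_rates * cfg.delta_t)
            state = update_search_state(state, frame)
            S += frame
            expected = oracle_llr(S, (t + 1) * cfg.delta_t, cfg)
            assert state.llr == pytest.approx(expected, abs=1e-8)


class TestSprtSearch:
    def test_degenerate_thresholds_declare_absent(self, rng):
        cfg = toy_config()
        scene = generate_scene(cfg, 1, rng)
        streams = sample_scene_streams(scene, cfg, 3, rng)
        d = sprt_search(streams, 0.0, 0.0, cfg)
        assert d.c_hat == 0 and d.stop_frame == -1 and not d.capped

    def test_threshold_ordering_enforced(self, rng):
        cfg = toy_config()
        scene = generate_scene(cfg, 0, rng)
        streams = sample_scene_streams(scene, cfg, 3, rng)
        with pytest.raises(ValueError):
            sprt_search(streams, 1.0, 2.0, cfg)

    def test_stops_correctly_on_easy_scenes(self, rng):
        cfg = standard_search_config(M=3, dy=90.0, delta_t=0.2)
        hits = 0
        for trial in range(10):
            c_true = trial % 2
            scene = generate_scene(cfg, c_true, rng)
            streams = sample_scene_streams(scene, cfg, 100, rng)
            d = sprt_search(streams, -4.0, 4.0, cfg, ppp_cap=50.0)
            hits += int(d.c_hat == c_true)
        assert hits >= 9

    def test_vectorized_matches_sequential(self, rng):
        """Lock-step trajectory math agrees with the reference per-frame
        update on identical counts."""
        cfg = standard_search_config(M=3, dy=90.0, delta_t=0.1)
        scene = generate_scene(cfg, 1, rng)
        rates = np.stack([_hypothesis_rates(cfg)[cfg.hypothesis_index(y)]
                          for y in scene.contents])
        counts = rng.poisson(rates * cfg.delta_t, size=(8,) + rates.shape)
        traj = llr_from_counts(cfg, counts[None].astype(float))[0]
        state = init_search_state(cfg)
        for t in range(8):
            state = update_search_state(state, counts[t])
            assert state.llr == pytest.approx(traj[t], abs=1e-9)


class TestSweeps:
    def test_error_bound_on_exact_toy(self, rng):
        """Symmetric thresholds +-theta bound both error rates by roughly
        1/(1+e^theta) on the exact-likelihood toy."""
        cfg = toy_config(L=2, M=1)
        theta = 2.2
        n = 800
        tp = simulate_llr_trajectories(cfg, 1, n, 60, rng)
        ta = simulate_llr_trajectories(cfg, 0, n, 60, rng)
        from lowlight.search import _first_crossing
        _, d_p, _ = _first_crossing(tp, -theta, theta)
        _, d_a, _ = _first_crossing(ta, -theta, theta)
        bound = 1.0 / (1.0 + np.exp(theta))
        se = np.sqrt(bound * (1 - bound) / n)
        assert (d_p != 1).mean() <= bound + 3 * se
        assert (d_a != 0).mean() <= bound + 3 * se

    def test_complexity_and_uncertainty_directions(self, rng):
        """More clutter, unknown clutter, and target-absent trials all
        require more photons at a matched error rate."""
        n, frames = 300, 200
        results = {}
        for name, cfg in {
            "M3": standard_search_config(M=3, dy=90.0),
            "M12": standard_search_config(M=12, dy=90.0),
            "M-unknown": standard_search_config(known_m=False, dy=90.0),
        }.items():
            tp = simulate_llr_trajectories(cfg, 1, n, frames, rng)
            ta = simulate_llr_trajectories(cfg, 0, n, frames, rng)
            results[name] = operating_point(tp, ta, cfg, 0.05)
        assert results["M3"]["median_ppp"] <= results["M12"]["median_ppp"]
        assert results["M12"]["median_ppp"] <= \
            results["M-unknown"]["median_ppp"] + 0.2
        rows = results["M12"]["rows"]
        mid = [r for r in rows if 0.02 <= r["error_rate"] <= 0.10]
        assert any(r["median_ppp_absent"] >= r["median_ppp_present"]
                   for r in mid)

    def test_search_er_ppp_schema(self, rng):
        rows = search_er_ppp({"toy": toy_config()}, n_trials=40, n_frames=30,
                             rng=rng, theta_grid=[1.0, 2.0])
        assert len(rows) == 2
        for key in ("condition", "theta", "error_rate", "fa_rate", "fr_rate",
                    "median_ppp_present", "median_ppp_absent", "n_trials"):
            assert key in rows[0]
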