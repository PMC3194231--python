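"""HMM core checks against brute-force path enumeration and EM theory."""

import numpy as np
import pytest

from conftest import (
    brute_force_forward,
    brute_force_viterbi,
    make_obs,
    path_joint_prob,
    random_parameters,
)
from cpgscan.hmm_core import (
    HmmError,
    HmmParameters,
    baum_welch,
    default_initial_parameters,
    forward_loglik,
    load_model,
    order_states_by_cpg,
    save_model,
    viterbi,
)
from cpgscan.sequence_io import GenomicSequence, encode
from cpgscan.simulate import SimulationSpec, simulate


def degenerate_single_state() -> HmmParameters:
    rng = np.random.default_rng(5)
    e = rng.dirichlet(np.ones(4), size=(2, 4))
    s = rng.dirichlet(np.ones(4), size=2)
    return HmmParameters(
        initial=np.array([1.0, 0.0]),
        transition=np.array([[1.0, 0.0], [0.5, 0.5]]),
        emission=e,
        start_emission=s,
    )


class TestForward:
    def test_degenerate_one_state_chain(self):
        """With pi=[1,0] and an absorbing state the likelihood is just the
        product of that state's emission terms."""
        params = degenerate_single_state()
        obs = make_obs([0, 1, 2, 3, 1, 2])
        expected = np.log(params.start_emission[0, 0])
        for t in range(1, 6):
            expected += np.log(params.emission[0, obs.bases[t - 1], obs.bases[t]])
        ll, _ = forward_loglik(params, obs)
        assert ll == pytest.approx(expected, abs=1e-12)

    def test_length_one_closed_form(self):
        rng = np.random.default_rng(3)
        params = random_parameters(rng)
        b = 2
        ll, _ = forward_loglik(params, make_obs([b]))
        expected = np.log(np.sum(params.initial * params.start_emission[:, b]))
        assert ll == pytest.approx(expected, abs=1e-12)

    def test_matches_brute_force_enumeration(self):
        """exp(loglik) equals the explicit sum over all 2^8 state paths."""
        rng = np.random.default_rng(11)
        for _ in range(5):
            params = random_parameters(rng)
            obs = make_obs(rng.integers(0, 4, size=8))
            ll, _ = forward_loglik(params, obs)
            assert ll == pytest.approx(brute_force_forward(params, obs), abs=1e-10)

    def test_masked_positions_skip_emissions(self):
        """Masking a position removes its emission factor but the chain
        still advances; the next base is scored with the start distribution."""
        rng = np.random.default_rng(13)
        params = random_parameters(rng)
        obs = make_obs([0, 2, 1, 3], mask=[False, True, False, False])
        ll, _ = forward_loglik(params, obs)
        assert ll == pytest.approx(brute_force_forward(params, obs), abs=1e-10)

    def test_scaled_forward_rows_sum_to_one(self):
        rng = np.random.default_rng(17)
        params = random_parameters(rng)
        obs = make_obs(rng.integers(0, 4, size=50))
        _, trellis = forward_loglik(params, obs)
        assert np.allclose(trellis.scaled_forward.sum(axis=1), 1.0, atol=1e-12)

    def test_scaling_consistency_with_unscaled_pass(self):
        """Scale-factor log-likelihood agrees with a raw unscaled forward
        pass on sequences short enough not to underflow."""
        rng = np.random.default_rng(19)
        params = random_parameters(rng)
        obs = make_obs(rng.integers(0, 4, size=200))
        ll, _ = forward_loglik(params, obs)
        # unscaled pass in plain probability space
        a = params.initial * params.start_emission[:, obs.bases[0]]
        for t in range(1, 200):
            e = params.emission[:, obs.bases[t - 1], obs.bases[t]]
            a = (a @ params.transition) * e
        assert ll == pytest.approx(np.log(a.sum()), abs=1e-8)

    def test_all_masked_errors(self):
        params = random_parameters(np.random.default_rng(0))
        with pytest.raises(HmmError):
            forward_loglik(params, make_obs([0, 0], mask=[True, True]))


class TestViterbi:
    def test_separable_emissions_track_generating_states(self):
        """When I only continues with G/C and B only with A/T the decoded
        path reads the composition directly."""
        e = np.zeros((2, 4, 4))
        e[0, :, [0, 3]] = 0.5  # B emits A/T
        e[1, :, [1, 2]] = 0.5  # I emits C/G
        params = HmmParameters(
            initial=np.array([0.5, 0.5]),
            transition=np.array([[0.9, 0.1], [0.1, 0.9]]),
            emission=e,
            start_emission=np.array([[0.5, 0, 0, 0.5], [0, 0.5, 0.5, 0]]),
        )
        obs = make_obs([0, 3, 0, 1, 2, 1, 3, 0])
        path = viterbi(params, obs)
        assert path.labels.tolist() == [0, 0, 0, 1, 1, 1, 0, 0]

    def test_absorbing_start_state_gives_all_b(self):
        params = degenerate_single_state()
        path = viterbi(params, make_obs([1, 2, 1, 2, 1]))
        assert path.labels.tolist() == [0] * 5

    def test_matches_brute_force_argmax(self):
        """Path log-probability equals the max over all 2^8 explicit paths
        and the decoded path attains it under the tie rule."""
        rng = np.random.default_rng(23)
        for _ in range(5):
            params = random_parameters(rng)
            obs = make_obs(rng.integers(0, 4, size=8))
            path = viterbi(params, obs)
            best_logp, best_path = brute_force_viterbi(params, obs)
            assert path.log_probability == pytest.approx(best_logp, abs=1e-10)
            assert tuple(path.labels.tolist()) == best_path

    def test_tie_breaks_toward_b(self):
        """A fully symmetric model makes every path co-optimal; the tie
        rule must return all-B."""
        params = HmmParameters(
            initial=np.array([0.5, 0.5]),
            transition=np.full((2, 2), 0.5),
            emission=np.full((2, 4, 4), 0.25),
            start_emission=np.full((2, 4), 0.25),
        )
        path = viterbi(params, make_obs([0, 1, 2, 3]))
        assert path.labels.tolist() == [0, 0, 0, 0]


class TestBaumWelch:
    def test_monotone_loglik_and_stochastic_rows(self):
        """50 EM iterations on 10 kb of simulated sequence: the trace never
        decreases and every probability row stays stochastic."""
        truth = simulate(SimulationSpec(length=10_000, seed=3, n_islands=3,
                                        island_length_range=(600, 900),
                                        min_island_separation=1000))
        obs = encode(truth.sequence)
        init = default_initial_parameters(obs, seed=1, jitter=0.1)
        res = baum_welch(init, obs, max_iter=50, tol=0.0)
        trace = np.array(res.loglik_trace)
        assert len(trace) == 50
        assert np.all(np.diff(trace) >= -1e-9)
        p = res.parameters
        assert abs(p.initial.sum() - 1) < 1e-12
        assert np.allclose(p.transition.sum(axis=1), 1, atol=1e-12)
        assert np.allclose(p.emission.sum(axis=2), 1, atol=1e-12)
        assert np.all(p.transition >= 0) and np.all(p.emission >= 0)

    def test_identical_states_stay_symmetric(self):
        """Data with no state signal: EM still improves and both states'
        emission rows end up near-identical."""
        rng = np.random.default_rng(9)
        seq = GenomicSequence("s", "".join(rng.choice(list("ACGT"), size=3000)))
        obs = encode(seq)
        freqs = rng.dirichlet(np.ones(4))
        init = HmmParameters(
            initial=np.array([0.5, 0.5]),
            transition=np.array([[0.99, 0.01], [0.01, 0.99]]),
            emission=np.tile(freqs, (2, 4, 1)),
            start_emission=np.tile(freqs, (2, 1)),
        )
        res = baum_welch(init, obs, max_iter=10, tol=0.0)
        assert np.all(np.diff(res.loglik_trace) >= -1e-9)
        assert np.allclose(res.parameters.emission[0], res.parameters.emission[1],
                           atol=1e-6)

    def test_single_iteration_never_decreases(self):
        truth = simulate(SimulationSpec(length=2_000, seed=5, n_islands=1,
                                        island_length_range=(400, 600),
                                        min_island_separation=300))
        obs = encode(truth.sequence)
        init = default_initial_parameters(obs, seed=2, jitter=0.2)
        res = baum_welch(init, obs, max_iter=2, tol=0.0)
        assert res.loglik_trace[1] >= res.loglik_trace[0] - 1e-9

    def test_label_swap_degeneracy(self):
        """Training from swapped initial labels yields the mirrored model
        with the same final log-likelihood."""
        truth = simulate(SimulationSpec(length=5_000, seed=7, n_islands=2,
                                        island_length_range=(400, 600),
                                        min_island_separation=500))
        obs = encode(truth.sequence)
        init = default_initial_parameters(obs, seed=3, jitter=0.05)
        r1 = baum_welch(init, obs, max_iter=20, tol=0.0)
        r2 = baum_welch(init.swapped(), obs, max_iter=20, tol=0.0)
        assert r1.loglik_trace[-1] == pytest.approx(r2.loglik_trace[-1], abs=1e-6)
        assert np.allclose(r1.parameters.emission,
                           r2.parameters.swapped().emission, atol=1e-8)

    def test_degenerate_init_rejected(self):
        obs = make_obs([0, 1, 2, 3])
        bad = HmmParameters(
            initial=np.array([0.5, 0.5]),
            transition=np.array([[0.0, 0.0], [0.5, 0.5]]),
            emission=np.full((2, 4, 4), 0.25),
            start_emission=np.full((2, 4), 0.25),
        )
        with pytest.raises(HmmError):
            baum_welch(bad, obs)

    def test_parameter_recovery_on_fixture(self, default_truth, trained_model):
        """Training on the 200 kb fixture recovers the generating dwell
        probabilities within 0.01 and emission entries within 0.05."""
        from cpgscan.simulate import default_simulation_params

        true = default_simulation_params()
        est = trained_model
        assert abs(est.transition[0, 0] - true.transition[0, 0]) < 0.01
        assert abs(est.transition[1, 1] - true.transition[1, 1]) < 0.01
        assert np.max(np.abs(est.emission - true.emission)) < 0.05


class TestModelFile:
    def test_round_trip(self, tmp_path):
        params = random_parameters(np.random.default_rng(31))
        p = tmp_path / "model.txt"
        save_model(params, p)
        loaded = load_model(p)
        for name in ("initial", "transition", "emission", "start_emission"):
            assert np.allclose(getattr(params, name), getattr(loaded, name))

    def test_missing_field_rejected(self, tmp_path):
        p = tmp_path / "model.txt"
        p.write_text("initial = 0.5 0.5\n")
        with pytest.raises(HmmError):
            load_model(p)


def test_order_states_by_cpg_puts_cpg_rich_second():
    rng = np.random.default_rng(41)
    params = random_parameters(rng)
    ordered, _ = order_states_by_cpg(params)
    assert ordered.emission[1, 1, 2] >= ordered.emission[0, 1, 2]
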