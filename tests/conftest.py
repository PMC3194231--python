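"""Shared fixtures and independent brute-force oracles.

The oracles deliberately use plain Python loops and explicit enumeration so
they share no code path with the implementation they check.
"""

from __future__ import annotations

from itertools import product

import numpy as np
import pytest

from cpgscan.hmm_core import HmmParameters
from cpgscan.sequence_io import ObservationSequence


def random_parameters(rng: np.random.Generator) -> HmmParameters:
    """A random valid two-state model (Dirichlet rows)."""
    return HmmParameters(
        initial=rng.dirichlet(np.ones(2)),
        transition=rng.dirichlet(np.ones(2), size=2),
        emission=rng.dirichlet(np.ones(4), size=(2, 4)),
        start_emission=rng.dirichlet(np.ones(4), size=2),
    )


def path_joint_prob(
    params: HmmParameters, obs: ObservationSequence, states: tuple[int, ...]
) -> float:
    """Joint probability of one explicit state path and the observations.

    Mirrors the model conventions: masked positions emit nothing, the first
    unmasked position (or the first after a masked run) uses the start-base
    distribution, all other unmasked positions use e_s(b | prev).
    """
    p = params.initial[states[0]]
    for t in range(1, len(states)):
        p *= params.transition[states[t - 1], states[t]]
    prev_masked = True
    for t, s in enumerate(states):
        if obs.mask[t]:
            prev_masked = True
            continue
        b = obs.bases[t]
        if prev_masked:
            p *= params.start_emission[s, b]
        else:
            p *= params.emission[s, obs.bases[t - 1], b]
        prev_masked = False
    return float(p)


def brute_force_forward(params: HmmParameters, obs: ObservationSequence) -> float:
    """log P(obs) by explicit summation over all 2^L state paths."""
    total = sum(
        path_joint_prob(params, obs, states)
        for states in product((0, 1), repeat=len(obs))
    )
    return float(np.log(total))


def brute_force_viterbi(
    params: HmmParameters, obs: ObservationSequence
) -> tuple[float, tuple[int, ...]]:
    """(max log path probability, the maximizing path under the tie rule).

    Among co-optimal paths the implementation's tie rule (prefer state B at
    every argmax, working backwards) selects the path whose reversed label
    tuple is lexicographically smallest; the enumeration reproduces that.
    """
    best_logp = -np.inf
    best_path = None
    for states in product((0, 1), repeat=len(obs)):
        p = path_joint_prob(params, obs, states)
        if p == 0.0:
            continue
        logp = float(np.log(p))
        if logp > best_logp + 1e-12:
            best_logp, best_path = logp, states
        elif abs(logp - best_logp) <= 1e-12:
            if states[::-1] < best_path[::-1]:
                best_path = states
    return best_logp, best_path


def make_obs(codes, mask=None) -> ObservationSequence:
    codes = np.asarray(codes, dtype=np.int8)
    if mask is None:
        mask = np.zeros(len(codes), dtype=bool)
    return ObservationSequence(bases=codes, mask=np.asarray(mask, dtype=bool))


@pytest.fixture(scope="session")
def default_truth():
    """The standard 200 kb fixture: 10 planted islands, 3 Alu-like decoys."""
    from cpgscan.simulate import default_fixture_spec, simulate

    return simulate(default_fixture_spec(42))


@pytest.fixture(scope="session")
def trained_model(default_truth):
    """Baum-Welch-trained parameters on the standard fixture, I state second."""
    from cpgscan import baum_welch, default_initial_parameters, encode
    from cpgscan.hmm_core import order_states_by_cpg

    obs = encode(default_truth.sequence)
    init = default_initial_parameters(obs, seed=42, jitter=0.05)
    result = baum_welch(init, obs, max_iter=200)
    params, _ = order_states_by_cpg(result.parameters)
    return params
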