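"""Two-state hidden Markov model over DNA with first-order emissions.

States are B (background, index 0) and I (CpG island, index 1). Emissions
are conditional on the previous base, ``e_s(b | prev)``, which is what lets
the island state encode CpG (C followed by G) dinucleotide enrichment —
an order-0 base model cannot represent that signal. The first position of
the sequence, and the first unmasked position after a run of Ns, are scored
with a per-state start-base distribution ``e_s(b)``.

All recursions run in log space (Viterbi) or with per-position scaling
(forward/backward), so chromosome-scale inputs do not underflow. Masked (N)
positions contribute no emission factor, but the state chain still advances
through them with the transition probabilities.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from cpgscan.sequence_io import BASES, ObservationSequence

N_STATES = 2
N_BASES = 4
STATE_NAMES = ("B", "I")


class HmmError(ValueError):
    """Invalid parameters or unusable observation sequence."""


@dataclass(frozen=True)
class HmmParameters:
    """Parameters of the two-state model.

    initial
        pi_i — probability the chain starts in state i; shape (2,).
    transition
        a_{i,j} — probability of moving from state i to state j; shape (2, 2).
    emission
        e_s(b | p) — probability of base b given previous base p in state s;
        shape (2, 4, 4), row-stochastic over the last axis.
    start_emission
        e_s(b) — base distribution used at the first unmasked position of
        the sequence or after a masked run; shape (2, 4).
    """

    initial: np.ndarray
    transition: np.ndarray
    emission: np.ndarray
    start_emission: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "initial", np.asarray(self.initial, dtype=float))
        object.__setattr__(self, "transition", np.asarray(self.transition, dtype=float))
        object.__setattr__(self, "emission", np.asarray(self.emission, dtype=float))
        object.__setattr__(
            self, "start_emission", np.asarray(self.start_emission, dtype=float)
        )

    def validate(self, atol: float = 1e-8) -> None:
        if self.initial.shape != (N_STATES,):
            raise HmmError(f"initial must have shape ({N_STATES},)")
        if self.transition.shape != (N_STATES, N_STATES):
            raise HmmError("transition must be 2x2")
        if self.emission.shape != (N_STATES, N_BASES, N_BASES):
            raise HmmError("emission must be 2x4x4")
        if self.start_emission.shape != (N_STATES, N_BASES):
            raise HmmError("start_emission must be 2x4")
        for name, arr in (
            ("initial", self.initial),
            ("transition", self.transition),
            ("emission", self.emission),
            ("start_emission", self.start_emission),
        ):
            if np.any(arr < -atol) or np.any(arr > 1 + atol):
                raise HmmError(f"{name} entries must lie in [0, 1]")
        if abs(self.initial.sum() - 1) > atol:
            raise HmmError("initial probabilities must sum to 1")
        rowsums = self.transition.sum(axis=1)
        if np.any(np.abs(rowsums - 1) > atol):
            raise HmmError("each transition row must sum to 1")
        if np.any(rowsums == 0):
            raise HmmError("degenerate transition row of zeros")
        if np.any(np.abs(self.emission.sum(axis=2) - 1) > atol):
            raise HmmError("each emission row must sum to 1")
        if np.any(np.abs(self.start_emission.sum(axis=1) - 1) > atol):
            raise HmmError("each start-base distribution must sum to 1")

    def swapped(self) -> "HmmParameters":
        """The same model with the two state labels exchanged."""
        idx = [1, 0]
        return HmmParameters(
            initial=self.initial[idx],
            transition=self.transition[np.ix_(idx, idx)],
            emission=self.emission[idx],
            start_emission=self.start_emission[idx],
        )


@dataclass(frozen=True)
class StatePath:
    """A decoded label sequence over {B, I} with its joint log probability."""

    labels: np.ndarray  # int8 over {0, 1}, one per observation position
    log_probability: float

    def __len__(self) -> int:
        return len(self.labels)

    def label_string(self) -> str:
        return "".join(STATE_NAMES[s] for s in self.labels)


@dataclass
class ForwardBackwardTrellis:
    scaled_forward: np.ndarray  # (L, 2); each row sums to 1
    scaled_backward: np.ndarray  # (L, 2)
    scale_factors: np.ndarray  # (L,); sum of logs = sequence log-likelihood


@dataclass
class TrainingResult:
    parameters: HmmParameters
    loglik_trace: list[float]
    iterations: int
    converged: bool


def _emission_columns(params: HmmParameters, obs: ObservationSequence) -> np.ndarray:
    """Per-position emission factors, shape (L, 2).

    Masked positions get factor 1 for both states (skipped); the sequence
    start and the first base after a masked run use the start-base
    distribution; every other position uses e_s(x_t | x_{t-1}).
    """
    L = len(obs)
    x = obs.bases
    m = obs.mask
    cols = np.ones((L, N_STATES))
    if L == 0:
        return cols
    prev_masked = np.empty(L, dtype=bool)
    prev_masked[0] = True
    prev_masked[1:] = m[:-1]
    unmasked = ~m
    starts = unmasked & prev_masked
    interior = unmasked & ~prev_masked
    if starts.any():
        cols[starts] = params.start_emission[:, x[starts]].T
    if interior.any():
        idx = np.where(interior)[0]
        cols[idx] = params.emission[:, x[idx - 1], x[idx]].T
    return cols


def _check_obs(obs: ObservationSequence) -> None:
    if len(obs) == 0 or bool(obs.mask.all()):
        raise HmmError("observation sequence is empty or fully masked")


def forward_loglik(
    params: HmmParameters, obs: ObservationSequence
) -> tuple[float, ForwardBackwardTrellis]:
    """Scaled forward-backward pass.

    Returns ``log P(observations | params)`` summed over all state paths,
    together with the scaled trellis used by Baum-Welch.
    """
    params.validate()
    _check_obs(obs)
    e = _emission_columns(params, obs)
    L = len(obs)
    A = params.transition
    alpha = np.empty((L, N_STATES))
    beta = np.empty((L, N_STATES))
    c = np.empty(L)

    a = params.initial * e[0]
    c[0] = a.sum()
    if c[0] == 0:
        raise HmmError("zero forward probability at position 0")
    alpha[0] = a / c[0]
    for t in range(1, L):
        a = (alpha[t - 1] @ A) * e[t]
        c[t] = a.sum()
        if c[t] == 0:
            raise HmmError(f"zero forward probability at position {t}")
        alpha[t] = a / c[t]

    beta[L - 1] = 1.0
    for t in range(L - 2, -1, -1):
        beta[t] = (A @ (e[t + 1] * beta[t + 1])) / c[t + 1]

    loglik = float(np.log(c).sum())
    return loglik, ForwardBackwardTrellis(alpha, beta, c)


def viterbi(params: HmmParameters, obs: ObservationSequence) -> StatePath:
    """Most probable state path via the log-space V_{l,k} recurrence.

    Ties at every argmax are broken toward state B (index 0), which makes
    island calling conservative and the output deterministic.
    """
    params.validate()
    _check_obs(obs)
    with np.errstate(divide="ignore"):
        log_e = np.log(_emission_columns(params, obs))
        log_pi = np.log(params.initial)
        log_A = np.log(params.transition)
    L = len(obs)
    V = np.empty((L, N_STATES))
    back = np.zeros((L, N_STATES), dtype=np.int8)
    V[0] = log_pi + log_e[0]
    for t in range(1, L):
        cand = V[t - 1][:, None] + log_A  # cand[i, k]: from state i into k
        # argmax with ties toward the smaller (B) predecessor index
        best_prev = np.argmax(cand, axis=0)
        back[t] = best_prev
        V[t] = cand[best_prev, np.arange(N_STATES)] + log_e[t]
    last = int(np.argmax(V[L - 1]))
    labels = np.empty(L, dtype=np.int8)
    labels[L - 1] = last
    for t in range(L - 1, 0, -1):
        labels[t - 1] = back[t, labels[t]]
    return StatePath(labels=labels, log_probability=float(V[L - 1, last]))


def baum_welch(
    init: HmmParameters,
    obs: ObservationSequence,
    max_iter: int = 500,
    tol: float = 1e-6,
) -> TrainingResult:
    """Baum-Welch (EM) re-estimation of pi, transitions, and emission rows.

    Uses the scaled forward-backward posteriors; stops when the relative
    log-likelihood improvement drops below ``tol`` or after ``max_iter``
    iterations. The returned ``loglik_trace`` holds the log-likelihood of
    the parameters at the start of each iteration and is non-decreasing up
    to numerical tolerance (EM monotonicity).
    """
    init.validate()
    _check_obs(obs)
    if int((~obs.mask).sum()) < 2:
        raise HmmError("need at least 2 unmasked positions to train")

    params = init
    trace: list[float] = []
    converged = False
    iterations = 0
    x = obs.bases
    m = obs.mask
    L = len(obs)
    prev_masked = np.empty(L, dtype=bool)
    prev_masked[0] = True
    prev_masked[1:] = m[:-1]
    starts = (~m) & prev_masked
    interior = (~m) & ~prev_masked
    interior_idx = np.where(interior)[0]

    for _ in range(max_iter):
        loglik, trellis = forward_loglik(params, obs)
        trace.append(loglik)
        # tol = 0 disables early stopping (run exactly max_iter iterations)
        if tol > 0 and len(trace) >= 2:
            prev = trace[-2]
            if (loglik - prev) < tol * abs(prev):
                converged = True
                break

        alpha, beta, c = (
            trellis.scaled_forward,
            trellis.scaled_backward,
            trellis.scale_factors,
        )
        e = _emission_columns(params, obs)
        gamma = alpha * beta
        gamma /= gamma.sum(axis=1, keepdims=True)

        # xi summed over t: alpha_t[i] A[i,j] e_{t+1}[j] beta_{t+1}[j] / c_{t+1}
        w = (e[1:] * beta[1:]) / c[1:, None]
        xi_sum = np.einsum("ti,tj->ij", alpha[:-1], w) * params.transition

        new_pi = gamma[0]
        new_A = xi_sum / xi_sum.sum(axis=1, keepdims=True)

        new_E = np.zeros((N_STATES, N_BASES, N_BASES))
        if interior_idx.size:
            np.add.at(
                new_E,
                (slice(None), x[interior_idx - 1], x[interior_idx]),
                gamma[interior_idx].T,
            )
        row_tot = new_E.sum(axis=2, keepdims=True)
        seen = row_tot[..., 0] > 0
        new_E = np.where(seen[..., None], new_E / np.where(row_tot, row_tot, 1.0),
                         params.emission)

        new_S = np.zeros((N_STATES, N_BASES))
        if starts.any():
            np.add.at(new_S, (slice(None), x[starts]), gamma[starts].T)
        s_tot = new_S.sum(axis=1, keepdims=True)
        new_S = np.where(s_tot > 0, new_S / np.where(s_tot, s_tot, 1.0),
                         params.start_emission)

        params = HmmParameters(new_pi, new_A, new_E, new_S)
        iterations += 1

    return TrainingResult(
        parameters=params,
        loglik_trace=trace,
        iterations=iterations,
        converged=converged,
    )


def base_frequencies(obs: ObservationSequence) -> np.ndarray:
    """Genome-wide unmasked base frequencies, shape (4,)."""
    counts = np.bincount(obs.bases[~obs.mask], minlength=N_BASES).astype(float)
    tot = counts.sum()
    if tot == 0:
        raise HmmError("no unmasked bases")
    return counts / tot


def default_initial_parameters(
    obs: Optional[ObservationSequence] = None,
    cpg_boost: float = 3.0,
    seed: Optional[int] = None,
    jitter: float = 0.0,
) -> HmmParameters:
    """Default training start point.

    pi = (0.5, 0.5); sticky transitions (a_BB = 0.9995, a_II = 0.995);
    emissions from genome-wide base frequencies with the island-state CpG
    continuation e_I(G | C) boosted ``cpg_boost``-fold then renormalized.
    The asymmetric boost breaks the label symmetry EM cannot break on its
    own. ``jitter`` adds a seeded multiplicative perturbation.
    """
    freqs = base_frequencies(obs) if obs is not None else np.full(N_BASES, 0.25)
    emission = np.tile(freqs, (N_STATES, N_BASES, 1))
    c, g = 1, 2
    emission[1, c, g] *= cpg_boost
    emission /= emission.sum(axis=2, keepdims=True)
    start = np.tile(freqs, (N_STATES, 1))
    params = HmmParameters(
        initial=np.array([0.5, 0.5]),
        transition=np.array([[0.9995, 0.0005], [0.005, 0.995]]),
        emission=emission,
        start_emission=start,
    )
    if jitter > 0:
        rng = np.random.default_rng(seed)

        def perturb(a):
            a = a * np.exp(rng.normal(0.0, jitter, size=a.shape))
            return a / a.sum(axis=-1, keepdims=True)

        params = HmmParameters(
            perturb(params.initial),
            perturb(params.transition),
            perturb(params.emission),
            perturb(params.start_emission),
        )
    params.validate()
    return params


def order_states_by_cpg(params: HmmParameters) -> tuple[HmmParameters, bool]:
    """Return params with the CpG-richer state (larger e(G|C)) as state I.

    Resolves the label-swap degeneracy of EM. The flag reports whether a
    swap was applied.
    """
    c, g = 1, 2
    if params.emission[0, c, g] > params.emission[1, c, g]:
        return params.swapped(), True
    return params, False


_MODEL_FIELDS = ("initial", "transition", "emission", "start_emission")


def save_model(params: HmmParameters, path: str | Path) -> None:
    """Serialize to a plain-text key-value model file (fixed field order)."""
    with open(path, "w") as fh:
        fh.write("# cpgscan HMM model, states B I; bases A C G T\n")
        for name in _MODEL_FIELDS:
            arr = getattr(params, name)
            flat = " ".join(f"{v:.17g}" for v in np.ravel(arr))
            fh.write(f"{name} = {flat}\n")


def load_model(path: str | Path) -> HmmParameters:
    shapes = {
        "initial": (N_STATES,),
        "transition": (N_STATES, N_STATES),
        "emission": (N_STATES, N_BASES, N_BASES),
        "start_emission": (N_STATES, N_BASES),
    }
    values = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, rest = line.partition("=")
            key = key.strip()
            if key not in shapes:
                raise HmmError(f"unknown model field {key!r}")
            values[key] = np.array([float(v) for v in rest.split()]).reshape(shapes[key])
    missing = set(shapes) - set(values)
    if missing:
        raise HmmError(f"model file missing fields: {sorted(missing)}")
    params = HmmParameters(**values)
    params.validate()
    return params
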