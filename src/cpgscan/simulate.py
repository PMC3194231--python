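"""Synthetic genomes with known ground truth.

The generative model is exactly the detection model: a hidden two-state
Markov chain (background/island) emitting bases conditional on the previous
base, so training on simulated data is a well-posed parameter-recovery
problem. Islands can either arise from the state chain itself or be planted
as explicit intervals; short Alu-like high-GC decoy repeats (~280 bp) can be
inserted in background regions to exercise the length criterion that is
meant to reject them.

Defaults emulate a desk-scale chromosome: 200 kb, ten planted islands of
800-1200 bp (echoing the 900-1500 bp range typical of promoter islands),
background GC 0.40 with depleted CpG, island GC 0.62 with Obs/Exp CpG near
1, and three 280 bp decoys.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from cpgscan.hmm_core import HmmParameters, StatePath
from cpgscan.sequence_io import BASES, GenomicSequence, MethylationRecord


class SimulationError(ValueError):
    """Invalid simulation specification."""


def default_simulation_params() -> HmmParameters:
    """Generative parameters for the default synthetic genome.

    Background: GC 0.40 with the CpG continuation e_B(G|C) depleted to 0.08
    (real background DNA is CpG-poor). Island: GC 0.62, bases conditionally
    independent so Obs/Exp CpG is ~1 inside islands. Transition dwell times
    give mean island length 1000 bp and mean background spacer 19 kb.
    """
    freq_b = np.array([0.30, 0.20, 0.20, 0.30])  # A C G T, GC = 0.40
    freq_i = np.array([0.19, 0.31, 0.31, 0.19])  # GC = 0.62
    emission = np.empty((2, 4, 4))
    emission[0] = np.tile(freq_b, (4, 1))
    emission[1] = np.tile(freq_i, (4, 1))
    c, g = 1, 2
    row = emission[0, c].copy()
    deficit = row[g] - 0.08
    row[g] = 0.08
    keep = [0, 1, 3]
    row[keep] += deficit * row[keep] / row[keep].sum()
    emission[0, c] = row
    a_bb = 1.0 - 1.0 / 19_000
    a_ii = 1.0 - 1.0 / 1_000
    transition = np.array([[a_bb, 1 - a_bb], [1 - a_ii, a_ii]])
    # stationary start: islands cover ~5% of positions
    p_i = (1 - a_bb) / ((1 - a_bb) + (1 - a_ii))
    params = HmmParameters(
        initial=np.array([1 - p_i, p_i]),
        transition=transition,
        emission=emission,
        start_emission=np.stack([freq_b, freq_i]),
    )
    params.validate()
    return params


@dataclass(frozen=True)
class Decoy:
    """An Alu-like insert: short, GC-rich, but labeled background."""

    length: int = 280
    gc_level: float = 0.65
    start: Optional[int] = None  # None: place randomly in background


def default_decoys() -> tuple[Decoy, ...]:
    return (Decoy(), Decoy(), Decoy())


@dataclass(frozen=True)
class SimulationSpec:
    """Recipe for one synthetic genome.

    ``n_islands=None`` samples the hidden state chain from ``params``;
    otherwise that many island intervals are planted explicitly (lengths
    uniform over ``island_length_range``) and the state path is fixed.
    ``planted`` overrides random placement with explicit (start, end)
    intervals.
    """

    length: int = 200_000
    params: Optional[HmmParameters] = None
    seed: int = 0
    n_islands: Optional[int] = 10
    island_length_range: tuple[int, int] = (800, 1200)
    min_island_separation: int = 2_000
    planted: Optional[tuple[tuple[int, int], ...]] = None
    decoys: tuple[Decoy, ...] = ()
    chrom_id: str = "sim"

    def resolved_params(self) -> HmmParameters:
        return self.params if self.params is not None else default_simulation_params()

    def validate(self) -> None:
        if self.length < 1:
            raise SimulationError("length must be >= 1")
        self.resolved_params().validate()
        if self.planted is not None:
            ivals = sorted(self.planted)
            for s, e in ivals:
                if not (0 <= s < e <= self.length):
                    raise SimulationError(f"planted interval ({s}, {e}) out of bounds")
            for (s1, e1), (s2, e2) in zip(ivals, ivals[1:]):
                if s2 < e1:
                    raise SimulationError("planted intervals overlap")


@dataclass
class SimulatedTruth:
    """A simulated genome with its generating path and interval truth."""

    sequence: GenomicSequence
    true_path: StatePath
    true_islands: list[tuple[int, int]]
    decoy_intervals: list[tuple[int, int]] = field(default_factory=list)
    score_table: Optional[list[MethylationRecord]] = None


def _place_intervals(
    rng: np.random.Generator,
    length: int,
    lengths: Sequence[int],
    existing: Sequence[tuple[int, int]],
    separation: int,
    max_tries: int = 10_000,
) -> list[tuple[int, int]]:
    placed = list(existing)
    out = []
    for ln in lengths:
        if length - ln - separation <= separation:
            raise SimulationError(
                f"sequence of {length} bp cannot hold a {ln} bp interval "
                f"with {separation} bp separation"
            )
        for _ in range(max_tries):
            s = int(rng.integers(separation, length - ln - separation))
            e = s + ln
            if all(s - separation >= pe or e + separation <= ps for ps, pe in placed):
                placed.append((s, e))
                out.append((s, e))
                break
        else:
            raise SimulationError("could not place all intervals; sequence too crowded")
    return sorted(out)


def _sample_bases(
    rng: np.random.Generator, params: HmmParameters, labels: np.ndarray
) -> str:
    L = len(labels)
    cum_e = np.cumsum(params.emission, axis=2)
    cum_s = np.cumsum(params.start_emission, axis=1)
    u = rng.random(L)
    codes = np.empty(L, dtype=np.int64)
    codes[0] = np.searchsorted(cum_s[labels[0]], u[0], side="right")
    for t in range(1, L):
        codes[t] = np.searchsorted(cum_e[labels[t], codes[t - 1]], u[t], side="right")
    np.clip(codes, 0, 3, out=codes)
    lut = np.frombuffer("ACGT".encode(), dtype=np.uint8)
    return lut[codes].tobytes().decode()


def _runs_of_ones(labels: np.ndarray) -> list[tuple[int, int]]:
    padded = np.concatenate(([0], (labels == 1).astype(np.int8), [0]))
    edges = np.flatnonzero(np.diff(padded))
    return list(zip(edges[::2].tolist(), edges[1::2].tolist()))


def simulate(spec: SimulationSpec) -> SimulatedTruth:
    """Generate a sequence + state path + island truth, reproducibly.

    All randomness flows from ``spec.seed``; the same spec always yields the
    same genome. Decoys listed in the spec are planted afterwards via
    :func:`plant_decoys` using the same random stream.
    """
    spec.validate()
    params = spec.resolved_params()
    rng = np.random.default_rng(spec.seed)
    L = spec.length

    if spec.planted is not None or spec.n_islands is not None:
        if spec.planted is not None:
            islands = sorted(spec.planted)
        else:
            lo, hi = spec.island_length_range
            lens = rng.integers(lo, hi + 1, size=spec.n_islands)
            islands = _place_intervals(rng, L, lens, [], spec.min_island_separation)
        labels = np.zeros(L, dtype=np.int8)
        for s, e in islands:
            labels[s:e] = 1
    else:
        # sample the hidden chain itself
        labels = np.empty(L, dtype=np.int8)
        u = rng.random(L)
        labels[0] = int(u[0] >= params.initial[0])
        stay = np.diag(params.transition)
        for t in range(1, L):
            prev = labels[t - 1]
            labels[t] = prev if u[t] < stay[prev] else 1 - prev
        islands = _runs_of_ones(labels)

    residues = _sample_bases(rng, params, labels)
    truth = SimulatedTruth(
        sequence=GenomicSequence(spec.chrom_id, residues),
        true_path=StatePath(labels=labels, log_probability=float("nan")),
        true_islands=islands,
    )
    if spec.decoys:
        truth = plant_decoys(truth, spec.decoys, rng=rng)
    return truth


def plant_decoys(
    truth: SimulatedTruth,
    decoys: Sequence[Decoy],
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
    margin: int = 600,
) -> SimulatedTruth:
    """Overwrite background intervals with GC-rich Alu-like repeats.

    Decoy bases are drawn i.i.d. at the requested GC level (so their
    Obs/Exp CpG is near 1), while the truth labels there stay B: by
    construction they are composition look-alikes, not islands. A decoy
    overlapping a true island is an error.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    if not decoys:
        return truth
    L = truth.sequence.length
    placed: list[tuple[int, int]] = []
    explicit = [d for d in decoys if d.start is not None]
    auto = [d for d in decoys if d.start is None]
    for d in explicit:
        s, e = d.start, d.start + d.length
        if not (0 <= s < e <= L):
            raise SimulationError(f"decoy at {s} out of bounds")
        if any(s < ie and isd < e for isd, ie in truth.true_islands):
            raise SimulationError(f"decoy at {s} overlaps a true island")
        placed.append((s, e))
    keep_clear = [(max(0, s - margin), min(L, e + margin)) for s, e in truth.true_islands]
    auto_placed = _place_intervals(
        rng, L, [d.length for d in auto], keep_clear + placed, margin
    )
    residues = list(truth.sequence.residues)
    lut = "ACGT"
    all_decoys = placed + auto_placed
    specs = explicit + auto
    for d, (s, e) in zip(specs, all_decoys):
        # exact base composition (GC level holds deterministically), random
        # arrangement: adjacent C,G pairs then occur at the product rate, so
        # the insert is CpG-rich (Obs/Exp near 1) like a young Alu
        ln = e - s
        n_gc = round(d.gc_level * ln)
        n_c = n_gc // 2 + n_gc % 2
        n_g = n_gc // 2
        n_a = (ln - n_gc) // 2 + (ln - n_gc) % 2
        n_t = ln - n_gc - n_a
        codes = np.repeat([0, 1, 2, 3], [n_a, n_c, n_g, n_t])
        rng.shuffle(codes)
        for off, code in enumerate(codes):
            residues[s + off] = lut[code]
    return replace(
        truth,
        sequence=GenomicSequence(truth.sequence.id, "".join(residues)),
        decoy_intervals=sorted(all_decoys),
    )


def default_fixture_spec(seed: int = 42) -> SimulationSpec:
    """The standard desk-scale fixture: 200 kb, 10 planted islands, 3 decoys."""
    return SimulationSpec(seed=seed, decoys=default_decoys())


def simulate_scores(
    true_islands: Sequence[tuple[int, int]] | Sequence[str],
    methylated_fraction: float = 0.08,
    methylated_mean: float = 1.2,
    methylated_sd: float = 0.4,
    unmethylated_mean: float = -0.5,
    unmethylated_sd: float = 0.4,
    seed: Optional[int] = None,
    chrom_id: str = "sim",
) -> list[MethylationRecord]:
    """Draw a methylation-score table with known component labels.

    Each island joins the methylated component with probability
    ``methylated_fraction`` (the default 0.08 mirrors the strong
    unmethylated majority typical of promoter islands) and draws its score
    from that component's normal distribution. The true component is stored
    on the record's ``true_status``; ``status`` is left unset for
    :func:`cpgscan.methylation.classify` to fill.
    """
    if not 0 <= methylated_fraction <= 1:
        raise SimulationError("methylated_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    ids = [
        t if isinstance(t, str) else f"{chrom_id}.{k + 1}"
        for k, t in enumerate(true_islands)
    ]
    out = []
    for island_id in ids:
        methylated = rng.random() < methylated_fraction
        if methylated:
            score = rng.normal(methylated_mean, methylated_sd)
        else:
            score = rng.normal(unmethylated_mean, unmethylated_sd)
        out.append(
            MethylationRecord(
                island_id,
                float(score),
                status=None,
                true_status="methylated" if methylated else "unmethylated",
            )
        )
    return out
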