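"""Sliding-window CpG-island calling over the decoded state path.

A 1-bp-step window qualifies when it passes the composition criteria
(GC >= 55%, Obs/Exp CpG >= 0.65 by default — the thresholds that exclude
~280 bp Alu repeats) and, when the HMM is in use, when at least half of its
positions carry the Viterbi island label. Qualifying windows are unioned,
nearby candidates merged, ends trimmed, and short calls discarded, giving a
deterministic O(L) procedure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np

from cpgscan.hmm_core import StatePath
from cpgscan.sequence_io import GenomicSequence


class ScanError(ValueError):
    """Unusable window or interval."""


@dataclass
class ScanConfig:
    """Detection thresholds; defaults follow the stringent island criteria."""

    window_length: int = 500
    min_gc: float = 0.55
    min_obs_exp: float = 0.65
    min_island_fraction: float = 0.5
    min_length: int = 500
    merge_gap: int = 100
    use_hmm: bool = True

    def validate(self) -> None:
        if self.window_length < 2:
            raise ScanError("window_length must be >= 2")
        for name in ("min_gc", "min_obs_exp", "min_island_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= (2.0 if name == "min_obs_exp" else 1.0):
                raise ScanError(f"{name}={v} outside its natural range")
        if self.min_length < 1 or self.merge_gap < 0:
            raise ScanError("min_length must be >= 1 and merge_gap >= 0")
        if self.min_length < self.window_length:
            warnings.warn("min_length < window_length: windows set the floor")


@dataclass(frozen=True)
class CpgIsland:
    """A called island: 0-based half-open interval with its statistics."""

    chrom: str
    start: int
    end: int
    gc_content: float
    obs_exp: float
    island_fraction: float
    island_id: str

    @property
    def length(self) -> int:
        return self.end - self.start


def gc_content(window: str) -> float:
    """(G + C) / unmasked bases of the window."""
    unmasked = sum(1 for c in window if c != "N")
    if unmasked == 0:
        raise ScanError("window is fully masked")
    gc = sum(1 for c in window if c in "GC")
    return gc / unmasked


def obs_exp_cpg(window: str) -> float:
    """Observed/expected CpG ratio, (N_CG * L) / (N_C * N_G).

    N_CG counts CG dinucleotides at adjacent unmasked positions, L counts
    unmasked bases. Defined as 0 when the window has no C or no G. The CG
    dinucleotide class is its own reverse complement, so this statistic is
    strand-symmetric.
    """
    unmasked = [c for c in window if c != "N"]
    if len(unmasked) < 2:
        raise ScanError("window needs at least 2 unmasked bases")
    n_c = window.count("C")
    n_g = window.count("G")
    if n_c * n_g == 0:
        return 0.0
    n_cg = sum(
        1 for a, b in zip(window, window[1:]) if a == "C" and b == "G"
    )
    return n_cg * len(unmasked) / (n_c * n_g)


def island_fraction(path: StatePath, start: int, end: int) -> float:
    """Fraction of positions in [start, end) that Viterbi labeled I."""
    if not (0 <= start < end <= len(path)):
        raise ScanError(f"invalid interval [{start}, {end}) for path of length {len(path)}")
    return float(np.mean(path.labels[start:end] == 1))


class _SeqCounts:
    """Prefix sums over the sequence for O(1) interval statistics."""

    def __init__(self, residues: str, labels: Optional[np.ndarray]):
        arr = np.frombuffer(residues.encode("ascii"), dtype=np.uint8)
        is_c = arr == ord("C")
        is_g = arr == ord("G")
        is_n = arr == ord("N")
        is_cg = np.zeros(len(arr), dtype=bool)
        if len(arr) > 1:
            is_cg[:-1] = is_c[:-1] & is_g[1:]
        self.c = np.concatenate(([0], np.cumsum(is_c)))
        self.g = np.concatenate(([0], np.cumsum(is_g)))
        self.n = np.concatenate(([0], np.cumsum(is_n)))
        self.cg = np.concatenate(([0], np.cumsum(is_cg)))
        if labels is not None:
            self.i = np.concatenate(([0], np.cumsum(labels == 1)))
        else:
            self.i = None

    def stats(self, s: int, e: int) -> tuple[float, float, float, int]:
        """(gc, obs_exp, island_fraction, n_masked) over [s, e)."""
        n_c = int(self.c[e] - self.c[s])
        n_g = int(self.g[e] - self.g[s])
        n_n = int(self.n[e] - self.n[s])
        n_cg = int(self.cg[e - 1] - self.cg[s])  # pairs fully inside [s, e)
        unmasked = (e - s) - n_n
        gc = (n_c + n_g) / unmasked if unmasked else 0.0
        oe = n_cg * unmasked / (n_c * n_g) if n_c * n_g else 0.0
        ifrac = float(self.i[e] - self.i[s]) / (e - s) if self.i is not None else 1.0
        return gc, oe, ifrac, n_n


def _passes(counts: _SeqCounts, s: int, e: int, cfg: ScanConfig) -> bool:
    gc, oe, ifrac, _ = counts.stats(s, e)
    if gc < cfg.min_gc or oe < cfg.min_obs_exp:
        return False
    return not (cfg.use_hmm and ifrac < cfg.min_island_fraction)


def scan(
    seq: GenomicSequence,
    path: Optional[StatePath],
    config: Optional[ScanConfig] = None,
) -> list[CpgIsland]:
    """Call islands on one sequence.

    ``path`` may be None only when ``config.use_hmm`` is off (criteria-only
    mode). Windows containing any masked base are disqualified rather than
    rescaled, so N runs cannot inflate the ratios.
    """
    cfg = config or ScanConfig()
    cfg.validate()
    if cfg.use_hmm:
        if path is None:
            raise ScanError("use_hmm is on but no state path was given")
        if len(path) != seq.length:
            raise ScanError("state path length does not match sequence length")
    L = seq.length
    w = cfg.window_length
    if L < w:
        warnings.warn(f"sequence {seq.id!r} shorter than window ({L} < {w}); no islands")
        return []

    counts = _SeqCounts(seq.residues, path.labels if (path is not None and cfg.use_hmm) else None)

    # window statistics for every start, via prefix-sum differences
    starts = np.arange(L - w + 1)
    n_c = counts.c[starts + w] - counts.c[starts]
    n_g = counts.g[starts + w] - counts.g[starts]
    n_n = counts.n[starts + w] - counts.n[starts]
    n_cg = counts.cg[starts + w - 1] - counts.cg[starts]
    gc_ok = (n_c + n_g) >= cfg.min_gc * w
    with np.errstate(divide="ignore", invalid="ignore"):
        oe = np.where(n_c * n_g > 0, n_cg * w / np.maximum(n_c * n_g, 1), 0.0)
    ok = gc_ok & (oe >= cfg.min_obs_exp) & (n_n == 0)
    if counts.i is not None:
        n_i = counts.i[starts + w] - counts.i[starts]
        ok &= n_i >= cfg.min_island_fraction * w

    if not ok.any():
        return []

    # union of qualifying windows -> covered positions -> candidate intervals
    delta = np.zeros(L + 1, dtype=np.int32)
    qs = starts[ok]
    np.add.at(delta, qs, 1)
    np.add.at(delta, qs + w, -1)
    covered = np.cumsum(delta[:-1]) > 0
    edges = np.flatnonzero(np.diff(np.concatenate(([0], covered.view(np.int8), [0]))))
    candidates = list(zip(edges[::2].tolist(), edges[1::2].tolist()))

    # merge candidates separated by <= merge_gap when the merged interval
    # still passes the composition thresholds over its full extent
    merged: list[list[int]] = []
    for s, e in candidates:
        if merged and s - merged[-1][1] <= cfg.merge_gap and _passes(
            counts, merged[-1][0], e, cfg
        ):
            merged[-1][1] = e
        else:
            merged.append([s, e])

    islands: list[CpgIsland] = []
    for s, e in merged:
        if counts.i is not None:
            s, e = _clip_to_island_labels(counts, s, e)
            if e - s < cfg.min_length:
                continue
        s, e = _trim(counts, s, e, cfg)
        if e - s < cfg.min_length:
            continue
        gc, oe_v, ifrac, _ = counts.stats(s, e)
        islands.append(
            CpgIsland(
                chrom=seq.id,
                start=int(s),
                end=int(e),
                gc_content=gc,
                obs_exp=oe_v,
                island_fraction=ifrac if cfg.use_hmm else float("nan"),
                island_id=f"{seq.id}.{len(islands) + 1}",
            )
        )
    return islands


def _clip_to_island_labels(counts: _SeqCounts, s: int, e: int) -> tuple[int, int]:
    """Clip a candidate to the span of Viterbi I labels inside it.

    The window union over-extends each call by up to a window length of
    background; the decoded path marks the island boundary far more
    precisely, so HMM-mode candidates are restricted to [first I, last I].
    This is also what discards short decoy repeats: their I-run is shorter
    than the minimum island length even when windows straddling them pass
    the composition thresholds.
    """
    # counts.i[k] = number of I labels before position k
    per_pos = np.diff(counts.i[s : e + 1])
    idx = np.flatnonzero(per_pos)
    if idx.size == 0:
        return s, s  # no I inside; will be discarded by min_length
    return s + int(idx[0]), s + int(idx[-1]) + 1


def _margin(counts: _SeqCounts, s: int, e: int, cfg: ScanConfig) -> float:
    """Worst criterion margin of [s, e); >= 0 iff the interval passes."""
    gc, oe, ifrac, _ = counts.stats(s, e)
    margins = [gc - cfg.min_gc, oe - cfg.min_obs_exp]
    if cfg.use_hmm:
        margins.append(ifrac - cfg.min_island_fraction)
    return min(margins)


def _trim(counts: _SeqCounts, s: int, e: int, cfg: ScanConfig) -> tuple[int, int]:
    """Shave 1 bp at a time off whichever end improves the failing interval
    more until the full-interval criteria pass.

    An exact tie shaves both ends, which keeps the rule mirror-symmetric:
    criteria-only calls on a reverse-complemented sequence are then the
    mirror image of the forward calls.
    """
    while e - s >= 2 and _margin(counts, s, e, cfg) < 0:
        left = _margin(counts, s + 1, e, cfg)
        right = _margin(counts, s, e - 1, cfg)
        if left > right:
            s += 1
        elif right > left:
            e -= 1
        else:
            s += 1
            e -= 1
    return s, e
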