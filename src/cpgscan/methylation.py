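"""Methylation-status analysis of called islands.

Islands are classified methylated/unmethylated by thresholding their
methylation score (e.g. a 5mC log2 ratio, default cutoff 0.4, boundary
inclusive), and the two groups are compared per trait (length, GC content,
Obs/Exp CpG) with the two-sample Kolmogorov-Smirnov test, plus
within-group z-scores of the scores and length histograms.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import special

from cpgscan.island_scan import CpgIsland
from cpgscan.sequence_io import MethylationRecord

METHYLATED = "methylated"
UNMETHYLATED = "unmethylated"

DEFAULT_THRESHOLD = 0.4

SMALL_SAMPLE_WARN = 25  # asymptotic KS p-values are shaky below this


class AnalysisError(ValueError):
    """Empty sample or unresolvable island id."""


def classify(
    records: Iterable[MethylationRecord],
    threshold: float = DEFAULT_THRESHOLD,
    reclassify: bool = False,
) -> list[MethylationRecord]:
    """Set status = methylated iff score >= threshold (boundary inclusive).

    Records arriving with a status keep it unless ``reclassify`` is set.
    """
    out = []
    for r in records:
        if r.status is None or reclassify:
            status = METHYLATED if r.score >= threshold else UNMETHYLATED
        else:
            status = r.status
        out.append(MethylationRecord(r.island_id, r.score, status, r.true_status))
    return out


@dataclass(frozen=True)
class EmpiricalDistribution:
    """Ordered sample defining a right-continuous step EDF."""

    points: np.ndarray

    @property
    def n(self) -> int:
        return len(self.points)


def edf(dist: EmpiricalDistribution | Sequence[float], x: float) -> float:
    """F_n(x) = (1/n) * #{y_i <= x}."""
    pts = dist.points if isinstance(dist, EmpiricalDistribution) else np.asarray(dist, float)
    if len(pts) == 0:
        raise AnalysisError("empty sample has no EDF")
    return float(np.count_nonzero(pts <= x)) / len(pts)


@dataclass(frozen=True)
class KsResult:
    d_statistic: float
    p_value: float
    method: str  # "asymptotic" | "permutation"
    n1: int
    n2: int


def _ks_d(x: np.ndarray, y: np.ndarray) -> float:
    """sup_t |F1(t) - F2(t)| over the pooled sample points.

    Both EDFs are right-continuous, so evaluating at the pooled sorted
    unique points attains the supremum and is deterministic under ties.
    """
    grid = np.unique(np.concatenate([x, y]))
    f1 = np.searchsorted(np.sort(x), grid, side="right") / len(x)
    f2 = np.searchsorted(np.sort(y), grid, side="right") / len(y)
    return float(np.max(np.abs(f1 - f2)))


def ks_two_sample(
    x: Sequence[float],
    y: Sequence[float],
    method: str = "asymptotic",
    max_enumeration: int = 20_000,
    n_permutations: int = 10_000,
    seed: Optional[int] = None,
) -> KsResult:
    """Two-sample Kolmogorov-Smirnov test.

    The default p-value uses the asymptotic Kolmogorov distribution at the
    effective sample size n_e = n*m/(n+m) with the standard small-sample
    correction sqrt(n_e) + 0.12 + 0.11/sqrt(n_e). ``method="permutation"``
    instead enumerates all group assignments of the pooled sample when
    there are at most ``max_enumeration`` of them, falling back to seeded
    Monte-Carlo sampling otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise AnalysisError("both samples must be non-empty")
    d = _ks_d(x, y)
    n1, n2 = len(x), len(y)
    if method == "asymptotic":
        ne = n1 * n2 / (n1 + n2)
        lam = (math.sqrt(ne) + 0.12 + 0.11 / math.sqrt(ne)) * d
        p = float(special.kolmogorov(lam))
        p = min(max(p, np.finfo(float).tiny), 1.0)
    elif method == "permutation":
        pooled = np.concatenate([x, y])
        if math.comb(n1 + n2, n1) <= max_enumeration:
            hits = total = 0
            for idx in combinations(range(n1 + n2), n1):
                sel = np.zeros(n1 + n2, dtype=bool)
                sel[list(idx)] = True
                if _ks_d(pooled[sel], pooled[~sel]) >= d - 1e-12:
                    hits += 1
                total += 1
            p = hits / total
        else:
            rng = np.random.default_rng(seed)
            hits = 0
            for _ in range(n_permutations):
                perm = rng.permutation(n1 + n2)
                if _ks_d(pooled[perm[:n1]], pooled[perm[n1:]]) >= d - 1e-12:
                    hits += 1
            p = (hits + 1) / (n_permutations + 1)
    else:
        raise AnalysisError(f"unknown KS method {method!r}")
    return KsResult(d_statistic=d, p_value=p, method=method, n1=n1, n2=n2)


TRAITS = ("length", "gc_percent", "obs_exp")


@dataclass
class GroupSummary:
    """Group sizes, per-trait mean +/- sample sd, and per-trait KS results."""

    n: dict[str, int]
    means: dict[str, dict[str, float]]  # group -> trait -> mean
    sds: dict[str, dict[str, float]]  # group -> trait -> sample sd (nan if n < 2)
    ks: dict[str, Optional[KsResult]] = field(default_factory=dict)  # trait -> result


def _trait_values(islands: list[CpgIsland]) -> dict[str, np.ndarray]:
    return {
        "length": np.array([i.length for i in islands], dtype=float),
        "gc_percent": np.array([i.gc_content * 100 for i in islands]),
        "obs_exp": np.array([i.obs_exp for i in islands]),
    }


def group_summary(
    islands: Sequence[CpgIsland],
    records: Sequence[MethylationRecord],
    ks_method: str = "asymptotic",
    seed: Optional[int] = None,
) -> GroupSummary:
    """Table of per-group trait means +/- sd with KS comparisons.

    Every record's island_id must resolve to exactly one island. Standard
    deviations use the n-1 (sample) denominator. If a group is empty the
    summary is still produced with the KS fields unavailable.
    """
    by_id = {i.island_id: i for i in islands}
    if len(by_id) != len(islands):
        raise AnalysisError("duplicate island ids in the analyzed set")
    missing = [r.island_id for r in records if r.island_id not in by_id]
    if missing:
        raise AnalysisError(f"island ids not found in the analyzed set: {missing}")

    groups: dict[str, list[CpgIsland]] = {UNMETHYLATED: [], METHYLATED: []}
    for r in records:
        if r.status in groups:
            groups[r.status].append(by_id[r.island_id])

    n = {g: len(members) for g, members in groups.items()}
    means: dict[str, dict[str, float]] = {}
    sds: dict[str, dict[str, float]] = {}
    values = {g: _trait_values(members) for g, members in groups.items()}
    for g, tv in values.items():
        means[g] = {t: (float(np.mean(v)) if len(v) else float("nan")) for t, v in tv.items()}
        sds[g] = {
            t: (float(np.std(v, ddof=1)) if len(v) >= 2 else float("nan"))
            for t, v in tv.items()
        }

    ks: dict[str, Optional[KsResult]] = {}
    if n[UNMETHYLATED] > 0 and n[METHYLATED] > 0:
        if min(n.values()) < SMALL_SAMPLE_WARN:
            warnings.warn(
                f"smallest group has n={min(n.values())} < {SMALL_SAMPLE_WARN}; "
                "asymptotic KS p-values may be inaccurate"
            )
        for t in TRAITS:
            ks[t] = ks_two_sample(
                values[UNMETHYLATED][t], values[METHYLATED][t],
                method=ks_method, seed=seed,
            )
    else:
        warnings.warn("one methylation group is empty; KS tests unavailable")
        ks = {t: None for t in TRAITS}
    return GroupSummary(n=n, means=means, sds=sds, ks=ks)


def z_scores(
    records: Sequence[MethylationRecord],
) -> tuple[dict[str, float], list[str]]:
    """Per-island z-score of the methylation score within its status group.

    Returns (island_id -> z, groups where z is undefined). A group needs at
    least 2 records and a nonzero sample sd for its z-scores to be defined.
    """
    by_group: dict[str, list[MethylationRecord]] = {}
    for r in records:
        if r.status is None:
            raise AnalysisError(f"record {r.island_id!r} has no status; classify first")
        by_group.setdefault(r.status, []).append(r)
    z: dict[str, float] = {}
    undefined: list[str] = []
    for g, members in by_group.items():
        scores = np.array([m.score for m in members], dtype=float)
        if len(scores) < 2 or np.std(scores, ddof=1) == 0:
            undefined.append(g)
            continue
        mu = float(np.mean(scores))
        sd = float(np.std(scores, ddof=1))
        for m in members:
            z[m.island_id] = (m.score - mu) / sd
    return z, undefined


def length_distribution(
    islands: Sequence[CpgIsland],
    records: Sequence[MethylationRecord],
    bin_width: int = 300,
) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Island-length histograms per status group.

    Bins are half-open [k*w, (k+1)*w). Returns (bin_edges, group -> counts);
    a group with no islands gets an all-zero histogram.
    """
    if not islands:
        raise AnalysisError("no islands to histogram")
    by_id = {i.island_id: i for i in islands}
    lengths = {g: [] for g in (UNMETHYLATED, METHYLATED)}
    for r in records:
        if r.status in lengths and r.island_id in by_id:
            lengths[r.status].append(by_id[r.island_id].length)
    max_len = max((max(v) for v in lengths.values() if v), default=0)
    n_bins = max_len // bin_width + 1
    edges = np.arange(n_bins + 1) * bin_width
    hists = {}
    for g, v in lengths.items():
        counts = np.zeros(n_bins, dtype=int)
        for length in v:
            counts[length // bin_width] += 1
        hists[g] = counts
    return edges, hists
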