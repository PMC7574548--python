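"""Monte Carlo null models and bootstrap confidence intervals.

Random-site nulls answer "how often would a uniformly placed site carry a
motif / fall in an IGR by chance"; the length-controlled IGR null re-draws
IGRs matching the length distribution of OM-positive IGRs, separating the
orientation preference from the length preference. All intervals are
summarized by the 95% percentile bootstrap.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy import stats

from .annotation import IGR
from .intervals import GenomicInterval
from .motifs import MotifUnionSet

__all__ = [
    "BootstrapCI",
    "bootstrap_ci",
    "random_site_motif_expectation",
    "random_site_igr_expectation",
    "random_igr_orientation",
    "length_matched_igr_sample",
    "mann_whitney_two_sided",
]

ORIENTATION_CLASSES = ("convergent", "tandem", "divergent")


@dataclass(frozen=True)
class BootstrapCI:
    estimate: float
    lower: float
    upper: float
    n_reps: int


def _percentile_ci(draws: np.ndarray, estimate: float | None = None) -> BootstrapCI:
    draws = np.asarray(draws, dtype=float)
    est = float(np.mean(draws)) if estimate is None else estimate
    return BootstrapCI(
        est, float(np.percentile(draws, 2.5)), float(np.percentile(draws, 97.5)),
        len(draws),
    )


def bootstrap_ci(
    values: Sequence[float],
    statistic: Callable[[np.ndarray], float] = np.mean,
    reps: int = 10_000,
    seed: int = 0,
) -> BootstrapCI:
    """95% percentile-bootstrap CI of ``statistic`` over ``values``."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("empty input")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, values.size, size=(reps, values.size))
    draws = np.array([statistic(values[row]) for row in idx])
    return _percentile_ci(draws, estimate=float(statistic(values)))


def _arm_positions(
    arms: dict[str, list[GenomicInterval]], margin: int
) -> tuple[list[str], list[GenomicInterval]]:
    """Arm intervals shrunk by ``margin`` so a ±margin window stays on the arm."""
    chroms, usable = [], []
    for chrom, ivs in arms.items():
        for iv in ivs:
            if iv.width > 2 * margin:
                chroms.append(chrom)
                usable.append(
                    GenomicInterval(chrom, iv.start + margin, iv.end - margin)
                )
    if not usable:
        raise ValueError("no arm sequence wide enough for the requested radius")
    return chroms, usable


def _draw_positions(
    rng: np.random.Generator,
    usable: list[GenomicInterval],
    n: int,
) -> list[tuple[str, int]]:
    widths = np.array([iv.width for iv in usable], dtype=float)
    probs = widths / widths.sum()
    picks = rng.choice(len(usable), size=n, p=probs)
    return [
        (usable[i].chrom, int(rng.integers(usable[i].start, usable[i].end)))
        for i in picks
    ]


def random_site_motif_expectation(
    arms: dict[str, list[GenomicInterval]],
    motif_union: MotifUnionSet,
    n_sites: int,
    radius: int = 250,
    reps: int = 1000,
    seed: int = 0,
) -> BootstrapCI:
    """Null fraction of random arm sites with >=1 motif-union site within ±radius."""
    rng = np.random.default_rng(seed)
    chroms, usable = _arm_positions(arms, radius)
    mids = {c: motif_union.midpoints(c)[0] for c in set(chroms)}
    fractions = np.empty(reps)
    for r in range(reps):
        hits = 0
        for chrom, pos in _draw_positions(rng, usable, n_sites):
            m = mids.get(chrom)
            if m is None or m.size == 0:
                continue
            lo = np.searchsorted(m, pos - radius, side="left")
            hi = np.searchsorted(m, pos + radius, side="right")
            hits += int(hi > lo)
        fractions[r] = hits / n_sites
    return _percentile_ci(fractions)


def random_site_igr_expectation(
    arms: dict[str, list[GenomicInterval]],
    igrs: Sequence[IGR],
    n_sites: int,
    reps: int = 1000,
    seed: int = 0,
) -> BootstrapCI:
    """Null fraction of random arm sites falling inside an IGR."""
    rng = np.random.default_rng(seed)
    chroms, usable = _arm_positions(arms, 0)
    starts: dict[str, np.ndarray] = {}
    ends: dict[str, np.ndarray] = {}
    for chrom in set(chroms):
        ivs = sorted(
            (g.interval for g in igrs if g.interval.chrom == chrom),
            key=lambda iv: iv.start,
        )
        starts[chrom] = np.array([iv.start for iv in ivs], dtype=np.int64)
        ends[chrom] = np.array([iv.end for iv in ivs], dtype=np.int64)
    fractions = np.empty(reps)
    for r in range(reps):
        hits = 0
        for chrom, pos in _draw_positions(rng, usable, n_sites):
            s = starts.get(chrom)
            if s is None or s.size == 0:
                continue
            j = int(np.searchsorted(s, pos, side="right")) - 1
            hits += int(j >= 0 and pos < ends[chrom][j])
        fractions[r] = hits / n_sites
    return _percentile_ci(fractions)


def _orientation_proportions(sampled: Sequence[str]) -> dict[str, float]:
    n = len(sampled)
    return {c: sum(1 for s in sampled if s == c) / n for c in ORIENTATION_CLASSES}


def random_igr_orientation(
    igrs: Sequence[IGR],
    n_sample: int,
    reps: int = 1000,
    seed: int = 0,
) -> dict[str, BootstrapCI]:
    """Orientation-class proportions of randomly sampled IGRs (no replacement
    within a draw), one 95% percentile CI per class."""
    rng = np.random.default_rng(seed)
    pool = [g.orientation for g in igrs if g.orientation != "edge"]
    if n_sample > len(pool):
        raise ValueError("sample larger than IGR pool")
    pool = np.array(pool)
    draws = {c: np.empty(reps) for c in ORIENTATION_CLASSES}
    for r in range(reps):
        sampled = rng.choice(pool, size=n_sample, replace=False)
        props = _orientation_proportions(list(sampled))
        for c in ORIENTATION_CLASSES:
            draws[c][r] = props[c]
    return {c: _percentile_ci(draws[c]) for c in ORIENTATION_CLASSES}


@dataclass
class LengthMatchedSample:
    class_cis: dict[str, BootstrapCI]
    sampled_lengths: np.ndarray  # (reps, n_targets)


def length_matched_igr_sample(
    igrs: Sequence[IGR],
    target_lengths: Sequence[int],
    reps: int = 1000,
    seed: int = 0,
    n_strata: int = 10,
) -> LengthMatchedSample:
    """Orientation proportions of IGRs drawn to match a target length profile.

    The pooled IGR length distribution is cut into ``n_strata`` quantile
    strata; each target length draws a not-yet-used IGR from its stratum,
    falling back to the globally nearest unused IGR when the stratum is
    exhausted.
    """
    rng = np.random.default_rng(seed)
    pool = [g for g in igrs if g.orientation != "edge"]
    if not pool:
        raise ValueError("no non-edge IGRs")
    lengths = np.array([g.interval.width for g in pool], dtype=float)
    orientations = np.array([g.orientation for g in pool])
    # unique quantile cut points; right-closed bins so heavy length ties
    # collapse into one stratum instead of absorbing the tail
    cuts = np.unique(np.quantile(lengths, np.linspace(0, 1, n_strata + 1)))
    n_bins = len(cuts)

    def stratum_of(x: np.ndarray) -> np.ndarray:
        return np.clip(np.searchsorted(cuts, x, side="left"), 0, n_bins - 1)

    strata = stratum_of(lengths)
    target = np.asarray(target_lengths, dtype=float)
    t_strata = stratum_of(np.clip(target, cuts[0], cuts[-1]))
    by_stratum = {s: np.flatnonzero(strata == s) for s in range(n_bins)}
    order_by_length = np.argsort(lengths)

    draws = {c: np.empty(reps) for c in ORIENTATION_CLASSES}
    sampled_lengths = np.empty((reps, len(target)))
    for r in range(reps):
        used = np.zeros(len(pool), dtype=bool)
        chosen: list[int] = []
        for t_len, t_s in zip(target, t_strata):
            cands = by_stratum[int(t_s)]
            free = cands[~used[cands]]
            if free.size:
                pick = int(rng.choice(free))
            else:  # nearest-length unused IGR
                remaining = order_by_length[~used[order_by_length]]
                pick = int(remaining[np.argmin(np.abs(lengths[remaining] - t_len))])
            used[pick] = True
            chosen.append(pick)
        props = _orientation_proportions(list(orientations[chosen]))
        for c in ORIENTATION_CLASSES:
            draws[c][r] = props[c]
        sampled_lengths[r] = lengths[chosen]
    return LengthMatchedSample(
        {c: _percentile_ci(draws[c]) for c in ORIENTATION_CLASSES}, sampled_lengths
    )


def mann_whitney_two_sided(a: Sequence[float], b: Sequence[float]) -> float:
    """Two-sided Mann-Whitney U p-value (tie-corrected; exact for tiny n)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("empty sample")
    method = "exact" if (a.size <= 8 and b.size <= 8 and
                         np.unique(np.concatenate([a, b])).size == a.size + b.size) \
        else "auto"
    return float(stats.mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue)
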