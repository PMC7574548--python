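"""Sequence-intrinsic origin features: AT content and DNA melting energy.

Two of the three origin determinants live here. ``l_at`` measures the extent
of the AT-rich segment associated with Mcm binding: the number of positions
in a window whose centered 101 bp neighbourhood has AT fraction >= 0.75.
``delta_g_melt_profile`` estimates the free energy needed to separate the
duplex over a 200 bp sliding window using dinucleotide nearest-neighbour
stacking parameters (unified SantaLucia ΔG°37 table by default); AT-rich DNA
takes less energy to melt, so the profile dips where Mcm binds.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np

from .intervals import GenomicInterval

__all__ = [
    "SANTALUCIA_UNIFIED_DG37",
    "at_indicator",
    "at_fraction",
    "at_profile",
    "l_at",
    "flank_at",
    "delta_g_melt_profile",
    "revcomp",
]

#: Unified nearest-neighbour ΔG°37 stacking free energies (kcal/mol per step),
#: symmetric under reverse complement. Duplex-initiation terms are omitted:
#: profiles are only compared across windows of equal width.
SANTALUCIA_UNIFIED_DG37: dict[str, float] = {
    "AA": -1.00, "TT": -1.00,
    "AT": -0.88,
    "TA": -0.58,
    "CA": -1.45, "TG": -1.45,
    "GT": -1.44, "AC": -1.44,
    "CT": -1.28, "AG": -1.28,
    "GA": -1.30, "TC": -1.30,
    "CG": -2.17,
    "GC": -2.24,
    "GG": -1.84, "CC": -1.84,
}

_COMP = str.maketrans("ACGTN", "TGCAN")

L_AT_WINDOW = 101
L_AT_THRESHOLD = 0.75
MELT_WINDOW = 200


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def at_indicator(seq: str) -> np.ndarray:
    """1 where the base is A or T, else 0 (N counts as non-AT)."""
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return ((arr == ord("A")) | (arr == ord("T"))).astype(np.uint8)


def at_fraction(seq: str, interval: GenomicInterval | None = None) -> float:
    """(#A + #T) / width over ``seq`` or a slice of it."""
    sub = seq if interval is None else seq[interval.start : interval.end]
    if not sub:
        raise ValueError("empty sequence")
    return float(at_indicator(sub).mean())


def _centered_window_sums(ind: np.ndarray, window: int) -> tuple[np.ndarray, np.ndarray]:
    """Sum and actual width of the window centered at each position.

    The window covering position i is ``[i - window//2, i - window//2 + window)``,
    truncated at the sequence ends.
    """
    n = ind.size
    csum = np.concatenate([[0], np.cumsum(ind, dtype=np.int64)])
    left = np.arange(n) - window // 2
    right = left + window
    left = np.clip(left, 0, n)
    right = np.clip(right, 0, n)
    return csum[right] - csum[left], (right - left)


def at_profile(seq: str, window: int = 100) -> np.ndarray:
    """Per-position AT fraction in a centered sliding window (edge-truncated)."""
    if window < 1:
        raise ValueError("window must be >= 1")
    sums, widths = _centered_window_sums(at_indicator(seq), window)
    return sums / widths


def l_at(
    seq: str,
    window_interval: GenomicInterval,
    w: int = L_AT_WINDOW,
    threshold: float = L_AT_THRESHOLD,
    profile: np.ndarray | None = None,
) -> int:
    """Number of positions in ``window_interval`` whose centered ``w``-window
    AT fraction is at or above ``threshold``.

    The w-windows may extend into the flanking genome sequence; ``seq`` is
    the whole chromosome. A precomputed chromosome-wide ``at_profile(seq, w)``
    may be passed to amortize repeated calls.
    """
    if window_interval.end > len(seq):
        raise ValueError("window extends past the sequence")
    if profile is None:
        lo = max(0, window_interval.start - w)
        hi = min(len(seq), window_interval.end + w)
        local = at_profile(seq[lo:hi], w)
        vals = local[window_interval.start - lo : window_interval.end - lo]
    else:
        vals = profile[window_interval.start : window_interval.end]
    return int(np.count_nonzero(vals >= threshold - 1e-12))


def flank_at(seq: str, summit: int) -> tuple[float, float]:
    """AT fractions of the 400 bp segments [summit-500, summit-100) and
    [summit+100, summit+500)."""
    if summit - 500 < 0 or summit + 500 > len(seq):
        raise ValueError("flank out of sequence range")
    left = at_fraction(seq[summit - 500 : summit - 100])
    right = at_fraction(seq[summit + 100 : summit + 500])
    return left, right


def _step_values(seq: str, params: Mapping[str, float]) -> np.ndarray:
    """ΔG°37 of each dinucleotide step; NaN where a step touches a non-ACGT base."""
    table = np.full((256, 256), np.nan)
    for dinuc, val in params.items():
        table[ord(dinuc[0]), ord(dinuc[1])] = val
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return table[arr[:-1], arr[1:]]


def delta_g_melt_profile(
    seq: str,
    window: int = MELT_WINDOW,
    params: Mapping[str, float] | None = None,
) -> np.ndarray:
    """Strand-separation free energy per position (kcal/mol, higher = harder).

    The value at position i sums the ``window - 1`` dinucleotide stacking
    terms of the window ``[i - window//2, i - window//2 + window)`` and
    negates the (negative) total. Positions whose full window does not fit in
    the sequence, or whose window contains N, are NaN.
    """
    params = SANTALUCIA_UNIFIED_DG37 if params is None else params
    n = len(seq)
    if window > n:
        raise ValueError("window longer than sequence")
    if window < 2:
        raise ValueError("window must span at least one dinucleotide step")
    steps = _step_values(seq, params)
    csum = np.concatenate([[0.0], np.cumsum(np.nan_to_num(steps))])
    bad = np.concatenate([[0], np.cumsum(np.isnan(steps).astype(np.int64))])
    out = np.full(n, np.nan)
    left = np.arange(n) - window // 2
    right = left + window - 1  # number of steps = window - 1
    ok = (left >= 0) & (right <= n - 1)
    lo, hi = left[ok], right[ok]
    sums = csum[hi] - csum[lo]
    has_n = (bad[hi] - bad[lo]) > 0
    vals = -sums
    vals[has_n] = np.nan
    out[ok] = vals
    return out
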