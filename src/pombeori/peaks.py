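"""ChIP-seq fold-enrichment tracks, peak calling and Orc/Mcm co-localization.

Peak semantics: a maximal run of consecutive 10 bp bins at or above the FE
threshold is one peak; runs narrower than 50 bp are discarded as
false-positive signals; the summit is the center of the highest-FE bin
(leftmost on ties). An Orc4 peak overlapping a Mcm2 peak by >=1 bp is an OM
site (co-localized pre-RC); Orc4 peaks with no Mcm2 overlap are O sites, and
Mcm2 peaks with no Orc4 overlap are M-only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .intervals import ArmMask, GenomicInterval

__all__ = [
    "FETrack",
    "Peak",
    "SiteSet",
    "compute_fe",
    "call_peaks",
    "apply_mask",
    "classify_sites",
    "venn_counts",
    "summit_offsets",
]

DEFAULT_BIN_WIDTH = 10
FE_THRESHOLD_ORC = 6.0
FE_THRESHOLD_MCM = 2.0
MIN_PEAK_WIDTH = 50


@dataclass
class FETrack:
    """Per-chromosome fold-enrichment values on a fixed bin grid."""

    data: dict[str, np.ndarray]
    bin_width: int = DEFAULT_BIN_WIDTH

    def __post_init__(self) -> None:
        for chrom, arr in self.data.items():
            arr = np.asarray(arr, dtype=float)
            if (arr < 0).any():
                raise ValueError(f"negative FE on {chrom}")
            self.data[chrom] = arr

    def value_at(self, chrom: str, pos: int) -> float:
        return float(self.data[chrom][pos // self.bin_width])


@dataclass(frozen=True)
class Peak:
    interval: GenomicInterval
    summit: int
    max_fe: float

    def __post_init__(self) -> None:
        if not self.interval.contains(self.summit):
            raise ValueError("summit outside peak interval")


@dataclass
class SiteSet:
    """OM / O / M-only partition of Orc and Mcm peaks."""

    om_sites: list[tuple[Peak, Peak]] = field(default_factory=list)
    o_sites: list[Peak] = field(default_factory=list)
    m_only: list[Peak] = field(default_factory=list)


def compute_fe(
    chip_counts: Mapping[str, np.ndarray],
    input_counts: Mapping[str, np.ndarray],
    pseudocount: float = 1.0,
    bin_width: int = DEFAULT_BIN_WIDTH,
) -> FETrack:
    """Fold enrichment per bin: depth-normalized (chip+pc)/(input+pc) ratio."""
    if set(chip_counts) != set(input_counts):
        raise ValueError("chip and input cover different chromosomes")
    chip_total = sum(float(np.sum(a)) for a in chip_counts.values())
    input_total = sum(float(np.sum(a)) for a in input_counts.values())
    if chip_total <= 0 or input_total <= 0:
        raise ValueError("zero total counts")
    data = {}
    for chrom, chip in chip_counts.items():
        chip = np.asarray(chip, dtype=float)
        inp = np.asarray(input_counts[chrom], dtype=float)
        if chip.shape != inp.shape:
            raise ValueError(f"mismatched bin grids on {chrom}")
        data[chrom] = ((chip + pseudocount) / chip_total) / (
            (inp + pseudocount) / input_total
        )
    return FETrack(data, bin_width)


def call_peaks(
    fe_track: FETrack, fe_threshold: float, min_width: int = MIN_PEAK_WIDTH
) -> list[Peak]:
    """Threshold-run peak caller implementing the stated post-processing rules."""
    if fe_threshold <= 0:
        raise ValueError("fe_threshold must be > 0")
    bw = fe_track.bin_width
    peaks: list[Peak] = []
    for chrom in sorted(fe_track.data):
        fe = fe_track.data[chrom]
        above = fe >= fe_threshold
        if not above.any():
            continue
        padded = np.concatenate([[False], above, [False]])
        d = np.diff(padded.astype(np.int8))
        run_starts = np.flatnonzero(d == 1)
        run_ends = np.flatnonzero(d == -1)
        for s, e in zip(run_starts, run_ends):
            width = (e - s) * bw
            if width < min_width:
                continue
            best = s + int(np.argmax(fe[s:e]))  # leftmost maximal bin
            summit = best * bw + bw // 2
            peaks.append(
                Peak(GenomicInterval(chrom, int(s * bw), int(e * bw)), summit,
                     float(fe[best]))
            )
    peaks.sort(key=lambda p: (p.interval.chrom, p.interval.start))
    return peaks


def apply_mask(peaks: Sequence[Peak], arm_mask: ArmMask) -> list[Peak]:
    """Drop peaks overlapping any masked region by >=1 bp."""
    return [p for p in peaks if not arm_mask.overlaps(p.interval)]


def classify_sites(orc_peaks: Sequence[Peak], mcm_peaks: Sequence[Peak]) -> SiteSet:
    """Partition Orc peaks into OM (>=1 bp Mcm overlap) and O; flag M-only Mcm.

    When one Orc peak overlaps several Mcm peaks it is paired with the
    largest-overlap one (leftmost on ties); such many-to-one overlaps are why
    the OM pair count and the per-protein overlap tallies need not add up.
    """
    site_set = SiteSet()
    mcm_hit = [False] * len(mcm_peaks)
    for orc in orc_peaks:
        best_j, best_ov = -1, 0
        for j, mcm in enumerate(mcm_peaks):
            ov = orc.interval.overlap_len(mcm.interval)
            if ov > 0:
                mcm_hit[j] = True
                if ov > best_ov or (
                    ov == best_ov
                    and best_j >= 0
                    and mcm.interval.start < mcm_peaks[best_j].interval.start
                ):
                    best_j, best_ov = j, ov
        if best_j >= 0:
            site_set.om_sites.append((orc, mcm_peaks[best_j]))
        else:
            site_set.o_sites.append(orc)
    site_set.m_only = [m for j, m in enumerate(mcm_peaks) if not mcm_hit[j]]
    return site_set


def venn_counts(site_set: SiteSet) -> tuple[int, int, int]:
    """(n_O, n_OM, n_M-only)."""
    return len(site_set.o_sites), len(site_set.om_sites), len(site_set.m_only)


def summit_offsets(site_set: SiteSet) -> list[int]:
    """Signed Mcm-minus-Orc summit distances at OM sites."""
    return [mcm.summit - orc.summit for orc, mcm in site_set.om_sites]
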