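"""Readers and writers for the plain-text formats the pipeline exchanges.

bedGraph and BED are 0-based half-open; GFF3 writing (1-based inclusive) is
handled here so the conversion lives in exactly one place alongside the
reader in :mod:`pombeori.annotation`.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .intervals import ArmMask, GenomicInterval

__all__ = [
    "read_bed_mask",
    "write_bed_mask",
    "read_bedgraph_bins",
    "write_bedgraph_bins",
    "read_bedgraph_per_base",
    "write_bedgraph_per_base",
    "write_peaks_bed",
    "read_peaks_bed",
    "write_json",
]


def read_bed_mask(path: str | Path) -> ArmMask:
    ivs = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            chrom, start, end = line.split("\t")[:3]
            ivs.append(GenomicInterval(chrom, int(start), int(end)))
    return ArmMask(ivs)


def write_bed_mask(mask: ArmMask, path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in mask.intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def read_bedgraph_bins(
    path: str | Path, bin_width: int, chrom_lengths: Mapping[str, int]
) -> dict[str, np.ndarray]:
    """Read a fixed-grid bedGraph into per-chromosome per-bin arrays.

    Every record must start on the bin grid; missing bins are 0.
    """
    arrays = {
        chrom: np.zeros(-(-length // bin_width), dtype=float)
        for chrom, length in chrom_lengths.items()
    }
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None,
        names=["chrom", "start", "end", "value"],
        dtype={"chrom": str, "start": int, "end": int, "value": float},
    )
    for chrom, sub in df.groupby("chrom", sort=False):
        if chrom not in arrays:
            raise ValueError(f"bedGraph chromosome {chrom!r} not in genome")
        if ((sub["start"] % bin_width) != 0).any():
            raise ValueError(f"bedGraph records off the {bin_width} bp bin grid")
        arr = arrays[chrom]
        for start, end, value in zip(sub["start"], sub["end"], sub["value"]):
            arr[start // bin_width : -(-end // bin_width)] = value
    return arrays


def write_bedgraph_bins(
    arrays: Mapping[str, np.ndarray], bin_width: int, path: str | Path,
    chrom_lengths: Mapping[str, int] | None = None,
) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(arrays):
            arr = arrays[chrom]
            length = chrom_lengths[chrom] if chrom_lengths else len(arr) * bin_width
            for i, v in enumerate(arr):
                start = i * bin_width
                end = min(start + bin_width, length)
                fh.write(f"{chrom}\t{start}\t{end}\t{v:.6g}\n")


def read_bedgraph_per_base(
    path: str | Path, chrom_lengths: Mapping[str, int]
) -> dict[str, np.ndarray]:
    """Read a run-length bedGraph into per-base arrays (uncovered = 0)."""
    arrays = {
        chrom: np.zeros(length, dtype=float) for chrom, length in chrom_lengths.items()
    }
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None,
        names=["chrom", "start", "end", "value"],
        dtype={"chrom": str, "start": int, "end": int, "value": float},
    )
    for chrom, sub in df.groupby("chrom", sort=False):
        if chrom not in arrays:
            raise ValueError(f"bedGraph chromosome {chrom!r} not in genome")
        arr = arrays[chrom]
        for start, end, value in zip(sub["start"], sub["end"], sub["value"]):
            arr[start:end] = value
    return arrays


def write_bedgraph_per_base(
    arrays: Mapping[str, np.ndarray], path: str | Path
) -> None:
    """Write per-base arrays as run-length-encoded bedGraph."""
    with open(path, "w") as fh:
        for chrom in sorted(arrays):
            arr = np.asarray(arrays[chrom])
            if arr.size == 0:
                continue
            breaks = np.flatnonzero(np.diff(arr)) + 1
            starts = np.concatenate([[0], breaks])
            ends = np.concatenate([breaks, [arr.size]])
            for s, e in zip(starts, ends):
                v = arr[s]
                if v != 0:
                    fh.write(f"{chrom}\t{s}\t{e}\t{v:.6g}\n")


def write_peaks_bed(peaks: Iterable, path: str | Path) -> None:
    """BED6; the summit is carried in the name field as ``summit=<bp>``."""
    with open(path, "w") as fh:
        for p in peaks:
            iv = p.interval
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\tsummit={p.summit}\t"
                f"{p.max_fe:.6g}\t.\n"
            )


def read_peaks_bed(path: str | Path) -> list:
    from .peaks import Peak  # local import: io stays dependency-light

    peaks = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            chrom, start, end, name, score, _strand = line.rstrip("\n").split("\t")[:6]
            summit = int(name.split("summit=")[1])
            peaks.append(
                Peak(GenomicInterval(chrom, int(start), int(end)), summit, float(score))
            )
    return peaks


def write_json(obj, path: str | Path) -> None:
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_default)
        fh.write("\n")
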