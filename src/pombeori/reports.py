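"""Descriptive analyses over classified sites and IGR features.

These reproduce, as report computations: motif positioning around site
summits (with the nearest-motif-rightward orientation convention), FE versus
local motif count, Orc/Mcm summit offset classes and flank-AT asymmetry,
intergenic/intragenic placement proportions, and the stacked L_AT x N_mt /
L_AT x L_ntx stratified histograms.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation import IGR, GeneModel
from .motifs import MotifUnionSet
from .peaks import FETrack, SiteSet
from .resampling import mann_whitney_two_sided
from .sequence import flank_at

__all__ = [
    "motif_position_matrix",
    "fe_by_motif_count",
    "offset_class",
    "flank_asymmetry_table",
    "placement_table",
    "stratified_feature_histogram",
]

OFFSET_DEAD_ZONE = 100


@dataclass
class SitePositions:
    """Per-site motif offsets after the nearest-motif-rightward flip."""

    offsets: list[np.ndarray]
    flipped: list[bool]


def motif_position_matrix(
    sites: Sequence[tuple[str, int]],
    motif_union: MotifUnionSet,
    half_width: int = 1000,
) -> SitePositions:
    """Motif-union midpoints within ±half_width of each summit, each site
    oriented so its nearest motif lies rightward (offsets flipped when the
    nearest motif is on the left)."""
    offsets_all: list[np.ndarray] = []
    flipped_all: list[bool] = []
    for chrom, summit in sites:
        mids, _ = motif_union.midpoints(chrom)
        lo = np.searchsorted(mids, summit - half_width, side="left")
        hi = np.searchsorted(mids, summit + half_width, side="right")
        offsets = (mids[lo:hi] - summit).astype(int)
        flip = False
        if offsets.size:
            nearest = offsets[np.argmin(np.abs(offsets))]
            if nearest < 0:
                flip = True
                offsets = -offsets
            offsets = np.sort(offsets)
        offsets_all.append(offsets)
        flipped_all.append(flip)
    return SitePositions(offsets_all, flipped_all)


def fe_by_motif_count(
    sites: Sequence[tuple[str, int]],
    fe_track: FETrack,
    motif_union: MotifUnionSet,
    radius: int = 250,
) -> tuple[dict[int, list[float]], pd.DataFrame]:
    """Summit FE grouped by the number of motifs within ±radius.

    Returns the raw groups and a summary table with group medians and the
    two-sided Mann-Whitney p-value between adjacent occupied groups.
    """
    groups: dict[int, list[float]] = {}
    for chrom, summit in sites:
        mids, _ = motif_union.midpoints(chrom)
        lo = np.searchsorted(mids, summit - radius, side="left")
        hi = np.searchsorted(mids, summit + radius, side="right")
        groups.setdefault(int(hi - lo), []).append(fe_track.value_at(chrom, summit))
    counts = sorted(groups)
    rows = []
    for i, c in enumerate(counts):
        p_next = np.nan
        if i + 1 < len(counts):
            p_next = mann_whitney_two_sided(groups[c], groups[counts[i + 1]])
        rows.append(
            {"motif_count": c, "n_sites": len(groups[c]),
             "median_fe": float(np.median(groups[c])),
             "mw_p_vs_next": p_next}
        )
    return groups, pd.DataFrame(rows)


def offset_class(offset: int, dead_zone: int = OFFSET_DEAD_ZONE) -> str:
    """Sign of the Mcm-minus-Orc summit offset with an overlap dead zone."""
    if abs(offset) <= dead_zone:
        return "overlap"
    return "right" if offset > 0 else "left"


def flank_asymmetry_table(
    site_set: SiteSet,
    genome: Mapping[str, str],
    dead_zone: int = OFFSET_DEAD_ZONE,
) -> pd.DataFrame:
    """Per-OM-site AT content of the two 400 bp flanks of the Orc4 summit,
    joined with the summit-offset class. Sites whose flanks leave the
    chromosome are skipped."""
    rows = []
    for orc, mcm in site_set.om_sites:
        chrom = orc.interval.chrom
        try:
            left, right = flank_at(genome[chrom], orc.summit)
        except ValueError:
            continue
        rows.append(
            {"chrom": chrom, "orc_summit": orc.summit, "mcm_summit": mcm.summit,
             "left_at": left, "right_at": right,
             "offset_class": offset_class(mcm.summit - orc.summit, dead_zone)}
        )
    return pd.DataFrame(
        rows, columns=["chrom", "orc_summit", "mcm_summit", "left_at", "right_at",
                       "offset_class"],
    )


def placement_table(
    summits_by_class: Mapping[str, Sequence[tuple[str, int]]],
    genes: Sequence[GeneModel],
    igrs: Sequence[IGR],
) -> pd.DataFrame:
    """Fraction of sites (by Orc summit position) inside IGRs versus genes."""
    spans: dict[str, list[tuple[int, int]]] = {}
    for g in genes:
        s = g.span
        spans.setdefault(s.chrom, []).append((s.start, s.end))
    rows = []
    for cls, summits in summits_by_class.items():
        n = len(summits)
        intra = 0
        for chrom, summit in summits:
            if any(s <= summit < e for s, e in spans.get(chrom, ())):
                intra += 1
        rows.append(
            {"class": cls, "n": n,
             "frac_intergenic": (n - intra) / n if n else np.nan,
             "frac_intragenic": intra / n if n else np.nan}
        )
    return pd.DataFrame(rows)


def stratified_feature_histogram(
    igr_features: pd.DataFrame,
    l_at_bins: Sequence[float] = (200, 250, 400),
    second_feature: str = "N_mt",
    second_bins: Sequence[float] = (1, 2, 3),
) -> pd.DataFrame:
    """Stacked counts of IGR classes per (L_AT stratum x second-feature stratum).

    ``igr_features`` must carry columns ``L_AT``, the second feature and
    ``class`` (OM / O / background). Bin edges are left-closed; the strata
    below the first edge and at/above the last are included so totals are
    conserved.
    """
    for col in ("L_AT", second_feature, "class"):
        if col not in igr_features.columns:
            raise ValueError(f"missing column {col!r}")
    l_edges = [-np.inf, *l_at_bins, np.inf]
    s_edges = [-np.inf, *second_bins, np.inf]
    df = igr_features.copy()
    df["L_AT_stratum"] = pd.cut(df["L_AT"], l_edges, right=False)
    df["second_stratum"] = pd.cut(df[second_feature], s_edges, right=False)
    out = (
        df.groupby(["L_AT_stratum", "second_stratum", "class"], observed=False)
        .size()
        .rename("count")
        .reset_index()
    )
    out["second_feature"] = second_feature
    return out
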