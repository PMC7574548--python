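"""Per-window feature vectors and classification datasets.

Every candidate site is scored over a 1000 bp window centered on its anchor
(an Orc4 peak summit for positive IGRs, the IGR midpoint for negatives). The
default feature set has 13 members; the core trio is N_mt (poly(dA)
motif-union sites in the window), L_AT (bp with 101 bp-window AT >= 0.75) and
L_ntx (longest run of RNA-seq depth <= 1). The remaining features elaborate
the same three characteristics (AT richness, motif signal, transcription and
IGR geometry); any named subset can be selected downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation import IGR
from .coverage import l_ntx, longest_run
from .intervals import ArmMask, GenomicInterval
from .motifs import MotifUnionSet
from .peaks import SiteSet
from .sequence import (
    L_AT_THRESHOLD,
    L_AT_WINDOW,
    at_indicator,
    at_profile,
    delta_g_melt_profile,
)

__all__ = [
    "WindowSpec",
    "Dataset",
    "FeatureExtractor",
    "FEATURE_NAMES",
    "CORE_TRIO",
    "build_window",
    "build_igr_dataset",
    "build_intragenic_dataset",
]

WINDOW_WIDTH = 1000

FEATURE_NAMES = [
    "N_mt",
    "L_AT",
    "L_ntx",
    "at_mean",
    "at_max_101",
    "dg_min_200",
    "motif_score_sum",
    "motif_dist_center",
    "run_max_AT",
    "igr_length",
    "rpkm_min_flank",
    "is_divergent",
    "is_convergent",
]

CORE_TRIO = ["N_mt", "L_AT", "L_ntx"]


@dataclass(frozen=True)
class WindowSpec:
    chrom: str
    anchor: int
    interval: GenomicInterval


@dataclass
class Dataset:
    """Feature matrix with labels and window metadata."""

    X: pd.DataFrame
    y: np.ndarray
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        if self.X.isna().any().any():
            raise ValueError("feature matrix contains missing values")

    @property
    def n_pos(self) -> int:
        return int(self.y.sum())

    @property
    def n_neg(self) -> int:
        return int((1 - self.y).sum())


def build_window(
    anchor: int, chrom_length: int, width: int = WINDOW_WIDTH, chrom: str = ""
) -> WindowSpec:
    """[anchor - width//2, anchor - width//2 + width); error when out of bounds."""
    start = anchor - width // 2
    end = start + width
    if start < 0 or end > chrom_length:
        raise ValueError(
            f"window [{start},{end}) around {anchor} leaves chromosome [0,{chrom_length})"
        )
    return WindowSpec(chrom, anchor, GenomicInterval(chrom or "chr", start, end))


def _shifted_window(
    anchor: int, chrom_length: int, width: int, chrom: str
) -> WindowSpec:
    """Like build_window but shifted minimally inward when near an edge."""
    half = width // 2
    anchor = min(max(anchor, half), chrom_length - (width - half))
    return build_window(anchor, chrom_length, width, chrom)


class FeatureExtractor:
    """Computes per-window feature vectors against cached chromosome profiles.

    Chromosome-wide 101 bp AT profiles and 200 bp melt profiles are computed
    lazily once per chromosome, so scoring thousands of windows stays cheap.
    """

    def __init__(
        self,
        genome: Mapping[str, str],
        motif_union: MotifUnionSet,
        coverage: Mapping[str, np.ndarray],
        width: int = WINDOW_WIDTH,
        l_at_window: int = L_AT_WINDOW,
        l_at_threshold: float = L_AT_THRESHOLD,
    ):
        self.genome = genome
        self.motif_union = motif_union
        self.coverage = coverage
        self.width = width
        self.l_at_window = l_at_window
        self.l_at_threshold = l_at_threshold
        self._at101: dict[str, np.ndarray] = {}
        self._melt: dict[str, np.ndarray] = {}
        self._at1: dict[str, np.ndarray] = {}

    def _profiles(self, chrom: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        if chrom not in self._at101:
            seq = self.genome[chrom]
            self._at101[chrom] = at_profile(seq, self.l_at_window)
            self._melt[chrom] = delta_g_melt_profile(seq)
            self._at1[chrom] = at_indicator(seq)
        return self._at101[chrom], self._melt[chrom], self._at1[chrom]

    def chrom_length(self, chrom: str) -> int:
        return len(self.genome[chrom])

    def extract(self, window: WindowSpec, igr_context: IGR | None = None) -> dict:
        at101, melt, at1 = self._profiles(window.chrom)
        iv = window.interval
        half = self.width // 2

        mids, scores = self.motif_union.midpoints(window.chrom)
        lo = np.searchsorted(mids, window.anchor - half, side="left")
        hi = np.searchsorted(mids, window.anchor + half, side="right")
        n_mt = int(hi - lo)
        score_sum = float(scores[lo:hi].sum())
        if mids.size:
            dist = int(np.abs(mids - window.anchor).min())
            motif_dist = min(dist, half)
        else:
            motif_dist = half

        at101_win = at101[iv.start : iv.end]
        l_at_val = int(np.count_nonzero(at101_win >= self.l_at_threshold - 1e-12))
        melt_win = melt[iv.start : iv.end]
        dg_min = float(np.nanmin(melt_win)) if np.isfinite(melt_win).any() else 0.0
        at_win = at1[iv.start : iv.end]

        cov = self.coverage[window.chrom]
        l_ntx_val = l_ntx(cov, iv)

        if igr_context is not None:
            igr_length = igr_context.interval.width
            flank_rpkms = [
                g.rpkm
                for g in (igr_context.left_gene, igr_context.right_gene)
                if g is not None
            ]
            rpkm_min = float(min(flank_rpkms)) if flank_rpkms else 0.0
            orientation = igr_context.orientation
        else:
            igr_length = 0
            rpkm_min = 0.0
            orientation = "none"

        return {
            "N_mt": n_mt,
            "L_AT": l_at_val,
            "L_ntx": l_ntx_val,
            "at_mean": float(at_win.mean()),
            "at_max_101": float(at101_win.max()),
            "dg_min_200": dg_min,
            "motif_score_sum": score_sum,
            "motif_dist_center": motif_dist,
            "run_max_AT": longest_run(at_win.astype(bool)),
            "igr_length": igr_length,
            "rpkm_min_flank": rpkm_min,
            "is_divergent": int(orientation == "divergent"),
            "is_convergent": int(orientation == "convergent"),
        }


def _assemble(rows: list[dict], metas: list[dict], labels: list[int]) -> Dataset:
    X = pd.DataFrame(rows, columns=FEATURE_NAMES)
    meta = pd.DataFrame(metas)
    return Dataset(X, np.asarray(labels, dtype=int), meta)


def build_igr_dataset(
    igrs: Sequence[IGR],
    site_set: SiteSet,
    extractor: FeatureExtractor,
    policy: str = "holdout",
) -> tuple[Dataset, list[WindowSpec]]:
    """Intergenic classification dataset.

    Positives: one window per intergenic OM site, centered on its Orc4
    summit. Negatives: windows on the midpoints of IGRs containing no OM
    site. O-site IGRs are held out for later scoring under
    ``policy='holdout'`` (returned as the second element), or kept as
    negatives under ``policy='include'``.
    """
    if policy not in ("holdout", "include"):
        raise ValueError(f"unknown policy {policy!r}")
    om_summits = [
        (orc.interval.chrom, orc.summit) for orc, _ in site_set.om_sites
    ]
    o_summits = [(p.interval.chrom, p.summit) for p in site_set.o_sites]

    rows: list[dict] = []
    metas: list[dict] = []
    labels: list[int] = []
    heldout: list[WindowSpec] = []
    heldout_igrs: list[IGR] = []

    for igr in igrs:
        iv = igr.interval
        om_here = [
            s for c, s in om_summits if c == iv.chrom and iv.contains(s)
        ]
        o_here = [s for c, s in o_summits if c == iv.chrom and iv.contains(s)]
        chrom_len = extractor.chrom_length(iv.chrom)
        if om_here:
            for summit in om_here:
                window = _shifted_window(summit, chrom_len, extractor.width, iv.chrom)
                rows.append(extractor.extract(window, igr))
                metas.append(
                    {"chrom": iv.chrom, "anchor": window.anchor,
                     "start": window.interval.start, "end": window.interval.end,
                     "kind": "OM"}
                )
                labels.append(1)
        elif o_here and policy == "holdout":
            window = _shifted_window(iv.midpoint, chrom_len, extractor.width, iv.chrom)
            heldout.append(window)
            heldout_igrs.append(igr)
        else:
            window = _shifted_window(iv.midpoint, chrom_len, extractor.width, iv.chrom)
            rows.append(extractor.extract(window, igr))
            metas.append(
                {"chrom": iv.chrom, "anchor": window.anchor,
                 "start": window.interval.start, "end": window.interval.end,
                 "kind": "O" if o_here else "background"}
            )
            labels.append(0)

    if not any(labels):
        raise ValueError("no positive windows: dataset is untrainable")
    ds = _assemble(rows, metas, labels)
    ds.heldout_igrs = heldout_igrs  # type: ignore[attr-defined]
    return ds, heldout


def heldout_features(
    extractor: FeatureExtractor,
    windows: Sequence[WindowSpec],
    igrs: Sequence[IGR] | None = None,
) -> pd.DataFrame:
    rows = []
    for i, w in enumerate(windows):
        igr = igrs[i] if igrs is not None else None
        rows.append(extractor.extract(w, igr))
    return pd.DataFrame(rows, columns=FEATURE_NAMES)


def build_intragenic_dataset(
    intragenic_summits: Sequence[tuple[str, int]],
    extractor: FeatureExtractor,
    site_intervals: Sequence[GenomicInterval],
    arm_mask: ArmMask,
    n_controls_per_pos: int = 5,
    min_dist: int = 1000,
    seed: int = 0,
) -> Dataset:
    """Intragenic evaluation dataset: planted positives vs random controls.

    Controls are sampled uniformly from unmasked arm positions whose distance
    to every OM/O site interval exceeds ``min_dist`` and whose window fits
    the chromosome. Only the core trio is meaningful here (the remaining
    features are still computed; select ``CORE_TRIO`` downstream).
    """
    if not intragenic_summits:
        raise ValueError("no intragenic positives")
    rng = np.random.default_rng(seed)
    rows, metas, labels = [], [], []
    for chrom, summit in intragenic_summits:
        window = _shifted_window(
            summit, extractor.chrom_length(chrom), extractor.width, chrom
        )
        rows.append(extractor.extract(window, None))
        metas.append({"chrom": chrom, "anchor": window.anchor,
                      "start": window.interval.start, "end": window.interval.end,
                      "kind": "intragenic_OM"})
        labels.append(1)

    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in site_intervals:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    chroms = sorted(extractor.genome)
    lengths = np.array([extractor.chrom_length(c) for c in chroms], dtype=float)
    probs = lengths / lengths.sum()
    half = extractor.width // 2

    n_controls = n_controls_per_pos * len(intragenic_summits)
    accepted = 0
    attempts = 0
    while accepted < n_controls:
        attempts += 1
        if attempts > 1000 * n_controls:
            raise RuntimeError("control sampling failed; constraints too tight")
        chrom = chroms[rng.choice(len(chroms), p=probs)]
        length = extractor.chrom_length(chrom)
        pos = int(rng.integers(half, length - half))
        if arm_mask.contains_point(chrom, pos):
            continue
        # distance from the point to each site interval must exceed min_dist
        too_close = any(
            max(iv.start - pos, pos - (iv.end - 1), 0) <= min_dist
            for iv in by_chrom.get(chrom, ())
        )
        if too_close:
            continue
        window = build_window(pos, length, extractor.width, chrom)
        rows.append(extractor.extract(window, None))
        metas.append({"chrom": chrom, "anchor": pos,
                      "start": window.interval.start, "end": window.interval.end,
                      "kind": "control"})
        labels.append(0)
        accepted += 1
    return _assemble(rows, metas, labels)
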