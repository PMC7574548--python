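"""Position-weight-matrix scanning for the poly(dA) motif.

The genome is scored on both strands with log-likelihood-ratio (bits) PWM
scores. Per-position p-values are exact: the null score distribution under
the 0-order background is computed by dynamic programming over the motif
columns with scores discretized to a fixed grid (1e-3 bits), and hits are
thresholded at 5% FDR by Benjamini-Hochberg over all scanned positions of
all sequences jointly. Overlapping hits (across motif discoverers and
strands) are united into strand-less motif-union sites, the unit in which
the N_mt feature counts motifs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import motifs as bio_motifs
from statsmodels.stats.multitest import multipletests

from .intervals import GenomicInterval

__all__ = [
    "PWM",
    "MotifHit",
    "MotifUnionSet",
    "read_meme_motifs",
    "write_meme_motifs",
    "default_polya_pwm",
    "scan_pwm",
    "union_motif_sites",
    "count_motifs_near",
]

BASES = "ACGT"
SCORE_GRID_BITS = 1e-3
DEFAULT_FDR = 0.05


@dataclass
class PWM:
    """Base-probability matrix (L x 4, columns A,C,G,T) with a background."""

    matrix: np.ndarray
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25)
    )
    name: str = "motif"

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4 or len(self.matrix) < 1:
            raise ValueError("PWM matrix must be L x 4 with L >= 1")
        if not np.allclose(self.matrix.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("PWM rows must sum to 1")
        if (self.background <= 0).any():
            raise ValueError("background must be strictly positive")

    def __len__(self) -> int:
        return len(self.matrix)

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.matrix.argmax(axis=1))

    def reverse_complement(self) -> "PWM":
        return PWM(self.matrix[::-1, ::-1], self.background[::-1], self.name)

    def log_odds(self, background: np.ndarray | None = None) -> np.ndarray:
        bg = self.background if background is None else np.asarray(background)
        floored = np.maximum(self.matrix, 1e-9)
        return np.log2(floored / bg)


@dataclass(frozen=True)
class MotifHit:
    interval: GenomicInterval
    score: float
    p_value: float
    q_value: float

    def __post_init__(self) -> None:
        if not (0.0 < self.p_value <= 1.0):
            raise ValueError("p_value must lie in (0, 1]")


@dataclass
class MotifUnionSet:
    """Sorted, disjoint, strand-less motif sites; per-site best hit score."""

    intervals: list[GenomicInterval]
    scores: list[float]
    _mid_cache: dict[str, tuple[np.ndarray, np.ndarray]] = field(
        default_factory=dict, repr=False
    )

    def __len__(self) -> int:
        return len(self.intervals)

    def midpoints(self, chrom: str) -> tuple[np.ndarray, np.ndarray]:
        """Sorted midpoints and matching scores for one chromosome (cached)."""
        if chrom not in self._mid_cache:
            mids, scores = [], []
            for iv, sc in zip(self.intervals, self.scores):
                if iv.chrom == chrom:
                    mids.append(iv.midpoint)
                    scores.append(sc)
            order = np.argsort(mids, kind="stable")
            self._mid_cache[chrom] = (
                np.asarray(mids, dtype=np.int64)[order],
                np.asarray(scores, dtype=float)[order],
            )
        return self._mid_cache[chrom]


def read_meme_motifs(path: str | Path) -> list[PWM]:
    """Read PWMs from a minimal MEME-format file."""
    with open(path) as fh:
        records = bio_motifs.parse(fh, "minimal")
    pwms = []
    for m in records:
        matrix = np.column_stack([m.pwm[b] for b in BASES])
        bg = np.array([m.background[b] for b in BASES], dtype=float)
        matrix = matrix / matrix.sum(axis=1, keepdims=True)
        pwms.append(PWM(matrix, bg, m.name or f"motif_{len(pwms) + 1}"))
    return pwms


def write_meme_motifs(pwms: Sequence[PWM], path: str | Path) -> None:
    """Write PWMs in minimal MEME format (round-trips with read_meme_motifs)."""
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        bg = pwms[0].background if pwms else np.full(4, 0.25)
        fh.write("Background letter frequencies\n")
        fh.write(
            " ".join(f"{b} {f:.6f}" for b, f in zip(BASES, bg)) + "\n\n"
        )
        for pwm in pwms:
            fh.write(f"MOTIF {pwm.name}\n")
            fh.write(
                # large nsites so count-based readers keep full precision
                f"letter-probability matrix: alength= 4 w= {len(pwm)} "
                f"nsites= 1000000 E= 0\n"
            )
            for row in pwm.matrix:
                fh.write(" " + " ".join(f"{v:.6f}" for v in row) + "\n")
            fh.write("\n")


def default_polya_pwm(at_background: float = 0.64) -> PWM:
    """A synthetic 15 bp A-rich PWM for simulated genomes.

    Strong-A columns interleaved with A/T-mixed columns, echoing the
    asymmetric A-stretch signature of Orc4-binding sequences. This matrix is
    NOT a catalogued fission-yeast motif; it exists so the scanning and
    classification machinery can be exercised on synthetic data.
    """
    strong_a = np.array([0.82, 0.06, 0.06, 0.06])
    mixed_at = np.array([0.50, 0.06, 0.06, 0.38])
    rows = [strong_a if i % 3 != 2 else mixed_at for i in range(15)]
    bg_at = at_background / 2.0
    bg = np.array([bg_at, 0.5 - bg_at, 0.5 - bg_at, bg_at])
    return PWM(np.vstack(rows), bg, "polyA_synthetic")


def _encode(seq: str) -> np.ndarray:
    lut = np.full(256, 4, dtype=np.int8)
    for i, b in enumerate(BASES):
        lut[ord(b)] = i
    return lut[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _estimate_background(sequences: Mapping[str, str]) -> np.ndarray:
    counts = np.zeros(4)
    for seq in sequences.values():
        codes = _encode(seq)
        counts += np.bincount(codes[codes < 4], minlength=4)
    if counts.sum() == 0:
        raise ValueError("no scannable bases")
    bg = counts / counts.sum()
    # strand-symmetrized so the null distribution is shared by both strands
    bg = (bg + bg[::-1]) / 2.0
    return np.maximum(bg, 1e-6)


def _null_survival(iscores: np.ndarray, background: np.ndarray) -> tuple[np.ndarray, int]:
    """Exact null P(score >= s) on the integer score grid.

    Returns (sf, offset) such that ``sf[isum - offset]`` is the p-value of an
    integer window score ``isum``.
    """
    L = iscores.shape[0]
    lo = int(iscores.min(axis=1).sum())
    hi = int(iscores.max(axis=1).sum())
    pmf = np.zeros(hi - lo + 1)
    pmf[0] = 1.0  # distribution of (sum - lo so far)
    size = 1
    for j in range(L):
        col = iscores[j]
        col_lo = int(col.min())
        new = np.zeros(hi - lo + 1)
        for base in range(4):
            shift = int(col[base]) - col_lo
            new[shift : shift + size] += background[base] * pmf[:size]
        pmf = new
        size += int(col.max()) - col_lo
    sf = np.cumsum(pmf[::-1])[::-1]
    sf = np.minimum(sf, 1.0)
    sf = np.maximum(sf, np.finfo(float).tiny)
    return sf, lo


def _window_int_scores(codes: np.ndarray, iscores: np.ndarray) -> np.ndarray:
    """Integer window scores at every start; int64 min where a window holds N."""
    L, n = iscores.shape[0], codes.size
    if n < L:
        return np.zeros(0, dtype=np.int64)
    nwin = n - L + 1
    total = np.zeros(nwin, dtype=np.int64)
    has_n = np.zeros(nwin, dtype=bool)
    for j in range(L):
        c = codes[j : j + nwin]
        valid = c < 4
        has_n |= ~valid
        total += iscores[j][np.where(valid, c, 0)]
    total[has_n] = np.iinfo(np.int64).min
    return total


def scan_pwm(
    sequences: Mapping[str, str],
    pwm: PWM,
    fdr: float = DEFAULT_FDR,
    both_strands: bool = True,
    background: np.ndarray | None = None,
    grid: float = SCORE_GRID_BITS,
) -> list[MotifHit]:
    """Scan sequences with a PWM; return hits with BH q-value <= ``fdr``.

    Scores are log2 likelihood ratios against the (strand-symmetrized)
    0-order background, discretized to the ``grid`` resolution so the DP
    p-value lookup is exact for the reported score. Windows containing N are
    skipped. BH correction is applied jointly over all scanned positions of
    all sequences and both strands.
    """
    bg = _estimate_background(sequences) if background is None else np.asarray(background)
    bg = np.maximum(bg, 1e-6)
    lod = pwm.log_odds(bg)
    iscores = np.round(lod / grid).astype(np.int64)
    sf, offset = _null_survival(iscores, bg)
    irc = iscores[::-1, ::-1]

    chroms: list[str] = []
    starts_all: list[np.ndarray] = []
    strands_all: list[np.ndarray] = []
    ints_all: list[np.ndarray] = []
    L = len(pwm)
    sentinel = np.iinfo(np.int64).min
    for chrom, seq in sequences.items():
        codes = _encode(seq)
        variants = [("+", iscores)]
        if both_strands:
            variants.append(("-", irc))
        for strand, mat in variants:
            ints = _window_int_scores(codes, mat)
            valid = ints != sentinel
            idx = np.flatnonzero(valid)
            if idx.size == 0:
                continue
            chroms.append(chrom)
            starts_all.append(idx)
            strands_all.append(np.full(idx.size, 0 if strand == "+" else 1, dtype=np.int8))
            ints_all.append(ints[idx])

    if not ints_all:
        return []
    ints_cat = np.concatenate(ints_all)
    pvals = sf[np.clip(ints_cat - offset, 0, sf.size - 1)]
    reject, qvals, _, _ = multipletests(pvals, alpha=fdr, method="fdr_bh")

    hits: list[MotifHit] = []
    pos = 0
    for chrom, idx, strands in zip(chroms, starts_all, strands_all):
        n = idx.size
        sel = np.flatnonzero(reject[pos : pos + n])
        for k in sel:
            start = int(idx[k])
            hits.append(
                MotifHit(
                    GenomicInterval(chrom, start, start + L,
                                    "+" if strands[k] == 0 else "-"),
                    score=float(ints_cat[pos + k] * grid),
                    p_value=float(pvals[pos + k]),
                    q_value=float(qvals[pos + k]),
                )
            )
        pos += n
    hits.sort(key=lambda h: (h.interval.chrom, h.interval.start, h.interval.strand))
    return hits


def union_motif_sites(*hit_lists: Iterable[MotifHit]) -> MotifUnionSet:
    """Merge hits from any number of scans into disjoint strand-less sites.

    Hits sharing >=1 bp are united into a single larger site; each union site
    keeps the best member score. Idempotent and order-invariant.
    """
    all_hits = sorted(
        (h for hits in hit_lists for h in hits),
        key=lambda h: (h.interval.chrom, h.interval.start, h.interval.end),
    )
    intervals: list[GenomicInterval] = []
    scores: list[float] = []
    cur = None  # (chrom, start, end, best_score)
    for h in all_hits:
        iv = h.interval
        if cur is not None and iv.chrom == cur[0] and iv.start < cur[2]:
            cur = (cur[0], cur[1], max(cur[2], iv.end), max(cur[3], h.score))
        else:
            if cur is not None:
                intervals.append(GenomicInterval(cur[0], cur[1], cur[2]))
                scores.append(cur[3])
            cur = (iv.chrom, iv.start, iv.end, h.score)
    if cur is not None:
        intervals.append(GenomicInterval(cur[0], cur[1], cur[2]))
        scores.append(cur[3])
    return MotifUnionSet(intervals, scores)


def count_motifs_near(
    union_set: MotifUnionSet, chrom: str, anchor: int, radius: int = 250
) -> int:
    """Union sites whose midpoint lies in the closed window [anchor-radius,
    anchor+radius]."""
    mids, _ = union_set.midpoints(chrom)
    lo = np.searchsorted(mids, anchor - radius, side="left")
    hi = np.searchsorted(mids, anchor + radius, side="right")
    return int(hi - lo)
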