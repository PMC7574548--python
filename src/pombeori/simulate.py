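"""Synthetic genome generator with planted origin architecture.

The simulator emits a fully specified multi-chromosome genome in which the
three DNA-encoded origin determinants are planted with known ground truth:

* OM-like IGRs — long intergenic regions carrying one or more A-rich motif
  instances at the Orc anchor, a few-hundred-bp AT-rich segment centered on
  the Mcm anchor (0-500 bp from the Orc anchor; near-zero offset for about
  half of the sites), and no transcription across the IGR;
* O-like IGRs — motif(s) at the Orc anchor but no AT segment and
  intermediate length;
* background IGRs — short on the whole, a minority carrying a decoy AT
  segment, plus genome-wide background motif instances at a density that
  leaves a random 1 kb window with a motif roughly a third of the time.

Genes tile the rest of each chromosome arm with log-normal transcribed
lengths and expression levels; telomere-like pads at the chromosome ends
form the excluded-region mask. ChIP fold-enrichment tracks place Gaussian
bumps on the planted anchors over multiplicative noise, and RNA-seq coverage
is per-base Poisson within transcribed spans. Everything is deterministic
given the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .annotation import GeneModel
from .intervals import ArmMask, GenomicInterval
from .motifs import PWM, default_polya_pwm
from .peaks import DEFAULT_BIN_WIDTH, FETrack

__all__ = [
    "SimulationConfig",
    "PlantedSite",
    "GroundTruth",
    "SimulatedGenome",
    "simulate_genome",
    "simulate_rnaseq",
    "simulate_fe_tracks",
    "write_simulation",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic genome. ``seed`` is mandatory."""

    seed: int
    n_chroms: int = 2
    telomere_pad: int = 5000
    background_at: float = 0.64
    # genes
    gene_length_log_mean: float = math.log(300.0)
    gene_length_log_sd: float = 0.35
    gene_min_length: int = 260
    utr5_length: int = 80
    utr3_length: int = 100
    rpkm_log_mean: float = math.log(8.0)
    rpkm_log_sd: float = 1.0
    # IGR classes
    n_om: int = 280
    n_o: int = 60
    n_background: int = 3000
    om_igr_log_mean: float = math.log(1466.0)
    om_igr_log_sd: float = 0.35
    om_igr_min: int = 700
    o_igr_log_mean: float = math.log(800.0)
    o_igr_log_sd: float = 0.4
    o_igr_min: int = 400
    bg_igr_log_mean: float = math.log(277.0)
    bg_igr_log_sd: float = 0.8
    bg_igr_min: int = 60
    # planted sequence features
    motif_counts: tuple[int, ...] = (1, 2, 3)
    motif_fidelity: float = 1.0
    bg_motif_rate_per_kb: float = 0.44
    decoy_at_prob: float = 0.10
    decoy_at_len: tuple[int, int] = (100, 300)
    at_segment_len: tuple[int, int] = (180, 400)
    at_segment_at: float = 0.88
    mcm_offset_near_prob: float = 0.5
    mcm_offset_near_max: int = 50
    mcm_offset_range: tuple[int, int] = (100, 500)
    # tracks
    bin_width: int = DEFAULT_BIN_WIDTH
    fe_noise_sigma: float = 0.15
    orc_peak_height_log_mean: float = math.log(12.0)
    orc_peak_height_log_sd: float = 0.2
    orc_peak_sd_bp: float = 200.0
    mcm_peak_height_log_mean: float = math.log(5.0)
    mcm_peak_height_log_sd: float = 0.2
    mcm_peak_sd_bp: float = 230.0
    rnaseq_depth_per_rpkm: float = 0.5

    pwm: PWM = field(default_factory=default_polya_pwm)

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for name in ("n_om", "n_o", "n_background", "n_chroms"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class PlantedSite:
    site_class: str  # OM | O
    chrom: str
    igr: GenomicInterval
    orc_anchor: int
    mcm_anchor: int | None
    motif_intervals: list[GenomicInterval]
    at_interval: GenomicInterval | None
    ntx_interval: GenomicInterval  # transcription-free span (the IGR itself)

    def to_dict(self) -> dict:
        return {
            "class": self.site_class,
            "chrom": self.chrom,
            "igr": [self.igr.start, self.igr.end],
            "orc_anchor": self.orc_anchor,
            "mcm_anchor": self.mcm_anchor,
            "motifs": [[m.start, m.end] for m in self.motif_intervals],
            "at_segment": (
                [self.at_interval.start, self.at_interval.end]
                if self.at_interval else None
            ),
            "ntx": [self.ntx_interval.start, self.ntx_interval.end],
        }


@dataclass
class GroundTruth:
    sites: list[PlantedSite]
    igr_classes: list[tuple[str, int, int, str]]  # chrom, start, end, class
    bg_motifs: list[GenomicInterval]
    chrom_lengths: dict[str, int]

    def sites_of(self, site_class: str) -> list[PlantedSite]:
        return [s for s in self.sites if s.site_class == site_class]

    def to_dict(self) -> dict:
        return {
            "sites": [s.to_dict() for s in self.sites],
            "igr_classes": [list(t) for t in self.igr_classes],
            "bg_motifs": [[m.chrom, m.start, m.end] for m in self.bg_motifs],
            "chrom_lengths": self.chrom_lengths,
        }


@dataclass
class SimulatedGenome:
    genome: dict[str, str]
    genes: list[GeneModel]
    mask: ArmMask
    truth: GroundTruth
    config: SimulationConfig


def _random_codes(rng: np.random.Generator, n: int, at: float) -> np.ndarray:
    p = np.array([at / 2, (1 - at) / 2, (1 - at) / 2, at / 2])
    return rng.choice(4, size=n, p=p).astype(np.int8)


def _lognormal_len(rng, log_mean, log_sd, minimum) -> int:
    return max(int(round(rng.lognormal(log_mean, log_sd))), minimum)


def _motif_codes(rng: np.random.Generator, pwm: PWM, fidelity: float) -> np.ndarray:
    """Consensus bases, each independently resampled from its PWM column with
    probability 1 - fidelity."""
    cons = pwm.matrix.argmax(axis=1)
    if fidelity >= 1.0:
        return cons.astype(np.int8)
    out = cons.copy()
    for j in range(len(pwm)):
        if rng.random() > fidelity:
            out[j] = rng.choice(4, p=pwm.matrix[j])
    return out.astype(np.int8)


def _plant_motifs(
    rng: np.random.Generator,
    codes: np.ndarray,
    chrom: str,
    igr: GenomicInterval,
    orc_anchor: int,
    n_motifs: int,
    pwm: PWM,
    fidelity: float,
) -> list[GenomicInterval]:
    L = len(pwm)
    placed: list[GenomicInterval] = []

    def place(center: int) -> GenomicInterval | None:
        start = center - L // 2
        if start < igr.start + 5 or start + L > igr.end - 5:
            return None
        if any(abs(start - p.start) < L + 1 for p in placed):
            return None
        codes[start : start + L] = _motif_codes(rng, pwm, fidelity)
        iv = GenomicInterval(chrom, start, start + L)
        placed.append(iv)
        return iv

    place(orc_anchor)
    attempts = 0
    while len(placed) < n_motifs and attempts < 50:
        attempts += 1
        place(orc_anchor + int(rng.integers(20, 201)) * (1 if rng.random() < 0.5 else -1))
    return placed


def _plant_at_segment(
    rng: np.random.Generator,
    codes: np.ndarray,
    chrom: str,
    center: int,
    length: int,
    at: float,
    bounds: GenomicInterval,
) -> GenomicInterval:
    start = max(bounds.start + 5, center - length // 2)
    end = min(bounds.end - 5, start + length)
    start = min(start, end - 1)
    codes[start:end] = _random_codes(rng, end - start, at)
    return GenomicInterval(chrom, start, end)


def simulate_genome(config: SimulationConfig) -> SimulatedGenome:
    """Generate the genome, gene models, mask and machine-readable truth."""
    ss = np.random.SeedSequence(config.seed)
    rng_layout, rng_seq, rng_plant, rng_expr = [
        np.random.default_rng(s) for s in ss.spawn(4)
    ]

    # assign IGR classes round-robin across chromosomes, shuffled within each
    classes = (["OM"] * config.n_om + ["O"] * config.n_o
               + ["background"] * config.n_background)
    rng_layout.shuffle(classes)
    per_chrom: list[list[str]] = [
        list(classes[i :: config.n_chroms]) for i in range(config.n_chroms)
    ]

    genome: dict[str, str] = {}
    genes: list[GeneModel] = []
    mask_ivs: list[GenomicInterval] = []
    sites: list[PlantedSite] = []
    igr_classes: list[tuple[str, int, int, str]] = []
    bg_motifs: list[GenomicInterval] = []
    chrom_lengths: dict[str, int] = {}

    igr_len_params = {
        "OM": (config.om_igr_log_mean, config.om_igr_log_sd, config.om_igr_min),
        "O": (config.o_igr_log_mean, config.o_igr_log_sd, config.o_igr_min),
        "background": (config.bg_igr_log_mean, config.bg_igr_log_sd,
                       config.bg_igr_min),
    }

    for ci in range(config.n_chroms):
        chrom = f"chr{ci + 1}"
        chrom_classes = per_chrom[ci]
        # layout: pad, gene, (igr, gene)*, pad
        gene_lens = [
            _lognormal_len(rng_layout, config.gene_length_log_mean,
                           config.gene_length_log_sd, config.gene_min_length)
            for _ in range(len(chrom_classes) + 1)
        ]
        igr_lens = [
            _lognormal_len(rng_layout, *igr_len_params[c][:2], igr_len_params[c][2])
            for c in chrom_classes
        ]
        length = 2 * config.telomere_pad + sum(gene_lens) + sum(igr_lens)
        codes = _random_codes(rng_seq, length, config.background_at)

        cursor = config.telomere_pad
        gene_spans: list[tuple[int, int]] = []
        igr_spans: list[tuple[int, int, str]] = []
        for i, glen in enumerate(gene_lens):
            gene_spans.append((cursor, cursor + glen))
            cursor += glen
            if i < len(chrom_classes):
                igr_spans.append((cursor, cursor + igr_lens[i], chrom_classes[i]))
                cursor += igr_lens[i]
        cursor += config.telomere_pad
        assert cursor == length

        for gi, (gs, ge) in enumerate(gene_spans):
            strand = "+" if rng_layout.random() < 0.5 else "-"
            if strand == "+":
                orf = GenomicInterval(chrom, gs + config.utr5_length,
                                      ge - config.utr3_length, "+")
                tss, tts = gs, ge
            else:
                orf = GenomicInterval(chrom, gs + config.utr3_length,
                                      ge - config.utr5_length, "-")
                tss, tts = ge, gs
            rpkm = float(rng_expr.lognormal(config.rpkm_log_mean, config.rpkm_log_sd))
            genes.append(
                GeneModel(f"{chrom}G{gi + 1:05d}", orf, tss, tts, rpkm=rpkm)
            )

        for start, end, cls in igr_spans:
            igr = GenomicInterval(chrom, start, end)
            igr_classes.append((chrom, start, end, cls))
            if cls == "background":
                if rng_plant.random() < config.decoy_at_prob:
                    dlen = int(rng_plant.integers(*config.decoy_at_len))
                    _plant_at_segment(
                        rng_plant, codes, chrom, igr.midpoint, dlen,
                        config.at_segment_at, igr,
                    )
                continue
            n_motifs = int(rng_plant.choice(config.motif_counts))
            if cls == "OM":
                at_len = int(rng_plant.integers(*config.at_segment_len))
                if rng_plant.random() < config.mcm_offset_near_prob:
                    offset = int(rng_plant.integers(0, config.mcm_offset_near_max + 1))
                else:
                    offset = int(rng_plant.integers(*config.mcm_offset_range))
                max_offset = max(igr.width - at_len - 80, 0)
                offset = min(offset, max_offset)
                sign = 1 if rng_plant.random() < 0.5 else -1
                center = igr.midpoint
                orc_anchor = center - sign * (offset // 2)
                mcm_anchor = orc_anchor + sign * offset
                # AT segment first: motifs must survive when anchors coincide
                at_iv = _plant_at_segment(
                    rng_plant, codes, chrom, mcm_anchor, at_len,
                    config.at_segment_at, igr,
                )
                motifs = _plant_motifs(
                    rng_plant, codes, chrom, igr, orc_anchor, n_motifs,
                    config.pwm, config.motif_fidelity,
                )
                sites.append(
                    PlantedSite("OM", chrom, igr, orc_anchor, mcm_anchor,
                                motifs, at_iv, igr)
                )
            else:  # O
                orc_anchor = igr.midpoint
                motifs = _plant_motifs(
                    rng_plant, codes, chrom, igr, orc_anchor, n_motifs,
                    config.pwm, config.motif_fidelity,
                )
                sites.append(
                    PlantedSite("O", chrom, igr, orc_anchor, None, motifs,
                                None, igr)
                )

        # genome-wide background motif instances, kept away from planted anchors
        n_bg = rng_plant.poisson(config.bg_motif_rate_per_kb * length / 1000.0)
        anchors = np.array(
            [s.orc_anchor for s in sites if s.chrom == chrom], dtype=np.int64
        )
        anchors.sort()
        L = len(config.pwm)
        placed_bg: list[int] = []
        for _ in range(int(n_bg)):
            pos = int(rng_plant.integers(config.telomere_pad,
                                         length - config.telomere_pad - L))
            j = np.searchsorted(anchors, pos)
            near = [anchors[k] for k in (j - 1, j) if 0 <= k < anchors.size]
            if any(abs(pos - a) < 300 for a in near):
                continue
            if any(abs(pos - p) < L + 1 for p in placed_bg):
                continue
            codes[pos : pos + L] = _motif_codes(
                rng_plant, config.pwm, config.motif_fidelity
            )
            placed_bg.append(pos)
            bg_motifs.append(GenomicInterval(chrom, pos, pos + L))

        genome[chrom] = _BASES[codes].tobytes().decode("ascii")
        chrom_lengths[chrom] = length
        mask_ivs.append(GenomicInterval(chrom, 0, config.telomere_pad))
        mask_ivs.append(GenomicInterval(chrom, length - config.telomere_pad, length))

    truth = GroundTruth(sites, igr_classes, bg_motifs, chrom_lengths)
    return SimulatedGenome(genome, genes, ArmMask(mask_ivs), truth, config)


def simulate_rnaseq(
    genes: Sequence[GeneModel],
    chrom_lengths: Mapping[str, int],
    config: SimulationConfig,
    seed: int | None = None,
) -> dict[str, np.ndarray]:
    """Per-base coverage: Poisson around the gene's expression level within its
    transcribed span, zero elsewhere (IGRs carry no transcription)."""
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    coverage = {
        chrom: np.zeros(length, dtype=np.int32)
        for chrom, length in chrom_lengths.items()
    }
    for g in sorted(genes, key=lambda g: (g.orf.chrom, g.span.start)):
        span = g.span
        lam = g.rpkm * config.rnaseq_depth_per_rpkm
        if lam <= 0:
            continue
        coverage[span.chrom][span.start : span.end] += rng.poisson(lam, span.width)
    return coverage


def _add_bump(arr: np.ndarray, bin_width: int, center: int, height: float,
              sd_bp: float) -> None:
    lo = max(int((center - 4 * sd_bp) // bin_width), 0)
    hi = min(int((center + 4 * sd_bp) // bin_width) + 1, arr.size)
    centers = np.arange(lo, hi) * bin_width + bin_width / 2.0
    arr[lo:hi] += height * np.exp(-((centers - center) ** 2) / (2 * sd_bp**2))


def simulate_fe_tracks(
    truth: GroundTruth,
    config: SimulationConfig,
    seed: int | None = None,
) -> tuple[FETrack, FETrack]:
    """Gaussian FE bumps at the planted anchors over multiplicative noise.

    Orc bumps sit at every planted Orc anchor (OM and O); Mcm bumps only at
    OM Mcm anchors. Elsewhere both tracks fluctuate multiplicatively around
    FE = 1.
    """
    ss = np.random.SeedSequence(config.seed + 2 if seed is None else seed)
    rng_noise, rng_height = [np.random.default_rng(s) for s in ss.spawn(2)]
    bw = config.bin_width
    orc_data: dict[str, np.ndarray] = {}
    mcm_data: dict[str, np.ndarray] = {}
    for chrom, length in truth.chrom_lengths.items():
        n_bins = -(-length // bw)
        orc = rng_noise.lognormal(0.0, config.fe_noise_sigma, n_bins)
        mcm = rng_noise.lognormal(0.0, config.fe_noise_sigma, n_bins)
        for site in truth.sites:
            if site.chrom != chrom:
                continue
            h_orc = rng_height.lognormal(
                config.orc_peak_height_log_mean, config.orc_peak_height_log_sd
            )
            _add_bump(orc, bw, site.orc_anchor, h_orc, config.orc_peak_sd_bp)
            if site.site_class == "OM" and site.mcm_anchor is not None:
                h_mcm = rng_height.lognormal(
                    config.mcm_peak_height_log_mean, config.mcm_peak_height_log_sd
                )
                _add_bump(mcm, bw, site.mcm_anchor, h_mcm, config.mcm_peak_sd_bp)
        orc_data[chrom] = orc
        mcm_data[chrom] = mcm
    return FETrack(orc_data, bw), FETrack(mcm_data, bw)


def write_simulation(sim: SimulatedGenome, outdir: str | Path) -> dict[str, Path]:
    """Write FASTA, GFF3, mask BED, expression TSV and truth JSON."""
    from . import io as pio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": outdir / "genome.fa",
        "gff": outdir / "genes.gff3",
        "mask": outdir / "mask.bed",
        "expression": outdir / "expression.tsv",
        "truth": outdir / "truth.json",
    }
    with open(paths["fasta"], "w") as fh:
        for chrom in sorted(sim.genome):
            fh.write(f">{chrom}\n")
            seq = sim.genome[chrom]
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")
    write_gff(sim.genes, paths["gff"])
    pio.write_bed_mask(sim.mask, paths["mask"])
    with open(paths["expression"], "w") as fh:
        fh.write("gene_id\trpkm\n")
        for g in sorted(sim.genes, key=lambda g: g.gene_id):
            fh.write(f"{g.gene_id}\t{g.rpkm:.6g}\n")
    pio.write_json(sim.truth.to_dict(), paths["truth"])
    return paths


def write_gff(genes: Sequence[GeneModel], path: str | Path) -> None:
    """GFF3 (1-based inclusive) with gene/CDS/UTR features per gene model."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(genes, key=lambda g: (g.orf.chrom, g.span.start)):
            chrom, strand = g.orf.chrom, g.orf.strand
            span = g.span

            def row(ftype: str, start0: int, end0: int, attrs: str) -> str:
                return (f"{chrom}\tsim\t{ftype}\t{start0 + 1}\t{end0}\t.\t"
                        f"{strand}\t.\t{attrs}\n")

            fh.write(row("gene", g.orf.start, g.orf.end, f"ID={g.gene_id}"))
            fh.write(row("CDS", g.orf.start, g.orf.end,
                         f"ID={g.gene_id}.cds;Parent={g.gene_id}"))
            if strand == "+":
                utr5 = (span.start, g.orf.start)
                utr3 = (g.orf.end, span.end)
            else:
                utr5 = (g.orf.end, span.end)
                utr3 = (span.start, g.orf.start)
            if utr5[1] > utr5[0]:
                fh.write(row("five_prime_UTR", utr5[0], utr5[1],
                             f"ID={g.gene_id}.utr5;Parent={g.gene_id}"))
            if utr3[1] > utr3[0]:
                fh.write(row("three_prime_UTR", utr3[0], utr3[1],
                             f"ID={g.gene_id}.utr3;Parent={g.gene_id}"))
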