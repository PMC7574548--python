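"""Shared locations and the pipeline config used by the numbered drivers.

Every driver works inside ``results/`` at the repository root; run them in
order (01 writes the synthetic dataset the rest consume).
"""

from pathlib import Path

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"
SIM = RESULTS / "sim"

MASTER_SEED = 20200722


def sim_paths() -> dict:
    return {
        "genome": str(SIM / "genome.fa"),
        "gff": str(SIM / "genes.gff3"),
        "mask": str(SIM / "mask.bed"),
        "expression": str(SIM / "expression.tsv"),
        "coverage": str(SIM / "rnaseq_coverage.bedgraph"),
        "orc_fe": str(SIM / "orc_fe.bedgraph"),
        "mcm_fe": str(SIM / "mcm_fe.bedgraph"),
        "truth": str(SIM / "truth.json"),
        "orc_peaks": str(RESULTS / "peaks" / "orc_peaks.bed"),
        "mcm_peaks": str(RESULTS / "peaks" / "mcm_peaks.bed"),
        "sites": str(RESULTS / "sites" / "sites.tsv"),
        "motif_union": str(RESULTS / "motifs" / "motif_union.bed"),
        "features": str(RESULTS / "features" / "features.tsv"),
    }


def pipeline_config():
    from pombeori.pipeline import PipelineConfig

    return PipelineConfig(paths=sim_paths(), seed=MASTER_SEED)
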