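"""Scan the poly(dA) motif and quantify its positioning around sites.

Scans both strands genome-wide at 5% FDR, merges overlapping hits into
motif-union sites, counts motifs within ±250 bp of OM and O Orc summits, and
contrasts the observed fraction with the Monte Carlo random-site null.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))
from common import RESULTS, MASTER_SEED, pipeline_config  # noqa: E402

from pombeori.annotation import read_genome  # noqa: E402
from pombeori.motifs import count_motifs_near  # noqa: E402
from pombeori.pipeline import read_union_bed, run_stage, _site_set_from_tsv  # noqa: E402
from pombeori.reports import motif_position_matrix  # noqa: E402
from pombeori.resampling import random_site_motif_expectation  # noqa: E402
from pombeori import io as pio  # noqa: E402


def main() -> None:
    cfg = pipeline_config()
    run_stage("scan-motifs", cfg, RESULTS / "motifs")
    union = read_union_bed(RESULTS / "motifs" / "motif_union.bed")
    print(f"{len(union)} motif-union sites genome-wide")

    site_set = _site_set_from_tsv(RESULTS / "sites" / "sites.tsv")
    summits = {
        "OM": [(o.interval.chrom, o.summit) for o, _ in site_set.om_sites],
        "O": [(p.interval.chrom, p.summit) for p in site_set.o_sites],
    }
    rows = []
    for cls, sites in summits.items():
        counts = [count_motifs_near(union, c, s, 250) for c, s in sites]
        frac = np.mean([c >= 1 for c in counts])
        print(f"{cls}: {100 * frac:.1f}% of {len(sites)} sites have >=1 motif "
              f"within 250 bp (mean count {np.mean(counts):.2f})")
        rows += [{"class": cls, "chrom": c, "summit": s, "n_motifs_250": n}
                 for (c, s), n in zip(sites, counts)]
    pd.DataFrame(rows).to_csv(RESULTS / "motifs" / "motifs_near_sites.tsv",
                              sep="\t", index=False)

    genome = read_genome(cfg.path("genome"))
    mask = pio.read_bed_mask(cfg.path("mask"))
    arms = mask.arms({c: len(s) for c, s in genome.items()})
    ci = random_site_motif_expectation(
        arms, union, n_sites=len(summits["OM"]), reps=400, seed=MASTER_SEED
    )
    print(f"random-site null: {100 * ci.lower:.0f}-{100 * ci.upper:.0f}% "
          f"(95% CI) of sites would carry a motif by chance")

    pos = motif_position_matrix(summits["OM"], union, half_width=1000)
    nearest = [o[np.argmin(np.abs(o))] for o in pos.offsets if len(o)]
    print(f"nearest motif within 100 bp of the Orc summit for "
          f"{100 * np.mean(np.abs(nearest) <= 100):.0f}% of OM sites")


if __name__ == "__main__":
    main()
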