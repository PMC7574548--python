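"""AT-content and melting-energy signatures around OM and O sites.

Computes averaged 100 bp-window AT profiles around site summits, the flank
AT asymmetry joined with the Orc-Mcm offset class (does the AT-rich side
face Mcm?), and the ΔG_melt minimum in site windows versus random windows.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))
from common import RESULTS, MASTER_SEED, pipeline_config  # noqa: E402

from pombeori.annotation import read_genome  # noqa: E402
from pombeori.pipeline import _site_set_from_tsv  # noqa: E402
from pombeori.reports import flank_asymmetry_table  # noqa: E402
from pombeori.sequence import at_profile, delta_g_melt_profile  # noqa: E402


def _mean_profile(genome, sites, half=1000):
    rows = []
    for chrom, summit in sites:
        seq = genome[chrom]
        if summit - half < 0 or summit + half > len(seq):
            continue
        rows.append(at_profile(seq[summit - half : summit + half], 100))
    return np.mean(rows, axis=0)


def main() -> None:
    cfg = pipeline_config()
    genome = read_genome(cfg.path("genome"))
    site_set = _site_set_from_tsv(RESULTS / "sites" / "sites.tsv")
    om = [(o.interval.chrom, o.summit) for o, _ in site_set.om_sites]
    o_only = [(p.interval.chrom, p.summit) for p in site_set.o_sites]

    outdir = RESULTS / "sequence"
    outdir.mkdir(parents=True, exist_ok=True)
    prof_om = _mean_profile(genome, om)
    prof_o = _mean_profile(genome, o_only)
    genome_at = np.mean([at_profile(s, 100).mean() for s in genome.values()])
    pd.DataFrame({
        "offset": np.arange(-1000, 1000),
        "at_om": prof_om, "at_o": prof_o,
    }).to_csv(outdir / "at_profiles.tsv", sep="\t", index=False)
    print(f"AT content at the summit: OM {100 * prof_om[1000]:.1f}%, "
          f"O {100 * prof_o[1000]:.1f}%, genome average {100 * genome_at:.1f}%")

    table = flank_asymmetry_table(site_set, genome)
    table.to_csv(outdir / "flank_asymmetry.tsv", sep="\t", index=False)
    shifted = table[table["offset_class"] != "overlap"]
    toward_mcm = np.where(
        shifted["offset_class"] == "right",
        shifted["right_at"] > shifted["left_at"],
        shifted["left_at"] > shifted["right_at"],
    )
    print(f"split OM sites with the AT-richer flank on the Mcm side: "
          f"{100 * toward_mcm.mean():.0f}% of {len(shifted)}")

    rng = np.random.default_rng(MASTER_SEED)
    dg_site, dg_rand = [], []
    for chrom, summit in om[:150]:
        seq = genome[chrom]
        lo, hi = summit - 700, summit + 700
        if lo < 0 or hi > len(seq):
            continue
        prof = delta_g_melt_profile(seq[lo:hi], 200)
        dg_site.append(np.nanmin(prof[500:900]))
        r = int(rng.integers(700, len(seq) - 700))
        prof_r = delta_g_melt_profile(seq[r - 700 : r + 700], 200)
        dg_rand.append(np.nanmin(prof_r[500:900]))
    print(f"median minimum ΔG_melt (200 bp) in OM windows: "
          f"{np.median(dg_site):.0f} kcal/mol vs {np.median(dg_rand):.0f} "
          f"kcal/mol at random positions (lower = easier to melt)")


if __name__ == "__main__":
    main()
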