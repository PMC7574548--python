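"""IGR placement, lengths and gene-orientation preference of OM sites.

Derives IGRs from the UTR-extended gene models, asks where OM/O sites sit
(intergenic vs intragenic, versus the random-site null), compares IGR length
distributions, and runs the orientation Monte Carlo: the divergent-IGR
preference of OM sites against both a plain random IGR draw and the
length-controlled draw that matches the OM IGR length distribution.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))
from common import RESULTS, MASTER_SEED, pipeline_config  # noqa: E402

from pombeori.annotation import attach_expression, derive_igrs, read_genes, \
    read_genome  # noqa: E402
from pombeori.pipeline import run_stage, _site_set_from_tsv  # noqa: E402
from pombeori.resampling import (  # noqa: E402
    length_matched_igr_sample,
    mann_whitney_two_sided,
    random_igr_orientation,
    random_site_igr_expectation,
)
from pombeori import io as pio  # noqa: E402


def main() -> None:
    cfg = pipeline_config()
    run_stage("features", cfg, RESULTS / "features")
    run_stage("report", cfg, RESULTS / "report")
    placement = pd.read_csv(RESULTS / "report" / "placement.tsv", sep="\t")
    print("site placement:")
    print(placement.to_string(index=False))

    genome = read_genome(cfg.path("genome"))
    lengths = {c: len(s) for c, s in genome.items()}
    mask = pio.read_bed_mask(cfg.path("mask"))
    genes = read_genes(cfg.path("gff"), chrom_lengths=lengths)
    expr = pd.read_csv(cfg.path("expression"), sep="\t")
    attach_expression(genes, dict(zip(expr["gene_id"], expr["rpkm"])))
    igrs = derive_igrs(genes, mask, lengths)
    site_set = _site_set_from_tsv(RESULTS / "sites" / "sites.tsv")

    ci = random_site_igr_expectation(
        mask.arms(lengths), igrs, n_sites=len(site_set.om_sites),
        reps=400, seed=MASTER_SEED,
    )
    print(f"random-site null for intergenic placement: "
          f"{100 * ci.lower:.0f}-{100 * ci.upper:.0f}% (95% CI)")

    def igr_class(igr):
        for o, _ in site_set.om_sites:
            if o.interval.chrom == igr.interval.chrom and \
                    igr.interval.contains(o.summit):
                return "OM"
        for p in site_set.o_sites:
            if p.interval.chrom == igr.interval.chrom and \
                    igr.interval.contains(p.summit):
                return "O"
        return "background"

    classes = [igr_class(g) for g in igrs]
    by = {c: [g.interval.width for g, cl in zip(igrs, classes) if cl == c]
          for c in ("OM", "O", "background")}
    p = mann_whitney_two_sided(by["OM"], by["background"])
    print(f"median IGR length: OM {np.median(by['OM']):.0f} bp, O "
          f"{np.median(by['O']):.0f} bp, background "
          f"{np.median(by['background']):.0f} bp "
          f"(OM vs background Mann-Whitney p = {p:.2g})")

    om_igrs = [g for g, cl in zip(igrs, classes)
               if cl == "OM" and g.orientation != "edge"]
    obs = pd.Series([g.orientation for g in om_igrs]).value_counts(normalize=True)
    print("OM-IGR orientation proportions:")
    print(obs.to_string())
    rand = random_igr_orientation(igrs, len(om_igrs), reps=400,
                                  seed=MASTER_SEED + 1)
    matched = length_matched_igr_sample(
        igrs, [g.interval.width for g in om_igrs], reps=200,
        seed=MASTER_SEED + 2,
    )
    rows = []
    for cls in ("convergent", "tandem", "divergent"):
        rows.append({
            "class": cls,
            "observed_om": obs.get(cls, 0.0),
            "random_low": rand[cls].lower, "random_high": rand[cls].upper,
            "length_controlled_low": matched.class_cis[cls].lower,
            "length_controlled_high": matched.class_cis[cls].upper,
        })
        print(f"  {cls}: observed {obs.get(cls, 0.0):.2f}, random CI "
              f"[{rand[cls].lower:.2f}, {rand[cls].upper:.2f}], "
              f"length-controlled CI [{matched.class_cis[cls].lower:.2f}, "
              f"{matched.class_cis[cls].upper:.2f}]")
    pd.DataFrame(rows).to_csv(RESULTS / "report" / "orientation_mc.tsv",
                              sep="\t", index=False)


if __name__ == "__main__":
    main()
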