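"""Call Orc/Mcm peaks and classify OM / O / M-only sites.

Applies the stated peak post-processing (FE threshold runs, <50 bp discard,
mask exclusion) at thresholds 6 (Orc) and 2 (Mcm), pairs overlapping peaks
into OM sites, and summarizes the Venn counts, peak widths and Orc-Mcm
summit offset classes.
"""

import json
import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))
from common import RESULTS, pipeline_config  # noqa: E402

from pombeori.pipeline import run_stage, _site_set_from_tsv  # noqa: E402
from pombeori.peaks import summit_offsets  # noqa: E402
from pombeori.reports import offset_class  # noqa: E402
from pombeori import io as pio  # noqa: E402


def main() -> None:
    cfg = pipeline_config()
    run_stage("call-peaks", cfg, RESULTS / "peaks")
    run_stage("classify-sites", cfg, RESULTS / "sites")

    venn = json.loads((RESULTS / "sites" / "venn.json").read_text())
    print(f"sites on arms: {venn['n_om']} OM, {venn['n_o']} O, "
          f"{venn['n_m_only']} Mcm-only")

    orc_peaks = pio.read_peaks_bed(RESULTS / "peaks" / "orc_peaks.bed")
    mcm_peaks = pio.read_peaks_bed(RESULTS / "peaks" / "mcm_peaks.bed")
    print(f"median peak width: Orc "
          f"{np.median([p.interval.width for p in orc_peaks]):.0f} bp, Mcm "
          f"{np.median([p.interval.width for p in mcm_peaks]):.0f} bp")

    site_set = _site_set_from_tsv(RESULTS / "sites" / "sites.tsv")
    offsets = summit_offsets(site_set)
    classes = pd.Series([offset_class(o) for o in offsets]).value_counts()
    print("OM summit-offset classes (100 bp dead zone):")
    print(classes.to_string())
    print(f"median |Mcm - Orc| summit offset: "
          f"{np.median(np.abs(offsets)):.0f} bp")
    out = RESULTS / "sites" / "summit_offsets.tsv"
    pd.DataFrame({"offset": offsets}).to_csv(out, sep="\t", index=False)
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
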