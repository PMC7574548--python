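"""End-to-end synthetic origin study, from generator to classifier report.

Thin orchestration over the library modules so that drivers (analysis
scripts, the pipeline CLI and the acceptance machinery) share one code path:
simulate the genome, scan the poly(dA) motif, derive IGRs, anchor windows on
site summits, assemble the feature table, and cross-validate the SVM on
named feature subsets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation import IGR, derive_igrs
from .classify import CVReport, SVMConfig, repeated_cv, score_heldout
from .features import (
    CORE_TRIO,
    Dataset,
    FeatureExtractor,
    WindowSpec,
    build_igr_dataset,
    heldout_features,
)
from .intervals import GenomicInterval
from .motifs import MotifUnionSet, scan_pwm, union_motif_sites
from .peaks import Peak, SiteSet, apply_mask, call_peaks, classify_sites
from .simulate import (
    SimulatedGenome,
    SimulationConfig,
    simulate_fe_tracks,
    simulate_genome,
    simulate_rnaseq,
)

__all__ = [
    "SyntheticStudy",
    "truth_site_set",
    "called_site_set",
    "prepare_study",
    "evaluate_feature_sets",
    "DEFAULT_FEATURE_SETS",
]

DEFAULT_FEATURE_SETS: dict[str, list[str]] = {
    "trio": CORE_TRIO,
    "L_AT": ["L_AT"],
    "N_mt": ["N_mt"],
}


def truth_site_set(sim: SimulatedGenome, half_width: int = 250) -> SiteSet:
    """Reference SiteSet built from the planted anchors (no peak calling).

    Peak intervals are nominal ±half_width spans; summits are the planted
    anchors exactly.
    """
    site_set = SiteSet()
    for s in sim.truth.sites:
        orc = Peak(
            GenomicInterval(s.chrom, s.orc_anchor - half_width,
                            s.orc_anchor + half_width),
            s.orc_anchor, 0.0,
        )
        if s.site_class == "OM":
            mcm = Peak(
                GenomicInterval(s.chrom, s.mcm_anchor - half_width,
                                s.mcm_anchor + half_width),
                s.mcm_anchor, 0.0,
            )
            site_set.om_sites.append((orc, mcm))
        else:
            site_set.o_sites.append(orc)
    return site_set


def called_site_set(
    sim: SimulatedGenome,
    fe_orc: float = 6.0,
    fe_mcm: float = 2.0,
    min_width: int = 50,
    seed: int | None = None,
):
    """Simulate FE tracks, call peaks, mask them and classify OM/O/M-only."""
    orc_track, mcm_track = simulate_fe_tracks(sim.truth, sim.config, seed=seed)
    orc_peaks = apply_mask(call_peaks(orc_track, fe_orc, min_width), sim.mask)
    mcm_peaks = apply_mask(call_peaks(mcm_track, fe_mcm, min_width), sim.mask)
    return classify_sites(orc_peaks, mcm_peaks), orc_track, mcm_track


@dataclass
class SyntheticStudy:
    sim: SimulatedGenome
    coverage: dict[str, np.ndarray]
    motif_union: MotifUnionSet
    igrs: list[IGR]
    site_set: SiteSet
    extractor: FeatureExtractor
    dataset: Dataset
    heldout_windows: list[WindowSpec] = field(default_factory=list)
    heldout_X: pd.DataFrame | None = None


def prepare_study(
    config: SimulationConfig,
    site_source: str = "truth",
    fdr: float = 0.05,
    policy: str = "holdout",
) -> SyntheticStudy:
    """Run the pipeline up to the assembled classification dataset.

    ``site_source='truth'`` anchors windows on the planted summits (the
    generator's analogue of the observed ChIP summits); ``'called'`` runs the
    full FE-track / peak-calling / classification path first.
    """
    sim = simulate_genome(config)
    coverage = simulate_rnaseq(sim.genes, sim.truth.chrom_lengths, config)
    hits = scan_pwm(sim.genome, config.pwm, fdr=fdr)
    union = union_motif_sites(hits)
    igrs = derive_igrs(sim.genes, sim.mask, sim.truth.chrom_lengths)
    if site_source == "truth":
        site_set = truth_site_set(sim)
    elif site_source == "called":
        site_set, _, _ = called_site_set(sim)
    else:
        raise ValueError(f"unknown site_source {site_source!r}")
    extractor = FeatureExtractor(sim.genome, union, coverage)
    dataset, heldout = build_igr_dataset(igrs, site_set, extractor, policy=policy)
    heldout_X = None
    if heldout:
        heldout_X = heldout_features(
            extractor, heldout, getattr(dataset, "heldout_igrs", None)
        )
    return SyntheticStudy(
        sim, coverage, union, igrs, site_set, extractor, dataset, heldout, heldout_X
    )


def evaluate_feature_sets(
    dataset: Dataset,
    feature_sets: Mapping[str, Sequence[str]] | None = None,
    svm_config: SVMConfig | None = None,
    k: int = 4,
    rounds: int = 10,
    seed: int = 0,
    heldout_X: pd.DataFrame | None = None,
    platt_for: Sequence[str] = ("trio",),
) -> tuple[dict[str, CVReport], dict[str, np.ndarray]]:
    """Repeated stratified CV per named feature subset.

    Platt sigmoids (needed for held-out probability scoring) are fitted only
    for the subsets in ``platt_for``. Returns the per-subset CV reports and,
    for those subsets, mean held-out probabilities when ``heldout_X`` is given.
    """
    feature_sets = DEFAULT_FEATURE_SETS if feature_sets is None else feature_sets
    svm_config = svm_config or SVMConfig()
    reports: dict[str, CVReport] = {}
    heldout_probs: dict[str, np.ndarray] = {}
    ss = np.random.SeedSequence(seed)
    subset_seeds = {
        name: int(s) for name, s in
        zip(feature_sets, ss.generate_state(len(feature_sets)) % (2**31 - 1))
    }
    for name, subset in feature_sets.items():
        fit_platt = name in platt_for
        report = repeated_cv(
            dataset, svm_config, feature_subset=subset, k=k, rounds=rounds,
            seed=subset_seeds[name], fit_platt=fit_platt,
        )
        reports[name] = report
        if fit_platt and heldout_X is not None and len(heldout_X):
            heldout_probs[name] = score_heldout(report.models, heldout_X[list(subset)])
    return reports, heldout_probs
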