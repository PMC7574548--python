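"""Stage orchestration: one config object, explicit seeds, manifests.

Each stage reads its parameters from a :class:`PipelineConfig`, writes its
outputs plus a machine-readable run manifest (inputs, parameters, seed,
sha256 checksums) into the stage output directory, and is byte-reproducible
given the same config and seed. A thin argparse CLI (console script
``pombeori``) exposes the stages as subcommands.
"""

from __future__ import annotations

import argparse
import hashlib
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as pio
from .annotation import attach_expression, derive_igrs, read_genes, read_genome
from .classify import SVMConfig, feature_fscore, repeated_cv, score_heldout
from .coverage import copy_number_ratio, loess_smooth, scale_quartile
from .features import (
    CORE_TRIO,
    FEATURE_NAMES,
    Dataset,
    FeatureExtractor,
    build_igr_dataset,
    build_intragenic_dataset,
    heldout_features,
)
from .intervals import GenomicInterval
from .motifs import MotifUnionSet, read_meme_motifs, scan_pwm, union_motif_sites
from .peaks import FETrack, apply_mask, call_peaks, classify_sites, venn_counts
from .reports import placement_table, stratified_feature_histogram
from .resampling import (
    length_matched_igr_sample,
    random_igr_orientation,
    random_site_igr_expectation,
    random_site_motif_expectation,
)
from .simulate import (
    SimulationConfig,
    simulate_fe_tracks,
    simulate_genome,
    simulate_rnaseq,
    write_simulation,
)

__all__ = ["PipelineConfig", "run_stage", "STAGES", "main"]

DEFAULT_PARAMS = {
    "fe_orc": 6.0,
    "fe_mcm": 2.0,
    "min_peak": 50,
    "fdr": 0.05,
    "at_threshold": 0.75,
    "at_window": 101,
    "melt_window": 200,
    "window": 1000,
    "bin_width": 10,
    "offset_dead_zone": 100,
    "policy": "holdout",
    "loess_span": 0.005,
    "cn_bin_width": 100,
}

DEFAULT_CV = {"k": 4, "rounds": 10}
DEFAULT_SVM = {"sigma": 0.01, "C": 10.0, "standardize": True}
DEFAULT_FEATURE_SETS = {
    "all13": FEATURE_NAMES,
    "trio": CORE_TRIO,
    "L_AT": ["L_AT"],
    "N_mt": ["N_mt"],
    "L_ntx": ["L_ntx"],
    "N_mt+L_ntx": ["N_mt", "L_ntx"],
}


@dataclass
class PipelineConfig:
    """All stage parameters in one place; stages read nothing else."""

    paths: dict = field(default_factory=dict)
    params: dict = field(default_factory=dict)
    svm: dict = field(default_factory=dict)
    cv: dict = field(default_factory=dict)
    sim: dict = field(default_factory=dict)
    feature_sets: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        self.params = {**DEFAULT_PARAMS, **self.params}
        self.svm = {**DEFAULT_SVM, **self.svm}
        self.cv = {**DEFAULT_CV, **self.cv}
        if not self.feature_sets:
            self.feature_sets = {k: list(v) for k, v in DEFAULT_FEATURE_SETS.items()}

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def path(self, key: str) -> Path:
        if key not in self.paths:
            raise KeyError(f"config paths.{key} is not set")
        p = Path(self.paths[key])
        if not p.exists():
            raise FileNotFoundError(
                f"input for config key paths.{key} not found: {p}"
            )
        return p

    def stage_seed(self, name: str) -> int:
        """Deterministic per-stage seed derived from the master seed."""
        digest = hashlib.sha256(f"{self.seed}:{name}".encode()).digest()
        return int.from_bytes(digest[:4], "big") % (2**31 - 1)

    def svm_config(self) -> SVMConfig:
        return SVMConfig(
            sigma=float(self.svm["sigma"]), C=float(self.svm["C"]),
            standardize=bool(self.svm["standardize"]),
        )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_manifest(stage: str, config: PipelineConfig, outdir: Path,
                    inputs: list[Path], outputs: list[Path]) -> Path:
    manifest = {
        "stage": stage,
        "seed": config.stage_seed(stage),
        "params": config.params,
        "inputs": {str(p): _sha256(p) for p in sorted(inputs)},
        "outputs": {p.name: _sha256(p) for p in sorted(outputs)},
    }
    path = outdir / "manifest.json"
    pio.write_json(manifest, path)
    return path


def _chrom_lengths(genome: dict[str, str]) -> dict[str, int]:
    return {c: len(s) for c, s in genome.items()}


def _load_genome_ctx(config: PipelineConfig):
    genome = read_genome(config.path("genome"))
    lengths = _chrom_lengths(genome)
    mask = pio.read_bed_mask(config.path("mask"))
    return genome, lengths, mask


def _sim_config(config: PipelineConfig) -> SimulationConfig:
    return SimulationConfig(seed=config.stage_seed("simulate"), **config.sim)


# --------------------------------------------------------------------------
# stages

def stage_simulate(config: PipelineConfig, outdir: Path) -> list[Path]:
    sim_cfg = _sim_config(config)
    sim = simulate_genome(sim_cfg)
    paths = write_simulation(sim, outdir)
    coverage = simulate_rnaseq(sim.genes, sim.truth.chrom_lengths, sim_cfg)
    cov_path = outdir / "rnaseq_coverage.bedgraph"
    pio.write_bedgraph_per_base(coverage, cov_path)
    orc, mcm = simulate_fe_tracks(sim.truth, sim_cfg)
    orc_path = outdir / "orc_fe.bedgraph"
    mcm_path = outdir / "mcm_fe.bedgraph"
    pio.write_bedgraph_bins(orc.data, orc.bin_width, orc_path,
                            sim.truth.chrom_lengths)
    pio.write_bedgraph_bins(mcm.data, mcm.bin_width, mcm_path,
                            sim.truth.chrom_lengths)
    return [*paths.values(), cov_path, orc_path, mcm_path]


def _read_fe(config: PipelineConfig, key: str, lengths: dict[str, int]) -> FETrack:
    bw = int(config.params["bin_width"])
    return FETrack(pio.read_bedgraph_bins(config.path(key), bw, lengths), bw)


def stage_call_peaks(config: PipelineConfig, outdir: Path) -> list[Path]:
    genome, lengths, mask = _load_genome_ctx(config)
    out = []
    for key, threshold in (("orc_fe", config.params["fe_orc"]),
                           ("mcm_fe", config.params["fe_mcm"])):
        track = _read_fe(config, key, lengths)
        peaks = apply_mask(
            call_peaks(track, float(threshold), int(config.params["min_peak"])), mask
        )
        path = outdir / f"{key.split('_')[0]}_peaks.bed"
        pio.write_peaks_bed(peaks, path)
        out.append(path)
    return out


def stage_classify_sites(config: PipelineConfig, outdir: Path) -> list[Path]:
    orc = pio.read_peaks_bed(config.path("orc_peaks"))
    mcm = pio.read_peaks_bed(config.path("mcm_peaks"))
    site_set = classify_sites(orc, mcm)
    rows = []
    for i, (o, m) in enumerate(site_set.om_sites):
        rows.append(["OM%04d" % i, "OM", o.interval.chrom, o.interval.start,
                     o.interval.end, o.summit, m.interval.start,
                     m.interval.end, m.summit, o.max_fe])
    for i, o in enumerate(site_set.o_sites):
        rows.append(["O%04d" % i, "O", o.interval.chrom, o.interval.start,
                     o.interval.end, o.summit, "", "", "", o.max_fe])
    for i, m in enumerate(site_set.m_only):
        rows.append(["M%04d" % i, "M_only", m.interval.chrom, m.interval.start,
                     m.interval.end, "", m.interval.start, m.interval.end,
                     m.summit, m.max_fe])
    df = pd.DataFrame(rows, columns=["site_id", "class", "chrom", "start", "end",
                                     "orc_summit", "mcm_start", "mcm_end",
                                     "mcm_summit", "max_fe"])
    path = outdir / "sites.tsv"
    df.to_csv(path, sep="\t", index=False)
    n_o, n_om, n_m = venn_counts(site_set)
    pio.write_json({"n_o": n_o, "n_om": n_om, "n_m_only": n_m},
                   outdir / "venn.json")
    return [path, outdir / "venn.json"]


def stage_scan_motifs(config: PipelineConfig, outdir: Path) -> list[Path]:
    genome = read_genome(config.path("genome"))
    if "motifs" in config.paths:
        pwms = read_meme_motifs(config.path("motifs"))
    else:
        from .motifs import default_polya_pwm

        pwms = [default_polya_pwm()]
    hit_lists = [scan_pwm(genome, pwm, fdr=float(config.params["fdr"]))
                 for pwm in pwms]
    union = union_motif_sites(*hit_lists)
    hits_path = outdir / "motif_hits.tsv"
    with open(hits_path, "w") as fh:
        fh.write("motif\tchrom\tstart\tend\tstrand\tscore\tp_value\tq_value\n")
        for pwm, hits in zip(pwms, hit_lists):
            for h in hits:
                fh.write(
                    f"{pwm.name}\t{h.interval.chrom}\t{h.interval.start}\t"
                    f"{h.interval.end}\t{h.interval.strand}\t{h.score:.3f}\t"
                    f"{h.p_value:.6g}\t{h.q_value:.6g}\n"
                )
    union_path = outdir / "motif_union.bed"
    with open(union_path, "w") as fh:
        for iv, score in zip(union.intervals, union.scores):
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{score:.3f}\n")
    return [hits_path, union_path]


def read_union_bed(path: str | Path) -> MotifUnionSet:
    intervals, scores = [], []
    with open(path) as fh:
        for line in fh:
            chrom, start, end, score = line.rstrip("\n").split("\t")[:4]
            intervals.append(GenomicInterval(chrom, int(start), int(end)))
            scores.append(float(score))
    return MotifUnionSet(intervals, scores)


def _load_feature_context(config: PipelineConfig):
    genome, lengths, mask = _load_genome_ctx(config)
    genes = read_genes(config.path("gff"), chrom_lengths=lengths)
    if "expression" in config.paths:
        table = pd.read_csv(config.path("expression"), sep="\t")
        attach_expression(genes, dict(zip(table["gene_id"], table["rpkm"])))
    igrs = derive_igrs(genes, mask, lengths)
    union = read_union_bed(config.path("motif_union"))
    coverage = pio.read_bedgraph_per_base(config.path("coverage"), lengths)
    extractor = FeatureExtractor(genome, union, coverage,
                                 width=int(config.params["window"]))
    return genome, lengths, mask, genes, igrs, union, coverage, extractor


def _site_set_from_tsv(path: Path):
    from .peaks import Peak, SiteSet

    df = pd.read_csv(path, sep="\t")
    site_set = SiteSet()
    for _, r in df.iterrows():
        chrom = str(r["chrom"])
        iv = GenomicInterval(chrom, int(r["start"]), int(r["end"]))
        if r["class"] == "OM":
            orc = Peak(iv, int(r["orc_summit"]), float(r["max_fe"]))
            mcm_iv = GenomicInterval(chrom, int(r["mcm_start"]), int(r["mcm_end"]))
            mcm = Peak(mcm_iv, int(r["mcm_summit"]), float(r["max_fe"]))
            site_set.om_sites.append((orc, mcm))
        elif r["class"] == "O":
            site_set.o_sites.append(Peak(iv, int(r["orc_summit"]), float(r["max_fe"])))
        else:
            site_set.m_only.append(Peak(iv, int(r["mcm_summit"]), float(r["max_fe"])))
    return site_set


def stage_features(config: PipelineConfig, outdir: Path) -> list[Path]:
    _, _, _, _, igrs, _, _, extractor = _load_feature_context(config)
    site_set = _site_set_from_tsv(config.path("sites"))
    dataset, heldout = build_igr_dataset(
        igrs, site_set, extractor, policy=str(config.params["policy"])
    )
    df = pd.concat([dataset.meta.reset_index(drop=True),
                    dataset.X.reset_index(drop=True)], axis=1)
    df.insert(0, "label", dataset.y)
    if heldout:
        hx = heldout_features(extractor, heldout,
                              getattr(dataset, "heldout_igrs", None))
        hmeta = pd.DataFrame(
            [{"chrom": w.chrom, "anchor": w.anchor, "start": w.interval.start,
              "end": w.interval.end, "kind": "O_heldout"} for w in heldout]
        )
        hdf = pd.concat([hmeta, hx], axis=1)
        hdf.insert(0, "label", -1)
        df = pd.concat([df, hdf], ignore_index=True)
    path = outdir / "features.tsv"
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
    return [path]


def _dataset_from_tsv(path: Path) -> tuple[Dataset, pd.DataFrame]:
    df = pd.read_csv(path, sep="\t")
    train = df[df["label"] >= 0].reset_index(drop=True)
    heldout = df[df["label"] < 0].reset_index(drop=True)
    meta_cols = [c for c in train.columns if c not in FEATURE_NAMES + ["label"]]
    ds = Dataset(train[FEATURE_NAMES], train["label"].to_numpy(int),
                 train[meta_cols])
    return ds, heldout


def stage_train_eval(config: PipelineConfig, outdir: Path) -> list[Path]:
    dataset, heldout = _dataset_from_tsv(config.path("features"))
    seed = config.stage_seed("train-eval")
    svm_cfg = config.svm_config()
    rows = []
    summary: dict = {"feature_sets": {}}
    for name, subset in config.feature_sets.items():
        fit_platt = name == "trio"
        report = repeated_cv(
            dataset, svm_cfg, feature_subset=subset,
            k=int(config.cv["k"]), rounds=int(config.cv["rounds"]),
            seed=seed, fit_platt=fit_platt,
        )
        for _, r in report.table.iterrows():
            rows.append({"feature_set": name, "round": int(r["round"]),
                         "fold": int(r["fold"]), "roc_auc": r["roc_auc"],
                         "pr_auc": r["pr_auc"]})
        entry = {
            "features": list(subset),
            "roc_auc_mean": report.mean_roc, "roc_auc_ci": list(report.roc_ci),
            "pr_auc_mean": report.mean_pr, "pr_auc_ci": list(report.pr_ci),
        }
        if fit_platt:
            probs = np.nanmean(report.oof_probs, axis=0)
            entry["median_prob_positive"] = float(np.median(probs[dataset.y == 1]))
            entry["median_prob_negative"] = float(np.median(probs[dataset.y == 0]))
            if len(heldout):
                hp = score_heldout(report.models, heldout[list(subset)])
                entry["median_prob_heldout_O"] = float(np.median(hp))
        summary["feature_sets"][name] = entry
    summary["fscores"] = feature_fscore(dataset.X, dataset.y)
    table_path = outdir / "cv_report.tsv"
    pd.DataFrame(rows).to_csv(table_path, sep="\t", index=False,
                              float_format="%.6g")
    summary_path = outdir / "summary.json"
    pio.write_json(summary, summary_path)
    return [table_path, summary_path]


def stage_intragenic_eval(config: PipelineConfig, outdir: Path) -> list[Path]:
    _, _, mask, _, _, _, _, extractor = _load_feature_context(config)
    dataset, _ = _dataset_from_tsv(config.path("features"))
    sites_df = pd.read_csv(config.path("sites"), sep="\t")
    site_ivs = [
        GenomicInterval(str(r["chrom"]), int(r["start"]), int(r["end"]))
        for _, r in sites_df.iterrows() if r["class"] in ("OM", "O")
    ]
    pos_df = pd.read_csv(config.path("intragenic_sites"), sep="\t")
    positives = [(str(r["chrom"]), int(r["pos"])) for _, r in pos_df.iterrows()]
    seed = config.stage_seed("intragenic-eval")
    intra = build_intragenic_dataset(positives, extractor, site_ivs, mask,
                                     seed=seed)
    report = repeated_cv(
        dataset, config.svm_config(), feature_subset=CORE_TRIO,
        k=int(config.cv["k"]), rounds=int(config.cv["rounds"]),
        seed=seed, fit_platt=True,
    )
    probs = score_heldout(report.models, intra.X[CORE_TRIO])
    from .classify import pr_auc, roc_auc

    summary = {
        "n_pos": intra.n_pos, "n_controls": intra.n_neg,
        "roc_auc": roc_auc(probs, intra.y),
        "pr_auc": pr_auc(probs, intra.y),
    }
    path = outdir / "intragenic_summary.json"
    pio.write_json(summary, path)
    return [path]


def stage_montecarlo(config: PipelineConfig, outdir: Path) -> list[Path]:
    _, lengths, mask, genes, igrs, union, _, _ = _load_feature_context(config)
    site_set = _site_set_from_tsv(config.path("sites"))
    seed = config.stage_seed("montecarlo")
    arms = mask.arms(lengths)
    n_om = len(site_set.om_sites)
    motif_ci = random_site_motif_expectation(
        arms, union, n_sites=max(n_om, 1), reps=500, seed=seed
    )
    igr_ci = random_site_igr_expectation(
        arms, igrs, n_sites=max(n_om, 1), reps=500, seed=seed + 1
    )
    om_igrs = [
        g for g in igrs
        if any(o.interval.chrom == g.interval.chrom and g.interval.contains(o.summit)
               for o, _ in site_set.om_sites)
    ]
    result = {
        "random_motif_fraction_ci": [motif_ci.lower, motif_ci.upper],
        "random_igr_fraction_ci": [igr_ci.lower, igr_ci.upper],
    }
    if om_igrs:
        rand = random_igr_orientation(igrs, n_sample=len(om_igrs), reps=500,
                                      seed=seed + 2)
        matched = length_matched_igr_sample(
            igrs, [g.interval.width for g in om_igrs], reps=200, seed=seed + 3
        )
        result["random_orientation_ci"] = {
            c: [ci.lower, ci.upper] for c, ci in rand.items()
        }
        result["length_controlled_orientation_ci"] = {
            c: [ci.lower, ci.upper] for c, ci in matched.class_cis.items()
        }
        om_orient = [g.orientation for g in om_igrs if g.orientation != "edge"]
        result["om_igr_divergent_fraction"] = (
            sum(1 for o in om_orient if o == "divergent") / len(om_orient)
            if om_orient else None
        )
    path = outdir / "montecarlo.json"
    pio.write_json(result, path)
    return [path]


def stage_copy_number(config: PipelineConfig, outdir: Path) -> list[Path]:
    genome = read_genome(config.path("genome"))
    lengths = _chrom_lengths(genome)
    bw = int(config.params["cn_bin_width"])
    binned_lengths = {c: -(-n // bw) for c, n in lengths.items()}
    sample = pio.read_bedgraph_bins(config.path("cn_sample"), bw, lengths)
    reference = pio.read_bedgraph_bins(config.path("cn_reference"), bw, lengths)
    ratios = copy_number_ratio(sample, reference)
    span = float(config.params["loess_span"])
    all_vals = np.concatenate([ratios[c] for c in sorted(ratios)])
    smoothed_all = loess_smooth(all_vals, span=span)
    scaled = scale_quartile(smoothed_all)
    out = {}
    pos = 0
    for c in sorted(ratios):
        n = ratios[c].size
        out[c] = scaled[pos : pos + n]
        pos += n
    path = outdir / "copy_number.bedgraph"
    pio.write_bedgraph_bins(out, bw, path, lengths)
    pio.write_json(
        {"q25_after_scaling": float(np.nanpercentile(scaled, 25)),
         "n_bins": int(scaled.size)},
        outdir / "copy_number_summary.json",
    )
    return [path, outdir / "copy_number_summary.json"]


def stage_report(config: PipelineConfig, outdir: Path) -> list[Path]:
    _, _, _, genes, igrs, _, _, _ = _load_feature_context(config)
    site_set = _site_set_from_tsv(config.path("sites"))
    features_df = pd.read_csv(config.path("features"), sep="\t")
    summits = {
        "OM": [(o.interval.chrom, o.summit) for o, _ in site_set.om_sites],
        "O": [(p.interval.chrom, p.summit) for p in site_set.o_sites],
    }
    placement = placement_table(summits, genes, igrs)
    placement_path = outdir / "placement.tsv"
    placement.to_csv(placement_path, sep="\t", index=False, float_format="%.6g")
    feats = features_df[features_df["label"] >= 0].copy()
    feats["class"] = feats["kind"].map(
        {"OM": "OM", "O": "O", "background": "background"}
    ).fillna("background")
    strata_nmt = stratified_feature_histogram(feats, second_feature="N_mt")
    strata_ntx = stratified_feature_histogram(
        feats, second_feature="L_ntx", second_bins=(200, 400, 600, 800)
    )
    strata_path = outdir / "strata.tsv"
    pd.concat([strata_nmt, strata_ntx], ignore_index=True).astype(str).to_csv(
        strata_path, sep="\t", index=False
    )
    return [placement_path, strata_path]


STAGES = {
    "simulate": (stage_simulate, []),
    "call-peaks": (stage_call_peaks, ["genome", "mask", "orc_fe", "mcm_fe"]),
    "classify-sites": (stage_classify_sites, ["orc_peaks", "mcm_peaks"]),
    "scan-motifs": (stage_scan_motifs, ["genome"]),
    "features": (stage_features, ["genome", "gff", "mask", "motif_union",
                                  "coverage", "sites"]),
    "train-eval": (stage_train_eval, ["features"]),
    "intragenic-eval": (stage_intragenic_eval,
                        ["genome", "gff", "mask", "motif_union", "coverage",
                         "features", "sites", "intragenic_sites"]),
    "montecarlo": (stage_montecarlo, ["genome", "gff", "mask", "motif_union",
                                      "coverage", "sites"]),
    "copy-number": (stage_copy_number, ["genome", "cn_sample", "cn_reference"]),
    "report": (stage_report, ["genome", "gff", "mask", "motif_union",
                              "coverage", "sites", "features"]),
}


def run_stage(name: str, config: PipelineConfig, outdir: str | Path) -> Path:
    """Run one stage; returns the path of the written manifest."""
    if name not in STAGES:
        raise ValueError(f"unknown stage {name!r}; choose from {sorted(STAGES)}")
    func, input_keys = STAGES[name]
    inputs = [config.path(k) for k in input_keys]
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs = func(config, outdir)
    return _write_manifest(name, config, outdir, inputs, [Path(p) for p in outputs])


def main(argv: list[str] | None = None) -> int:
    parser = argparse.ArgumentParser(
        prog="pombeori",
        description="Replication-origin dissection pipeline stages",
    )
    parser.add_argument("stage", choices=sorted(STAGES))
    parser.add_argument("--config", help="YAML pipeline config", default=None)
    parser.add_argument("--out", required=True, help="stage output directory")
    parser.add_argument("--seed", type=int, default=None,
                        help="override the master seed")
    args = parser.parse_args(argv)
    config = (PipelineConfig.from_yaml(args.config) if args.config
              else PipelineConfig())
    if args.seed is not None:
        config.seed = args.seed
    try:
        manifest = run_stage(args.stage, config, args.out)
    except (KeyError, FileNotFoundError, ValueError) as exc:
        print(f"error: {exc}", file=sys.stderr)
        return 1
    print(f"stage {args.stage} complete; manifest: {manifest}")
    return 0


if __name__ == "__main__":  # pragma: no cover
    raise SystemExit(main())
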