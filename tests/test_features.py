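"""Window construction, feature extraction and dataset assembly."""

import numpy as np
import pytest

from pombeori.annotation import IGR, GeneModel
from pombeori.coverage import longest_run
from pombeori.features import (
    CORE_TRIO,
    FeatureExtractor,
    build_igr_dataset,
    build_intragenic_dataset,
    build_window,
)
from pombeori.intervals import ArmMask, GenomicInterval
from pombeori.motifs import MotifUnionSet
from pombeori.peaks import Peak, SiteSet


class TestBuildWindow:
    def test_centered_window(self):
        w = build_window(5000, chrom_length=100_000)
        assert (w.interval.start, w.interval.end) == (4500, 5500)

    def test_out_of_bounds_error(self):
        with pytest.raises(ValueError, match="window"):
            build_window(300, chrom_length=100_000)

    def test_odd_width_left_bias(self):
        w = build_window(5000, chrom_length=100_000, width=1001)
        assert (w.interval.start, w.interval.end) == (4500, 5501)


def _null_extractor(rng, n=5000):
    """GC-balanced, uniformly transcribed, motif-free context."""
    seq = "".join(rng.choice(list("ACGT"), size=n))
    union = MotifUnionSet([], [])
    coverage = {"c": np.full(n, 5.0)}
    return FeatureExtractor({"c": seq}, union, coverage)


class TestExtractFeatures:
    def test_null_window(self, rng):
        ex = _null_extractor(rng)
        feats = ex.extract(build_window(2500, 5000, chrom="c"))
        assert feats["N_mt"] == 0
        assert feats["L_AT"] == 0
        assert feats["L_ntx"] == 0
        assert feats["motif_dist_center"] == 500
        assert feats["is_divergent"] == 0 and feats["is_convergent"] == 0

    def test_planted_om_windows(self, small_study):
        """Planted OM windows show the expected N_mt / L_AT / L_ntx signature."""
        ex = small_study.extractor
        sites = small_study.sim.truth.sites_of("OM")
        good = 0
        for s in sites:
            w = build_window(s.orc_anchor,
                             small_study.sim.truth.chrom_lengths[s.chrom],
                             chrom=s.chrom)
            f = ex.extract(w)
            good += int(f["N_mt"] >= 1 and f["L_AT"] >= 150 and f["L_ntx"] >= 600)
        assert good >= 0.9 * len(sites)

    def test_matches_naive_recomputation(self, small_study, rng):
        """Independent per-window recomputation of the core trio + extras."""
        ex = small_study.extractor
        genome = small_study.sim.genome
        union = small_study.motif_union
        chroms = sorted(genome)
        for _ in range(20):
            chrom = chroms[int(rng.integers(len(chroms)))]
            seq = genome[chrom]
            anchor = int(rng.integers(1000, len(seq) - 1000))
            w = build_window(anchor, len(seq), chrom=chrom)
            f = ex.extract(w)
            # N_mt: naive midpoint count
            mids = [iv.midpoint for iv in union.intervals if iv.chrom == chrom]
            n_mt = sum(1 for m in mids if anchor - 500 <= m <= anchor + 500)
            assert f["N_mt"] == n_mt
            # L_AT: naive per-position 101-mer count
            lat = 0
            for i in range(w.interval.start, w.interval.end):
                lo, hi = max(0, i - 50), min(len(seq), i + 51)
                sub = seq[lo:hi]
                frac = sum(1 for b in sub if b in "AT") / len(sub)
                lat += int(frac >= 0.75 - 1e-12)
            assert f["L_AT"] == lat
            # L_ntx: naive longest run
            cov = small_study.coverage[chrom][w.interval.start : w.interval.end]
            best = cur = 0
            for v in cov:
                cur = cur + 1 if v <= 1 else 0
                best = max(best, cur)
            assert f["L_ntx"] == best
            # at_mean plain count
            sub = seq[w.interval.start : w.interval.end]
            assert f["at_mean"] == pytest.approx(
                sum(1 for b in sub if b in "AT") / 1000
            )
            assert f["run_max_AT"] == longest_run(
                np.array([b in "AT" for b in sub])
            )


def _mini_context(rng):
    n = 40_000
    seq = "".join(rng.choice(list("ACGT"), size=n, p=[0.32, 0.18, 0.18, 0.32]))
    union = MotifUnionSet([], [])
    coverage = {"c": np.zeros(n)}
    return FeatureExtractor({"c": seq}, union, coverage)


def _igr(start, end, chrom="c"):
    return IGR(GenomicInterval(chrom, start, end), None, None)


def _site_set(om_summits, o_summits, chrom="c"):
    ss = SiteSet()
    for s in om_summits:
        p = Peak(GenomicInterval(chrom, s - 100, s + 100), s, 8.0)
        ss.om_sites.append((p, p))
    for s in o_summits:
        ss.o_sites.append(Peak(GenomicInterval(chrom, s - 100, s + 100), s, 8.0))
    return ss


class TestBuildIgrDataset:
    def _igrs(self):
        return [_igr(2000 * i + 1000, 2000 * i + 2500) for i in range(14)]

    def test_holdout_policy_counts(self, rng):
        ex = _mini_context(rng)
        igrs = self._igrs()
        om = [igrs[i].interval.midpoint for i in range(3)]
        o = [igrs[3].interval.midpoint]
        ds, heldout = build_igr_dataset(igrs, _site_set(om, o), ex, policy="holdout")
        assert (ds.n_pos, ds.n_neg, len(heldout)) == (3, 10, 1)
        assert set(ds.meta["kind"]) == {"OM", "background"}

    def test_include_policy_counts(self, rng):
        ex = _mini_context(rng)
        igrs = self._igrs()
        om = [igrs[i].interval.midpoint for i in range(3)]
        o = [igrs[3].interval.midpoint]
        ds, heldout = build_igr_dataset(igrs, _site_set(om, o), ex, policy="include")
        assert (ds.n_pos, ds.n_neg, len(heldout)) == (3, 11, 0)

    def test_no_positives_error(self, rng):
        ex = _mini_context(rng)
        with pytest.raises(ValueError, match="positive"):
            build_igr_dataset(self._igrs(), _site_set([], []), ex)

    def test_positives_match_planted_count(self, small_study):
        n_planted = len(small_study.sim.truth.sites_of("OM"))
        assert small_study.dataset.n_pos == n_planted

    def test_windows_disjoint_between_classes(self, small_study):
        meta = small_study.dataset.meta
        pos = meta[small_study.dataset.y == 1]
        neg = meta[small_study.dataset.y == 0]
        pos_keys = set(zip(pos["chrom"], pos["start"], pos["end"]))
        neg_keys = set(zip(neg["chrom"], neg["start"], neg["end"]))
        assert not pos_keys & neg_keys


class TestBuildIntragenicDataset:
    def test_control_counts_and_distance(self, rng):
        ex = _mini_context(rng)
        sites = [GenomicInterval("c", 5000, 5400), GenomicInterval("c", 20_000, 20_300)]
        positives = [("c", 10_000)] * 27
        ds = build_intragenic_dataset(
            positives, ex, sites, ArmMask(), n_controls_per_pos=5, seed=5
        )
        assert (ds.n_pos, ds.n_neg) == (27, 135)
        controls = ds.meta[ds.meta["kind"] == "control"]
        for _, r in controls.iterrows():
            for iv in sites:
                dist = max(iv.start - r["anchor"], r["anchor"] - (iv.end - 1), 0)
                assert dist > 1000

    def test_seed_reproducibility(self, rng):
        ex = _mini_context(rng)
        sites = [GenomicInterval("c", 5000, 5400)]
        args = ([("c", 10_000)] * 3, ex, sites, ArmMask())
        a = build_intragenic_dataset(*args, seed=9)
        b = build_intragenic_dataset(*args, seed=9)
        assert list(a.meta["anchor"]) == list(b.meta["anchor"])
        c = build_intragenic_dataset(*args, seed=10)
        assert list(a.meta["anchor"]) != list(c.meta["anchor"])

    def test_trio_features_present(self, rng):
        ex = _mini_context(rng)
        ds = build_intragenic_dataset(
            [("c", 10_000)] * 3, ex, [], ArmMask(), seed=1
        )
        assert set(CORE_TRIO) <= set(ds.X.columns)
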