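"""Descriptive report computations: positioning, asymmetry, placement, strata."""

import numpy as np
import pandas as pd
import pytest

from pombeori.annotation import GeneModel, IGR, derive_igrs
from pombeori.intervals import ArmMask, GenomicInterval
from pombeori.motifs import MotifHit, MotifUnionSet, union_motif_sites
from pombeori.peaks import FETrack
from pombeori.reports import (
    fe_by_motif_count,
    flank_asymmetry_table,
    motif_position_matrix,
    offset_class,
    placement_table,
    stratified_feature_histogram,
)
from pombeori.workflow import truth_site_set


def _union(*starts, width=10, chrom="c"):
    hits = [
        MotifHit(GenomicInterval(chrom, s, s + width), 1.0, 1e-3, 1e-2)
        for s in starts
    ]
    return union_motif_sites(hits)


class TestOffsetClass:
    @pytest.mark.parametrize(
        "offset,expected",
        [(200, "right"), (0, "overlap"), (-150, "left"),
         (100, "overlap"), (-100, "overlap"), (101, "right")],
    )
    def test_dead_zone_rule(self, offset, expected):
        assert offset_class(offset) == expected


class TestMotifPositionMatrix:
    def test_rightward_motif_not_flipped(self):
        res = motif_position_matrix([("c", 1000)], _union(1025))
        assert not res.flipped[0]
        assert list(res.offsets[0]) == [30]

    def test_leftward_motif_flipped(self):
        res = motif_position_matrix([("c", 1000)], _union(965))
        assert res.flipped[0]
        assert list(res.offsets[0]) == [30]

    def test_flip_is_an_involution(self):
        res = motif_position_matrix([("c", 1000)], _union(965, 1200))
        again = [-o for o in res.offsets[0]]
        nearest = min(again, key=abs)
        flipped_back = [-o for o in again] if nearest < 0 else again
        assert sorted(abs(o) for o in flipped_back) == sorted(
            abs(o) for o in res.offsets[0]
        )

    def test_matches_naive_scan(self, rng):
        union = _union(*rng.integers(0, 10_000, size=40))
        mids = [iv.midpoint for iv in union.intervals]
        sites = [("c", int(s)) for s in rng.integers(1000, 9000, size=10)]
        res = motif_position_matrix(sites, union, half_width=500)
        for (chrom, summit), offsets, flipped in zip(
            sites, res.offsets, res.flipped
        ):
            naive = [m - summit for m in mids if abs(m - summit) <= 500]
            if naive and min(naive, key=abs) < 0:
                naive = [-o for o in naive]
                assert flipped
            assert sorted(naive) == list(offsets)


class TestFeByMotifCount:
    def test_fe_increases_with_motif_count(self):
        fe = np.ones(1100)
        sites = []
        starts = []
        for i, count in enumerate([0, 1, 2, 3] * 5):
            summit = 500 * (i + 1)
            for j in range(count):
                starts.append(summit - 40 + 30 * j)
            fe[summit // 10] = 2.0 + count + 0.01 * i
            sites.append(("c", summit))
        track = FETrack({"c": fe}, 10)
        groups, table = fe_by_motif_count(sites, track, _union(*starts))
        medians = table.set_index("motif_count")["median_fe"]
        assert (medians.diff().dropna() > 0).all()
        assert set(groups) == {0, 1, 2, 3}

    def test_empty_groups_omitted(self):
        track = FETrack({"c": np.full(100, 5.0)}, 10)
        groups, table = fe_by_motif_count([("c", 500)], track, _union(480))
        assert list(table["motif_count"]) == [1]


class TestFlankAsymmetry:
    def test_shifted_sites_have_higher_mcm_side_at(self, small_study):
        table = flank_asymmetry_table(
            truth_site_set(small_study.sim), small_study.sim.genome
        )
        shifted = table[table["offset_class"] != "overlap"]
        if len(shifted) == 0:
            pytest.skip("no split sites in this draw")
        correct = np.where(
            shifted["offset_class"] == "right",
            shifted["right_at"] > shifted["left_at"],
            shifted["left_at"] > shifted["right_at"],
        )
        assert correct.mean() >= 0.9

    def test_overlapping_sites_roughly_symmetric(self, small_study):
        table = flank_asymmetry_table(
            truth_site_set(small_study.sim), small_study.sim.genome
        )
        overlap = table[table["offset_class"] == "overlap"]
        assert abs((overlap["right_at"] - overlap["left_at"]).median()) < 0.08

    def test_empty_input(self):
        from pombeori.peaks import SiteSet

        table = flank_asymmetry_table(SiteSet(), {"c": "ACGT" * 1000})
        assert len(table) == 0


def _gene(chrom, start, end, strand, gene_id="g"):
    if strand == "+":
        return GeneModel(gene_id, GenomicInterval(chrom, start + 5, end - 5, "+"),
                         start, end)
    return GeneModel(gene_id, GenomicInterval(chrom, start + 5, end - 5, "-"),
                     end, start)


class TestPlacementTable:
    def test_summits_in_igrs(self):
        genes = [_gene("c", 0, 400, "+", "a"), _gene("c", 900, 1300, "+", "b")]
        igrs = derive_igrs(genes, ArmMask(), {"c": 1500})
        table = placement_table({"OM": [("c", 600), ("c", 700)]}, genes, igrs)
        row = table.set_index("class").loc["OM"]
        assert row["frac_intergenic"] == 1.0

    def test_summit_at_plus_strand_tss_is_intragenic(self):
        genes = [_gene("c", 500, 900, "+", "a")]
        table = placement_table({"OM": [("c", 500)]}, genes, [])
        assert table.iloc[0]["frac_intragenic"] == 1.0

    def test_matches_membership_oracle(self, rng):
        genes = [_gene("c", int(s), int(s) + 300, "+", f"g{i}")
                 for i, s in enumerate(range(0, 9000, 900))]
        summits = [("c", int(p)) for p in rng.integers(0, 9000, size=50)]
        table = placement_table({"X": summits}, genes, [])
        frac_intra = table.iloc[0]["frac_intragenic"]
        oracle = np.mean([
            any(g.span.start <= p < g.span.end for g in genes)
            for _, p in summits
        ])
        assert frac_intra == pytest.approx(oracle)

    def test_fractions_sum_to_one(self, small_study):
        ss = small_study.site_set
        genes = small_study.sim.genes
        table = placement_table(
            {"OM": [(o.interval.chrom, o.summit) for o, _ in ss.om_sites],
             "O": [(p.interval.chrom, p.summit) for p in ss.o_sites]},
            genes, small_study.igrs,
        )
        assert np.allclose(
            table["frac_intergenic"] + table["frac_intragenic"], 1.0
        )
        # planted sites are intergenic by construction
        assert (table["frac_intergenic"] == 1.0).all()


class TestStratifiedHistogram:
    def _features(self, small_study):
        ds = small_study.dataset
        df = ds.X.copy()
        df["class"] = np.where(ds.y == 1, "OM", "background")
        if small_study.heldout_X is not None:
            held = small_study.heldout_X.copy()
            held["class"] = "O"
            df = pd.concat([df, held], ignore_index=True)
        return df

    def test_totals_conserved(self, small_study):
        df = self._features(small_study)
        out = stratified_feature_histogram(df)
        assert out["count"].sum() == len(df)

    def test_all_zero_features_single_stratum(self):
        df = pd.DataFrame(
            {"L_AT": [0] * 7, "N_mt": [0] * 7, "class": ["background"] * 7}
        )
        out = stratified_feature_histogram(df)
        assert out["count"].max() == 7
        assert out["count"].sum() == 7

    def test_om_fraction_rises_with_n_mt_at_moderate_l_at(self, small_study):
        """Within intermediate AT-richness, motif count carries information."""
        df = self._features(small_study)
        mid = df[(df["L_AT"] >= 200) & (df["L_AT"] < 400)]
        low = mid[mid["N_mt"] == 0]
        high = mid[mid["N_mt"] >= 1]
        if len(low) < 3 or len(high) < 3:
            pytest.skip("stratum too sparse in this draw")
        frac = lambda d: (d["class"] == "OM").mean()
        assert frac(high) > frac(low)

    def test_missing_column_error(self):
        with pytest.raises(ValueError, match="missing column"):
            stratified_feature_histogram(pd.DataFrame({"L_AT": [1]}))
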