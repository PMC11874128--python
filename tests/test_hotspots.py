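"""Incidence tracks, threshold resolution, island calling and annotation."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest

from runscape import (
    IslandSpec, PopulationDesign, ROHParams, Run, RunSet, SimConfig,
    ThresholdSpec, annotate_islands, call_islands, classify_run_length,
    detect_roh, incidence_track, overlap_islands, resolve_threshold,
    simulate_dataset,
)
from runscape.hotspots import HotspotError, IncidenceTrack, Island
from runscape.runs import ROH

from conftest import make_dataset


def _mk_run(sample, start, end, chrom=1):
    return Run(
        sample_id=sample, population="POP", kind=ROH, chrom=chrom,
        start_bp=start, end_bp=end, n_snp=60,
        length_class=classify_run_length(end - start + 1, ROH),
    )


def _track_from_fractions(fracs, positions=None):
    m = len(fracs)
    positions = positions if positions is not None else (np.arange(m) + 1) * 100_000
    return IncidenceTrack(
        population="POP", kind=ROH,
        table=pd.DataFrame(
            {
                "chrom": np.ones(m, dtype=int),
                "pos_bp": positions,
                "n_in_run": (np.asarray(fracs) * 100).astype(int),
                "n_genotyped": np.full(m, 100),
                "fraction": np.asarray(fracs, dtype=float),
            }
        ),
    )


class TestIncidenceTrack:
    def test_empty_runset_gives_zero_fractions(self):
        ds = make_dataset(np.ones((5, 10), dtype=np.int8))
        rs = RunSet(runs=[], kind=ROH, params=ROHParams())
        track = incidence_track(rs, ds)
        assert (track.table["fraction"] == 0).all()

    def test_covered_fraction_counts_only_genotyped_samples(self):
        """6 covering runs over 10 genotyped samples -> fraction 0.6; where
        one sample is uncalled the denominator shrinks to 9."""
        from runscape import MISSING

        g = np.ones((10, 5), dtype=np.int8)
        g[7, 2] = MISSING
        ds = make_dataset(g, positions=(np.arange(5) + 1) * 1_000_000)
        runs = [
            _mk_run(f"ind{i}", 1, 6_000_000) for i in range(6)
        ]
        track = incidence_track(RunSet(runs=runs, kind=ROH, params=ROHParams()), ds)
        t = track.table
        assert t.loc[0, "fraction"] == pytest.approx(0.6)
        assert t.loc[2, "n_genotyped"] == 9
        assert t.loc[2, "fraction"] == pytest.approx(6 / 9)


class TestResolveThreshold:
    def test_absolute_mode_ignores_track(self):
        track = _track_from_fractions([0.1, 0.9, 0.3])
        spec = ThresholdSpec(mode="absolute", value=0.5)
        assert resolve_threshold(track, spec) == 0.5

    def test_top_permille_of_single_spike(self):
        """999 zeros and one 1.0: the top 0.1% threshold resolves to 1.0."""
        fracs = np.zeros(1_000)
        fracs[500] = 1.0
        track = _track_from_fractions(fracs)
        spec = ThresholdSpec(mode="top_quantile", quantile_tail=0.001)
        assert resolve_threshold(track, spec) == pytest.approx(1.0)

    def test_constant_track_resolves_to_the_constant(self):
        track = _track_from_fractions(np.full(100, 0.4))
        spec = ThresholdSpec(mode="top_quantile", quantile_tail=0.005)
        assert resolve_threshold(track, spec) == pytest.approx(0.4)
        # inclusive comparison: every marker becomes a hotspot SNP
        assert len(call_islands(track, spec)) >= 1

    def test_combined_mode_takes_the_larger_cutoff(self):
        track = _track_from_fractions(np.linspace(0, 0.4, 100))
        spec = ThresholdSpec(mode="combined", value=0.5, quantile_tail=0.01)
        assert resolve_threshold(track, spec) == 0.5

    def test_quantile_hotspot_count_bounded(self):
        rng = np.random.default_rng(3)
        fracs = rng.random(500)
        track = _track_from_fractions(fracs)
        q = 0.01
        thr = resolve_threshold(track, ThresholdSpec(mode="top_quantile", quantile_tail=q))
        n_hot = int((fracs >= thr).sum())
        ties = int((fracs == thr).sum())
        assert n_hot <= math.ceil(q * len(fracs)) + ties


class TestCallIslands:
    def test_nothing_above_threshold(self):
        track = _track_from_fractions(np.full(50, 0.2))
        out = call_islands(track, ThresholdSpec(mode="absolute", value=0.5))
        assert out == []

    def test_consecutive_hot_markers_form_one_island(self):
        fracs = np.zeros(20)
        fracs[5:10] = 0.6
        track = _track_from_fractions(fracs)
        out = call_islands(track, ThresholdSpec(mode="absolute", value=0.5))
        assert len(out) == 1
        isl = out[0]
        assert (isl.start_bp, isl.end_bp, isl.n_snp) == (600_000, 1_000_000, 5)
        assert isl.peak_fraction == pytest.approx(0.6)

    def test_distant_clusters_stay_separate(self):
        fracs = np.zeros(60)
        fracs[5:8] = 0.7
        fracs[40:43] = 0.7  # 3.2 Mb away at 100 kb spacing
        track = _track_from_fractions(fracs)
        out = call_islands(
            track, ThresholdSpec(mode="absolute", value=0.5), merge_gap_bp=500_000
        )
        assert len(out) == 2

    def test_island_members_all_at_or_above_threshold(self):
        rng = np.random.default_rng(4)
        fracs = rng.random(300)
        track = _track_from_fractions(fracs)
        spec = ThresholdSpec(mode="top_quantile", quantile_tail=0.02)
        thr = resolve_threshold(track, spec)
        for isl in call_islands(track, spec):
            inside = track.table[
                (track.table["pos_bp"] >= isl.start_bp)
                & (track.table["pos_bp"] <= isl.end_bp)
            ]
            hot = inside[inside["fraction"] >= thr]
            assert len(hot) == isl.n_snp
            assert (hot["fraction"] >= isl.resolved_threshold).all()


class TestOverlapIslands:
    def _island(self, pop, start, end, chrom=1):
        return Island(
            population=pop, kind=ROH, chrom=chrom, start_bp=start, end_bp=end,
            n_snp=10, peak_fraction=0.8, mean_fraction=0.7,
            resolved_threshold=0.5,
        )

    def test_identical_islands_share_fully(self):
        out = overlap_islands(
            {"A": [self._island("A", 100, 200)], "B": [self._island("B", 100, 200)]}
        )
        assert out.iloc[0][["start_bp", "end_bp"]].tolist() == [100, 200]
        assert out.iloc[0]["populations"] == "A,B"

    def test_disjoint_islands_share_nothing(self):
        out = overlap_islands(
            {"A": [self._island("A", 100, 200)], "B": [self._island("B", 300, 400)]}
        )
        assert out.empty

    def test_partial_overlap_intersects(self):
        out = overlap_islands(
            {
                "A": [self._island("A", 10_000_000, 20_000_000)],
                "B": [self._island("B", 15_000_000, 25_000_000)],
            }
        )
        assert out.iloc[0][["start_bp", "end_bp"]].tolist() == [15_000_000, 20_000_000]

    def test_three_way_region_lists_all_carriers(self):
        out = overlap_islands(
            {
                "A": [self._island("A", 100, 300)],
                "B": [self._island("B", 200, 400)],
                "C": [self._island("C", 250, 350)],
            }
        )
        best = out[out["n_populations"] == 3]
        assert best.iloc[0][["start_bp", "end_bp"]].tolist() == [250, 300]

    def test_single_population_rejected(self):
        with pytest.raises(HotspotError):
            overlap_islands({"A": []})


class TestAnnotateIslands:
    def _island(self, start, end):
        return Island(
            population="A", kind=ROH, chrom=1, start_bp=start, end_bp=end,
            n_snp=5, peak_fraction=0.6, mean_fraction=0.55, resolved_threshold=0.5,
        )

    def test_bed_zero_based_conversion(self, tmp_path):
        """BED feature 99-150 (0-based half-open) = 1-based [100, 150]:
        overlap with island [100, 200] is 51 bp."""
        bed = tmp_path / "genes.bed"
        bed.write_text("1\t99\t150\tgeneX\n")
        out = annotate_islands([self._island(100, 200)], str(bed))
        assert len(out) == 1
        assert out.iloc[0]["overlap_bp"] == 51
        assert out.iloc[0]["feature"] == "geneX"

    def test_abutting_feature_does_not_overlap(self, tmp_path):
        bed = tmp_path / "genes.bed"
        bed.write_text("1\t200\t250\tgeneY\n")  # 1-based [201, 250]
        out = annotate_islands([self._island(100, 200)], str(bed))
        assert out.empty

    def test_gff3_one_based_inclusive(self, tmp_path):
        gff = tmp_path / "genes.gff3"
        gff.write_text(
            "##gff-version 3\n"
            "1\tsrc\tgene\t150\t250\t.\t+\t.\tID=g1;Name=geneZ\n"
        )
        out = annotate_islands([self._island(100, 200)], str(gff))
        assert out.iloc[0]["feature"] == "geneZ"
        assert out.iloc[0]["overlap_bp"] == 51

    def test_empty_annotation_file(self, tmp_path):
        bed = tmp_path / "empty.bed"
        bed.write_text("")
        out = annotate_islands([self._island(100, 200)], str(bed))
        assert out.empty


class TestPlantedIslandRecovery:
    def test_planted_roh_island_recovered(self):
        """Carrier fraction 0.6 against an absolute 0.5 cutoff: the called
        island overlaps the planted interval (a handful of seeds here; the
        100-seed sweep runs with the acceptance checks)."""
        from runscape import plant_islands

        for seed in range(5):
            cfg = SimConfig(
                rng_seed=seed + 100,
                pedigree=(PopulationDesign("P", n_founders=30, n_generations=1,
                                           n_offspring_per_generation=30),),
                n_chromosomes=1, markers_per_chromosome=1_000,
                chromosome_length_bp=50_000_000,
            )
            ds, truth = simulate_dataset(cfg)
            final = [i for i, s in enumerate(ds.sample_ids) if "_g1_" in s]
            cohort = ds.subset_samples(final)
            cohort, truth = plant_islands(
                cohort, truth,
                [IslandSpec(1, 20_000_000, 25_000_000, "roh", 0.6, "P")],
                np.random.default_rng(seed + 100),
            )
            runset = detect_roh(cohort)
            track = incidence_track(runset, cohort, population="P")
            islands = call_islands(track, ThresholdSpec(mode="absolute", value=0.5))
            hits = [
                i for i in islands
                if i.start_bp <= 25_000_000 and i.end_bp >= 20_000_000
            ]
            assert len(hits) >= 1
            assert len(islands) == len(hits)  # no false islands
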