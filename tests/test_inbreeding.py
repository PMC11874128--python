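"""F_ROH, VanRaden F_G, excess-homozygosity F_exH and their correlations."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from runscape import (
    MISSING, GenomeExtent, ROHParams, ROHetParams, Run, RunSet,
    classify_run_length, f_exh, f_roh, grm_vanraden, het_coefficient,
    inbreeding_correlations, inbreeding_table,
)
from runscape.inbreeding import InbreedingError
from runscape.runs import ROH, ROHET

from conftest import make_dataset


def _mk_run(sample, start, end, kind=ROH, chrom=1):
    return Run(
        sample_id=sample, population="POP", kind=kind, chrom=chrom,
        start_bp=start, end_bp=end, n_snp=60,
        length_class=classify_run_length(end - start + 1, kind),
    )


class TestFROH:
    def test_no_runs_gives_zero(self):
        rs = RunSet(runs=[], kind=ROH, params=ROHParams())
        out = f_roh(rs, GenomeExtent(10_000_000), sample_ids=["a"])
        assert out.loc["a", "f_roh_total"] == 0.0

    def test_single_run_spanning_extent_gives_one(self):
        ext = GenomeExtent(5_000_000)
        rs = RunSet(runs=[_mk_run("a", 1, 5_000_000)], kind=ROH, params=ROHParams())
        assert f_roh(rs, ext)["f_roh_total"].loc["a"] == pytest.approx(1.0)

    def test_published_scale_division(self):
        """Runs totalling 123,437,460 bp over L_TOTAL 2,468,749,207 bp give
        F_ROH ~ 0.0500 (direct division)."""
        ext = GenomeExtent(2_468_749_207)
        rs = RunSet(
            runs=[
                _mk_run("a", 1, 100_000_000),
                _mk_run("a", 200_000_001, 223_437_460, chrom=1),
            ],
            kind=ROH, params=ROHParams(),
        )
        got = f_roh(rs, ext)["f_roh_total"].loc["a"]
        assert got == pytest.approx(123_437_460 / 2_468_749_207, abs=1e-9)
        assert got == pytest.approx(0.05, abs=1e-4)

    def test_class_components_sum_to_total(self, fullsib_sim):
        ext = GenomeExtent.from_dataset(fullsib_sim["lenient"])
        table = f_roh(
            fullsib_sim["roh"], ext, sample_ids=fullsib_sim["lenient"].sample_ids
        )
        class_cols = [c for c in table.columns if c != "f_roh_total"]
        np.testing.assert_allclose(
            table[class_cols].sum(axis=1), table["f_roh_total"], atol=1e-12
        )


class TestGRM:
    def test_all_heterozygous_gives_f_minus_one(self):
        ds = make_dataset(np.ones((4, 10), dtype=np.int8))
        grm, fg = grm_vanraden(ds)
        np.testing.assert_allclose(grm.g, 0.0, atol=1e-12)
        np.testing.assert_allclose(fg, -1.0)

    def test_single_marker_closed_form(self):
        """Two samples (2, 0) at one marker: p = 0.5, Z = (1, -1),
        G_ii = 1 / 0.5 = 2, F_G = 1."""
        ds = make_dataset(np.array([[2], [0]], dtype=np.int8))
        grm, fg = grm_vanraden(ds)
        assert grm.scale == pytest.approx(0.5)
        assert fg.iloc[0] == pytest.approx(1.0)
        assert grm.g[0, 0] == pytest.approx(2.0)

    def test_hwe_simulation_mean_f_near_zero(self):
        rng = np.random.default_rng(31)
        p = rng.uniform(0.1, 0.9, size=5_000)
        g = rng.binomial(2, p, size=(500, 5_000)).astype(np.int8)
        ds = make_dataset(g, positions=(np.arange(5_000) + 1) * 1_000)
        grm, fg = grm_vanraden(ds)
        assert abs(fg.mean()) < 0.02
        assert abs(np.diag(grm.g).mean() - 1.0) < 0.02

    def test_missing_imputed_to_mean_contributes_zero(self):
        """A missing call must not move G: dropping the marker entirely for
        that sample's relationships gives the same G row."""
        g = np.array([[2, 0], [0, 2], [1, MISSING]], dtype=np.int8)
        grm, _ = grm_vanraden(make_dataset(g))
        # marker 1 is imputed to its mean for sample 2, so only marker 0
        # contributes to G[2, :]; recompute that contribution directly
        p0 = (2 + 0 + 1) / 6
        scale = grm.scale
        z0 = np.array([2, 0, 1]) - 2 * p0
        np.testing.assert_allclose(grm.g[2], z0[2] * z0 / scale, atol=1e-12)

    def test_all_monomorphic_rejected(self):
        ds = make_dataset(np.zeros((3, 5), dtype=np.int8))
        with pytest.raises(InbreedingError, match="monomorphic"):
            grm_vanraden(ds)

    def test_symmetry(self):
        rng = np.random.default_rng(32)
        g = rng.integers(0, 3, size=(20, 100)).astype(np.int8)
        grm, _ = grm_vanraden(make_dataset(g))
        np.testing.assert_allclose(grm.g, grm.g.T, atol=1e-10)


class TestFexH:
    def test_fully_homozygous_sample_gives_one(self):
        g = np.array([[0, 2, 0, 2], [0, 1, 1, 2], [1, 1, 0, 0]], dtype=np.int8)
        out = f_exh(make_dataset(g))
        assert out["f_exh"].iloc[0] == pytest.approx(1.0)

    def test_manual_formula_evaluation(self):
        """Spreadsheet-style evaluation of the excess-homozygosity formula
        on a 3 x 4 table, checked to 1e-12."""
        g = np.array(
            [[0, 1, 2, 1], [1, 1, 0, MISSING], [2, 0, 0, 1]], dtype=np.int8
        )
        out = f_exh(make_dataset(g))
        # independent evaluation, marker by marker
        p = []
        nc = []
        for j in range(4):
            col = [x for x in g[:, j] if x != MISSING]
            nc.append(len(col))
            p.append(sum(col) / (2 * len(col)))
        exp_marker = [
            1 - 2 * pj * (1 - pj) * (n / (n - 1)) for pj, n in zip(p, nc)
        ]
        for i in range(3):
            called = [j for j in range(4) if g[i, j] != MISSING]
            obs = sum(1 for j in called if g[i, j] in (0, 2))
            exp = sum(exp_marker[j] for j in called)
            total = len(called)
            want = (obs - exp) / (total - exp)
            assert out["f_exh"].iloc[i] == pytest.approx(want, abs=1e-12)
            assert out["obs_homo"].iloc[i] == obs
            assert out["total_observation"].iloc[i] == total

    def test_single_called_sample_markers_excluded(self):
        g = np.array([[0], [MISSING], [MISSING]], dtype=np.int8)
        out = f_exh(make_dataset(g))
        assert (out["exp_homo"] == 0).all()
        assert (out["f_exh"] == 0).all()  # degenerate denominator -> 0


class TestHetCoefficient:
    def test_no_rohet_gives_zero(self):
        rs = RunSet(runs=[], kind=ROHET, params=ROHetParams())
        out = het_coefficient(rs, GenomeExtent(10_000_000), sample_ids=["a"])
        assert out.loc["a"] == 0.0

    def test_tenth_of_extent(self):
        ext = GenomeExtent(10_000_000)
        rs = RunSet(
            runs=[_mk_run("a", 1, 1_000_000, kind=ROHET)],
            kind=ROHET, params=ROHetParams(),
        )
        assert het_coefficient(rs, ext).loc["a"] == pytest.approx(0.1)

    def test_definitions_agree_in_ranking(self):
        """Across 20 samples with graded heterozygous stretches, the
        length-based and marker-fraction-based coefficients rank samples
        nearly identically."""
        from runscape import detect_rohet

        rng = np.random.default_rng(55)
        m = 2_000
        pos = 1 + np.sort(rng.choice(50_000_000, size=m, replace=False))
        g = rng.choice([0, 2], size=(20, m)).astype(np.int8)
        for i in range(20):
            g[i, : 100 + 80 * i] = 1  # growing heterozygous stretch
        ds = make_dataset(g, positions=pos)
        rohet = detect_rohet(ds)
        ext = GenomeExtent(int(pos[-1] - pos[0] + 1))
        ids = ds.sample_ids
        by_len = het_coefficient(rohet, ext, sample_ids=ids)
        by_snp = het_coefficient(
            rohet, ext, sample_ids=ids, definition="snp_fraction", dataset=ds
        )
        rho = stats.spearmanr(by_len, by_snp).statistic
        assert rho > 0.9


class TestCorrelations:
    def test_perfect_linear_relation(self):
        rng = np.random.default_rng(41)
        x = rng.random(12)
        table = pd.DataFrame({"f_roh_total": x, "f_g": 2 * x + 1, "f_exh": x})
        r, _ = inbreeding_correlations(table)
        assert r.loc["f_roh_total", "f_g"] == pytest.approx(1.0)
        assert np.allclose(np.diag(r), 1.0)

    def test_matches_direct_formula(self):
        rng = np.random.default_rng(42)
        x = rng.random(10)
        y = rng.random(10)
        table = pd.DataFrame({"f_roh_total": x, "f_g": y, "f_exh": x + y})
        r, p = inbreeding_correlations(table)
        xm, ym = x - x.mean(), y - y.mean()
        want = (xm @ ym) / np.sqrt((xm @ xm) * (ym @ ym))
        assert r.loc["f_roh_total", "f_g"] == pytest.approx(want, abs=1e-12)
        t = want * np.sqrt(8 / (1 - want**2))
        want_p = 2 * stats.t.sf(abs(t), df=8)
        assert p.loc["f_roh_total", "f_g"] == pytest.approx(want_p, rel=1e-9)

    def test_too_few_samples_rejected(self):
        table = pd.DataFrame({"f_roh_total": [0.1, 0.2], "f_g": [0.0, 0.1]})
        with pytest.raises(InbreedingError):
            inbreeding_correlations(table)


class TestRecoveryOnSimulation:
    def test_froh_tracks_true_ibd_fraction(self, fullsib_sim):
        """Regression of F_ROH on the true autozygous fraction: slope within
        1 +- 0.1, intercept within +-0.03."""
        lenient = fullsib_sim["lenient"]
        ext = GenomeExtent.from_dataset(lenient)
        table = f_roh(fullsib_sim["roh"], ext, sample_ids=lenient.sample_ids)
        ibd = fullsib_sim["truth"].ibd_fraction(lenient.sample_ids)
        slope, intercept = np.polyfit(
            ibd.loc[table.index], table["f_roh_total"], 1
        )
        assert slope == pytest.approx(1.0, abs=0.1)
        assert abs(intercept) < 0.03

    def test_long_class_correlates_more_with_total_than_short_class(self, fullsib_sim):
        """Recent-inbreeding pattern: corr(total, >8 Mb) beats
        corr(total, 1-2 Mb)."""
        lenient = fullsib_sim["lenient"]
        ext = GenomeExtent.from_dataset(lenient)
        table = f_roh(fullsib_sim["roh"], ext, sample_ids=lenient.sample_ids)
        c_long = np.corrcoef(table["f_roh_total"], table["f_roh_>8 Mb"])[0, 1]
        c_short = np.corrcoef(table["f_roh_total"], table["f_roh_1-2 Mb"])[0, 1]
        assert c_long > c_short

    def test_full_table_assembles(self, fullsib_sim):
        strict, _ = __import__("runscape").apply_qc(
            fullsib_sim["dataset"], __import__("runscape").QCConfig(track="strict")
        )
        ext = GenomeExtent.from_dataset(fullsib_sim["lenient"])
        table = inbreeding_table(
            strict, fullsib_sim["roh"], fullsib_sim["rohet"], extent=ext
        )
        assert {"f_roh_total", "f_g", "f_exh", "het_coefficient"} <= set(table.columns)
        assert len(table) == strict.n_samples
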