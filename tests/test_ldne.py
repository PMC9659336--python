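"""LD statistics, the Sved-relation inversion and trajectory calibration."""

import numpy as np
import pandas as pd
import pytest

import lowcovpop as lcp
from lowcovpop.core import Genotypes, InputError
from lowcovpop.ldne import (
    LDNe,
    attach_constant_rate_map,
    bootstrap_ne,
    calibrate_trajectory,
    default_c_bins,
    ne_from_ld,
    pairwise_r2,
)
from lowcovpop.wright_fisher import haldane_c_from_cM


def _geno_from_dosages(dosages, cm, chrom="chr1"):
    dosages = np.asarray(dosages, dtype=np.int8)
    n = dosages.shape[1]
    sites = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": (np.asarray(cm) * 1e6 / 2.54).astype(np.int64) + 1,
            "allele_a": "A",
            "allele_b": "T",
            "cm": cm,
        }
    )
    return Genotypes(dosages, sites, [f"s{i}" for i in range(dosages.shape[0])])


class TestPairwiseR2:
    def test_duplicated_locus_has_r2_one_at_c_zero(self):
        rng = np.random.default_rng(81)
        col = rng.integers(0, 3, size=200)
        g = _geno_from_dosages(np.c_[col, col], cm=[1.0, 1.0])
        out = pairwise_r2(g)
        assert len(out) == 1
        assert out["c"][0] == 0.0
        assert out["r2"][0] == pytest.approx(1.0, abs=1e-12)

    def test_perfect_repulsion_has_r2_one(self):
        # haplotypes AB/ba only: dosages at the two loci are perfectly
        # anti-correlated, so r^2 is still 1
        rng = np.random.default_rng(82)
        h = rng.integers(0, 2, size=(400, 1))
        dos = (h[::2] + h[1::2]).astype(int)
        g = _geno_from_dosages(np.c_[dos, 2 - dos], cm=[0.0, 0.5])
        out = pairwise_r2(g)
        assert out["r2"][0] == pytest.approx(1.0, abs=1e-12)

    def test_independent_loci_baseline_near_one_over_n(self):
        """Unlinked loci in a large sample show the 1/n sampling floor."""
        rng = np.random.default_rng(83)
        n_dip, n_loci = 500, 60
        p = rng.uniform(0.2, 0.8, size=n_loci)
        dos = rng.binomial(2, p, size=(n_dip, n_loci))
        # place loci very far apart so c ~ 0.5 but within c_max=0.5 bound
        g = _geno_from_dosages(dos, cm=np.arange(n_loci) * 1_000.0)
        out = pairwise_r2(g, c_max=0.5)
        # dosage-correlation r2 of independent loci has mean ~ 1/n_dip
        expect = 1.0 / n_dip
        se = out["r2"].std(ddof=1) / np.sqrt(len(out))
        assert abs(out["r2"].mean() - expect) < 3 * se

    def test_monomorphic_input_rejected(self):
        g = _geno_from_dosages(np.full((10, 3), 2), cm=[0.0, 0.1, 0.2])
        with pytest.raises(InputError):
            pairwise_r2(g)

    def test_c_from_inverse_haldane(self):
        assert haldane_c_from_cM(0.0) == 0.0
        assert haldane_c_from_cM(1e9) == pytest.approx(0.5)
        assert haldane_c_from_cM(50.0) == pytest.approx((1 - np.exp(-1)) / 2)


class TestNeFromLD:
    def test_closed_form_point(self):
        """r2 = 0.2 at c = 0.01 with no sampling term inverts to Ne = 100 at
        t = 50 generations."""
        n_hap = 10**9  # effectively infinite sample
        pairs = pd.DataFrame({"c": [0.01] * 30, "r2": [0.2] * 30})
        bins = np.array([0.009, 0.011])
        traj = ne_from_ld(pairs, n_hap, c_bins=bins)
        assert traj.table["ne"][0] == pytest.approx(100.0, rel=1e-6)
        assert traj.table["t_generations"][0] == pytest.approx(50.0)

    def test_analytic_inversion_recovers_ne_everywhere(self):
        """Pairs generated exactly from 1/(1+4Nc) + 1/n invert to N with
        1e-9 relative error in every bin."""
        n_true, n_hap = 350.0, 200
        bins = default_c_bins()
        centers = np.sqrt(bins[:-1] * bins[1:])
        rows = []
        for c in centers:
            r2 = 1.0 / (1.0 + 4.0 * n_true * c) + 1.0 / n_hap
            rows += [{"c": c, "r2": r2}] * 30
        traj = ne_from_ld(pd.DataFrame(rows), n_hap)
        np.testing.assert_allclose(traj.table["ne"], n_true, rtol=1e-9)

    def test_bins_below_sampling_floor_dropped(self):
        n_hap = 100
        pairs = pd.DataFrame({"c": [0.01] * 30, "r2": [0.9 / n_hap] * 30})
        with pytest.warns(UserWarning):
            with pytest.raises(InputError):
                ne_from_ld(pairs, n_hap, c_bins=np.array([0.009, 0.011]))

    def test_t_increases_as_c_decreases(self):
        n_hap = 1_000
        rows = []
        for c in [0.2, 0.05, 0.01, 0.002]:
            rows += [{"c": c, "r2": 1.0 / (1.0 + 4 * 100 * c) + 1.0 / n_hap}] * 30
        traj = ne_from_ld(pd.DataFrame(rows), n_hap)
        t = traj.table["t_generations"].to_numpy()
        c = traj.table["c"].to_numpy()
        assert (np.diff(t) > 0).all()
        assert (np.diff(c) < 0).all()


class TestBootstrap:
    @pytest.fixture(scope="class")
    def wf_genotypes(self):
        from lowcovpop.wright_fisher import PopulationModel, simulate_wright_fisher

        model = PopulationModel(
            ne_trajectory=[(0, 150), (250, 150)], n_loci=400,
            chromosome_length_bp=int(100 / 2.54 * 1e6), seed=84,
        )
        return simulate_wright_fisher(model, 75)

    def test_single_iteration_equals_plain_estimate(self, wf_genotypes):
        traj1 = LDNe(wf_genotypes).fit(n_boot=1)
        pairs = pairwise_r2(wf_genotypes)
        traj2 = ne_from_ld(pairs, 2 * wf_genotypes.n_individuals)
        pd.testing.assert_frame_equal(traj1.table, traj2.table)

    def test_geometric_mean_at_most_arithmetic_mean(self, wf_genotypes):
        traj = bootstrap_ne(wf_genotypes, n_boot=6, snps_per_chromosome=250, seed=85)
        # recompute per-iteration estimates and compare aggregations per bin
        assert (traj.table["ne"] > 0).all()
        assert (traj.table["lo"] <= traj.table["hi"]).all()
        # AM-GM: the stored gmean must not exceed the midpoint-free arithmetic
        # mean reconstructed from percentile-spanned samples is not available;
        # assert against a direct recomputation instead
        from lowcovpop.core import derive_rng

        per_iter = []
        bins = default_c_bins()
        for it in range(6):
            rng = derive_rng(85, it)
            idx = np.sort(rng.choice(wf_genotypes.n_sites, size=250, replace=False))
            sub = wf_genotypes.subset_sites(idx)
            import warnings as _w

            with _w.catch_warnings():
                _w.simplefilter("ignore")
                t = ne_from_ld(pairwise_r2(sub), 2 * wf_genotypes.n_individuals, bins)
            df = t.table.copy()
            df["bin"] = np.digitize(df["c"], bins) - 1
            per_iter.append(df)
        allit = pd.concat(per_iter)
        for b, grp in allit.groupby("bin"):
            ne = grp["ne"].to_numpy()
            gmean = np.exp(np.mean(np.log(ne)))
            row = traj.table.loc[
                np.digitize(traj.table["c"], bins) - 1 == b
            ]
            if len(row):
                assert row["ne"].iloc[0] == pytest.approx(gmean, rel=1e-9)
                assert gmean <= ne.mean() + 1e-12

    def test_reproducible(self, wf_genotypes):
        a = bootstrap_ne(wf_genotypes, n_boot=3, snps_per_chromosome=200, seed=86)
        b = bootstrap_ne(wf_genotypes, n_boot=3, snps_per_chromosome=200, seed=86)
        pd.testing.assert_frame_equal(a.table, b.table)


class TestCalibration:
    def _traj(self, t_values, ne=500.0):
        df = pd.DataFrame(
            {"c": 1.0 / (2 * np.asarray(t_values, dtype=float)),
             "t_generations": np.asarray(t_values, dtype=float),
             "ne": ne}
        )
        return lcp.NeTrajectory(df, n_haplotypes=100)

    def test_confidence_boundary_600_and_400_years(self):
        """200-generation horizon maps to 600 years at 3 y/generation
        (autumn spawners) and 400 years at 2 y/generation (spring)."""
        traj = self._traj([10, 100, 250])
        aut = calibrate_trajectory(traj, 3.0, 2010)
        spr = calibrate_trajectory(traj, 2.0, 2010)
        assert aut.metadata["confidence_horizon_years"] == 600
        assert spr.metadata["confidence_horizon_years"] == 400
        assert bool(aut.table["low_confidence"].iloc[-1]) is True
        assert bool(aut.table["low_confidence"].iloc[0]) is False

    def test_trim_zero_is_identity_on_points(self):
        traj = self._traj([2, 10, 50])
        cal = calibrate_trajectory(traj, 3.0, 2000, trim_recent=0)
        assert len(cal.table) == 3
        np.testing.assert_allclose(cal.table["ne"], traj.table["ne"])

    def test_recent_generations_trimmed(self):
        traj = self._traj([1, 2, 3, 4, 10, 50])
        cal = calibrate_trajectory(traj, 2.0, 2000, trim_recent=4)
        assert list(cal.table["t_generations"]) == [10, 50]

    def test_years_multiply_generations(self):
        traj = self._traj([100])
        cal = calibrate_trajectory(traj, 2.0, 2010, trim_recent=0)
        assert cal.table["years_before_sampling"][0] == pytest.approx(200.0)
        assert cal.table["calendar_year"][0] == pytest.approx(1810.0)

    def test_ne_values_untouched(self):
        traj = self._traj([10, 20, 40], ne=123.456)
        cal = calibrate_trajectory(traj, 3.0, 1990)
        np.testing.assert_allclose(cal.table["ne"], 123.456)

    def test_summary_mentions_calibration(self):
        cal = calibrate_trajectory(self._traj([10, 100]), 3.0, 2005)
        s = cal.summary()
        assert "sampling year 2005" in s
        assert "600" in s
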