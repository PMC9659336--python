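"""Windowed diversity, kinship and ROH detection/dating."""

import itertools

import numpy as np
import pandas as pd
import pytest

import lowcovpop as lcp
from lowcovpop.core import Genotypes, InputError
from lowcovpop.popgen import (
    date_and_bin_roh,
    detect_roh,
    expected_roh_length_cM,
    roh_age_generations,
    windowed_pi,
)


def _geno(dosages, positions, chrom="chr1", labels=None, cm=None):
    dosages = np.asarray(dosages, dtype=np.int8)
    sites = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": np.asarray(positions, dtype=np.int64),
            "allele_a": "A",
            "allele_b": "T",
        }
    )
    if cm is not None:
        sites["cm"] = cm
    samples = [f"s{i}" for i in range(dosages.shape[0])]
    return Genotypes(dosages, sites, samples, labels)


class TestWindowedPi:
    def test_two_haplotypes_single_difference(self):
        m = np.array([[0], [1]])
        out = windowed_pi(m, [5_000], window_bp=100_000, ploidy=1)
        assert len(out) == 1
        assert out["pi"][0] == pytest.approx(1e-5, abs=1e-18)

    def test_identical_sequences_zero_everywhere(self):
        m = np.ones((6, 30), dtype=int)
        out = windowed_pi(m, np.arange(1, 31) * 10_000, window_bp=100_000, ploidy=1)
        assert (out["pi"] == 0).all()

    def test_matches_brute_force_all_pairs(self):
        """Windowed pi equals the all-pairs Hamming average per site."""
        rng = np.random.default_rng(71)
        n_hap, n_sites, w = 10, 50, 1_000
        m = rng.integers(0, 2, size=(n_hap, n_sites))
        pos = np.sort(rng.choice(np.arange(1, 5_001), size=n_sites, replace=False))
        out = windowed_pi(m, pos, window_bp=w, ploidy=1)

        brute = np.zeros(len(out))
        n_pairs = n_hap * (n_hap - 1) // 2
        for j in range(n_sites):
            diffs = sum(
                int(m[a, j] != m[b, j]) for a, b in itertools.combinations(range(n_hap), 2)
            )
            brute[(pos[j] - 1) // w] += diffs / n_pairs
        brute /= w
        np.testing.assert_allclose(out["pi"], brute, atol=1e-12)

    def test_diploid_dosages_equal_expanded_haplotypes(self):
        """Per-site pair differences depend only on allele counts, so diploid
        dosage input must agree with any phasing of the same counts."""
        rng = np.random.default_rng(72)
        dos = rng.integers(0, 3, size=(5, 40))
        pos = np.arange(1, 41) * 100
        out_d = windowed_pi(dos, pos, window_bp=10_000, ploidy=2)
        haps = np.zeros((10, 40), dtype=int)
        for i in range(5):
            haps[2 * i] = (dos[i] >= 1).astype(int)
            haps[2 * i + 1] = (dos[i] == 2).astype(int)
        out_h = windowed_pi(haps, pos, window_bp=10_000, ploidy=1)
        np.testing.assert_allclose(out_d["pi"], out_h["pi"], atol=1e-12)

    def test_invariant_to_individual_permutation_and_allele_relabeling(self):
        rng = np.random.default_rng(73)
        m = rng.integers(0, 2, size=(8, 25))
        pos = np.arange(1, 26) * 1_000
        base = windowed_pi(m, pos, ploidy=1)["pi"]
        perm = windowed_pi(m[rng.permutation(8)], pos, ploidy=1)["pi"]
        flip = windowed_pi(1 - m, pos, ploidy=1)["pi"]
        np.testing.assert_allclose(base, perm, atol=1e-15)
        np.testing.assert_allclose(base, flip, atol=1e-15)


class TestKinship:
    def test_self_kinship_is_half(self):
        rng = np.random.default_rng(74)
        g = _geno(rng.integers(0, 3, size=(3, 500)), np.arange(1, 501) * 10)
        assert lcp.kinship(g, 0, 0) == pytest.approx(0.5)

    def test_symmetric(self):
        rng = np.random.default_rng(75)
        g = _geno(rng.integers(0, 3, size=(4, 300)), np.arange(1, 301) * 10)
        assert lcp.kinship(g, 1, 3) == lcp.kinship(g, 3, 1)

    def test_unrelated_individuals_near_zero(self):
        truth = lcp.simulate_divergent_populations(10_000, 0.0, seed=76)
        # keep frequencies away from fixation so heterozygotes are common
        truth.freq_pop_a[:] = np.clip(truth.freq_pop_a, 0.2, 0.8)
        truth.freq_pop_b[:] = truth.freq_pop_a
        g = lcp.sample_genotypes(truth, 2, seed=77)
        phi = lcp.kinship(g, 0, 1)
        assert abs(phi) < 0.02

    def test_parent_offspring_quarter(self):
        rng = np.random.default_rng(78)
        n = 10_000
        p = rng.uniform(0.2, 0.8, size=n)
        pa = rng.binomial(1, p, size=(2, n))  # parent A's two haplotypes
        pb = rng.binomial(1, p, size=(2, n))
        child = pa[rng.integers(0, 2, size=n), np.arange(n)] + pb[
            rng.integers(0, 2, size=n), np.arange(n)
        ]
        dos = np.vstack([pa.sum(axis=0), pb.sum(axis=0), child])
        g = _geno(dos, np.arange(1, n + 1) * 10)
        assert lcp.kinship(g, 0, 2) == pytest.approx(0.25, abs=0.03)
        assert lcp.kinship(g, 1, 2) == pytest.approx(0.25, abs=0.03)


class TestDetectROH:
    def _background(self, rng, n_sites, het_rate=0.3):
        """One diploid with the given background heterozygosity."""
        dos = np.where(rng.random(n_sites) < het_rate, 1, 2 * rng.integers(0, 2, n_sites))
        return dos

    def test_fully_heterozygous_individual_has_no_segments(self):
        g = _geno(np.ones((1, 300)), np.arange(1, 301) * 1_000)
        seg = detect_roh(g, window_snps=50, max_het_per_window=1, min_length_bp=10_000)
        assert len(seg) == 0

    def test_fully_homozygous_chromosome_is_one_segment(self):
        pos = np.arange(1, 501) * 1_000  # 500 kb
        g = _geno(np.full((1, 500), 2), pos)
        seg = detect_roh(g, window_snps=50, max_het_per_window=1, min_length_bp=100_000)
        assert len(seg) == 1
        assert seg["start"][0] == pos[0]
        assert seg["end"][0] == pos[-1]

    def test_unsorted_positions_rejected(self):
        g = _geno(np.full((1, 60), 2), np.r_[np.arange(30, 60), np.arange(0, 30)] * 100 + 1)
        with pytest.raises(InputError):
            detect_roh(g, window_snps=10)

    def test_segments_disjoint_per_individual(self):
        rng = np.random.default_rng(79)
        dos = np.array([self._background(rng, 3_000, het_rate=0.12)])
        g = _geno(dos, np.arange(1, 3_001) * 500)
        seg = detect_roh(g, window_snps=25, max_het_per_window=1, min_length_bp=10_000)
        for _, grp in seg.groupby(["individual", "chrom"]):
            s = grp.sort_values("start")
            assert (s["start"].values[1:] > s["end"].values[:-1]).all()

    def test_planted_tract_recovered(self):
        """A 200-kb homozygous tract in a 30%-heterozygous background is found
        with boundary error under one window span in >= 45/50 replicates."""
        hits = 0
        window_snps = 50
        snp_spacing = 1_000
        for rep in range(50):
            rng = np.random.default_rng(1_000 + rep)
            n_sites = 1_000  # 1 Mb at 1 SNP/kb
            dos = self._background(rng, n_sites, het_rate=0.3)
            tract = slice(400, 600)  # 200 kb
            dos[tract] = 2 * rng.integers(0, 2, 200)
            g = _geno(np.array([dos]), np.arange(1, n_sites + 1) * snp_spacing)
            seg = detect_roh(
                g, window_snps=window_snps, max_het_per_window=1, min_length_bp=50_000
            )
            if len(seg) != 1:
                continue
            span = window_snps * snp_spacing
            start_err = abs(int(seg["start"][0]) - 400 * snp_spacing)
            end_err = abs(int(seg["end"][0]) - 600 * snp_spacing)
            if start_err < span and end_err < span:
                hits += 1
        assert hits >= 45


class TestDating:
    def test_formula_arithmetic(self):
        seg = pd.DataFrame(
            {"individual": ["i"], "chrom": ["c"], "start": [1], "end": [2],
             "length_bp": [2], "length_cM": [1.0]}
        )
        dated, _ = date_and_bin_roh(seg, generation_time_years=2.0)
        assert dated["age_generations"][0] == pytest.approx(50.0)
        assert dated["age_years"][0] == pytest.approx(100.0)

    def test_100kb_segment_at_herring_rate_dates_to_older_bin(self):
        """100 kb at 2.54 cM/Mb with 3-year generations: ~196.85 generations,
        ~590.6 years, falling in the 650-400 bin."""
        seg = pd.DataFrame(
            {"individual": ["i"], "chrom": ["c"], "start": [1], "end": [100_000],
             "length_bp": [100_000]}
        )
        dated, summary = date_and_bin_roh(seg, generation_time_years=3.0)
        assert dated["length_cM"][0] == pytest.approx(0.254)
        assert dated["age_generations"][0] == pytest.approx(196.85, abs=0.01)
        assert dated["age_years"][0] == pytest.approx(590.55, abs=0.01)
        assert dated["bin"][0] == "650-400"
        assert summary.loc[summary["bin"] == "650-400", "n_segments"].iloc[0] == 1

    def test_longer_segments_date_younger(self):
        lengths = np.array([0.1, 0.5, 1.0, 5.0])
        ages = roh_age_generations(lengths)
        assert (np.diff(ages) < 0).all()

    def test_round_trip_exact(self):
        g = np.array([7.3, 50.0, 196.8503937])
        np.testing.assert_allclose(
            roh_age_generations(expected_roh_length_cM(g)), g, rtol=1e-12
        )

    def test_bin_edge_goes_to_younger_bin(self):
        # a segment dated exactly 400 years must land in the 400-200 bin
        gen_time = 2.0
        g = 400.0 / gen_time
        seg = pd.DataFrame(
            {"individual": ["i"], "chrom": ["c"], "start": [1], "end": [2],
             "length_bp": [2], "length_cM": [expected_roh_length_cM(g)]}
        )
        dated, _ = date_and_bin_roh(seg, generation_time_years=gen_time)
        assert dated["age_years"][0] == pytest.approx(400.0, abs=1e-9)
        assert dated["bin"][0] == "400-200"
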