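"""Window-based diversity, pairwise kinship, and runs of homozygosity with
coalescent dating.

Nucleotide diversity is the classical per-site average pairwise difference
accumulated in fixed physical windows. Kinship is the robust within-population
estimator built from heterozygote and opposite-homozygote counts. ROH
detection is a SNP-count sliding window; each called segment's genetic length
L (cM) implies the age of the underlying coalescent event through
g = 100 / (2 L) generations, and dated segments are binned into
years-before-present intervals.
"""

from __future__ import annotations

import warnings
from math import comb

import numpy as np
import pandas as pd

from .core import Genotypes, InputError
from .wright_fisher import HERRING_RECOMBINATION_CM_PER_MB

DEFAULT_WINDOW_BP = 100_000

#: ROH caller defaults: 50-SNP windows tolerating one heterozygote, and a
#: 50 kb floor on reported segments.
DEFAULT_ROH_WINDOW_SNPS = 50
DEFAULT_ROH_MAX_HET = 1
DEFAULT_ROH_MIN_LENGTH_BP = 50_000

#: Default years-before-present bins for dated ROH segments
#: (older bound inclusive, younger bound exclusive).
DEFAULT_ROH_BINS = ((650.0, 400.0), (400.0, 200.0))


def _pi_counts(matrix: np.ndarray, ploidy: int) -> tuple[np.ndarray, np.ndarray]:
    """Per-site haplotype totals and alternate counts from a call matrix."""
    m = np.asarray(matrix)
    called = m >= 0
    if ploidy == 1:
        n_hap = called.sum(axis=0)
        n_alt = np.where(called, m, 0).sum(axis=0)
    elif ploidy == 2:
        n_hap = 2 * called.sum(axis=0)
        n_alt = np.where(called, m, 0).sum(axis=0)
    else:
        raise InputError("ploidy must be 1 or 2")
    return n_hap.astype(np.int64), n_alt.astype(np.int64)


def windowed_pi(
    matrix: np.ndarray,
    positions: np.ndarray,
    window_bp: int = DEFAULT_WINDOW_BP,
    ploidy: int = 2,
    chrom: str = "chr1",
) -> pd.DataFrame:
    """Nucleotide diversity per fixed window along one chromosome.

    Parameters
    ----------
    matrix
        ``(n_individuals, n_sites)`` calls: 0/1 haplotypes (``ploidy=1``) or
        0/1/2 diploid dosages (``ploidy=2``); -1 is missing.
    positions
        1-based site positions, one per matrix column.
    window_bp
        Window width; windows tile ``[k*w, (k+1)*w)`` in 0-based half-open
        coordinates, so 1-based position p falls in window ``(p-1) // w``.

    Per window, pi is the sum over sites of the fraction of haplotype pairs
    differing at that site — ``n_ref * n_alt / C(n, 2)`` — divided by the
    window width, so monomorphic (and absent) sites contribute zero.
    """
    if window_bp < 1:
        raise InputError("window_bp must be >= 1")
    positions = np.asarray(positions, dtype=np.int64)
    if len(positions) != np.asarray(matrix).shape[1]:
        raise InputError("one position per site column required")
    n_hap, n_alt = _pi_counts(matrix, ploidy)
    if np.all(n_hap < 2):
        raise InputError("need at least one site with two called haplotypes")

    usable = n_hap >= 2
    pairs = n_hap * (n_hap - 1) // 2
    with np.errstate(invalid="ignore", divide="ignore"):
        site_pi = np.where(usable, n_alt * (n_hap - n_alt) / np.where(usable, pairs, 1), 0.0)

    win = (positions - 1) // window_bp
    n_windows = int(win.max()) + 1 if len(win) else 0
    pi = np.zeros(n_windows)
    np.add.at(pi, win, site_pi)
    pi /= window_bp
    starts = np.arange(n_windows, dtype=np.int64) * window_bp
    return pd.DataFrame(
        {"chrom": chrom, "start": starts, "end": starts + window_bp, "pi": pi}
    )


def windowed_pi_genotypes(geno: Genotypes, window_bp: int = DEFAULT_WINDOW_BP) -> pd.DataFrame:
    """Windowed diversity for a diploid genotype container, per chromosome."""
    out = []
    for chrom, idx in geno.sites.groupby("chrom", sort=True).groups.items():
        idx = np.asarray(idx)
        out.append(
            windowed_pi(
                geno.dosages[:, idx],
                geno.sites["pos"].to_numpy()[idx],
                window_bp=window_bp,
                ploidy=2,
                chrom=str(chrom),
            )
        )
    return pd.concat(out, ignore_index=True)


def kinship(geno: Genotypes, i: int | str, j: int | str) -> float:
    """Robust pairwise kinship coefficient from biallelic genotypes.

    phi = (N_het,het - 2 N_opp_hom) / (N_het(i) + N_het(j)) over sites where
    both individuals are called. Self-comparison gives exactly 0.5; unrelated
    individuals from one population at Hardy-Weinberg give ~0;
    parent-offspring pairs give ~0.25. NaN when the denominator is zero.
    """
    a = geno.dosages[geno.sample_index(i)]
    b = geno.dosages[geno.sample_index(j)]
    called = (a >= 0) & (b >= 0)
    if not called.any():
        raise InputError("no jointly called site for this pair")
    a, b = a[called], b[called]
    het_a = a == 1
    het_b = b == 1
    opp = ((a == 0) & (b == 2)) | ((a == 2) & (b == 0))
    denom = int(het_a.sum() + het_b.sum())
    if denom == 0:
        return float("nan")
    return float((int((het_a & het_b).sum()) - 2 * int(opp.sum())) / denom)


def kinship_matrix(geno: Genotypes) -> pd.DataFrame:
    """Symmetric matrix of pairwise kinship coefficients."""
    n = geno.n_individuals
    phi = np.full((n, n), np.nan)
    for i in range(n):
        for j in range(i, n):
            phi[i, j] = phi[j, i] = kinship(geno, i, j)
    return pd.DataFrame(phi, index=geno.samples, columns=geno.samples)


def detect_roh(
    geno: Genotypes,
    window_snps: int = DEFAULT_ROH_WINDOW_SNPS,
    max_het_per_window: int = DEFAULT_ROH_MAX_HET,
    min_length_bp: int = DEFAULT_ROH_MIN_LENGTH_BP,
) -> pd.DataFrame:
    """Runs of homozygosity per individual via a SNP-count sliding window.

    Every window of ``window_snps`` consecutive SNPs with at most
    ``max_het_per_window`` heterozygous calls is flagged; overlapping flagged
    windows merge, merged runs shorter than ``min_length_bp`` are dropped, and
    segments never span chromosomes. Missing calls count as non-heterozygous
    (they neither break nor shorten a run). Chromosomes with fewer SNPs than
    one window are skipped.

    Returns a DataFrame with columns ``individual, chrom, start, end,
    length_bp`` (1-based inclusive bounds at the first/last SNP of the run).
    """
    rows = []
    for chrom, idx in geno.sites.groupby("chrom", sort=True).groups.items():
        idx = np.asarray(idx)
        pos = geno.sites["pos"].to_numpy()[idx]
        if np.any(np.diff(pos) < 0):
            raise InputError(f"positions on {chrom} are not sorted")
        if len(idx) < window_snps:
            continue
        het = (geno.dosages[:, idx] == 1).astype(np.int32)
        # sliding het counts over windows [k, k + window_snps)
        cums = np.concatenate(
            [np.zeros((het.shape[0], 1), dtype=np.int32), np.cumsum(het, axis=1)], axis=1
        )
        counts = cums[:, window_snps:] - cums[:, :-window_snps]
        flagged = counts <= max_het_per_window
        for ii, sample in enumerate(geno.samples):
            hits = np.nonzero(flagged[ii])[0]
            if len(hits) == 0:
                continue
            # windows k and k' share SNPs iff |k - k'| < window_snps, so any
            # gap smaller than the window size keeps the run going
            breaks = np.nonzero(np.diff(hits) >= window_snps)[0]
            starts = hits[np.concatenate([[0], breaks + 1])]
            ends = hits[np.concatenate([breaks, [len(hits) - 1]])]
            for s, e in zip(starts, ends):
                lo = int(pos[s])
                hi = int(pos[e + window_snps - 1])
                length = hi - lo + 1
                if length >= min_length_bp:
                    rows.append(
                        {
                            "individual": sample,
                            "chrom": str(chrom),
                            "start": lo,
                            "end": hi,
                            "length_bp": length,
                        }
                    )
    return pd.DataFrame(rows, columns=["individual", "chrom", "start", "end", "length_bp"])


def roh_age_generations(length_cM: np.ndarray | float) -> np.ndarray | float:
    """Implied age (generations) of the coalescent event behind a segment of
    genetic length L: g = 100 / (2 L)."""
    return 100.0 / (2.0 * np.asarray(length_cM, dtype=float))


def expected_roh_length_cM(generations: np.ndarray | float) -> np.ndarray | float:
    """Inverse of :func:`roh_age_generations`: L = 100 / (2 g) cM."""
    return 100.0 / (2.0 * np.asarray(generations, dtype=float))


def date_and_bin_roh(
    segments: pd.DataFrame,
    generation_time_years: float,
    recombination_rate_cM_per_Mb: float = HERRING_RECOMBINATION_CM_PER_MB,
    bins: tuple[tuple[float, float], ...] = DEFAULT_ROH_BINS,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Date each segment and bin it into years-before-present intervals.

    Physical length converts to genetic length at the constant rate unless a
    ``length_cM`` column is already present. A segment of L cM implies
    g = 100/(2L) generations and g * generation_time years. A bin
    ``(older, younger)`` is half-open: it contains y with younger < y <=
    older, so a segment dated exactly at a shared edge falls in the younger
    bin. Segments outside all bins are labelled ``outside``.

    Returns (dated segments, per-bin summary with counts and summed lengths).
    """
    if generation_time_years <= 0:
        raise InputError("generation_time_years must be positive")
    seg = segments.copy()
    if "length_cM" not in seg.columns:
        seg["length_cM"] = seg["length_bp"] * recombination_rate_cM_per_Mb / 1e6
    zero = seg["length_cM"] <= 0
    if zero.any():
        warnings.warn(f"skipping {int(zero.sum())} zero-length segment(s)")
        seg = seg.loc[~zero].reset_index(drop=True)
    seg["age_generations"] = roh_age_generations(seg["length_cM"].to_numpy())
    seg["age_years"] = seg["age_generations"] * generation_time_years

    def _bin_label(years: float) -> str:
        for older, younger in bins:
            if younger < years <= older:
                return f"{older:g}-{younger:g}"
        return "outside"

    seg["bin"] = [_bin_label(y) for y in seg["age_years"]]
    summary = (
        seg.groupby("bin", sort=False)
        .agg(
            n_segments=("bin", "size"),
            total_length_bp=("length_bp", "sum"),
            total_length_cM=("length_cM", "sum"),
        )
        .reset_index()
    )
    order = [f"{o:g}-{y:g}" for o, y in bins] + ["outside"]
    summary["bin"] = pd.Categorical(summary["bin"], categories=order, ordered=True)
    summary = summary.sort_values("bin").reset_index(drop=True)
    return seg, summary
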