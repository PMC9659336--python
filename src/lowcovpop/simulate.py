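"""Synthetic truth generators: divergent populations, diploid genotypes and
ultra-low-coverage read observations with sequencing error and post-mortem
damage.

The generators produce every input the assignment pipeline consumes with the
ground truth attached, so classification accuracy can be measured exactly.
The read model is deliberately site-level: a specimen's genome-wide aligned
reads hit a diagnostic panel with probability (panel footprint / genome
size); only the panel-hitting reads are materialised as records. Post-mortem
deamination is modelled as a per-observation C->T (and complementary G->A)
substitution, the way it looks to per-site allele counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import (
    BASES,
    ConfigurationError,
    Genotypes,
    InputError,
    ReadObservations,
    derive_rng,
    empty_records,
)

#: Herring-scale nuclear genome size used to convert total aligned reads into
#: expected panel hits.
DEFAULT_GENOME_SIZE_BP = 726_000_000

#: Read length used only for the panel footprint; typical of degraded
#: ancient-DNA libraries.
DEFAULT_READ_LENGTH_BP = 60


@dataclass
class TwoPopTruth:
    """Known per-SNP allele frequencies for a binary population contrast.

    ``freq_pop_a``/``freq_pop_b`` are the frequencies of ``allele_a`` (as
    listed in ``sites``) in each population.
    """

    sites: pd.DataFrame  # chrom, pos, allele_a, allele_b
    freq_pop_a: np.ndarray
    freq_pop_b: np.ndarray
    labels: tuple[str, str] = ("group1", "group2")

    def __post_init__(self) -> None:
        self.freq_pop_a = np.asarray(self.freq_pop_a, dtype=float)
        self.freq_pop_b = np.asarray(self.freq_pop_b, dtype=float)
        n = len(self.sites)
        if len(self.freq_pop_a) != n or len(self.freq_pop_b) != n:
            raise InputError("frequency vectors must match the site table length")
        for f in (self.freq_pop_a, self.freq_pop_b):
            if np.any((f < 0) | (f > 1)):
                raise InputError("allele frequencies must lie in [0, 1]")

    @property
    def n_snps(self) -> int:
        return len(self.sites)

    @property
    def delta_p(self) -> np.ndarray:
        return np.abs(self.freq_pop_a - self.freq_pop_b)


def _draw_delta_p(spec, n: int, rng: np.random.Generator) -> np.ndarray:
    """Per-SNP |delta p| values from a distribution spec.

    Accepts a fixed float, a ``("uniform", lo, hi)`` tuple, or any object
    with an ``rvs(size, random_state)`` method (scipy frozen distributions).
    """
    if isinstance(spec, (int, float)):
        d = np.full(n, float(spec))
    elif isinstance(spec, tuple) and len(spec) == 3 and spec[0] == "uniform":
        lo, hi = float(spec[1]), float(spec[2])
        if not (0.0 <= lo <= hi <= 1.0):
            raise ConfigurationError("uniform delta_p bounds must satisfy 0 <= lo <= hi <= 1")
        d = rng.uniform(lo, hi, size=n)
    elif hasattr(spec, "rvs"):
        d = np.asarray(spec.rvs(size=n, random_state=rng), dtype=float)
    else:
        raise ConfigurationError(f"unrecognised delta_p spec: {spec!r}")
    if np.any((d < 0) | (d > 1)):
        raise ConfigurationError("delta_p values must lie in [0, 1]")
    return d


def simulate_divergent_populations(
    n_snps: int,
    delta_p,
    seed: int,
    labels: tuple[str, str] = ("group1", "group2"),
    chrom: str = "chr1",
    pos_span_bp: int | None = None,
) -> TwoPopTruth:
    """Two populations whose allele-frequency differentials follow ``delta_p``.

    For each SNP a differential d is drawn from ``delta_p``, a base frequency
    u ~ Uniform(0, 1 - d) places the pair (u + d, u) inside [0, 1], and a fair
    coin decides which population carries the higher frequency. SNP positions
    are distinct uniform draws on ``[1, pos_span_bp]`` (default 10 kb per SNP).
    """
    if n_snps < 1:
        raise ConfigurationError("n_snps must be >= 1")
    rng = derive_rng(seed)
    d = _draw_delta_p(delta_p, n_snps, rng)
    u = rng.uniform(0.0, 1.0 - d)
    hi, lo = u + d, u
    swap = rng.random(n_snps) < 0.5
    freq_a = np.where(swap, lo, hi)
    freq_b = np.where(swap, hi, lo)

    span = pos_span_bp if pos_span_bp is not None else max(n_snps * 10_000, 1_000)
    pos = np.sort(rng.choice(np.arange(1, span + 1), size=n_snps, replace=False))
    allele_a_idx = rng.integers(0, 4, size=n_snps)
    allele_b_idx = (allele_a_idx + rng.integers(1, 4, size=n_snps)) % 4
    sites = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": pos.astype(np.int64),
            "allele_a": BASES[allele_a_idx],
            "allele_b": BASES[allele_b_idx],
        }
    )
    return TwoPopTruth(sites, freq_a, freq_b, tuple(labels))


def sample_genotypes(
    truth: TwoPopTruth, n_per_pop: int, seed: int, prefix: str = "ind"
) -> Genotypes:
    """Diploid Hardy-Weinberg genotypes from the truth frequencies.

    Returns ``2 * n_per_pop`` individuals labelled with the truth's population
    names; dosages count copies of ``allele_a``.
    """
    if n_per_pop < 1:
        raise ConfigurationError("n_per_pop must be >= 1")
    rng = derive_rng(seed)
    dos_a = rng.binomial(2, truth.freq_pop_a, size=(n_per_pop, truth.n_snps))
    dos_b = rng.binomial(2, truth.freq_pop_b, size=(n_per_pop, truth.n_snps))
    dosages = np.vstack([dos_a, dos_b]).astype(np.int8)
    la, lb = truth.labels
    samples = [f"{prefix}_{la}_{i}" for i in range(n_per_pop)] + [
        f"{prefix}_{lb}_{i}" for i in range(n_per_pop)
    ]
    labels = np.array([la] * n_per_pop + [lb] * n_per_pop)
    return Genotypes(dosages, truth.sites.copy(), samples, labels)


_DAMAGE = {"C": "T", "G": "A"}


def simulate_reads(
    genotypes: Genotypes,
    individual: int | str,
    total_reads: int,
    genome_size_bp: int = DEFAULT_GENOME_SIZE_BP,
    read_length_bp: int = DEFAULT_READ_LENGTH_BP,
    error_rate: float = 0.0,
    damage_rate: float = 0.0,
    seed: int = 0,
    specimen: str | None = None,
) -> ReadObservations:
    """Genome-wide low-coverage reads reduced to their panel-site observations.

    The number of reads overlapping any panel site is Binomial(total_reads,
    footprint / genome_size) with footprint = n_sites * read_length_bp. Each
    hit lands on a uniformly chosen panel site and observes one of the
    individual's two alleles; with probability ``error_rate`` the base is
    replaced by a uniformly chosen different base, then C->T / G->A damage is
    applied with probability ``damage_rate``.
    """
    if total_reads < 0:
        raise ConfigurationError("total_reads must be >= 0")
    for name, r in (("error_rate", error_rate), ("damage_rate", damage_rate)):
        if not (0.0 <= r < 1.0):
            raise ConfigurationError(f"{name} must lie in [0, 1)")
    footprint = genotypes.n_sites * read_length_bp
    if footprint > genome_size_bp:
        raise ConfigurationError("panel footprint exceeds genome size")

    i = genotypes.sample_index(individual)
    name = specimen if specimen is not None else genotypes.samples[i]
    rng = derive_rng(seed)
    n_hits = rng.binomial(total_reads, footprint / genome_size_bp) if total_reads else 0
    if n_hits == 0:
        return ReadObservations(name, empty_records(), total_reads)

    site_idx = rng.integers(0, genotypes.n_sites, size=n_hits)
    dos = genotypes.dosages[i, site_idx].astype(float)
    called = dos >= 0
    site_idx, dos = site_idx[called], dos[called]
    is_a = rng.random(len(site_idx)) < dos / 2.0
    sites = genotypes.sites
    base = np.where(
        is_a,
        sites["allele_a"].to_numpy()[site_idx],
        sites["allele_b"].to_numpy()[site_idx],
    ).astype(object)

    if error_rate > 0.0 and len(base):
        err = rng.random(len(base)) < error_rate
        if err.any():
            # replace by one of the three other bases, uniformly
            shift = rng.integers(1, 4, size=int(err.sum()))
            cur = np.searchsorted(BASES, np.asarray(base[err], dtype=str))
            base[err] = BASES[(cur + shift) % 4]
    if damage_rate > 0.0 and len(base):
        dam = rng.random(len(base)) < damage_rate
        for j in np.nonzero(dam)[0]:
            base[j] = _DAMAGE.get(base[j], base[j])

    records = pd.DataFrame(
        {
            "chrom": sites["chrom"].to_numpy()[site_idx],
            "pos": sites["pos"].to_numpy()[site_idx].astype(np.int64),
            "allele": np.asarray(base, dtype=str),
        }
    ).sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)
    return ReadObservations(name, records, total_reads)


def downsample_reads(obs: ReadObservations, target: int, seed: int) -> ReadObservations:
    """Simulate drawing ``target`` of the original total aligned reads.

    Each panel-hit record survives independently with probability
    target / total (binomial thinning); the result's ``total_read_count`` is
    ``min(target, total)``. Downsampling to at least the original total is the
    identity.
    """
    if target < 0:
        raise ConfigurationError("target must be >= 0")
    total = obs.total_read_count
    if target >= total:
        return obs.copy()
    if target == 0 or total == 0:
        return ReadObservations(obs.specimen, empty_records(), target)
    rng = derive_rng(seed)
    keep = rng.random(obs.n_records) < target / total
    records = obs.records.loc[keep].reset_index(drop=True)
    return ReadObservations(obs.specimen, records, target)
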