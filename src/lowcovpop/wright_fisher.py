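"""Forward-in-time Wright-Fisher simulation of diploids with recombination.

Used to generate multi-locus genotypes whose linkage-disequilibrium structure
reflects a specified effective-population-size history, which is the
validation input for the LD-decay Ne estimator. The model is neutral
standing variation only: loci start at draws from a uniform frequency band,
no new mutation enters during the simulated span, and mating is random with
selfing allowed (the classical Wright-Fisher diploid model).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import BASES, ConfigurationError, Genotypes, derive_rng

#: Population-wide recombination rate for Baltic herring, cM per Mb.
HERRING_RECOMBINATION_CM_PER_MB = 2.54


@dataclass
class PopulationModel:
    """Piecewise-constant Ne history plus the chromosome it acts on.

    ``ne_trajectory`` lists ``(generation_before_sampling, Ne)`` change
    points with strictly increasing generations; Ne(g) is the value of the
    largest change point <= g, and the simulated span is the largest listed
    generation. A constant-Ne run of G generations is thus
    ``[(0, Ne), (G, Ne)]``.
    """

    ne_trajectory: list[tuple[int, float]]
    chromosome_length_bp: int = 40_000_000
    recombination_rate_cM_per_Mb: float = HERRING_RECOMBINATION_CM_PER_MB
    n_loci: int = 500
    init_freq_range: tuple[float, float] = (0.05, 0.95)
    seed: int = 0
    chrom: str = "chr1"

    def __post_init__(self) -> None:
        if not self.ne_trajectory:
            raise ConfigurationError("ne_trajectory must be non-empty")
        gens = [g for g, _ in self.ne_trajectory]
        if any(b <= a for a, b in zip(gens, gens[1:])):
            raise ConfigurationError("ne_trajectory generations must be strictly increasing")
        if gens[0] != 0:
            raise ConfigurationError("ne_trajectory must start at generation 0")
        if any(ne <= 1 for _, ne in self.ne_trajectory):
            raise ConfigurationError("Ne values must exceed 1")
        if self.recombination_rate_cM_per_Mb <= 0:
            raise ConfigurationError("recombination rate must be positive")
        if self.chromosome_length_bp <= 0:
            raise ConfigurationError("chromosome length must be positive")
        if self.n_loci < 2:
            raise ConfigurationError("at least 2 loci required")

    @property
    def span_generations(self) -> int:
        return self.ne_trajectory[-1][0]

    def ne_at(self, generation_before_sampling: int) -> int:
        g = generation_before_sampling
        if g < 0 or g > self.span_generations:
            raise ConfigurationError(
                f"generation {g} outside the trajectory span {self.span_generations}"
            )
        ne = self.ne_trajectory[0][1]
        for gen, value in self.ne_trajectory:
            if gen <= g:
                ne = value
            else:
                break
        return int(round(ne))


def _recombinant_gametes(
    haps: np.ndarray, parents: np.ndarray, c_adj: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """One gamete per parent, recombining the parent's two haplotypes.

    ``haps`` is the (2N, L) parental haplotype matrix; ``parents`` indexes
    diploid parents; ``c_adj`` gives the recombination fraction between
    adjacent loci. Crossover state along the chromosome is a Markov chain:
    independent Bernoulli(c) switch indicators between neighbours, resolved
    with a parity scan.
    """
    n, l = len(parents), haps.shape[1]
    switches = rng.random((n, l - 1)) < c_adj
    state = np.empty((n, l), dtype=bool)
    state[:, 0] = rng.integers(0, 2, size=n, dtype=np.uint8).astype(bool)
    parity = np.cumsum(switches, axis=1, dtype=np.int32) & 1
    state[:, 1:] = state[:, [0]] ^ parity.astype(bool)
    hap_a = haps[2 * parents]
    hap_b = haps[2 * parents + 1]
    return np.where(state, hap_b, hap_a)


def haldane_c_from_cM(d_cM: np.ndarray | float) -> np.ndarray | float:
    """Recombination fraction from genetic distance (inverse Haldane map)."""
    return 0.5 * (1.0 - np.exp(-2.0 * np.asarray(d_cM, dtype=float) / 100.0))


def simulate_wright_fisher(
    model: PopulationModel, sample_size: int, seed: int | None = None
) -> Genotypes:
    """Simulate the model forward and genotype ``sample_size`` individuals.

    Loci sit at distinct uniform positions along the chromosome; genetic-map
    positions (``cm`` column of the returned site table) follow the model's
    constant rate. The simulation runs from the oldest change point to the
    sampling generation with population size following the trajectory, then
    samples individuals without replacement from the final generation.
    """
    min_ne = min(int(round(ne)) for _, ne in model.ne_trajectory)
    if sample_size > min_ne:
        raise ConfigurationError(
            f"sample_size {sample_size} exceeds the smallest Ne ({min_ne}) in the trajectory"
        )
    span = model.span_generations
    if span < 1:
        raise ConfigurationError(
            "ne_trajectory spans zero generations; add a terminal (span, Ne) entry"
        )
    rng = derive_rng(model.seed if seed is None else seed)

    pos = np.sort(
        rng.choice(np.arange(1, model.chromosome_length_bp + 1), size=model.n_loci, replace=False)
    )
    cm = pos * model.recombination_rate_cM_per_Mb / 1e6
    c_adj = haldane_c_from_cM(np.diff(cm))

    lo, hi = model.init_freq_range
    p0 = rng.uniform(lo, hi, size=model.n_loci)
    n0 = model.ne_at(span)
    haps = rng.random((2 * n0, model.n_loci)) < p0

    for g in range(span - 1, -1, -1):
        n_now = model.ne_at(g)
        n_parents = haps.shape[0] // 2
        mothers = rng.integers(0, n_parents, size=n_now)
        fathers = rng.integers(0, n_parents, size=n_now)
        parents = np.empty(2 * n_now, dtype=np.int64)
        parents[0::2] = mothers
        parents[1::2] = fathers
        haps = _recombinant_gametes(haps, parents, c_adj, rng)

    n_final = haps.shape[0] // 2
    chosen = rng.choice(n_final, size=sample_size, replace=False)
    dosages = (haps[2 * chosen].astype(np.int8) + haps[2 * chosen + 1].astype(np.int8))

    allele_a_idx = rng.integers(0, 4, size=model.n_loci)
    allele_b_idx = (allele_a_idx + rng.integers(1, 4, size=model.n_loci)) % 4
    sites = pd.DataFrame(
        {
            "chrom": model.chrom,
            "pos": pos.astype(np.int64),
            "allele_a": BASES[allele_a_idx],
            "allele_b": BASES[allele_b_idx],
            "cm": cm,
        }
    )
    samples = [f"wf_{i}" for i in range(sample_size)]
    return Genotypes(dosages, sites, samples)
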