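"""Shared containers and deterministic seed derivation.

Conventions used throughout the package:

* genomic positions are 1-based (VCF convention); window outputs are
  0-based half-open (BED convention) and say so in their headers;
* diploid genotypes are stored as dosages of ``allele_a`` in {0, 1, 2},
  with -1 marking a missing call;
* every stochastic operation takes an integer seed and is bit-reproducible
  given (inputs, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

BASES = np.array(["A", "C", "G", "T"])

SITE_COLUMNS = ["chrom", "pos", "allele_a", "allele_b"]


class InputError(ValueError):
    """Invalid data handed to an operation."""


class ConfigurationError(ValueError):
    """Invalid parameter combination."""


class FormatError(ValueError):
    """Malformed file content; message names the offending line."""


def derive_rng(seed: int, *key: int) -> np.random.Generator:
    """Child generator deterministically derived from ``seed`` and an integer key.

    Uses :class:`numpy.random.SeedSequence` spawn keys, so distinct keys give
    statistically independent, reproducible streams.
    """
    ss = np.random.SeedSequence(int(seed), spawn_key=tuple(int(k) for k in key))
    return np.random.default_rng(ss)


def derive_seed(seed: int, *key: int) -> int:
    """A plain integer child seed (< 2**32) for APIs that take one."""
    ss = np.random.SeedSequence(int(seed), spawn_key=tuple(int(k) for k in key))
    return int(ss.generate_state(1, dtype=np.uint32)[0])


@dataclass
class Genotypes:
    """Diploid genotype matrix with per-site metadata.

    Parameters
    ----------
    dosages
        ``(n_individuals, n_sites)`` int8 array counting copies of
        ``allele_a``; -1 marks a missing call.
    sites
        DataFrame with at least ``chrom, pos, allele_a, allele_b``; an
        optional ``cm`` column carries genetic-map positions.
    samples
        Individual identifiers, one per dosage row.
    labels
        Optional population label per individual (aligned with ``samples``).
    """

    dosages: np.ndarray
    sites: pd.DataFrame
    samples: list[str]
    labels: pd.Series | None = None

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        if self.dosages.ndim != 2:
            raise InputError("dosages must be a 2-D (individuals x sites) array")
        if self.dosages.shape[0] != len(self.samples):
            raise InputError("one dosage row per sample required")
        if self.dosages.shape[1] != len(self.sites):
            raise InputError("one dosage column per site required")
        missing = [c for c in SITE_COLUMNS if c not in self.sites.columns]
        if missing:
            raise InputError(f"sites table lacks columns {missing}")
        self.sites = self.sites.reset_index(drop=True)
        if self.labels is not None:
            self.labels = pd.Series(
                np.asarray(self.labels), index=pd.Index(self.samples, name="sample")
            )

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_sites(self) -> int:
        return self.dosages.shape[1]

    def sample_index(self, individual: int | str) -> int:
        if isinstance(individual, str):
            return self.samples.index(individual)
        return int(individual)

    def allele_freq(self, individuals: Sequence[int] | None = None) -> np.ndarray:
        """Frequency of ``allele_a`` per site from called genotypes only.

        Sites with no calls return NaN.
        """
        d = self.dosages if individuals is None else self.dosages[list(individuals)]
        called = d >= 0
        n = 2.0 * called.sum(axis=0)
        tot = np.where(called, d, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n > 0, tot / n, np.nan)

    def subset_sites(self, idx: np.ndarray) -> "Genotypes":
        return Genotypes(
            self.dosages[:, idx],
            self.sites.iloc[np.asarray(idx)].reset_index(drop=True),
            list(self.samples),
            None if self.labels is None else self.labels.values,
        )

    def subset_individuals(self, idx: Iterable[int]) -> "Genotypes":
        idx = list(idx)
        return Genotypes(
            self.dosages[idx],
            self.sites.copy(),
            [self.samples[i] for i in idx],
            None if self.labels is None else self.labels.values[idx],
        )


@dataclass
class ReadObservations:
    """Per-specimen allele observations at known SNP positions.

    ``records`` has columns ``chrom, pos, allele`` (pos 1-based), one row per
    sequencing read overlapping a panel site. ``total_read_count`` is the
    genome-wide number of aligned reads the record set was drawn from, which
    is the unit the read-depth sensitivity grid is expressed in.
    """

    specimen: str
    records: pd.DataFrame
    total_read_count: int

    def __post_init__(self) -> None:
        cols = ["chrom", "pos", "allele"]
        if list(self.records.columns[:3]) != cols:
            self.records = self.records.reindex(columns=cols)
        self.records = self.records.reset_index(drop=True)
        if self.total_read_count < len(self.records):
            raise InputError(
                "total_read_count must be at least the number of panel-hit records"
            )

    @property
    def n_records(self) -> int:
        return len(self.records)

    def copy(self) -> "ReadObservations":
        return ReadObservations(self.specimen, self.records.copy(), self.total_read_count)


def empty_records() -> pd.DataFrame:
    return pd.DataFrame({"chrom": pd.Series(dtype=str),
                         "pos": pd.Series(dtype=np.int64),
                         "allele": pd.Series(dtype=str)})
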