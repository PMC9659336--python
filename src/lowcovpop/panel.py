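"""Diagnostic SNP panel construction for a binary population contrast.

A panel records, for every retained SNP, the frequency of ``allele_a`` in
each of two reference groups. Panels are either *selected* from labelled
reference genotypes by an allele-frequency-differential threshold, or
*imported* from a table of previously published diagnostic loci.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import FormatError, Genotypes, InputError

PANEL_COLUMNS = ["chrom", "pos", "allele_a", "allele_b", "p_group1", "p_group2"]

#: Default selection threshold on |p_group1 - p_group2|; sites this divergent
#: remain informative down to a handful of read observations.
DEFAULT_MIN_ABS_DELTA_P = 0.5

#: Minimum called genotypes per group for a site's frequencies to be trusted.
DEFAULT_MIN_GROUP_CALLS = 2


@dataclass
class SNPPanel:
    """Diagnostic loci with per-group allele frequencies for one contrast."""

    contrast: str
    table: pd.DataFrame
    groups: tuple[str, str]
    provenance: str = "selected"

    def __post_init__(self) -> None:
        missing = [c for c in PANEL_COLUMNS if c not in self.table.columns]
        if missing:
            raise InputError(f"panel table lacks columns {missing}")
        self.table = self.table.reset_index(drop=True)
        dup = self.table.duplicated(subset=["chrom", "pos"])
        if dup.any():
            first = self.table.loc[dup, ["chrom", "pos"]].iloc[0]
            raise FormatError(
                f"duplicate panel position {first['chrom']}:{first['pos']}"
            )
        for col in ("p_group1", "p_group2"):
            v = self.table[col].to_numpy(dtype=float)
            if np.any((v < 0) | (v > 1)) or np.any(~np.isfinite(v)):
                raise FormatError(f"{col} outside [0, 1]")

    @property
    def n_snps(self) -> int:
        return len(self.table)

    @property
    def delta_p(self) -> np.ndarray:
        return np.abs(
            self.table["p_group1"].to_numpy(dtype=float)
            - self.table["p_group2"].to_numpy(dtype=float)
        )

    def swap_groups(self) -> "SNPPanel":
        """The same panel seen from the other group's side."""
        t = self.table.copy()
        t[["p_group1", "p_group2"]] = t[["p_group2", "p_group1"]].to_numpy()
        return SNPPanel(self.contrast, t, (self.groups[1], self.groups[0]), self.provenance)


def select_divergent_snps(
    genotypes: Genotypes,
    groups: tuple[str, str] | None = None,
    min_abs_delta_p: float = DEFAULT_MIN_ABS_DELTA_P,
    min_group_calls: int = DEFAULT_MIN_GROUP_CALLS,
    contrast: str = "contrast",
) -> SNPPanel:
    """Select SNPs whose between-group frequency differential passes a threshold.

    Frequencies are computed from called genotypes only (missing calls do not
    enter the denominators); sites with fewer than ``min_group_calls`` called
    individuals in either group are dropped. The output is ordered by
    (chromosome, position). Selection is label-symmetric: swapping the two
    groups returns the same SNP set with the frequency columns exchanged.
    """
    if genotypes.labels is None:
        raise InputError("genotypes must carry population labels")
    if not (0.0 < min_abs_delta_p <= 1.0):
        raise InputError("min_abs_delta_p must lie in (0, 1]")
    labels = genotypes.labels.to_numpy()
    if groups is None:
        uniq = pd.unique(labels)
        if len(uniq) != 2:
            raise InputError(
                f"need exactly two groups (found {list(uniq)}); pass groups= explicitly"
            )
        groups = (str(uniq[0]), str(uniq[1]))
    for g in groups:
        if g not in labels:
            raise InputError(f"group {g!r} absent from genotype labels")

    idx1 = np.nonzero(labels == groups[0])[0]
    idx2 = np.nonzero(labels == groups[1])[0]

    def _freq_and_calls(idx: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        d = genotypes.dosages[idx]
        called = d >= 0
        n_called = called.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(n_called > 0, np.where(called, d, 0).sum(axis=0) / (2.0 * n_called), np.nan)
        return p, n_called

    p1, n1 = _freq_and_calls(idx1)
    p2, n2 = _freq_and_calls(idx2)
    ok_calls = (n1 >= min_group_calls) & (n2 >= min_group_calls)
    with np.errstate(invalid="ignore"):
        keep = ok_calls & (np.abs(p1 - p2) >= min_abs_delta_p)

    sites = genotypes.sites
    bad_alleles = ~(
        sites["allele_a"].astype(str).str.len().eq(1)
        & sites["allele_b"].astype(str).str.len().eq(1)
    )
    if bad_alleles.any():
        warnings.warn(
            f"dropping {int(bad_alleles.sum())} multi-allelic/indel site(s) from selection"
        )
        keep &= ~bad_alleles.to_numpy()

    table = sites.loc[keep, ["chrom", "pos", "allele_a", "allele_b"]].copy()
    table["p_group1"] = p1[keep]
    table["p_group2"] = p2[keep]
    table = table.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)
    return SNPPanel(contrast, table, groups, provenance="selected")


def import_panel(
    records: pd.DataFrame, groups: tuple[str, str], contrast: str = "imported"
) -> SNPPanel:
    """Build a panel from a table of previously published diagnostic loci.

    ``records`` must have the panel columns; alleles must be single IUPAC
    bases, positions unique, frequencies within [0, 1]. An empty table is a
    valid (empty) panel.
    """
    records = records.reindex(columns=PANEL_COLUMNS)
    if records[["chrom", "pos"]].isna().any().any():
        raise FormatError("panel records must provide chrom and pos for every row")
    iupac = set("ACGTRYSWKMBDHVN")
    for col in ("allele_a", "allele_b"):
        vals = records[col].astype(str)
        bad = ~(vals.str.len().eq(1) & vals.str.upper().isin(iupac))
        if bad.any():
            raise FormatError(
                f"line {int(np.nonzero(bad.to_numpy())[0][0]) + 1}: "
                f"{col} must be a single IUPAC base"
            )
    table = records.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)
    return SNPPanel(contrast, table, tuple(groups), provenance="imported")


def panel_from_truth(truth, contrast: str = "truth") -> SNPPanel:
    """Panel carrying a :class:`~lowcovpop.simulate.TwoPopTruth`'s exact frequencies."""
    table = truth.sites.copy()
    table["p_group1"] = truth.freq_pop_a
    table["p_group2"] = truth.freq_pop_b
    return SNPPanel(contrast, table, truth.labels, provenance="imported")
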