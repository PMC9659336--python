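"""Downsampling + bootstrap protocol for a test's minimum reliable read depth.

Each test individual's read set is repeatedly downsampled to a grid of
total-read-count targets; at every grid point the binary assignment test is
run on 20 bootstrap replicates per individual, and the minimum required
depth is the smallest grid value from which every individual classifies
correctly in all replicates at that depth and every deeper one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .assign import NO_CALL, classify, score_assignment
from .core import InputError, ReadObservations, derive_seed
from .panel import SNPPanel
from .simulate import downsample_reads

DEFAULT_N_BOOT = 20


def downsampling_grid() -> list[int]:
    """Read-count grid: 500-read steps up to 10k, then 10k steps up to 100k."""
    return list(range(500, 10_001, 500)) + list(range(20_000, 100_001, 10_000))


@dataclass
class SensitivityCurve:
    """Per-depth, per-individual correct-replicate counts for one contrast."""

    contrast: str
    grid: list[int]
    individuals: list[str]
    truth: list[str]
    n_boot: int
    correct: np.ndarray  # (n_grid, n_individuals) counts in [0, n_boot]

    def correctness_by_depth(self) -> np.ndarray:
        """Fraction of all replicates correct at each grid value."""
        return self.correct.sum(axis=1) / (self.n_boot * len(self.individuals))

    def all_correct(self) -> np.ndarray:
        """Boolean per grid value: every individual's every replicate correct."""
        return (self.correct == self.n_boot).all(axis=1)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for gi, g in enumerate(self.grid):
            for ii, ind in enumerate(self.individuals):
                rows.append(
                    {
                        "contrast": self.contrast,
                        "depth": g,
                        "individual": ind,
                        "truth": self.truth[ii],
                        "n_correct": int(self.correct[gi, ii]),
                        "n_boot": self.n_boot,
                    }
                )
        return pd.DataFrame(rows)


def run_sensitivity(
    individuals: list[tuple[ReadObservations, str]],
    panel: SNPPanel,
    n_boot: int = DEFAULT_N_BOOT,
    seed: int = 0,
    grid: list[int] | None = None,
    freq_clamp: float = 1e-3,
) -> SensitivityCurve:
    """Bootstrap-downsample every individual over the grid and score each draw.

    Replicate seeds derive deterministically from (seed, grid value,
    individual index, replicate index), so replicates are independent yet the
    whole curve is reproducible. Classification is the binary split at 0.5
    with no middle class; a ``no_call`` replicate counts as incorrect.
    """
    if grid is None:
        grid = downsampling_grid()
    grid = list(grid)
    if any(b <= a for a, b in zip(grid, grid[1:])):
        raise InputError("grid must be strictly increasing")
    for obs, truth in individuals:
        if truth not in panel.groups:
            raise InputError(
                f"truth label {truth!r} is not one of the panel groups {panel.groups}"
            )
        if obs.total_read_count < grid[0]:
            raise InputError(
                f"individual {obs.specimen} has fewer total reads than the smallest grid value"
            )

    correct = np.zeros((len(grid), len(individuals)), dtype=np.int32)
    for gi, g in enumerate(grid):
        for ii, (obs, truth) in enumerate(individuals):
            for b in range(n_boot):
                sub = downsample_reads(obs, g, derive_seed(seed, g, ii, b))
                res = classify(score_assignment(sub, panel, freq_clamp))
                correct[gi, ii] += int(res.call == truth)
    return SensitivityCurve(
        panel.contrast,
        grid,
        [obs.specimen for obs, _ in individuals],
        [t for _, t in individuals],
        n_boot,
        correct,
    )


def minimum_read_depth(curve: SensitivityCurve) -> int | None:
    """Smallest grid value from which classification stays perfect.

    Requires all replicates of all individuals correct at that depth *and at
    every larger grid value* (stability), since the minimum is used as a gate
    for real specimens; returns None when no such depth exists.
    """
    if len(curve.grid) == 0:
        raise InputError("empty sensitivity curve")
    ok = curve.all_correct()
    depth = None
    for g, good in zip(reversed(curve.grid), reversed(ok)):
        if not good:
            break
        depth = g
    return depth
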