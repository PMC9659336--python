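"""Low-coverage population assignment from per-site allele observations.

Each read observation at a diagnostic SNP contributes the log-likelihood
ratio of its allele's (clamped) frequencies in the two reference groups;
under equal priors the logistic transform of the summed log-odds is the
posterior weight of group 1. A hierarchical scheme combines three contrasts
— spawning season, chromosomal-inversion haplotype (autumn spawners only),
and salinity adaptation — into one composite population label.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.special import expit

from .core import ConfigurationError, InputError, ReadObservations
from .panel import SNPPanel

#: Frequencies are clamped into [clamp, 1-clamp] before taking log ratios,
#: so fixed differences contribute finite (but large) weights.
DEFAULT_FREQ_CLAMP = 1e-3

#: Read-depth gates per contrast: minimum genome-wide aligned reads at which
#: each test classifies reliably.
DEFAULT_MIN_READS = {"season": 50_000, "inversion": 50_000, "salinity": 60_000}

#: Score band treated as intermediate ("mid") where a middle class is allowed.
DEFAULT_TAU_LOW = 0.3
DEFAULT_TAU_HIGH = 0.7

NO_CALL = "no_call"
MID = "mid"


@dataclass
class AssignmentResult:
    """Outcome of one assignment test for one specimen."""

    contrast: str
    groups: tuple[str, str]
    score: float | None
    log_odds: float | None
    n_informative_sites: int
    n_observations: int
    call: str | None = None

    def classified(self, **kwargs) -> "AssignmentResult":
        return classify(self, **kwargs)


def score_assignment(
    obs: ReadObservations, panel: SNPPanel, freq_clamp: float = DEFAULT_FREQ_CLAMP
) -> AssignmentResult:
    """Posterior weight of group 1 from allele observations at panel SNPs.

    For an observation of ``allele_a`` at a panel SNP the weight is
    ln(clamp(p1)/clamp(p2)); for ``allele_b`` it is
    ln(clamp(1-p1)/clamp(1-p2)). Observations at non-panel positions or
    showing a non-panel allele are ignored but counted in ``n_observations``.
    With no informative site the score is undefined and the call is
    ``no_call``.
    """
    if not (0.0 < freq_clamp < 0.5):
        raise ConfigurationError("freq_clamp must lie in (0, 0.5)")
    if panel.n_snps == 0:
        raise InputError("cannot score against an empty panel")

    merged = obs.records.merge(panel.table, on=["chrom", "pos"], how="inner")
    n_obs = obs.n_records
    if len(merged) == 0:
        return AssignmentResult(panel.contrast, panel.groups, None, None, 0, n_obs, NO_CALL)

    allele = merged["allele"].to_numpy(dtype=str)
    is_a = allele == merged["allele_a"].to_numpy(dtype=str)
    is_b = allele == merged["allele_b"].to_numpy(dtype=str)
    informative = is_a | is_b
    if not informative.any():
        return AssignmentResult(panel.contrast, panel.groups, None, None, 0, n_obs, NO_CALL)

    m = merged.loc[informative]
    obs_is_a = is_a[informative]
    p1 = m["p_group1"].to_numpy(dtype=float)
    p2 = m["p_group2"].to_numpy(dtype=float)
    f1 = np.where(obs_is_a, p1, 1.0 - p1)
    f2 = np.where(obs_is_a, p2, 1.0 - p2)
    f1 = np.clip(f1, freq_clamp, 1.0 - freq_clamp)
    f2 = np.clip(f2, freq_clamp, 1.0 - freq_clamp)
    log_odds = float(np.sum(np.log(f1) - np.log(f2)))
    n_sites = int(m.drop_duplicates(subset=["chrom", "pos"]).shape[0])
    return AssignmentResult(
        panel.contrast,
        panel.groups,
        float(expit(log_odds)),
        log_odds,
        n_sites,
        n_obs,
    )


def classify(
    result: AssignmentResult,
    tau_low: float = 0.5,
    tau_high: float = 0.5,
    allow_mid: bool = False,
) -> AssignmentResult:
    """Turn a score into a call.

    score >= tau_high -> group 1; score <= tau_low -> group 2; scores in
    between are ``mid`` when a middle class is allowed, otherwise the nearer
    side (ties to group 1). Zero informative sites always yields ``no_call``.
    """
    if not (0.0 < tau_low <= tau_high < 1.0):
        raise ConfigurationError("thresholds must satisfy 0 < tau_low <= tau_high < 1")
    if result.n_informative_sites == 0 or result.score is None:
        return replace(result, call=NO_CALL)
    s = result.score
    g1, g2 = result.groups
    if s >= tau_high:
        call = g1
    elif s <= tau_low:
        call = g2
    elif allow_mid:
        call = MID
    else:
        # nearer side; exact midpoint ties resolve to group 1
        call = g1 if s >= (tau_low + tau_high) / 2.0 else g2
    return replace(result, call=call)


@dataclass
class TestOutcome:
    """One test inside a hierarchical assignment: its call plus bookkeeping."""

    call: str
    result: AssignmentResult | None = None
    reason: str | None = None

    @property
    def ran(self) -> bool:
        return self.result is not None


@dataclass
class FinalAssignment:
    """Composite population label from the hierarchical test sequence."""

    specimen: str
    total_reads: int
    season: TestOutcome
    inversion: TestOutcome | None  # None when not applicable (spring spawners)
    salinity: TestOutcome
    label: str | None

    def as_row(self) -> dict:
        return {
            "specimen": self.specimen,
            "total_reads": self.total_reads,
            "season": self.season.call,
            "inversion": self.inversion.call if self.inversion is not None else "",
            "salinity": self.salinity.call,
            "label": self.label if self.label is not None else "",
        }


def compose_label(season: str, inversion: str | None, salinity: str) -> str:
    """Composite label string; the inversion slot exists only for autumn fish."""
    parts = [season] + ([] if inversion is None else [inversion]) + [salinity]
    return "/".join(parts)


def hierarchical_assign(
    obs: ReadObservations,
    season_panel: SNPPanel,
    inversion_panel: SNPPanel,
    salinity_panel: SNPPanel,
    min_reads: dict[str, int] | None = None,
    tau_low: float = DEFAULT_TAU_LOW,
    tau_high: float = DEFAULT_TAU_HIGH,
    freq_clamp: float = DEFAULT_FREQ_CLAMP,
    autumn_label: str = "autumn",
) -> FinalAssignment:
    """Run season, then inversion (autumn only), then salinity, and combine.

    Each test runs only if the specimen's total aligned reads meet that
    test's gate; a gated-out test reports ``no_call`` with reason
    ``insufficient_reads`` and contributes "NA" to the composite. A test that
    ran but found no informative site nullifies the composite. The salinity
    test allows a ``mid`` class via (tau_low, tau_high); season and inversion
    are binary splits at 0.5.
    """
    for name, p in (
        ("season", season_panel),
        ("inversion", inversion_panel),
        ("salinity", salinity_panel),
    ):
        if p is None:
            raise ConfigurationError(f"missing {name} panel")
    gates = dict(DEFAULT_MIN_READS)
    if min_reads:
        gates.update(min_reads)
    total = obs.total_read_count

    def _run(panel: SNPPanel, name: str, **cls_kwargs) -> TestOutcome:
        if total < gates[name]:
            return TestOutcome(NO_CALL, None, "insufficient_reads")
        res = classify(score_assignment(obs, panel, freq_clamp), **cls_kwargs)
        return TestOutcome(res.call, res, None if res.call != NO_CALL else "no_informative_sites")

    season = _run(season_panel, "season")
    invalid = season.ran and season.call == NO_CALL

    inversion: TestOutcome | None
    if season.call == autumn_label:
        inversion = _run(inversion_panel, "inversion")
        invalid |= inversion.ran and inversion.call == NO_CALL
    elif season.ran and season.call != NO_CALL:
        inversion = None  # spring spawners carry no inversion test
    else:
        inversion = TestOutcome(NO_CALL, None, "season_unresolved")

    salinity = _run(salinity_panel, "salinity", tau_low=tau_low, tau_high=tau_high, allow_mid=True)
    invalid |= salinity.ran and salinity.call == NO_CALL

    label: str | None
    if invalid or not season.ran:
        label = None
    else:
        inv_part = None
        if inversion is not None:
            inv_part = inversion.call if inversion.ran else "NA"
        sal_part = salinity.call if salinity.ran else "NA"
        label = compose_label(season.call, inv_part, sal_part)

    return FinalAssignment(obs.specimen, total, season, inversion, salinity, label)


@dataclass
class SiteAggregate:
    count: int
    n: int
    percentage: float


def aggregate_site(labels: list[str | None], target_label: str) -> SiteAggregate:
    """Share of specimens at one site carrying a target composite label.

    The denominator is every sampled specimen, including those without a
    composite label; the percentage is rounded to one decimal.
    """
    if len(labels) == 0:
        raise InputError("cannot aggregate an empty specimen list")
    count = sum(1 for lab in labels if lab == target_label)
    n = len(labels)
    return SiteAggregate(count, n, round(100.0 * count / n, 1))


def brute_force_score(
    obs: ReadObservations, panel: SNPPanel, freq_clamp: float = DEFAULT_FREQ_CLAMP
) -> float | None:
    """Independent oracle: per-observation clamped-frequency products,
    normalised over the two groups.

    Same arithmetic as :func:`score_assignment` but implemented as a naive
    per-record loop over raw products; used to cross-check the vectorised
    log-domain path.
    """
    lookup = {
        (r.chrom, r.pos): (r.allele_a, r.allele_b, r.p_group1, r.p_group2)
        for r in panel.table.itertuples()
    }

    def _clamp(x: float) -> float:
        return min(max(x, freq_clamp), 1.0 - freq_clamp)

    prod1 = prod2 = 1.0
    seen = 0
    for rec in obs.records.itertuples():
        entry = lookup.get((rec.chrom, rec.pos))
        if entry is None:
            continue
        allele_a, allele_b, p1, p2 = entry
        if rec.allele == allele_a:
            prod1 *= _clamp(p1)
            prod2 *= _clamp(p2)
        elif rec.allele == allele_b:
            prod1 *= _clamp(1.0 - p1)
            prod2 *= _clamp(1.0 - p2)
        else:
            continue
        seen += 1
    if seen == 0:
        return None
    return prod1 / (prod1 + prod2)
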