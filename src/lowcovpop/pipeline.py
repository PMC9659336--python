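"""End-to-end demo workflow on synthetic truth, with manifest and checksums.

The demo exercises the full inference chain the package implements:
simulate divergent populations -> select diagnostic panels -> read-depth
sensitivity -> hierarchical assignment of synthetic "specimens" ->
per-site aggregation -> window statistics -> LD-decay demography with
calendar calibration. Every stage seeds deterministically from one master
seed, and the manifest records parameters plus a checksum per output table,
so a repeated run is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .assign import aggregate_site, hierarchical_assign
from .core import ConfigurationError, Genotypes, ReadObservations, derive_seed
from .io import (
    write_genotypes_tsv,
    write_observations_tsv,
    write_panel_tsv,
    write_trajectory_tsv,
    write_vcf,
    write_windows_tsv,
)
from .ldne import LDNe
from .panel import SNPPanel, select_divergent_snps
from .popgen import date_and_bin_roh, detect_roh, kinship_matrix, windowed_pi_genotypes
from .sensitivity import minimum_read_depth, run_sensitivity
from .simulate import sample_genotypes, simulate_divergent_populations, simulate_reads
from .wright_fisher import PopulationModel, simulate_wright_fisher

#: Minimum generation times by spawning ecotype (years).
GENERATION_TIME_YEARS = {"autumn": 3.0, "spring": 2.0}


@dataclass
class RunConfig:
    """Parameters of the demo workflow (the package's constants in one place)."""

    seed: int = 0
    out_dir: str = "demo_out"
    # panel truth sizes, loosely mirroring season / inversion / salinity scales
    n_snps_season: int = 800
    n_snps_inversion: int = 4_500
    n_snps_salinity: int = 2_300
    delta_p: tuple = ("uniform", 0.9, 1.0)
    n_reference_per_group: int = 100
    min_abs_delta_p: float = 0.5
    # specimens
    n_specimens_per_site: int = 8
    specimen_reads: int = 100_000
    low_read_specimens: int = 2        # per-site-A specimens at 55k reads
    low_read_count: int = 55_000
    min_reads: dict = field(
        default_factory=lambda: {"season": 50_000, "inversion": 50_000, "salinity": 60_000}
    )
    tau_low: float = 0.3
    tau_high: float = 0.7
    # sensitivity
    n_sensitivity_individuals: int = 8
    n_boot_sensitivity: int = 20
    # demography
    wf_trajectory: tuple = ((0, 150), (80, 600), (280, 600))
    wf_sample_size: int = 60
    wf_n_loci: int = 500
    n_boot_ne: int = 8
    ne_snps_per_chromosome: int = 400  # genuine subsample of wf_n_loci
    generation_time_years: float = GENERATION_TIME_YEARS["autumn"]
    sampling_year: int = 2010
    window_bp: int = 100_000
    make_plots: bool = False
    # optional pre-built panel paths; when given they must exist
    season_panel_path: str | None = None
    inversion_panel_path: str | None = None
    salinity_panel_path: str | None = None

    def validate(self) -> None:
        for gt in GENERATION_TIME_YEARS.values():
            if gt <= 0:
                raise ConfigurationError("generation times must be positive")
        if self.generation_time_years <= 0:
            raise ConfigurationError("generation_time_years must be positive")
        for name in ("season_panel_path", "inversion_panel_path", "salinity_panel_path"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise ConfigurationError(f"{name} does not exist: {p}")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _combined_observations(
    specimen: str,
    memberships: dict[str, str],
    truths: dict,
    total_reads: int,
    seed: int,
) -> ReadObservations:
    """Genome-wide reads of one specimen reduced to the three panels' hits.

    ``memberships`` maps contrast name -> the truth group the specimen
    belongs to; each panel's hits are thinned independently from the same
    genome-wide total.
    """
    frames = []
    for k, (contrast, truth) in enumerate(truths.items()):
        group = memberships[contrast]
        gi = 0 if group == truth.labels[0] else 1
        geno = sample_genotypes(truth, 1, derive_seed(seed, k, 0), prefix=specimen)
        individual = gi  # row 0 is group1's individual, row 1 group2's
        obs = simulate_reads(
            geno, individual, total_reads, seed=derive_seed(seed, k, 1), specimen=specimen
        )
        frames.append(obs.records)
    records = pd.concat(frames, ignore_index=True)
    return ReadObservations(specimen, records, total_reads)


def run_demo(config: RunConfig) -> Path:
    """Execute the full synthetic workflow; returns the artifact directory."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = config.seed
    manifest: dict = {
        "package": "lowcovpop",
        "version": __version__,
        "seed": seed,
        "config": {k: v for k, v in asdict(config).items()},
        "stages": {},
        "outputs": {},
    }

    def _stage(name: str, **info) -> None:
        manifest["stages"][name] = info

    # ---- stage 1: truths and reference panels ---------------------------
    contrasts = {
        "season": ("autumn", "spring", config.n_snps_season, "chr4"),
        "inversion": ("atlantic", "baltic", config.n_snps_inversion, "chr12"),
        "salinity": ("high", "low", config.n_snps_salinity, "chr20"),
    }
    truths: dict = {}
    panels: dict[str, SNPPanel] = {}
    for k, (name, (g1, g2, n_snps, chrom)) in enumerate(contrasts.items()):
        truth = simulate_divergent_populations(
            n_snps, config.delta_p, derive_seed(seed, 10, k), labels=(g1, g2), chrom=chrom
        )
        ref = sample_genotypes(
            truth, config.n_reference_per_group, derive_seed(seed, 11, k), prefix=f"ref_{name}"
        )
        panel = select_divergent_snps(
            ref, (g1, g2), min_abs_delta_p=config.min_abs_delta_p, contrast=name
        )
        truths[name] = truth
        panels[name] = panel
        write_panel_tsv(panel, str(out / f"panel_{name}.tsv"))
        write_vcf(ref, str(out / f"reference_{name}.vcf"))
    _stage("panels", sizes={k: p.n_snps for k, p in panels.items()})

    # ---- stage 2: sensitivity on the season panel -----------------------
    sens_truth = truths["season"]
    sens_geno = sample_genotypes(
        sens_truth, config.n_sensitivity_individuals // 2, derive_seed(seed, 20), prefix="sens"
    )
    sens_individuals = []
    for i in range(sens_geno.n_individuals):
        obs = simulate_reads(
            sens_geno, i, 200_000, seed=derive_seed(seed, 21, i)
        )
        sens_individuals.append((obs, str(sens_geno.labels.iloc[i])))
    curve = run_sensitivity(
        sens_individuals,
        panels["season"],
        n_boot=config.n_boot_sensitivity,
        seed=derive_seed(seed, 22),
    )
    curve.to_frame().to_csv(out / "sensitivity_season.tsv", sep="\t", index=False)
    min_depth = minimum_read_depth(curve)
    pd.DataFrame(
        [{"contrast": "season", "min_depth": min_depth if min_depth is not None else ""}]
    ).to_csv(out / "sensitivity_summary.tsv", sep="\t", index=False)
    _stage("sensitivity", min_depth=min_depth)

    # ---- stage 3: specimens, assignment, aggregation --------------------
    site_plan = {
        "site_A": [("autumn", "baltic", "high")] * 5 + [("autumn", "baltic", "low")] * 3,
        "site_B": [("autumn", "baltic", "high")] * 3
        + [("autumn", "baltic", "low")] * 4
        + [("spring", "baltic", "low")] * 1,
        "site_C": [("autumn", "baltic", "low")] * 6 + [("spring", "baltic", "low")] * 2,
    }
    assignments = []
    planted = []
    obs_all = []
    sidx = 0
    for site, plan in site_plan.items():
        for j, (season, inversion, salinity) in enumerate(plan):
            total = config.specimen_reads
            if site == "site_A" and j < config.low_read_specimens:
                total = config.low_read_count
            name = f"{site}_sp{j}"
            obs = _combined_observations(
                name,
                {"season": season, "inversion": inversion, "salinity": salinity},
                truths,
                total,
                derive_seed(seed, 30, sidx),
            )
            obs_all.append(obs)
            fa = hierarchical_assign(
                obs,
                panels["season"],
                panels["inversion"],
                panels["salinity"],
                min_reads=config.min_reads,
                tau_low=config.tau_low,
                tau_high=config.tau_high,
            )
            row = fa.as_row()
            row["site"] = site
            truth_label = "/".join(
                [season] + ([inversion] if season == "autumn" else []) + [salinity]
            )
            row["truth"] = truth_label
            assignments.append(row)
            planted.append({"site": site, "specimen": name, "truth": truth_label})
            sidx += 1
    write_observations_tsv(obs_all, str(out / "observations.tsv"))
    adf = pd.DataFrame(assignments)
    adf.to_csv(out / "assignments.tsv", sep="\t", index=False)

    target = "autumn/baltic/high"  # western-Baltic-like composite
    site_rows = []
    for site, grp in adf.groupby("site", sort=True):
        agg = aggregate_site([x if x else None for x in grp["label"]], target)
        site_rows.append(
            {"site": site, "target": target, "count": agg.count, "n": agg.n,
             "percentage": agg.percentage}
        )
    site_table = pd.DataFrame(site_rows)
    site_table.to_csv(out / "site_aggregation.tsv", sep="\t", index=False)
    _stage(
        "assignment",
        n_specimens=len(adf),
        n_recovered=int((adf["label"] == adf["truth"]).sum()),
    )

    # ---- stage 4: window statistics on Wright-Fisher genotypes ----------
    model = PopulationModel(
        ne_trajectory=[tuple(x) for x in config.wf_trajectory],
        n_loci=config.wf_n_loci,
        seed=derive_seed(seed, 40),
    )
    wf = simulate_wright_fisher(model, config.wf_sample_size)
    write_genotypes_tsv(wf, str(out / "wf_genotypes.tsv"))
    pi = windowed_pi_genotypes(wf, window_bp=config.window_bp)
    write_windows_tsv(pi, str(out / "pi_windows.tsv"))
    kin = kinship_matrix(wf.subset_individuals(range(8)))
    kin.to_csv(out / "kinship.tsv", sep="\t")
    roh = detect_roh(wf)
    if len(roh):
        dated, bins = date_and_bin_roh(roh, config.generation_time_years)
        dated.to_csv(out / "roh_segments.tsv", sep="\t", index=False)
        bins.to_csv(out / "roh_bins.tsv", sep="\t", index=False)
    _stage("stats", n_pi_windows=len(pi), n_roh=len(roh))

    # ---- stage 5: LD-decay demography -----------------------------------
    traj = LDNe(wf).fit(
        n_boot=config.n_boot_ne,
        snps_per_chromosome=min(config.ne_snps_per_chromosome, config.wf_n_loci),
        seed=derive_seed(seed, 50),
    )
    calibrated = traj.calibrate(config.generation_time_years, config.sampling_year)
    write_trajectory_tsv(calibrated, str(out / "ne_trajectory.tsv"))
    if config.make_plots:
        import matplotlib

        matplotlib.use("Agg")
        ax = calibrated.plot()
        ax.figure.savefig(out / "ne_trajectory.png", dpi=120)
    _stage("demography", n_points=len(calibrated.table))

    # ---- manifest --------------------------------------------------------
    for p in sorted(out.glob("*.tsv")) + sorted(out.glob("*.vcf")):
        manifest["outputs"][p.name] = _sha256(p)
    manifest["finished_utc"] = time.strftime("%Y-%m-%dT%H:%M:%SZ", time.gmtime())
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return out
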