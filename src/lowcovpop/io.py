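"""Readers and writers for the pipeline's on-disk formats.

Formats and coordinate conventions:

* minimal VCF (GT-only, diploid, unphased) — positions 1-based; ``allele_a``
  is written as REF and ``allele_b`` as ALT, genotypes encode ALT counts;
* panel TSV — ``contrast, chrom, pos, allele_a, allele_b, p_group1,
  p_group2`` with group names in a header comment; positions 1-based;
* read-observations TSV (pileup dialect) — ``specimen, chrom, pos, allele,
  total_reads``; positions 1-based;
* window TSV (BED-like) — ``chrom, start, end, ...`` 0-based half-open;
* trajectory TSV — one row per time point.

Every writer round-trips losslessly through its reader; bespoke TSV dialects
are parsed line by line so malformed input fails with the offending line
number.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import FormatError, Genotypes, ReadObservations, empty_records
from .ldne import NeTrajectory
from .panel import PANEL_COLUMNS, SNPPanel


# ---------------------------------------------------------------- VCF

def write_vcf(geno: Genotypes, path: str) -> None:
    """Write genotypes as a minimal GT-only VCF (uncompressed text)."""
    sites = geno.sites
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=lowcovpop\n")
        for chrom in pd.unique(sites["chrom"]):
            length = int(sites.loc[sites["chrom"] == chrom, "pos"].max()) + 1
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(geno.samples) + "\n")
        for j, site in enumerate(sites.itertuples()):
            dos = geno.dosages[:, j]
            # dosage counts allele_a (= REF); GT encodes ALT copies
            gts = []
            for d in dos:
                if d < 0:
                    gts.append("./.")
                else:
                    alt = 2 - int(d)
                    gts.append(["0/0", "0/1", "1/1"][alt])
            fh.write(
                f"{site.chrom}\t{site.pos}\t.\t{site.allele_a}\t{site.allele_b}"
                f"\t.\t.\t.\tGT\t" + "\t".join(gts) + "\n"
            )


def read_vcf(path: str) -> Genotypes:
    """Read a GT-only diploid VCF back into a genotype container."""
    from cyvcf2 import VCF

    vcf = VCF(path)
    samples = list(vcf.samples)
    chroms, poss, ref, alt, rows = [], [], [], [], []
    for v in vcf:
        chroms.append(v.CHROM)
        poss.append(v.POS)
        ref.append(v.REF)
        alt.append(v.ALT[0] if v.ALT else ".")
        dos = []
        for g in v.genotypes:
            a = [x for x in g[:-1]]
            if any(x < 0 for x in a):
                dos.append(-1)
            else:
                dos.append(2 - sum(a))  # back to allele_a (REF) dosage
        rows.append(dos)
    vcf.close()
    sites = pd.DataFrame(
        {"chrom": chroms, "pos": np.asarray(poss, dtype=np.int64),
         "allele_a": ref, "allele_b": alt}
    )
    dosages = np.asarray(rows, dtype=np.int8).T if rows else np.zeros((len(samples), 0), np.int8)
    return Genotypes(dosages, sites, samples)


# ---------------------------------------------------------------- genotype TSV

def write_genotypes_tsv(geno: Genotypes, path: str) -> None:
    """Site-by-individual dosage matrix with site metadata columns."""
    df = geno.sites.copy()
    for i, s in enumerate(geno.samples):
        df[s] = geno.dosages[i]
    with open(path, "w") as fh:
        fh.write("# genotype dosages of allele_a; pos is 1-based; -1 = missing\n")
        if geno.labels is not None:
            lab = ",".join(f"{s}={v}" for s, v in geno.labels.items())
            fh.write(f"# labels: {lab}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_genotypes_tsv(path: str) -> Genotypes:
    labels = None
    with open(path) as fh:
        head = []
        for line in fh:
            if line.startswith("#"):
                if line.startswith("# labels:"):
                    pairs = line.split(":", 1)[1].strip().split(",")
                    labels = dict(p.split("=") for p in pairs if p)
                continue
            head.append(line)
            break
        df = pd.read_csv(fh, sep="\t", names=head[0].rstrip("\n").split("\t"))
    meta_cols = [c for c in df.columns if c in ("chrom", "pos", "allele_a", "allele_b", "cm")]
    samples = [c for c in df.columns if c not in meta_cols]
    dosages = df[samples].to_numpy(dtype=np.int8).T
    lab = None
    if labels is not None:
        lab = np.array([labels.get(s, "") for s in samples])
    return Genotypes(dosages, df[meta_cols], samples, lab)


# ---------------------------------------------------------------- panel TSV

def write_panel_tsv(panel: SNPPanel, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("# diagnostic SNP panel; pos is 1-based\n")
        fh.write(f"# groups: {panel.groups[0]}\t{panel.groups[1]}\n")
        fh.write(f"# provenance: {panel.provenance}\n")
        df = panel.table.copy()
        df.insert(0, "contrast", panel.contrast)
        df.to_csv(fh, sep="\t", index=False)


def read_panel_tsv(path: str) -> SNPPanel:
    groups = ("group1", "group2")
    provenance = "imported"
    rows = []
    header: list[str] | None = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                if line.startswith("# groups:"):
                    parts = line.split(":", 1)[1].strip().split("\t")
                    if len(parts) == 2:
                        groups = (parts[0], parts[1])
                elif line.startswith("# provenance:"):
                    provenance = line.split(":", 1)[1].strip()
                continue
            fields = line.split("\t")
            if header is None:
                header = fields
                expected = ["contrast"] + PANEL_COLUMNS
                if header != expected:
                    raise FormatError(f"line {lineno}: expected columns {expected}")
                continue
            if len(fields) != len(header):
                raise FormatError(f"line {lineno}: expected {len(header)} fields, got {len(fields)}")
            try:
                rows.append(
                    {
                        "contrast": fields[0],
                        "chrom": fields[1],
                        "pos": int(fields[2]),
                        "allele_a": fields[3],
                        "allele_b": fields[4],
                        "p_group1": float(fields[5]),
                        "p_group2": float(fields[6]),
                    }
                )
            except ValueError as exc:
                raise FormatError(f"line {lineno}: {exc}") from None
    if header is None:
        raise FormatError("line 1: missing header")
    contrast = rows[0]["contrast"] if rows else "imported"
    df = pd.DataFrame(rows, columns=["contrast"] + PANEL_COLUMNS)
    panel = SNPPanel(contrast, df[PANEL_COLUMNS], groups, provenance)
    return panel


# ---------------------------------------------------------------- observations TSV

OBS_HEADER = ["specimen", "chrom", "pos", "allele", "total_reads"]


def write_observations_tsv(obs_list: list[ReadObservations], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("# read observations at panel positions; pos is 1-based\n")
        fh.write("\t".join(OBS_HEADER) + "\n")
        for obs in obs_list:
            if obs.n_records == 0:
                fh.write(f"{obs.specimen}\t.\t0\t.\t{obs.total_read_count}\n")
            for rec in obs.records.itertuples():
                fh.write(
                    f"{obs.specimen}\t{rec.chrom}\t{rec.pos}\t{rec.allele}"
                    f"\t{obs.total_read_count}\n"
                )


def read_observations_tsv(path: str) -> list[ReadObservations]:
    per: dict[str, dict] = {}
    header_seen = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if not header_seen:
                if fields != OBS_HEADER:
                    raise FormatError(f"line {lineno}: expected header {OBS_HEADER}")
                header_seen = True
                continue
            if len(fields) != 5:
                raise FormatError(f"line {lineno}: expected 5 fields, got {len(fields)}")
            spec, chrom, pos, allele, total = fields
            try:
                pos_i, total_i = int(pos), int(total)
            except ValueError as exc:
                raise FormatError(f"line {lineno}: {exc}") from None
            entry = per.setdefault(spec, {"rows": [], "total": total_i})
            entry["total"] = total_i
            if chrom != ".":
                entry["rows"].append({"chrom": chrom, "pos": pos_i, "allele": allele})
    if not header_seen:
        raise FormatError("line 1: missing header")
    out = []
    for spec, entry in per.items():
        records = pd.DataFrame(entry["rows"]) if entry["rows"] else empty_records()
        out.append(ReadObservations(spec, records, entry["total"]))
    return out


# ---------------------------------------------------------------- windows / trajectory

def write_windows_tsv(df: pd.DataFrame, path: str, value_name: str = "pi") -> None:
    with open(path, "w") as fh:
        fh.write("# BED-like windows: start/end are 0-based half-open\n")
        df.to_csv(fh, sep="\t", index=False)


def write_trajectory_tsv(traj: NeTrajectory, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("# LD-decay Ne trajectory; t_generations = 1/(2c)\n")
        for k, v in traj.metadata.items():
            fh.write(f"# {k}: {v}\n")
        fh.write(f"# n_haplotypes: {traj.n_haplotypes}\n")
        traj.table.to_csv(fh, sep="\t", index=False)


def read_trajectory_tsv(path: str) -> NeTrajectory:
    meta: dict = {}
    with open(path) as fh:
        lines = fh.readlines()
    body = []
    for line in lines:
        if line.startswith("#"):
            if ":" in line:
                k, v = line[1:].split(":", 1)
                meta[k.strip()] = v.strip()
        else:
            body.append(line)
    from io import StringIO

    table = pd.read_csv(StringIO("".join(body)), sep="\t")
    n_hap = int(meta.pop("n_haplotypes", 0))
    return NeTrajectory(table, n_hap, meta)


def bed_window_of(pos_1based: int, window_bp: int) -> tuple[int, int]:
    """0-based half-open window containing a 1-based position."""
    start = ((pos_1based - 1) // window_bp) * window_bp
    return start, start + window_bp
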