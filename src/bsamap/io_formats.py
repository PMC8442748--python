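"""Readers and writers for the interchange formats the pipeline touches.

VCF 4.2 is the single variant interchange format. A loaded :class:`Dataset`
carries one row per site with the four role columns the scan needs
(parent_sterile, parent_fertile, bulk_sterile, bulk_fertile): parent genotype
strings plus per-sample ref/alt allele depths. Coordinates are 1-based
inclusive internally (the VCF convention); BED output converts to 0-based
half-open. Chromosome order is taken from the VCF header contig lines, with
a lexicographic fallback when the header declares none.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

ROLES = ("parent_sterile", "parent_fertile", "bulk_sterile", "bulk_fertile")

__all__ = ["Dataset", "read_vcf", "write_vcf", "write_bed", "read_bed", "write_tsv", "ROLES"]


@dataclass
class Dataset:
    """Variant sites plus the genome layout implied by the VCF header."""

    sites: pd.DataFrame
    chromosomes: tuple[tuple[str, int], ...]  # (name, length); length 0 if undeclared

    @property
    def chrom_names(self) -> tuple[str, ...]:
        return tuple(c for c, _ in self.chromosomes)


def _gt_string(sample) -> str:
    alleles = sample.get("GT", (None,))
    if alleles is None or any(a is None for a in alleles):
        return "./."
    return "/".join(str(a) for a in alleles)


def read_vcf(path: str | Path, role_map: Mapping[str, str] | None = None) -> Dataset:
    """Load a four-role VCF into a Dataset.

    ``role_map`` maps role name -> sample name in the file; identity by
    default. Sites are sorted by (header contig order, position); an unsorted
    input is sorted with a warning. Multi-allelic sites are kept, with
    ``n_alt_alleles`` recording the alternate count and depths taken for the
    first alternate allele — the filtering stage discards them by rule.
    """
    role_map = dict(role_map or {r: r for r in ROLES})
    missing_roles = [r for r in ROLES if r not in role_map]
    if missing_roles:
        raise ValueError(f"role_map missing roles: {missing_roles}")

    vf = pysam.VariantFile(str(path))
    for role, sample in role_map.items():
        if sample not in vf.header.samples:
            raise ValueError(f"sample {sample!r} for role {role!r} not in VCF")

    contigs = [(name, int(c.length or 0)) for name, c in vf.header.contigs.items()]
    rows = []
    for rec in vf:
        if rec.alts is None or len(rec.ref) != 1:
            continue
        row = {
            "chrom": rec.chrom,
            "pos": rec.pos,
            "ref": rec.ref,
            "alt": rec.alts[0],
            "n_alt_alleles": len(rec.alts),
        }
        for role in ("parent_sterile", "parent_fertile"):
            row[f"gt_{role}"] = _gt_string(rec.samples[role_map[role]])
        for role in ROLES:
            ad = rec.samples[role_map[role]].get("AD")
            if ad is None or ad[0] is None:
                raise ValueError(
                    f"sample {role_map[role]!r} lacks AD at {rec.chrom}:{rec.pos}"
                )
            row[f"ad_ref_{role}"] = int(ad[0])
            row[f"ad_alt_{role}"] = int(ad[1])
        rows.append(row)
    vf.close()
    sites = pd.DataFrame(rows)
    if sites.empty:
        raise ValueError(f"no usable SNP records in {path}")

    if contigs:
        order = {name: i for i, (name, _) in enumerate(contigs)}
        undeclared = sorted(set(sites["chrom"]) - set(order))
        for name in undeclared:
            order[name] = len(order)
            contigs.append((name, 0))
    else:
        names = sorted(set(sites["chrom"]))
        order = {name: i for i, name in enumerate(names)}
        contigs = [(name, 0) for name in names]

    key = sites["chrom"].map(order).to_numpy() * (sites["pos"].max() + 1) + sites["pos"].to_numpy()
    if not np.all(np.diff(key) > 0):
        warnings.warn(f"{path}: records out of order; sorting by (contig, pos)")
        sites = sites.iloc[np.argsort(key, kind="stable")].reset_index(drop=True)
    return Dataset(sites, tuple(contigs))


def write_vcf(
    sites: pd.DataFrame,
    chromosomes: Sequence[tuple[str, int]],
    path: str | Path,
) -> Path:
    """Write the four-role site table as an uncompressed VCF 4.2 file."""
    header = pysam.VariantHeader()
    header.add_line('##source=bsamap')
    for name, length in chromosomes:
        if length > 0:
            header.contigs.add(name, length=length)
        else:
            header.contigs.add(name)
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    header.add_line('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">')
    for role in ROLES:
        header.add_sample(role)

    path = Path(path)
    out = pysam.VariantFile(str(path), "w", header=header)
    has_parent_ad = "ad_ref_parent_sterile" in sites.columns
    for row in sites.itertuples(index=False):
        rec = out.new_record(
            contig=row.chrom, start=row.pos - 1, alleles=(row.ref, row.alt)
        )
        gts = {
            "parent_sterile": row.gt_parent_sterile,
            "parent_fertile": row.gt_parent_fertile,
        }
        for role in ROLES:
            sample = rec.samples[role]
            if role in gts:
                a, b = gts[role].split("/")
                sample["GT"] = (None, None) if a == "." else (int(a), int(b))
            else:
                sample["GT"] = (None, None)
            if role.startswith("bulk") or has_parent_ad:
                sample["AD"] = (
                    int(getattr(row, f"ad_ref_{role}")),
                    int(getattr(row, f"ad_alt_{role}")),
                )
        out.write(rec)
    out.close()
    return path


def write_bed(regions: Iterable, path: str | Path, comment: str | None = None) -> Path:
    """Write candidate regions as BED (0-based half-open): start-1, end."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# bsamap candidate regions{': ' + comment if comment else ''}\n")
        for r in regions:
            fh.write(f"{r.chrom}\t{r.start - 1}\t{r.end}\t{r.peak_value:.6g}\n")
    return path


def read_bed(path: str | Path) -> pd.DataFrame:
    """Read a BED written by :func:`write_bed` back to 1-based inclusive."""
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None,
        names=["chrom", "start0", "end", "score"],
    )
    df["start"] = df["start0"] + 1
    return df[["chrom", "start", "end", "score"]]


def write_tsv(frame: pd.DataFrame, path: str | Path, params: Mapping | None = None) -> Path:
    """Write a table as TSV with ``# key=value`` provenance header comments."""
    path = Path(path)
    with open(path, "w") as fh:
        for key, value in (params or {}).items():
            fh.write(f"# {key}={value}\n")
        frame.to_csv(fh, sep="\t", index=False)
    return path
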