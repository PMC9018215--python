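"""Readers and writers for VCF, PED, BED/GFF3 and the TSV tables.

VCF parsing goes through pysam; multiallelic records are split into one
biallelic record per ALT allele on read, phase separators are accepted and
phase discarded, and genotypes become ALT-allele dosages in {0, 1, 2} or
``None`` when missing.  BED (0-based, half-open) and GFF3 (1-based,
inclusive) exon annotations are both converted to the package's internal
1-based inclusive intervals at the boundary.
"""
from __future__ import annotations

import re
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

from .core import (
    FormatError,
    GenomicInterval,
    ParseError,
    PedigreeMember,
    StructureError,
    VariantRecord,
    pedigree_by_id,
    topological_order,
)

__all__ = [
    "read_vcf",
    "write_vcf",
    "read_ped",
    "write_ped",
    "read_bed",
    "read_gff3_exons",
    "read_exons",
    "write_bed",
]


def read_vcf(path) -> Tuple[List[VariantRecord], List[str]]:
    """Read a VCF v4.2 into biallelic VariantRecords plus the sample list."""
    import pysam

    records: List[VariantRecord] = []
    with pysam.VariantFile(str(path)) as vf:
        samples = list(vf.header.samples)
        for rec in vf:
            if rec.alts is None:
                continue
            if samples and "GT" not in rec.format:
                raise FormatError(
                    f"{path}: record {rec.chrom}:{rec.pos} has no GT field"
                )
            # one biallelic record per ALT allele; a diploid call contributes
            # to each ALT the number of alleles equal to that ALT's index
            per_alt_dosages = [dict() for _ in rec.alts]
            depths = {}
            for sid in samples:
                call = rec.samples[sid]
                gt = call.get("GT")
                dp = call.get("DP")
                try:
                    depths[sid] = None if dp is None else int(dp)
                except (TypeError, ValueError):
                    depths[sid] = None
                if gt is None or any(a is None for a in gt):
                    for d in per_alt_dosages:
                        d[sid] = None
                else:
                    for k, d in enumerate(per_alt_dosages):
                        d[sid] = sum(1 for a in gt if a == k + 1)
            for k, alt in enumerate(rec.alts):
                records.append(VariantRecord(
                    chrom=rec.chrom, pos=rec.pos, ref=rec.ref, alt=alt,
                    dosages=per_alt_dosages[k], depths=dict(depths),
                    vid=rec.id,
                ))
    return records, samples


def _chrom_sort_key(chrom: str):
    c = chrom[3:] if chrom.lower().startswith("chr") else chrom
    return (0, int(c)) if c.isdigit() else (1, c)


def write_vcf(path, variants: Sequence[VariantRecord], samples: Sequence[str],
              source: str = "hyperlpa") -> None:
    """Write biallelic VariantRecords as a plain-text VCF v4.2 (GT + DP)."""
    variants = sorted(variants, key=lambda v: (_chrom_sort_key(v.chrom), v.pos,
                                               v.ref, v.alt))
    chroms = []
    for v in variants:
        if v.chrom not in chroms:
            chroms.append(v.chrom)
    lines = ["##fileformat=VCFv4.2", f"##source={source}"]
    lines += [f"##contig=<ID={c}>" for c in chroms]
    lines += [
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
    ]
    header = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO",
              "FORMAT"] + list(samples)
    lines.append("\t".join(header))
    for v in variants:
        fields = [v.chrom, str(v.pos), v.vid or ".", v.ref, v.alt, ".", "PASS",
                  ".", "GT:DP"]
        for sid in samples:
            d = v.dosages.get(sid)
            if d is None:
                gt = "./."
            else:
                di = int(d)
                if di != d or di not in (0, 1, 2):
                    raise FormatError(
                        f"{v.chrom}:{v.pos} sample {sid}: dosage {d!r} is not "
                        "a hard call; cannot encode as GT"
                    )
                gt = {0: "0/0", 1: "0/1", 2: "1/1"}[di]
            dp = v.depths.get(sid)
            fields.append(f"{gt}:{'.' if dp is None else int(dp)}")
        lines.append("\t".join(fields))
    Path(path).write_text("\n".join(lines) + "\n")


_AFFECTION_TO_PHENOTYPE = {"2": "high", "1": "normal", "0": "unassigned",
                           "-9": "unassigned"}
_PHENOTYPE_TO_AFFECTION = {"high": "2", "normal": "1", "unassigned": "-9"}


def read_ped(path) -> List[PedigreeMember]:
    """Read a 6-column PED file into PedigreeMembers.

    The affection column encodes the high-Lp(a) phenotype
    (1 unaffected, 2 affected, 0/-9 unassigned).
    """
    members: List[PedigreeMember] = []
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) < 6:
            raise ParseError(f"{path} line {ln}: expected >= 6 columns")
        _fam, mid, father, mother, sex, affection = parts[:6]
        if sex not in ("1", "2"):
            raise ParseError(f"{path} line {ln}: sex must be 1 or 2")
        if affection not in _AFFECTION_TO_PHENOTYPE:
            raise ParseError(f"{path} line {ln}: bad affection {affection!r}")
        members.append(PedigreeMember(
            member_id=mid,
            father_id=None if father == "0" else father,
            mother_id=None if mother == "0" else mother,
            sex="male" if sex == "1" else "female",
            lpa_phenotype=_AFFECTION_TO_PHENOTYPE[affection],
        ))
    topological_order(members)   # raises on unknown parents / cycles
    return members


def write_ped(path, members: Sequence[PedigreeMember],
              family_id: str = "FAM1") -> None:
    lines = []
    for m in members:
        lines.append("\t".join([
            family_id, m.member_id, m.father_id or "0", m.mother_id or "0",
            "1" if m.sex == "male" else "2",
            _PHENOTYPE_TO_AFFECTION[m.lpa_phenotype],
        ]))
    Path(path).write_text("\n".join(lines) + "\n")


def read_bed(path) -> List[GenomicInterval]:
    """Read BED intervals, converting 0-based half-open to 1-based inclusive."""
    import pyranges as pr

    df = pr.read_bed(str(path)).df
    return [GenomicInterval(str(r.Chromosome), int(r.Start) + 1, int(r.End))
            for r in df.itertuples()]


def read_gff3_exons(path) -> List[GenomicInterval]:
    """Read exon features from a GFF3 file (1-based inclusive already)."""
    intervals = []
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 5:
            raise ParseError(f"{path} line {ln}: expected >= 5 GFF3 columns")
        if parts[2].lower() != "exon":
            continue
        intervals.append(GenomicInterval(parts[0], int(parts[3]), int(parts[4])))
    return intervals


def read_exons(path) -> List[GenomicInterval]:
    """Dispatch on extension: .bed or .gff/.gff3."""
    suffix = Path(path).suffix.lower()
    if suffix == ".bed":
        return read_bed(path)
    if suffix in (".gff", ".gff3"):
        return read_gff3_exons(path)
    raise FormatError(f"{path}: unknown exon annotation format {suffix!r}")


def write_bed(path, intervals: Sequence[GenomicInterval],
              names: Optional[Sequence[str]] = None) -> None:
    """Write 1-based inclusive intervals as BED (0-based half-open)."""
    lines = []
    for i, iv in enumerate(intervals):
        name = names[i] if names else f"exon{i + 1}"
        lines.append(f"{iv.chrom}\t{iv.start - 1}\t{iv.end}\t{name}")
    Path(path).write_text("\n".join(lines) + "\n")
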