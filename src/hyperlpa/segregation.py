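"""Family-based exome variant prioritization.

The scan mirrors a dominant-model family filter: variants must be
confidently covered in every analyzed individual (depth filter), lie within
a window of annotated exons (proximity filter), and segregate with the
phenotype — every affected individual carries at least one alternate
allele, no (or up to a tolerated number of) unaffected carriers, and at
most a tolerated number of homozygous-alternate carriers among the
affected.  Missing genotypes fail the affected-carrier requirement and
never count as phenocopies.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import pandas as pd

from .core import (
    ConfigurationError,
    GenomicInterval,
    VariantRecord,
    norm_chrom,
)

__all__ = [
    "SegregationConfig",
    "SegregationDiagnostics",
    "filter_depth",
    "filter_exon_proximity",
    "segregates_dominant",
    "run_scan",
]

logger = logging.getLogger(__name__)


@dataclass
class SegregationConfig:
    """Filter-chain parameters (defaults follow the study design)."""

    min_depth: int = 4
    exon_pad: int = 50
    max_phenocopies: int = 0
    max_hom_carriers: int = 0
    mode: str = "dominant"

    def __post_init__(self):
        for name in ("min_depth", "exon_pad", "max_phenocopies",
                     "max_hom_carriers"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if self.mode != "dominant":
            raise ConfigurationError(f"unsupported mode {self.mode!r}")


@dataclass
class SegregationDiagnostics:
    """Counts backing a segregation verdict."""

    phenocopies: int = 0          # unaffected carriers
    hom_affected: int = 0         # affected homozygous-alternate
    missing_affected: int = 0
    missing_unaffected: int = 0


def filter_depth(variants: Sequence[VariantRecord], samples: Sequence[str],
                 min_depth: int) -> List[VariantRecord]:
    """Retain variants where every analyzed sample has depth >= min_depth.

    A sample absent from a variant's depth records counts as depth 0.
    """
    return [v for v in variants
            if all(v.depth(s) >= min_depth for s in samples)]


def filter_exon_proximity(variants: Sequence[VariantRecord],
                          exons: Sequence[GenomicInterval],
                          pad: int) -> List[VariantRecord]:
    """Retain variants within ``pad`` bp of any exon (distance 0 inside)."""
    if not list(exons):
        logger.warning("empty exon set: all %d variants dropped", len(variants))
        return []
    by_chrom: Dict[str, list] = {}
    for e in exons:
        by_chrom.setdefault(norm_chrom(e.chrom), []).append(e)
    out = []
    for v in variants:
        cand = by_chrom.get(norm_chrom(v.chrom), ())
        if any(e.distance(v.chrom, v.pos) <= pad for e in cand):
            out.append(v)
    return out


def segregates_dominant(variant: VariantRecord,
                        affected: Iterable[str],
                        unaffected: Iterable[str],
                        config: Optional[SegregationConfig] = None,
                        ) -> Tuple[bool, SegregationDiagnostics]:
    """Dominant-model segregation test with phenocopy/homozygosity tolerance.

    True iff every affected sample carries >= 1 alternate allele, the number
    of unaffected carriers does not exceed ``max_phenocopies`` and the
    number of homozygous-alternate affected samples does not exceed
    ``max_hom_carriers``.
    """
    cfg = config or SegregationConfig()
    aff, unaff = set(affected), set(unaffected)
    if not aff or not unaff:
        raise ConfigurationError("affected and unaffected sets must be non-empty")
    if aff & unaff:
        raise ConfigurationError(
            f"samples in both groups: {sorted(aff & unaff)}"
        )
    diag = SegregationDiagnostics()
    carriers_ok = True
    for s in sorted(aff):
        d = variant.dosage(s)
        if d is None:
            diag.missing_affected += 1
            carriers_ok = False
        elif d >= 1:
            if d >= 2:
                diag.hom_affected += 1
        else:
            carriers_ok = False
    for s in sorted(unaff):
        d = variant.dosage(s)
        if d is None:
            diag.missing_unaffected += 1
        elif d >= 1:
            diag.phenocopies += 1
    verdict = (carriers_ok
               and diag.phenocopies <= cfg.max_phenocopies
               and diag.hom_affected <= cfg.max_hom_carriers)
    return verdict, diag


def run_scan(vcf_path, ped_path, exons_path,
             config: Optional[SegregationConfig] = None,
             samples: Optional[Sequence[str]] = None,
             ) -> Tuple[pd.DataFrame, Dict[str, dict]]:
    """Depth -> exon-proximity -> dominant-segregation scan over a VCF.

    Affection status comes from the PED file (unassigned individuals are
    excluded); ``samples`` optionally restricts the analyzed set (e.g. the
    sequenced subset of a larger pedigree).  Returns the candidate table
    and per-stage survivor counts.
    """
    from . import io as hio

    cfg = config or SegregationConfig()
    variants, vcf_samples = hio.read_vcf(vcf_path)
    members = hio.read_ped(ped_path)
    exons = hio.read_exons(exons_path)

    analyzed = set(vcf_samples)
    if samples is not None:
        analyzed &= set(samples)
    affected = [m.member_id for m in members
                if m.lpa_phenotype == "high" and m.member_id in analyzed]
    unaffected = [m.member_id for m in members
                  if m.lpa_phenotype == "normal" and m.member_id in analyzed]
    if not affected:
        raise ConfigurationError("no affected individuals among analyzed samples")
    used = affected + unaffected

    counts: Dict[str, dict] = {}
    stage_in = variants
    depth_pass = filter_depth(stage_in, used, cfg.min_depth)
    counts["depth"] = {"in": len(stage_in), "out": len(depth_pass),
                       "dropped": len(stage_in) - len(depth_pass)}
    prox_pass = filter_exon_proximity(depth_pass, exons, cfg.exon_pad)
    counts["exon_proximity"] = {"in": len(depth_pass), "out": len(prox_pass),
                                "dropped": len(depth_pass) - len(prox_pass)}

    rows = []
    for v in prox_pass:
        ok, diag = segregates_dominant(v, affected, unaffected, cfg)
        if ok:
            rows.append({
                "chrom": v.chrom, "pos": v.pos, "id": v.vid or ".",
                "ref": v.ref, "alt": v.alt,
                "phenocopies": diag.phenocopies,
                "hom_affected": diag.hom_affected,
                "missing": diag.missing_affected + diag.missing_unaffected,
            })
    counts["segregation"] = {"in": len(prox_pass), "out": len(rows),
                             "dropped": len(prox_pass) - len(rows)}
    for stage, c in counts.items():
        logger.info("stage=%s in=%d out=%d dropped=%d",
                    stage, c["in"], c["out"], c["dropped"])
    table = pd.DataFrame(rows, columns=["chrom", "pos", "id", "ref", "alt",
                                        "phenocopies", "hom_affected",
                                        "missing"])
    return table, counts
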