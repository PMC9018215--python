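"""Synthetic-data generator for the hyper-Lp(a) pedigree study design.

This module emulates the study material end to end so that every downstream
stage (scoring, percentile placement, segregation filtering, phenotype
models) can be exercised without any external download:

* a three-generation, 22-member pedigree in which a single short apo(a)
  allele (21 total KIV domains) carrying three rare Lp(a)-raising SNPs
  (rs3798220, rs186696265, rs140570886) segregates with Lp(a) > 150 nmol/L;
* Mendelian gene dropping of founder haplotypes through the pedigree
  (no recombination within a chromosome; independent assortment across
  chromosomes);
* phenotypes with isoform-size-dependent Lp(a) expression, elevated
  oxidized phospholipids per particle on rs3798220 alleles, LDL-C, and
  CAD status from a liability-threshold model dominated by the Lp(a)
  contribution;
* an unrelated reference cohort in Hardy-Weinberg equilibrium;
* synthetic scoring-weight panels (48-row Lp(a) score, genome-wide-style
  CAD score with rows inside the LPA ablation interval).

All randomness flows from a single integer seed fanned out into
independent per-stage substreams; identical config + seed produce
byte-identical output files.
"""
from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy.stats import norm, truncnorm

from .core import (
    KIV2_4925,
    KNOWN_SNP_FLAGS,
    LPA_LOCUS,
    RS10455872,
    RS140570886,
    RS186696265,
    RS3798220,
    ConfigurationError,
    GenomicInterval,
    LpaAllele,
    PedigreeMember,
    PhenotypeRecord,
    StructureError,
    VariantRecord,
    pedigree_by_id,
    topological_order,
)

__all__ = [
    "SimConfig",
    "figure_pedigree",
    "default_founder_alleles",
    "make_allele",
    "gene_drop",
    "template_gene_drop",
    "simulate_lpa",
    "simulate_reference_cohort",
    "simulate_cad",
    "liability_threshold",
    "write_fixtures",
    "SiteDef",
    "EXOME_SAMPLES",
]


@dataclass
class SimConfig:
    """Parameters of the synthetic study.

    Expression of an allele with ``k`` total KIV domains follows
    ``e0 * exp(-decay * (k - k_ref))`` nmol/L, a monotone-decreasing curve
    capturing the inverse isoform-size/concentration relationship.
    Per-SNP effects are additive on the allele contribution and quoted in
    mg/dL (converted with ``nmol_per_mg_dl``); allele expression noise is
    multiplicative log-normal.
    """

    # isoform-size expression curve
    e0: float = 160.0
    k_ref: int = 15
    decay: float = 0.12
    noise_sigma: float = 0.25
    # additive per-allele SNP effects, mg/dL
    snp_effects_mg_dl: dict = field(
        default_factory=lambda: {
            RS186696265: 47.6,
            RS140570886: 23.8,
            RS3798220: 43.0,
            RS10455872: 0.0,
            KIV2_4925: -5.0,
        }
    )
    nmol_per_mg_dl: float = 2.4
    # other phenotypes
    ldl_mean: float = 3.0
    ldl_sd: float = 0.75
    oxpl_baseline: float = 7.45
    oxpl_rs3798220_increment: float = 1.32
    oxpl_sd_noncarrier: float = 1.65
    oxpl_sd_carrier: float = 0.68
    dominant_fraction_mean: float = 0.86
    dominant_fraction_sd: float = 0.14
    # CAD liability-threshold model
    cad_beta: float = 1.0
    cad_residual_sd: float = 0.5
    cad_baseline_prevalence: float = 0.05
    lpa_pop_mean: float = 35.0
    lpa_pop_sd: float = 45.0
    # reference cohort
    reference_n: int = 1000
    seed: int = 0

    def __post_init__(self):
        for name in ("noise_sigma", "ldl_sd", "oxpl_sd_noncarrier",
                     "oxpl_sd_carrier", "dominant_fraction_sd",
                     "cad_residual_sd", "lpa_pop_sd"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if not (0.0 <= self.cad_baseline_prevalence <= 1.0):
            raise ConfigurationError("cad_baseline_prevalence must lie in [0, 1]")
        if self.nmol_per_mg_dl <= 0:
            raise ConfigurationError("nmol_per_mg_dl must be > 0")
        if self.reference_n < 1:
            raise ConfigurationError("reference_n must be >= 1")
        unknown = set(self.snp_effects_mg_dl) - KNOWN_SNP_FLAGS
        if unknown:
            raise ConfigurationError(f"unknown SNP flags in config: {sorted(unknown)}")

    def expression(self, kiv_count: int) -> float:
        """Expected allele contribution (nmol/L) from isoform size alone."""
        return self.e0 * math.exp(-self.decay * (kiv_count - self.k_ref))


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# Pedigree template
# ---------------------------------------------------------------------------

# (id, father, mother, sex, age, lpa_phenotype, cad_status).  The deceased
# grandparents carry `unassigned` Lp(a) labels (no plasma sample); the
# high/normal labels of the remaining 20 follow the family classification:
# high > 150 nmol/L, normal <= 90 nmol/L.
_TEMPLATE_ROWS = [
    ("I-1", None, None, "male", 80, "unassigned", "affected"),
    ("I-2", None, None, "female", 82, "unassigned", "affected"),
    ("II-A1", None, None, "female", 58, "normal", "unaffected"),
    ("II-A2", "I-1", "I-2", "male", 60, "high", "unaffected"),
    ("II-B1", "I-1", "I-2", "male", 57, "high", "affected"),
    ("II-B2", None, None, "female", 55, "normal", "unaffected"),
    ("II-C1", None, None, "male", 62, "high", "affected"),
    ("II-C2", "I-1", "I-2", "female", 59, "high", "unaffected"),
    ("II-D1", "I-1", "I-2", "male", 54, "high", "affected"),
    ("II-D2", None, None, "female", 53, "normal", "unaffected"),
    ("II-E1", None, None, "male", 52, "normal", "unaffected"),
    ("II-E2", "I-1", "I-2", "female", 50, "high", "unaffected"),
    ("III-A1", "II-A2", "II-A1", "female", 35, "high", "unaffected"),
    ("III-A2", "II-A2", "II-A1", "male", 33, "high", "unaffected"),
    ("III-A3", "II-A2", "II-A1", "male", 32, "high", "affected"),
    ("III-B1", "II-B1", "II-B2", "male", 35, "high", "affected"),
    ("III-B2", "II-B1", "II-B2", "female", 31, "high", "unaffected"),
    ("III-B3", "II-B1", "II-B2", "female", 28, "normal", "unaffected"),
    ("III-C1", "II-C1", "II-C2", "female", 36, "high", "unaffected"),
    ("III-C2", "II-C1", "II-C2", "female", 34, "high", "unaffected"),
    ("III-C3", "II-C1", "II-C2", "female", 30, "high", "unaffected"),
    ("III-C4", "II-C1", "II-C2", "male", 27, "high", "affected"),
]

# Fixed Mendelian transmission reproducing the published segregation pattern:
# member -> (index into father's allele pair, index into mother's pair).
_TEMPLATE_CHOICES = {
    "II-A2": (0, 0),
    "II-B1": (0, 1),
    "II-C2": (0, 0),
    "II-D1": (0, 1),
    "II-E2": (0, 0),
    "III-A1": (0, 0),
    "III-A2": (0, 1),
    "III-A3": (0, 0),
    "III-B1": (0, 0),
    "III-B2": (0, 1),
    "III-B3": (1, 0),
    "III-C1": (0, 0),
    "III-C2": (1, 0),
    "III-C3": (0, 1),
    "III-C4": (1, 0),
}

# 13-member whole-exome subset: 9 with the high-Lp(a) phenotype (all of them
# 21-KIV carriers) and 4 with normal Lp(a).
EXOME_SAMPLES = [
    "II-A2", "II-B1", "II-C2", "II-D1", "II-E2",
    "III-A3", "III-B1", "III-C1", "III-C4",
    "II-A1", "II-B2", "II-D2", "III-B3",
]


def figure_pedigree() -> List[PedigreeMember]:
    """The packaged 22-member, three-generation pedigree template."""
    return [
        PedigreeMember(member_id=i, father_id=f, mother_id=m, sex=s, age=a,
                       lpa_phenotype=lp, cad_status=cad)
        for (i, f, m, s, a, lp, cad) in _TEMPLATE_ROWS
    ]


def make_allele(allele_id: str, kiv_count: int, snp_flags: Iterable[str],
                config: SimConfig) -> LpaAllele:
    """Build an allele with expression taken from the config's size curve."""
    return LpaAllele(
        allele_id=allele_id,
        kiv_count=kiv_count,
        snp_flags=frozenset(snp_flags),
        base_expression=config.expression(kiv_count),
    )


def default_founder_alleles(config: Optional[SimConfig] = None) -> Dict[str, tuple]:
    """Founder allele pairs of the template.

    The 21-KIV allele ``A21`` (on founder I-1) carries the three rare
    Lp(a)-raising SNPs; the spouse II-C1 carries the alternative
    high-Lp(a) combination of a 15-KIV allele and a 20-KIV allele tagged by
    rs10455872; one grandmaternal allele carries the KIV-2 splice-site
    variant 4925G>A.  All other alleles are ordinary large isoforms.
    """
    cfg = config or SimConfig()
    A = lambda aid, k, flags=(): make_allele(aid, k, flags, cfg)
    return {
        "I-1": (A("A21", 21, (RS3798220, RS186696265, RS140570886)), A("N30.I1", 30)),
        "I-2": (A("N28.I2", 28), A("N32.I2", 32, (KIV2_4925,))),
        "II-A1": (A("N29.A1", 29), A("N33.A1", 33)),
        "II-B2": (A("N31.B2", 31), A("N34.B2", 34)),
        "II-C1": (A("S15", 15), A("S20", 20, (RS10455872,))),
        "II-D2": (A("N30.D2", 30), A("N35.D2", 35)),
        "II-E1": (A("N27.E1", 27), A("N36.E1", 36)),
    }


# ---------------------------------------------------------------------------
# Gene dropping
# ---------------------------------------------------------------------------

def _drop_paths(members: Sequence[PedigreeMember], rng,
                choices: Optional[Mapping[str, tuple]] = None) -> Dict[str, tuple]:
    """Trace each member's two haplotypes back to founder haplotype labels.

    Without recombination every transmitted haplotype *is* one founder
    haplotype, so a member's genome (for one chromosome) is fully described
    by a pair of labels ``founder_id.slot``.  ``choices`` fixes the
    transmission (template mode); otherwise each inherited haplotype is
    drawn uniformly from the parent's pair.
    """
    order = topological_order(members)
    paths: Dict[str, tuple] = {}
    for m in order:
        if m.is_founder:
            paths[m.member_id] = (f"{m.member_id}.0", f"{m.member_id}.1")
        else:
            if choices is not None:
                fi, mi = choices[m.member_id]
            else:
                fi, mi = int(rng.integers(2)), int(rng.integers(2))
            paths[m.member_id] = (
                paths[m.father_id][fi],
                paths[m.mother_id][mi],
            )
    return paths


def gene_drop(pedigree: Sequence[PedigreeMember],
              founder_alleles: Mapping[str, tuple],
              seed=0) -> Dict[str, tuple]:
    """Drop founder LPA alleles through the pedigree under Mendelian rules.

    Each non-founder receives one allele drawn uniformly from each parent's
    pair; founders keep their assigned pair.  Deterministic for a fixed seed.
    """
    rng = _as_rng(seed)
    index = pedigree_by_id(pedigree)
    for m in pedigree:
        if m.is_founder and m.member_id not in founder_alleles:
            raise ConfigurationError(
                f"founder {m.member_id} has no allele assignment"
            )
    paths = _drop_paths(pedigree, rng)
    out: Dict[str, tuple] = {}
    for mid, (pat, mat) in paths.items():
        def resolve(label):
            fid, slot = label.rsplit(".", 1)
            return founder_alleles[fid][int(slot)]
        out[mid] = (resolve(pat), resolve(mat))
    return out


def template_gene_drop(config: Optional[SimConfig] = None,
                       founder_alleles: Optional[Mapping[str, tuple]] = None
                       ) -> Dict[str, tuple]:
    """The fixed, published segregation pattern of the template pedigree."""
    fa = founder_alleles or default_founder_alleles(config)
    paths = _drop_paths(figure_pedigree(), rng=None, choices=_TEMPLATE_CHOICES)
    out = {}
    for mid, (pat, mat) in paths.items():
        def resolve(label):
            fid, slot = label.rsplit(".", 1)
            return fa[fid][int(slot)]
        out[mid] = (resolve(pat), resolve(mat))
    return out


# ---------------------------------------------------------------------------
# Phenotype simulation
# ---------------------------------------------------------------------------

def _allele_contribution(allele: LpaAllele, config: SimConfig, rng) -> float:
    """nmol/L contribution: size-curve expression x log-normal noise, plus
    additive SNP effects (converted from mg/dL); floored at 0."""
    for flag in allele.snp_flags:
        if flag not in config.snp_effects_mg_dl:
            raise ConfigurationError(
                f"allele {allele.allele_id}: no configured effect for {flag!r}"
            )
    if config.noise_sigma > 0:
        noise = math.exp(config.noise_sigma * rng.standard_normal()
                         - 0.5 * config.noise_sigma ** 2)
    else:
        noise = 1.0
    snp = sum(config.snp_effects_mg_dl[f] for f in allele.snp_flags)
    return max(0.0, allele.base_expression * noise
               + snp * config.nmol_per_mg_dl)


def expected_lpa(genotype: tuple, config: SimConfig) -> float:
    """Closed-form expectation of the simulated Lp(a) total (nmol/L).

    The multiplicative noise has unit mean, so the expectation is the sum of
    per-allele means ignoring the floor at zero (exact whenever the floored
    mass is negligible).
    """
    total = 0.0
    for allele in genotype:
        snp = sum(config.snp_effects_mg_dl[f] for f in allele.snp_flags)
        total += max(0.0, allele.base_expression + snp * config.nmol_per_mg_dl)
    return total


def simulate_lpa(genotype: tuple, config: Optional[SimConfig] = None,
                 seed=0, member_id: str = "") -> PhenotypeRecord:
    """Simulate one individual's Lp(a)-related phenotypes from an allele pair."""
    cfg = config or SimConfig()
    rng = _as_rng(seed)
    a, b = genotype
    ca = _allele_contribution(a, cfg, rng)
    cb = _allele_contribution(b, cfg, rng)
    total = ca + cb

    shorter, longer = (a, b) if a.kiv_count <= b.kiv_count else (b, a)
    c_short = ca if shorter is a else cb
    fraction: Optional[float] = None
    if total > 0:
        if shorter.snp_flags & {RS186696265, RS140570886}:
            lo, hi = 0.5, 1.0
            mu, sd = cfg.dominant_fraction_mean, cfg.dominant_fraction_sd
            if sd > 0:
                fraction = float(truncnorm.rvs((lo - mu) / sd, (hi - mu) / sd,
                                               loc=mu, scale=sd, random_state=rng))
            else:
                fraction = mu
        else:
            fraction = min(1.0, max(0.5, c_short / total))

    ldl = max(0.0, cfg.ldl_mean + cfg.ldl_sd * rng.standard_normal())
    carrier = any(RS3798220 in al.snp_flags for al in genotype)
    if carrier:
        oxpl = cfg.oxpl_baseline + cfg.oxpl_rs3798220_increment \
            + cfg.oxpl_sd_carrier * rng.standard_normal()
    else:
        oxpl = cfg.oxpl_baseline + cfg.oxpl_sd_noncarrier * rng.standard_normal()

    return PhenotypeRecord(
        member_id=member_id,
        lpa_nmol_l=total,
        ldl_c_mmol_l=ldl,
        oxpl_per_lpa_nmol_l=max(0.0, oxpl),
        isoform_sizes=(shorter.kiv_count, longer.kiv_count),
        dominant_isoform_fraction=fraction,
    )


# ---------------------------------------------------------------------------
# Reference cohort and CAD liability
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SiteDef:
    """One biallelic site of the synthetic genotyping panel."""

    key: str
    chrom: str
    pos: int
    ref: str
    alt: str
    freq: float   # effect/ALT allele frequency

    def __post_init__(self):
        if not (0.0 <= self.freq <= 1.0):
            raise ConfigurationError(
                f"{self.key}: allele frequency {self.freq} outside [0, 1]"
            )


def simulate_reference_cohort(n: int, site_spec: Sequence, seed=0,
                              prefix: str = "R"):
    """Draw an unrelated cohort under Hardy-Weinberg equilibrium.

    ``site_spec`` is a sequence of :class:`SiteDef` or ``(locus_key, freq)``
    pairs.  Returns a pandas DataFrame of ALT dosages (samples x sites),
    genotypes independent across sites and individuals with dosage
    distribution (q^2, 2pq, p^2).
    """
    import pandas as pd

    if n < 1:
        raise ConfigurationError("n must be >= 1")
    rng = _as_rng(seed)
    keys, freqs = [], []
    for s in site_spec:
        if isinstance(s, SiteDef):
            keys.append(s.key)
            freqs.append(s.freq)
        else:
            k, f = s
            if not (0.0 <= f <= 1.0):
                raise ConfigurationError(f"{k}: frequency {f} outside [0, 1]")
            keys.append(k)
            freqs.append(f)
    mat = rng.binomial(2, np.asarray(freqs)[None, :], size=(n, len(keys)))
    samples = [f"{prefix}{i + 1:05d}" for i in range(n)]
    return pd.DataFrame(mat, index=samples, columns=keys)


def cohort_variants(dosages, sites: Sequence[SiteDef],
                    depth: int = 35) -> List[VariantRecord]:
    """Convert a cohort dosage table into VariantRecords for scoring."""
    by_key = {s.key: s for s in sites}
    records = []
    for key in dosages.columns:
        s = by_key[key]
        col = dosages[key]
        records.append(VariantRecord(
            chrom=s.chrom, pos=s.pos, ref=s.ref, alt=s.alt, vid=s.key,
            dosages={sid: int(v) for sid, v in col.items()},
            depths={sid: depth for sid in dosages.index},
        ))
    return records


def liability_threshold(config: SimConfig) -> float:
    """Liability threshold giving the configured baseline prevalence at
    beta = 0 (polygenic component standardized, residual N(0, sigma^2))."""
    if config.cad_baseline_prevalence == 0:
        return math.inf
    null_sd = math.sqrt(1.0 + config.cad_residual_sd ** 2)
    return float(norm.ppf(1.0 - config.cad_baseline_prevalence) * null_sd)


def simulate_cad(lpa_nmol_l: float, polygenic_component: float,
                 config: Optional[SimConfig] = None, seed=0) -> str:
    """Liability-threshold CAD status.

    liability = polygenic + beta * standardized Lp(a) + residual;
    affected iff liability exceeds the baseline-prevalence threshold.
    """
    cfg = config or SimConfig()
    rng = _as_rng(seed)
    z = (lpa_nmol_l - cfg.lpa_pop_mean) / cfg.lpa_pop_sd if cfg.lpa_pop_sd > 0 else 0.0
    liab = polygenic_component + cfg.cad_beta * z \
        + cfg.cad_residual_sd * rng.standard_normal()
    return "affected" if liab > liability_threshold(cfg) else "unaffected"


# ---------------------------------------------------------------------------
# Genotyping panel and weight files
# ---------------------------------------------------------------------------

# Positions approximate GRCh37 and lie inside the LPA ablation interval.
LPA_SNP_SITES = {
    RS186696265: SiteDef(RS186696265, "chr6", 160_926_500, "C", "T", 0.005),
    RS140570886: SiteDef(RS140570886, "chr6", 160_966_077, "G", "A", 0.010),
    KIV2_4925: SiteDef(KIV2_4925, "chr6", 160_987_000, "G", "A", 0.010),
    RS10455872: SiteDef(RS10455872, "chr6", 161_006_077, "A", "G", 0.070),
    RS3798220: SiteDef(RS3798220, "chr6", 161_010_118, "T", "C", 0.010),
}

# The synthetic panel itself (filler frequencies, background sites, weight
# draws) is frozen with an internal constant so that the emitted weight
# files behave as fixed inputs regardless of the simulation seed.
_PANEL_SEED = 726_100_105

_BG_CHROMS = ["1", "2", "3", "7", "11", "17", "19"]
_EXONS_PER_BG_CHROM = [(100_000, 100_200), (200_000, 200_180), (305_000, 305_150)]
_LPA_EXONS = [(160_986_900, 160_986_960),    # KIV-2 splice region
              (161_010_050, 161_010_250)]    # protease-domain exon
# exonic background sites where one analyzed sample is left under-covered
_LOW_DEPTH_KEYS = {"BG1_100050", "BG3_100050", "BG7_100120"}
_LOW_DEPTH_SAMPLE = "II-B2"


def build_panel() -> dict:
    """Assemble the full synthetic site panel and both weight tables.

    Returns a dict with ``sites`` (list of SiteDef), ``lpa_weights`` and
    ``cad_weights`` (lists of (SiteDef, weight)), ``tag_keys`` and
    ``exons`` (list of (chrom, start, end), 1-based inclusive).
    """
    rng = np.random.default_rng(_PANEL_SEED)
    sites: List[SiteDef] = list(LPA_SNP_SITES.values())

    tags = [SiteDef(f"TAG{i + 1:02d}", "chr6", 160_100_000 + i * 1_000, "A", "G", 0.15)
            for i in range(12)]
    fillers = [
        SiteDef(f"FIL{i + 1:02d}", "chr6", 160_300_000 + i * 7_000, "C", "T",
                round(float(rng.uniform(0.05, 0.5)), 3))
        for i in range(32)
    ]
    sites += tags + fillers

    bg = []
    for chrom in _BG_CHROMS:
        e1, e2, e3 = _EXONS_PER_BG_CHROM
        positions = [e1[0] + 50, e1[0] + 120,      # inside first exon
                     e2[1] + 30,                   # within the 50 bp pad
                     e3[1] + 120]                  # beyond the pad
        for pos in positions:
            bg.append(SiteDef(f"BG{chrom}_{pos}", f"chr{chrom}", pos, "G", "A",
                              round(float(rng.uniform(0.05, 0.4)), 3)))
    sites += bg

    cad_bg = []
    cad_chroms = [c for c in [str(i) for i in range(1, 23)] if c != "6"]
    for i in range(40):
        chrom = cad_chroms[i % len(cad_chroms)]
        cad_bg.append(SiteDef(f"CAD{i + 1:02d}", f"chr{chrom}",
                              5_000_000 + i * 1_000, "T", "C",
                              round(float(rng.uniform(0.1, 0.5)), 3)))
    sites += cad_bg

    lpa_weights = [
        (LPA_SNP_SITES[RS186696265], 47.6 * 2.4),
        (LPA_SNP_SITES[RS140570886], 23.8 * 2.4),
        (LPA_SNP_SITES[RS3798220], 43.0 * 2.4),
        (LPA_SNP_SITES[RS10455872], 55.0),
    ]
    lpa_weights += [(t, 8.0) for t in tags]
    lpa_weights += [(f, round(float(rng.normal(0.0, 3.0)), 4)) for f in fillers]
    assert len(lpa_weights) == 48

    cad_weights = [
        (LPA_SNP_SITES[RS186696265], 0.30),
        (LPA_SNP_SITES[RS140570886], 0.25),
        (LPA_SNP_SITES[RS3798220], 0.35),
        (LPA_SNP_SITES[RS10455872], 0.20),
    ]
    cad_weights += [(t, 0.10) for t in tags]
    cad_weights += [(c, round(float(rng.normal(0.0, 0.08)), 4)) for c in cad_bg]

    exons = [(f"chr{c}", a, b) for c in _BG_CHROMS for (a, b) in _EXONS_PER_BG_CHROM]
    exons += [("chr6", a, b) for (a, b) in _LPA_EXONS]

    return {
        "sites": sites,
        "lpa_weights": lpa_weights,
        "cad_weights": cad_weights,
        "tag_keys": [t.key for t in tags],
        "exons": exons,
    }


# Haplotype carriage of the named LPA variants is fixed, not drawn: the
# 21-KIV haplotype carries the three rare SNPs plus every tag site, the
# spouse haplotypes carry their published combination, and the variants are
# absent from all other founder haplotypes.
_HAP_OVERRIDES = {
    "I-1.0": {RS3798220: 1, RS186696265: 1, RS140570886: 1,
              **{f"TAG{i + 1:02d}": 1 for i in range(12)}},
    "II-C1.0": {"TAG01": 1},
    "II-C1.1": {RS10455872: 1, "TAG02": 1, "TAG03": 1},
    "I-2.1": {KIV2_4925: 1},
}
_OVERRIDE_ONLY_KEYS = {RS3798220, RS186696265, RS140570886, RS10455872, KIV2_4925}


def _founder_haplotype_matrix(founders: Sequence[str], sites: Sequence[SiteDef],
                              rng) -> Dict[str, dict]:
    """Per-founder-haplotype allele assignment (0/1 per site)."""
    haps: Dict[str, dict] = {}
    for fid in founders:
        for slot in (0, 1):
            label = f"{fid}.{slot}"
            alleles = {}
            for s in sites:
                if s.key in _OVERRIDE_ONLY_KEYS:
                    alleles[s.key] = 0
                else:
                    alleles[s.key] = int(rng.random() < s.freq)
            alleles.update(_HAP_OVERRIDES.get(label, {}))
            haps[label] = alleles
    return haps


def _member_site_paths(members, rng) -> Dict[str, Dict[str, tuple]]:
    """Per-chromosome founder-haplotype paths (independent assortment)."""
    chroms = ["chr6"] + [f"chr{c}" for c in _BG_CHROMS] \
        + [f"chr{c}" for c in [str(i) for i in range(1, 23)] if c not in _BG_CHROMS]
    paths = {}
    for chrom in chroms:
        if chrom == "chr6":
            paths[chrom] = _drop_paths(members, rng=None, choices=_TEMPLATE_CHOICES)
        else:
            paths[chrom] = _drop_paths(members, rng)
    return paths


def _segregates_in_subset(dosages: Mapping[str, int], affected, unaffected) -> bool:
    # Local dominant-pattern check used only to guarantee uniqueness of the
    # planted causal site; intentionally independent of the segregation module.
    if any((dosages.get(s) or 0) < 1 for s in affected):
        return False
    if any((dosages.get(s) or 0) >= 1 for s in unaffected):
        return False
    return True


def write_fixtures(outdir, config: Optional[SimConfig] = None, seed=None) -> dict:
    """Generate the full fixture set and return its manifest.

    Writes under ``outdir``: family.vcf, reference.vcf, family.ped,
    phenotypes.tsv, founder_alleles.tsv, exons.bed, lpa_weights.tsv,
    cad_weights.tsv and manifest.json.
    """
    import pandas as pd

    from . import io as hio
    from . import __version__

    cfg = config or SimConfig()
    if seed is not None:
        cfg = dataclasses.replace(cfg, seed=int(seed))
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)

    ss = np.random.SeedSequence(cfg.seed)
    rng_hap, rng_drop, rng_pheno, rng_ref, rng_fix = (
        np.random.default_rng(s) for s in ss.spawn(5)
    )

    panel = build_panel()
    sites: List[SiteDef] = panel["sites"]
    members = figure_pedigree()
    founder_alleles = default_founder_alleles(cfg)
    founders = [m.member_id for m in members if m.is_founder]

    haps = _founder_haplotype_matrix(founders, sites, rng_hap)
    paths = _member_site_paths(members, rng_drop)

    member_ids = [m.member_id for m in members]
    genotypes: Dict[str, Dict[str, int]] = {s.key: {} for s in sites}
    for s in sites:
        chrom_paths = paths[s.chrom]
        for mid in member_ids:
            pat, mat = chrom_paths[mid]
            genotypes[s.key][mid] = haps[pat][s.key] + haps[mat][s.key]

    # guarantee that the planted causal site is the unique dominant-pattern
    # survivor among exon-proximal sites in the exome subset
    affected = [m.member_id for m in members
                if m.member_id in EXOME_SAMPLES and m.lpa_phenotype == "high"]
    unaffected = [m.member_id for m in members
                  if m.member_id in EXOME_SAMPLES and m.lpa_phenotype == "normal"]
    exon_proximal = {
        s.key for s in sites
        if any(c == s.chrom and a - 50 <= s.pos <= b + 50
               for (c, a, b) in panel["exons"])
    }
    fixed_sites = []
    for s in sites:
        if s.key == RS3798220 or s.key not in exon_proximal:
            continue
        if _segregates_in_subset(genotypes[s.key], affected, unaffected):
            haps["II-A1.0"][s.key] = 1
            chrom_paths = paths[s.chrom]
            for mid in member_ids:
                pat, mat = chrom_paths[mid]
                genotypes[s.key][mid] = haps[pat][s.key] + haps[mat][s.key]
            fixed_sites.append(s.key)

    # per-sample depths: uniform coverage except the designed dropouts
    depths = {s.key: {mid: 35 for mid in member_ids} for s in sites}
    for key in _LOW_DEPTH_KEYS:
        depths[key][_LOW_DEPTH_SAMPLE] = 2

    family_variants = [
        VariantRecord(chrom=s.chrom, pos=s.pos, ref=s.ref, alt=s.alt, vid=s.key,
                      dosages=dict(genotypes[s.key]), depths=dict(depths[s.key]))
        for s in sites
    ]
    hio.write_vcf(out / "family.vcf", family_variants, member_ids,
                  source=f"hyperlpa {__version__} simulate seed={cfg.seed}")

    # reference cohort under HWE at the same sites
    ref_dosages = simulate_reference_cohort(cfg.reference_n, sites, seed=rng_ref)
    ref_variants = cohort_variants(ref_dosages, sites)
    hio.write_vcf(out / "reference.vcf", ref_variants, list(ref_dosages.index),
                  source=f"hyperlpa {__version__} simulate seed={cfg.seed}")

    hio.write_ped(out / "family.ped", members)
    hio.write_bed(out / "exons.bed",
                  [GenomicInterval(c, a, b) for (c, a, b) in panel["exons"]])

    for name, rows in (("lpa_weights.tsv", panel["lpa_weights"]),
                       ("cad_weights.tsv", panel["cad_weights"])):
        df = pd.DataFrame(
            [(s.chrom, s.pos, s.alt, s.ref, w, s.key) for (s, w) in rows],
            columns=["chrom", "pos", "effect_allele", "other_allele",
                     "weight", "id"],
        )
        df.to_csv(out / name, sep="\t", index=False)

    # phenotypes from the template transmission
    drop = template_gene_drop(cfg, founder_alleles)
    rows = []
    for m in members:
        rec = simulate_lpa(drop[m.member_id], cfg, seed=rng_pheno,
                           member_id=m.member_id)
        a, b = drop[m.member_id]
        rows.append({
            "member_id": m.member_id,
            "sex": m.sex,
            "age": m.age,
            "lpa_phenotype": m.lpa_phenotype,
            "cad_status": m.cad_status,
            "lpa_nmol_l": round(rec.lpa_nmol_l, 3),
            "ldl_c_mmol_l": round(rec.ldl_c_mmol_l, 3),
            "oxpl_per_lpa_nmol_l": round(rec.oxpl_per_lpa_nmol_l, 3),
            "isoform_short_kiv": rec.isoform_sizes[0],
            "isoform_long_kiv": rec.isoform_sizes[1],
            "dominant_isoform_fraction": round(rec.dominant_isoform_fraction, 3),
            "carries_21kiv": int(any(al.kiv_count == 21 for al in (a, b))),
            "carries_4925": int(any(KIV2_4925 in al.snp_flags for al in (a, b))),
            "allele_1": a.allele_id,
            "allele_2": b.allele_id,
        })
    pd.DataFrame(rows).to_csv(out / "phenotypes.tsv", sep="\t", index=False)

    frows = []
    for fid in founders:
        for slot in (0, 1):
            al = founder_alleles[fid][slot]
            frows.append({
                "founder_id": fid, "hap": slot, "allele_id": al.allele_id,
                "kiv_count": al.kiv_count,
                "snp_flags": ",".join(sorted(al.snp_flags)),
                "base_expression_nmol_l": round(al.base_expression, 3),
            })
    pd.DataFrame(frows).to_csv(out / "founder_alleles.tsv", sep="\t", index=False)

    planted = LPA_SNP_SITES[RS3798220]
    manifest = {
        "tool": "hyperlpa",
        "version": __version__,
        "seed": cfg.seed,
        "lpa_interval": f"chr6:{LPA_LOCUS.start}-{LPA_LOCUS.end}",
        "planted_causal": {"id": planted.key, "chrom": planted.chrom,
                           "pos": planted.pos, "ref": planted.ref,
                           "alt": planted.alt},
        "exome_samples": EXOME_SAMPLES,
        "n_sites": len(sites),
        "n_reference": cfg.reference_n,
        "uniqueness_fixed_sites": fixed_sites,
        "files": ["family.vcf", "reference.vcf", "family.ped", "phenotypes.tsv",
                  "founder_alleles.tsv", "exons.bed", "lpa_weights.tsv",
                  "cad_weights.tsv"],
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
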