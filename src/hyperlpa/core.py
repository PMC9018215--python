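"""Shared domain types for the hyper-Lp(a) pedigree toolkit.

Conventions used throughout the package:

* genomic coordinates are 1-based and inclusive of both interval endpoints;
  BED input (0-based, half-open) is converted at the boundary by the readers
  in :mod:`hyperlpa.io`;
* chromosome labels are compared after stripping a leading ``chr`` prefix;
* diploid genotypes are carried as effect/ALT-allele dosages in {0, 1, 2}
  (fractional dosages are tolerated by the scoring engine) or ``None`` when
  the call is missing.
"""
from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

# Identifiers of the rare LPA variants modelled by the simulator.  The three
# Lp(a)-raising SNPs co-occur on the family's short 21-KIV haplotype;
# rs10455872 tags the spouse's 20-KIV allele and the KIV-2 splice-site
# variant 4925G>A dampens expression of the allele that carries it.
RS3798220 = "rs3798220"
RS186696265 = "rs186696265"
RS140570886 = "rs140570886"
RS10455872 = "rs10455872"
KIV2_4925 = "KIV2_4925G>A"

KNOWN_SNP_FLAGS = frozenset(
    {RS3798220, RS186696265, RS140570886, RS10455872, KIV2_4925}
)

# Conversion constants for Lp(a) mass/particle units and cholesterol.
NMOL_PER_MG_DL = 2.4          # Lp(a) particle-to-mass convention (configurable)
MG_DL_TO_MMOL_L = 0.02586     # cholesterol mg/dL -> mmol/L


class ConfigurationError(ValueError):
    """A parameter or input combination is invalid."""


class StructureError(ValueError):
    """A pedigree or file structure violates its invariants."""


class ParseError(ValueError):
    """A text input could not be parsed."""


class FormatError(ValueError):
    """A file does not conform to its declared format."""


class AlleleMismatchError(ValueError):
    """Weight-file alleles do not match the genotype record at a site."""


def norm_chrom(chrom: str) -> str:
    """Normalize a chromosome label by stripping a leading ``chr`` prefix."""
    return chrom[3:] if chrom.lower().startswith("chr") else chrom


@dataclass(frozen=True)
class LpaAllele:
    """One LPA haplotype: isoform size, rare-SNP carriage and expression.

    ``kiv_count`` is the *total* number of kringle-IV domains of the encoded
    apo(a) isoform (the 9 unique KIV types plus the variable KIV-2 repeat);
    ``kiv2_copies`` exposes the repeat number itself.  ``base_expression`` is
    the expected plasma Lp(a) contribution of the allele in nmol/L before
    any SNP effect is added.
    """

    allele_id: str
    kiv_count: int
    snp_flags: frozenset = field(default_factory=frozenset)
    base_expression: float = 0.0

    def __post_init__(self):
        if not (10 <= int(self.kiv_count) <= 50):
            raise ConfigurationError(
                f"kiv_count must lie in [10, 50], got {self.kiv_count!r}"
            )
        if self.base_expression < 0:
            raise ConfigurationError("base_expression must be >= 0")
        object.__setattr__(self, "snp_flags", frozenset(self.snp_flags))

    @property
    def kiv2_copies(self) -> int:
        """Number of KIV-2 repeats (total KIV count minus the 9 unique types)."""
        return int(self.kiv_count) - 9


@dataclass
class PedigreeMember:
    """An individual in the pedigree with parent links and phenotype labels."""

    member_id: str
    father_id: Optional[str] = None
    mother_id: Optional[str] = None
    sex: str = "female"
    age: Optional[float] = None
    lpa_phenotype: str = "unassigned"   # {high, normal, unassigned}
    cad_status: str = "unaffected"      # {affected, unaffected}

    def __post_init__(self):
        if (self.father_id is None) != (self.mother_id is None):
            raise StructureError(
                f"{self.member_id}: parent links must be both present or both absent"
            )
        if self.sex not in ("male", "female"):
            raise ConfigurationError(f"{self.member_id}: sex must be male/female")
        if self.lpa_phenotype not in ("high", "normal", "unassigned"):
            raise ConfigurationError(f"{self.member_id}: bad lpa_phenotype")
        if self.cad_status not in ("affected", "unaffected"):
            raise ConfigurationError(f"{self.member_id}: bad cad_status")

    @property
    def is_founder(self) -> bool:
        return self.father_id is None


def pedigree_by_id(members: Sequence[PedigreeMember]) -> dict:
    index = {}
    for m in members:
        if m.member_id in index:
            raise StructureError(f"duplicate member id {m.member_id}")
        index[m.member_id] = m
    return index


def topological_order(members: Sequence[PedigreeMember]) -> list:
    """Return members ordered parents-before-children.

    Raises :class:`StructureError` on unknown parents or cycles (a member
    that is its own ancestor).
    """
    index = pedigree_by_id(members)
    for m in members:
        for pid in (m.father_id, m.mother_id):
            if pid is not None and pid not in index:
                raise StructureError(
                    f"{m.member_id} references unknown parent {pid}"
                )
    order: list = []
    state: dict = {}  # 0 = visiting, 1 = done

    def visit(mid: str, stack: tuple):
        if state.get(mid) == 1:
            return
        if mid in stack:
            raise StructureError(f"pedigree cycle involving {mid}")
        m = index[mid]
        for pid in (m.father_id, m.mother_id):
            if pid is not None:
                visit(pid, stack + (mid,))
        if state.get(mid) != 1:
            state[mid] = 1
            order.append(m)

    for m in members:
        visit(m.member_id, ())
    return order


@dataclass
class PhenotypeRecord:
    """Simulated or measured phenotypes for one individual."""

    member_id: str = ""
    lpa_nmol_l: float = 0.0
    ldl_c_mmol_l: float = 0.0
    oxpl_per_lpa_nmol_l: float = 0.0
    isoform_sizes: Optional[tuple] = None       # (shorter KIV, longer KIV)
    dominant_isoform_fraction: Optional[float] = None

    def __post_init__(self):
        if self.lpa_nmol_l < 0:
            raise ConfigurationError("lpa_nmol_l must be >= 0")
        if self.dominant_isoform_fraction is not None and not (
            0.5 - 1e-9 <= self.dominant_isoform_fraction <= 1.0 + 1e-9
        ):
            raise ConfigurationError("dominant_isoform_fraction must lie in [0.5, 1]")


@dataclass
class VariantRecord:
    """One biallelic site with per-sample ALT dosage and read depth."""

    chrom: str
    pos: int
    ref: str
    alt: str
    dosages: dict = field(default_factory=dict)   # sample -> {0,1,2}|float|None
    depths: dict = field(default_factory=dict)    # sample -> int|None
    vid: Optional[str] = None

    def dosage(self, sample: str):
        return self.dosages.get(sample)

    def depth(self, sample: str) -> int:
        d = self.depths.get(sample)
        return 0 if d is None else int(d)

    @property
    def key(self):
        return (norm_chrom(self.chrom), int(self.pos), self.ref, self.alt)


_INTERVAL_RE = re.compile(r"^\s*(\S+?)\s*:\s*([\d,.\s ]+?)\s*-\s*([\d,.\s ]+?)\s*$")


@dataclass(frozen=True)
class GenomicInterval:
    """A 1-based genomic interval, inclusive of both endpoints."""

    chrom: str
    start: int
    end: int

    def __post_init__(self):
        if self.start > self.end:
            raise ConfigurationError(
                f"interval start {self.start} > end {self.end}"
            )
        if self.start < 1:
            raise ConfigurationError("interval coordinates are 1-based")

    def contains(self, chrom: str, pos: int) -> bool:
        return norm_chrom(chrom) == norm_chrom(self.chrom) and (
            self.start <= pos <= self.end
        )

    def distance(self, chrom: str, pos: int) -> float:
        """Distance in bp from ``pos`` to the interval; 0 inside, inf off-chromosome."""
        if norm_chrom(chrom) != norm_chrom(self.chrom):
            return math.inf
        if pos < self.start:
            return self.start - pos
        if pos > self.end:
            return pos - self.end
        return 0

    @classmethod
    def from_string(cls, text: str) -> "GenomicInterval":
        """Parse ``chr6:159991850-161753083`` (separators in numbers allowed)."""
        m = _INTERVAL_RE.match(text)
        if not m:
            raise ParseError(f"cannot parse interval {text!r}")
        clean = lambda s: int(re.sub(r"[,\s. ]", "", s))
        return cls(m.group(1), clean(m.group(2)), clean(m.group(3)))


# Broader-sense LPA locus used for CAD-score ablation: the region harbouring
# all genome-wide significant Lp(a) hits.
LPA_LOCUS = GenomicInterval("chr6", 159_991_850, 161_753_083)


@dataclass(frozen=True)
class ScoreWeight:
    """One scoring-file row: site, effect allele and per-allele weight."""

    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    weight: float

    def __post_init__(self):
        if self.pos < 1:
            raise ConfigurationError("pos must be >= 1 (1-based)")
        if self.effect_allele == self.other_allele:
            raise ConfigurationError(
                f"{self.chrom}:{self.pos}: effect and other allele are identical"
            )
        if not math.isfinite(self.weight):
            raise ConfigurationError(f"{self.chrom}:{self.pos}: weight not finite")


@dataclass
class GrsResult:
    """Per-individual polygenic score and row-accounting diagnostics."""

    sample_id: str
    score: float
    n_used: int
    n_missing: int
    n_excluded: int


@dataclass
class PercentileReport:
    """Placement of one score within an empirical reference distribution."""

    sample_id: str
    score: float
    percentile: float
    flag_95: bool
    flag_975: bool

    def __post_init__(self):
        if not (0.0 <= self.percentile <= 100.0):
            raise ConfigurationError("percentile must lie in [0, 100]")
        if self.flag_975 and not self.flag_95:
            raise ConfigurationError("flag_975 implies flag_95")


@dataclass
class ModelFit:
    """Summary of one ordinary-least-squares fit."""

    label: str
    covariates: list
    r_squared: float
    coefficients: "object"   # pandas.DataFrame: coef, se, t, p per term
    p_value: float
    n_obs: int
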