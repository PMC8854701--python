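"""Domain types and gland-level primitives: somatic-call filtering, MAF
classification, coverage QC, allelic-imbalance testing and the
cumulative-menstrual-cycle clock covariate.

Coordinates are 1-based inclusive (VCF convention). Trinucleotide contexts
are stored on the reference strand and pyrimidine-normalized only when a
spectrum is built.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from scipy import stats

#: Empirical variant-score cut-off used for caller output, -10*log10(0.05).
QUALITY_SCORE_THRESHOLD = -10.0 * math.log10(0.05)

#: Population-frequency cut-off above which a call is treated as germline.
MAX_POPULATION_FREQUENCY = 0.001

#: Read-level thresholds for whole-genome calls.
MIN_DEPTH = 20
MIN_ALT_READS = 8
MIN_SOMATIC_MAF = 0.25
MAX_BLOOD_MAF = 0.05

#: Fraction of target bases that must be covered by >=20 reads for a gland
#: to enter the analysis (strict inequality).
MIN_COVERAGE20_FRACTION = 0.70

NONSILENT_CONSEQUENCES = frozenset(
    {"missense", "nonsense", "splice", "inframe_indel", "frameshift"}
)
SNV_CONSEQUENCES = frozenset(
    {"missense", "nonsense", "synonymous", "splice", "noncoding"}
)


@dataclass
class MutationRecord:
    """One somatic call in one gland, with read support and context."""

    gland_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    depth: int
    alt_reads: int
    blood_depth: int = 0
    blood_alt_reads: int = 0
    context: str = ""
    consequence: str = "noncoding"
    gene: str = ""
    pop_freq: float = 0.0
    quality_pass: bool = True
    subject_id: str = ""

    def __post_init__(self) -> None:
        if not 0 <= self.alt_reads <= self.depth:
            raise ValueError(
                f"alt_reads {self.alt_reads} outside [0, depth={self.depth}]"
            )
        if not 0 <= self.blood_alt_reads <= max(self.blood_depth, 0):
            raise ValueError("blood_alt_reads outside [0, blood_depth]")
        if self.is_snv and self.context:
            if len(self.context) != 3 or self.context[1].upper() != self.ref.upper():
                raise ValueError(
                    f"context {self.context!r} inconsistent with ref {self.ref!r}"
                )

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1

    @property
    def maf(self) -> float:
        """Mutant allele frequency; NaN when the site has no coverage."""
        return self.alt_reads / self.depth if self.depth > 0 else math.nan

    @property
    def blood_maf(self) -> float:
        return (
            self.blood_alt_reads / self.blood_depth if self.blood_depth > 0 else 0.0
        )

    @property
    def is_nonsilent(self) -> bool:
        return self.consequence in NONSILENT_CONSEQUENCES


@dataclass
class GlandSample:
    """A single gland: QC status, spatial grid cell, and its mutation set."""

    gland_id: str
    subject_id: str
    grid_id: str = ""
    callable_bases: int = 0
    coverage20_fraction: float | None = None
    mutations: list[MutationRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.callable_bases < 0:
            raise ValueError("callable_bases must be >= 0")
        if self.coverage20_fraction is not None and not (
            0.0 <= self.coverage20_fraction <= 1.0
        ):
            raise ValueError("coverage20_fraction outside [0, 1]")


@dataclass
class SubjectClinical:
    """Clinical covariates for one subject."""

    subject_id: str
    age: float
    menarche_age: float | None = None
    parity: int | None = None
    bmi: float | None = None
    pack_years: float | None = None
    disease: str = ""
    cnmc: float | None = None

    def __post_init__(self) -> None:
        if self.menarche_age is not None and self.age < self.menarche_age:
            raise ValueError(
                f"age {self.age} below menarche age {self.menarche_age}"
            )
        if self.cnmc is not None and self.cnmc < 0:
            raise ValueError("cnmc must be >= 0")


def classify_maf(maf: float) -> str:
    """Trimodal MAF classification of a somatic mutation.

    Returns ``"subclonal"`` (< 0.25), ``"clonal"`` ([0.25, 0.75)) or
    ``"clonal_imbalanced"`` (>= 0.75, clonal with allelic imbalance such as
    loss of the wild-type allele).
    """
    if not 0.0 <= maf <= 1.0:
        raise ValueError(f"MAF {maf} outside [0, 1]")
    if maf < 0.25:
        return "subclonal"
    if maf >= 0.75:
        return "clonal_imbalanced"
    return "clonal"


#: Filtering criteria in fixed attribution order. A rejected record is
#: tallied under the first criterion it fails.
FILTER_CRITERIA = ("quality", "pop_freq", "depth", "alt_reads", "maf", "blood")


def filter_somatic_calls(
    records: Iterable[MutationRecord], mode: str = "wgs"
) -> tuple[list[MutationRecord], Counter]:
    """Apply the somatic-call confidence filters.

    ``wgs`` mode applies, in order: caller quality pass, population
    frequency < 0.001, depth >= 20, >= 8 mutant reads, MAF >= 0.25, and
    matched-blood MAF <= 0.05. ``target`` mode applies only the quality
    and population-frequency criteria (read-level thresholds are handled
    by the targeted-panel caller upstream).

    Returns the kept records and a tally of rejections keyed by the first
    failing criterion; records with zero depth are tallied as
    ``"no coverage"``.
    """
    if mode not in ("wgs", "target"):
        raise ValueError(f"unknown filter mode {mode!r}")
    active = FILTER_CRITERIA if mode == "wgs" else ("quality", "pop_freq")
    kept: list[MutationRecord] = []
    tally: Counter = Counter()
    for rec in records:
        if rec.depth == 0:
            tally["no coverage"] += 1
            continue
        reason = _first_failure(rec, active)
        if reason is None:
            kept.append(rec)
        else:
            tally[reason] += 1
    return kept, tally


def _first_failure(rec: MutationRecord, active: Sequence[str]) -> str | None:
    for crit in active:
        if crit == "quality" and not rec.quality_pass:
            return crit
        if crit == "pop_freq" and rec.pop_freq >= MAX_POPULATION_FREQUENCY:
            return crit
        if crit == "depth" and rec.depth < MIN_DEPTH:
            return crit
        if crit == "alt_reads" and rec.alt_reads < MIN_ALT_READS:
            return crit
        if crit == "maf" and rec.maf < MIN_SOMATIC_MAF:
            return crit
        if crit == "blood" and rec.blood_maf > MAX_BLOOD_MAF:
            return crit
    return None


def gland_qc(sample: GlandSample) -> bool:
    """Coverage QC: pass iff more than 70% of target bases have >=20 reads."""
    if sample.coverage20_fraction is None:
        raise ValueError(f"gland {sample.gland_id}: coverage20_fraction not set")
    return sample.coverage20_fraction > MIN_COVERAGE20_FRACTION


def binomial_imbalance_test(
    alt_reads: int, depth: int, p0: float = 0.5
) -> float:
    """Exact two-sided binomial test of allelic balance at a site.

    Tests the observed mutant-read count against Binomial(depth, p0);
    used to call allelic imbalance favouring the mutant allele.
    """
    if not 0.0 < p0 < 1.0:
        raise ValueError(f"p0 {p0} outside (0, 1)")
    if depth < 1:
        raise ValueError("depth must be >= 1")
    if not 0 <= alt_reads <= depth:
        raise ValueError("alt_reads outside [0, depth]")
    return stats.binomtest(alt_reads, depth, p0, alternative="two-sided").pvalue


def compute_cnmc(
    clinical: SubjectClinical,
    cycles_per_year: float = 13.0,
    cycles_lost_per_parity: float = 15.0,
) -> float:
    """Cumulative number of menstrual cycles (CNMC) for a subject.

    Modelled as ``cycles_per_year * (age - menarche_age)`` minus a fixed
    number of cycles suppressed per pregnancy, floored at zero. The two
    parameters are explicit assumptions and configurable; the default of
    13 cycles/year corresponds to a 28-day cycle.
    """
    if clinical.menarche_age is None:
        raise ValueError("menarche_age required to compute CNMC")
    if clinical.menarche_age > clinical.age:
        raise ValueError("menarche_age must not exceed age")
    parity = clinical.parity or 0
    cycles = cycles_per_year * (clinical.age - clinical.menarche_age)
    return max(0.0, cycles - cycles_lost_per_parity * parity)
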