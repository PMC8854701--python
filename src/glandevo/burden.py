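"""Per-subject mutation burden, mutational spectra and clinical associations.

The burden of subject i pools mutation counts and callable bases over that
subject's glands:

    b_i = sum_j n_ij * 1e6 / sum_j l_ij

where n_ij is the number of high-MAF somatic SNVs and l_ij the number of
target bases covered by >= 20 reads in gland j. Pooling numerators and
denominators makes the burden invariant to how mutations are split among
glands.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .catalog import GlandSample, MutationRecord
from .contexts import SBS96_CLASSES, SUBSTITUTIONS, sbs96_label

#: The nine driver genes: targeted genes present in both the Cancer Gene
#: Census and the pan-gynecologic cancer-associated gene list.
DRIVER_GENES = frozenset(
    {"ARID1A", "CTNNB1", "FBXW7", "KRAS", "PIK3CA", "PIK3R1",
     "PPP2R1A", "PTEN", "TP53"}
)


@dataclass
class SpectrumCounts:
    """96-class SNV counts (pyrimidine substitution x 5'/3' flanks)."""

    counts: np.ndarray
    skipped: int = 0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (96,):
            raise ValueError("spectrum must be a 96-vector")
        if np.any(self.counts < 0):
            raise ValueError("negative class count")

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    def by_substitution(self) -> dict[str, float]:
        """Counts collapsed to the six pyrimidine substitutions."""
        out = {}
        for k, sub in enumerate(SUBSTITUTIONS):
            out[sub] = float(self.counts[16 * k : 16 * (k + 1)].sum())
        return out

    def cpg_ct(self) -> float:
        """C>T transitions at CpG motifs: classes N[C>T]G."""
        return float(
            sum(
                self.counts[i]
                for i, label in enumerate(SBS96_CLASSES)
                if label[2:5] == "C>T" and label[6] == "G"
            )
        )


@dataclass
class BurdenResult:
    """Mutation burden of one subject pooled over glands (per Mbp)."""

    subject_id: str
    burden: float
    by_substitution: dict[str, float] = field(default_factory=dict)
    cpg_ct_burden: float = math.nan
    n_mutations: int = 0
    callable_bases: int = 0


def spectrum_96(snvs: Iterable[MutationRecord]) -> SpectrumCounts:
    """Classify SNVs into the 96 trinucleotide classes.

    Purine-reference SNVs are reverse-complemented onto the pyrimidine
    strand. Records with invalid contexts are skipped with a warning tally
    rather than failing the whole spectrum.
    """
    counts = np.zeros(96)
    skipped = 0
    for rec in snvs:
        if not rec.is_snv:
            skipped += 1
            continue
        try:
            label = sbs96_label(rec.ref, rec.alt, rec.context)
        except (ValueError, KeyError):
            skipped += 1
            continue
        counts[SBS96_CLASSES.index(label)] += 1
    if skipped:
        warnings.warn(f"spectrum_96: skipped {skipped} unclassifiable records")
    return SpectrumCounts(counts=counts, skipped=skipped)


def mutation_burden(
    samples: Sequence[GlandSample], maf_min: float = 0.25
) -> BurdenResult:
    """Pooled high-MAF SNV burden for one subject's glands, per Mbp."""
    if not samples:
        raise ValueError("no glands supplied")
    subject = samples[0].subject_id
    total_callable = sum(s.callable_bases for s in samples)
    if total_callable <= 0:
        raise ValueError("total callable bases is zero")
    high: list[MutationRecord] = []
    for s in samples:
        for rec in s.mutations:
            if rec.is_snv and rec.depth > 0 and rec.maf >= maf_min:
                high.append(rec)
    scale = 1e6 / total_callable
    spec = spectrum_96(high) if high else SpectrumCounts(np.zeros(96))
    by_sub = {sub: c * scale for sub, c in spec.by_substitution().items()}
    return BurdenResult(
        subject_id=subject,
        burden=len(high) * scale,
        by_substitution=by_sub,
        cpg_ct_burden=spec.cpg_ct() * scale,
        n_mutations=len(high),
        callable_bases=total_callable,
    )


def driver_burden(
    samples: Sequence[GlandSample],
    driver_genes: frozenset[str] | set[str] = DRIVER_GENES,
    maf_min: float = 0.25,
) -> float:
    """Mean number of nonsilent high-MAF driver-gene mutations per gland."""
    if not samples:
        raise ValueError("no glands supplied")
    if not driver_genes:
        raise ValueError("empty driver gene set")
    n = 0
    for s in samples:
        for rec in s.mutations:
            if (
                rec.gene in driver_genes
                and rec.is_nonsilent
                and rec.depth > 0
                and rec.maf >= maf_min
            ):
                n += 1
    return n / len(samples)


@dataclass
class AssociationResult:
    """Correlation of burden with a clinical covariate."""

    r: float
    p: float
    slope: float
    slope_ci: tuple[float, float]
    n: int
    adjusted_for_age: bool = False


def covariate_association(
    burdens: Sequence[float],
    covariate: Sequence[float],
    adjust_age: bool = False,
    ages: Sequence[float] | None = None,
) -> AssociationResult:
    """Pearson correlation and regression slope of burden on a covariate.

    Unadjusted: two-tailed Pearson r plus the OLS slope with its 95% CI.
    Age-adjusted: both variables are regressed on age and the residuals
    correlated (a partial correlation, tested on n - 3 degrees of
    freedom); the slope is the age-adjusted regression coefficient of the
    covariate.
    """
    y = np.asarray(burdens, dtype=float)
    x = np.asarray(covariate, dtype=float)
    if y.shape != x.shape or y.ndim != 1:
        raise ValueError("burdens and covariate must be equal-length vectors")
    n = y.size
    if n < 3:
        raise ValueError("need at least 3 subjects")
    if np.isclose(np.var(x), 0) or np.isclose(np.var(y), 0):
        raise ValueError("zero variance in burden or covariate")
    if not adjust_age:
        r, p = stats.pearsonr(x, y)
        res = stats.linregress(x, y)
        half = stats.t.ppf(0.975, n - 2) * res.stderr
        return AssociationResult(
            r=float(r), p=float(p), slope=float(res.slope),
            slope_ci=(float(res.slope - half), float(res.slope + half)), n=n,
        )
    if ages is None:
        raise ValueError("ages required when adjust_age=True")
    a = np.asarray(ages, dtype=float)
    if a.shape != y.shape:
        raise ValueError("ages must match burdens in length")
    if n < 4:
        raise ValueError("need at least 4 subjects for age adjustment")
    rx = x - np.polyval(np.polyfit(a, x, 1), a)
    ry = y - np.polyval(np.polyfit(a, y, 1), a)
    if np.allclose(rx, 0) or np.allclose(ry, 0):
        raise ValueError("a variable is collinear with age")
    r = float(np.corrcoef(rx, ry)[0, 1])
    df = n - 3  # one extra df consumed by the age regression
    t_stat = r * math.sqrt(df / max(1.0 - r * r, 1e-300))
    p = float(2.0 * stats.t.sf(abs(t_stat), df))
    res = stats.linregress(rx, ry)
    half = stats.t.ppf(0.975, df) * res.stderr
    return AssociationResult(
        r=r, p=p, slope=float(res.slope),
        slope_ci=(float(res.slope - half), float(res.slope + half)),
        n=n, adjusted_for_age=True,
    )


def group_difference_test(
    values_a: Sequence[float], values_b: Sequence[float]
) -> float:
    """Two-sided Wilcoxon rank-sum p-value between two groups.

    Exact for small samples without ties; normal approximation (with tie
    correction) for larger samples (n > 50 in either group). When every
    observation across both groups is identical the test is degenerate and
    p = 1 by convention.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return 1.0
    has_ties = np.unique(pooled).size < pooled.size
    method = (
        "exact" if (max(a.size, b.size) <= 50 and not has_ties) else "asymptotic"
    )
    return float(
        stats.mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue
    )
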