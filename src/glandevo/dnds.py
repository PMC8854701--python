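"""Trinucleotide-context Poisson dN/dS selection inference.

The observed numbers of coding SNVs producing missense (n^m), nonsense (n^n)
and synonymous (n^s) changes in trinucleotide-context class i are modelled as

    n_i^m ~ Poisson(t * r_i * L_i^m * omega_m)
    n_i^n ~ Poisson(t * r_i * L_i^n * omega_n)
    n_i^s ~ Poisson(t * r_i * L_i^s)

where L_i^{m,n,s} counts the coding sites at which substitution class i
would produce each consequence ("site opportunities"), r_i is the relative
substitution rate of class i estimated from a large noncoding SNV catalog,
and the baseline rate t is calibrated so that total expected counts equal
total observed counts. omega (dN/dS) > 1 indicates positive selection;
the fraction of genuine drivers among observed nonsynonymous mutations is
f = (omega - 1) / omega.

omega is estimated by a shared-scale Poisson model with the log expected
counts as offsets, so the point estimate is the ratio of observed/expected
ratios; significance comes from a likelihood-ratio test of omega = 1, with
Benjamini-Hochberg control across genes.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.stats.multitest import multipletests

from .catalog import MutationRecord
from .contexts import BASES, sbs96_index

GENETIC_CODE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

CONSEQUENCE_CLASSES = ("missense", "nonsense", "synonymous")


@dataclass
class GeneModel:
    """A gene's CDS and its per-context site-opportunity counts.

    ``flanked_cds`` is the coding sequence with one extra reference base on
    each side (needed for the trinucleotide context of the first and last
    coding positions). ``L`` maps each consequence to a 96-vector of site
    counts; summed over consequences and contexts it equals 3x the CDS
    length, since every coding site admits three substitutions and each is
    classified exactly once.
    """

    gene: str
    flanked_cds: str
    L: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def cds_length(self) -> int:
        return len(self.flanked_cds) - 2

    def total_opportunities(self) -> float:
        return float(sum(v.sum() for v in self.L.values()))


@dataclass
class ContextRates:
    """Relative substitution rates per 96-class plus the baseline rate."""

    r: np.ndarray
    t: float

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        if self.r.shape != (96,):
            raise ValueError("r must be a 96-vector")
        if np.any(self.r < 0) or self.t < 0:
            raise ValueError("rates must be non-negative")


@dataclass
class OmegaEstimate:
    """Point estimate of omega with 95% CI and LRT p-value.

    ``dn`` and ``ds`` are the observed/expected ratios for the tested and
    synonymous class; when no synonymous mutations are observed omega is
    undefined (NaN) and only dn/ds are meaningful.
    """

    omega: float
    ci_low: float
    ci_high: float
    p: float
    dn: float
    ds: float
    n_obs: int
    n_syn: int


@dataclass
class DnDsFit:
    """dN/dS results for a gene or gene set (missense and nonsense)."""

    scope: str
    missense: OmegaEstimate | None = None
    nonsense: OmegaEstimate | None = None
    fdr_missense: float = math.nan
    fdr_nonsense: float = math.nan

    @property
    def driver_fraction_missense(self) -> float:
        if self.missense is None or not math.isfinite(self.missense.omega):
            return math.nan
        return driver_fraction(self.missense.omega)

    @property
    def driver_fraction_nonsense(self) -> float:
        if self.nonsense is None or not math.isfinite(self.nonsense.omega):
            return math.nan
        return driver_fraction(self.nonsense.omega)


def count_site_opportunities(gene: str, flanked_cds: str) -> GeneModel:
    """Enumerate all single-base substitutions in a CDS and tally them.

    Every coding position admits three alternative bases; each resulting
    codon change is classified as missense, nonsense or synonymous and
    tallied into the pyrimidine-normalized 96-class of the substitution.
    A premature internal stop codon or an ambiguous base is an error.
    Substitutions within a terminal stop codon count as synonymous when the
    codon remains a stop and as missense (stop loss) otherwise.
    """
    seq = flanked_cds.upper()
    if any(b not in BASES for b in seq):
        raise ValueError(f"{gene}: ambiguous base in CDS")
    cds = seq[1:-1]
    if len(cds) % 3 != 0:
        raise ValueError(f"{gene}: CDS length {len(cds)} not divisible by 3")
    n_codons = len(cds) // 3
    for c in range(n_codons - 1):
        if GENETIC_CODE[cds[3 * c : 3 * c + 3]] == "*":
            raise ValueError(f"{gene}: internal stop codon at codon {c + 1}")

    L = {c: np.zeros(96, dtype=float) for c in CONSEQUENCE_CLASSES}
    for p in range(len(cds)):
        codon_start = 3 * (p // 3)
        offset = p % 3
        codon = cds[codon_start : codon_start + 3]
        aa = GENETIC_CODE[codon]
        ref = cds[p]
        context = seq[p : p + 3]  # flanked coordinates: seq[p] is 5' of cds[p]
        for alt in BASES:
            if alt == ref:
                continue
            new_codon = codon[:offset] + alt + codon[offset + 1 :]
            new_aa = GENETIC_CODE[new_codon]
            if new_aa == aa:
                consequence = "synonymous"
            elif new_aa == "*":
                consequence = "nonsense"
            else:
                consequence = "missense"
            L[consequence][sbs96_index(ref, alt, context)] += 1
    return GeneModel(gene=gene, flanked_cds=seq, L=L)


def estimate_context_rates(
    noncoding_counts: np.ndarray,
    models: Iterable[GeneModel],
    observed_total: float,
    context_opportunities: np.ndarray | None = None,
) -> ContextRates:
    """Calibrate per-context relative rates and the baseline rate.

    ``r_i`` is proportional to the noncoding catalog count of class i,
    divided by the class's trinucleotide opportunity when one is supplied,
    and normalized to mean 1 (the overall scale is absorbed by ``t``).
    ``t`` is then chosen so that the total expected coding count over all
    supplied gene models equals ``observed_total`` exactly.
    """
    counts = np.asarray(noncoding_counts, dtype=float)
    if counts.shape != (96,):
        raise ValueError("noncoding_counts must be a 96-vector")
    if counts.sum() <= 0:
        raise ValueError("noncoding catalog is empty")
    if context_opportunities is None:
        rel = counts.copy()
    else:
        opp = np.asarray(context_opportunities, dtype=float)
        if np.any((opp <= 0) & (counts > 0)):
            raise ValueError("zero opportunity for a class with observed counts")
        with np.errstate(divide="ignore", invalid="ignore"):
            rel = np.where(opp > 0, counts / opp, 0.0)
    r = rel / rel.mean()
    denom = 0.0
    for model in models:
        for cls in CONSEQUENCE_CLASSES:
            denom += float(r @ model.L[cls])
    if denom <= 0:
        raise ValueError("no site opportunities among supplied gene models")
    t = float(observed_total) / denom
    if t < 0:
        raise ValueError("observed_total must be >= 0")
    return ContextRates(r=r, t=t)


def expected_counts(
    rates: ContextRates, models: Iterable[GeneModel]
) -> pd.DataFrame:
    """Expected mutation counts per gene and consequence, E = t * sum r_i L_i."""
    rows = []
    for model in models:
        row = {"gene": model.gene}
        for cls in CONSEQUENCE_CLASSES:
            row[cls] = rates.t * float(rates.r @ model.L[cls])
        rows.append(row)
    return pd.DataFrame(rows).set_index("gene")


def count_coding_mutations(
    records: Iterable[MutationRecord],
    genes: Sequence[str] | None = None,
    maf_min: float = 0.25,
) -> pd.DataFrame:
    """Observed high-MAF coding SNV counts per gene and consequence.

    Indels and splice SNVs are excluded: selection is inferred in a
    substitution-only framework.
    """
    counts: dict[str, dict[str, int]] = {}
    for rec in records:
        if not rec.is_snv or rec.consequence not in CONSEQUENCE_CLASSES:
            continue
        if not rec.gene or (genes is not None and rec.gene not in genes):
            continue
        if rec.depth > 0 and rec.maf >= maf_min:
            counts.setdefault(rec.gene, dict.fromkeys(CONSEQUENCE_CLASSES, 0))
            counts[rec.gene][rec.consequence] += 1
    index = list(counts) if genes is None else list(genes)
    frame = pd.DataFrame(
        [
            counts.get(g, dict.fromkeys(CONSEQUENCE_CLASSES, 0))
            for g in index
        ],
        index=pd.Index(index, name="gene"),
    )
    return frame[list(CONSEQUENCE_CLASSES)].astype(int)


def _poisson_loglik(omega: float, n_obs: float, e_obs: float,
                    n_syn: float, e_syn: float) -> float:
    """Profile log-likelihood in omega (shared scale mu maximized out)."""
    rate = e_obs * omega + e_syn
    mu = (n_obs + n_syn) / rate
    ll = -mu * rate
    if n_obs > 0:
        ll += n_obs * math.log(mu * e_obs * omega)
    elif omega == 0.0:
        pass  # 0*log(0) -> 0
    if n_syn > 0:
        ll += n_syn * math.log(mu * e_syn)
    return ll


def estimate_omega(
    n_obs: int, e_obs: float, n_syn: int, e_syn: float
) -> OmegaEstimate:
    """Estimate omega = (n_obs/E_obs)/(n_syn/E_syn) with CI and LRT p-value.

    Under the shared-scale Poisson model the MLE of omega is the ratio of
    observed/expected ratios. The 95% CI is Wald on log(omega) with
    variance 1/n_obs + 1/n_syn, replaced by a profile-likelihood interval
    when either count is below 5 (where the normal approximation is poor).
    The p-value is a 1-df likelihood-ratio test of omega = 1. With zero
    synonymous counts omega is undefined and dn/ds are reported alone.
    """
    if e_obs <= 0 or e_syn <= 0:
        raise ValueError("expected counts must be positive")
    if n_obs < 0 or n_syn < 0:
        raise ValueError("observed counts must be non-negative")
    dn = n_obs / e_obs
    ds = n_syn / e_syn
    if n_syn == 0:
        return OmegaEstimate(
            omega=math.nan, ci_low=math.nan, ci_high=math.nan, p=math.nan,
            dn=dn, ds=ds, n_obs=n_obs, n_syn=n_syn,
        )
    omega = dn / ds
    lrt = 2.0 * (
        _poisson_loglik(omega, n_obs, e_obs, n_syn, e_syn)
        - _poisson_loglik(1.0, n_obs, e_obs, n_syn, e_syn)
    )
    p = float(stats.chi2.sf(max(lrt, 0.0), df=1))
    if n_obs >= 5 and n_syn >= 5:
        se = math.sqrt(1.0 / n_obs + 1.0 / n_syn)
        ci_low = omega * math.exp(-1.959963984540054 * se)
        ci_high = omega * math.exp(1.959963984540054 * se)
    else:
        ci_low, ci_high = _profile_ci(n_obs, e_obs, n_syn, e_syn, omega)
    return OmegaEstimate(
        omega=omega, ci_low=ci_low, ci_high=ci_high, p=p,
        dn=dn, ds=ds, n_obs=n_obs, n_syn=n_syn,
    )


def _profile_ci(
    n_obs: int, e_obs: float, n_syn: int, e_syn: float, omega: float,
    crit: float = 3.841458820694124,  # chi2(1) 95% quantile
) -> tuple[float, float]:
    ll_hat = _poisson_loglik(omega, n_obs, e_obs, n_syn, e_syn)

    def deviance_gap(w: float) -> float:
        return 2.0 * (ll_hat - _poisson_loglik(w, n_obs, e_obs, n_syn, e_syn)) - crit

    if n_obs == 0:
        ci_low = 0.0
    else:
        lo = omega
        while deviance_gap(lo) < 0 and lo > 1e-12:
            lo /= 4.0
        ci_low = optimize.brentq(deviance_gap, lo, omega) if lo < omega else 0.0
    hi = max(omega, 1e-12)
    while deviance_gap(hi) < 0 and hi < 1e12:
        hi *= 4.0
    ci_high = (
        optimize.brentq(deviance_gap, max(omega, 1e-12), hi)
        if hi > max(omega, 1e-12)
        else math.inf
    )
    return float(ci_low), float(ci_high)


def driver_fraction(omega: float) -> float:
    """Fraction of observed nonsynonymous mutations that are drivers.

    f = (omega - 1) / omega, floored at 0 for omega <= 1.
    """
    if omega <= 0:
        raise ValueError(f"omega must be positive, got {omega}")
    return max(0.0, (omega - 1.0) / omega)


def gene_set_dnds(
    observed: pd.DataFrame,
    rates: ContextRates,
    models: Mapping[str, GeneModel],
    set_name: str,
    genes: Sequence[str] | None = None,
) -> DnDsFit:
    """Pooled dN/dS for a gene set: sum counts and expectations, then fit.

    ``observed`` is the per-gene count table from
    :func:`count_coding_mutations`; ``genes`` selects the member genes
    (default: all genes in the table).
    """
    members = list(genes) if genes is not None else list(observed.index)
    if not members:
        raise ValueError("empty gene set")
    missing = [g for g in members if g not in models]
    if missing:
        raise KeyError(f"no gene model for {missing}")
    exp = expected_counts(rates, [models[g] for g in members])
    if exp["synonymous"].sum() <= 0:
        raise ValueError(f"gene set {set_name!r} has no synonymous sites")
    obs = observed.reindex(members).fillna(0)
    n_m = int(obs["missense"].sum())
    n_n = int(obs["nonsense"].sum())
    n_s = int(obs["synonymous"].sum())
    e_m, e_n, e_s = (float(exp[c].sum()) for c in CONSEQUENCE_CLASSES)
    return DnDsFit(
        scope=set_name,
        missense=estimate_omega(n_m, e_m, n_s, e_s),
        nonsense=estimate_omega(n_n, e_n, n_s, e_s),
    )


def per_gene_selection(
    observed: pd.DataFrame,
    rates: ContextRates,
    models: Mapping[str, GeneModel],
    min_snvs: int = 5,
    fdr_q: float = 0.1,
) -> list[DnDsFit]:
    """Gene-level positive-selection scan.

    Only genes with at least ``min_snvs`` coding SNVs are considered, and a
    class (missense or nonsense) is tested only when its observed count
    exceeds its expectation. P-values come from the omega = 1 LRT and are
    BH-adjusted separately within each class across the tested genes;
    genes at FDR < ``fdr_q`` are flagged by the caller via the fdr fields.
    """
    fits: list[DnDsFit] = []
    tested: dict[str, list[tuple[int, float]]] = {"missense": [], "nonsense": []}
    for idx, gene in enumerate(observed.index):
        if gene not in models:
            warnings.warn(f"no gene model for {gene}; skipped")
            fits.append(DnDsFit(scope=gene))
            continue
        row = observed.loc[gene]
        exp = expected_counts(rates, [models[gene]]).loc[gene]
        fit = DnDsFit(scope=gene)
        if int(row.sum()) >= min_snvs:
            for cls, attr in (("missense", "missense"), ("nonsense", "nonsense")):
                if int(row[cls]) > float(exp[cls]):
                    est = estimate_omega(
                        int(row[cls]), float(exp[cls]),
                        int(row["synonymous"]), float(exp["synonymous"]),
                    )
                    setattr(fit, attr, est)
                    if math.isfinite(est.p):
                        tested[cls].append((idx, est.p))
        fits.append(fit)
    for cls, attr in (("missense", "fdr_missense"), ("nonsense", "fdr_nonsense")):
        if tested[cls]:
            idxs, ps = zip(*tested[cls])
            adj = bh_fdr(list(ps))
            for i, q in zip(idxs, adj):
                setattr(fits[i], attr, float(q))
    return fits


def bh_fdr(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(list(pvals), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values outside [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
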