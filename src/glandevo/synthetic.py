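"""Synthetic multi-gland cohorts with full ground truth.

The generator emulates the statistical structure the analysis assumes so
that every downstream stage has a recovery test:

* per-subject clone clusters with public / partially shared / private
  mutations, counts proportional in expectation to the planted expansion
  age (clock-like accrual at a constant rate from birth to sampling);
* binomial read sampling at configurable depth (optionally beta-binomial
  overdispersed; default off so count oracles stay exact);
* trinucleotide contexts drawn from a mixture of reference signatures;
* arm-level copy-neutral LOH with a planted occurrence age and per-gland
  cellular fraction rho — mutations predating the event are emitted at
  expected MAF rho (and survive the allele loss with probability 1/2),
  later mutations at rho / 2, matching the read-level timing model;
* genes under configurable omega for selection-inference catalogs.

Clone structure is specified, not emergent: there is no forward simulation
of tissue dynamics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .catalog import GlandSample, MutationRecord, SubjectClinical, compute_cnmc
from .cnloh import HetSiteSignal
from .contexts import SBS96_CLASSES, class_components
from .dnds import CONSEQUENCE_CLASSES, GeneModel, count_site_opportunities
from .signatures import SignatureMatrix

#: Synthetic genome: chromosome -> length in bp. Small on purpose; the
#: surveyed ("callable") fraction is what sets mutation counts.
DEFAULT_CHROM_LENGTHS = {
    "chr1": 40_000_000,
    "chr2": 30_000_000,
    "chr3": 20_000_000,
    "chr10": 10_000_000,
}


def clocklike_signature_matrix() -> SignatureMatrix:
    """Two synthetic clock-like signatures with well-separated profiles.

    ``CpG-CtoT`` concentrates on C>T at NpCpG (spontaneous-deamination
    style); ``Flat`` spreads mass broadly with a mild tilt toward C>T and
    T>C. These emulate the roles of the aging-associated signatures
    without copying any reference file.
    """
    cpg = np.full(96, 0.10 / 92)
    flat = np.empty(96)
    for i, label in enumerate(SBS96_CLASSES):
        sub = label[2:5]
        if sub == "C>T" and label[6] == "G":
            cpg[i] = 0.90 / 4
        flat[i] = {"C>T": 2.0, "T>C": 1.5}.get(sub, 1.0)
    flat /= flat.sum()
    return SignatureMatrix(
        names=("CpG-CtoT", "Flat"), probabilities=np.column_stack([cpg, flat])
    )


def random_signature_matrix(
    k: int, seed: int | None = None, concentration: float = 0.3
) -> SignatureMatrix:
    """K random sparse signatures (Dirichlet columns), well separated."""
    rng = np.random.default_rng(seed)
    probs = rng.dirichlet(np.full(96, concentration), size=k).T
    return SignatureMatrix(
        names=tuple(f"SYN{i + 1}" for i in range(k)), probabilities=probs
    )


@dataclass
class CnlohEventSpec:
    """A planted copy-neutral LOH event."""

    chrom: str
    start: int
    end: int
    true_age: float
    rho: float = 1.0  # cellular fraction; may be overridden per gland

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("event start must be < end")
        if not 0.0 < self.rho <= 1.0:
            raise ValueError("rho must be in (0, 1]")


@dataclass
class CloneSpec:
    """One clone cluster within a subject."""

    name: str
    n_glands: int
    expansion_age: float
    grid_cells: tuple[str, ...] = ()
    partial_fraction: float = 0.4  # share of post-expansion mutations that
    # are partially shared (the rest are private)
    cnloh_events: tuple[CnlohEventSpec, ...] = ()


@dataclass
class SimulationConfig:
    """The study conditions a synthetic cohort is generated under.

    Defaults mirror a multi-gland sequencing study of normal endometrium:
    subjects aged 21-53, ~30 Mbp effectively surveyed per gland at mean
    depth 80, a clock-like mutation rate of 0.08 high-MAF SNVs/Mbp/year,
    and one mid-life clonal expansion of five glands per subject.
    """

    n_subjects: int = 8
    ages: tuple[float, ...] = ()
    mutation_rate_per_year: float = 0.08  # SNVs / Mbp / year
    callable_mb: float = 30.0  # surveyed Mbp per gland
    depth_mean: float = 80.0
    blood_depth_mean: float = 40.0
    signature_mix: tuple[float, ...] = (0.3, 0.7)
    signature_matrix: SignatureMatrix | None = None
    clone_specs: Mapping[str, tuple[CloneSpec, ...]] | None = None
    driver_mutations_per_gland: float = 0.3
    overdispersion: float = 0.0  # beta-binomial rho; 0 = pure binomial
    germline_contamination: float = 0.0
    chrom_lengths: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_CHROM_LENGTHS)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.ages:
            rng = np.random.default_rng(self.seed + 1_000_003)
            self.ages = tuple(
                float(a) for a in np.sort(rng.integers(21, 54, self.n_subjects))
            )
        if len(self.ages) != self.n_subjects:
            raise ValueError("ages must have one entry per subject")
        mix = np.asarray(self.signature_mix, dtype=float)
        if mix.size == 0 or not np.isclose(mix.sum(), 1.0):
            raise ValueError("signature_mix must be nonempty and sum to 1")
        if self.depth_mean <= 0:
            raise ValueError("depth_mean must be positive")
        if self.signature_matrix is None:
            self.signature_matrix = clocklike_signature_matrix()
        if len(self.signature_mix) != self.signature_matrix.k:
            raise ValueError("signature_mix length must match signature matrix")


DRIVER_GENE_POOL = (
    "ARID1A", "CTNNB1", "FBXW7", "KRAS", "PIK3CA", "PIK3R1",
    "PPP2R1A", "PTEN", "TP53",
)


@dataclass
class GroundTruth:
    """Planted quantities behind an emitted cohort."""

    mutations: pd.DataFrame  # one row per emitted mutation site
    clusters: pd.DataFrame  # subject, cluster, expansion_age, n_glands
    subjects: pd.DataFrame  # subject, age, expected burden per Mbp
    events: pd.DataFrame  # planted CN-LOH events


def _default_clone_specs(config: SimulationConfig) -> dict[str, tuple[CloneSpec, ...]]:
    specs = {}
    for s, age in enumerate(config.ages):
        subject = f"S{s + 1:02d}"
        specs[subject] = (
            CloneSpec(
                name="cluster1",
                n_glands=5,
                expansion_age=round(0.5 * age, 1),
                grid_cells=tuple(f"{r},{c}" for r in (0, 1) for c in (0, 1, 2))[:5],
            ),
        )
    return specs


def _draw_site(rng, config, class_probs, region=None):
    """Random genomic site with a signature-drawn substitution class."""
    cls = SBS96_CLASSES[rng.choice(96, p=class_probs)]
    ref, alt, context = class_components(cls)
    if region is not None:
        chrom, start, end = region
        pos = int(rng.integers(start, end))
    else:
        chroms = list(config.chrom_lengths)
        weights = np.array([config.chrom_lengths[c] for c in chroms], dtype=float)
        chrom = chroms[rng.choice(len(chroms), p=weights / weights.sum())]
        pos = int(rng.integers(1, config.chrom_lengths[chrom]))
    return chrom, pos, ref, alt, context


def _alt_reads(rng, depth: int, p: float, overdispersion: float) -> int:
    if p <= 0:
        return 0
    if overdispersion > 0:
        a = p * (1.0 - overdispersion) / overdispersion
        b = (1.0 - p) * (1.0 - overdispersion) / overdispersion
        p = rng.beta(a, b)
    return int(rng.binomial(depth, min(p, 1.0)))


def simulate_cohort(
    config: SimulationConfig,
) -> tuple[list[GlandSample], list[SubjectClinical], GroundTruth]:
    """Generate a cohort of glands with reads, clinical data and truth.

    Every mutation of a subject is read-sampled in *every* gland of its
    cluster (mpileup-style), so absence is encoded as zero mutant reads
    rather than a missing record; matched blood is emitted mutation-free
    unless germline contamination is switched on. Deterministic given the
    config (which includes the seed).
    """
    rng = np.random.default_rng(config.seed)
    sig = config.signature_matrix
    class_probs = sig.probabilities @ np.asarray(config.signature_mix, dtype=float)
    class_probs = class_probs / class_probs.sum()
    clone_specs = (
        dict(config.clone_specs)
        if config.clone_specs is not None
        else _default_clone_specs(config)
    )

    glands: list[GlandSample] = []
    clinical: list[SubjectClinical] = []
    truth_rows: list[dict] = []
    cluster_rows: list[dict] = []
    event_rows: list[dict] = []
    callable_bases = int(config.callable_mb * 1e6)
    genome_bp = float(sum(config.chrom_lengths.values()))
    mu = config.mutation_rate_per_year * config.callable_mb  # SNVs/year/gland

    for s, (subject, specs) in enumerate(clone_specs.items()):
        age = float(config.ages[s])
        menarche = float(rng.integers(11, 16))
        parity = int(min(rng.poisson(1.0), 4))
        clin = SubjectClinical(
            subject_id=subject, age=age, menarche_age=menarche,
            parity=parity, bmi=float(np.round(rng.normal(22.0, 3.0), 1)),
            pack_years=float(rng.choice([0.0, 0.0, 0.0, 5.0, 10.0])),
        )
        clin.cnmc = compute_cnmc(clin)
        clinical.append(clin)

        subject_glands: dict[str, GlandSample] = {}
        mut_counter = 0
        for spec in specs:
            if spec.expansion_age >= age:
                raise ValueError(
                    f"{subject}/{spec.name}: expansion age must precede sampling age"
                )
            gland_ids = [
                f"{subject}_{spec.name}_g{i + 1}" for i in range(spec.n_glands)
            ]
            grid = list(spec.grid_cells) or [""] * spec.n_glands
            for i, gid in enumerate(gland_ids):
                subject_glands[gid] = GlandSample(
                    gland_id=gid, subject_id=subject,
                    grid_id=grid[i % len(grid)] if grid else "",
                    callable_bases=callable_bases,
                    coverage20_fraction=float(rng.uniform(0.85, 0.98)),
                )
            cluster_rows.append(
                {
                    "subject_id": subject, "cluster": spec.name,
                    "expansion_age": spec.expansion_age,
                    "n_glands": spec.n_glands,
                    "glands": ";".join(gland_ids),
                }
            )
            for ev in spec.cnloh_events:
                if ev.true_age >= spec.expansion_age:
                    raise ValueError(
                        "CN-LOH age must precede the clonal expansion it is "
                        "public within"
                    )
                event_rows.append(
                    {
                        "subject_id": subject, "cluster": spec.name,
                        "chrom": ev.chrom, "start": ev.start, "end": ev.end,
                        "true_age": ev.true_age, "rho": ev.rho,
                    }
                )

            # --- mutation sites -------------------------------------------
            sites: list[dict] = []
            n_pub = rng.poisson(mu * spec.expansion_age)
            for _ in range(n_pub):
                t_origin = float(rng.uniform(0.0, spec.expansion_age))
                chrom, pos, ref, alt, context = _draw_site(
                    rng, config, class_probs
                )
                cn_phase, maf, rho = "", 0.5, 1.0
                for ev in spec.cnloh_events:
                    if ev.chrom == chrom and ev.start <= pos < ev.end:
                        if t_origin < ev.true_age:
                            if rng.random() < 0.5:  # resided on the lost allele
                                cn_phase = "lost"
                            else:
                                cn_phase, maf, rho = "pre", ev.rho, ev.rho
                        else:
                            cn_phase, maf, rho = "post", ev.rho / 2.0, ev.rho
                        break
                if cn_phase == "lost":
                    continue
                sites.append(
                    {
                        "category": "public", "carriers": tuple(gland_ids),
                        "t_origin": t_origin, "chrom": chrom, "pos": pos,
                        "ref": ref, "alt": alt, "context": context,
                        "maf": maf, "cn_phase": cn_phase,
                        "gene": "", "consequence": "noncoding",
                    }
                )
            n_post = rng.poisson(mu * (age - spec.expansion_age))
            for _ in range(n_post):
                t_origin = float(rng.uniform(spec.expansion_age, age))
                chrom, pos, ref, alt, context = _draw_site(rng, config, class_probs)
                if spec.n_glands >= 3 and rng.random() < spec.partial_fraction:
                    size = int(rng.integers(2, spec.n_glands))
                    start_i = int(rng.integers(0, spec.n_glands - size + 1))
                    carriers = tuple(gland_ids[start_i : start_i + size])
                    category = "partial"
                else:
                    carriers = (gland_ids[int(rng.integers(spec.n_glands))],)
                    category = "private"
                sites.append(
                    {
                        "category": category, "carriers": carriers,
                        "t_origin": t_origin, "chrom": chrom, "pos": pos,
                        "ref": ref, "alt": alt, "context": context,
                        "maf": 0.5, "cn_phase": "",
                        "gene": "", "consequence": "noncoding",
                    }
                )
            # planted driver mutations: private, clonal within their gland
            for gid in gland_ids:
                for _ in range(rng.poisson(config.driver_mutations_per_gland)):
                    chrom, pos, ref, alt, context = _draw_site(
                        rng, config, class_probs
                    )
                    sites.append(
                        {
                            "category": "private", "carriers": (gid,),
                            "t_origin": float(rng.uniform(spec.expansion_age, age)),
                            "chrom": chrom, "pos": pos, "ref": ref,
                            "alt": alt, "context": context, "maf": 0.5,
                            "cn_phase": "",
                            "gene": str(rng.choice(DRIVER_GENE_POOL)),
                            "consequence": "missense",
                        }
                    )

            # --- read sampling --------------------------------------------
            for site in sites:
                mut_counter += 1
                mut_id = f"{subject}_{spec.name}_m{mut_counter}"
                truth_rows.append(
                    {
                        "mut_id": mut_id, "subject_id": subject,
                        "cluster": spec.name, "category": site["category"],
                        "cn_phase": site["cn_phase"],
                        "t_origin": site["t_origin"], "chrom": site["chrom"],
                        "pos": site["pos"], "ref": site["ref"],
                        "alt": site["alt"], "context": site["context"],
                        "gene": site["gene"],
                        "consequence": site["consequence"],
                        "n_carriers": len(site["carriers"]),
                    }
                )
                for gid in gland_ids:
                    depth = max(1, int(rng.poisson(config.depth_mean)))
                    p = site["maf"] if gid in site["carriers"] else 0.0
                    alt_reads = _alt_reads(rng, depth, p, config.overdispersion)
                    blood_depth = max(1, int(rng.poisson(config.blood_depth_mean)))
                    blood_alt = 0
                    if (
                        config.germline_contamination > 0
                        and rng.random() < config.germline_contamination
                    ):
                        blood_alt = int(rng.binomial(blood_depth, 0.5))
                    subject_glands[gid].mutations.append(
                        MutationRecord(
                            gland_id=gid, subject_id=subject,
                            chrom=site["chrom"], pos=site["pos"],
                            ref=site["ref"], alt=site["alt"], depth=depth,
                            alt_reads=alt_reads, blood_depth=blood_depth,
                            blood_alt_reads=blood_alt,
                            context=site["context"],
                            consequence=site["consequence"],
                            gene=site["gene"],
                        )
                    )
        glands.extend(subject_glands.values())

    subjects = pd.DataFrame(
        {
            "subject_id": [c.subject_id for c in clinical],
            "age": [c.age for c in clinical],
            "cnmc": [c.cnmc for c in clinical],
            "expected_burden_per_mb": [
                config.mutation_rate_per_year * c.age for c in clinical
            ],
        }
    )
    truth = GroundTruth(
        mutations=pd.DataFrame(truth_rows),
        clusters=pd.DataFrame(cluster_rows),
        subjects=subjects,
        events=pd.DataFrame(event_rows),
    )
    return glands, clinical, truth


def simulate_noncoding_catalog(
    signature_mix: Sequence[float],
    n_snvs: int,
    seed: int | None = None,
    signature_matrix: SignatureMatrix | None = None,
) -> np.ndarray:
    """96-class noncoding SNV counts: a multinomial draw from a signature mix."""
    mix = np.asarray(signature_mix, dtype=float)
    if mix.size == 0:
        raise ValueError("empty signature mix")
    if n_snvs < 1:
        raise ValueError("n_snvs must be >= 1")
    sig = signature_matrix if signature_matrix is not None else clocklike_signature_matrix()
    if mix.size != sig.k:
        raise ValueError("mix length must match signature matrix")
    p = sig.probabilities @ (mix / mix.sum())
    rng = np.random.default_rng(seed)
    return rng.multinomial(n_snvs, p / p.sum()).astype(float)


def simulate_selection_catalog(
    gene_models: Mapping[str, GeneModel],
    omega_map: Mapping[str, float],
    t: float,
    r: np.ndarray,
    seed: int | None = None,
) -> pd.DataFrame:
    """Draw per-gene coding SNV counts under the Poisson selection model.

    Missense counts use lambda = t * r_i * L_i^m * omega (nonsense
    likewise with its own omega; here a single omega per gene scales
    both), synonymous counts are neutral. Returns a per-gene table of
    observed counts plus the planted omega.
    """
    if t < 0:
        raise ValueError("t must be >= 0")
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("negative context rates")
    rng = np.random.default_rng(seed)
    rows = []
    for gene, model in gene_models.items():
        omega = float(omega_map.get(gene, 1.0))
        if omega < 0:
            raise ValueError(f"negative omega for {gene}")
        lam = {
            "missense": t * float(r @ model.L["missense"]) * omega,
            "nonsense": t * float(r @ model.L["nonsense"]) * omega,
            "synonymous": t * float(r @ model.L["synonymous"]),
        }
        rows.append(
            {
                "gene": gene,
                **{c: int(rng.poisson(lam[c])) for c in CONSEQUENCE_CLASSES},
                "true_omega": omega,
            }
        )
    return pd.DataFrame(rows).set_index("gene")


def random_gene_model(
    gene: str, n_codons: int, seed: int | None = None
) -> GeneModel:
    """A random stop-free CDS (with flanks) and its site opportunities."""
    rng = np.random.default_rng(seed)
    stops = {"TAA", "TAG", "TGA"}
    codons = []
    while len(codons) < n_codons:
        codon = "".join(rng.choice(list("ACGT"), 3))
        if codon not in stops:
            codons.append(codon)
    flank5, flank3 = rng.choice(list("ACGT")), rng.choice(list("ACGT"))
    return count_site_opportunities(gene, flank5 + "".join(codons) + flank3)


def simulate_het_signal(
    n_sites: int,
    events: Sequence[CnlohEventSpec] = (),
    chrom_lengths: Mapping[str, int] | None = None,
    depth: float = 30.0,
    seed: int | None = None,
    exact: bool = False,
) -> HetSiteSignal:
    """Germline-heterozygous-site allelic-imbalance signal for one gland.

    Sites are spread evenly over the genome. Outside planted CN-LOH events
    the gland B-allele fraction is 0.5; inside an event with cellular
    fraction rho it is shifted to 0.5 +/- rho/2 (one parental allele
    duplicated, the other lost). The |log odds ratio| versus matched blood
    is computed from binomially sampled read counts (with 0.5
    pseudocounts), or deterministically from the expected fractions when
    ``exact`` is set.
    """
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    lengths = dict(chrom_lengths or DEFAULT_CHROM_LENGTHS)
    rng = np.random.default_rng(seed)
    total = sum(lengths.values())
    rows = []
    for chrom, length in lengths.items():
        n_chrom = max(1, int(round(n_sites * length / total)))
        positions = np.linspace(1, length, n_chrom, dtype=int)
        for pos in positions:
            rho_here = 0.0
            for ev in events:
                if ev.chrom == chrom and ev.start <= pos < ev.end:
                    rho_here = ev.rho
                    break
            if exact:
                if rho_here > 0:
                    hi, lo = 0.5 + rho_here / 2.0, 0.5 - rho_here / 2.0
                    value = abs(np.log(hi / max(lo, 1e-12)) - np.log(1.0))
                else:
                    value = 0.0
            else:
                sign = 1 if rng.random() < 0.5 else -1
                baf = 0.5 + sign * rho_here / 2.0
                d_g = max(1, int(rng.poisson(depth)))
                d_b = max(1, int(rng.poisson(depth)))
                alt_g = rng.binomial(d_g, baf)
                alt_b = rng.binomial(d_b, 0.5)
                or_g = (alt_g + 0.5) / (d_g - alt_g + 0.5)
                or_b = (alt_b + 0.5) / (d_b - alt_b + 0.5)
                value = abs(np.log(or_g / or_b))
            rows.append({"chrom": chrom, "pos": int(pos), "abs_log_or": float(value)})
    return HetSiteSignal(sites=pd.DataFrame(rows))
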