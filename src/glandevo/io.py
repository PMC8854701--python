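"""Flat-file interfaces: mutation/clinical/gland TSVs, VCF input, MAF
matrices and result tables. All formats are plain text and round-trip."""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .catalog import GlandSample, MutationRecord, SubjectClinical
from .clones import MafMatrix

MUTATION_COLUMNS = [
    "gland_id", "subject_id", "chrom", "pos", "ref", "alt", "depth",
    "alt_reads", "blood_depth", "blood_alt_reads", "context", "consequence",
    "gene", "pop_freq", "quality_pass",
]

CLINICAL_COLUMNS = [
    "subject_id", "age", "menarche_age", "parity", "bmi", "pack_years",
    "disease",
]

GLAND_COLUMNS = [
    "gland_id", "subject_id", "grid_id", "callable_bases",
    "coverage20_fraction",
]


def records_to_frame(records: Iterable[MutationRecord]) -> pd.DataFrame:
    rows = [
        {
            "gland_id": r.gland_id, "subject_id": r.subject_id,
            "chrom": r.chrom, "pos": r.pos, "ref": r.ref, "alt": r.alt,
            "depth": r.depth, "alt_reads": r.alt_reads,
            "blood_depth": r.blood_depth,
            "blood_alt_reads": r.blood_alt_reads, "context": r.context,
            "consequence": r.consequence, "gene": r.gene,
            "pop_freq": r.pop_freq, "quality_pass": r.quality_pass,
        }
        for r in records
    ]
    return pd.DataFrame(rows, columns=MUTATION_COLUMNS)


def frame_to_records(frame: pd.DataFrame) -> list[MutationRecord]:
    records = []
    for row in frame.itertuples(index=False):
        records.append(
            MutationRecord(
                gland_id=str(row.gland_id),
                subject_id=str(getattr(row, "subject_id", "")),
                chrom=str(row.chrom), pos=int(row.pos),
                ref=str(row.ref), alt=str(row.alt),
                depth=int(row.depth), alt_reads=int(row.alt_reads),
                blood_depth=int(getattr(row, "blood_depth", 0)),
                blood_alt_reads=int(getattr(row, "blood_alt_reads", 0)),
                context=_string(getattr(row, "context", "")),
                consequence=_string(getattr(row, "consequence", "noncoding"))
                or "noncoding",
                gene=_string(getattr(row, "gene", "")),
                pop_freq=float(getattr(row, "pop_freq", 0.0)),
                quality_pass=bool(getattr(row, "quality_pass", True)),
            )
        )
    return records


def _string(value) -> str:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return ""
    return str(value)


def write_mutation_tsv(records: Iterable[MutationRecord], path) -> None:
    records_to_frame(records).to_csv(path, sep="\t", index=False)


def read_mutation_tsv(path) -> list[MutationRecord]:
    return frame_to_records(pd.read_csv(path, sep="\t", dtype={"chrom": str}))


def write_clinical_tsv(subjects: Iterable[SubjectClinical], path) -> None:
    rows = [
        {
            "subject_id": s.subject_id, "age": s.age,
            "menarche_age": s.menarche_age, "parity": s.parity,
            "bmi": s.bmi, "pack_years": s.pack_years, "disease": s.disease,
        }
        for s in subjects
    ]
    pd.DataFrame(rows, columns=CLINICAL_COLUMNS).to_csv(path, sep="\t", index=False)


def read_clinical_tsv(path) -> list[SubjectClinical]:
    frame = pd.read_csv(path, sep="\t")
    out = []
    for row in frame.itertuples(index=False):
        out.append(
            SubjectClinical(
                subject_id=str(row.subject_id), age=float(row.age),
                menarche_age=_opt_float(getattr(row, "menarche_age", None)),
                parity=_opt_int(getattr(row, "parity", None)),
                bmi=_opt_float(getattr(row, "bmi", None)),
                pack_years=_opt_float(getattr(row, "pack_years", None)),
                disease=_string(getattr(row, "disease", "")),
            )
        )
    return out


def _opt_float(value) -> float | None:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    return float(value)


def _opt_int(value) -> int | None:
    f = _opt_float(value)
    return None if f is None else int(f)


def write_gland_tsv(glands: Iterable[GlandSample], path) -> None:
    rows = [
        {
            "gland_id": g.gland_id, "subject_id": g.subject_id,
            "grid_id": g.grid_id, "callable_bases": g.callable_bases,
            "coverage20_fraction": g.coverage20_fraction,
        }
        for g in glands
    ]
    pd.DataFrame(rows, columns=GLAND_COLUMNS).to_csv(path, sep="\t", index=False)


def read_gland_tsv(path, mutations: Iterable[MutationRecord] = ()) -> list[GlandSample]:
    """Read gland metadata and attach mutation records by gland id."""
    frame = pd.read_csv(path, sep="\t")
    by_gland: dict[str, list[MutationRecord]] = {}
    for rec in mutations:
        by_gland.setdefault(rec.gland_id, []).append(rec)
    out = []
    for row in frame.itertuples(index=False):
        gid = str(row.gland_id)
        out.append(
            GlandSample(
                gland_id=gid, subject_id=str(row.subject_id),
                grid_id=_string(getattr(row, "grid_id", "")),
                callable_bases=int(row.callable_bases),
                coverage20_fraction=_opt_float(
                    getattr(row, "coverage20_fraction", None)
                ),
                mutations=by_gland.get(gid, []),
            )
        )
    return out


def read_vcf(
    path,
    gland_sample: str,
    blood_sample: str | None = None,
    subject_id: str = "",
) -> list[MutationRecord]:
    """Read somatic calls from a (plain-text or bgzipped) VCF.

    Per-sample allele depths come from FORMAT/AD and total depth from
    FORMAT/DP (or the AD sum when DP is absent). ``gland_sample`` and
    ``blood_sample`` name the VCF sample columns. Population frequency is
    taken from INFO/POP_AF when present and the trinucleotide context from
    INFO/CONTEXT.
    """
    import pysam

    records = []
    with pysam.VariantFile(str(path)) as vcf:
        for var in vcf.fetch() if vcf.index is not None else vcf:
            for alt_i, alt in enumerate(var.alts or ()):
                sample = var.samples[gland_sample]
                ad = sample.get("AD")
                if ad is None:
                    continue
                alt_reads = int(ad[alt_i + 1] or 0)
                depth = int(sample.get("DP") or sum(int(x or 0) for x in ad))
                blood_depth = blood_alt = 0
                if blood_sample is not None:
                    bl = var.samples[blood_sample]
                    bad = bl.get("AD")
                    if bad is not None:
                        blood_alt = int(bad[alt_i + 1] or 0)
                        blood_depth = int(
                            bl.get("DP") or sum(int(x or 0) for x in bad)
                        )
                info = var.info
                pop = info.get("POP_AF", 0.0)
                if isinstance(pop, tuple):
                    pop = pop[alt_i] if alt_i < len(pop) else pop[0]
                records.append(
                    MutationRecord(
                        gland_id=gland_sample, subject_id=subject_id,
                        chrom=str(var.chrom), pos=int(var.pos),
                        ref=str(var.ref), alt=str(alt),
                        depth=depth, alt_reads=min(alt_reads, depth),
                        blood_depth=blood_depth,
                        blood_alt_reads=min(blood_alt, max(blood_depth, 0)),
                        context=str(info.get("CONTEXT", "") or ""),
                        consequence=str(info.get("CSQ_CLASS", "noncoding") or "noncoding"),
                        gene=str(info.get("GENE", "") or ""),
                        pop_freq=float(pop or 0.0),
                        quality_pass="PASS" in (var.filter.keys() or ["PASS"]),
                    )
                )
    return records


def site_key(rec: MutationRecord) -> str:
    return f"{rec.chrom}:{rec.pos}:{rec.ref}>{rec.alt}"


def maf_matrix_from_glands(
    glands: Sequence[GlandSample], subject_id: str | None = None
) -> MafMatrix:
    """Compile the sites x glands MAF matrix for one subject's glands.

    A site absent from a gland's records is taken as MAF 0 (no mutant
    reads observed). Gland metadata carries the grid assignment; site
    metadata carries gene and matched-blood MAF (maximum across glands).
    """
    use = [
        g for g in glands if subject_id is None or g.subject_id == subject_id
    ]
    if not use:
        raise ValueError("no glands selected")
    mafs: dict[str, dict[str, float]] = {}
    genes: dict[str, str] = {}
    blood: dict[str, float] = {}
    for g in use:
        for rec in g.mutations:
            key = site_key(rec)
            if rec.depth > 0:
                mafs.setdefault(key, {})[g.gland_id] = rec.maf
            genes.setdefault(key, rec.gene)
            blood[key] = max(blood.get(key, 0.0), rec.blood_maf)
    values = pd.DataFrame(
        mafs, index=[g.gland_id for g in use]
    ).T.fillna(0.0).sort_index()
    site_meta = pd.DataFrame(
        {
            "gene": pd.Series(genes).reindex(values.index),
            "blood_maf": pd.Series(blood).reindex(values.index),
        }
    )
    gland_meta = pd.DataFrame(
        {"grid_id": {g.gland_id: g.grid_id for g in use}}
    ).reindex(values.columns)
    return MafMatrix(values=values, site_meta=site_meta, gland_meta=gland_meta)


def write_maf_matrix(matrix: MafMatrix, path) -> None:
    matrix.values.to_csv(path, sep="\t", index_label="site")


def read_maf_matrix(path) -> MafMatrix:
    return MafMatrix(values=pd.read_csv(path, sep="\t", index_col="site"))
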