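"""End-to-end orchestration of the analysis stages on a cohort.

``run_pipeline`` drives: simulate (optional) -> filter/QC -> burden,
spectrum and signature exposures -> dN/dS on a selection catalog ->
clone clustering and phylogeny -> CN-LOH signal -> timing. Every stage
writes plain-text TSV outputs into the run directory and the manifest
records the seed, package version and a checksum per output so a run is
reproducible byte-for-byte.
"""

from __future__ import annotations

import hashlib
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .burden import mutation_burden, spectrum_96
from .catalog import filter_somatic_calls, gland_qc
from .clones import classify_sharing, cluster_glands, nj_tree, hamming_matrix, select_informative_mutations
from .cnloh import call_segments, normalize_imbalance
from .dnds import estimate_context_rates, gene_set_dnds
from .io import (
    maf_matrix_from_glands,
    write_clinical_tsv,
    write_gland_tsv,
    write_maf_matrix,
    write_mutation_tsv,
)
from .signatures import fit_exposures
from .synthetic import (
    CnlohEventSpec,
    CloneSpec,
    SimulationConfig,
    clocklike_signature_matrix,
    random_gene_model,
    simulate_cohort,
    simulate_het_signal,
    simulate_noncoding_catalog,
    simulate_selection_catalog,
)
from .timing import snv_cnloh_weights, time_cnloh, time_expansion

log = logging.getLogger("glandevo")

DEFAULT_CONFIG = {
    "seed": 0,
    "n_subjects": 4,
    "depth_mean": 80.0,
    "mutation_rate_per_year": 0.08,
    "callable_mb": 30.0,
    "n_boot": 200,
    "n_iter_timing": 10_000,
    "cnloh": True,
    "dnds_genes": 12,
    "dnds_omega": 5.0,
}


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config: dict | None = None, out_dir: str | Path = "glandevo_run") -> dict:
    """Run all stages under one seed; returns the run manifest."""
    cfg = dict(DEFAULT_CONFIG)
    cfg.update(config or {})
    seed = int(cfg["seed"])
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "seed": seed, "outputs": {}}

    def _save(name: str, writer) -> None:
        path = out / name
        writer(path)
        manifest["outputs"][name] = _checksum(path)
        log.info("wrote %s", path)

    # --- simulate -------------------------------------------------------
    log.info("stage: simulate")
    sim = SimulationConfig(
        n_subjects=int(cfg["n_subjects"]),
        depth_mean=float(cfg["depth_mean"]),
        mutation_rate_per_year=float(cfg["mutation_rate_per_year"]),
        callable_mb=float(cfg["callable_mb"]),
        seed=seed,
    )
    if cfg["cnloh"]:
        # plant one CN-LOH in the first subject's cluster, halfway to its
        # clonal expansion
        from .synthetic import _default_clone_specs

        specs = _default_clone_specs(sim)
        first = next(iter(specs))
        clone = specs[first][0]
        cnloh_event = CnlohEventSpec(
            chrom="chr3", start=1, end=20_000_000,
            true_age=round(0.5 * clone.expansion_age, 1), rho=1.0,
        )
        specs[first] = (
            CloneSpec(
                name=clone.name, n_glands=clone.n_glands,
                expansion_age=clone.expansion_age,
                grid_cells=clone.grid_cells,
                cnloh_events=(cnloh_event,),
            ),
        )
        sim.clone_specs = specs
    glands, clinical, truth = simulate_cohort(sim)
    _save("mutations.tsv", lambda p: write_mutation_tsv(
        [m for g in glands for m in g.mutations], p))
    _save("glands.tsv", lambda p: write_gland_tsv(glands, p))
    _save("clinical.tsv", lambda p: write_clinical_tsv(clinical, p))
    _save("truth_mutations.tsv", lambda p: truth.mutations.to_csv(p, sep="\t", index=False))
    _save("truth_clusters.tsv", lambda p: truth.clusters.to_csv(p, sep="\t", index=False))

    # --- filter / QC ----------------------------------------------------
    log.info("stage: filter")
    qc_pass = [g for g in glands if gland_qc(g)]
    kept_by_gland = {}
    tally_total: dict[str, int] = {}
    for g in qc_pass:
        kept, tally = filter_somatic_calls(g.mutations, mode="wgs")
        kept_by_gland[g.gland_id] = kept
        for k, v in tally.items():
            tally_total[k] = tally_total.get(k, 0) + v
    _save("filter_tally.tsv", lambda p: pd.Series(
        tally_total, name="rejected").to_csv(p, sep="\t", index_label="criterion"))

    # --- burden / spectrum / signatures --------------------------------
    log.info("stage: burden")
    rows = []
    for subject in sorted({g.subject_id for g in qc_pass}):
        subject_glands = [g for g in qc_pass if g.subject_id == subject]
        res = mutation_burden(subject_glands)
        rows.append({"subject_id": subject, "burden_per_mb": res.burden,
                     "cpg_ct_burden": res.cpg_ct_burden,
                     "n_mutations": res.n_mutations})
    _save("burden.tsv", lambda p: pd.DataFrame(rows).to_csv(p, sep="\t", index=False))

    log.info("stage: signatures")
    high = [m for kept in kept_by_gland.values() for m in kept]
    spec96 = spectrum_96([m for m in high if m.is_snv])
    sigs = clocklike_signature_matrix()
    exposures = fit_exposures(
        spec96, sigs, n_boot=int(cfg["n_boot"]), seed=seed + 1)
    _save("exposures.tsv", lambda p: exposures.to_frame().to_csv(
        p, sep="\t", index_label="signature"))

    # --- dN/dS ----------------------------------------------------------
    log.info("stage: dnds")
    n_genes = int(cfg["dnds_genes"])
    models = {
        f"G{i + 1}": random_gene_model(f"G{i + 1}", 400, seed=seed + 10 + i)
        for i in range(n_genes)
    }
    selected = list(models)[: max(2, n_genes // 3)]
    omega_map = {g: float(cfg["dnds_omega"]) for g in selected}
    noncoding = simulate_noncoding_catalog(
        sim.signature_mix, 1_000_000, seed=seed + 2,
        signature_matrix=sim.signature_matrix)
    rates0 = estimate_context_rates(noncoding, models.values(), observed_total=1.0)
    catalog = simulate_selection_catalog(
        models, omega_map, t=3e-4, r=rates0.r, seed=seed + 3)
    observed_total = float(
        catalog[["missense", "nonsense", "synonymous"]].to_numpy().sum())
    rates = estimate_context_rates(
        noncoding, models.values(), observed_total=observed_total)
    fit_sel = gene_set_dnds(catalog, rates, models, "selected", selected)
    neutral = [g for g in models if g not in selected]
    fit_neu = gene_set_dnds(catalog, rates, models, "neutral", neutral)
    dnds_rows = []
    for fit in (fit_sel, fit_neu):
        for cls in ("missense", "nonsense"):
            est = getattr(fit, cls)
            if est is None:
                continue
            dnds_rows.append({
                "set": fit.scope, "class": cls, "omega": est.omega,
                "ci_low": est.ci_low, "ci_high": est.ci_high, "p": est.p,
                "driver_fraction": getattr(fit, f"driver_fraction_{cls}"),
            })
    _save("dnds_sets.tsv", lambda p: pd.DataFrame(dnds_rows).to_csv(
        p, sep="\t", index=False))

    # --- clustering / phylogeny ----------------------------------------
    log.info("stage: cluster")
    subject0 = clinical[0].subject_id
    matrix = maf_matrix_from_glands(qc_pass, subject_id=subject0)
    informative = select_informative_mutations(matrix)
    clusters, _ = cluster_glands(informative)
    cluster_rows = [
        {"cluster": c.cluster_id, "n_glands": c.size,
         "members": ";".join(c.members),
         "n_defining": len(c.defining_mutations)}
        for c in clusters
    ]
    _save("clusters.tsv", lambda p: pd.DataFrame(cluster_rows).to_csv(
        p, sep="\t", index=False))
    _save("maf_matrix.tsv", lambda p: write_maf_matrix(informative, p))
    presence = (informative.values >= 0.25).astype(int).T
    if presence.shape[0] >= 3:
        tree = nj_tree(
            hamming_matrix(presence), list(informative.values.columns))
        _save("tree.nwk", lambda p: tree.write(str(p)))

    # --- CN-LOH + timing -----------------------------------------------
    log.info("stage: timing")
    timing_rows = []
    multi = [c for c in clusters if c.size >= 2]
    age0 = clinical[0].age
    for c in multi:
        # timing needs private mutations too, so classify on the full matrix
        sharing = classify_sharing(c, matrix)
        if sharing.total == 0:
            continue
        est = time_expansion(age0, sharing.mb_pub, sharing.mb_ps, sharing.mb_priv)
        timing_rows.append({
            "subject_id": subject0, "cluster": c.cluster_id,
            "event": "expansion", "estimate": est.age_estimate,
            "ci_low": est.ci_low, "ci_high": est.ci_high,
            "m": est.inputs["m"], "p": est.inputs["p"],
            "n_iter": 0, "seed": seed,
        })
        if cfg["cnloh"] and not truth.events.empty:
            ev = truth.events.iloc[0]
            region_sites = [
                s for s, lab in sharing.labels.items()
                if lab == "public" and s.startswith(f"{ev.chrom}:")
                and ev.start <= int(s.split(":")[1]) < ev.end
            ]
            if region_sites:
                gland_ids = list(c.members)
                weights = []
                depth_map = {
                    (m.gland_id, f"{m.chrom}:{m.pos}:{m.ref}>{m.alt}"): m
                    for g in qc_pass if g.subject_id == subject0
                    for m in g.mutations
                }
                for site in region_sites:
                    recs = [depth_map.get((gid, site)) for gid in gland_ids]
                    recs = [r for r in recs if r is not None]
                    if not recs:
                        continue
                    weights.append(snv_cnloh_weights(
                        site,
                        [r.depth for r in recs],
                        [r.alt_reads for r in recs],
                        [float(ev.rho)] * len(recs),
                    ))
                if weights:
                    est_cn = time_cnloh(
                        est, weights, n_iter=int(cfg["n_iter_timing"]),
                        seed=seed + 5)
                    timing_rows.append({
                        "subject_id": subject0, "cluster": c.cluster_id,
                        "event": "cnloh", "estimate": est_cn.age_estimate,
                        "ci_low": est_cn.ci_low, "ci_high": est_cn.ci_high,
                        "m": est_cn.inputs["n_snvs"], "p": np.nan,
                        "n_iter": int(cfg["n_iter_timing"]), "seed": seed + 5,
                    })
    _save("timing.tsv", lambda p: pd.DataFrame(timing_rows).to_csv(
        p, sep="\t", index=False))

    if cfg["cnloh"] and not truth.events.empty:
        ev = truth.events.iloc[0]
        signal = simulate_het_signal(
            4000,
            events=[CnlohEventSpec(
                chrom=str(ev.chrom), start=int(ev.start), end=int(ev.end),
                true_age=float(ev.true_age), rho=float(ev.rho))],
            seed=seed + 6,
        )
        norm = normalize_imbalance(signal)
        segments = call_segments(norm, rho=float(ev.rho))
        seg_rows = [
            {"chrom": s.chrom, "start": s.start, "end": s.end,
             "rho": s.rho, "copy_state": s.copy_state, "n_sites": s.n_sites}
            for s in segments
        ]
        _save("cnloh_segments.tsv", lambda p: pd.DataFrame(seg_rows).to_csv(
            p, sep="\t", index=False))

    import yaml

    (out / "manifest.yaml").write_text(yaml.safe_dump(manifest, sort_keys=True))
    return manifest
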