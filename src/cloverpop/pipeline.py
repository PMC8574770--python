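"""End-to-end orchestration: counts -> calls -> diversity/AMOVA/structure ->
DAPC -> selection scans -> variant effects, with per-stage reproducibility.

Every stochastic stage receives an independent child seed derived from the
master seed and the stage name, so a stage re-run in isolation reproduces
its slice of a full run. Each output table carries the config hash and the
master seed in its metadata header; the genotype stage is cached on disk
(VCF + summary) and reused when the config hash matches.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from . import calling, dapc, diversity, effects, selection, simulate, structure
from .amova import AmovaResult, amova as run_amova
from .io_formats import (
    AlleleCountTable,
    GenotypeMatrix,
    PopulationMap,
    RunConfig,
    read_allele_counts,
    read_genotypes_vcf,
    read_population_map,
    write_genotypes_vcf,
    write_table,
)

log = logging.getLogger("cloverpop")


def child_seed(master: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    digest = hashlib.sha256(f"{master}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31 - 1)


@dataclass
class ReportBundle:
    """All result tables of one pipeline run plus run metadata."""

    locus_summary: calling.LocusClassSummary | None = None
    genotypes: GenotypeMatrix | None = None
    diversity: diversity.DiversitySummary | None = None
    group_summaries: dict[str, pd.DataFrame] = field(default_factory=dict)
    amova: dict[str, AmovaResult] = field(default_factory=dict)
    distances: dict[str, structure.DistanceMatrix] = field(default_factory=dict)
    trees: dict[str, str] = field(default_factory=dict)  # name -> newick
    pcoa: structure.PcoaResult | None = None
    dapc: dapc.DapcResult | None = None
    selection: pd.DataFrame | None = None
    effect_table: pd.DataFrame | None = None
    failures: dict[str, str] = field(default_factory=dict)
    metadata: dict[str, object] = field(default_factory=dict)


ALL_STAGES = (
    "call",
    "diversity",
    "amova",
    "structure",
    "dapc",
    "selection",
    "effects",
)


def run_pipeline(
    cfg: RunConfig,
    out_dir: str | Path,
    sim: simulate.SimulationConfig | None = None,
    stages: Iterable[str] = ALL_STAGES,
    cds_inputs: tuple[Mapping[str, str], pd.DataFrame] | None = None,
) -> ReportBundle:
    """Run the analysis stages in order, writing tables under ``out_dir``.

    Inputs are either simulated (``sim`` given; the synthetic cohort's CDS
    contexts are generated alongside) or read from the paths in ``cfg``.
    A failing stage is recorded in ``bundle.failures`` and downstream stages
    that can still run do so.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages = list(stages)
    meta = {"seed": cfg.seed, "config_hash": cfg.content_hash()}
    bundle = ReportBundle(metadata=dict(meta))
    t0 = time.time()

    # ------------------------------------------------------------------ input
    if sim is not None:
        sim_seeded = simulate.SimulationConfig(
            **{**sim.__dict__, "seed": child_seed(cfg.seed, "simulate")}
        )
        truth_matrix, truth = simulate.simulate_populations(sim_seeded)
        counts = simulate.simulate_read_counts(
            truth_matrix,
            truth,
            mean_coverage=sim_seeded.mean_coverage,
            error_rate=sim_seeded.error_rate,
            low_coverage_locus_fraction=sim_seeded.low_coverage_locus_fraction,
            seed=child_seed(cfg.seed, "reads"),
        )
        pm = simulate.make_population_map(sim_seeded)
        locus_meta = {l.locus_id: (l.gene_id, l.position) for l in truth_matrix.loci}
    else:
        counts = read_allele_counts(cfg.input_counts)
        pm = read_population_map(cfg.input_population_map)
        locus_meta = None
    _log_stage("input", t0, counts=getattr(counts, "n_loci", None))

    # ------------------------------------------------------------------- call
    vcf_path = out / "genotypes.vcf"
    summary_path = out / "locus_class_summary.tsv"
    m: GenotypeMatrix | None = None
    if "call" in stages:
        if _cached(vcf_path, summary_path, meta["config_hash"]):
            m = read_genotypes_vcf(vcf_path)
            log.info("call: reusing cached genotypes (%d loci)", m.n_loci)
            bundle.genotypes = m
        else:
            raw = calling.call_genotypes(counts, cfg.min_allele_count)
            m, summary = calling.classify_and_filter(
                raw, cfg.max_missing_fraction, locus_meta=locus_meta
            )
            bundle.locus_summary = summary
            bundle.genotypes = m
            write_genotypes_vcf(m, vcf_path)
            write_table(summary.to_frame(), summary_path, meta)
        _log_stage("call", t0, loci=m.n_loci)
    if m is None:
        bundle.failures["call"] = "stage skipped; downstream stages unavailable"
        return bundle

    # -------------------------------------------------------------- diversity
    ft = diversity.allele_frequencies(m, pm)
    if "diversity" in stages:
        try:
            ds = diversity.diversity_summary(m, pm)
            bundle.diversity = ds
            write_table(ds.per_accession, out / "diversity_per_accession.tsv", meta)
            write_table(
                pd.DataFrame([ds.overall]), out / "diversity_overall.tsv", meta
            )
            for grouping in cfg.groupings:
                gs = diversity.group_summary(m, pm, grouping)
                bundle.group_summaries[grouping] = gs
                write_table(gs, out / f"diversity_by_{grouping}.tsv", meta)
            _log_stage("diversity", t0)
        except Exception as exc:  # pragma: no cover - defensive
            bundle.failures["diversity"] = repr(exc)

    # ------------------------------------------------------------------ amova
    if "amova" in stages:
        try:
            designs: list[tuple[str, object]] = [("ungrouped", None)]
            designs += [(g, g) for g in cfg.groupings]
            for name, grouping in designs:
                res = run_amova(
                    m,
                    pm,
                    grouping=grouping,
                    n_permutations=cfg.n_permutations,
                    seed=child_seed(cfg.seed, f"amova:{name}"),
                )
                bundle.amova[name] = res
                amova_meta = {**meta, "indices": res.indices, "p_values": res.p_values}
                write_table(res.table, out / f"amova_{name}.tsv", amova_meta)
            _log_stage("amova", t0)
        except Exception as exc:
            bundle.failures["amova"] = repr(exc)

    # -------------------------------------------------------------- structure
    if "structure" in stages:
        try:
            nei_std = structure.nei_distance(ft, "standard")
            nei_unb = structure.nei_distance(ft, "unbiased")
            fst = structure.pairwise_fst(
                m,
                pm,
                n_permutations=cfg.n_pairwise_permutations,
                seed=child_seed(cfg.seed, "pairwise_fst"),
            )
            bundle.distances = {
                "nei_standard": nei_std,
                "nei_unbiased": nei_unb,
                "fst": fst,
            }
            for name, dm in bundle.distances.items():
                write_table(dm.to_frame().reset_index(), out / f"distance_{name}.tsv", meta)
            write_table(structure.mean_pairwise_fst(fst), out / "mean_pairwise_fst.tsv", meta)
            tree = structure.neighbor_joining(nei_unb)
            bundle.trees["accessions_nei_unbiased"] = tree.to_newick()
            tn = structure.tamura_nei_distance(m)
            bundle.distances["tamura_nei"] = tn
            if np.isfinite(tn.matrix).all():
                ind_tree = structure.neighbor_joining(tn)
                bundle.trees["individuals_tn93"] = ind_tree.to_newick()
            for name, newick in bundle.trees.items():
                (out / f"tree_{name}.nwk").write_text(newick + "\n")
            bundle.pcoa = structure.pcoa(nei_unb, n_axes=2)
            coords = pd.DataFrame(
                bundle.pcoa.coordinates,
                columns=[f"axis{k + 1}" for k in range(bundle.pcoa.coordinates.shape[1])],
            )
            coords.insert(0, "accession", bundle.pcoa.ids)
            write_table(coords, out / "pcoa_coordinates.tsv", meta)
            _log_stage("structure", t0)
        except Exception as exc:
            bundle.failures["structure"] = repr(exc)

    # ------------------------------------------------------------------- dapc
    if "dapc" in stages:
        try:
            seed = child_seed(cfg.seed, "dapc")
            search = dapc.find_clusters(m, max_k=8, n_pcs=100, seed=seed)
            if search.k >= 2:
                labels = search.labels
            else:
                # no de-novo clusters: describe prior accession membership instead
                labels = np.array([pm.accession_of(i) for i in m.individual_ids])
            fit = dapc.dapc_fit(m, labels, n_pcs=min(100, m.n_individuals - 1), pm=pm)
            bundle.dapc = fit
            write_table(
                fit.posteriors.reset_index(names="individual"),
                out / "dapc_posteriors.tsv",
                meta,
            )
            if fit.accession_memberships is not None:
                write_table(
                    fit.accession_memberships.reset_index(),
                    out / "dapc_accession_memberships.tsv",
                    meta,
                )
            _log_stage("dapc", t0, k=search.k)
        except Exception as exc:
            bundle.failures["dapc"] = repr(exc)

    # -------------------------------------------------------------- selection
    if "selection" in stages:
        try:
            hwe = selection.hwe_scan(m)
            fdist = selection.fdist_scan(
                m,
                pm,
                n_simulations=cfg.n_fdist_simulations,
                seed=child_seed(cfg.seed, "fdist"),
            )
            bundle.selection = selection.selection_report(hwe, fdist)
            write_table(bundle.selection, out / "selection_scan.tsv", meta)
            _log_stage("selection", t0)
        except Exception as exc:
            bundle.failures["selection"] = repr(exc)

    # ---------------------------------------------------------------- effects
    if "effects" in stages:
        try:
            if cds_inputs is not None:
                sequences, variants = cds_inputs
            else:
                n = m.n_loci
                n_mis = int(round(0.581 * n))
                n_non = max(1, int(round(0.005 * n)))
                sequences, variants = simulate.generate_cds_fixtures(
                    n,
                    seed=child_seed(cfg.seed, "cds"),
                    class_counts={
                        "missense": n_mis,
                        "nonsense": n_non,
                        "same_sense": n - n_mis - n_non,
                    },
                )
                variants = variants.drop(columns=["effect"])
                variants.insert(0, "locus_id", m.locus_ids[: len(variants)])
            classified = effects.classify_variants(sequences, variants)
            bundle.effect_table = classified
            write_table(classified, out / "variant_effects.tsv", meta)
            _log_stage("effects", t0)
        except Exception as exc:
            bundle.failures["effects"] = repr(exc)

    if bundle.failures:
        (out / "failures.json").write_text(json.dumps(bundle.failures, indent=2))
    return bundle


def _cached(vcf_path: Path, summary_path: Path, config_hash: str) -> bool:
    if not (vcf_path.exists() and summary_path.exists()):
        return False
    with open(summary_path) as fh:
        head = fh.readline()
    return config_hash in head or f"config_hash: {config_hash}" in head


def _log_stage(stage: str, t0: float, **shapes: object) -> None:
    extra = " ".join(f"{k}={v}" for k, v in shapes.items() if v is not None)
    log.info("stage=%s elapsed=%.1fs %s", stage, time.time() - t0, extra)
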