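"""End-to-end orchestration: config, staged execution, manifest, provenance.

Stages run in order (cooccurrence -> profile -> group -> gene maps ->
feature maps -> distances -> fusion -> biomarkers); every intermediate is
written as TSV and recorded in a JSON manifest with its SHA-256 hash, the
full configuration echo and the package version, so a run is
self-describing and reruns with the same config and seed are verifiable
bit-for-bit. All stages are pure functions of (inputs, config, seed); a
resumed run recomputes deterministically but refuses to overwrite
intermediates whose hashes no longer match the manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .comorbidity import comorbidity_profile, select_by_rr
from .data_model import (
    build_cooccurrence,
    read_diagnoses,
    read_gene_disease_sources,
    read_gmt,
    read_network,
)
from .gene_maps import (
    GeneDiseaseMap,
    aggregate_genes_to_dg,
    build_geneset_feature_map,
    gene_feature_map,
    integrate_sources,
    ppi_extend,
    read_crosswalk,
)
from .grouping import (
    aggregate_patients_to_dg,
    cluster_leaf_order,
    load_group_assignment,
    rr_distance_matrix,
)
from .mech_distance import build_rank_table, measure_outlier_diagnostic, similarity_table, summarize_distance
from .rank_fusion import biomarker_table, final_dg_ranking

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    diagnoses: str
    gene_sources: list[str]
    crosswalk: str
    genesets: list[str]
    network: str
    dg_map: str
    outdir: str
    seed: int
    index_code: str = "496"
    rr_select: float = 1.2
    alpha_map: float = 0.01
    alpha_report: float = 0.1
    min_set_size: int = 20
    max_set_size: int = 200
    fwer_threshold: float = 0.05
    n_perm: int = 10_000
    bootstrap_reps: int = 1000
    linkage: str = "complete"
    outlier_threshold: float = 0.2
    summary_pathway_exclude: list[str] = field(default_factory=lambda: ["BIOCARTA"])

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is required")
        for name, value, lo, hi in (
            ("rr_select", self.rr_select, 0, float("inf")),
            ("alpha_map", self.alpha_map, 0, 1),
            ("alpha_report", self.alpha_report, 0, 1),
            ("fwer_threshold", self.fwer_threshold, 0, 1),
        ):
            if not lo < value <= hi:
                raise ValueError(f"{name}={value} outside ({lo}, {hi}]")
        if not 0 < self.min_set_size < self.max_set_size:
            raise ValueError("set size filter must satisfy 0 < min < max")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(cfg: RunConfig, resume: bool = False, through: str | None = None) -> dict:
    """Execute the pipeline; returns the artifact manifest.

    ``through`` optionally names the last stage to run ("distances" stops
    after the rank table, for instance). On ``resume``, existing outputs are
    hash-checked against the previous manifest and the run refuses to
    continue over inconsistent intermediates.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest_path = outdir / "manifest.json"
    previous = {}
    if resume and manifest_path.exists():
        previous = json.loads(manifest_path.read_text()).get("stages", {})
    manifest: dict = {
        "version": __version__,
        "config": dataclasses.asdict(cfg),
        "stages": {},
    }

    def emit(stage: str, name: str, frame: pd.DataFrame, index: bool = True) -> None:
        path = outdir / name
        if resume and stage in previous and name in previous[stage] and path.exists():
            if _sha256(path) != previous[stage][name]:
                raise RuntimeError(
                    f"resume refused: {name} on disk does not match the manifest"
                )
        frame.to_csv(path, sep="\t", index=index)
        manifest["stages"].setdefault(stage, {})[name] = _sha256(path)

    def finish(stage: str) -> bool:
        manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
        return through == stage

    current_stage = "cooccurrence"
    try:
        # --- co-occurrence and index profile at ICD9 level
        diag = read_diagnoses(cfg.diagnoses)
        cooc = build_cooccurrence(diag)
        emit("cooccurrence", "incidence.tsv",
             pd.Series(cooc.I, name="incidence").rename_axis("code").to_frame())
        if finish("cooccurrence"):
            return manifest

        current_stage = "profile"
        profile = comorbidity_profile(cooc, cfg.index_code)
        emit("profile", "profile.tsv", profile.rows)
        selected = select_by_rr(profile, cfg.rr_select)
        emit("profile", "icd9_selected.tsv",
             pd.DataFrame({"code": selected}), index=False)
        if finish("profile"):
            return manifest

        current_stage = "group"
        # --- clustering aid + DG aggregation
        if len(selected) >= 2:
            dm = rr_distance_matrix(cooc, selected)
            order = cluster_leaf_order(dm, cfg.linkage)
            emit("group", "leaf_order.tsv", pd.DataFrame({"code": order}), index=False)
        dgm = load_group_assignment(cfg.dg_map, universe=selected)
        diag_dg = aggregate_patients_to_dg(diag, dgm, passthrough=(cfg.index_code,))
        cooc_dg = build_cooccurrence(diag_dg)
        profile_dg = comorbidity_profile(cooc_dg, cfg.index_code)
        emit("group", "dg_profile.tsv", profile_dg.rows.loc[dgm.dg_ids()])
        if finish("group"):
            return manifest

        current_stage = "gene_maps"
        # --- gene maps
        raw = read_gene_disease_sources(cfg.gene_sources)
        xw = read_crosswalk(cfg.crosswalk)
        mapping1 = integrate_sources(raw, xw)
        m1_dg = aggregate_genes_to_dg(mapping1, dgm, passthrough=(cfg.index_code,))
        net = read_network(cfg.network)
        m2_dg = ppi_extend(m1_dg, net)
        emit("gene_maps", "mapping1.tsv", mapping1.to_frame(), index=False)
        emit("gene_maps", "mapping1_DG.tsv", m1_dg.to_frame(), index=False)
        emit("gene_maps", "mapping2_DG.tsv", m2_dg.to_frame(), index=False)
        if finish("gene_maps"):
            return manifest

        current_stage = "feature_maps"
        # --- gene-set feature maps
        collections = [read_gmt(p) for p in cfg.genesets]
        fmaps = {}
        for label, m in (("mapping1", m1_dg), ("mapping2", m2_dg)):
            fm, enr = build_geneset_feature_map(
                m, collections, cfg.min_set_size, cfg.max_set_size, cfg.alpha_map
            )
            fmaps[label] = fm
            emit("feature_maps", f"geneset_map_{label}.tsv", fm.to_frame())
            emit("feature_maps", f"enrichment_{label}.tsv", enr.rows, index=False)
        if finish("feature_maps"):
            return manifest

        current_stage = "distances"
        # --- mechanistic similarities and rank table
        dgs = dgm.dg_ids()
        values = pd.DataFrame(index=dgs)
        values["RR"] = profile_dg.rows["RR"].reindex(dgs)
        values["Phi"] = profile_dg.rows["Phi"].reindex(dgs)
        gene_summary_cols: list[str] = []
        pathway_summary_cols: list[str] = []

        def add_similarities(prefix: str, index_feats: set, per_dg: dict,
                             universe: set, summary: list[str] | None) -> None:
            if not universe:
                return
            sim = similarity_table(index_feats, per_dg, universe)
            for meas in ("T", "JC", "phi"):
                values[f"{prefix}-{meas}"] = sim[meas].reindex(dgs)
            if summary is not None:
                # summaries use JC and phi; T is near-duplicate of JC
                summary.extend([f"{prefix}-JC", f"{prefix}-phi"])

        for label, m in (("genes", m1_dg), ("genesEXT", m2_dg)):
            add_similarities(
                label,
                m.genes_for(cfg.index_code),
                {dg: m.genes_for(dg) for dg in dgs},
                m.genes(),
                gene_summary_cols if label == "genes" else None,
            )
        excluded = {e.upper() for e in cfg.summary_pathway_exclude}
        for label, fm in fmaps.items():
            suffix = "" if label == "mapping1" else "EXT"
            for coll in collections:
                cols = {f for f in fm.features if f.startswith(f"{coll.source_label}:")}
                if not cols:
                    continue
                is_outlier_coll = any(tok in coll.source_label.upper() for tok in excluded)
                add_similarities(
                    f"{coll.source_label}{suffix}",
                    fm.features_of(cfg.index_code) & cols,
                    {dg: fm.features_of(dg) & cols for dg in dgs},
                    cols,
                    pathway_summary_cols
                    if label == "mapping1" and not is_outlier_coll
                    else None,
                )
        rt = build_rank_table(values)
        emit("distances", "measure_values.tsv", values)
        emit("distances", "rank_table.tsv", rt.ranks)
        if rt.ranks.shape[1] >= 3 and rt.ranks.shape[0] >= 3:
            corr, flagged, loadings = measure_outlier_diagnostic(rt, cfg.outlier_threshold)
            emit("distances", "measure_correlations.tsv", corr)
            emit("distances", "measure_pca_loadings.tsv", loadings)
            manifest["stages"]["distances"]["flagged_measures"] = flagged

        summary = pd.DataFrame(index=dgs)
        summary["RR"] = rt.ranks["RR"]
        summary["Phi"] = rt.ranks["Phi"]
        if gene_summary_cols:
            summary["genes"] = summarize_distance(rt, gene_summary_cols)
        if pathway_summary_cols:
            summary["pathways"] = summarize_distance(rt, pathway_summary_cols)
        emit("distances", "summary_ranks.tsv", summary)
        if finish("distances"):
            return manifest

        current_stage = "fusion"
        # --- final DG ranking
        final = final_dg_ranking(summary)
        emit("fusion", "final_dg_ranking.tsv",
             summary.join(final).sort_values("combined_rank", ascending=False))
        if finish("fusion"):
            return manifest

        current_stage = "biomarkers"
        # --- biomarker scores with permutation FWER
        phi_w = profile_dg.rows["Phi"].reindex(dgs).fillna(0.0)
        rr_w = profile_dg.rows["RR"].reindex(dgs).fillna(0.0)
        dg_only = GeneDiseaseMap(
            associations={(g, d) for g, d in m1_dg.associations if d in set(dgs)},
            level="DG", variant=m1_dg.variant,
        )
        fm_genes = gene_feature_map(dg_only)
        biomarkers = biomarker_table(
            fm_genes, phi_w, rr_w,
            n_perm=cfg.n_perm, seed=cfg.seed, fwer_threshold=cfg.fwer_threshold,
        )
        emit("biomarkers", "biomarkers.tsv", biomarkers)
        fm_sets = fmaps["mapping1"]
        if fm_sets.features:
            sub_idx = [i for i, d in enumerate(fm_sets.diseases) if d in set(dgs)]
            fm_sets_dg = dataclasses.replace(
                fm_sets,
                diseases=[fm_sets.diseases[i] for i in sub_idx],
                M=fm_sets.M[sub_idx],
            )
            pathways = biomarker_table(
                fm_sets_dg, phi_w, rr_w,
                n_perm=cfg.n_perm, seed=cfg.seed + 1, fwer_threshold=cfg.fwer_threshold,
            )
            emit("biomarkers", "pathway_biomarkers.tsv", pathways)
        finish("biomarkers")
        return manifest
    except Exception:
        manifest["failed_stage"] = current_stage
        manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
        raise
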