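"""Synthetic claims populations, gene maps, networks and gene sets.

Every generator plants structure that downstream stages must recover, and
returns that structure as an explicit truth record, so the whole pipeline
is testable without any external data.

The population model: an elderly claims population (ages uniform on
[65, 95], 58.3 % female by default, mirroring the demographic structure of
U.S. Medicare extracts). Each patient carries the index disease with
probability p_c; given index status, the other diseases are conditionally
independent Bernoulli indicators with

    P(d | index)     = r_d * p_d
    P(d | no index)  = p_d * (1 - r_d * p_c) / (1 - p_c)

which fixes the marginal prevalence of d at exactly p_d and the
population-level relative risk between d and the index disease at exactly
r_d. Conditional independence given index status is the minimal model that
pins down every pairwise index-vs-disease relative risk without committing
to disease-disease dependence, which the analysis never uses.

Every simulated patient additionally carries a routine-exam filler code so
the population denominator N is recoverable from the claims table alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data_model import (
    DiagnosisTable,
    GeneDiseaseMap,
    GeneSetCollection,
    InteractionNetwork,
    write_diagnoses,
    write_gmt,
    write_network,
)
from .gene_maps import Crosswalk, write_crosswalk
from .grouping import DiseaseGroupMap, write_group_assignment

#: routine general medical examination; carried by every simulated patient
FILLER_CODE = "V70"


@dataclass
class DiseasePlan:
    """Marginal prevalence and planted relative risk of one disease."""

    prevalence: float
    rr: float = 1.0
    rr_female: float | None = None  # optional sex-specific relative risk
    rr_by_age: dict[tuple[int, int], float] | None = None  # closed age windows


@dataclass
class PopulationSpec:
    n_patients: int
    index_code: str = "496"
    index_prevalence: float = 0.1
    diseases: dict[str, DiseasePlan] = field(default_factory=dict)
    age_min: int = 65
    age_max: int = 95
    sex_female: float = 0.583
    seed: int = 0

    def validate(self) -> None:
        if not 0 < self.index_prevalence < 1:
            raise ValueError("index prevalence must lie in (0, 1)")
        for code, plan in self.diseases.items():
            rs = [plan.rr]
            if plan.rr_female is not None:
                rs.append(plan.rr_female)
            if plan.rr_by_age:
                rs.extend(plan.rr_by_age.values())
            for r in rs:
                if r < 0:
                    raise ValueError(f"{code}: negative relative risk")
                if r * plan.prevalence > 1 or r * self.index_prevalence > 1:
                    raise ValueError(
                        f"{code}: rr={r} with p_d={plan.prevalence}, "
                        f"p_c={self.index_prevalence} violates conditional-"
                        "probability validity (r*p_d <= 1 and r*p_c <= 1)"
                    )


@dataclass
class PlantedTruth:
    """The generator's ground truth, echoed for recovery tests."""

    expected_rr: dict[str, float] = field(default_factory=dict)
    shared_genes: dict[str, int] = field(default_factory=dict)
    private_genes: dict[str, int] = field(default_factory=dict)
    planted_neighbor_links: dict[str, int] = field(default_factory=dict)
    enriched_sets: list[tuple[str, str]] = field(default_factory=list)  # (disease, set)


def generate_population(spec: PopulationSpec) -> tuple[DiagnosisTable, PlantedTruth]:
    """Sample a claims-style diagnosis table with planted relative risks."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_patients
    p_c = spec.index_prevalence

    ages = rng.integers(spec.age_min, spec.age_max + 1, size=n)
    is_female = rng.random(n) < spec.sex_female
    sex = np.where(is_female, "F", "M")
    has_index = rng.random(n) < p_c

    pid = np.array([f"p{i:08d}" for i in range(n)])
    frames = [
        pd.DataFrame({"patient_id": pid, "code": FILLER_CODE, "age": ages, "sex": sex}),
        pd.DataFrame(
            {
                "patient_id": pid[has_index],
                "code": spec.index_code,
                "age": ages[has_index],
                "sex": sex[has_index],
            }
        ),
    ]
    truth = PlantedTruth()
    for code, plan in spec.diseases.items():
        r = np.full(n, plan.rr)
        if plan.rr_female is not None:
            r[is_female] = plan.rr_female
        if plan.rr_by_age:
            for (lo, hi), rv in plan.rr_by_age.items():
                r[(ages >= lo) & (ages <= hi)] = rv
        p = np.where(
            has_index,
            r * plan.prevalence,
            plan.prevalence * (1 - r * p_c) / (1 - p_c),
        )
        has_d = rng.random(n) < p
        frames.append(
            pd.DataFrame(
                {
                    "patient_id": pid[has_d],
                    "code": code,
                    "age": ages[has_d],
                    "sex": sex[has_d],
                }
            )
        )
        truth.expected_rr[code] = plan.rr
    records = pd.concat(frames, ignore_index=True)
    return DiagnosisTable(records), truth


# ---------------------------------------------------------------------------
# Gene maps


def generate_gene_map(
    diseases: Sequence[str],
    index_disease: str,
    n_genes: int,
    shared_counts: Mapping[str, int],
    private_counts: Mapping[str, int],
    seed: int = 0,
    level: str = "DG",
) -> tuple[GeneDiseaseMap, PlantedTruth]:
    """Plant exact shared-gene counts between the index disease and others.

    The index disease receives all shared genes plus its own private genes;
    every other disease receives exactly ``shared_counts[d]`` genes in
    common with the index and ``private_counts[d]`` disjoint private genes,
    so T(index, d) is exactly the planted count. Gene identifiers are drawn
    at random, but the planted T/JC structure is seed-invariant.
    """
    need = sum(shared_counts.get(d, 0) for d in diseases)
    need += sum(private_counts.get(d, 0) for d in diseases)
    need += private_counts.get(index_disease, 0)
    if need > n_genes:
        raise ValueError(f"need {need} genes but n_genes={n_genes}")
    rng = np.random.default_rng(seed)
    pool = [str(g) for g in rng.choice(np.arange(10_000, 1_000_000), n_genes, replace=False)]
    cursor = 0

    def take(k: int) -> list[str]:
        nonlocal cursor
        out = pool[cursor : cursor + k]
        cursor += k
        return out

    associations: set[tuple[str, str]] = set()
    truth = PlantedTruth()
    index_genes = take(private_counts.get(index_disease, 0))
    truth.private_genes[index_disease] = len(index_genes)
    for d in diseases:
        shared = take(shared_counts.get(d, 0))
        private = take(private_counts.get(d, 0))
        truth.shared_genes[d] = len(shared)
        truth.private_genes[d] = len(private)
        for g in shared + private:
            associations.add((g, d))
        index_genes.extend(shared)
    for g in index_genes:
        associations.add((g, index_disease))
    m = GeneDiseaseMap(
        associations=associations,
        provenance={a: {"synthetic"} for a in associations},
        level=level,
        variant="mapping1",
    )
    return m, truth


def generate_network_and_sets(
    disease_genes: Mapping[str, set[str]],
    universe: Sequence[str],
    edge_density: float = 0.0,
    planted_neighbor_links: Mapping[str, int] | None = None,
    set_size_range: tuple[int, int] = (20, 200),
    planted_enriched_pairs: Sequence[tuple[str, str]] = (),
    n_random_sets: int = 8,
    collection_label: str = "SIM",
    seed: int = 0,
) -> tuple[InteractionNetwork, GeneSetCollection, PlantedTruth]:
    """Random interaction network and gene sets with planted structure.

    ``planted_neighbor_links[d]`` genes that are *not* associated with
    disease d are wired to one of d's genes, so the one-hop network
    extension of the gene map grows by at least that many genes per
    disease (exactly, when ``edge_density`` is 0). For every
    (disease, set_name) pair in ``planted_enriched_pairs``, a gene set is
    built with heavy overlap with the disease's genes so it passes
    over-representation at stringent cutoffs; remaining sets are uniform
    draws from the universe.
    """
    if not 0.0 <= edge_density < 1.0:
        raise ValueError("edge_density must lie in [0, 1)")
    lo, hi = set_size_range
    if not 0 < lo < hi:
        raise ValueError("invalid set size range")
    rng = np.random.default_rng(seed)
    universe = list(universe)
    truth = PlantedTruth()

    edges: set[frozenset[str]] = set()
    # planted neighbors are drawn outside EVERY disease's gene set so the
    # one-hop growth of each disease is exactly its planted count
    all_disease_genes = set().union(*disease_genes.values()) if disease_genes else set()
    used: set[str] = set()
    for d, k in (planted_neighbor_links or {}).items():
        dg = sorted(disease_genes[d])
        outside = sorted(set(universe) - all_disease_genes - used)
        if k > len(outside):
            raise ValueError(f"cannot plant {k} neighbor links for {d}")
        new = rng.choice(outside, size=k, replace=False)
        for g in new:
            edges.add(frozenset((g, dg[int(rng.integers(len(dg)))])))
        used.update(new)
        truth.planted_neighbor_links[d] = k
    n = len(universe)
    n_bg = int(round(edge_density * n * (n - 1) / 2))
    while n_bg > 0:
        a, b = rng.choice(n, size=2, replace=False)
        e = frozenset((universe[a], universe[b]))
        if e not in edges:
            edges.add(e)
            n_bg -= 1

    sets: dict[str, set[str]] = {}
    for disease, set_name in planted_enriched_pairs:
        dg = sorted(disease_genes[disease])
        size = max(lo, min(hi - 1, len(dg) + 5))
        k_overlap = min(len(dg), size - 5)
        members = set(rng.choice(dg, size=k_overlap, replace=False))
        outside = sorted(set(universe) - set(dg))
        members |= set(rng.choice(outside, size=size - len(members), replace=False))
        sets[set_name] = members
        truth.enriched_sets.append((disease, set_name))
    for i in range(n_random_sets):
        size = int(rng.integers(lo, hi))
        size = min(size, n)
        sets[f"RAND_SET_{i}"] = set(rng.choice(universe, size=size, replace=False))

    net = InteractionNetwork(edges=edges)
    coll = GeneSetCollection(sets=sets, source_label=collection_label)
    return net, coll, truth


# ---------------------------------------------------------------------------
# A coherent end-to-end study scenario


@dataclass
class SimulatedStudy:
    """All inputs of one synthetic study, plus the planted ground truth."""

    spec: PopulationSpec
    diagnoses: DiagnosisTable
    dg_map: DiseaseGroupMap
    gene_map: GeneDiseaseMap  # ICD9 level, mapping1
    network: InteractionNetwork
    collections: list[GeneSetCollection]
    truth: PlantedTruth


# planted study conditions: three disease groups ordered in both
# co-occurrence strength (rr 3.0 > 2.0 > 1.2) and mechanistic overlap
# (20 > 10 > 2 genes shared with the index disease)
DEFAULT_DGS: dict[str, tuple[str, tuple[str, ...]]] = {
    "DG1": ("respiratory", ("491", "492")),
    "DG2": ("cardiac", ("410", "428")),
    "DG3": ("metabolic", ("250", "272")),
}
DEFAULT_RR = {"DG1": 3.0, "DG2": 2.0, "DG3": 1.2}
DEFAULT_SHARED_GENES = {"DG1": 20, "DG2": 10, "DG3": 2}


def default_scenario(seed: int = 0, n_patients: int = 20_000) -> SimulatedStudy:
    """Standard synthetic study used for end-to-end recovery checks."""
    diseases = {}
    for dg, (_, codes) in DEFAULT_DGS.items():
        for code in codes:
            diseases[code] = DiseasePlan(prevalence=0.05, rr=DEFAULT_RR[dg])
    spec = PopulationSpec(
        n_patients=n_patients, index_code="496", index_prevalence=0.1,
        diseases=diseases, seed=seed,
    )
    diag, truth = generate_population(spec)
    dgm = DiseaseGroupMap(
        groups={dg: (name, set(codes)) for dg, (name, codes) in DEFAULT_DGS.items()}
    )

    # plant each DG's genes on its first member code so the DG-level
    # aggregation reproduces the exact shared counts
    anchor = {dg: sorted(codes)[0] for dg, (_, codes) in DEFAULT_DGS.items()}
    shared = {anchor[dg]: k for dg, k in DEFAULT_SHARED_GENES.items()}
    private = {anchor[dg]: 10 for dg in DEFAULT_DGS}
    private["496"] = 15
    gmap, gtruth = generate_gene_map(
        diseases=sorted(anchor.values()), index_disease="496", n_genes=300,
        shared_counts=shared, private_counts=private, seed=seed + 1, level="ICD9",
    )
    truth.shared_genes = {dg: DEFAULT_SHARED_GENES[dg] for dg in DEFAULT_DGS}
    truth.private_genes = gtruth.private_genes

    rng = np.random.default_rng(seed + 2)
    extra = [str(g) for g in rng.choice(np.arange(1_000_000, 2_000_000), 150, replace=False)]
    universe = sorted(gmap.genes()) + extra
    net, coll, ntruth = generate_network_and_sets(
        disease_genes={d: gmap.genes_for(d) for d in gmap.diseases()},
        universe=universe,
        edge_density=0.0,
        planted_neighbor_links={anchor["DG1"]: 3, anchor["DG2"]: 2},
        planted_enriched_pairs=[(anchor["DG1"], "PLANTED_PATHWAY")],
        n_random_sets=8,
        collection_label="KEGGSIM",
        seed=seed + 3,
    )
    truth.planted_neighbor_links = ntruth.planted_neighbor_links
    truth.enriched_sets = ntruth.enriched_sets
    return SimulatedStudy(
        spec=spec, diagnoses=diag, dg_map=dgm, gene_map=gmap,
        network=net, collections=[coll], truth=truth,
    )


def write_input_bundle(study: SimulatedStudy, outdir: str | Path) -> dict[str, Path]:
    """Write every pipeline input file for a simulated study.

    The ICD9-level gene map is emitted as two overlapping source tables in a
    MESH-style vocabulary plus the crosswalk translating the terms back to
    ICD9 codes, so the integration path is exercised end to end.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["diagnoses"] = outdir / "diagnoses.tsv"
    write_diagnoses(study.diagnoses, paths["diagnoses"])

    assocs = sorted(study.gene_map.associations)
    half = len(assocs) // 2
    xw_entries = set()
    for i, name in enumerate(("sourceA", "sourceB")):
        # the two sources overlap so the non-redundant union is exercised
        chunk = assocs[: half + 5] if i == 0 else assocs[half - 5 :]
        rows = []
        for gene, code in chunk:
            term = f"term_{code}"
            xw_entries.add((term, "MESH", code))
            rows.append((gene, term, "MESH", name))
        p = outdir / f"gene_disease_{name}.tsv"
        pd.DataFrame(rows, columns=["gene", "term", "vocabulary", "source"]).to_csv(
            p, sep="\t", index=False
        )
        paths[name] = p

    paths["crosswalk"] = outdir / "crosswalk.tsv"
    write_crosswalk(Crosswalk(entries=xw_entries), paths["crosswalk"])

    paths["network"] = outdir / "network.tsv"
    write_network(study.network, paths["network"])

    for coll in study.collections:
        p = outdir / f"genesets_{coll.source_label}.gmt"
        write_gmt(coll, p)
        paths[f"genesets_{coll.source_label}"] = p

    paths["dg_map"] = outdir / "dg_map.tsv"
    write_group_assignment(study.dg_map, paths["dg_map"])
    return paths
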