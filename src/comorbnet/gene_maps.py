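"""Disease-gene map integration, PPI extension, and gene-set feature maps.

mapping1 is the non-redundant union of heterogeneous gene-disease sources
translated to 3-digit ICD9 codes through vocabulary crosswalks; mapping1_DG
aggregates it to disease groups (a gene is associated with a DG if it is
associated with any member code). mapping2 / mapping2_DG extend the map
over a protein-interaction network: each disease additionally receives the
first neighbors of its associated genes. Disease x gene-set feature maps
come from one-sided Fisher over-representation tests with Benjamini-
Hochberg adjustment within one (disease, collection) family.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .data_model import (
    GeneDiseaseMap,
    GeneSetCollection,
    InteractionNetwork,
    normalize_code,
)
from .grouping import DiseaseGroupMap

logger = logging.getLogger(__name__)

#: gene-set size filter: retain sets with MIN_SET_SIZE <= size < MAX_SET_SIZE
MIN_SET_SIZE = 20
MAX_SET_SIZE = 200

#: adjusted-p cutoff used when building binary feature maps
ALPHA_MAP = 0.01
#: adjusted-p cutoff used for standalone over-representation reporting
ALPHA_REPORT = 0.1


@dataclass
class Crosswalk:
    """Flat (term, vocabulary) -> ICD9 translation table; fan-out allowed."""

    entries: set[tuple[str, str, str]]  # (term, vocabulary, icd9)

    def lookup(self, term: str, vocabulary: str) -> set[str]:
        return {c for t, v, c in self.entries if t == term and v == vocabulary}


def read_crosswalk(path: str | Path, sep: str = "\t") -> Crosswalk:
    df = pd.read_csv(path, sep=sep, dtype=str)
    required = {"term", "vocabulary", "icd9"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(required)}")
    entries = {
        (r.term, r.vocabulary, normalize_code(r.icd9)) for r in df.itertuples()
    }
    return Crosswalk(entries=entries)


def write_crosswalk(xw: Crosswalk, path: str | Path, sep: str = "\t") -> None:
    pd.DataFrame(sorted(xw.entries), columns=["term", "vocabulary", "icd9"]).to_csv(
        path, sep=sep, index=False
    )


def integrate_sources(raw_tables: Iterable[pd.DataFrame], xw: Crosswalk) -> GeneDiseaseMap:
    """Union heterogeneous sources into mapping1 (gene <-> ICD9).

    Terms natively in the ICD9 vocabulary are zero-padded directly; other
    terms are expanded through the crosswalk (possibly to several codes).
    Unmapped terms are skipped with a logged count. Provenance labels from
    all sources contributing an association are merged.
    """
    associations: set[tuple[str, str]] = set()
    provenance: dict[tuple[str, str], set[str]] = {}
    n_unmapped = 0
    for table in raw_tables:
        for row in table.itertuples():
            if row.vocabulary == "ICD9":
                codes = {normalize_code(row.term)}
            else:
                codes = xw.lookup(row.term, row.vocabulary)
                if not codes:
                    n_unmapped += 1
                    continue
            for code in codes:
                assoc = (str(row.gene), code)
                associations.add(assoc)
                provenance.setdefault(assoc, set()).add(row.source)
    if n_unmapped:
        logger.warning("skipped %d rows with terms absent from the crosswalk", n_unmapped)
    return GeneDiseaseMap(
        associations=associations, provenance=provenance, level="ICD9", variant="mapping1"
    )


def aggregate_genes_to_dg(
    m1: GeneDiseaseMap, dgm: DiseaseGroupMap, passthrough: Sequence[str] = ()
) -> GeneDiseaseMap:
    """mapping1_DG: gene <-> DG iff the gene maps to any member ICD9 code."""
    if m1.level != "ICD9":
        raise ValueError("expected an ICD9-level map")
    keep = set(passthrough)
    associations: set[tuple[str, str]] = set()
    provenance: dict[tuple[str, str], set[str]] = {}
    for (gene, code), sources in m1.provenance.items():
        target = code if code in keep else dgm.dg_of(code)
        if target is None:
            continue
        assoc = (gene, target)
        associations.add(assoc)
        provenance.setdefault(assoc, set()).update(sources)
    return GeneDiseaseMap(
        associations=associations, provenance=provenance, level="DG", variant=m1.variant
    )


def ppi_extend(m: GeneDiseaseMap, net: InteractionNetwork) -> GeneDiseaseMap:
    """mapping2: add first network neighbors of each disease's genes.

    The result always contains the input map; added associations carry the
    provenance label "ppi-extension". Only one hop is taken: a neighbor of a
    neighbor is not added.
    """
    graph = net.graph()
    associations = set(m.associations)
    provenance = {a: set(s) for a, s in m.provenance.items()}
    for gene, disease in m.associations:
        if gene not in graph:
            continue
        for neighbor in graph.neighbors(gene):
            assoc = (neighbor, disease)
            if assoc not in associations:
                associations.add(assoc)
                provenance.setdefault(assoc, set()).add("ppi-extension")
    return GeneDiseaseMap(
        associations=associations, provenance=provenance, level=m.level, variant="mapping2"
    )


# ---------------------------------------------------------------------------
# Over-representation analysis


def fisher_enrichment(
    disease_genes: set[str], gene_set: set[str], universe: set[str]
) -> float:
    """One-sided over-representation p-value P(X >= observed overlap).

    X follows a hypergeometric distribution: |universe| balls, |gene_set|
    of them marked, |disease_genes| drawn.
    """
    if not universe:
        raise ValueError("empty gene universe")
    gs = gene_set & universe
    dg = disease_genes & universe
    k = len(gs & dg)
    return float(hypergeom.sf(k - 1, len(universe), len(gs), len(dg)))


def bh_adjust(ps: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    arr = np.asarray(ps, dtype=float)
    if arr.size == 0:
        return arr
    if np.any((arr < 0) | (arr > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(arr, method="fdr_bh")[1]


def filter_sets(collection: GeneSetCollection,
                min_size: int = MIN_SET_SIZE,
                max_size: int = MAX_SET_SIZE) -> dict[str, set[str]]:
    """Retain sets with min_size <= |set| < max_size (raw size, before any
    universe intersection); excludes too-specific and too-generic terms."""
    if min_size >= max_size:
        raise ValueError("min_size must be < max_size")
    return {
        name: genes
        for name, genes in collection.sets.items()
        if min_size <= len(genes) < max_size
    }


@dataclass
class DiseaseFeatureMap:
    """Binary disease x feature matrix (features: genes or gene sets)."""

    diseases: list[str]
    features: list[str]
    M: np.ndarray
    feature_kind: str  # "gene" | "geneset"
    mapping_variant: str = "mapping1"

    def __post_init__(self) -> None:
        self.M = np.asarray(self.M, dtype=np.int8)
        if self.M.shape != (len(self.diseases), len(self.features)):
            raise ValueError("matrix shape does not match labels")
        if not np.isin(self.M, (0, 1)).all():
            raise ValueError("feature map entries must be 0/1")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.M, index=self.diseases, columns=self.features)

    def features_of(self, disease: str) -> set[str]:
        row = self.M[self.diseases.index(disease)]
        return {f for f, v in zip(self.features, row) if v}


def gene_feature_map(m: GeneDiseaseMap) -> DiseaseFeatureMap:
    """Represent a gene-disease map as a binary disease x gene matrix."""
    diseases = sorted(m.diseases())
    features = sorted(m.genes())
    gi = {g: k for k, g in enumerate(features)}
    di = {d: k for k, d in enumerate(diseases)}
    mat = np.zeros((len(diseases), len(features)), dtype=np.int8)
    for gene, disease in m.associations:
        mat[di[disease], gi[gene]] = 1
    return DiseaseFeatureMap(
        diseases=diseases, features=features, M=mat,
        feature_kind="gene", mapping_variant=m.variant,
    )


@dataclass
class EnrichmentResult:
    """Per (disease, gene set) over-representation test results."""

    rows: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["disease", "collection", "set_name", "overlap", "p", "p_adj"]
        )
    )


def build_geneset_feature_map(
    m: GeneDiseaseMap,
    collections: Sequence[GeneSetCollection],
    min_size: int = MIN_SET_SIZE,
    max_size: int = MAX_SET_SIZE,
    alpha: float = ALPHA_MAP,
    universe: set[str] | None = None,
) -> tuple[DiseaseFeatureMap, EnrichmentResult]:
    """Disease x gene-set binary map via Fisher/BH over-representation.

    Per disease and collection, a Fisher test is run against every retained
    set (size filter applied to raw set sizes) and BH-adjusted within that
    (disease, collection) family; the map entry is 1 iff p_adj < alpha.
    Unless overridden, the universe is all genes in the disease map plus the
    collection under test. Diseases with no mapped genes get all-zero rows.
    Feature names are qualified as "<collection label>:<set name>".
    """
    diseases = sorted(m.diseases())
    records = []
    feature_names: list[str] = []
    columns: dict[str, np.ndarray] = {}
    for coll in collections:
        retained = filter_sets(coll, min_size, max_size)
        names = sorted(retained)
        univ = universe if universe is not None else (
            m.genes() | set().union(*retained.values()) if retained else m.genes()
        )
        hits = np.zeros((len(diseases), len(names)), dtype=np.int8)
        for di, disease in enumerate(diseases):
            dgenes = m.genes_for(disease)
            if not dgenes:
                logger.warning("disease %s has no mapped genes; all-zero row", disease)
            if not names:
                continue
            ps = [fisher_enrichment(dgenes, retained[n], univ) for n in names]
            padj = bh_adjust(ps)
            for si, name in enumerate(names):
                overlap = len((retained[name] & univ) & (dgenes & univ))
                records.append(
                    (disease, coll.source_label, name, overlap, ps[si], padj[si])
                )
                if padj[si] < alpha:
                    hits[di, si] = 1
        for si, name in enumerate(names):
            qualified = f"{coll.source_label}:{name}"
            feature_names.append(qualified)
            columns[qualified] = hits[:, si]
    mat = (
        np.column_stack([columns[f] for f in feature_names])
        if feature_names
        else np.zeros((len(diseases), 0), dtype=np.int8)
    )
    fm = DiseaseFeatureMap(
        diseases=diseases, features=feature_names, M=mat,
        feature_kind="geneset", mapping_variant=m.variant,
    )
    res = EnrichmentResult(
        rows=pd.DataFrame(
            records, columns=["disease", "collection", "set_name", "overlap", "p", "p_adj"]
        )
    )
    return fm, res
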