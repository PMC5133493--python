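"""Domain types and readers/writers for the pipeline's external formats.

All tabular inputs are delimited text (tab-separated by default, with a
header row). Diagnosis codes are 3-digit ICD9-CM categories stored as
zero-padded 3-character strings ("8" -> "008") so leading zeros survive
round trips through text files.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd
import scipy.sparse as sp

logger = logging.getLogger(__name__)

#: a run fails when more than this fraction of rows is malformed
MALFORMED_ROW_THRESHOLD = 0.10

DIAGNOSIS_COLUMNS = ("patient_id", "icd9", "age", "sex")


class ConfigurationError(ValueError):
    """Missing column, unknown layout, or invalid reader configuration."""


class FormatError(ValueError):
    """Malformed content in an input file."""


def normalize_code(code: object) -> str:
    """Zero-pad a 3-digit ICD9 category ("8" -> "008", 42 -> "042")."""
    s = str(code).strip()
    if not s:
        raise FormatError("empty diagnosis code")
    return s.zfill(3)


# ---------------------------------------------------------------------------
# Diagnosis records


@dataclass
class DiagnosisTable:
    """Deduplicated patient-level diagnosis records.

    ``records`` has columns ``patient_id`` (str), ``code`` (ICD9-3 str or
    disease-group id), ``age`` (int years) and ``sex`` ("M"/"F"). Each
    (patient, code) pair appears once.
    """

    records: pd.DataFrame

    def __post_init__(self) -> None:
        missing = {"patient_id", "code", "age", "sex"} - set(self.records.columns)
        if missing:
            raise ConfigurationError(f"DiagnosisTable missing columns: {sorted(missing)}")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def n_patients(self) -> int:
        return self.records["patient_id"].nunique()

    def codes(self) -> list[str]:
        return sorted(self.records["code"].unique())

    def patients(self) -> pd.DataFrame:
        """One row per patient with age and sex (age = max across records)."""
        return (
            self.records.groupby("patient_id", sort=False)
            .agg(age=("age", "max"), sex=("sex", "first"))
            .reset_index()
        )


def read_diagnoses(
    path: str | Path,
    dialect: Mapping[str, str] | None = None,
    sep: str = "\t",
) -> DiagnosisTable:
    """Read a claims-style diagnosis table.

    ``dialect`` maps the canonical column names (patient_id, icd9, age, sex)
    to the names used in the file. Duplicate (patient, code) pairs are
    collapsed; rows with unparseable ages are dropped, and the run fails if
    more than :data:`MALFORMED_ROW_THRESHOLD` of rows are malformed.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    colmap = {c: c for c in DIAGNOSIS_COLUMNS}
    if dialect:
        colmap.update(dialect)
    raw = pd.read_csv(path, sep=sep, dtype=str)
    missing = [v for v in colmap.values() if v not in raw.columns]
    if missing:
        raise ConfigurationError(f"diagnosis file {path} missing columns: {missing}")
    df = raw.rename(columns={v: k for k, v in colmap.items()})[
        ["patient_id", "icd9", "age", "sex"]
    ].rename(columns={"icd9": "code"})
    if df.empty:
        logger.warning("diagnosis file %s is empty", path)
        return DiagnosisTable(
            pd.DataFrame(columns=["patient_id", "code", "age", "sex"]).astype(
                {"age": int}
            )
        )

    n_raw = len(df)
    age = pd.to_numeric(df["age"], errors="coerce")
    bad = age.isna() | (age < 0) | df["code"].isna() | df["patient_id"].isna()
    n_bad = int(bad.sum())
    if n_bad:
        logger.warning("%s: dropped %d malformed rows", path, n_bad)
        if n_bad / n_raw > MALFORMED_ROW_THRESHOLD:
            raise FormatError(
                f"{path}: {n_bad}/{n_raw} malformed rows exceeds the "
                f"{MALFORMED_ROW_THRESHOLD:.0%} guardrail"
            )
    df = df.loc[~bad].copy()
    df["age"] = age.loc[~bad].astype(int)
    df["code"] = df["code"].map(normalize_code)

    n_before = len(df)
    df = df.drop_duplicates(subset=["patient_id", "code"], keep="first")
    n_dup = n_before - len(df)
    if n_dup:
        logger.info("%s: collapsed %d duplicate (patient, code) pairs", path, n_dup)
    return DiagnosisTable(df.reset_index(drop=True))


def write_diagnoses(diag: DiagnosisTable, path: str | Path, sep: str = "\t") -> None:
    out = diag.records.rename(columns={"code": "icd9"})
    out.to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# Co-occurrence summary


@dataclass
class CooccurrenceTable:
    """Population co-diagnosis summary.

    ``N`` is the number of distinct patients, ``I[i]`` the incidence of code
    ``i`` (distinct patients carrying it) and ``C[(i, j)]`` the number of
    distinct patients diagnosed with both ``i`` and ``j`` (keys are sorted
    pairs; absent pairs mean zero co-diagnoses).
    """

    N: int
    I: dict[str, int]
    C: dict[tuple[str, str], int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for code, inc in self.I.items():
            if not 0 <= inc <= self.N:
                raise ValueError(f"incidence of {code} outside [0, N]")
        for (i, j), c in self.C.items():
            if (i, j) != tuple(sorted((i, j))):
                raise ValueError(f"co-diagnosis key {(i, j)} not sorted")
            if c > min(self.I[i], self.I[j]):
                raise ValueError(f"C[{i},{j}]={c} exceeds min incidence")

    def codes(self) -> list[str]:
        return sorted(self.I)

    def get_C(self, i: str, j: str) -> int:
        return self.C.get(tuple(sorted((i, j))), 0)


def build_cooccurrence(
    diag: DiagnosisTable, codes: Iterable[str] | None = None
) -> CooccurrenceTable:
    """Count distinct-patient incidences and pairwise co-diagnoses.

    ``N`` counts every distinct patient in the table (also those with no
    code in ``codes``). Counting is sparse-matrix based, so populations of a
    few hundred thousand patients are handled in seconds.
    """
    if len(diag) == 0:
        raise ValueError("diagnosis table is empty")
    df = diag.records
    n_patients = df["patient_id"].nunique()
    if codes is not None:
        keep = set(codes)
        df = df[df["code"].isin(keep)]
        code_list = sorted(keep & set(df["code"].unique()))
    else:
        code_list = sorted(df["code"].unique())
    if not code_list:
        return CooccurrenceTable(N=n_patients, I={}, C={})

    pid_idx, _ = pd.factorize(df["patient_id"])
    code_cat = pd.Categorical(df["code"], categories=code_list)
    m = sp.coo_matrix(
        (np.ones(len(df), dtype=np.int64), (pid_idx, code_cat.codes)),
        shape=(pid_idx.max() + 1, len(code_list)),
    ).tocsr()
    m.data[:] = 1  # distinct-patient counting
    co = (m.T @ m).toarray()
    incidences = {c: int(co[k, k]) for k, c in enumerate(code_list)}
    pairs: dict[tuple[str, str], int] = {}
    for a in range(len(code_list)):
        for b in range(a + 1, len(code_list)):
            if co[a, b]:
                pairs[(code_list[a], code_list[b])] = int(co[a, b])
    return CooccurrenceTable(N=n_patients, I=incidences, C=pairs)


# ---------------------------------------------------------------------------
# Gene-disease associations


@dataclass
class GeneDiseaseMap:
    """Non-redundant gene <-> disease associations with provenance.

    ``level`` says whether the disease key is a 3-digit ICD9 code or a
    disease-group (DG) id; ``variant`` distinguishes the directly integrated
    map (mapping1) from its one-hop protein-interaction extension (mapping2).
    """

    associations: set[tuple[str, str]]  # (gene, disease)
    provenance: dict[tuple[str, str], set[str]] = field(default_factory=dict)
    level: str = "ICD9"  # "ICD9" | "DG"
    variant: str = "mapping1"  # "mapping1" | "mapping2"

    def __post_init__(self) -> None:
        for assoc in self.associations:
            self.provenance.setdefault(assoc, set())

    def genes(self) -> set[str]:
        return {g for g, _ in self.associations}

    def diseases(self) -> set[str]:
        return {d for _, d in self.associations}

    def genes_for(self, disease: str) -> set[str]:
        return {g for g, d in self.associations if d == disease}

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (g, d, ";".join(sorted(self.provenance.get((g, d), set()))))
            for g, d in sorted(self.associations)
        ]
        return pd.DataFrame(rows, columns=["gene", "disease", "sources"])


def read_gene_disease_sources(
    paths: Iterable[str | Path], sep: str = "\t"
) -> list[pd.DataFrame]:
    """Read raw gene-disease association tables, one per source.

    Each file must carry columns gene, term, vocabulary, source. Terms stay
    in their native vocabulary; blank gene ids are dropped (counts logged)
    and duplicate (gene, term) pairs within one file are kept once.
    """
    tables = []
    for path in paths:
        df = pd.read_csv(path, sep=sep, dtype=str)
        required = {"gene", "term", "vocabulary", "source"}
        if not required <= set(df.columns):
            raise ConfigurationError(
                f"{path}: expected columns {sorted(required)}, got {list(df.columns)}"
            )
        blank = df["gene"].isna() | (df["gene"].str.strip() == "")
        if blank.any():
            logger.warning("%s: dropped %d rows with blank gene id", path, int(blank.sum()))
        df = df.loc[~blank].drop_duplicates(subset=["gene", "term", "vocabulary"])
        tables.append(df.reset_index(drop=True))
    return tables


def write_gene_disease_map(m: GeneDiseaseMap, path: str | Path, sep: str = "\t") -> None:
    m.to_frame().to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# Gene sets (GMT) and interaction network


@dataclass
class GeneSetCollection:
    """Named gene sets from one source (GO-BP, KEGG, Reactome, Biocarta...)."""

    sets: dict[str, set[str]]
    source_label: str = ""

    def __len__(self) -> int:
        return len(self.sets)


def read_gmt(path: str | Path, source_label: str | None = None) -> GeneSetCollection:
    """Read a GMT file: name<TAB>description<TAB>gene1<TAB>gene2...

    The description column is discarded and duplicate genes within a line
    are collapsed. Duplicate set names are an error.
    """
    path = Path(path)
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line has fewer than 3 fields")
            name = fields[0]
            if name in sets:
                raise FormatError(f"{path}:{lineno}: duplicate gene-set name {name!r}")
            sets[name] = {g for g in fields[2:] if g}
    return GeneSetCollection(sets=sets, source_label=source_label or path.stem)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name in sorted(collection.sets):
            genes = sorted(collection.sets[name])
            fh.write("\t".join([name, collection.source_label, *genes]) + "\n")


@dataclass
class InteractionNetwork:
    """Undirected protein-interaction network without self-loops."""

    edges: set[frozenset[str]]

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_edges_from(tuple(sorted(e)) for e in self.edges)
        return g

    def __len__(self) -> int:
        return len(self.edges)


def read_network(path: str | Path, sep: str = "\t") -> InteractionNetwork:
    """Read a 2-column edge list; self-loops dropped, reciprocals collapsed."""
    path = Path(path)
    edges: set[frozenset[str]] = set()
    n_loops = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split(sep) if sep in line else line.split()
            if len(parts) < 2 or not parts[0] or not parts[1]:
                raise FormatError(f"{path}:{lineno}: malformed edge line")
            a, b = parts[0], parts[1]
            if a == b:
                n_loops += 1
                continue
            edges.add(frozenset((a, b)))
    if n_loops:
        logger.warning("%s: dropped %d self-loops", path, n_loops)
    return InteractionNetwork(edges=edges)


def write_network(net: InteractionNetwork, path: str | Path, sep: str = "\t") -> None:
    with open(path, "w") as fh:
        for a, b in sorted(tuple(sorted(e)) for e in net.edges):
            fh.write(f"{a}{sep}{b}\n")
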