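"""Inverse-RR distances, clustering leaf order, and disease-group aggregation.

Closely defined ICD9 categories co-occur strongly with each other, so codes
are aggregated into clinically curated disease groups (DGs). The pipeline
supports the curation by ordering the codes along a dendrogram built from
the inverse relative risk (strongly comorbid codes end up adjacent); the
grouping itself is an expert-provided input file, never an automatic cut.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import squareform

from .comorbidity import DegenerateMarginError, pair_statistics
from .data_model import CooccurrenceTable, DiagnosisTable, normalize_code

logger = logging.getLogger(__name__)

#: multiplier applied to the largest finite distance to stand in for 1/RR
#: when RR = 0 (never co-diagnosed); keeps the matrix clusterable
RR_ZERO_CAP_FACTOR = 10.0

LINKAGE_METHODS = ("complete", "average", "single")


@dataclass
class CodeDistanceMatrix:
    """Symmetric inverse-RR distances over an ordered code list."""

    codes: list[str]
    d: np.ndarray
    capped: np.ndarray  # bool mask of pairs where the RR=0 cap was applied

    def __post_init__(self) -> None:
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(self.d) != 0):
            raise ValueError("distance matrix must have a zero diagonal")


@dataclass
class DiseaseGroupMap:
    """Expert assignment of ICD9 codes to disease groups."""

    groups: dict[str, tuple[str, set[str]]]  # dg_id -> (name, codes)

    def __post_init__(self) -> None:
        seen: dict[str, str] = {}
        for dg, (_, codes) in self.groups.items():
            if not codes:
                raise ValueError(f"disease group {dg} is empty")
            for code in codes:
                if code in seen:
                    raise ValueError(
                        f"code {code} assigned to both {seen[code]} and {dg}"
                    )
                seen[code] = dg
        self._code_to_dg = seen

    def dg_of(self, code: str) -> str | None:
        return self._code_to_dg.get(code)

    def codes(self) -> set[str]:
        return set(self._code_to_dg)

    def dg_ids(self) -> list[str]:
        return sorted(self.groups)


def rr_distance_matrix(
    cooc: CooccurrenceTable, codes: Iterable[str]
) -> CodeDistanceMatrix:
    """Distance d_ij = 1 / RR_ij between all pairs of the given codes.

    Pairs never co-diagnosed (RR = 0) get a capped distance of
    ``RR_ZERO_CAP_FACTOR`` times the largest finite distance and are flagged
    in ``capped``. Degenerate margins (incidence 0 or N) are an error.
    """
    code_list = sorted(set(codes))
    missing = [c for c in code_list if c not in cooc.I]
    if missing:
        raise KeyError(f"codes absent from co-occurrence table: {missing}")
    degenerate = [c for c in code_list if cooc.I[c] in (0, cooc.N)]
    if degenerate:
        raise DegenerateMarginError(
            f"codes with degenerate margins (incidence 0 or N): {degenerate}"
        )
    n = len(code_list)
    d = np.zeros((n, n))
    capped = np.zeros((n, n), dtype=bool)
    for a in range(n):
        for b in range(a + 1, n):
            C = cooc.get_C(code_list[a], code_list[b])
            rr, _ = pair_statistics(C, cooc.I[code_list[a]], cooc.I[code_list[b]], cooc.N)
            if rr > 0:
                d[a, b] = d[b, a] = 1.0 / rr
            else:
                d[a, b] = d[b, a] = np.inf
                capped[a, b] = capped[b, a] = True
    finite = d[np.isfinite(d) & (d > 0)]
    cap = RR_ZERO_CAP_FACTOR * finite.max() if finite.size else 1.0
    d[np.isinf(d)] = cap
    return CodeDistanceMatrix(codes=code_list, d=d, capped=capped)


def cluster_leaf_order(dm: CodeDistanceMatrix, method: str = "complete") -> list[str]:
    """Dendrogram leaf order from agglomerative clustering of the distances.

    Codes are processed in lexicographic order so that tied merges resolve
    deterministically toward the lexicographically earlier codes.
    """
    if method not in LINKAGE_METHODS:
        raise ValueError(f"linkage must be one of {LINKAGE_METHODS}")
    if len(dm.codes) < 2:
        raise ValueError("need at least 2 codes to cluster")
    if not np.all(np.isfinite(dm.d)):
        raise ValueError("distance matrix contains non-finite entries")
    order = np.argsort(dm.codes)
    codes_sorted = [dm.codes[i] for i in order]
    d = dm.d[np.ix_(order, order)]
    z = linkage(squareform(d, checks=False), method=method)
    # canonical leaf order: at every merge the subtree holding the smallest
    # code label goes left, so tied merges resolve lexicographically
    n = len(codes_sorted)
    leaves: dict[int, tuple[list[int], int]] = {i: ([i], i) for i in range(n)}
    for k, (a, b) in enumerate(z[:, :2].astype(int)):
        (la, ma), (lb, mb) = leaves.pop(a), leaves.pop(b)
        if mb < ma:
            la, lb, ma = lb, la, mb
        leaves[n + k] = (la + lb, ma)
    (final_order, _), = leaves.values()
    return [codes_sorted[i] for i in final_order]


def load_group_assignment(
    path: str | Path, universe: Iterable[str] | None = None, sep: str = "\t"
) -> DiseaseGroupMap:
    """Read a TSV (icd9, dg_id, dg_name) into a validated group map.

    A code appearing in two DGs is an error; codes outside the universe are
    retained with a warning; universe codes missing from the file are
    reported as unassigned.
    """
    df = pd.read_csv(path, sep=sep, dtype=str)
    required = {"icd9", "dg_id", "dg_name"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(required)}")
    df["icd9"] = df["icd9"].map(normalize_code)
    groups: dict[str, tuple[str, set[str]]] = {}
    for dg_id, sub in df.groupby("dg_id"):
        name = sub["dg_name"].iloc[0]
        groups[str(dg_id)] = (name, set(sub["icd9"]))
    dgm = DiseaseGroupMap(groups=groups)  # validates single membership
    if universe is not None:
        universe = set(universe)
        outside = dgm.codes() - universe
        if outside:
            logger.warning("%d assigned codes outside the universe: %s",
                           len(outside), sorted(outside)[:10])
        unassigned = universe - dgm.codes()
        if unassigned:
            logger.warning("%d universe codes unassigned to any DG", len(unassigned))
    return dgm


def write_group_assignment(dgm: DiseaseGroupMap, path: str | Path, sep: str = "\t") -> None:
    rows = [
        (code, dg, name)
        for dg, (name, codes) in sorted(dgm.groups.items())
        for code in sorted(codes)
    ]
    pd.DataFrame(rows, columns=["icd9", "dg_id", "dg_name"]).to_csv(
        path, sep=sep, index=False
    )


def aggregate_patients_to_dg(
    diag: DiagnosisTable,
    dgm: DiseaseGroupMap,
    passthrough: Sequence[str] = (),
    drop_unassigned: bool = False,
) -> DiagnosisTable:
    """Re-code diagnoses at the disease-group level.

    A patient is "diagnosed" with a DG iff they carry at least one member
    code. Codes outside every DG (the index disease and any code listed in
    ``passthrough`` in particular) are kept under their own code by default
    so the population denominator stays intact; with ``drop_unassigned``
    only DG and passthrough codes survive.
    """
    df = diag.records.copy()
    keep = set(passthrough)

    def recode(c: str) -> str | None:
        if c in keep:
            return c
        dg = dgm.dg_of(c)
        if dg is not None:
            return dg
        return None if drop_unassigned else c

    df["code"] = df["code"].map(recode)
    df = df.dropna(subset=["code"])
    df = df.drop_duplicates(subset=["patient_id", "code"])
    return DiagnosisTable(df.reset_index(drop=True))
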