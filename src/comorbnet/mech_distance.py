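"""Mechanistic similarity between the index disease and disease groups.

Given the feature sets (associated genes, or enriched gene sets) of the
index disease and of each disease group, three similarity measures are
computed over a shared feature universe:

* T    — number of common features, |A ∩ B|
* JC   — Jaccard ratio, |A ∩ B| / |A ∪ B|
* phi  — Pearson correlation of the binary membership indicators
         (the same formula as the patient-level Phi, applied to features)

Each measure column is turned into ranks with the convention "larger rank =
closer to the index disease"; ties share the average rank. Summarized
gene-based and pathway-based distances are rank combinations over selected
columns, and a Spearman/PCA diagnostic flags redundant or outlying measures.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .comorbidity import DegenerateMarginError, pair_statistics
from .rank_fusion import combine_ranks

MEASURES = ("T", "JC", "phi")


class FeatureSimilarity(NamedTuple):
    T: int
    JC: float
    phi: float  # NaN when a margin is degenerate (empty or full set)


def feature_similarity(
    A: set[str], B: set[str], universe: set[str]
) -> FeatureSimilarity:
    """T, JC and phi between two feature sets over a universe.

    T and JC depend only on A and B; phi additionally depends on the
    universe size (it is the binary correlation of membership indicators
    across all universe features) and is undefined (NaN) when either set is
    empty or covers the whole universe.
    """
    if not universe:
        raise ValueError("universe must be nonempty")
    if not A <= universe or not B <= universe:
        raise ValueError("feature sets must be subsets of the universe")
    T = len(A & B)
    union = len(A | B)
    jc = T / union if union else 0.0
    try:
        _, phi = pair_statistics(T, len(A), len(B), len(universe))
    except DegenerateMarginError:
        phi = float("nan")
    return FeatureSimilarity(T=T, JC=jc, phi=phi)


def similarity_table(
    index_features: set[str],
    dg_features: Mapping[str, set[str]],
    universe: set[str],
) -> pd.DataFrame:
    """Per-DG T/JC/phi similarity to the index disease's feature set."""
    rows = {
        dg: feature_similarity(index_features, feats & universe, universe)
        for dg, feats in dg_features.items()
    }
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(MEASURES)).sort_index()


@dataclass
class RankTable:
    """Per-DG ranks across similarity / co-occurrence measure columns.

    Each column is a tie-shared (average) ranking of 1..n with larger rank
    meaning closer to the index disease. Missing values rank lowest.
    """

    ranks: pd.DataFrame

    def columns(self) -> list[str]:
        return list(self.ranks.columns)


def build_rank_table(values: pd.DataFrame) -> RankTable:
    """Rank every measure column with larger-value -> larger-rank.

    ``values`` holds one row per DG and one column per measure (similarity
    values or co-occurrence RR/Phi versus the index disease). NaN values
    (e.g. a DG with no mapped genes) are placed at the bottom of the
    ranking rather than dropped, so columns stay commensurate.
    """
    filled = values.astype(float).fillna(-np.inf)
    return RankTable(ranks=filled.rank(method="average", ascending=True))


def measure_outlier_diagnostic(
    rt: RankTable, min_mean_corr: float = 0.2
) -> tuple[pd.DataFrame, list[str], pd.DataFrame]:
    """Spearman redundancy/outlier diagnostic across rank columns.

    Returns the pairwise Spearman correlation matrix, the measures flagged
    as outliers (mean correlation with all other columns below the
    threshold, or undefined because the column is constant), and the
    principal-component loadings of the rank matrix. Intended use: combine
    near-duplicate measure columns, drop flagged outliers before
    summarization.
    """
    if rt.ranks.shape[1] < 3:
        raise ValueError("need at least 3 measure columns for the diagnostic")
    cols = list(rt.ranks.columns)
    n = len(cols)
    corr = np.full((n, n), np.nan)
    np.fill_diagonal(corr, 1.0)
    for a in range(n):
        for b in range(a + 1, n):
            x, y = rt.ranks.iloc[:, a], rt.ranks.iloc[:, b]
            if x.nunique() < 2 or y.nunique() < 2:
                continue  # constant column: correlation undefined
            corr[a, b] = corr[b, a] = spearmanr(x, y).statistic
    corr_df = pd.DataFrame(corr, index=cols, columns=cols)
    flagged = []
    for a, col in enumerate(cols):
        others = np.delete(corr[a], a)
        if np.all(np.isnan(others)) or np.nanmean(others) < min_mean_corr:
            flagged.append(col)

    # PCA loadings of the column-standardized rank matrix
    X = rt.ranks.to_numpy(dtype=float)
    Xc = X - X.mean(axis=0)
    sd = Xc.std(axis=0)
    sd[sd == 0] = 1.0
    Xc /= sd
    _, _, vt = np.linalg.svd(Xc, full_matrices=False)
    k = vt.shape[0]
    loadings = pd.DataFrame(
        vt.T[:, :k], index=cols, columns=[f"PC{i + 1}" for i in range(k)]
    )
    return corr_df, flagged, loadings


def summarize_distance(rt: RankTable, columns: Sequence[str]) -> pd.Series:
    """Combined rank over the named measure columns (tie-shared).

    Typical uses: the gene-based summary over {genes-JC, genes-phi} and the
    pathway-based summary over the GO/KEGG/Reactome-derived columns.
    """
    unknown = [c for c in columns if c not in rt.ranks.columns]
    if unknown:
        raise KeyError(f"unknown measure columns: {unknown}")
    if len(columns) == 1:
        return rt.ranks[columns[0]]
    return combine_ranks(rt.ranks[list(columns)])["combined_rank"]
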