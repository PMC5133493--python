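"""Rank combination with tie sharing, biomarker relevance, and maxperm FWER.

Rank combination: per item, the individual ranks from several measures are
summed; the sums are then ranked again, with tied sums sharing the mean of
the combined positions they occupy (so combined ranks always sum to
n(n+1)/2). The convention throughout is "larger rank = closer to the index
disease", so significance lives in the upper tail.

Biomarker relevance of a gene is the sum, over the disease groups the gene
is associated with, of that group's co-occurrence weight (Phi, or RR)
versus the index disease. Genes are ranked by Phi-relevance and by
RR-relevance; the final ranking averages the two.

Family-wise error control uses the max-statistic permutation null: each of
n_perm permutations sums two independent uniform random rankings of the
genes and records the maximum summed rank (maxperm); the FWER of an
observed rank-sum s is the fraction of permutations with maxperm >= s.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .gene_maps import DiseaseFeatureMap

DEFAULT_N_PERM = 10_000
DEFAULT_FWER_THRESHOLD = 0.05


def _rank(values: pd.Series) -> pd.Series:
    """Ascending average-tie rank: larger value -> larger rank."""
    return values.rank(method="average", ascending=True)


def combine_ranks(rank_columns: pd.DataFrame) -> pd.DataFrame:
    """Sum >= 2 aligned rank columns and re-rank the sums with tie sharing.

    Returns a frame indexed like the input with columns ``rank_sum`` and
    ``combined_rank``; combined ranks occupy 1..n with tied sums sharing
    the mean of their positions.
    """
    if rank_columns.shape[1] < 2:
        raise ValueError("rank combination needs at least 2 columns")
    if rank_columns.isna().any().any():
        raise ValueError("rank columns contain missing values")
    rank_sum = rank_columns.sum(axis=1)
    return pd.DataFrame(
        {"rank_sum": rank_sum, "combined_rank": _rank(rank_sum)},
        index=rank_columns.index,
    )


def final_dg_ranking(
    rank_table: pd.DataFrame,
    columns: Sequence[str] = ("RR", "Phi", "genes", "pathways"),
) -> pd.DataFrame:
    """Final disease-group ranking over the four evidence channels.

    Combines exactly the co-occurrence ranks (RR, Phi) and the summarized
    gene-based and pathway-based mechanistic ranks.
    """
    missing = [c for c in columns if c not in rank_table.columns]
    if missing:
        raise KeyError(f"rank table lacks required columns: {missing}")
    return combine_ranks(rank_table[list(columns)])


# ---------------------------------------------------------------------------
# Biomarker relevance


def _relevance(fm: DiseaseFeatureMap, weights: pd.Series | dict) -> pd.Series:
    w = pd.Series(weights, dtype=float)
    missing = [d for d in fm.diseases if d not in w.index]
    if missing:
        raise KeyError(f"missing weights for diseases: {missing}")
    scores = fm.M.T @ w.loc[fm.diseases].to_numpy()
    return pd.Series(scores, index=fm.features, name="relevance")


def gene_relevance(fm: DiseaseFeatureMap, weights: pd.Series | dict) -> pd.Series:
    """relevance(gene) = sum of the per-DG weight over DGs the gene maps to.

    ``fm`` is a binary DG x gene map (mapping1_DG or mapping2_DG) and
    ``weights`` the per-DG Phi (or RR) versus the index disease.
    """
    if fm.feature_kind != "gene":
        raise ValueError("expected a gene-feature map")
    return _relevance(fm, weights)


def pathway_relevance(fm: DiseaseFeatureMap, weights: pd.Series | dict) -> pd.Series:
    """Same relevance score over a DG x gene-set feature map."""
    if fm.feature_kind != "geneset":
        raise ValueError("expected a gene-set feature map")
    return _relevance(fm, weights)


def rank_average(rank_phi: pd.Series, rank_rr: pd.Series) -> pd.Series:
    """Final gene ranking: average of two rankings, re-ranked with ties."""
    if len(rank_phi) != len(rank_rr):
        raise ValueError("rank vectors must have equal length")
    avg = (rank_phi + rank_rr.loc[rank_phi.index]) / 2.0
    return _rank(avg)


# ---------------------------------------------------------------------------
# Max-statistic permutation FWER


def permutation_maxima(
    n_genes: int, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    """maxperm distribution: max of the sum of two random rankings."""
    base = np.tile(np.arange(1, n_genes + 1), (n_perm, 1))
    s = rng.permuted(base, axis=1) + rng.permuted(base, axis=1)
    return s.max(axis=1)


def permutation_fwer(
    observed: Sequence[float],
    n_genes: int,
    n_perm: int = DEFAULT_N_PERM,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """FWER of each observed rank-sum under the two-ranking permutation null.

    fwer(g) = #{permutations with maxperm >= observed(g)} / n_perm.
    Observed values must lie on the scale of a sum of two ranks over
    ``n_genes`` items, i.e. at most 2 * n_genes.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    obs = np.asarray(observed, dtype=float)
    if np.any(obs > 2 * n_genes):
        raise ValueError("observed score exceeds the maximum possible rank sum")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    maxima = permutation_maxima(n_genes, n_perm, rng)
    return (maxima[None, :] >= obs[:, None]).mean(axis=1)


def biomarker_table(
    fm: DiseaseFeatureMap,
    phi_weights: pd.Series | dict,
    rr_weights: pd.Series | dict,
    n_perm: int = DEFAULT_N_PERM,
    seed: int | np.random.Generator = 0,
    fwer_threshold: float = DEFAULT_FWER_THRESHOLD,
) -> pd.DataFrame:
    """Score, rank and FWER every feature (gene or gene set).

    Columns: score_phi, score_rr, rank_phi, rank_rr, rank_avg, rank_sum,
    fwer, significant (fwer < threshold). Sorted by rank_avg descending
    (top candidates first).
    """
    score_phi = _relevance(fm, phi_weights)
    score_rr = _relevance(fm, rr_weights)
    rank_phi = _rank(score_phi)
    rank_rr = _rank(score_rr)
    rank_sum = rank_phi + rank_rr
    fwer = permutation_fwer(rank_sum.to_numpy(), len(fm.features), n_perm, seed)
    out = pd.DataFrame(
        {
            "score_phi": score_phi,
            "score_rr": score_rr,
            "rank_phi": rank_phi,
            "rank_rr": rank_rr,
            "rank_avg": rank_average(rank_phi, rank_rr),
            "rank_sum": rank_sum,
            "fwer": fwer,
        }
    )
    out["significant"] = out["fwer"] < fwer_threshold
    return out.sort_values("rank_avg", ascending=False)
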