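"""Pairwise co-occurrence statistics against an index disease.

Two complementary comorbidity measures are computed for each disease pair
(i, j) in a population of N patients with incidences I_i, I_j and
co-diagnosis count C_ij:

* relative risk         RR_ij = C_ij / (I_i * I_j / N)
* phi coefficient       Phi_ij = (N*C_ij - I_i*I_j) /
                                 sqrt(I_i*I_j*(N-I_i)*(N-I_j))

RR is the observed co-diagnosis count over its expectation under
independence; Phi is the Pearson correlation of the two binary diagnosis
indicators. RR = 1 and Phi = 0 both flag independence. Phi is undefined
when a margin is degenerate (incidence 0 or N); such pairs are reported as
missing, never as 0, so they cannot silently enter a ranking.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .data_model import CooccurrenceTable, DiagnosisTable, build_cooccurrence

logger = logging.getLogger(__name__)


class DegenerateMarginError(ValueError):
    """Phi is undefined: one of the diseases affects nobody or everybody."""


class PairStats(NamedTuple):
    rr: float
    phi: float


def pair_statistics(C_ij: int, I_i: int, I_j: int, N: int) -> PairStats:
    """Relative risk and phi coefficient for one disease pair.

    Raises :class:`DegenerateMarginError` when I_i or I_j is 0 or N.
    """
    if C_ij > min(I_i, I_j):
        raise ValueError(f"C_ij={C_ij} exceeds min(I_i, I_j)={min(I_i, I_j)}")
    if I_i in (0, N) or I_j in (0, N):
        raise DegenerateMarginError(
            f"phi undefined for margins I_i={I_i}, I_j={I_j}, N={N}"
        )
    rr = C_ij / (I_i * I_j / N)
    phi = (N * C_ij - I_i * I_j) / math.sqrt(
        I_i * I_j * (N - I_i) * (N - I_j)
    )
    return PairStats(rr=rr, phi=phi)


@dataclass
class ComorbidityProfile:
    """Per-code RR/Phi versus a fixed index disease.

    ``rows`` is indexed by code with columns C_ij, I_i (the code), I_j (the
    index), N, RR, Phi; Phi is NaN with ``degenerate`` True where a margin
    makes it undefined. The index code itself is excluded.
    """

    index_code: str
    rows: pd.DataFrame

    def rr(self) -> pd.Series:
        return self.rows["RR"]

    def phi(self) -> pd.Series:
        return self.rows["Phi"]


def comorbidity_profile(cooc: CooccurrenceTable, index_code: str) -> ComorbidityProfile:
    """Compute RR and Phi of every code against the index disease."""
    if index_code not in cooc.I:
        raise KeyError(f"index code {index_code!r} not present in co-occurrence table")
    I_j = cooc.I[index_code]
    records = []
    for code in cooc.codes():
        if code == index_code:
            continue
        I_i = cooc.I[code]
        C = cooc.get_C(code, index_code)
        try:
            rr, phi = pair_statistics(C, I_i, I_j, cooc.N)
            degenerate = False
        except DegenerateMarginError:
            # RR is still well defined unless I_i == 0
            rr = C / (I_i * I_j / cooc.N) if I_i and I_j else float("nan")
            phi = float("nan")
            degenerate = True
        records.append((code, C, I_i, I_j, cooc.N, rr, phi, degenerate))
    rows = pd.DataFrame(
        records,
        columns=["code", "C_ij", "I_i", "I_j", "N", "RR", "Phi", "degenerate"],
    ).set_index("code")
    return ComorbidityProfile(index_code=index_code, rows=rows)


def select_by_rr(profile: ComorbidityProfile, threshold: float = 1.2) -> list[str]:
    """Codes with RR strictly above ``threshold``, sorted lexicographically."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    return sorted(profile.rows.index[profile.rows["RR"] > threshold])


# ---------------------------------------------------------------------------
# Age-window prevalence


def bootstrap_prevalence_ci(
    member_flags: Sequence[int],
    B: int = 1000,
    level: float = 0.95,
    seed: int | np.random.Generator = 0,
) -> tuple[float, float]:
    """Percentile bootstrap CI for a prevalence (mean of 0/1 flags).

    Resamples patients with replacement B times and returns the
    (1-level)/2 and 1-(1-level)/2 percentiles of the resampled means.
    """
    flags = np.asarray(member_flags, dtype=float)
    if flags.size == 0:
        raise ValueError("cannot bootstrap an empty sample")
    if B < 1:
        raise ValueError("B must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    idx = rng.integers(0, flags.size, size=(B, flags.size))
    means = flags[idx].mean(axis=1)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(means, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


def stratified_prevalence(
    diag: DiagnosisTable,
    target: Iterable[str],
    index_code: str,
    window_centers: Sequence[int] = tuple(range(65, 100, 5)),
    half_width: int = 2,
    bootstrap_reps: int = 1000,
    level: float = 0.95,
    seed: int = 0,
) -> pd.DataFrame:
    """Prevalence of a target code set over closed age windows.

    Within each window [center - half_width, center + half_width] (both ends
    included, so center 75 with half-width 2 covers ages 73-77), the
    prevalence of "carries at least one target code" is computed separately
    among index-disease patients and their complement, with percentile
    bootstrap confidence intervals. Empty windows yield NaN, not 0.
    """
    if half_width < 0:
        raise ValueError("half_width must be >= 0")
    target = set(target)
    patients = diag.patients()
    by_patient = diag.records.groupby("patient_id")["code"].agg(set)
    patients["has_index"] = patients["patient_id"].map(
        lambda p: index_code in by_patient[p]
    )
    patients["has_target"] = patients["patient_id"].map(
        lambda p: bool(by_patient[p] & target)
    )
    rng = np.random.default_rng(seed)
    out = []
    for center in window_centers:
        in_win = patients[
            (patients["age"] >= center - half_width)
            & (patients["age"] <= center + half_width)
        ]
        row: dict[str, float] = {"center_age": center}
        for label, grp in (
            ("index", in_win[in_win["has_index"]]),
            ("complement", in_win[~in_win["has_index"]]),
        ):
            flags = grp["has_target"].to_numpy(dtype=int)
            row[f"n_{label}"] = len(flags)
            if len(flags) == 0:
                row[f"prev_{label}"] = np.nan
                row[f"ci_low_{label}"] = np.nan
                row[f"ci_high_{label}"] = np.nan
            else:
                row[f"prev_{label}"] = flags.mean()
                lo, hi = bootstrap_prevalence_ci(flags, bootstrap_reps, level, rng)
                row[f"ci_low_{label}"] = lo
                row[f"ci_high_{label}"] = hi
        out.append(row)
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# Gender stratification


def gender_stratified_profile(
    diag: DiagnosisTable,
    index_code: str,
    codes: Iterable[str] | None = None,
) -> pd.DataFrame:
    """RR, Phi and co-diagnosis fraction per code, within each sex stratum.

    Statistics use stratum-specific N, I and C. ``pct`` is the fraction of
    index-disease patients in the stratum also diagnosed with the code.
    Adds Male - Female differences and their ratio to the male value.
    Strata with no index-disease patients are skipped with a warning.
    """
    frames = {}
    for sex in ("M", "F"):
        sub = DiagnosisTable(diag.records[diag.records["sex"] == sex])
        if len(sub) == 0:
            logger.warning("no records for sex %s; stratum skipped", sex)
            continue
        cooc = build_cooccurrence(sub, codes=None if codes is None else set(codes) | {index_code})
        if cooc.I.get(index_code, 0) == 0:
            logger.warning("no index-disease patients of sex %s; stratum skipped", sex)
            continue
        prof = comorbidity_profile(cooc, index_code)
        t = prof.rows[["RR", "Phi"]].copy()
        t["pct"] = prof.rows["C_ij"] / prof.rows["I_j"]
        frames[sex] = t
    if not frames:
        raise ValueError("no usable sex stratum")
    combined = pd.concat(frames, axis=1)  # columns (sex, stat)
    if {"M", "F"} <= set(frames):
        for stat in ("RR", "Phi", "pct"):
            diff = combined[("M", stat)] - combined[("F", stat)]
            combined[("diff_M_minus_F", stat)] = diff
            combined[("diff_over_male", stat)] = diff / combined[("M", stat)]
    return combined
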