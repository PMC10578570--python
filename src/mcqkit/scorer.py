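"""Consistency-score estimation of individual discount rates.

With items arranged in ascending k order, a respondent who discounts at rate
``k`` should choose the immediate reward on items whose k lies below their
own and the delayed reward on items above it.  Each candidate switch
position is scored by the proportion of responses consistent with it; the
rate estimate is read off at the position(s) of maximal consistency, as the
geometric mean of the bracketing item k values.

A single pattern yields five estimates: one from all items ordered together
(overall), one per amount set (small / medium / large), and a composite
defined as the geometric mean of the three set estimates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .item_bank import SET_LABELS, Item, ItemBank, overall_order
from .responses import ResponseMatrix

__all__ = [
    "ScoringError",
    "ScoreResult",
    "consistency_profile",
    "estimate_k_from_profile",
    "proportion_delayed",
    "score_respondent",
    "score_cohort",
    "SCORE_COLUMNS",
]

SCORE_COLUMNS = [
    "respondent_id",
    "overall_k",
    "small_k",
    "medium_k",
    "large_k",
    "composite_k",
    "ln_composite_k",
    "consistency_overall",
    "consistency_small",
    "consistency_medium",
    "consistency_large",
    "proportion_delayed",
    "n_missing",
]


class ScoringError(ValueError):
    pass


@dataclass(frozen=True)
class ScoreResult:
    """Five k estimates plus consistency and proportion-delayed scores."""

    respondent_id: str
    overall_k: Optional[float]
    small_k: Optional[float]
    medium_k: Optional[float]
    large_k: Optional[float]
    composite_k: Optional[float]
    consistency_overall: Optional[float]
    consistency_small: Optional[float]
    consistency_medium: Optional[float]
    consistency_large: Optional[float]
    proportion_delayed: Optional[float]
    n_missing: int

    @property
    def ln_composite_k(self) -> Optional[float]:
        if self.composite_k is None:
            return None
        return math.log(self.composite_k)


# ----------------------------------------------------------------------
# single-pattern operations
# ----------------------------------------------------------------------

def consistency_profile(responses: Sequence[float]) -> np.ndarray:
    """Consistency of every switch position for one complete pattern.

    ``responses`` must be 0/1 codes over items already sorted ascending in
    k.  Entry ``s`` of the returned length ``n+1`` vector is the proportion
    of responses consistent with switching from immediate to delayed just
    before item ``s+1``: immediate choices among the first ``s`` items plus
    delayed choices among the rest, divided by ``n``.
    """
    arr = np.asarray(responses, dtype=float)
    if arr.ndim != 1:
        raise ScoringError("responses must be a flat vector")
    if np.isnan(arr).any():
        raise ScoringError(
            "pattern contains missing responses; impute before scoring"
        )
    n = arr.size
    if n == 0:
        raise ScoringError("empty response pattern")
    counts = _profile_counts(arr[None, :])[0]
    return counts / n


def _profile_counts(R: np.ndarray) -> np.ndarray:
    """Consistent-response counts per switch position, rows of 0/1 codes."""
    imm = (R == 0.0).astype(np.int64)
    dly = (R == 1.0).astype(np.int64)
    zero = np.zeros((R.shape[0], 1), dtype=np.int64)
    cum_imm = np.concatenate([zero, np.cumsum(imm, axis=1)], axis=1)
    cum_dly = np.concatenate([zero, np.cumsum(dly, axis=1)], axis=1)
    total_dly = cum_dly[:, -1][:, None]
    return cum_imm + (total_dly - cum_dly)


def _candidate_ln_k(k_values: np.ndarray) -> np.ndarray:
    """ln of the k estimate assigned to each of the n+1 switch positions.

    Interior position s brackets items s and s+1 (1-based) and maps to the
    geometric mean of their nominal ks; the boundary positions map to the
    scope's minimum (all delayed) and maximum (all immediate) nominal k,
    keeping estimates inside the instrument's measurable range.
    """
    ln_k = np.log(np.asarray(k_values, dtype=float))
    cand = np.empty(ln_k.size + 1)
    cand[0] = ln_k[0]
    cand[-1] = ln_k[-1]
    cand[1:-1] = 0.5 * (ln_k[:-1] + ln_k[1:])
    return cand


def estimate_k_from_profile(
    profile: Sequence[float], k_values: Sequence[float]
) -> tuple[float, float]:
    """Rate estimate and maximal consistency from a consistency profile.

    When several positions tie for maximal consistency the estimate is the
    geometric mean of all tied candidate k values (the convention of the
    Kaplan et al. scorer).
    """
    k_values = np.asarray(k_values, dtype=float)
    if k_values.size == 0:
        raise ScoringError("empty item list")
    prof = np.asarray(profile, dtype=float)
    if prof.size != k_values.size + 1:
        raise ScoringError(
            f"profile length {prof.size} does not match {k_values.size} items"
        )
    cand = _candidate_ln_k(k_values)
    best = prof.max()
    tied = prof >= best - 1e-12
    k_est = float(np.exp(cand[tied].mean()))
    return k_est, float(best)


def proportion_delayed(responses: Sequence[float]) -> float:
    """Proportion of delayed choices among non-missing responses."""
    arr = np.asarray(responses, dtype=float)
    observed = ~np.isnan(arr)
    if not observed.any():
        raise ScoringError("all responses missing; proportion undefined")
    return float((arr[observed] == 1.0).mean())


# ----------------------------------------------------------------------
# cohort scoring (vectorised)
# ----------------------------------------------------------------------

@lru_cache(maxsize=8)
def _scoring_plan(bank: ItemBank):
    """Column indices and candidate ln-k grids for every scoring scope."""
    scopes: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    ordered = overall_order(bank)
    scopes["overall"] = (
        np.array([it.item_id - 1 for it in ordered]),
        _candidate_ln_k(np.array([it.k_nominal for it in ordered])),
    )
    for label in SET_LABELS:
        members = bank.set_items(label)
        scopes[label] = (
            np.array([it.item_id - 1 for it in members]),
            _candidate_ln_k(np.array([it.k_nominal for it in members])),
        )
    return scopes


def _score_scope(
    values: np.ndarray, cols: np.ndarray, cand_ln_k: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """(k estimate, consistency) per row; NaN where the scope is incomplete."""
    sub = values[:, cols]
    n = sub.shape[1]
    complete = ~np.isnan(sub).any(axis=1)
    k_est = np.full(sub.shape[0], np.nan)
    consistency = np.full(sub.shape[0], np.nan)
    if complete.any():
        counts = _profile_counts(np.nan_to_num(sub[complete]))
        best = counts.max(axis=1)
        tied = counts == best[:, None]
        ln_est = (tied * cand_ln_k).sum(axis=1) / tied.sum(axis=1)
        k_est[complete] = np.exp(ln_est)
        consistency[complete] = best / n
    return k_est, consistency


def score_cohort(bank: ItemBank, matrix: ResponseMatrix) -> pd.DataFrame:
    """Score every respondent; one row per respondent, order preserved.

    k estimates and consistencies are ``NaN`` wherever their item scope
    contains a missing response.  The composite follows the strict rule
    (defined only when all three set estimates are defined); the relaxed
    rule lives in :mod:`mcqkit.imputation`.
    """
    if matrix.n_items != bank.version:
        raise ScoringError(
            f"matrix has {matrix.n_items} items, bank has {bank.version}"
        )
    plan = _scoring_plan(bank)
    values = matrix.values
    out: dict[str, np.ndarray] = {}
    out["overall_k"], out["consistency_overall"] = _score_scope(
        values, *plan["overall"]
    )
    for label in SET_LABELS:
        k, c = _score_scope(values, *plan[label])
        out[f"{label}_k"] = k
        out[f"consistency_{label}"] = c

    set_ks = np.column_stack(
        [out["small_k"], out["medium_k"], out["large_k"]]
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        composite = np.exp(np.log(set_ks).mean(axis=1))
    composite[np.isnan(set_ks).any(axis=1)] = np.nan

    observed = ~matrix.missing_mask
    n_obs = observed.sum(axis=1)
    with np.errstate(invalid="ignore"):
        prop = np.where(
            n_obs > 0,
            np.nansum(matrix.values == 1.0, axis=1) / np.maximum(n_obs, 1),
            np.nan,
        )

    df = pd.DataFrame(
        {
            "respondent_id": list(matrix.ids),
            "overall_k": out["overall_k"],
            "small_k": out["small_k"],
            "medium_k": out["medium_k"],
            "large_k": out["large_k"],
            "composite_k": composite,
            "ln_composite_k": np.log(
                composite, where=~np.isnan(composite), out=np.full_like(composite, np.nan)
            ),
            "consistency_overall": out["consistency_overall"],
            "consistency_small": out["consistency_small"],
            "consistency_medium": out["consistency_medium"],
            "consistency_large": out["consistency_large"],
            "proportion_delayed": prop,
            "n_missing": matrix.missing_mask.sum(axis=1).astype(int),
        }
    )
    return df


def score_respondent(
    bank: ItemBank, responses: Sequence[float], respondent_id: str = "0"
) -> ScoreResult:
    """Score one respondent; missing responses leave affected scopes undefined."""
    arr = np.asarray(responses, dtype=float)
    if arr.size != bank.version:
        raise ScoringError(
            f"pattern has {arr.size} responses, bank has {bank.version} items"
        )
    matrix = ResponseMatrix(ids=(respondent_id,), values=arr[None, :])
    row = score_cohort(bank, matrix).iloc[0]

    def _opt(v: float) -> Optional[float]:
        return None if pd.isna(v) else float(v)

    return ScoreResult(
        respondent_id=respondent_id,
        overall_k=_opt(row["overall_k"]),
        small_k=_opt(row["small_k"]),
        medium_k=_opt(row["medium_k"]),
        large_k=_opt(row["large_k"]),
        composite_k=_opt(row["composite_k"]),
        consistency_overall=_opt(row["consistency_overall"]),
        consistency_small=_opt(row["consistency_small"]),
        consistency_medium=_opt(row["consistency_medium"]),
        consistency_large=_opt(row["consistency_large"]),
        proportion_delayed=_opt(row["proportion_delayed"]),
        n_missing=int(row["n_missing"]),
    )
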