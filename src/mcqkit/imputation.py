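"""The four missing-response handling approaches.

1. ``mode``       - fill each missing cell with the per-item mode.
2. ``ggm``        - no item-level fill; relax the composite rule so the
                    composite k is the geometric mean of whichever amount-set
                    estimates are available ("group geometric mean").
3. ``inn``        - item nearest neighbour: fill a missing cell from the
                    congruent non-missing responses of the other items
                    sharing its k value; incongruent or unreferenced cells
                    stay missing, and scoring falls back to the relaxed
                    composite.
4. ``inn_random`` - as ``inn``, then fill every still-missing cell with a
                    fair random 0/1 draw, so nothing stays missing.

All fills read their references from the original (pre-imputation) matrix,
so results are independent of cell visit order, and observed cells are never
altered.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .item_bank import ItemBank
from .responses import ResponseMatrix
from .scorer import score_cohort

__all__ = [
    "METHODS",
    "ImputationError",
    "ImputationReport",
    "mode_impute",
    "relaxed_composite",
    "inn_impute",
    "apply_approach",
]

METHODS = ("mode", "ggm", "inn", "inn_random")

#: Cell-level fill provenance codes used in report matrices.
PROVENANCE_LABELS = {
    1: "mode",
    2: "congruent-copy",
    3: "single-ref-copy",
    4: "random",
}


class ImputationError(ValueError):
    pass


@dataclass
class ImputationReport:
    """Per-cell provenance of fills and residual missingness for one run."""

    method: str
    provenance: np.ndarray  # int8, same shape as the matrix; 0 = untouched
    residual_missing_cells: int
    unimputable_respondents: Optional[int] = None
    mode_tied_items: tuple[int, ...] = ()
    fills: Optional[pd.DataFrame] = field(default=None, repr=False)

    def build_fills(self, imputed: ResponseMatrix) -> pd.DataFrame:
        """Long table of (respondent, item, filled value, provenance)."""
        rows, cols = np.nonzero(self.provenance)
        self.fills = pd.DataFrame(
            {
                "respondent_id": [imputed.ids[i] for i in rows],
                "item_id": cols + 1,
                "filled_value": imputed.values[rows, cols].astype(int),
                "provenance": [
                    PROVENANCE_LABELS[p] for p in self.provenance[rows, cols]
                ],
            }
        )
        return self.fills


# ----------------------------------------------------------------------
# approach 1: mode imputation
# ----------------------------------------------------------------------

def mode_impute(matrix: ResponseMatrix) -> tuple[ResponseMatrix, ImputationReport]:
    """Fill every missing cell with the mode of its item's observed responses.

    Ties (equal 0/1 counts among observed responses) break toward the
    delayed choice (1), deterministically; tied items are listed in the
    report.  An item that has a missing cell but no observed response at
    all cannot provide a mode and raises :class:`ImputationError`.
    """
    values = matrix.values.copy()
    missing = matrix.missing_mask
    provenance = np.zeros(values.shape, dtype=np.int8)
    tied: list[int] = []

    n_delayed = np.nansum(values == 1.0, axis=0)
    n_observed = (~missing).sum(axis=0)
    needs_fill = missing.any(axis=0)

    empty = needs_fill & (n_observed == 0)
    if empty.any():
        j = int(np.argmax(empty))
        raise ImputationError(
            f"item {j + 1} is entirely missing; no mode exists"
        )

    n_immediate = n_observed - n_delayed
    modes = np.where(n_delayed >= n_immediate, 1.0, 0.0)
    tied = [int(j) + 1 for j in np.nonzero(needs_fill & (n_delayed == n_immediate))[0]]

    fill = np.broadcast_to(modes, values.shape)
    values[missing] = fill[missing]
    provenance[missing] = 1

    report = ImputationReport(
        method="mode",
        provenance=provenance,
        residual_missing_cells=0,
        mode_tied_items=tuple(tied),
    )
    return matrix.with_values(values), report


# ----------------------------------------------------------------------
# approach 2: relaxed (group-geometric-mean) composite
# ----------------------------------------------------------------------

def relaxed_composite(
    small_k: Optional[float],
    medium_k: Optional[float],
    large_k: Optional[float],
) -> Optional[float]:
    """Geometric mean of whichever amount-set estimates are defined.

    Returns ``None`` only when all three are undefined.  With a single
    defined set the composite equals that set's estimate.
    """
    ks = [
        k for k in (small_k, medium_k, large_k)
        if k is not None and not (isinstance(k, float) and math.isnan(k))
    ]
    if not ks:
        return None
    return float(math.exp(sum(math.log(k) for k in ks) / len(ks)))


def _relaxed_composite_rows(set_ks: np.ndarray) -> np.ndarray:
    """Vectorised relaxed composite over rows of (small, medium, large) ks."""
    with np.errstate(invalid="ignore", divide="ignore"):
        ln = np.log(set_ks)
    n_defined = (~np.isnan(ln)).sum(axis=1)
    out = np.full(set_ks.shape[0], np.nan)
    ok = n_defined > 0
    out[ok] = np.exp(np.nansum(ln[ok], axis=1) / n_defined[ok])
    return out


# ----------------------------------------------------------------------
# approaches 3 & 4: item nearest neighbour
# ----------------------------------------------------------------------

def inn_impute(
    matrix: ResponseMatrix,
    bank: ItemBank,
    fill_random: bool = False,
    rng: Optional[np.random.Generator] = None,
) -> tuple[ResponseMatrix, ImputationReport]:
    """Fill missing cells from same-k-rank responses in the other amount sets.

    For each missing cell the references are the non-missing responses (in
    the *original* matrix) among the other two items of the same k rank:
    two congruent references copy the shared value, a single reference is
    copied as-is, and incongruent or absent references leave the cell
    missing.  With ``fill_random`` every cell still missing afterwards is
    filled with an independent fair 0/1 draw from ``rng``.
    """
    if matrix.n_items != bank.version:
        raise ImputationError(
            f"matrix has {matrix.n_items} items, bank has {bank.version}"
        )
    if fill_random and rng is None:
        raise ImputationError("fill_random requires a seeded rng")

    original = matrix.values
    values = original.copy()
    provenance = np.zeros(values.shape, dtype=np.int8)

    for rank in range(1, bank.items_per_set + 1):
        group = bank.rank_group(rank)
        cols = [it.item_id - 1 for it in group]
        for pos, col in enumerate(cols):
            target_missing = np.isnan(original[:, col])
            if not target_missing.any():
                continue
            others = [c for c in cols if c != col]
            r1 = original[:, others[0]]
            r2 = original[:, others[1]]
            have1 = ~np.isnan(r1)
            have2 = ~np.isnan(r2)

            congruent = target_missing & have1 & have2 & (r1 == r2)
            single1 = target_missing & have1 & ~have2
            single2 = target_missing & ~have1 & have2

            values[congruent, col] = r1[congruent]
            provenance[congruent, col] = 2
            values[single1, col] = r1[single1]
            provenance[single1, col] = 3
            values[single2, col] = r2[single2]
            provenance[single2, col] = 3

    still_missing = np.isnan(values)
    if fill_random and still_missing.any():
        draws = rng.integers(0, 2, size=int(still_missing.sum())).astype(float)
        values[still_missing] = draws
        provenance[still_missing] = 4
        residual = 0
    else:
        residual = int(still_missing.sum())

    report = ImputationReport(
        method="inn_random" if fill_random else "inn",
        provenance=provenance,
        residual_missing_cells=residual,
    )
    return matrix.with_values(values), report


# ----------------------------------------------------------------------
# dispatcher
# ----------------------------------------------------------------------

def _canonical_method(method: str) -> str:
    name = method.replace("-", "_").lower()
    if name not in METHODS:
        raise ImputationError(
            f"unknown method {method!r}; expected one of {METHODS}"
        )
    return name


def apply_approach(
    matrix: ResponseMatrix,
    bank: ItemBank,
    method: str,
    rng: Optional[np.random.Generator] = None,
    record_fills: bool = True,
) -> tuple[pd.DataFrame, ImputationReport]:
    """Run one approach end to end and score the result.

    Returns the cohort score table (see :func:`mcqkit.scorer.score_cohort`)
    with the composite column following each approach's composite rule, and
    the imputation report with ``unimputable_respondents`` set to the number
    of rows left without a composite k.
    """
    name = _canonical_method(method)

    if name == "mode":
        imputed, report = mode_impute(matrix)
        scores = score_cohort(bank, imputed)
    elif name == "ggm":
        imputed = matrix
        report = ImputationReport(
            method="ggm",
            provenance=np.zeros(matrix.values.shape, dtype=np.int8),
            residual_missing_cells=matrix.n_missing_cells,
        )
        scores = score_cohort(bank, matrix)
        _relax(scores)
    elif name == "inn":
        imputed, report = inn_impute(matrix, bank, fill_random=False)
        scores = score_cohort(bank, imputed)
        _relax(scores)
    else:  # inn_random
        if rng is None:
            raise ImputationError("method inn_random requires a seeded rng")
        imputed, report = inn_impute(matrix, bank, fill_random=True, rng=rng)
        scores = score_cohort(bank, imputed)

    report.unimputable_respondents = int(scores["composite_k"].isna().sum())
    if record_fills:
        report.build_fills(imputed)
    return scores, report


def _relax(scores: pd.DataFrame) -> None:
    """Replace the strict composite column with the relaxed one, in place."""
    set_ks = scores[["small_k", "medium_k", "large_k"]].to_numpy()
    composite = _relaxed_composite_rows(set_ks)
    scores["composite_k"] = composite
    with np.errstate(invalid="ignore"):
        scores["ln_composite_k"] = np.log(composite)
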