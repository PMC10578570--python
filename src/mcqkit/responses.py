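"""Ternary respondent-by-item response matrices.

Responses are coded 0 (smaller-immediate chosen), 1 (larger-delayed chosen)
or missing.  Internally the matrix is a float array with ``NaN`` marking
missing cells, which keeps every bulk operation vectorised.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["ResponseMatrix"]


@dataclass(frozen=True)
class ResponseMatrix:
    """Respondents x items matrix of ternary choice codes.

    Attributes
    ----------
    ids
        Opaque respondent identifiers, order preserved.
    values
        Float array of shape ``(n_respondents, n_items)`` whose entries are
        0.0, 1.0 or ``NaN`` (missing).
    """

    ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float)
        if arr.ndim != 2:
            raise ValueError(f"values must be 2-D, got shape {arr.shape}")
        if len(self.ids) != arr.shape[0]:
            raise ValueError(
                f"{len(self.ids)} ids for {arr.shape[0]} rows"
            )
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate respondent ids")
        ok = np.isnan(arr) | (arr == 0.0) | (arr == 1.0)
        if not ok.all():
            i, j = np.argwhere(~ok)[0]
            raise ValueError(
                f"invalid response code {arr[i, j]!r} for respondent "
                f"{self.ids[i]!r}, item {j + 1}"
            )
        object.__setattr__(self, "values", arr)
        object.__setattr__(self, "ids", tuple(str(i) for i in self.ids))

    # ------------------------------------------------------------------
    @property
    def n_respondents(self) -> int:
        return self.values.shape[0]

    @property
    def n_items(self) -> int:
        return self.values.shape[1]

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.values)

    @property
    def n_missing_cells(self) -> int:
        return int(self.missing_mask.sum())

    def is_complete(self) -> bool:
        return not self.missing_mask.any()

    def with_values(self, values: np.ndarray) -> "ResponseMatrix":
        """Same respondents, new cell values."""
        return ResponseMatrix(ids=self.ids, values=values)

    # ------------------------------------------------------------------
    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "ResponseMatrix":
        """Build from a wide frame with ``respondent_id`` + ``item_*`` columns."""
        if "respondent_id" not in df.columns:
            raise ValueError("missing 'respondent_id' column")
        ids = tuple(str(v) for v in df["respondent_id"])
        item_cols = [c for c in df.columns if c != "respondent_id"]
        vals = df[item_cols].to_numpy(dtype=float)
        return cls(ids=ids, values=vals)

    def to_dataframe(self) -> pd.DataFrame:
        """Wide frame with ``respondent_id`` then ``item_1..item_n``."""
        cols = [f"item_{j + 1}" for j in range(self.n_items)]
        df = pd.DataFrame(self.values, columns=cols)
        df.insert(0, "respondent_id", list(self.ids))
        return df
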