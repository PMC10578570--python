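"""Item parameter tables for the 21- and 27-item Monetary Choice Questionnaires.

Each MCQ item offers a smaller-immediate amount ``V`` against a larger-delayed
amount ``A`` available after ``D`` days.  Under the simple hyperbolic model
``V = A / (1 + kD)`` the two options are subjectively equal at the discount
rate ``k = (A/V - 1)/D``; every item is built around one such indifference
rate.  Items come in three amount sets (small / medium / large delayed
amounts) that share a common ladder of nominal k values, so items of equal
rank across sets are "nearest neighbours".

The two standard questionnaires ship as packaged CSV tables (``mcq21.csv``,
``mcq27.csv``) and are validated on load against the recomputed rates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Item",
    "ItemBank",
    "InvalidItemError",
    "BankValidationError",
    "SET_LABELS",
    "compute_item_k",
    "load_item_bank",
    "load_packaged_bank",
    "overall_order",
]

#: Fixed tie order inside a rank block of the overall k-ascending ordering.
SET_LABELS: tuple[str, ...] = ("small", "medium", "large")

#: Relative tolerance between a published (rounded) nominal k and the exact
#: recomputed (A/V - 1)/D; published values carry one significant figure.
K_NOMINAL_RTOL = 0.15


class InvalidItemError(ValueError):
    """An item's amounts or delay admit no positive discount rate."""


class BankValidationError(ValueError):
    """An item table violates the questionnaire's structural invariants."""


def compute_item_k(
    immediate_amount: float, delayed_amount: float, delay_days: float
) -> float:
    """Discount rate at which the two options of an item are equivalent.

    Solves ``V = A / (1 + kD)`` for k: ``k = (A/V - 1) / D``.

    Parameters
    ----------
    immediate_amount
        Smaller-immediate amount ``V``; must be positive.
    delayed_amount
        Larger-delayed amount ``A``; must exceed ``immediate_amount``.
    delay_days
        Delay ``D`` in days; must be at least 1.

    Returns
    -------
    float
        The positive indifference rate ``k`` (1/day).

    Raises
    ------
    InvalidItemError
        If amounts or delay are non-positive, the delay is below one day,
        or the delayed amount does not exceed the immediate amount.
    """
    if immediate_amount <= 0 or delayed_amount <= 0:
        raise InvalidItemError(
            f"amounts must be positive, got V={immediate_amount!r}, "
            f"A={delayed_amount!r}"
        )
    if delay_days < 1:
        raise InvalidItemError(f"delay must be >= 1 day, got D={delay_days!r}")
    if delayed_amount <= immediate_amount:
        raise InvalidItemError(
            "delayed amount must exceed immediate amount "
            f"(V={immediate_amount!r}, A={delayed_amount!r}); "
            "no positive k exists"
        )
    return (delayed_amount / immediate_amount - 1.0) / delay_days


@dataclass(frozen=True)
class Item:
    """One binary choice question of the questionnaire."""

    item_id: int
    set_label: str
    immediate_amount: float
    delayed_amount: float
    delay_days: int
    k_nominal: float
    k_rank: int

    @property
    def k_exact(self) -> float:
        """Recomputed indifference rate ``(A/V - 1)/D``."""
        return compute_item_k(
            self.immediate_amount, self.delayed_amount, self.delay_days
        )


@dataclass(frozen=True)
class ItemBank:
    """A validated 21- or 27-item questionnaire, in administered order."""

    version: int
    items: tuple[Item, ...]

    # ---- derived lookups (built once, cached on the instance) -------------
    _by_id: dict[int, Item] = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "_by_id", {it.item_id: it for it in self.items})

    def __len__(self) -> int:
        return len(self.items)

    def __iter__(self):
        return iter(self.items)

    @property
    def items_per_set(self) -> int:
        return self.version // 3

    def item(self, item_id: int) -> Item:
        return self._by_id[item_id]

    def set_items(self, set_label: str) -> tuple[Item, ...]:
        """Items of one amount set, ascending in k rank."""
        members = [it for it in self.items if it.set_label == set_label]
        return tuple(sorted(members, key=lambda it: it.k_rank))

    def rank_group(self, k_rank: int) -> tuple[Item, ...]:
        """The (three) nearest-neighbour items sharing one k rank."""
        members = [it for it in self.items if it.k_rank == k_rank]
        return tuple(sorted(members, key=lambda it: SET_LABELS.index(it.set_label)))

    def k_ladder(self, set_label: str) -> np.ndarray:
        return np.array([it.k_nominal for it in self.set_items(set_label)])

    def to_dataframe(self) -> pd.DataFrame:
        """Item table in administered order, including derived k ranks."""
        return pd.DataFrame(
            {
                "item_id": [it.item_id for it in self.items],
                "set_label": [it.set_label for it in self.items],
                "immediate_amount": [it.immediate_amount for it in self.items],
                "delayed_amount": [it.delayed_amount for it in self.items],
                "delay_days": [it.delay_days for it in self.items],
                "k_nominal": [it.k_nominal for it in self.items],
                "k_rank": [it.k_rank for it in self.items],
            }
        )


def _rank_within_sets(records: pd.DataFrame) -> pd.Series:
    """1-based rank of k_nominal inside each amount set (ascending)."""
    return (
        records.groupby("set_label")["k_nominal"]
        .rank(method="first")
        .astype(int)
    )


def load_item_bank(table: pd.DataFrame | Iterable[dict], version: int) -> ItemBank:
    """Build a validated :class:`ItemBank` from item-parameter records.

    ``table`` needs one record per item with columns ``item_id``,
    ``set_label``, ``immediate_amount``, ``delayed_amount``, ``delay_days``
    and ``k_nominal``; ``k_rank`` is derived here.

    Raises
    ------
    BankValidationError
        On a wrong item count, unequal set sizes, duplicated nominal k
        within a set, or a nominal k inconsistent with the amounts/delay
        beyond the rounding tolerance.  The message names the offending item.
    """
    if version not in (21, 27):
        raise BankValidationError(f"version must be 21 or 27, got {version!r}")
    df = pd.DataFrame(table).copy()
    required = {
        "item_id", "set_label", "immediate_amount",
        "delayed_amount", "delay_days", "k_nominal",
    }
    missing_cols = required - set(df.columns)
    if missing_cols:
        raise BankValidationError(f"missing columns: {sorted(missing_cols)}")
    if len(df) != version:
        raise BankValidationError(
            f"expected {version} items, got {len(df)} records"
        )
    if df["item_id"].duplicated().any():
        dupes = df.loc[df["item_id"].duplicated(), "item_id"].tolist()
        raise BankValidationError(f"duplicate item_id(s): {dupes}")

    bad_labels = set(df["set_label"]) - set(SET_LABELS)
    if bad_labels:
        raise BankValidationError(f"unknown set label(s): {sorted(bad_labels)}")
    per_set = df["set_label"].value_counts()
    m = version // 3
    for label in SET_LABELS:
        if per_set.get(label, 0) != m:
            raise BankValidationError(
                f"amount set {label!r} has {per_set.get(label, 0)} items, "
                f"expected {m}"
            )

    for rec in df.itertuples(index=False):
        try:
            k_exact = compute_item_k(
                rec.immediate_amount, rec.delayed_amount, rec.delay_days
            )
        except InvalidItemError as exc:
            raise BankValidationError(f"item {rec.item_id}: {exc}") from exc
        if abs(k_exact - rec.k_nominal) > K_NOMINAL_RTOL * rec.k_nominal:
            raise BankValidationError(
                f"item {rec.item_id}: nominal k {rec.k_nominal} disagrees with "
                f"computed (A/V-1)/D = {k_exact:.6g} beyond "
                f"{K_NOMINAL_RTOL:.0%} tolerance"
            )

    for label in SET_LABELS:
        ks = df.loc[df["set_label"] == label, "k_nominal"]
        if ks.duplicated().any():
            raise BankValidationError(
                f"amount set {label!r} has duplicated nominal k values; "
                "ranks would be ambiguous"
            )

    df["k_rank"] = _rank_within_sets(df)
    items = tuple(
        Item(
            item_id=int(rec.item_id),
            set_label=str(rec.set_label),
            immediate_amount=float(rec.immediate_amount),
            delayed_amount=float(rec.delayed_amount),
            delay_days=int(rec.delay_days),
            k_nominal=float(rec.k_nominal),
            k_rank=int(rec.k_rank),
        )
        for rec in df.itertuples(index=False)
    )
    return ItemBank(version=version, items=items)


def load_packaged_bank(version: int) -> ItemBank:
    """Load one of the two standard questionnaires shipped with the package."""
    if version not in (21, 27):
        raise BankValidationError(f"version must be 21 or 27, got {version!r}")
    ref = resources.files("mcqkit.data") / f"mcq{version}.csv"
    with resources.as_file(ref) as path:
        df = pd.read_csv(path)
    return load_item_bank(df, version)


def load_item_bank_csv(path: str | Path, version: int) -> ItemBank:
    """Load and validate an item-parameter CSV (see packaged files for layout)."""
    return load_item_bank(pd.read_csv(path), version)


def overall_order(bank: ItemBank) -> tuple[Item, ...]:
    """All items sorted by nominal k ascending, for overall-k scoring.

    Items of equal nominal k (the same rank across sets) form contiguous
    blocks; inside a block the order is small, medium, large.  Any fixed
    block order yields the same maximal consistency because tied items share
    their k value.
    """
    return tuple(
        sorted(
            bank.items,
            key=lambda it: (it.k_nominal, SET_LABELS.index(it.set_label)),
        )
    )
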