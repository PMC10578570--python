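"""Monte Carlo evaluation of the imputation approaches.

Per iteration: remove exactly ``r`` responses per respondent from a complete
base matrix, apply each approach to that same degraded dataset, and compare
the resulting composite k values with the ones scored from the intact
matrix.  Five measures are tracked per (method, r) condition: mean
difference, RMSD, Pearson correlation with the true composites (all on the
raw k scale), the number of respondents left without a composite, and the
change in the correlation between ln composite k and an external covariate.

The expected number of respondents the group-geometric-mean approach cannot
handle is also available in closed form (inclusion-exclusion over the three
amount sets), which pins down the structurally determined table rows
without any real data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .imputation import METHODS, apply_approach
from .item_bank import ItemBank
from .responses import ResponseMatrix
from .scorer import score_cohort
from .synthetic import inject_missing

__all__ = [
    "SimulationConfig",
    "METRIC_NAMES",
    "compute_metrics",
    "run_condition",
    "run_study",
    "expected_ggm_failures",
    "metrics_to_table",
]

METRIC_NAMES = (
    "mean_difference",
    "rmsd",
    "corr_true",
    "n_unimputable",
    "delta_corr_covariate",
)

#: Human-readable table section titles, in printed order.
MEASURE_TITLES = {
    "mean_difference": "Mean difference from true scores",
    "rmsd": "Root-mean-square deviation from true scores",
    "corr_true": "Correlation with true scores",
    "n_unimputable": "Number of missing after imputation",
    "delta_corr_covariate": "Difference in correlation with covariate",
}

METHOD_TITLES = {
    "mode": "Mode",
    "ggm": "GGM",
    "inn": "INN without random",
    "inn_random": "INN with random",
}


@dataclass
class SimulationConfig:
    """One full study: a complete base matrix, a method/r grid, a seed."""

    bank: ItemBank
    base_matrix: ResponseMatrix
    covariate: Optional[np.ndarray] = None
    r_values: Sequence[int] = ()
    iterations: int = 1000
    methods: Sequence[str] = METHODS
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.r_values:
            self.r_values = tuple(
                range(1, 6 if self.bank.version == 21 else 8)
            )
        self.r_values = tuple(int(r) for r in self.r_values)
        self.methods = tuple(
            m.replace("-", "_").lower() for m in self.methods
        )
        for m in self.methods:
            if m not in METHODS:
                raise ValueError(f"unknown method {m!r}")
        if self.iterations <= 0:
            raise ValueError("iterations must be positive")
        if self.seed < 0:
            raise ValueError("seed must be non-negative")
        if not self.base_matrix.is_complete():
            raise ValueError("base matrix must be complete (no missing cells)")
        if self.base_matrix.n_items != self.bank.version:
            raise ValueError("base matrix does not match the bank")
        n = self.bank.version
        if max(self.r_values) > math.ceil(0.25 * n) + 1:
            import warnings

            warnings.warn(
                f"max r = {max(self.r_values)} exceeds ~25% of the {n} items; "
                "outside the evaluated design range",
                stacklevel=2,
            )
        if self.covariate is not None:
            self.covariate = np.asarray(self.covariate, dtype=float)
            if self.covariate.shape != (self.base_matrix.n_respondents,):
                raise ValueError("covariate length does not match base matrix")


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    if x.size < 3 or np.std(x) == 0 or np.std(y) == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def compute_metrics(
    true_scores: pd.DataFrame,
    imputed_scores: pd.DataFrame,
    covariate: Optional[np.ndarray] = None,
) -> dict[str, float]:
    """One metrics row comparing an imputed score table with the truth.

    Rows whose imputed composite is undefined are excluded pairwise from
    the mean difference, RMSD and correlation, and counted in
    ``n_unimputable``.  Correlations over fewer than 3 defined pairs are
    reported as NaN.
    """
    true_c = true_scores["composite_k"].to_numpy(dtype=float)
    imp_c = imputed_scores["composite_k"].to_numpy(dtype=float)
    if np.isnan(true_c).any():
        raise ValueError("true scores must have a defined composite for every row")
    if true_c.shape != imp_c.shape:
        raise ValueError("score tables are not aligned")

    defined = ~np.isnan(imp_c)
    diff = imp_c[defined] - true_c[defined]
    out: dict[str, float] = {
        "mean_difference": float(diff.mean()) if diff.size else float("nan"),
        "rmsd": float(np.sqrt(np.mean(diff**2))) if diff.size else float("nan"),
        "corr_true": _pearson(imp_c[defined], true_c[defined]),
        "n_unimputable": float((~defined).sum()),
    }
    if covariate is None:
        out["delta_corr_covariate"] = float("nan")
    else:
        cov = np.asarray(covariate, dtype=float)
        base_corr = _pearson(np.log(true_c), cov)
        imp_corr = _pearson(np.log(imp_c[defined]), cov[defined])
        out["delta_corr_covariate"] = imp_corr - base_corr
    return out


# ----------------------------------------------------------------------
# seeding: the removal stream is keyed by (seed, r, iteration) only, so
# every method sees the same degraded dataset within an iteration; the
# random-fill stream is keyed by the method as well.
# ----------------------------------------------------------------------

def _removal_rng(seed: int, r: int, iteration: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, r, iteration]))


def _fill_rng(seed: int, r: int, iteration: int, method: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([seed, r, iteration, METHODS.index(method), 1])
    )


def run_condition(
    config: SimulationConfig,
    method: str,
    r: int,
    true_scores: Optional[pd.DataFrame] = None,
) -> pd.DataFrame:
    """Per-iteration metric rows for one (method, r) condition."""
    method = method.replace("-", "_").lower()
    if true_scores is None:
        true_scores = score_cohort(config.bank, config.base_matrix)
    rows = []
    for it in range(config.iterations):
        degraded = inject_missing(
            config.base_matrix, r, _removal_rng(config.seed, r, it)
        )
        scores, _ = apply_approach(
            degraded,
            config.bank,
            method,
            rng=_fill_rng(config.seed, r, it, method),
            record_fills=False,
        )
        row = compute_metrics(true_scores, scores, config.covariate)
        row.update(method=method, r=r, iteration=it)
        rows.append(row)
    return pd.DataFrame(rows)


def run_study(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full (methods x r_values) grid.

    Returns ``(metrics, archive)``: ``archive`` holds one row per
    (method, r, iteration); ``metrics`` holds the across-iteration mean and
    standard deviation of each measure per condition, plus one ``overall``
    row per method pooling all iterations across r values (unweighted,
    since every r has the same number of iterations).
    """
    true_scores = score_cohort(config.bank, config.base_matrix)
    parts = []
    for method in config.methods:
        for r in config.r_values:
            parts.append(run_condition(config, method, r, true_scores))
    archive = pd.concat(parts, ignore_index=True)

    summaries = []
    for method in config.methods:
        sub_m = archive[archive["method"] == method]
        for r in config.r_values:
            sub = sub_m[sub_m["r"] == r]
            summaries.append(_summarise(sub, method, str(r)))
        summaries.append(_summarise(sub_m, method, "overall"))
    metrics = pd.DataFrame(summaries)
    return metrics, archive


def _summarise(rows: pd.DataFrame, method: str, r_label: str) -> dict:
    out: dict = {"method": method, "r": r_label}
    for name in METRIC_NAMES:
        vals = rows[name].to_numpy(dtype=float)
        out[name] = float(np.nanmean(vals)) if vals.size else float("nan")
        out[f"{name}_sd"] = float(np.nanstd(vals, ddof=1)) if vals.size > 1 else 0.0
    return out


def expected_ggm_failures(n_respondents: int, items_per_set: int, r: int) -> float:
    """Expected respondents unimputable under GGM at removal size ``r``.

    A respondent fails iff every amount set loses at least one response.
    With ``r`` cells removed uniformly without replacement from ``3m``
    items, inclusion-exclusion over the events "set untouched" gives
    ``P = 1 - [3 C(2m, r) - 3 C(m, r)] / C(3m, r)`` (0 for r < 3).
    """
    m = items_per_set
    if not 1 <= r <= 3 * m:
        raise ValueError(f"r must be in [1, {3 * m}], got {r}")
    if n_respondents <= 0:
        raise ValueError("n_respondents must be positive")
    p_fail = 1.0 - (
        3 * math.comb(2 * m, r) - 3 * math.comb(m, r)
    ) / math.comb(3 * m, r)
    return n_respondents * p_fail


def metrics_to_table(metrics: pd.DataFrame, sd_digits: int = 3) -> pd.DataFrame:
    """Reshape a metrics frame into the printed table layout.

    Rows are (measure, method); columns are the r values plus Overall, each
    cell formatted ``mean (sd)``.
    """
    r_labels = [r for r in metrics["r"].unique() if r != "overall"]
    methods = list(dict.fromkeys(metrics["method"]))
    records = []
    for name in METRIC_NAMES:
        for method in methods:
            row = {
                "measure": MEASURE_TITLES[name],
                "method": METHOD_TITLES.get(method, method),
            }
            for label in r_labels + ["overall"]:
                sub = metrics[
                    (metrics["method"] == method) & (metrics["r"] == label)
                ]
                if sub.empty:
                    continue
                mean = sub[name].iloc[0]
                sd = sub[f"{name}_sd"].iloc[0]
                col = "Overall" if label == "overall" else f"r = {label}"
                row[col] = f"{mean:.{sd_digits}g} ({sd:.{sd_digits}g})"
            records.append(row)
    return pd.DataFrame(records)
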