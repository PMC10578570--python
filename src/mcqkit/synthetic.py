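"""Synthetic cohorts of hyperbolic discounters with known true rates.

The generator emulates the study design's raw material — a complete
respondent x item matrix plus an external covariate correlated with ln k —
without any real data.  Each respondent owns a latent log discount rate;
choices follow a logistic rule in ln k with a single inverse-temperature
(noise) parameter, so ``noise_beta = inf`` gives a deterministic chooser
whose pattern switches exactly at their rate.

All defaults are artifact choices (the cohort sizes mirror the 900/512 of
the original datasets); nothing here claims to reproduce any real cohort.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .item_bank import ItemBank
from .responses import ResponseMatrix

__all__ = [
    "SyntheticConfig",
    "default_config",
    "draw_respondents",
    "simulate_responses",
    "inject_missing",
    "generate_cohort",
]

TRUTH_COLUMNS = ["respondent_id", "true_ln_k", "covariate"]


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic-respondent generator."""

    n_respondents: int
    ln_k_mean: float
    ln_k_sd: float
    noise_beta: float = 8.0
    covariate_rho: float = 0.35
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_respondents <= 0:
            raise ValueError("n_respondents must be positive")
        if self.ln_k_sd < 0:
            raise ValueError("ln_k_sd must be non-negative")
        if not -1.0 < self.covariate_rho < 1.0:
            raise ValueError("covariate_rho must lie in (-1, 1)")
        if self.noise_beta < 0:
            raise ValueError("noise_beta must be positive (inf allowed)")


def default_config(bank: ItemBank, seed: int = 0, **overrides) -> SyntheticConfig:
    """Defaults keyed to a bank: cohort size 900 (21-item) or 512 (27-item),
    ln k centred on the middle of the bank's nominal-k ladder with sd of
    three rank spacings (so many respondents sit at or beyond the ladder's
    edges, as real cohorts do), and mild choice noise.  All are artifact
    choices; see the package docs."""
    ladder = np.log(np.sort(np.unique([it.k_nominal for it in bank.items])))
    spacing = float(np.diff(ladder).mean())
    params = dict(
        n_respondents=900 if bank.version == 21 else 512,
        ln_k_mean=float(ladder.mean()),
        ln_k_sd=3.0 * spacing,
        noise_beta=8.0,
        covariate_rho=0.35,
        seed=seed,
    )
    params.update(overrides)
    return SyntheticConfig(**params)


def _check_coverage(config: SyntheticConfig, bank: ItemBank) -> None:
    ladder = np.log(np.sort(np.unique([it.k_nominal for it in bank.items])))
    lo = max(config.ln_k_mean - 2 * config.ln_k_sd, ladder[0])
    hi = min(config.ln_k_mean + 2 * config.ln_k_sd, ladder[-1])
    covered = int(np.sum((ladder[:-1] >= lo) & (ladder[1:] <= hi)))
    if covered < 3:
        warnings.warn(
            f"ln_k_mean +/- 2 sd covers only {covered} rank intervals of the "
            f"{bank.version}-item ladder; estimates will cluster at the edges",
            stacklevel=2,
        )


def draw_respondents(
    config: SyntheticConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Draw latent log rates and a correlated covariate.

    ``true_ln_k ~ Normal(ln_k_mean, ln_k_sd^2)``; the covariate is built
    from the standardised ln k by the bivariate-normal construction
    ``rho * z + sqrt(1 - rho^2) * e`` so its population correlation with
    ln k equals ``covariate_rho``.
    """
    n = config.n_respondents
    z = rng.standard_normal(n)
    true_ln_k = config.ln_k_mean + config.ln_k_sd * z
    rho = config.covariate_rho
    covariate = rho * z + math.sqrt(1.0 - rho * rho) * rng.standard_normal(n)
    return pd.DataFrame(
        {
            "respondent_id": [str(i + 1) for i in range(n)],
            "true_ln_k": true_ln_k,
            "covariate": covariate,
        }
    )


def simulate_responses(
    bank: ItemBank,
    respondents: pd.DataFrame,
    noise_beta: float,
    rng: np.random.Generator,
) -> ResponseMatrix:
    """Complete choice matrix under the logistic-in-ln-k choice rule.

    ``P(delayed) = logistic(noise_beta * (ln k_item - true_ln_k))``: items
    whose k exceeds the respondent's rate attract the delayed choice.  With
    ``noise_beta = inf`` the chooser is deterministic (delayed iff
    ``ln k_item > true_ln_k``).
    """
    ln_k_items = np.log(
        np.array([bank.item(j + 1).k_nominal for j in range(bank.version)])
    )
    true_ln_k = respondents["true_ln_k"].to_numpy()
    margin = ln_k_items[None, :] - true_ln_k[:, None]
    if math.isinf(noise_beta):
        values = (margin > 0).astype(float)
    else:
        with np.errstate(over="ignore"):
            p_delayed = 1.0 / (1.0 + np.exp(-noise_beta * margin))
        values = (rng.random(margin.shape) < p_delayed).astype(float)
    ids = tuple(str(v) for v in respondents["respondent_id"])
    return ResponseMatrix(ids=ids, values=values)


def inject_missing(
    matrix: ResponseMatrix, r: int, rng: np.random.Generator
) -> ResponseMatrix:
    """Blank exactly ``r`` cells per row, uniformly without replacement.

    This is the study's missingness mechanism: a fixed number of responses
    removed completely at random, independently for each respondent.
    """
    n = matrix.n_items
    if not 1 <= r <= n:
        raise ValueError(f"r must be in [1, {n}], got {r}")
    values = matrix.values.copy()
    # uniform r-subset per row: the r smallest of n iid uniforms
    keys = rng.random(values.shape)
    drop = np.argpartition(keys, r - 1, axis=1)[:, :r]
    np.put_along_axis(values, drop, np.nan, axis=1)
    return matrix.with_values(values)


def generate_cohort(
    bank: ItemBank, config: SyntheticConfig
) -> tuple[ResponseMatrix, pd.DataFrame]:
    """Draw respondents and their complete response matrix in one call."""
    _check_coverage(config, bank)
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    respondents = draw_respondents(config, rng)
    matrix = simulate_responses(bank, respondents, config.noise_beta, rng)
    return matrix, respondents
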