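"""Rejection ABC: scenario choice and parameter estimation.

Approximate Bayesian computation in its plainest form. A reference table
is built by drawing scenarios with equal prior probability, drawing
parameters from their priors, simulating one mtDNA sample per draw and
recording its summary statistics. Given an observed summary-statistic
vector, the Euclidean distance is computed after standardizing every
statistic by its reference-table standard deviation; the "direct
approach" model posterior is the per-scenario fraction among the k
closest simulations, and rejection parameter posteriors are the medians
and 2.5/97.5 percentiles of the accepted draws. No regression adjustment
is applied.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .coalescent import (
    SUMMARY_STAT_NAMES,
    ScenarioPriors,
    sample_priors,
    simulate_coalescent,
    summarize_sample,
)

__all__ = [
    "AbcResult",
    "build_reference_table",
    "abc_model_choice",
    "abc_estimate_params",
]

PARAM_COLUMNS = ["ne", "ne_north", "nf", "t1", "t2", "u"]


@dataclass
class AbcResult:
    model_posterior: dict[int, float]
    k: int
    accepted: pd.DataFrame  # the k closest reference rows
    posterior_summaries: pd.DataFrame | None = None  # per-parameter quantiles


def build_reference_table(
    n_sims: int,
    sample_sizes: tuple[int, int] = (50, 50),
    priors: ScenarioPriors = ScenarioPriors(),
    seed: int = 0,
    scenarios: tuple[int, ...] = (1, 2),
) -> pd.DataFrame:
    """Simulate the ABC reference table (one row per simulation).

    Scenarios are drawn with equal prior probability. Columns: scenario,
    the parameter draw, and the summary statistics. Fully reproducible
    given the seed.
    """
    if n_sims < 1:
        raise ValueError("n_sims must be positive")
    rng = np.random.default_rng(seed)
    rows = np.empty((n_sims, 1 + len(PARAM_COLUMNS) + len(SUMMARY_STAT_NAMES)))
    for i in range(n_sims):
        scenario = int(scenarios[rng.integers(len(scenarios))])
        params = sample_priors(scenario, rng, priors)
        sample = simulate_coalescent(params, scenario, sample_sizes, rng, L=priors.L)
        stats = summarize_sample(sample)
        rows[i, 0] = scenario
        rows[i, 1 : 1 + len(PARAM_COLUMNS)] = [
            params.get(c, np.nan) for c in PARAM_COLUMNS
        ]
        rows[i, 1 + len(PARAM_COLUMNS) :] = stats
    return pd.DataFrame(
        rows, columns=["scenario"] + PARAM_COLUMNS + SUMMARY_STAT_NAMES
    )


def _standardized_distances(
    observed: np.ndarray, table: pd.DataFrame
) -> np.ndarray:
    stats = table[SUMMARY_STAT_NAMES].values
    sd = stats.std(axis=0, ddof=1)
    keep = sd > 0
    if not keep.all():
        dropped = [SUMMARY_STAT_NAMES[i] for i in np.flatnonzero(~keep)]
        warnings.warn(f"zero-variance statistics dropped from distance: {dropped}")
    z = (stats[:, keep] - observed[keep]) / sd[keep]
    return np.sqrt((z**2).sum(axis=1))


def abc_model_choice(
    observed: np.ndarray, table: pd.DataFrame, k: int = 500
) -> AbcResult:
    """Direct-approach model choice: scenario frequencies among the k rows
    whose standardized summary statistics are closest to the observation."""
    observed = np.asarray(observed, dtype=float)
    if k > len(table):
        raise ValueError(f"k={k} exceeds reference table size {len(table)}")
    d = _standardized_distances(observed, table)
    idx = np.argsort(d, kind="stable")[:k]
    accepted = table.iloc[idx]
    scen = accepted["scenario"].astype(int)
    posterior = {
        int(s): float((scen == s).mean()) for s in sorted(table["scenario"].unique())
    }
    return AbcResult(model_posterior=posterior, k=k, accepted=accepted)


def abc_estimate_params(
    observed: np.ndarray,
    table: pd.DataFrame,
    scenario: int,
    k: int = 500,
) -> pd.DataFrame:
    """Plain rejection posterior for one scenario's parameters.

    Restricts the reference table to the scenario, takes the k closest
    rows and reports median and the 2.5 / 97.5 percentiles per parameter.
    """
    sub = table[table["scenario"] == scenario]
    if len(sub) < k:
        raise ValueError(
            f"scenario {scenario} has {len(sub)} rows in the table, need >= k={k}"
        )
    observed = np.asarray(observed, dtype=float)
    d = _standardized_distances(observed, sub)
    idx = np.argsort(d, kind="stable")[:k]
    accepted = sub.iloc[idx]
    cols = [c for c in PARAM_COLUMNS if accepted[c].notna().all()]
    out = pd.DataFrame(
        {
            "median": accepted[cols].median(),
            "q2.5": accepted[cols].quantile(0.025),
            "q97.5": accepted[cols].quantile(0.975),
        }
    )
    out.index.name = "parameter"
    return out
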