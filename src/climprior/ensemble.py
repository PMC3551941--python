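"""Ensemble consensus, richness, turnover, range change and the per-cell
two-way ANOVA uncertainty decomposition.

Binary projections from the different modelling methods (and, for the
future, climate scenarios) are combined into a TSS-weighted frequency per
cell; a majority rule (frequency >= 0.5) yields the consensus map. Cellwise
two-way ANOVA without replication on the method x scenario richness table
partitions projection variance into method, scenario and residual sums of
squares; the proportion attributable to the two main effects becomes the
prioritization cost c_i = 1 + proportion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class EnsemblePrediction:
    species_id: str
    scenario_id: str
    frequency: np.ndarray  # (N,), in [0, 1]
    consensus: np.ndarray  # bool (N,): frequency >= threshold


@dataclass
class TurnoverMap:
    richness_current: np.ndarray  # S per cell
    gains: np.ndarray  # G
    losses: np.ndarray  # L
    turnover: np.ndarray  # (G+L)/(S+G), 0 where S+G == 0


@dataclass
class UncertaintyMap:
    ss_method: np.ndarray
    ss_gcm: np.ndarray
    ss_residual: np.ndarray
    ss_total: np.ndarray
    proportion: np.ndarray  # uncertainty proportion in [0, 1]
    cost: np.ndarray  # c_i = 1 + proportion


def ensemble_frequency(
    binaries: np.ndarray, tss_weights: np.ndarray
) -> np.ndarray:
    """TSS-weighted model frequency per cell.

    ``binaries`` is (M, N) of 0/1 predictions, ``tss_weights`` (M,). Models
    with TSS <= 0 are clamped to weight 0 (worse-than-random models do not
    vote); if no model has positive skill the ensemble is undefined.
    """
    binaries = np.asarray(binaries, dtype=float)
    w = np.clip(np.asarray(tss_weights, dtype=float), 0.0, None)
    if binaries.ndim != 2 or w.shape != (binaries.shape[0],):
        raise ValueError("binaries must be (M, N) with one weight per model")
    total = w.sum()
    if total <= 0:
        raise ValueError("no skillful models: all TSS weights <= 0")
    return (w @ binaries) / total


def consensus_map(frequency: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Majority consensus: presence where frequency >= threshold (inclusive)."""
    frequency = np.asarray(frequency, dtype=float)
    if frequency.min() < -1e-12 or frequency.max() > 1 + 1e-12:
        raise ValueError("frequency must lie in [0, 1]")
    return frequency >= threshold


def richness(consensus_by_species: np.ndarray) -> np.ndarray:
    """Cellwise species richness from an (S, N) stack of binary maps."""
    stack = np.asarray(consensus_by_species)
    if stack.ndim != 2:
        raise ValueError("expected an (S, N) stack of binary maps")
    return stack.astype(int).sum(axis=0)


def turnover(current: np.ndarray, future: np.ndarray) -> TurnoverMap:
    """Per-cell species turnover (G + L) / (S + G).

    ``current`` and ``future`` are (S, N) boolean occupancy stacks. Cells
    with S + G = 0 (nothing there in either period) get turnover 0.
    """
    current = np.asarray(current).astype(bool)
    future = np.asarray(future).astype(bool)
    if current.shape != future.shape:
        raise ValueError("current and future stacks must share shape")
    s = current.sum(axis=0)
    g = (future & ~current).sum(axis=0)
    losses = (current & ~future).sum(axis=0)
    denom = s + g
    value = np.divide(g + losses, denom, out=np.zeros(denom.shape, float),
                      where=denom > 0)
    return TurnoverMap(s, g, losses, value)


def uncertainty_anova(
    richness_stack: np.ndarray,
    numerator: str = "main_effects",
) -> UncertaintyMap:
    """Cellwise two-way ANOVA without replication on richness.

    ``richness_stack`` has shape (M, K, N): M modelling methods x K climate
    scenarios, one richness value per cell. Sums of squares:

        SS_method   = K * sum_m (rowmean_m - grand)^2
        SS_gcm      = M * sum_k (colmean_k - grand)^2
        SS_residual = sum_mk (x_mk - rowmean_m - colmean_k + grand)^2

    so that SS_method + SS_gcm + SS_residual = SS_total identically.

    The uncertainty proportion is (SS_method + SS_gcm) / SS_total (or with
    the residual included when ``numerator='main_plus_interaction'``); cells
    with SS_total = 0 get proportion 0. Cost = 1 + proportion.
    """
    x = np.asarray(richness_stack, dtype=float)
    if x.ndim != 3 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("richness_stack must be (M, K, N) with M, K >= 2")
    if not np.isfinite(x).all():
        raise ValueError("missing (method, gcm) combination in richness stack")
    m, k, _ = x.shape
    grand = x.mean(axis=(0, 1))
    row_means = x.mean(axis=1)  # (M, N)
    col_means = x.mean(axis=0)  # (K, N)
    ss_method = k * ((row_means - grand) ** 2).sum(axis=0)
    ss_gcm = m * ((col_means - grand) ** 2).sum(axis=0)
    # residual from the interaction deviations directly: exact zero (not
    # subtraction crumbs) for tables with pure main effects
    interaction = x - row_means[:, None, :] - col_means[None, :, :] + grand
    ss_residual = (interaction**2).sum(axis=(0, 1))
    ss_total = ss_method + ss_gcm + ss_residual
    if numerator == "main_effects":
        num = ss_method + ss_gcm
    elif numerator == "main_plus_interaction":
        num = ss_method + ss_gcm + ss_residual
    else:
        raise ValueError(f"unknown ANOVA numerator rule {numerator!r}")
    proportion = np.divide(num, ss_total, out=np.zeros_like(ss_total),
                           where=ss_total > 0)
    proportion = np.clip(proportion, 0.0, 1.0)
    return UncertaintyMap(ss_method, ss_gcm, ss_residual, ss_total,
                          proportion, 1.0 + proportion)


def range_change_summary(
    current_consensus: np.ndarray,
    future_consensus: np.ndarray,
    species_ids: list[str],
) -> tuple[pd.DataFrame, dict]:
    """Per-species range change between consensus maps, plus cohort stats.

    Contraction% = 100 * (A_now - A_fut) / A_now for species present at
    baseline (negative values are expansions); a species with empty future
    consensus range is flagged regionally extinct. Species absent at
    baseline are flagged and excluded from the contraction statistics.
    """
    cur = np.asarray(current_consensus).astype(bool)
    fut = np.asarray(future_consensus).astype(bool)
    a_now = cur.sum(axis=1)
    a_fut = fut.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        contraction = np.where(a_now > 0, 100.0 * (a_now - a_fut) / np.maximum(a_now, 1), np.nan)
    df = pd.DataFrame(
        {
            "species_id": species_ids,
            "cells_current": a_now,
            "cells_future": a_fut,
            "contraction_pct": contraction,
            "regionally_extinct": (a_fut == 0) & (a_now > 0),
            "absent_at_baseline": a_now == 0,
        }
    )
    valid = df[~df.absent_at_baseline]
    summary = {
        "n_species": int(len(df)),
        "n_baseline_present": int(len(valid)),
        "mean_contraction_pct": float(valid.contraction_pct.mean()) if len(valid) else float("nan"),
        "sd_contraction_pct": float(valid.contraction_pct.std()) if len(valid) else float("nan"),
        "max_contraction_pct": float(valid.contraction_pct.max()) if len(valid) else float("nan"),
        "pct_extinct": float(100.0 * valid.regionally_extinct.mean()) if len(valid) else float("nan"),
    }
    return df, summary
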