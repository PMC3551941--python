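"""Greedy reverse-elimination site ranking (mini-Zonation).

Starting from the full landscape, the algorithm repeatedly removes the
unlocked cell whose loss would least reduce total conservation value and
records the removal order; the last cells standing are the top priorities.
Two marginal-loss rules are provided:

* ``basic`` (core-area): delta_i = max_j w_j q_ij / (c_i Q_j(S)) — a cell is
  as valuable as its single most-dependent feature;
* ``abf`` (additive benefit function): delta_i = (1/c_i) sum_j w_j
  [V(Q_j(S)) - V(Q_j(S) - q_ij)] with concave benefit V(Q) = Q^z — rewards
  cells carrying many features, with diminishing returns per feature.

Here q_ij is feature j's representation in cell i (normalized to sum 1 over
the landscape), w_j its weight, c_i the cell's cost and Q_j(S) the fraction
of feature j remaining in the surviving set S. Locked (protected) cells are
never candidates for removal and end up holding the top ranks; their
feature content still counts toward Q_j throughout.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .grid import IUCN_WEIGHTS, SpeciesRecord


@dataclass
class ConservationFeature:
    """One feature (a species or e.g. vegetation) with weight and q_ij layer."""

    feature_id: str
    weight: float
    q: np.ndarray  # (N,), >= 0, sums to 1 after build_problem

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        if self.weight <= 0:
            raise ValueError(f"feature {self.feature_id!r}: weight must be > 0")
        if (self.q < 0).any():
            raise ValueError(f"feature {self.feature_id!r}: q values must be >= 0")


@dataclass
class PrioritizationProblem:
    features: list[ConservationFeature]
    cost: np.ndarray  # (N,), >= 1
    locked: np.ndarray  # bool (N,)
    rule: str = "abf"
    z: float = 0.25

    @property
    def n_cells(self) -> int:
        return self.cost.size

    def q_matrix(self) -> np.ndarray:
        return np.stack([f.q for f in self.features], axis=1)  # (N, F)

    def weights(self) -> np.ndarray:
        return np.array([f.weight for f in self.features])


@dataclass
class PrioritizerState:
    """Remaining set and per-feature remaining fractions during ranking."""

    remaining: np.ndarray  # bool (N,)
    Q: np.ndarray  # (F,)


@dataclass
class RankResult:
    removal_order: np.ndarray  # cell ids, first-removed (worst) first; locked last
    rank_fraction: np.ndarray  # (N,): (position+1)/N, 1 = best
    locked: np.ndarray
    feature_ids: list[str]
    # performance curves: landscape fraction remaining at each step (before
    # any removal down to locked-only), and Q_j at those steps
    curve_landscape: np.ndarray = field(repr=False)  # (steps+1,)
    curve_features: np.ndarray = field(repr=False)  # (steps+1, F)
    curve_mean: np.ndarray = field(repr=False)  # (steps+1,)


def build_problem(
    feature_layers: dict[str, np.ndarray],
    species: list[SpeciesRecord] | None = None,
    cost: np.ndarray | None = None,
    locked: np.ndarray | None = None,
    extra_weights: dict[str, float] | None = None,
    rule: str = "abf",
    z: float = 0.25,
) -> PrioritizationProblem:
    """Assemble and validate a prioritization problem.

    Feature layers are normalized to sum 1. Species features get IUCN
    weights from ``species``; other features (e.g. ``vegetation``) take
    their weight from ``extra_weights`` (default 1). A missing cost layer
    defaults to c_i = 1 everywhere.
    """
    by_species = {s.species_id: s for s in (species or [])}
    features = []
    n = None
    for fid, layer in feature_layers.items():
        layer = np.asarray(layer, dtype=float)
        n = layer.size if n is None else n
        if layer.size != n:
            raise ValueError("feature layers must share one domain")
        total = layer.sum()
        if total <= 0:
            raise ValueError(f"empty feature {fid!r}: total representation is 0")
        if fid in by_species:
            weight = IUCN_WEIGHTS[by_species[fid].iucn_category]
        else:
            weight = (extra_weights or {}).get(fid, 1.0)
        features.append(ConservationFeature(fid, weight, layer / total))
    if not features:
        raise ValueError("no features given")
    cost = np.ones(n) if cost is None else np.asarray(cost, dtype=float)
    if cost.size != n:
        raise ValueError("cost layer does not match feature domain")
    if (cost <= 0).any():
        raise ValueError("costs must be positive")
    locked = np.zeros(n, bool) if locked is None else np.asarray(locked).astype(bool)
    if locked.size != n:
        raise ValueError("locked mask does not match feature domain")
    if rule not in {"basic", "abf"}:
        raise ValueError(f"unknown rule {rule!r}")
    if z <= 0:
        raise ValueError("benefit exponent z must be > 0")
    return PrioritizationProblem(features, cost, locked, rule=rule, z=z)


def marginal_loss_basic(
    cell: int, state: PrioritizerState, problem: PrioritizationProblem
) -> float:
    """Core-area marginal loss: max_j w_j q_ij / (c_i Q_j(S))."""
    q = problem.q_matrix()[cell]
    w = problem.weights()
    Q = state.Q
    if ((Q <= 0) & (q > 0)).any():
        raise AssertionError("invariant violation: q_ij > 0 with Q_j(S) = 0")
    terms = np.divide(w * q, Q, out=np.zeros_like(Q), where=Q > 0)
    return float(terms.max() / problem.cost[cell])


def marginal_loss_abf(
    cell: int, state: PrioritizerState, problem: PrioritizationProblem
) -> float:
    """Additive-benefit marginal loss with V(Q) = Q^z."""
    q = problem.q_matrix()[cell]
    Q = state.Q
    if ((Q - q) < -1e-12).any():
        raise AssertionError("invariant violation: Q_j(S) - q_ij < 0")
    z = problem.z
    v_now = Q**z
    v_without = np.clip(Q - q, 0.0, None) ** z
    return float((problem.weights() * (v_now - v_without)).sum() / problem.cost[cell])


def _delta_all(
    q: np.ndarray, w: np.ndarray, cost: np.ndarray, Q: np.ndarray,
    rule: str, z: float,
) -> np.ndarray:
    """Vectorized marginal loss for every cell (rows of q)."""
    if rule == "basic":
        terms = np.divide(q * w, Q, out=np.zeros_like(q), where=Q > 0)
        return terms.max(axis=1) / cost
    v_now = Q**z
    v_without = np.clip(Q - q, 0.0, None) ** z
    return ((v_now - v_without) * w).sum(axis=1) / cost


def rank_cells(problem: PrioritizationProblem) -> RankResult:
    """Exact greedy ranking: full marginal-loss recomputation each step.

    Ties in delta are broken toward the lower cell id. Locked cells receive
    the top |locked| rank positions, internally ordered by their marginal
    loss at termination (highest delta = best rank).
    """
    q = problem.q_matrix()
    w = problem.weights()
    cost = problem.cost
    locked = problem.locked
    n, f = q.shape
    remaining = np.ones(n, bool)
    Q = q.sum(axis=0)
    n_unlocked = int((~locked).sum())

    order = np.empty(n, dtype=np.int64)
    curve_land = [1.0]
    curve_feat = [Q.copy()]
    candidate = ~locked  # removable cells still present
    for step in range(n_unlocked):
        idx = np.nonzero(candidate)[0]  # ascending cell id
        delta = _delta_all(q[idx], w, cost[idx], Q, problem.rule, problem.z)
        pick = idx[int(np.argmin(delta))]  # first minimum -> lowest cell id
        order[step] = pick
        candidate[pick] = False
        remaining[pick] = False
        Q = np.clip(Q - q[pick], 0.0, None)
        curve_land.append((n - step - 1) / n)
        curve_feat.append(Q.copy())

    # locked cells: top ranks, ordered by terminal delta ascending so the
    # highest-delta locked cell lands in the final (best) position
    locked_ids = np.nonzero(locked)[0]
    if locked_ids.size:
        delta_locked = _delta_all(q[locked_ids], w, cost[locked_ids], Q,
                                  problem.rule, problem.z)
        locked_sorted = locked_ids[np.lexsort((locked_ids, delta_locked))]
        order[n_unlocked:] = locked_sorted

    rank_fraction = np.empty(n)
    rank_fraction[order] = (np.arange(n) + 1) / n
    curve_feat = np.vstack(curve_feat)
    wn = w / w.sum()
    return RankResult(
        removal_order=order,
        rank_fraction=rank_fraction,
        locked=locked.copy(),
        feature_ids=[ft.feature_id for ft in problem.features],
        curve_landscape=np.array(curve_land),
        curve_features=curve_feat,
        curve_mean=curve_feat @ wn,
    )


def performance_curves(result: RankResult) -> dict[str, np.ndarray]:
    """Curve arrays keyed for tabular export."""
    out = {"landscape_fraction": result.curve_landscape,
           "mean_feature_fraction": result.curve_mean}
    for j, fid in enumerate(result.feature_ids):
        out[f"feature:{fid}"] = result.curve_features[:, j]
    return out


@dataclass
class CoverageReport:
    fraction: float
    n_cells: int
    n_selected: int
    n_locked_selected: int
    n_additional: int
    additional_pct: float  # 100 * |selected \ locked| / N
    target_met_by_existing: bool


def top_fraction(
    result: RankResult, fraction: float = 0.17
) -> tuple[np.ndarray, CoverageReport]:
    """Select the best-ranked ``fraction`` of cells and report the extra
    protection needed beyond the locked network.

    The selection size is round-half-up(fraction * N). The additional-
    protection percentage is the share of the landscape selected but not
    already protected.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    n = result.rank_fraction.size
    n_top = int(math.floor(fraction * n + 0.5))
    selected_ids = result.removal_order[n - n_top:]
    selected = np.zeros(n, bool)
    selected[selected_ids] = True
    n_locked = int(result.locked.sum())
    if n_top < n_locked:
        warnings.warn(
            "coverage target is smaller than the locked protected network; "
            "target met by existing protection",
            stacklevel=2,
        )
    n_additional = int((selected & ~result.locked).sum())
    report = CoverageReport(
        fraction=fraction,
        n_cells=n,
        n_selected=n_top,
        n_locked_selected=int((selected & result.locked).sum()),
        n_additional=n_additional,
        additional_pct=100.0 * n_additional / n,
        target_met_by_existing=n_top < n_locked,
    )
    return selected, report
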