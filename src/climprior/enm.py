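"""Niche models: calibration splits, pseudo-absence selection, suitability
methods, ROC thresholding and the True Skill Statistic.

For each species the labelled data are its presence cells plus an equal
number of pseudo-absence cells drawn from outside the 95% per-variable
bioclimatic envelope of the presences. Data are split 75/25 into
calibration and validation, stratified by label, 50 times; each repetition
fits every registered suitability method on the current climate, picks the
threshold maximizing sensitivity + specificity on the validation cells, and
projects the fitted model (same threshold) onto every scenario's climate.
Per-(species, method, scenario) binaries are the majority vote across
repetitions; the method's skill is its mean validation TSS.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression

from ._rng import substream
from .grid import ClimateLayerSet, OccupancyMatrix, SpeciesRecord


class DegenerateRangeError(ValueError):
    """Species has too few presence cells to model."""


@dataclass(frozen=True)
class CalibrationSplit:
    """One 75/25 stratified partition of the labelled cells."""

    rep_index: int
    calibration_cells: np.ndarray  # cell ids
    calibration_labels: np.ndarray  # 0/1
    validation_cells: np.ndarray
    validation_labels: np.ndarray


@dataclass(frozen=True)
class ModelEvaluation:
    sensitivity: float
    specificity: float
    tss: float
    threshold: float


@dataclass
class BinaryProjection:
    species_id: str
    method_id: str
    scenario_id: str
    rep_index: int
    prediction: np.ndarray  # bool, (N,)
    evaluation: ModelEvaluation


def select_pseudo_absences(
    presence_cells: np.ndarray,
    climate_values: np.ndarray,
    envelope_pct: float = 95.0,
) -> np.ndarray:
    """Cells outside the presences' per-variable percentile envelope.

    The envelope is the box [(100-p)/2, 100-(100-p)/2] percentile of the
    presence cells' climate, per variable; any cell falling outside the box
    in at least one variable — and not itself a presence — is a candidate
    pseudo-absence.
    """
    presence_cells = np.asarray(presence_cells)
    if presence_cells.size < 2:
        raise DegenerateRangeError(
            f"degenerate range: {presence_cells.size} presence cell(s), need >= 2"
        )
    if not 0 < envelope_pct < 100:
        raise ValueError("envelope_pct must be in (0, 100)")
    tail = (100.0 - envelope_pct) / 2.0
    pres_climate = climate_values[presence_cells]
    lo = np.percentile(pres_climate, tail, axis=0)
    hi = np.percentile(pres_climate, 100.0 - tail, axis=0)
    outside = ((climate_values < lo) | (climate_values > hi)).any(axis=1)
    outside[presence_cells] = False
    return np.nonzero(outside)[0]


def make_splits(
    cells: np.ndarray,
    labels: np.ndarray,
    frac: float = 0.75,
    n_reps: int = 50,
    seed: int = 0,
) -> list[CalibrationSplit]:
    """Stratified random calibration/validation splits, seeded.

    Each repetition puts round(frac * n) of each class into calibration,
    preserving the observed prevalence up to rounding.
    """
    cells = np.asarray(cells)
    labels = np.asarray(labels)
    if not 0 < frac < 1:
        raise ValueError("frac must be in (0, 1)")
    pres = cells[labels == 1]
    absn = cells[labels == 0]
    if pres.size < 2 or absn.size < 2:
        raise ValueError(
            f"need >= 2 presences and >= 2 absences, got {pres.size}/{absn.size}"
        )
    n_cal_p = int(round(frac * pres.size))
    n_cal_a = int(round(frac * absn.size))
    # keep both partitions non-empty in each class
    n_cal_p = min(max(n_cal_p, 1), pres.size - 1)
    n_cal_a = min(max(n_cal_a, 1), absn.size - 1)
    rng = substream(seed, "splits")
    splits = []
    for rep in range(n_reps):
        pp = rng.permutation(pres)
        aa = rng.permutation(absn)
        cal_c = np.concatenate([pp[:n_cal_p], aa[:n_cal_a]])
        cal_y = np.concatenate([np.ones(n_cal_p, int), np.zeros(n_cal_a, int)])
        val_c = np.concatenate([pp[n_cal_p:], aa[n_cal_a:]])
        val_y = np.concatenate(
            [np.ones(pres.size - n_cal_p, int), np.zeros(absn.size - n_cal_a, int)]
        )
        splits.append(CalibrationSplit(rep, cal_c, cal_y, val_c, val_y))
    return splits


def compute_tss(predicted: np.ndarray, observed: np.ndarray,
                threshold: float = math.nan) -> ModelEvaluation:
    """Sensitivity, specificity and TSS = sens + spec - 1 of a binary map."""
    predicted = np.asarray(predicted).astype(bool)
    observed = np.asarray(observed).astype(bool)
    if predicted.shape != observed.shape:
        raise ValueError("predicted and observed must have the same length")
    n_pres = observed.sum()
    n_abs = (~observed).sum()
    if n_pres == 0 or n_abs == 0:
        raise ValueError("observed labels must contain both classes")
    sens = float((predicted & observed).sum() / n_pres)
    spec = float((~predicted & ~observed).sum() / n_abs)
    return ModelEvaluation(sens, spec, sens + spec - 1.0, threshold)


def binarize(
    suitability: np.ndarray, labels: np.ndarray
) -> tuple[float, ModelEvaluation]:
    """ROC-style threshold choice: among observed suitability values, pick
    the one maximizing sensitivity + specificity (prediction = suit >= t);
    ties go to the lower threshold."""
    suitability = np.asarray(suitability, dtype=float)
    labels = np.asarray(labels).astype(bool)
    if labels.all() or not labels.any():
        raise ValueError("validation labels must contain both classes")
    candidates = np.unique(suitability)
    best_t, best_eval = None, None
    for t in candidates:  # ascending; strict > keeps the lower threshold on ties
        ev = compute_tss(suitability >= t, labels, threshold=float(t))
        if best_eval is None or ev.tss > best_eval.tss + 1e-12:
            best_t, best_eval = float(t), ev
    return best_t, best_eval


# ---------------------------------------------------------------------------
# Suitability methods


class SuitabilityMethod:
    """fit(X, y) -> self; predict(X) -> suitability in [0, 1] per row.

    Presence-only methods ignore the absence rows of ``y``.
    """

    method_id: str = "base"

    def fit(self, X: np.ndarray, y: np.ndarray) -> "SuitabilityMethod":
        raise NotImplementedError

    def predict(self, X: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class BioclimEnvelope(SuitabilityMethod):
    """Percentile bioclimatic envelope (presence-only).

    A cell's score per variable is twice the smaller tail percentile rank of
    its value within the calibration presences (1 at the presence median,
    0 outside the presence range); suitability is the minimum over variables.
    """

    method_id = "envelope"

    def fit(self, X, y):
        self._pres = np.sort(np.asarray(X, float)[np.asarray(y) == 1], axis=0)
        return self

    def predict(self, X):
        X = np.asarray(X, float)
        n = self._pres.shape[0]
        scores = np.empty_like(X)
        for k in range(X.shape[1]):
            col = self._pres[:, k]
            # mid-rank percentile of each value within the presence sample
            lo = np.searchsorted(col, X[:, k], side="left")
            hi = np.searchsorted(col, X[:, k], side="right")
            p = (lo + hi) / (2.0 * n)
            scores[:, k] = 2.0 * np.minimum(p, 1.0 - p)
        return np.clip(scores.min(axis=1), 0.0, 1.0)


class RegularizedLogistic(SuitabilityMethod):
    """L2-regularized logistic regression on standardized climate plus
    squared terms (a curved presence/absence response surface)."""

    method_id = "logistic"

    def fit(self, X, y):
        X = np.asarray(X, float)
        self._mean = X.mean(axis=0)
        sd = X.std(axis=0)
        self._sd = np.where(sd > 0, sd, 1.0)
        self._model = LogisticRegression(C=1.0, max_iter=500)
        self._model.fit(self._design(X), np.asarray(y).astype(int))
        return self

    def _design(self, X):
        Z = (np.asarray(X, float) - self._mean) / self._sd
        return np.hstack([Z, Z**2])

    def predict(self, X):
        return self._model.predict_proba(self._design(X))[:, 1]


class ClimateDistance(SuitabilityMethod):
    """Suitability = 1 - scaled distance to the presence climate centroid
    (presence-only). Distances are scaled by the presences' per-variable SD
    and hit zero at ``d0`` scaled units."""

    method_id = "distance"

    def __init__(self, d0: float = 3.0):
        self.d0 = d0

    def fit(self, X, y):
        pres = np.asarray(X, float)[np.asarray(y) == 1]
        self._center = pres.mean(axis=0)
        sd = pres.std(axis=0)
        self._scale = np.where(sd > 0, sd, 1.0)
        return self

    def predict(self, X):
        Z = (np.asarray(X, float) - self._center) / self._scale
        d = np.sqrt((Z**2).mean(axis=1))
        return np.clip(1.0 - d / self.d0, 0.0, 1.0)


METHODS: dict[str, type[SuitabilityMethod] | object] = {
    "envelope": BioclimEnvelope,
    "logistic": RegularizedLogistic,
    "distance": ClimateDistance,
}


def get_method(method_id: str) -> SuitabilityMethod:
    try:
        factory = METHODS[method_id]
    except KeyError:
        raise KeyError(f"unknown suitability method {method_id!r}") from None
    return factory() if isinstance(factory, type) else factory


def _checked_predict(method: SuitabilityMethod, X: np.ndarray) -> np.ndarray:
    suit = np.asarray(method.predict(X), dtype=float)
    if suit.min() < -1e-9 or suit.max() > 1 + 1e-9:
        raise ValueError(
            f"method {method.method_id!r} violated the [0, 1] suitability contract"
        )
    return np.clip(suit, 0.0, 1.0)


def fit_and_project(
    species_id: str,
    method_id: str,
    split: CalibrationSplit,
    climate_by_scenario: dict[str, ClimateLayerSet],
) -> list[BinaryProjection]:
    """Fit one method on one split and project it to every scenario.

    The threshold is fitted once, on the current-climate validation cells,
    and reused for all scenarios (model-transferability assumption).
    """
    current = climate_by_scenario["current"]
    method = get_method(method_id)
    method.fit(current.values[split.calibration_cells], split.calibration_labels)
    val_suit = _checked_predict(method, current.values[split.validation_cells])
    threshold, evaluation = binarize(val_suit, split.validation_labels)
    out = []
    for scenario_id, clim in climate_by_scenario.items():
        suit = _checked_predict(method, clim.values)
        out.append(
            BinaryProjection(
                species_id, method_id, scenario_id, split.rep_index,
                suit >= threshold, evaluation,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Species-level driver


@dataclass
class ENMResult:
    """Majority-vote binaries and skill scores for the whole assemblage.

    ``binaries[(species_id, method_id, scenario_id)]`` is the boolean (N,)
    prediction after the across-repetition vote; ``tss[(species_id,
    method_id)]`` the mean validation TSS; ``evaluations`` the per-repetition
    table (species, method, rep, sensitivity, specificity, tss, threshold).
    """

    binaries: dict[tuple[str, str, str], np.ndarray]
    tss: dict[tuple[str, str], float]
    evaluations: pd.DataFrame


def build_labelled_cells(
    presence_cells: np.ndarray,
    climate_current: ClimateLayerSet,
    occupancy_row: np.ndarray,
    envelope_pct: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Presences plus an equal number of seeded pseudo-absences (1:1).

    Pseudo-absences come from outside the presences' bioclimatic envelope;
    if that pool is too small, unoccupied in-envelope cells top it up.
    """
    pseudo_pool = select_pseudo_absences(
        presence_cells, climate_current.values, envelope_pct
    )
    n_abs = presence_cells.size
    if pseudo_pool.size >= n_abs:
        absences = rng.choice(pseudo_pool, size=n_abs, replace=False)
    else:
        unoccupied = np.nonzero(occupancy_row == 0)[0]
        extra_pool = np.setdiff1d(unoccupied, pseudo_pool)
        need = min(n_abs - pseudo_pool.size, extra_pool.size)
        extra = rng.choice(extra_pool, size=need, replace=False) if need else np.array([], int)
        absences = np.concatenate([pseudo_pool, extra]).astype(int)
    if absences.size < 2:
        raise DegenerateRangeError(
            "cannot assemble an absence sample: envelope covers the whole domain"
        )
    cells = np.concatenate([presence_cells, absences])
    labels = np.concatenate([np.ones(presence_cells.size, int), np.zeros(absences.size, int)])
    return cells, labels


def run_enm(
    occupancy_current: OccupancyMatrix,
    climate_by_scenario: dict[str, ClimateLayerSet],
    species: list[SpeciesRecord],
    methods: list[str] = ("envelope", "logistic", "distance"),
    n_reps: int = 50,
    calib_frac: float = 0.75,
    envelope_pct: float = 95.0,
    seed: int = 0,
) -> ENMResult:
    """Full ENM stage over all species, methods and repetitions."""
    binaries: dict[tuple[str, str, str], np.ndarray] = {}
    tss: dict[tuple[str, str], float] = {}
    rows = []
    climate_current = climate_by_scenario["current"]
    n_cells = climate_current.domain.n_cells
    for sp in species:
        occ_row = occupancy_current.row(sp.species_id)
        presence_cells = np.nonzero(occ_row)[0]
        rng = substream(seed, "enm", sp.species_id)
        cells, labels = build_labelled_cells(
            presence_cells, climate_current, occ_row, envelope_pct, rng
        )
        splits = make_splits(
            cells, labels, frac=calib_frac, n_reps=n_reps,
            seed=int(rng.integers(2**31)),
        )
        for method_id in methods:
            votes = {scn: np.zeros(n_cells, int) for scn in climate_by_scenario}
            tss_sum = 0.0
            for split in splits:
                projections = fit_and_project(
                    sp.species_id, method_id, split, climate_by_scenario
                )
                for proj in projections:
                    votes[proj.scenario_id] += proj.prediction
                ev = projections[0].evaluation
                tss_sum += ev.tss
                rows.append(
                    (sp.species_id, method_id, split.rep_index,
                     ev.sensitivity, ev.specificity, ev.tss, ev.threshold)
                )
            for scn, v in votes.items():
                binaries[(sp.species_id, method_id, scn)] = v * 2 >= n_reps
            tss[(sp.species_id, method_id)] = tss_sum / n_reps
    evaluations = pd.DataFrame(
        rows,
        columns=["species_id", "method_id", "rep", "sensitivity",
                 "specificity", "tss", "threshold"],
    )
    return ENMResult(binaries=binaries, tss=tss, evaluations=evaluations)
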