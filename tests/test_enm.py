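import numpy as np
import pytest

from climprior.enm import (
    DegenerateRangeError,
    binarize,
    compute_tss,
    fit_and_project,
    get_method,
    make_splits,
    select_pseudo_absences,
    CalibrationSplit,
)
from climprior.grid import ClimateLayerSet, rasterize_domain


def _climate_1d(temps):
    """Single-variable toy embedded in the 4-variable layout (other
    variables constant so they never leave any envelope)."""
    values = np.zeros((len(temps), 4))
    values[:, 0] = temps
    return values


class TestPseudoAbsences:
    def test_percentile_box_excludes_tails_only(self):
        # presences with temp 1..100; candidates 0, 50, 200 at ids 100..102
        temps = np.concatenate([np.arange(1.0, 101.0), [0.0, 50.0, 200.0]])
        climate = _climate_1d(temps)
        chosen = select_pseudo_absences(np.arange(100), climate, 95.0)
        assert set(chosen) == {100, 102}  # 0 and 200 are outside the box

    def test_full_envelope_leaves_no_pseudo_absences(self):
        temps = np.array([1.0, 2.0, 3.0, 2.0, 1.5])
        chosen = select_pseudo_absences(
            np.arange(5), _climate_1d(temps), 99.999
        )
        assert chosen.size == 0

    def test_cell_matching_presence_climate_never_selected(self):
        temps = np.array([1.0, 2.0, 3.0, 2.0])  # id 3 equals a presence value
        chosen = select_pseudo_absences(np.arange(3), _climate_1d(temps), 95.0)
        assert 3 not in chosen

    def test_single_presence_is_degenerate(self):
        with pytest.raises(DegenerateRangeError):
            select_pseudo_absences(np.array([0]), _climate_1d([1.0, 2.0]), 95.0)


class TestSplits:
    def test_calibration_takes_75_percent(self):
        cells = np.arange(120)
        labels = np.concatenate([np.ones(100, int), np.zeros(20, int)])
        (split,) = make_splits(cells, labels, frac=0.75, n_reps=1, seed=0)
        assert (split.calibration_labels == 1).sum() == 75
        assert (split.validation_labels == 1).sum() == 25

    def test_prevalence_is_preserved_in_both_partitions(self):
        cells = np.arange(100)
        labels = (cells < 20).astype(int)  # prevalence 0.2
        (split,) = make_splits(cells, labels, frac=0.75, n_reps=1, seed=0)
        assert split.calibration_labels.mean() == pytest.approx(0.2)
        assert split.validation_labels.mean() == pytest.approx(0.2)

    def test_partitions_are_disjoint_and_cover(self):
        cells = np.arange(40)
        labels = (cells % 3 == 0).astype(int)
        for split in make_splits(cells, labels, n_reps=5, seed=1):
            union = np.concatenate([split.calibration_cells, split.validation_cells])
            assert sorted(union) == list(cells)

    def test_same_seed_identical_splits(self):
        cells = np.arange(50)
        labels = (cells < 10).astype(int)
        a = make_splits(cells, labels, n_reps=3, seed=7)
        b = make_splits(cells, labels, n_reps=3, seed=7)
        for x, y in zip(a, b):
            assert (x.calibration_cells == y.calibration_cells).all()

    def test_too_few_labelled_cells_rejected(self):
        with pytest.raises(ValueError):
            make_splits(np.arange(3), np.array([1, 0, 0]), n_reps=1, seed=0)


class TestTss:
    def test_worked_confusion_matrix(self):
        obs = np.concatenate([np.ones(50), np.zeros(50)]).astype(bool)
        pred = np.concatenate([np.ones(40), np.zeros(10), np.ones(15), np.zeros(35)]).astype(bool)
        ev = compute_tss(pred, obs)
        assert ev.sensitivity == pytest.approx(0.8)
        assert ev.specificity == pytest.approx(0.7)
        assert ev.tss == pytest.approx(0.5)

    def test_perfect_and_inverted_predictions(self):
        obs = np.array([1, 1, 0, 0], bool)
        assert compute_tss(obs, obs).tss == 1.0
        assert compute_tss(~obs, obs).tss == -1.0

    def test_prevalence_invariance_under_absence_duplication(self, rng):
        obs = rng.random(60) < 0.3
        obs[:2] = [True, False]
        pred = obs ^ (rng.random(60) < 0.2)
        base = compute_tss(pred, obs).tss
        dup = np.concatenate([np.arange(60), np.nonzero(~obs)[0]])
        assert compute_tss(pred[dup], obs[dup]).tss == pytest.approx(base)

    def test_single_class_observations_rejected(self):
        with pytest.raises(ValueError):
            compute_tss(np.array([1, 0], bool), np.array([1, 1], bool))


class TestBinarize:
    def test_separable_suitabilities_give_tss_one(self):
        suit = np.array([0.9, 0.8, 0.4, 0.1])
        labels = np.array([1, 1, 0, 0])
        t, ev = binarize(suit, labels)
        assert ev.tss == 1.0
        assert t == pytest.approx(0.8)  # maximizing observed value, low-tie rule

    def test_constant_suitability_degenerates_gracefully(self):
        t, ev = binarize(np.full(6, 0.5), np.array([1, 1, 0, 0, 0, 1]))
        assert t == 0.5
        assert ev.sensitivity == 1.0 and ev.specificity == 0.0
        assert ev.tss == 0.0

    def test_threshold_is_optimal_by_enumeration(self, rng):
        for _ in range(100):
            n = int(rng.integers(6, 25))
            labels = rng.integers(0, 2, n)
            if labels.sum() in (0, n):
                labels[0], labels[1] = 0, 1
            suit = np.round(rng.random(n), 2)
            t, ev = binarize(suit, labels)
            best = max(
                compute_tss(suit >= c, labels.astype(bool)).tss
                for c in np.unique(suit)
            )
            assert ev.tss == pytest.approx(best)


class TestFitAndProject:
    @pytest.fixture
    def toy(self):
        domain = rasterize_domain(6, 6, 0.1, (0.0, 0.0))
        temps = np.linspace(0, 10, domain.n_cells)
        climate = {
            "current": ClimateLayerSet("current", domain, _climate_1d(temps)),
            "same": ClimateLayerSet("same", domain, _climate_1d(temps)),
        }
        # presence band around t = 5 with a separating margin to the absences
        presence = np.abs(temps - 5) < 2
        absence = np.abs(temps - 5) > 3
        cells = np.nonzero(presence | absence)[0]
        labels = presence[cells].astype(int)
        split = make_splits(cells, labels, frac=0.75, n_reps=1, seed=0)[0]
        return climate, split

    def test_identical_future_climate_gives_identical_binaries(self, toy):
        climate, split = toy
        projections = fit_and_project("sp", "envelope", split, climate)
        by_scen = {p.scenario_id: p.prediction for p in projections}
        assert (by_scen["current"] == by_scen["same"]).all()

    def test_envelope_method_recovers_envelope_truth(self, toy):
        """Presences defined by a climate band are perfectly separable for
        the percentile-envelope method when validation presences lie inside
        the calibrated envelope."""
        climate, _ = toy
        temps = climate["current"].values[:, 0]
        presence = np.nonzero(np.abs(temps - 5) < 2)[0]
        absence = np.nonzero(np.abs(temps - 5) > 3)[0]
        split = CalibrationSplit(
            rep_index=0,
            calibration_cells=np.concatenate([presence, absence]),
            calibration_labels=np.concatenate(
                [np.ones(presence.size, int), np.zeros(absence.size, int)]
            ),
            validation_cells=np.concatenate([presence[1:-1], absence]),
            validation_labels=np.concatenate(
                [np.ones(presence.size - 2, int), np.zeros(absence.size, int)]
            ),
        )
        projections = fit_and_project("sp", "envelope", split, climate)
        assert projections[0].evaluation.tss == 1.0

    def test_logistic_separates_linearly_separable_labels(self, toy):
        climate, _ = toy
        # one-sided labels with a margin: linearly separable in temperature
        temps = climate["current"].values[:, 0]
        cells = np.nonzero((temps > 6) | (temps < 4))[0]
        labels = (temps[cells] > 6).astype(int)
        split = make_splits(cells, labels, n_reps=1, seed=0)[0]
        projections = fit_and_project("sp", "logistic", split, climate)
        assert projections[0].evaluation.tss == 1.0

    def test_suitability_methods_respect_unit_interval(self, toy, rng):
        climate, split = toy
        X = climate["current"].values
        y = np.zeros(X.shape[0], int)
        y[split.calibration_cells[split.calibration_labels == 1]] = 1
        for method_id in ("envelope", "logistic", "distance"):
            m = get_method(method_id).fit(X, y)
            suit = m.predict(X)
            assert suit.min() >= 0 and suit.max() <= 1


def test_tiny_run_tss_table_is_complete(tiny_run):
    ev = tiny_run.enm.evaluations
    cfg = tiny_run.config
    assert len(ev) == len(tiny_run.species) * len(cfg.enm.methods) * cfg.enm.n_reps
    assert ((ev.tss >= -1) & (ev.tss <= 1)).all()
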