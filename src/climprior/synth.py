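"""Synthetic landscapes: climate gradients, envelope-truth species ranges,
protected areas and vegetation cover.

The generator stands in for rasterized expert range maps and downscaled
climate surfaces. Every species' true range is defined by a bioclimatic
envelope: the cells whose climate lies within a fixed axis-scaled
(diagonal-Mahalanobis) distance of the species' niche centre. Because the
same envelope rule is re-evaluated under each future climate, ground truth
for range shifts, centroid displacements and regional extinctions is exact
and available to recovery tests.

All generators are pure functions of (parameters, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from ._rng import substream
from .grid import CLIMATE_VARS, ClimateLayerSet, GridDomain, OccupancyMatrix, SpeciesRecord

#: envelope cutoff on the axis-scaled climate distance (in niche-breadth units)
ENVELOPE_CUTOFF = 1.96

#: default per-variable (base, south-north slope, west-east slope, noise scale)
#: spanning plausible subtropical values: temperature falls poleward,
#: precipitation and its seasonality follow coast-interior gradients.
DEFAULT_GRADIENTS = {
    "annual_mean_temp": (28.0, -16.0, -2.0, 0.6),
    "temp_seasonality": (150.0, 80.0, 40.0, 8.0),
    "annual_precip": (2000.0, -900.0, -400.0, 80.0),
    "precip_seasonality": (35.0, 20.0, 10.0, 2.0),
}

DEFAULT_IUCN_MIX = {"LC": 0.50, "NT": 0.10, "VU": 0.15, "DD": 0.05, "EN": 0.12, "CR": 0.08}


@dataclass(frozen=True)
class ScenarioDelta:
    """Offset applied to current climate to produce one future scenario.

    ``temp_offset`` is the mean warming (degC), mirroring equilibrium climate
    sensitivities in the 3.1-4.4 degC range; ``precip_multiplier`` scales
    annual precipitation; ``gradient_strength`` adds a south-north tilt to
    the warming so scenarios differ spatially as well as in magnitude.
    """

    scenario_id: str
    temp_offset: float
    precip_multiplier: float = 1.0
    gradient_strength: float = 0.0


def default_scenario_deltas() -> list[ScenarioDelta]:
    """Three future scenarios with distinct warming magnitudes."""
    return [
        ScenarioDelta("gcm1_2080", 3.1, 0.95, 0.5),
        ScenarioDelta("gcm2_2080", 3.75, 0.92, 0.5),
        ScenarioDelta("gcm3_2080", 4.4, 0.90, 0.5),
    ]


@dataclass
class NicheTruth:
    """Ground truth behind the synthetic species.

    Niche centres and breadths live in standardized climate space (current-
    climate z-scores). ``ranges[scenario]`` is the (S, N) boolean matrix of
    true occupancy; re-evaluating :meth:`evaluate_envelope` on the emitted
    climate reproduces it exactly.
    """

    centers: np.ndarray  # (S, 4)
    breadths: np.ndarray  # (S, 4), > 0
    climate_mean: np.ndarray  # (4,) standardization of current climate
    climate_sd: np.ndarray  # (4,)
    ranges: dict[str, np.ndarray] = field(default_factory=dict)
    cutoff: float = ENVELOPE_CUTOFF

    def standardize(self, climate: ClimateLayerSet) -> np.ndarray:
        return (climate.values - self.climate_mean) / self.climate_sd

    def evaluate_envelope(self, climate: ClimateLayerSet) -> np.ndarray:
        """(S, N) boolean truth ranges implied by the envelope rule."""
        z = self.standardize(climate)  # (N, 4)
        # distance_sj = || (z_s - center_j) / breadth_j ||
        diff = z[None, :, :] - self.centers[:, None, :]
        d = np.sqrt(((diff / self.breadths[:, None, :]) ** 2).sum(axis=2))
        return d <= self.cutoff

    def true_centroid(self, scenario_id: str, domain: GridDomain) -> np.ndarray:
        """(S, 2) centroids (cell units) of true ranges; NaN for empty ranges."""
        centers = domain.cell_centers_units()
        out = np.full((self.centers.shape[0], 2), np.nan)
        for s, row in enumerate(self.ranges[scenario_id]):
            if row.any():
                out[s] = centers[row].mean(axis=0)
        return out


def _smoothed_noise(rng: np.random.Generator, shape: tuple[int, int], width: int = 5) -> np.ndarray:
    """Spatially autocorrelated noise: moving-average-smoothed white noise,
    rescaled to unit variance."""
    white = rng.standard_normal(shape)
    sm = ndimage.uniform_filter(white, size=width, mode="nearest")
    sd = sm.std()
    return sm / sd if sd > 0 else sm


def generate_current_climate(
    domain: GridDomain,
    gradient_params: dict[str, tuple[float, float, float, float]] | None = None,
    noise_sd: float = 1.0,
    seed: int = 0,
) -> ClimateLayerSet:
    """Current climate: smooth latitudinal/longitudinal gradients plus
    spatially autocorrelated noise.

    ``noise_sd`` multiplies each variable's own noise scale; 0 gives exact
    linear gradients.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    params = dict(DEFAULT_GRADIENTS)
    if gradient_params:
        params.update(gradient_params)
    rows_norm = domain.cell_rows / max(domain.n_rows - 1, 1)
    cols_norm = domain.cell_cols / max(domain.n_cols - 1, 1)
    values = np.empty((domain.n_cells, len(CLIMATE_VARS)))
    for k, var in enumerate(CLIMATE_VARS):
        base, ns, ew, scale = params[var]
        layer = base + ns * rows_norm + ew * cols_norm
        if noise_sd > 0:
            noise = _smoothed_noise(substream(seed, "climate", var), domain.study_mask.shape)
            layer = layer + noise_sd * scale * domain.from_grid(noise)
        values[:, k] = layer
    return ClimateLayerSet("current", domain, values)


def generate_future_climate(
    current: ClimateLayerSet, deltas: list[ScenarioDelta]
) -> list[ClimateLayerSet]:
    """Apply scenario deltas to the current climate.

    Future annual mean temperature = current + offset + tilt, where the tilt
    is ``gradient_strength * offset * (row_norm - 1/2)``; precipitation is
    scaled by the multiplier; seasonality layers are carried unchanged.
    """
    if not deltas:
        raise ValueError("at least one scenario delta required")
    ids = [d.scenario_id for d in deltas]
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate scenario_id in {ids}")
    domain = current.domain
    rows_norm = domain.cell_rows / max(domain.n_rows - 1, 1)
    out = []
    for d in deltas:
        values = current.values.copy()
        tilt = d.gradient_strength * d.temp_offset * (rows_norm - 0.5)
        values[:, CLIMATE_VARS.index("annual_mean_temp")] += d.temp_offset + tilt
        values[:, CLIMATE_VARS.index("annual_precip")] *= d.precip_multiplier
        out.append(ClimateLayerSet(d.scenario_id, domain, values))
    return out


def generate_species(
    domain: GridDomain,
    climate_current: ClimateLayerSet,
    climate_futures: list[ClimateLayerSet],
    n_species: int = 30,
    breadth_log_mean: float = math.log(0.55),
    breadth_log_sd: float = 0.35,
    iucn_mix: dict[str, float] | None = None,
    min_range_cells: int = 5,
    seed: int = 0,
) -> tuple[dict[str, OccupancyMatrix], list[SpeciesRecord], NicheTruth]:
    """Draw envelope-truth species and their occupancy under every scenario.

    Each species' niche centre is the standardized climate of a randomly
    chosen in-mask cell (guaranteeing a viable current range) and its
    per-variable breadths are log-normal. A species occupies exactly the
    cells whose axis-scaled climate distance to its centre is <= 1.96,
    evaluated separately under current and each future climate. Species
    whose current range holds fewer than ``min_range_cells`` cells are
    redrawn, so downstream calibration splits are always well-posed.
    """
    if n_species < 1:
        raise ValueError("n_species must be >= 1")
    mix = dict(iucn_mix or DEFAULT_IUCN_MIX)
    if abs(sum(mix.values()) - 1.0) > 1e-6:
        raise ValueError(f"iucn_mix must sum to 1, got {sum(mix.values())!r}")

    mean = climate_current.values.mean(axis=0)
    sd = climate_current.values.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    z_current = (climate_current.values - mean) / sd

    rng = substream(seed, "species")
    centers = np.empty((n_species, 4))
    breadths = np.empty((n_species, 4))
    for s in range(n_species):
        for _attempt in range(1000):
            cell = rng.integers(domain.n_cells)
            c = z_current[cell] + 0.1 * rng.standard_normal(4)
            b = np.exp(breadth_log_mean + breadth_log_sd * rng.standard_normal(4))
            d = np.sqrt((((z_current - c) / b) ** 2).sum(axis=1))
            if (d <= ENVELOPE_CUTOFF).sum() >= min_range_cells:
                centers[s], breadths[s] = c, b
                break
        else:
            raise RuntimeError("could not draw a species with a viable range")

    truth = NicheTruth(centers=centers, breadths=breadths, climate_mean=mean, climate_sd=sd)
    categories = list(mix)
    probs = np.array([mix[c] for c in categories])
    draws = substream(seed, "iucn").choice(len(categories), size=n_species, p=probs)
    species = [
        SpeciesRecord(f"sp{s:03d}", categories[draws[s]]) for s in range(n_species)
    ]
    ids = [sp.species_id for sp in species]

    occupancy: dict[str, OccupancyMatrix] = {}
    for clim in [climate_current, *climate_futures]:
        ranges = truth.evaluate_envelope(clim)
        truth.ranges[clim.scenario_id] = ranges
        occupancy[clim.scenario_id] = OccupancyMatrix(
            clim.scenario_id, ids, ranges.astype(np.uint8)
        )
    return occupancy, species, truth


def generate_landscape(
    domain: GridDomain,
    pa_fraction: float,
    veg_smooth_width: int = 7,
    veg_logit_scale: float = 2.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Protected-area mask and natural-vegetation-fraction layer.

    The number of protected cells is round-half-up(pa_fraction * N); cells
    are spatially clumped by growing patches from random seeds. Vegetation
    fraction is a logistic transform of smoothed noise, in [0, 1].
    """
    if not 0 <= pa_fraction < 1:
        raise ValueError("pa_fraction must be in [0, 1)")
    n = domain.n_cells
    n_protected = int(math.floor(pa_fraction * n + 0.5))
    protected = np.zeros(n, dtype=bool)
    rng = substream(seed, "landscape", "pa")
    if n_protected > 0:
        n_patches = max(1, n_protected // 60)
        seeds = rng.choice(n, size=min(n_patches, n), replace=False)
        protected[seeds] = True
        # neighbour lookup on the full grid
        idgrid = domain.cell_id_grid
        frontier = set()

        def neighbours(cid: int) -> list[int]:
            r, c = domain.row_col(cid)
            out = []
            for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                rr, cc = r + dr, c + dc
                if 0 <= rr < domain.n_rows and 0 <= cc < domain.n_cols:
                    nid = idgrid[rr, cc]
                    if nid >= 0:
                        out.append(int(nid))
            return out

        for cid in np.nonzero(protected)[0]:
            frontier.update(x for x in neighbours(int(cid)) if not protected[x])
        while protected.sum() < n_protected:
            if not frontier:  # patches filled their components; reseed
                free = np.nonzero(~protected)[0]
                frontier.add(int(rng.choice(free)))
            pick = sorted(frontier)[rng.integers(len(frontier))]
            frontier.discard(pick)
            protected[pick] = True
            frontier.update(x for x in neighbours(pick) if not protected[x])

    noise = _smoothed_noise(substream(seed, "landscape", "veg"),
                            domain.study_mask.shape, width=veg_smooth_width)
    vegetation = 1.0 / (1.0 + np.exp(-veg_logit_scale * domain.from_grid(noise)))
    return protected, vegetation
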