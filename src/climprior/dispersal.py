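"""Climate-forced dispersal: centroid shifts, negative-exponential kernels
and distribution smoothing.

The displacement between a species' current and future distribution
centroids measures how far its suitable climate moves; that distance D sets
a species-specific negative-exponential smoothing kernel with decay
alpha = 2/D (the standard conversion of a dispersal distance into a kernel
width). Convolving each occupancy layer with its kernel turns hard range
edges into connectivity-aware suitability surfaces; the geometric mean of
the smoothed current and future layers then values only sites useful in
both periods.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .grid import GridDomain


class EmptyRangeError(ValueError):
    """Raised when a centroid is requested for an empty distribution."""


@dataclass
class DispersalSpec:
    species_id: str
    centroid_now: tuple[float, float]  # (x, y) in cell units
    centroid_future: tuple[float, float] | None  # None if extinct in future
    shift_km: float  # D_j
    alpha: float  # 2 / D_j (1/km); inf when D_j == 0
    truncation_km: float
    extinct_in_future: bool = False


def centroid(binary: np.ndarray, domain: GridDomain) -> tuple[float, float]:
    """Unweighted mean of occupied cell centers, in cell units."""
    binary = np.asarray(binary).astype(bool)
    if binary.shape != (domain.n_cells,):
        raise ValueError("binary map length must equal domain.n_cells")
    if not binary.any():
        raise EmptyRangeError("empty range: centroid undefined")
    xy = domain.cell_centers_units()[binary]
    x, y = xy.mean(axis=0)
    return float(x), float(y)


def shift_distance(
    centroid_now: tuple[float, float],
    centroid_future: tuple[float, float],
    km_per_unit: float,
) -> float:
    """Euclidean centroid displacement scaled to km."""
    dx = centroid_future[0] - centroid_now[0]
    dy = centroid_future[1] - centroid_now[1]
    return math.hypot(dx, dy) * km_per_unit


def build_kernel(
    shift_km: float,
    km_per_cell: float,
    truncation_factor: float = 3.0,
    alpha_coefficient: float = 2.0,
) -> np.ndarray:
    """Discrete radially-symmetric negative-exponential kernel.

    Weights are proportional to exp(-alpha * d) with alpha =
    alpha_coefficient / D (so the weight at distance D is e^-2 relative to
    the center before normalization), truncated at truncation_factor * D
    (at least one cell) and renormalized to sum 1. D = 0 degenerates to the
    identity (delta) kernel.
    """
    if shift_km < 0:
        raise ValueError("shift_km must be >= 0")
    if shift_km == 0:
        return np.ones((1, 1))
    alpha = alpha_coefficient / shift_km
    radius_km = truncation_factor * shift_km
    radius_cells = max(1, int(math.ceil(radius_km / km_per_cell)))
    offsets = np.arange(-radius_cells, radius_cells + 1)
    dy, dx = np.meshgrid(offsets, offsets, indexing="ij")
    d_km = np.hypot(dx, dy) * km_per_cell
    kernel = np.where(d_km <= radius_km, np.exp(-alpha * d_km), 0.0)
    return kernel / kernel.sum()


def smooth_distribution(
    layer: np.ndarray, kernel: np.ndarray, domain: GridDomain
) -> np.ndarray:
    """Kernel-smooth a per-cell layer, conserving total mass on the mask.

    Mass a source cell would spread onto out-of-mask (or off-grid) targets
    is renormalized back, per source cell, so the smoothed layer sums to the
    input total exactly. Implemented as two convolutions: the per-source
    in-mask kernel sum, then the convolution of the rescaled sources.
    """
    layer = np.asarray(layer, dtype=float)
    if layer.shape != (domain.n_cells,):
        raise ValueError("layer length must equal domain.n_cells")
    if kernel.shape == (1, 1):
        return layer.copy()
    maskf = domain.study_mask.astype(float)
    # kernel is symmetric, so convolve == correlate and the in-mask kernel
    # sum seen from each source equals the mask convolved with the kernel
    in_sum = ndimage.convolve(maskf, kernel, mode="constant", cval=0.0)
    src = np.zeros_like(maskf)
    src[domain.cell_rows, domain.cell_cols] = layer
    with np.errstate(divide="ignore", invalid="ignore"):
        scaled = np.where(in_sum > 0, src / in_sum, 0.0)
    out = ndimage.convolve(scaled, kernel, mode="constant", cval=0.0)
    return domain.from_grid(out)


def interaction_feature(
    smoothed_now: np.ndarray,
    smoothed_future: np.ndarray,
    mode: str = "geomean",
) -> np.ndarray:
    """Combine smoothed current and future layers into one feature layer.

    ``geomean`` (default) takes the cellwise geometric mean — zero wherever
    either period is unsuitable, comparable in units to occupancy; ``min``
    and ``product`` are alternatives. The result is normalized to sum 1 so
    it can serve directly as a prioritization feature; an all-zero
    combination (disjoint supports) is returned as-is for the caller's
    extinct/disjoint fallback.
    """
    now = np.asarray(smoothed_now, dtype=float)
    fut = np.asarray(smoothed_future, dtype=float)
    if now.shape != fut.shape:
        raise ValueError("layers must share shape")
    if mode == "geomean":
        combined = np.sqrt(now * fut)
    elif mode == "min":
        combined = np.minimum(now, fut)
    elif mode == "product":
        combined = now * fut
    else:
        raise ValueError(f"unknown combination mode {mode!r}")
    total = combined.sum()
    return combined / total if total > 0 else combined


def build_dispersal_features(
    consensus_now: np.ndarray,
    consensus_future: np.ndarray,
    species_ids: list[str],
    domain: GridDomain,
    truncation_factor: float = 3.0,
    alpha_coefficient: float = 2.0,
    combine: str = "geomean",
) -> tuple[list[DispersalSpec], np.ndarray]:
    """Per-species dispersal specs and combined smoothed feature layers.

    ``consensus_now`` / ``consensus_future`` are (S, N) boolean stacks.
    Species regionally extinct in the future (or with disjoint smoothed
    supports) fall back to their smoothed current layer so they still value
    present-day sites; they are flagged on their dispersal record.
    """
    specs: list[DispersalSpec] = []
    features = np.zeros((len(species_ids), domain.n_cells))
    km_per_cell = domain.km_per_cell
    for s, sid in enumerate(species_ids):
        now = np.asarray(consensus_now[s]).astype(bool)
        fut = np.asarray(consensus_future[s]).astype(bool)
        if not now.any():
            raise EmptyRangeError(f"species {sid!r} has no current consensus range")
        c_now = centroid(now, domain)
        extinct = not fut.any()
        if extinct:
            c_fut, d_km = None, 0.0
        else:
            c_fut = centroid(fut, domain)
            d_km = shift_distance(c_now, c_fut, km_per_cell)
        kernel = build_kernel(d_km, km_per_cell, truncation_factor, alpha_coefficient)
        sm_now = smooth_distribution(now.astype(float), kernel, domain)
        if extinct:
            feature = sm_now / sm_now.sum()
        else:
            sm_fut = smooth_distribution(fut.astype(float), kernel, domain)
            feature = interaction_feature(sm_now, sm_fut, mode=combine)
            if feature.sum() == 0:  # disjoint supports: keep current value
                extinct = True
                feature = sm_now / sm_now.sum()
        specs.append(
            DispersalSpec(
                species_id=sid,
                centroid_now=c_now,
                centroid_future=c_fut,
                shift_km=d_km,
                alpha=(alpha_coefficient / d_km) if d_km > 0 else math.inf,
                truncation_km=truncation_factor * d_km,
                extinct_in_future=extinct,
            )
        )
        features[s] = feature
    return specs, features
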