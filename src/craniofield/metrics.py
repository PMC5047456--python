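"""Efficacy and safety statistics derived from field solutions.

* TER — therapeutic enhancement ratio, the relative reduction in tumor
  growth rate, mapped from |E| through a cubic dose-response fit to in-vitro
  glioma data (valid 110-240 V/m; zero below, clamped to 1.245 above).
* Volume-weighted medians / IQR of |E| per region; P100 and P225, the
  volume fractions at >= 100 and >= 225 V/m (any growth-rate reduction /
  growth arrest or regression).
* SAR = (E . sigma E) / rho, the local power absorption per unit mass.
* Paired per-element differences and coefficients of determination between
  scenarios sharing one mesh.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .conductivity import ConductivityField, TissueTable
from .mesh import VolumeMesh
from .solver import FieldSolution

__all__ = ["TERModel", "ter", "weighted_quantile", "region_stats", "sar",
           "sar_stats", "paired_difference", "r_squared"]


@dataclass(frozen=True)
class TERModel:
    """Cubic dose-response mapping |E| (V/m) -> TER.

    ``coeffs`` are in descending powers of x.  Below ``lower`` the mapping
    returns 0 (no measured effect); above ``upper`` it returns ``clamp``
    (the fitted value at the upper end of the measured range), keeping the
    assessment conservative outside the measurements.
    """

    coeffs: tuple = (4.06e-7, -1.72e-4, 2.96e-2, -1.54)
    lower: float = 110.0
    upper: float = 240.0
    clamp: float = 1.245


def ter(field_magnitude, model: TERModel | None = None):
    """Evaluate the TER mapping (vectorized; scalar in, scalar out)."""
    model = model or TERModel()
    x = np.asarray(field_magnitude, dtype=float)
    if np.any(x < 0):
        raise ValueError("field magnitude must be >= 0")
    # the published 3-significant-digit coefficients slightly overshoot the
    # published end-of-range value near the upper bound; capping at the
    # clamp keeps the mapping nondecreasing
    val = np.minimum(np.polyval(model.coeffs, x), model.clamp)
    out = np.where(x < model.lower, 0.0, np.where(x > model.upper,
                                                  model.clamp, val))
    if np.isscalar(field_magnitude) or np.ndim(field_magnitude) == 0:
        return float(out)
    return out


def weighted_quantile(values: np.ndarray, q, weights: np.ndarray | None = None):
    """Weight-aware quantile with linear interpolation between order
    statistics (cumulative-weight midpoint rule).

    With equal weights the median coincides with the unweighted sample
    median; weights are element volumes throughout this package, making
    every statistic a 'percentage of tissue' quantity.
    """
    values = np.asarray(values, dtype=float)
    if len(values) == 0:
        raise ValueError("weighted_quantile of empty set")
    if weights is None:
        weights = np.ones_like(values)
    weights = np.asarray(weights, dtype=float)
    order = np.argsort(values, kind="stable")
    v, w = values[order], weights[order]
    cw = np.cumsum(w)
    positions = (cw - 0.5 * w) / cw[-1]
    return np.interp(np.asarray(q, dtype=float), positions, v,
                     left=v[0], right=v[-1])


def region_stats(solution: FieldSolution, mesh: VolumeMesh,
                 region_mask: np.ndarray, model: TERModel | None = None,
                 region_name: str = "region", weighted: bool = True) -> dict:
    """Volume-weighted summary of |E| over one region.

    Returns Q2 (median), IQR (Q3 - Q1), P100, P225 (volume %, thresholds
    inclusive), p99 and the volume-weighted mean TER.  ``weighted=False``
    gives the unweighted variant used for testing.
    """
    region_mask = np.asarray(region_mask, dtype=bool)
    if not np.any(region_mask):
        raise ValueError(f"region {region_name!r} is empty")
    mag = solution.magnitude[region_mask]
    w = mesh.volumes[region_mask] if weighted else np.ones(mag.shape)
    q1, q2, q3, p99 = weighted_quantile(mag, [0.25, 0.5, 0.75, 0.99], w)
    wsum = w.sum()
    t = ter(mag, model)
    return {
        "Q2": float(q2),
        "IQR": float(q3 - q1),
        "P100": float(100.0 * w[mag >= 100.0].sum() / wsum),
        "P225": float(100.0 * w[mag >= 225.0].sum() / wsum),
        "p99": float(p99),
        "mean_TER": float((t * w).sum() / wsum),
    }


def sar(solution: FieldSolution, sigma: ConductivityField, mesh: VolumeMesh,
        table: TissueTable | None = None) -> np.ndarray:
    """Per-element SAR = (E . sigma E) / rho in W/kg (reduces to
    sigma |E|^2 / rho for isotropic conductivity)."""
    table = table or (sigma.table or TissueTable())
    rho = np.empty(mesh.n_elements)
    rho.fill(np.nan)
    for tissue, dens in table.density.items():
        rho[mesh.labels == tissue] = dens
    if np.any(np.isnan(rho)):
        missing = sorted(set(mesh.labels[np.isnan(rho)].tolist()))
        raise ValueError(f"missing mass density for tissue codes {missing}")
    power = np.einsum("mi,mij,mj->m", solution.E, sigma.tensors, solution.E)
    return power / rho


def sar_stats(values: np.ndarray, mesh: VolumeMesh,
              region_mask: np.ndarray, region_name: str = "region") -> dict:
    """Volume-weighted median and 99th percentile of per-element SAR."""
    region_mask = np.asarray(region_mask, dtype=bool)
    if not np.any(region_mask):
        raise ValueError(f"region {region_name!r} is empty")
    w = mesh.volumes[region_mask]
    med, p99 = weighted_quantile(values[region_mask], [0.5, 0.99], w)
    return {"SAR_median": float(med), "SAR_p99": float(p99)}


def paired_difference(sol_a: FieldSolution, sol_b: FieldSolution,
                      mesh: VolumeMesh,
                      region_mask: np.ndarray | None = None) -> dict:
    """Per-element difference of field magnitudes, a - b, on one mesh.

    Returns the per-element array plus the volume-weighted median change and
    the volume fraction with a strict increase.
    """
    if sol_a.mesh_hash != sol_b.mesh_hash:
        raise ValueError("paired_difference requires solutions on the "
                         "identical mesh (geometry hash mismatch)")
    delta = sol_a.magnitude - sol_b.magnitude
    if region_mask is None:
        region_mask = np.ones(mesh.n_elements, dtype=bool)
    region_mask = np.asarray(region_mask, dtype=bool)
    d = delta[region_mask]
    w = mesh.volumes[region_mask]
    return {
        "delta": delta,
        "median_delta": float(weighted_quantile(d, 0.5, w)),
        "fraction_increased": float(w[d > 0].sum() / w.sum()),
    }


def r_squared(sol_a: FieldSolution, sol_b: FieldSolution, mesh: VolumeMesh,
              region_mask: np.ndarray) -> float:
    """Square of the volume-weighted Pearson correlation between paired
    |E| values in a region.  Raises on zero variance (undefined)."""
    if sol_a.mesh_hash != sol_b.mesh_hash:
        raise ValueError("r_squared requires solutions on the identical mesh")
    region_mask = np.asarray(region_mask, dtype=bool)
    if not np.any(region_mask):
        raise ValueError("r_squared over an empty region")
    x = sol_a.magnitude[region_mask]
    y = sol_b.magnitude[region_mask]
    w = mesh.volumes[region_mask]
    w = w / w.sum()
    mx, my = w @ x, w @ y
    cov = w @ ((x - mx) * (y - my))
    vx = w @ ((x - mx) ** 2)
    vy = w @ ((y - my) ** 2)
    tiny_x = vx <= (1e-10 * (abs(mx) + 1.0)) ** 2
    tiny_y = vy <= (1e-10 * (abs(my) + 1.0)) ** 2
    if tiny_x or tiny_y:
        raise ValueError("r_squared undefined: zero variance in a field")
    return float(cov * cov / (vx * vy))
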