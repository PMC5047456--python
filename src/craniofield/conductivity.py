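"""Per-element conductivity tensors.

CSF, scalp and skull get isotropic in-vivo literature values; gray matter,
white matter and tumor get anisotropic tensors derived from the diffusion
tensors by direct linear mapping, sigma = s * D, with the slope s chosen to
minimize the mean squared error between the mapped scalar conductivities of
healthy GM/WM and the literature targets (0.275 / 0.126 S/m).  Elements
relabeled by virtual surgery inherit the isotropic value of their new
tissue (skin over the defect, CSF in the resection cavity).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum

import numpy as np

from .constants import (DEFAULT_DENSITY, ISOTROPIC_CONDUCTIVITY,
                        LITERATURE_CONDUCTIVITY, Tissue)
from .mesh import VolumeMesh
from .phantom import DiffusionTensorField

__all__ = ["TissueTable", "ConductivityField", "Provenance", "direct_map",
           "scalar_summary", "optimize_slope", "build_conductivity_field"]


class Provenance(IntEnum):
    """How an element's conductivity tensor was obtained."""

    ISOTROPIC_TABLE = 0
    MAPPED_DTI = 1
    SURGERY_REASSIGNED = 2


@dataclass(frozen=True)
class TissueTable:
    """Isotropic conductivities (S/m), literature anisotropy-calibration
    targets (S/m) and mass densities (kg/m^3)."""

    conductivity: dict = field(
        default_factory=lambda: dict(ISOTROPIC_CONDUCTIVITY))
    literature: dict = field(
        default_factory=lambda: dict(LITERATURE_CONDUCTIVITY))
    density: dict = field(default_factory=lambda: dict(DEFAULT_DENSITY))

    def validate(self) -> None:
        for d in (self.conductivity, self.literature, self.density):
            for t, v in d.items():
                if v <= 0:
                    raise ValueError(f"tissue property for {t} must be > 0 (got {v})")


@dataclass
class ConductivityField:
    """Per-element symmetric positive-definite conductivity tensors (S/m)."""

    tensors: np.ndarray            # (M, 3, 3)
    provenance: np.ndarray         # (M,) Provenance codes
    slope: float | None = None
    table: TissueTable | None = None

    def scalar(self) -> np.ndarray:
        """Mean-eigenvalue (trace/3) scalar conductivity per element."""
        return np.trace(self.tensors, axis1=1, axis2=2) / 3.0


def _check_spd(D: np.ndarray) -> None:
    D = np.asarray(D, dtype=float)
    if D.shape != (3, 3):
        raise ValueError("tensor must be 3x3")
    if not np.allclose(D, D.T, rtol=1e-8, atol=1e-12):
        raise ValueError("tensor must be symmetric")
    if np.any(np.linalg.eigvalsh(D) <= 0):
        raise ValueError("tensor must be positive definite")


def direct_map(D: np.ndarray, s: float) -> np.ndarray:
    """Map a diffusion tensor to a conductivity tensor: sigma = s * D.

    Eigenvectors are shared; eigenvalues scale by s.  D must be SPD and
    s > 0.
    """
    if s <= 0:
        raise ValueError("mapping slope must be > 0")
    _check_spd(D)
    return s * np.asarray(D, dtype=float)


def scalar_summary(sigma: np.ndarray) -> float:
    """Scalar conductivity of a tensor: arithmetic mean of the eigenvalues,
    i.e. trace/3 (linear in the mapping slope, which gives the closed-form
    slope optimum)."""
    _check_spd(sigma)
    return float(np.trace(np.asarray(sigma, dtype=float)) / 3.0)


def optimize_slope(tensors: DiffusionTensorField, mesh: VolumeMesh,
                   table: TissueTable | None = None) -> float:
    """Least-squares slope of the direct mapping against literature targets.

    Minimizes sum_i (s m_i - sigma_target(tissue_i))^2 over healthy GM and
    WM elements (tumor and peritumoral elements excluded), where
    m_i = trace(D_i)/3.  The minimizer is closed-form:

        s* = (sigma_gm sum_gm m_i + sigma_wm sum_wm m_i) / sum_all m_i^2
    """
    table = table or TissueTable()
    peritumor = mesh.get_flag("peritumoral")
    num = 0.0
    den = 0.0
    for tissue in (Tissue.GM, Tissue.WM):
        sel = (mesh.labels == tissue) & ~peritumor & tensors.covered
        if not np.any(sel):
            raise ValueError(f"optimize_slope: no healthy {Tissue(tissue).name} "
                             "elements with tensors")
        m = np.trace(tensors.tensors[sel], axis1=1, axis2=2) / 3.0
        num += table.literature[tissue] * m.sum()
        den += (m ** 2).sum()
    return float(num / den)


def build_conductivity_field(mesh: VolumeMesh, table: TissueTable | None,
                             tensors: DiffusionTensorField | None,
                             slope: float | None) -> ConductivityField:
    """Assemble the full per-element conductivity field.

    GM/WM/tumor elements receive ``slope * D``; scalp, skull and CSF receive
    isotropic table values; elements relabeled by virtual surgery receive
    the isotropic value of their new tissue and are flagged
    SURGERY_REASSIGNED.
    """
    table = table or TissueTable()
    table.validate()
    M = mesh.n_elements
    out = np.zeros((M, 3, 3))
    prov = np.full(M, Provenance.ISOTROPIC_TABLE, dtype=np.int64)
    eye = np.eye(3)

    mapped = np.isin(mesh.labels, (Tissue.GM, Tissue.WM, Tissue.TUMOR))
    if np.any(mapped):
        if tensors is None or slope is None:
            raise ValueError("brain/tumor elements present but no diffusion "
                             "tensors or slope supplied")
        if slope <= 0:
            raise ValueError("mapping slope must be > 0")
        missing = mapped & ~tensors.covered
        if np.any(missing):
            ids = np.flatnonzero(missing)
            raise ValueError(
                "missing diffusion tensors for brain elements: "
                f"{ids[:10].tolist()}{'...' if len(ids) > 10 else ''}")
        out[mapped] = slope * tensors.tensors[mapped]
        prov[mapped] = Provenance.MAPPED_DTI

    for tissue in (Tissue.SCALP, Tissue.SKULL, Tissue.CSF):
        sel = mesh.labels == tissue
        out[sel] = table.conductivity[tissue] * eye
    reassigned = mesh.get_flag("defect_relabeled") | mesh.get_flag("resected")
    prov[reassigned] = Provenance.SURGERY_REASSIGNED

    return ConductivityField(tensors=out, provenance=prov, slope=slope,
                             table=table)
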