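"""Quasi-static volume-conduction solver.

Solves div(sigma grad phi) = 0 with current-controlled Neumann electrode
patches on linear (P1) tetrahedra.  At TTFields frequencies (~200 kHz) the
head behaves as a resistive volume conductor instant-by-instant, so one
static solve per electrode pair — at the waveform's peak current —
represents the maximum field distribution of the duty cycle.

Also provides the semi-analytic N-layer concentric-sphere solution
(Legendre series with a numerically stable admittance propagation) used as
an independent validation oracle, and flux audits for conservation checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .constants import MM2_TO_M2, MM3_TO_M3, V_PER_MM_TO_V_PER_M
from .mesh import VolumeMesh, face_areas
from .conductivity import ConductivityField
from .phantom import ElectrodePair

__all__ = ["FemSystem", "FieldSolution", "assemble", "solve_pair",
           "analytic_layered_sphere", "flux_audit", "cylinder_flux"]


@dataclass
class FemSystem:
    """Assembled stiffness operator plus the element data needed for
    post-processing (gradients in 1/mm, volumes in mm^3)."""

    K: sp.csr_matrix
    mesh: VolumeMesh
    sigma: ConductivityField
    grads: np.ndarray           # (M, 3, 4) barycentric gradients, 1/mm

    @property
    def n_nodes(self) -> int:
        return self.mesh.n_nodes


@dataclass
class FieldSolution:
    """Nodal potential and per-element field/current-density vectors for one
    active electrode pair."""

    pair_name: str
    current: float
    phi: np.ndarray             # (N,) V, zero-mean
    E: np.ndarray               # (M, 3) V/m, constant per element
    J: np.ndarray               # (M, 3) A/m^2
    mesh_hash: str
    diagnostics: dict = field(default_factory=dict)

    @property
    def magnitude(self) -> np.ndarray:
        """|E| per element, V/m."""
        return np.linalg.norm(self.E, axis=1)


def assemble(mesh: VolumeMesh, sigma: ConductivityField) -> FemSystem:
    """Assemble the P1 stiffness operator K_ij = int grad N_i . sigma grad N_j.

    K is symmetric positive-semidefinite with the constant vector spanning
    its nullspace (pure Neumann problem).  Anisotropic tensors enter the
    per-element bilinear form directly.  Units: K in siemens, so K phi = b
    couples volts with amperes.
    """
    nodes, tets = mesh.nodes, mesh.tets
    vols = mesh.volumes
    tiny = vols <= 1e-9 * vols.max()
    if np.any(tiny):
        raise ValueError("degenerate (near-zero volume) elements: "
                         f"{np.flatnonzero(tiny)[:10].tolist()}")

    p = nodes[tets]                                   # (M, 4, 3)
    A = np.stack([p[:, 1] - p[:, 0], p[:, 2] - p[:, 0], p[:, 3] - p[:, 0]],
                 axis=2)                              # columns = edge vectors
    Ainv = np.linalg.inv(A)                           # (M, 3, 3)
    grads = np.empty((len(tets), 3, 4))
    grads[:, :, 1:] = np.transpose(Ainv, (0, 2, 1))   # grad of lambda_1..3
    grads[:, :, 0] = -grads[:, :, 1:].sum(axis=2)

    # Ke = V * G^T sigma G; mm/SI factor folds to 1e-3 (grads 1/mm, V mm^3)
    sG = np.einsum("mab,mbj->maj", sigma.tensors, grads)
    Ke = np.einsum("mai,maj->mij", grads, sG) * (vols * 1e-3)[:, None, None]

    rows = np.repeat(tets, 4, axis=1).reshape(-1)
    cols = np.tile(tets, (1, 4)).reshape(-1)
    K = sp.coo_matrix((Ke.reshape(-1), (rows, cols)),
                      shape=(mesh.n_nodes, mesh.n_nodes)).tocsr()
    return FemSystem(K=K, mesh=mesh, sigma=sigma, grads=grads)


def _electrode_load(system: FemSystem, pair: ElectrodePair) -> np.ndarray:
    """Nodal load vector for uniform current density over each patch,
    integrating to +I on patch_a and -I on patch_b exactly."""
    b = np.zeros(system.n_nodes)
    for faces, sign in ((pair.faces_a, +1.0), (pair.faces_b, -1.0)):
        areas = face_areas(system.mesh.nodes, faces)
        total = areas.sum()
        w = sign * pair.current * areas / (3.0 * total)
        for k in range(3):
            np.add.at(b, faces[:, k], w)
    return b


def solve_pair(system: FemSystem, pair: ElectrodePair,
               tol: float = 1e-9, max_refine: int = 10) -> FieldSolution:
    """Solve for one active pair with a zero-mean potential constraint.

    The singular Neumann system is regularized by a Lagrange multiplier
    enforcing sum(phi) = 0; the factorized solve is polished by iterative
    refinement until the relative residual of K phi = b (in the zero-mean
    subspace) is <= tol.
    """
    b = _electrode_load(system, pair)
    N = system.n_nodes
    # Ground node 0 to remove the constant nullspace (the grounded solution
    # differs from the zero-mean one only by a constant, restored below),
    # keeping the reduced system symmetric positive-definite for CG.
    K_red = system.K[1:, :][:, 1:].tocsr()
    b_red = b[1:]
    diag = K_red.diagonal()
    precond = spla.LinearOperator(K_red.shape, lambda x: x / diag)
    bnorm = np.linalg.norm(b)
    phi = np.zeros(N)
    history = []
    iters = 0
    if bnorm > 0:
        x = np.zeros(N - 1)
        for _ in range(max_refine + 1):
            counter = [0]
            x, _ = spla.cg(K_red, b_red, x0=x, rtol=tol / 10.0, atol=0.0,
                           maxiter=50 * int(np.sqrt(N)) + 1000, M=precond,
                           callback=lambda _v: counter.__setitem__(0, counter[0] + 1))
            iters += counter[0]
            phi[1:] = x
            rel = np.linalg.norm(b - system.K @ phi) / bnorm
            history.append(rel)
            if rel <= tol:
                break
        else:
            raise RuntimeError(
                f"solver did not reach tol={tol:g}; residual history {history}")

    phi = phi - phi.mean()
    phi_e = phi[system.mesh.tets]                       # (M, 4)
    E = -np.einsum("maj,mj->ma", system.grads, phi_e) * V_PER_MM_TO_V_PER_M
    J = np.einsum("mab,mb->ma", system.sigma.tensors, E)
    return FieldSolution(
        pair_name=pair.name, current=pair.current, phi=phi, E=E, J=J,
        mesh_hash=system.mesh.geometry_hash(),
        diagnostics={"iterations": iters,
                     "residual": history[-1] if history else 0.0,
                     "residual_history": history})


# ---------------------------------------------------------------------------
# analytic layered-sphere oracle
# ---------------------------------------------------------------------------

def analytic_layered_sphere(radii, conductivities, electrode_dirs,
                            current: float = 0.9, n_terms: int = 12000,
                            cap_half_angle_deg: float | None = None):
    """Legendre-series surface potential of an N-layer isotropic sphere.

    Parameters
    ----------
    radii : outer radii of the layers in mm, strictly decreasing
        (radii[0] is the outer surface).
    conductivities : S/m, one per layer, outermost first.
    electrode_dirs : two unit vectors — source (+I) and sink (-I) positions
        on the outer surface.
    current : injected current, A.
    n_terms : series length (>= 50).
    cap_half_angle_deg : if given, electrodes are uniform-current spherical
        caps of this half-angle; if None, ideal point sources.

    Returns a callable mapping (Q, 3) unit direction vectors to surface
    potentials (V, zero mean over the sphere).  Raises if the series has not
    converged to 1e-8 relative by ``n_terms``.

    Per harmonic degree n the radial profile in each layer is
    A r^n + B r^-(n+1); instead of solving the (ill-conditioned at large n)
    interface system directly, the local admittance Y = sigma phi'/phi is
    propagated outward with the bounded reflection variable
    t = (B/A) r^-(2n+1), which keeps every step well-scaled.
    """
    radii = np.asarray(radii, dtype=float) * 1e-3       # -> m
    sig = np.asarray(conductivities, dtype=float)
    if len(radii) != len(sig):
        raise ValueError("need one conductivity per layer")
    if np.any(np.diff(radii) >= 0) or np.any(radii <= 0):
        raise ValueError("radii must be strictly decreasing and positive")
    if np.any(sig <= 0):
        raise ValueError("conductivities must be > 0")
    if n_terms < 50:
        raise ValueError("n_terms must be >= 50")
    ua, ub = (np.asarray(d, dtype=float) for d in electrode_dirs)
    ua = ua / np.linalg.norm(ua)
    ub = ub / np.linalg.norm(ub)

    R = radii[0]
    nlay = len(radii)
    ns = np.arange(1, n_terms + 1)

    # admittance recursion, innermost -> surface, vectorized over n; the
    # reflection variable t = (B/A) r^-(2n+1) stays bounded throughout
    t_inner = np.zeros((nlay, n_terms))   # t at each layer's inner radius
    t_outer = np.zeros((nlay, n_terms))   # t at each layer's outer radius
    Y = sig[-1] * ns / radii[-1]          # innermost layer, regular at 0
    for j in range(nlay - 2, -1, -1):
        a, bnd = radii[j], radii[j + 1]
        t_b = (sig[j] * ns - Y * bnd) / (sig[j] * (ns + 1) + Y * bnd)
        t_a = t_b * (bnd / a) ** (2 * ns + 1)
        t_inner[j], t_outer[j] = t_b, t_a
        Y = sig[j] * (ns - (ns + 1) * t_a) / (a * (1.0 + t_a))

    if cap_half_angle_deg is None:
        f_n = current * (2 * ns + 1) / (4 * np.pi * R ** 2)
    else:
        c = np.cos(np.deg2rad(cap_half_angle_deg))
        j0 = current / (2 * np.pi * R ** 2 * (1.0 - c))
        p = _legendre_table(np.array([c]), n_terms + 1)[:, 0]
        f_n = j0 * (p[ns - 1] - p[ns + 1]) / 2.0
    coeff = f_n / Y                        # phi_n at the outer surface

    # layer amplitudes C_j = A_j a_j^n (the regular part evaluated at the
    # layer's own outer radius), propagated inward by interface continuity
    C = np.zeros((nlay, n_terms))
    C[0] = coeff / (1.0 + t_outer[0])
    for j in range(nlay - 1):
        bnd, a = radii[j + 1], radii[j]
        phi_b = C[j] * (bnd / a) ** ns * (1.0 + t_inner[j])
        if j + 1 < nlay - 1:
            C[j + 1] = phi_b / (1.0 + t_outer[j + 1])
        else:
            C[j + 1] = phi_b                # innermost: t = 0 everywhere

    return LayeredSphereSolution(radii_m=radii, ns=ns, coeff=coeff, C=C,
                                 t_inner=t_inner, ua=ua, ub=ub)


@dataclass
class LayeredSphereSolution:
    """Converged Legendre-series solution; callable for the surface
    potential, with :meth:`at_radius` for interior potentials."""

    radii_m: np.ndarray
    ns: np.ndarray
    coeff: np.ndarray
    C: np.ndarray
    t_inner: np.ndarray
    ua: np.ndarray
    ub: np.ndarray

    def _sum(self, weights: np.ndarray, directions, tol: float = 1e-8):
        """Accumulate sum_n w_n (P_n(cos g_a) - P_n(cos g_b)) with rolling
        window averaging of the partial sums, which damps the oscillatory
        tail of the conditionally convergent surface series; convergence is
        declared when consecutive window means differ < tol relative."""
        dirs = np.atleast_2d(np.asarray(directions, dtype=float))
        dirs = dirs / np.linalg.norm(dirs, axis=1, keepdims=True)
        xa = dirs @ self.ua
        xb = dirs @ self.ub
        n_terms = len(self.ns)
        W = max(8, min(512, n_terms // 4))
        ring = np.zeros((2 * W, len(dirs)))
        phi = np.zeros(len(dirs))
        pa_prev, pa = np.ones_like(xa), xa.copy()
        pb_prev, pb = np.ones_like(xb), xb.copy()
        for i, n in enumerate(self.ns):
            phi = phi + weights[i] * (pa - pb)
            ring[i % (2 * W)] = phi
            pa_prev, pa = pa, ((2 * n + 1) * xa * pa - n * pa_prev) / (n + 1)
            pb_prev, pb = pb, ((2 * n + 1) * xb * pb - n * pb_prev) / (n + 1)
        idx = np.arange(n_terms - 2 * W, n_terms) % (2 * W)
        older = ring[idx[:W]].mean(axis=0)
        newer = ring[idx[W:]].mean(axis=0)
        scale = float(np.linalg.norm(newer))
        if scale > 0 and float(np.linalg.norm(newer - older)) > tol * scale:
            raise RuntimeError(
                f"Legendre series not converged after {n_terms} terms "
                f"(relative L2 change of windowed partial sums "
                f"{np.linalg.norm(newer - older) / scale:.3e}); raise n_terms")
        out = newer
        return out if len(np.shape(directions)) > 1 else out[0]

    def __call__(self, directions) -> np.ndarray:
        """Surface potential (V) at unit direction vectors."""
        return self._sum(self.coeff, directions)

    def at_radius(self, r_mm: float, directions) -> np.ndarray:
        """Interior potential (V) at radius r (mm) and unit directions."""
        r = r_mm * 1e-3
        if r > self.radii_m[0] + 1e-12 or r < 0:
            raise ValueError("radius outside the sphere")
        j = int(np.searchsorted(-self.radii_m, -r))    # radii descending
        j = min(j, len(self.radii_m) - 1)
        a = self.radii_m[j]
        ns = self.ns
        if j < len(self.radii_m) - 1:
            bnd = self.radii_m[j + 1]
            t_r = self.t_inner[j] * (bnd / max(r, bnd)) ** (2 * ns + 1)
            w = self.C[j] * (r / a) ** ns * (1.0 + t_r)
        else:
            w = self.C[j] * (r / a) ** ns
        return self._sum(w, directions)


def _legendre_table(x: np.ndarray, n_max: int) -> np.ndarray:
    """P_n(x) for n = 0..n_max as an (n_max + 1, len(x)) table."""
    out = np.empty((n_max + 1, len(x)))
    out[0] = 1.0
    if n_max >= 1:
        out[1] = x
    for n in range(1, n_max):
        out[n + 1] = ((2 * n + 1) * x * out[n] - n * out[n - 1]) / (n + 1)
    return out


def homogeneous_sphere_surface_potential(R_mm, sigma, electrode_dirs, dirs,
                                         current: float = 0.9) -> np.ndarray:
    """Closed-form surface potential for point source/sink on a homogeneous
    sphere — the textbook reduction used to verify the series oracle:

        phi(gamma) = I / (4 pi sigma R) * [1/s - 2 - ln(s (1 + s))],
        s = sin(gamma / 2)

    (summed closed form of sum_n (2n+1)/n P_n(cos gamma)), minus the same
    expression at the sink angle.
    """
    R = R_mm * 1e-3
    ua, ub = (np.asarray(d, float) / np.linalg.norm(d) for d in electrode_dirs)
    dirs = np.atleast_2d(np.asarray(dirs, dtype=float))
    dirs = dirs / np.linalg.norm(dirs, axis=1, keepdims=True)

    def g(cosg):
        s = np.sqrt(np.maximum((1.0 - cosg) / 2.0, 1e-300))
        return 1.0 / s - 2.0 - np.log(s * (1.0 + s))

    pref = current / (4.0 * np.pi * sigma * R)
    return pref * (g(dirs @ ua) - g(dirs @ ub))


# ---------------------------------------------------------------------------
# flux audits
# ---------------------------------------------------------------------------

def flux_audit(solution: FieldSolution, mesh: VolumeMesh,
               pair: ElectrodePair) -> dict:
    """Integrate J.n over the electrode patches and the remaining outer
    boundary (raw per-element current densities, not the discrete loads).

    Returns fluxes in A plus relative mismatches: ``net_imbalance`` is
    |flux_a + flux_b| / I (conservation: current in equals current out) and
    ``leakage`` the non-electrode boundary flux relative to I.
    """
    faces, owners = mesh.boundary_faces()
    p = mesh.nodes[faces]
    n_vec = np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0]) / 2.0  # area-weighted
    flux = np.einsum("fj,fj->f", solution.J[owners], n_vec) * MM2_TO_M2

    key = {tuple(sorted(f)): i for i, f in enumerate(faces)}
    in_a = np.zeros(len(faces), dtype=bool)
    in_b = np.zeros(len(faces), dtype=bool)
    for f in pair.faces_a:
        in_a[key[tuple(sorted(f))]] = True
    for f in pair.faces_b:
        in_b[key[tuple(sorted(f))]] = True

    inflow_a = -float(flux[in_a].sum())    # current entering at the source
    outflow_b = float(flux[in_b].sum())    # current exiting at the sink
    flux_rest = float(flux[~(in_a | in_b)].sum())
    I = pair.current
    return {
        "inflow_a": inflow_a,
        "outflow_b": outflow_b,
        "flux_other": flux_rest,
        "mismatch_a": abs(inflow_a - I) / I,
        "mismatch_b": abs(outflow_b - I) / I,
        "net_imbalance": abs(inflow_a - outflow_b) / I,
        "leakage": abs(flux_rest) / I,
    }


def cylinder_flux(solution: FieldSolution, mesh: VolumeMesh, direction,
                  radius_mm: float, axial_range_mm: tuple) -> float:
    """Volume-averaged axial current (A) through a cylindrical corridor.

    Averages J . d over elements whose centroids lie within ``radius_mm`` of
    the axis (through the origin along ``direction``) and whose axial
    coordinate falls in ``axial_range_mm``; the volume integral divided by
    the slab thickness is the mean current crossing the corridor.
    """
    d = np.asarray(direction, dtype=float)
    d /= np.linalg.norm(d)
    c = mesh.centroids
    ax = c @ d
    perp = np.linalg.norm(c - ax[:, None] * d, axis=1)
    lo, hi = axial_range_mm
    sel = (perp <= radius_mm) & (ax >= lo) & (ax <= hi)
    if not np.any(sel):
        raise ValueError("cylinder selects no elements")
    Jd = solution.J[sel] @ d
    vol = mesh.volumes[sel]
    return float((Jd * vol).sum() * MM3_TO_M3 / ((hi - lo) * 1e-3))
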