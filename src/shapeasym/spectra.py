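"""Laplace-Beltrami spectra of closed triangle meshes (Shape-DNA).

The Helmholtz equation ``Delta f = -lambda f`` on a surface is discretized
with Lagrange finite elements (linear by default, cubic available) into a
generalized eigenproblem ``K f = lambda M f`` with sparse stiffness K and
mass M.  The ascending eigenvalues form an isometry-invariant shape
descriptor; on a closed surface the first eigenvalue is zero.

Size normalizations:

* area normalization multiplies eigenvalues by the total surface area,
  exactly equivalent to rescaling vertex coordinates to a unit-area
  surface (coordinates scaled by s scale eigenvalues by 1/s^2); this
  makes spectra of same-shape, different-size objects identical and, by
  Weyl's law (lambda_n ~ 4 pi n / area), gives all spectra a common
  asymptotic slope of 4 pi.
* volume normalization multiplies eigenvalues by v^(2/D) with v the
  enclosed volume and D = 3 by default; it equalizes volume but not
  surface area, so spectral slopes still differ between shapes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.linalg import eigh
from numpy.polynomial.legendre import leggauss

from shapeasym.mesh import TriangleMesh, repair_orientation, validate_mesh, _signed_volume

__all__ = [
    "FEMSystem",
    "EigenSpectrum",
    "assemble_fem",
    "compute_spectrum",
    "surface_area",
    "enclosed_volume",
    "normalize_area",
    "normalize_volume",
]

# tolerance ratio for the "lambda_1 = 0" closed-surface check
_ZERO_MODE_RATIO = 1e-6


@dataclass
class FEMSystem:
    """Sparse FEM discretization of the Laplace-Beltrami operator."""

    stiffness: sp.csc_matrix
    mass: sp.csc_matrix
    degree: int

    @property
    def n_nodes(self) -> int:
        return self.stiffness.shape[0]


@dataclass
class EigenSpectrum:
    """Ascending eigenvalues with their normalization state.

    ``values[0]`` is the (near-)zero mode of a closed surface; indexing in
    the scientific sense is 1-based, i.e. ``values[i-1]`` is "eigenvalue i".
    Units are 1/mm^2 when unnormalized and dimensionless after area
    normalization.
    """

    values: np.ndarray
    normalization: str = "none"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)

    @property
    def k(self) -> int:
        return self.values.size


# ---------------------------------------------------------------------------
# geometry


def surface_area(mesh: TriangleMesh) -> float:
    """Total area (mm^2): sum of triangle areas."""
    tri = mesh.vertices[mesh.faces]
    cross = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    return float(0.5 * np.linalg.norm(cross, axis=1).sum())


def enclosed_volume(mesh: TriangleMesh) -> float:
    """Enclosed volume (mm^3) by the divergence theorem.

    Requires a closed mesh; orientation is repaired first so the result
    is positive.
    """
    report = validate_mesh(mesh)
    if not report.closed:
        raise ValueError("enclosed_volume requires a closed mesh")
    mesh = repair_orientation(mesh)
    return abs(_signed_volume(mesh.vertices, mesh.faces))


# ---------------------------------------------------------------------------
# linear (P1) elements


def _triangle_frames(mesh: TriangleMesh):
    """Per-face 3D Jacobians, first fundamental forms and areas."""
    tri = mesh.vertices[mesh.faces]
    e1 = tri[:, 1] - tri[:, 0]
    e2 = tri[:, 2] - tri[:, 0]
    g11 = np.einsum("ij,ij->i", e1, e1)
    g12 = np.einsum("ij,ij->i", e1, e2)
    g22 = np.einsum("ij,ij->i", e2, e2)
    detg = g11 * g22 - g12 ** 2
    if np.any(detg <= 0):
        bad = int(np.argmax(detg <= 0))
        raise ValueError(f"degenerate (zero-area) triangle at face {bad}")
    return g11, g12, g22, detg


def _assemble_p1(mesh: TriangleMesh) -> FEMSystem:
    nv = mesh.n_vertices
    faces = mesh.faces
    g11, g12, g22, detg = _triangle_frames(mesh)
    sqrtg = np.sqrt(detg)
    area = 0.5 * sqrtg

    # reference gradients of (1-x-y, x, y)
    grads = np.array([[-1.0, -1.0], [1.0, 0.0], [0.0, 1.0]])
    # inverse metric entries
    i11 = g22 / detg
    i12 = -g12 / detg
    i22 = g11 / detg

    rows, cols, kv, mv = [], [], [], []
    mass_local = np.array([[2.0, 1.0, 1.0], [1.0, 2.0, 1.0], [1.0, 1.0, 2.0]]) / 12.0
    for a in range(3):
        for b in range(3):
            ga, gb = grads[a], grads[b]
            kab = (
                i11 * ga[0] * gb[0]
                + i12 * (ga[0] * gb[1] + ga[1] * gb[0])
                + i22 * ga[1] * gb[1]
            ) * area
            rows.append(faces[:, a])
            cols.append(faces[:, b])
            kv.append(kab)
            mv.append(mass_local[a, b] * area)
    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    K = sp.coo_matrix((np.concatenate(kv), (rows, cols)), shape=(nv, nv)).tocsc()
    M = sp.coo_matrix((np.concatenate(mv), (rows, cols)), shape=(nv, nv)).tocsc()
    return FEMSystem(K, M, degree=1)


# ---------------------------------------------------------------------------
# cubic (P3) elements
#
# 10 nodes per triangle: 3 vertices, 2 per edge (at 1/3 and 2/3), 1 interior.
# Shape functions are obtained from the degree-3 monomial basis through the
# inverse Vandermonde at the node locations; reference stiffness/mass
# integrals are computed once with a Duffy-transformed Gauss rule that is
# exact for the polynomial integrands involved.

_P3_NODES = np.array([
    [0.0, 0.0], [1.0, 0.0], [0.0, 1.0],          # vertices 0, 1, 2
    [1 / 3, 0.0], [2 / 3, 0.0],                  # edge 0-1
    [2 / 3, 1 / 3], [1 / 3, 2 / 3],              # edge 1-2
    [0.0, 2 / 3], [0.0, 1 / 3],                  # edge 2-0
    [1 / 3, 1 / 3],                              # interior
])

_P3_MONOMIALS = [(i, j) for d in range(4) for i in range(d + 1) for j in [d - i]]


def _p3_reference_matrices():
    V = np.array([[x ** i * y ** j for (i, j) in _P3_MONOMIALS] for x, y in _P3_NODES])
    coeff = np.linalg.inv(V)  # column n: monomial coefficients of shape fn n

    gl_x, gl_w = leggauss(8)
    gl_x = 0.5 * (gl_x + 1.0)
    gl_w = 0.5 * gl_w
    # Duffy map of the unit square onto the reference triangle
    u, v = np.meshgrid(gl_x, gl_x, indexing="ij")
    wq = (gl_w[:, None] * gl_w[None, :] * (1.0 - u)).ravel()
    xq = u.ravel()
    yq = (v * (1.0 - u)).ravel()

    def eval_basis(dx, dy):
        vals = np.zeros((xq.size, len(_P3_MONOMIALS)))
        for m, (i, j) in enumerate(_P3_MONOMIALS):
            ci = i - dx
            cj = j - dy
            if ci < 0 or cj < 0:
                continue
            fac = 1.0
            if dx:
                fac *= i
            if dy:
                fac *= j
            vals[:, m] = fac * xq ** ci * yq ** cj
        return vals @ coeff

    phi = eval_basis(0, 0)
    phix = eval_basis(1, 0)
    phiy = eval_basis(0, 1)
    Mref = np.einsum("q,qi,qj->ij", wq, phi, phi)
    Axx = np.einsum("q,qi,qj->ij", wq, phix, phix)
    Axy = np.einsum("q,qi,qj->ij", wq, phix, phiy)
    Ayy = np.einsum("q,qi,qj->ij", wq, phiy, phiy)
    return Mref, Axx, Axy, Ayy


_P3_REF = None


def _assemble_p3(mesh: TriangleMesh) -> FEMSystem:
    global _P3_REF
    if _P3_REF is None:
        _P3_REF = _p3_reference_matrices()
    Mref, Axx, Axy, Ayy = _P3_REF

    faces = mesh.faces
    nv = mesh.n_vertices
    nf = mesh.n_faces
    g11, g12, g22, detg = _triangle_frames(mesh)
    sqrtg = np.sqrt(detg)

    # global edge-node numbering: two nodes per undirected edge, ordered
    # from the lower-index endpoint
    edges = np.concatenate([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]])
    ekeys = np.sort(edges, axis=1)
    uniq, inv = np.unique(ekeys, axis=0, return_inverse=True)
    ne = len(uniq)
    forward = edges[:, 0] == ekeys[:, 0]  # edge traversed low->high
    # local edge nodes come in traversal order (1/3 then 2/3 from the first
    # local endpoint); map to the canonical low->high global pair
    first = nv + 2 * inv + np.where(forward, 0, 1)
    second = nv + 2 * inv + np.where(forward, 1, 0)
    conn = np.empty((nf, 10), dtype=np.int64)
    conn[:, 0:3] = faces
    conn[:, 3] = first[0:nf]
    conn[:, 4] = second[0:nf]
    conn[:, 5] = first[nf:2 * nf]
    conn[:, 6] = second[nf:2 * nf]
    conn[:, 7] = first[2 * nf:3 * nf]
    conn[:, 8] = second[2 * nf:3 * nf]
    conn[:, 9] = nv + 2 * ne + np.arange(nf)
    nn = nv + 2 * ne + nf

    i11 = g22 / detg * sqrtg
    i12 = -g12 / detg * sqrtg
    i22 = g11 / detg * sqrtg

    Klocal = (
        i11[:, None, None] * Axx[None]
        + i12[:, None, None] * (Axy[None] + Axy.T[None])
        + i22[:, None, None] * Ayy[None]
    )
    Mlocal = sqrtg[:, None, None] * Mref[None]

    rows = np.repeat(conn, 10, axis=1).ravel()
    cols = np.tile(conn, (1, 10)).ravel()
    K = sp.coo_matrix((Klocal.ravel(), (rows, cols)), shape=(nn, nn)).tocsc()
    M = sp.coo_matrix((Mlocal.ravel(), (rows, cols)), shape=(nn, nn)).tocsc()
    return FEMSystem(K, M, degree=3)


def assemble_fem(mesh: TriangleMesh, degree: int = 1) -> FEMSystem:
    """Assemble stiffness and mass matrices for the given element degree.

    The stiffness matrix annihilates constants (closed-surface null space)
    and the total mass equals the surface area.
    """
    report = validate_mesh(mesh)
    if not (report.closed and report.manifold):
        raise ValueError("spectral analysis requires a closed manifold mesh")
    if degree == 1:
        return _assemble_p1(mesh)
    if degree == 3:
        return _assemble_p3(mesh)
    raise ValueError("degree must be 1 or 3")


# ---------------------------------------------------------------------------
# eigensolve


def solve_spectrum(system: FEMSystem, k: int) -> np.ndarray:
    """k algebraically smallest eigenvalues of K f = lambda M f, ascending.

    Sparse shift-invert Lanczos about a small negative shift (so the zero
    mode is retrieved reliably); small systems fall back to a dense solve.
    The shift is scaled to the spectrum via the Rayleigh-quotient scale
    trace(K)/trace(M).
    """
    n = system.n_nodes
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the node count {n}")
    K, M = system.stiffness, system.mass
    if n <= 600:
        vals = eigh(K.toarray(), M.toarray(), eigvals_only=True,
                    subset_by_index=[0, k - 1])
        return np.sort(vals)
    scale = K.diagonal().sum() / M.diagonal().sum()
    sigma = -1e-3 * scale
    kk = min(k + 2, n - 1)
    try:
        vals = spla.eigsh(K, k=kk, M=M, sigma=sigma, which="LM",
                          return_eigenvectors=False, tol=0)
    except Exception as exc:  # pragma: no cover - solver diagnostics
        raise RuntimeError(f"sparse eigensolver failed: {exc!r}") from exc
    vals = np.sort(vals)[:k]
    # clip the tiny negative zero mode produced by round-off
    vals[(vals < 0) & (np.abs(vals) < _ZERO_MODE_RATIO * max(vals.max(), 1.0))] = 0.0
    return vals


def compute_spectrum(mesh: TriangleMesh, k: int, degree: int = 1) -> EigenSpectrum:
    """First k Laplace-Beltrami eigenvalues of a closed mesh (unnormalized)."""
    system = assemble_fem(mesh, degree=degree)
    vals = solve_spectrum(system, k)
    if vals.size > 1 and not vals[0] < max(_ZERO_MODE_RATIO * abs(vals[1]), 1e-30):
        # closed surfaces must have a zero mode; warn via exception only if
        # grossly violated (an order of magnitude above tolerance)
        if vals[0] > 10 * _ZERO_MODE_RATIO * abs(vals[1]):
            raise RuntimeError(
                f"first eigenvalue {vals[0]:.3e} is not numerically zero")
    return EigenSpectrum(vals, normalization="none")


# ---------------------------------------------------------------------------
# normalizations


def normalize_area(spectrum: EigenSpectrum, area: float) -> EigenSpectrum:
    """Surface-area normalization: lambda' = area * lambda.

    Equivalent to dividing every vertex coordinate by sqrt(area) before
    solving, i.e. rescaling the surface to unit area.
    """
    if spectrum.normalization != "none":
        raise ValueError("spectrum is already normalized")
    if area <= 0:
        raise ValueError("area must be positive")
    return EigenSpectrum(spectrum.values * area, normalization="area")


def normalize_volume(spectrum: EigenSpectrum, volume: float, D: int = 3) -> EigenSpectrum:
    """Volume normalization: lambda' = v^(2/D) * lambda (unit-volume rescale)."""
    if spectrum.normalization != "none":
        raise ValueError("spectrum is already normalized")
    if volume <= 0:
        raise ValueError("volume must be positive")
    return EigenSpectrum(spectrum.values * volume ** (2.0 / D),
                         normalization="volume")
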