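"""Synthetic surfaces and cohorts with known ground truth.

Surface generators produce closed genus-0 meshes built from subdivided
icosahedra whose vertices are displaced radially by random real
spherical-harmonic fields.  Because the displacement basis is organised by
harmonic degree, injected shape signal has a controllable spatial scale
that maps directly onto the eigen-groups of the spectral analysis, which
is what makes scale-recovery tests possible.

A longitudinal cohort emulates left/right hemisphere surfaces of several
subjects over >= 2 sessions: each hemisphere is the base sphere plus a
subject-specific field (shared by both hemispheres and all sessions), a
hemisphere-specific asymmetry field (stable across sessions) and
per-session noise.  The right hemisphere is built by mirroring, so with
asymmetry amplitude zero the two hemispheres are exactly mirror-isometric
and the shape asymmetry signature has an exact zero reference.

The twin-cohort generator draws phenotypes from the ACTE variance
decomposition: additive genetic effects (fully shared by MZ co-twins,
correlation 0.5 between DZ co-twins and twin-sibling/sibling pairs),
common family environment, twin-specific environment (shared within a
twin pair only) and unique environment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import trimesh as _trimesh
from scipy.special import sph_harm_y

from shapeasym.mesh import TriangleMesh

__all__ = [
    "icosphere",
    "ellipsoid",
    "perturb_with_harmonics",
    "CohortSpec",
    "generate_cohort",
    "TwinSpec",
    "generate_twin_phenotypes",
]


def icosphere(subdivisions: int = 4, radius: float = 1.0) -> TriangleMesh:
    """Subdivided icosahedron projected onto a sphere.

    Has ``10 * 4**s + 2`` vertices, all at distance ``radius`` from the
    origin, and Euler characteristic 2.
    """
    if subdivisions < 0:
        raise ValueError("subdivisions must be >= 0")
    if radius <= 0:
        raise ValueError("radius must be positive")
    tm = _trimesh.creation.icosphere(subdivisions=subdivisions, radius=1.0)
    verts = np.asarray(tm.vertices, dtype=np.float64)
    verts = verts / np.linalg.norm(verts, axis=1, keepdims=True) * radius
    return TriangleMesh(verts, np.asarray(tm.faces, dtype=np.int64),
                        {"source": f"icosphere({subdivisions}, r={radius})"})


def ellipsoid(a: float, b: float, c: float, subdivisions: int = 4) -> TriangleMesh:
    """Icosphere vertices scaled anisotropically to semi-axes (a, b, c) mm."""
    if min(a, b, c) <= 0:
        raise ValueError("semi-axes must be positive")
    base = icosphere(subdivisions, 1.0)
    verts = base.vertices * np.array([a, b, c])
    return TriangleMesh(verts, base.faces,
                        {"source": f"ellipsoid({a},{b},{c},s={subdivisions})"})


# ---------------------------------------------------------------------------
# spherical-harmonic displacement fields


def _real_sh_basis(directions: np.ndarray, degrees: list[int]) -> dict[int, np.ndarray]:
    """Real orthonormal spherical harmonics evaluated at unit directions.

    Returns ``{degree: (n_points, 2*degree+1) array}``.
    """
    x, y, z = directions.T
    theta = np.arccos(np.clip(z, -1.0, 1.0))
    phi = np.arctan2(y, x)
    out = {}
    for ell in degrees:
        cols = []
        for m in range(-ell, ell + 1):
            Y = sph_harm_y(ell, abs(m), theta, phi)
            if m > 0:
                cols.append(np.sqrt(2.0) * (-1.0) ** m * Y.real)
            elif m < 0:
                cols.append(np.sqrt(2.0) * (-1.0) ** m * Y.imag)
            else:
                cols.append(Y.real)
        out[ell] = np.column_stack(cols)
    return out


def _harmonic_field(directions: np.ndarray, amplitudes: dict[int, float],
                    rng: np.random.Generator) -> np.ndarray:
    """Random radial field: degree-l coefficients i.i.d. N(0, amplitudes[l]^2)."""
    degrees = sorted(d for d, a in amplitudes.items() if a > 0)
    f = np.zeros(len(directions))
    if not degrees:
        return f
    basis = _real_sh_basis(directions, degrees)
    for ell in degrees:
        coeffs = rng.normal(0.0, amplitudes[ell], size=2 * ell + 1)
        f += basis[ell] @ coeffs
    return f


def perturb_with_harmonics(mesh: TriangleMesh, amplitudes, seed: int) -> TriangleMesh:
    """Displace vertices radially by a random spherical-harmonic field.

    ``amplitudes[l]`` is the standard deviation of the degree-l
    coefficients (fractional radial displacement).  Requires a mesh
    star-shaped about the origin; identical seed gives identical output.
    """
    amplitudes = np.asarray(amplitudes, dtype=float)
    rng = np.random.default_rng(seed)
    radii = np.linalg.norm(mesh.vertices, axis=1)
    directions = mesh.vertices / radii[:, None]
    amp = {ell: amplitudes[ell] for ell in range(len(amplitudes))}
    f = _harmonic_field(directions, amp, rng)
    factor = 1.0 + f
    if np.any(factor <= 0):
        raise ValueError("harmonic displacement collapses radius to <= 0")
    return TriangleMesh(mesh.vertices * factor[:, None], mesh.faces.copy(),
                        {**mesh.metadata, "perturbed": True})


# ---------------------------------------------------------------------------
# longitudinal left/right cohort


@dataclass
class CohortSpec:
    """Conditions for a longitudinal two-hemisphere surface cohort.

    Amplitudes are fractional radial displacements.  ``scale_band`` is the
    inclusive range of spherical-harmonic degrees carrying the
    subject-specific signal (both the shared-shape and the asymmetry
    fields); session noise is spread over degrees 1..noise_lmax.
    """

    n_subjects: int = 10
    n_sessions: int = 2
    subject_sd: float = 0.03
    asym_sd: float = 0.01
    session_sd: float = 0.003
    scale_band: tuple[int, int] = (1, 6)
    noise_lmax: int = 10
    subdivisions: int = 4
    radius: float = 67.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sessions < 2:
            raise ValueError("n_sessions must be >= 2")
        if min(self.subject_sd, self.asym_sd, self.session_sd) < 0:
            raise ValueError("amplitudes must be >= 0")
        lo, hi = self.scale_band
        if not (1 <= lo <= hi <= self.noise_lmax):
            raise ValueError("scale_band must lie within 1..noise_lmax")


def _band_amplitudes(sd: float, band: tuple[int, int], lmax: int) -> dict[int, float]:
    lo, hi = band
    return {ell: (sd if lo <= ell <= hi else 0.0) for ell in range(1, lmax + 1)}


def generate_cohort(spec: CohortSpec) -> dict[tuple[str, str, str], TriangleMesh]:
    """Meshes keyed by ``(subject, session, hemisphere)``.

    The left hemisphere is the displaced base sphere; the right hemisphere
    is the mirror image (x negated, winding fixed) of the base sphere
    displaced by the same subject field plus its own asymmetry and session
    fields, so ``asym_sd = session_sd = 0`` makes the hemispheres exactly
    mirror-isometric.
    """
    rng = np.random.default_rng(spec.seed)
    base = icosphere(spec.subdivisions, spec.radius)
    directions = base.vertices / spec.radius
    degrees = list(range(1, spec.noise_lmax + 1))
    basis = _real_sh_basis(directions, degrees)

    def draw(amp: dict[int, float]) -> np.ndarray:
        f = np.zeros(len(directions))
        for ell in degrees:
            if amp[ell] > 0:
                f += basis[ell] @ rng.normal(0.0, amp[ell], size=2 * ell + 1)
        return f

    subj_amp = _band_amplitudes(spec.subject_sd, spec.scale_band, spec.noise_lmax)
    asym_amp = _band_amplitudes(spec.asym_sd, spec.scale_band, spec.noise_lmax)
    noise_amp = {ell: spec.session_sd for ell in degrees}

    mirror_faces = base.faces[:, [0, 2, 1]]
    out: dict[tuple[str, str, str], TriangleMesh] = {}
    for s in range(spec.n_subjects):
        subject = f"sub{s:03d}"
        f_subj = draw(subj_amp)
        f_asym = {"L": draw(asym_amp), "R": draw(asym_amp)}
        for t in range(spec.n_sessions):
            session = f"ses{t + 1:02d}"
            for hemi in ("L", "R"):
                f = f_subj + f_asym[hemi] + draw(noise_amp)
                factor = 1.0 + f
                if np.any(factor <= 0):
                    raise ValueError("cohort displacement collapses radius")
                verts = base.vertices * factor[:, None]
                if hemi == "R":
                    verts = verts * np.array([-1.0, 1.0, 1.0])
                    faces = mirror_faces
                else:
                    faces = base.faces
                out[(subject, session, hemi)] = TriangleMesh(
                    verts, faces.copy(),
                    {"source": f"cohort:{subject}:{session}:{hemi}"})
    return out


# ---------------------------------------------------------------------------
# twin phenotypes


@dataclass
class TwinSpec:
    """Conditions for a simulated twin/sibling phenotype cohort.

    Variance proportions (a2, c2, t2, e2) must sum to one.  Family sizes
    default to the scale of a large twin imaging cohort: MZ pairs, same-sex
    DZ pairs, and twin-pair-plus-sibling trios (alternating MZ/DZ twin
    zygosity).
    """

    n_mz_pairs: int = 138
    n_dz_pairs: int = 79
    n_sib_trios: int = 160
    a2: float = 0.1
    c2: float = 0.0
    t2: float = 0.0
    e2: float = 0.9
    beta_age: float = 0.0
    beta_sex: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        props = np.array([self.a2, self.c2, self.t2, self.e2])
        if np.any(props < 0) or np.any(props > 1):
            raise ValueError("variance proportions must lie in [0, 1]")
        if abs(props.sum() - 1.0) > 1e-9:
            raise ValueError("a2 + c2 + t2 + e2 must equal 1")


def generate_twin_phenotypes(spec: TwinSpec, n_traits: int = 1,
                             a2_per_trait=None) -> pd.DataFrame:
    """Simulate phenotypes under the ACTE decomposition.

    Returns one row per individual with columns ``subject, family,
    zygosity, role, age, sex`` and ``trait0001..``.  ``a2_per_trait``
    optionally overrides ``spec.a2`` per trait (the remaining variance is
    assigned to E beyond the fixed c2/t2), which is how simulations with a
    heritability profile across features are produced.
    """
    rng = np.random.default_rng(spec.seed)
    if a2_per_trait is None:
        a2_per_trait = np.full(n_traits, spec.a2)
    a2_per_trait = np.asarray(a2_per_trait, dtype=float)
    n_traits = a2_per_trait.size
    e2_per_trait = 1.0 - a2_per_trait - spec.c2 - spec.t2
    if np.any(e2_per_trait < -1e-9):
        raise ValueError("a2 + c2 + t2 exceeds 1 for some trait")
    e2_per_trait = np.clip(e2_per_trait, 0.0, None)

    families = []
    fam = 0
    for _ in range(spec.n_mz_pairs):
        families.append((fam, "MZ", ["twin1", "twin2"])); fam += 1
    for _ in range(spec.n_dz_pairs):
        families.append((fam, "DZ", ["twin1", "twin2"])); fam += 1
    for i in range(spec.n_sib_trios):
        zyg = "MZ" if i % 2 == 0 else "DZ"
        families.append((fam, zyg, ["twin1", "twin2", "sib"])); fam += 1

    a = np.sqrt(a2_per_trait)
    c = np.sqrt(spec.c2)
    t = np.sqrt(spec.t2)
    e = np.sqrt(e2_per_trait)

    rows = []
    sid = 0
    for fam_id, zygosity, roles in families:
        n = len(roles)
        # additive genetic: shared parental part + segregation part;
        # all latent draws are independent across traits
        g_fam = rng.normal(size=n_traits)
        g_mz = np.sqrt(0.5) * g_fam + np.sqrt(0.5) * rng.normal(size=n_traits)
        G = np.empty((n, n_traits))
        for i, role in enumerate(roles):
            if role.startswith("twin") and zygosity == "MZ":
                G[i] = g_mz
            else:
                G[i] = np.sqrt(0.5) * g_fam + np.sqrt(0.5) * rng.normal(size=n_traits)
        C = rng.normal(size=n_traits)              # shared within family
        T_twin = rng.normal(size=n_traits)         # shared within the twin pair
        age = rng.uniform(22.0, 36.0)
        sex_twin = int(rng.integers(2))            # MZ/DZ pairs are same-sex
        for i, role in enumerate(roles):
            T = T_twin if role.startswith("twin") else rng.normal(size=n_traits)
            E = rng.normal(size=n_traits)
            sex = sex_twin if role.startswith("twin") else int(rng.integers(2))
            ind_age = age if role.startswith("twin") else age + rng.uniform(-5, 5)
            y = (a * G[i] + c * C + t * T + e * E
                 + spec.beta_age * ind_age + spec.beta_sex * sex)
            row = {
                "subject": f"sub{sid:05d}",
                "family": f"fam{fam_id:04d}",
                "zygosity": zygosity,
                "role": role,
                "age": ind_age,
                "sex": sex,
            }
            row.update({f"trait{j + 1:04d}": y[j] for j in range(n_traits)})
            rows.append(row)
            sid += 1
    return pd.DataFrame(rows)
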