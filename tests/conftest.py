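import numpy as np
import pytest

from shapeasym.mesh import TriangleMesh
from shapeasym.spectra import compute_spectrum, normalize_area, surface_area
from shapeasym.synthetic import CohortSpec, generate_cohort, icosphere


@pytest.fixture
def tetrahedron() -> TriangleMesh:
    """Regular tetrahedron, outward-oriented: the smallest closed triangle mesh."""
    v = np.array([[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]], dtype=float)
    f = np.array([[0, 1, 2], [0, 3, 1], [0, 2, 3], [1, 3, 2]])
    return TriangleMesh(v, f)


@pytest.fixture
def unit_cube() -> TriangleMesh:
    """Unit cube split into 12 outward-oriented triangles."""
    v = np.array([[x, y, z] for x in (0, 1) for y in (0, 1) for z in (0, 1)],
                 dtype=float)
    f = np.array([
        [0, 1, 3], [0, 3, 2],          # x = 0
        [4, 7, 5], [4, 6, 7],          # x = 1
        [0, 4, 5], [0, 5, 1],          # y = 0
        [2, 3, 7], [2, 7, 6],          # y = 1
        [0, 2, 6], [0, 6, 4],          # z = 0
        [1, 5, 7], [1, 7, 3],          # z = 1
    ])
    return TriangleMesh(v, f)


@pytest.fixture(scope="session")
def ico5_spectrum():
    """First 302 eigenvalues of the unit icosphere(5), linear elements.

    Shared by the sphere-oracle and Weyl tests (the expensive solve runs
    once per session).
    """
    mesh = icosphere(5, 1.0)
    spec = compute_spectrum(mesh, k=302, degree=1)
    return mesh, spec


@pytest.fixture(scope="session")
def cohort_sas():
    """SAS and spectra features of the default synthetic cohort.

    10 subjects x 2 sessions x 2 hemispheres at icosphere(4), 121
    area-normalized eigenvalues each (through eigen-group 10).
    """
    spec = CohortSpec(seed=7)
    cohort = generate_cohort(spec)
    k = 121
    feats = {}
    for key, mesh in cohort.items():
        es = normalize_area(compute_spectrum(mesh, k=k), surface_area(mesh))
        feats[key] = es.values
    subjects = sorted({key[0] for key in feats})

    def sas(session):
        return np.stack([feats[(s, session, "L")] - feats[(s, session, "R")]
                         for s in subjects])

    def spectra_of(session, hemi):
        return np.stack([feats[(s, session, hemi)] for s in subjects])

    return {
        "spec": spec,
        "subjects": subjects,
        "sas_t1": sas("ses01"),
        "sas_t2": sas("ses02"),
        "left_t1": spectra_of("ses01", "L"),
        "right_t1": spectra_of("ses01", "R"),
        "left_t2": spectra_of("ses02", "L"),
    }
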