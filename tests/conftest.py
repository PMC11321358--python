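import numpy as np
import pytest

from phrenicmap import generate_anatomy, generate_calibrated_cohort, load_study_summary


@pytest.fixture(scope="session")
def study():
    return load_study_summary()


@pytest.fixture(scope="session")
def anatomy():
    return generate_anatomy(seed=7)


@pytest.fixture(scope="session")
def cohort():
    """One deterministic calibrated cohort of 1033 site records."""
    return generate_calibrated_cohort(seed=42)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def brute_force_mesh_distance(p, vertices, faces):
    """Independent exhaustive-face oracle: plane projection + barycentric
    inclusion, else minimum over the three edge distances."""
    p = np.asarray(p, dtype=float)

    def seg_dist(u, v):
        uv = v - u
        t = np.clip(np.dot(p - u, uv) / np.dot(uv, uv), 0.0, 1.0)
        return np.linalg.norm(p - (u + t * uv))

    best = np.inf
    for fa, fb, fc in faces:
        a, b, c = vertices[fa], vertices[fb], vertices[fc]
        n = np.cross(b - a, c - a)
        nn = np.linalg.norm(n)
        n = n / nn
        off = np.dot(p - a, n)
        q = p - off * n
        # barycentric coordinates of the projection
        v0, v1, v2 = b - a, c - a, q - a
        d00, d01, d11 = np.dot(v0, v0), np.dot(v0, v1), np.dot(v1, v1)
        d20, d21 = np.dot(v2, v0), np.dot(v2, v1)
        den = d00 * d11 - d01 * d01
        v = (d11 * d20 - d01 * d21) / den
        w = (d00 * d21 - d01 * d20) / den
        if v >= 0 and w >= 0 and v + w <= 1:
            d = abs(off)
        else:
            d = min(seg_dist(a, b), seg_dist(b, c), seg_dist(c, a))
        best = min(best, d)
    return best
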