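"""Synthetic data: geometric anatomy and calibrated statistical cohorts.

Two generators stand in for the undeposited clinical raw data.

* The **geometric** generator builds a left-atrium-like endocardial shell with
  four pulmonary-vein ostia and an epicardial nerve polyline whose clearance
  to the septal shell spans ~1 mm to >30 mm, then samples pacing sites on the
  endocardium. It feeds the full image/registration/capture pipeline.

* The **calibrated** generator draws per-category site-to-nerve distances from
  truncated normal distributions whose post-truncation mean and SD are solved
  to match the published per-category summaries (n, mean, SD, minimum). The
  truncation at the printed minimum is essential: untruncated normals put
  probability mass at implausibly small distances in the remote categories and
  understate the high specificities of the high-output cutoffs.

Cohorts are tidy tables with one row per pacing site (the analysis atom):
site_id, patient_id, region, distance_mm, category.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
import trimesh
from scipy import optimize, stats

from .capture import ThresholdCategory
from .geometry import Polyline3, TriangleMesh, points_to_polyline_distances

__all__ = [
    "CategorySummary",
    "AnatomyModel",
    "load_study_summary",
    "calibrate_truncated_normal",
    "generate_calibrated_cohort",
    "generate_anatomy",
    "sample_pacing_sites",
    "REGION_LA_SEPTAL",
    "REGION_SVC_RA",
]

REGION_LA_SEPTAL = "LA-septal"
REGION_SVC_RA = "SVC/RA"


@dataclass(frozen=True)
class CategorySummary:
    """Per-category published summary: count, distance mean/SD/minimum (mm)."""

    label: str
    n: int
    mean_mm: float
    sd_mm: float
    min_mm: float

    def __post_init__(self):
        if self.n < 0 or self.sd_mm < 0 or self.min_mm > self.mean_mm:
            raise ValueError("invalid category summary")


def load_study_summary() -> dict:
    """Packaged published-summary fixture (counts, category summaries, reference
    diagnostics). Category summaries are returned as :class:`CategorySummary`."""
    with resources.files("phrenicmap.data").joinpath("study_summary.json").open() as fh:
        raw = json.load(fh)
    raw["categories"] = [CategorySummary(**c) for c in raw["categories"]]
    return raw


def calibrate_truncated_normal(mean_mm: float, sd_mm: float, lower_mm: float):
    """Parent (mu, sigma) of a lower-truncated normal with given realized moments.

    Solves the truncated-normal moment equations so the distribution truncated
    at ``lower_mm`` has post-truncation mean ``mean_mm`` and SD ``sd_mm``
    (residuals < 1e-6).
    """
    if mean_mm <= lower_mm:
        raise ValueError("target mean must exceed the truncation bound")
    if sd_mm <= 0:
        raise ValueError("target SD must be > 0")

    def eqs(x):
        mu, log_sig = x
        sig = np.exp(log_sig)
        a = (lower_mm - mu) / sig
        d = stats.truncnorm(a, np.inf, loc=mu, scale=sig)
        return [d.mean() - mean_mm, d.std() - sd_mm]

    sol = optimize.root(eqs, x0=[mean_mm, np.log(sd_mm)], tol=1e-12)
    if not sol.success or np.max(np.abs(sol.fun)) > 1e-6:
        raise RuntimeError(f"truncated-normal calibration failed: {sol.message}")
    return float(sol.x[0]), float(np.exp(sol.x[1]))


def _assign_patients(n_records: int, n_patients: int, rng: np.random.Generator) -> np.ndarray:
    """Random site->patient assignment (counts ~ multinomial, mean n/n_patients)."""
    return rng.integers(0, n_patients, size=n_records)


def generate_calibrated_cohort(summaries=None, seed: int | np.random.Generator = 0,
                               n_patients: int = 45, la_fraction: float | None = None
                               ) -> pd.DataFrame:
    """Cohort of site-distance records matching the published category summaries.

    For each category, exactly ``n`` distances are drawn from its calibrated
    lower-truncated normal. Region labels follow the published LA vs SVC/RA
    site split (872/161 by default) independently of category, and sites are
    spread over ``n_patients`` synthetic patients. Deterministic per seed.
    """
    study = None
    if summaries is None:
        study = load_study_summary()
        summaries = study["categories"]
    if la_fraction is None:
        study = study or load_study_summary()
        la_fraction = study["n_la_sites"] / study["n_sites"]
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    frames = []
    for cat, s in zip(ThresholdCategory, summaries):
        mu, sig = calibrate_truncated_normal(s.mean_mm, s.sd_mm, s.min_mm)
        a = (s.min_mm - mu) / sig
        d = stats.truncnorm.rvs(a, np.inf, loc=mu, scale=sig, size=s.n, random_state=rng)
        frames.append(pd.DataFrame({"distance_mm": d, "category": int(cat)}))
    df = pd.concat(frames, ignore_index=True)
    df.insert(0, "site_id", np.arange(len(df)))
    df.insert(1, "patient_id", _assign_patients(len(df), n_patients, rng))
    df.insert(2, "region", np.where(rng.random(len(df)) < la_fraction,
                                    REGION_LA_SEPTAL, REGION_SVC_RA))
    return df


# --------------------------------------------------------------------------
# geometric anatomy
# --------------------------------------------------------------------------

@dataclass
class AnatomyModel:
    """Synthetic atrial anatomy in the CT (image) frame.

    ``shell`` is the closed left-atrium-like ellipsoid endocardial surface
    (PV ostia stubs are carried separately in ``pv_tubes`` so the shell stays
    watertight); ``nerve_path`` runs epicardially near the right-superior-PV /
    SVC aspect; ``pv_ostia`` are the four ostium center landmarks used as
    registration fiducials.
    """

    shell: TriangleMesh
    nerve_path: Polyline3
    pv_ostia: np.ndarray          # (4, 3) mm
    pv_tubes: TriangleMesh | None
    semi_axes_mm: np.ndarray      # (3,)
    clearance_range_mm: tuple     # configured (min, max) nerve-to-shell clearance

    @property
    def centroid(self) -> np.ndarray:
        return self.shell.vertices.mean(axis=0)

    def fiducials(self) -> np.ndarray:
        """Registration landmarks: four PV ostium centers + chamber centroid."""
        return np.vstack([self.pv_ostia, self.centroid])


def _ellipsoid_point(theta, phi, semi):
    return np.stack([semi[0] * np.cos(theta) * np.cos(phi),
                     semi[1] * np.sin(theta) * np.cos(phi),
                     semi[2] * np.sin(phi)], axis=-1)


def _ellipsoid_normal(p, semi):
    n = p / semi ** 2
    return n / np.linalg.norm(n, axis=-1, keepdims=True)


def generate_anatomy(seed: int = 0, semi_axes_mm=(30.0, 25.0, 25.0),
                     clearance_min_mm: float = 1.2, clearance_max_mm: float = 32.0,
                     n_nerve_vertices: int = 80, subdivisions: int = 3) -> AnatomyModel:
    """Left-atrium-like shell, PV ostia landmarks and an epicardial nerve path.

    The shell is an icosphere scaled to ``semi_axes_mm`` (+x is the septal /
    right-PV aspect). The nerve path follows a meridian on the +x side,
    offset outward along the surface normal by a smooth clearance profile that
    dips to ``clearance_min_mm`` near the right-superior-PV level and grows to
    ``clearance_max_mm`` at both ends, reproducing the clinical finding that
    endocardium-to-nerve proximity spans ~1 mm to beyond 3 cm. Deterministic
    per seed (the seed jitters the meridian and the clearance profile shape).
    """
    if not (0 < clearance_min_mm < clearance_max_mm):
        raise ValueError("need 0 < clearance_min < clearance_max")
    semi = np.asarray(semi_axes_mm, dtype=float)
    rng = np.random.default_rng(seed)

    sphere = trimesh.creation.icosphere(subdivisions=subdivisions, radius=1.0)
    shell = TriangleMesh(np.asarray(sphere.vertices) * semi, np.asarray(sphere.faces))

    # PV ostia: two right-sided (septal, +x) and two left-sided (-x), superior/inferior
    ang = np.radians([[20, 35], [20, -25], [160, 35], [160, -25]])
    ang += rng.normal(0, np.radians(2), size=ang.shape)
    pv_ostia = _ellipsoid_point(ang[:, 0], ang[:, 1], semi)

    tubes = []
    for p in pv_ostia:
        n = _ellipsoid_normal(p, semi)
        seg = np.vstack([p, p + 8.0 * n])
        tubes.append(trimesh.creation.cylinder(radius=5.0, segment=seg, sections=16))
    tube_mesh = trimesh.util.concatenate(tubes)
    pv_tubes = TriangleMesh(np.asarray(tube_mesh.vertices), np.asarray(tube_mesh.faces))

    # nerve meridian on the septal (+x) aspect, vertical course past the RSPV level
    phi = np.linspace(np.radians(-55), np.radians(60), n_nerve_vertices)
    theta = np.radians(18.0 + rng.normal(0, 1.5)) + 0.15 * np.sin(2 * phi + rng.normal(0, 0.3))
    surf = _ellipsoid_point(theta, phi, semi)
    normals = _ellipsoid_normal(surf, semi)
    # clearance dips to the minimum near the RSPV level (phi ~ +30 deg)
    phi0 = np.radians(30.0 + rng.normal(0, 2.0))
    u = (phi - phi0) / (phi.max() - phi.min())
    profile = clearance_min_mm + (clearance_max_mm - clearance_min_mm) * np.minimum(
        (2.2 * np.abs(u)) ** 1.5, 1.0)
    nerve = Polyline3(surf + profile[:, None] * normals)

    model = AnatomyModel(shell, nerve, pv_ostia, pv_tubes, semi,
                         (clearance_min_mm, clearance_max_mm))
    # invariant: every nerve vertex strictly outside the closed shell
    inside = np.sum((nerve.vertices / semi) ** 2, axis=1)
    if np.any(inside <= 1.0):
        raise RuntimeError("generated nerve path intersects the endocardial shell")
    return model


def sample_pacing_sites(anatomy: AnatomyModel, n_sites: int, region: str = REGION_LA_SEPTAL,
                        seed: int | np.random.Generator = 0, n_patients: int = 45
                        ) -> pd.DataFrame:
    """Pacing sites on the shell surface within a region patch, with true distances.

    ``LA-septal`` samples the +x (right-PV septal) aspect; ``SVC/RA`` the
    superior (+z) cap. Sites are drawn area-weighted over the patch faces with
    uniform barycentric coordinates, so each site lies exactly on the surface.
    The true shortest distance to the nerve centerline is computed and stored.
    """
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    v, f = anatomy.shell.vertices, anatomy.shell.faces
    tri_c = v[f].mean(axis=1)
    unit = tri_c / anatomy.semi_axes_mm
    if region == REGION_LA_SEPTAL:
        # septal patch facing the right PVs, confined to the nerve's expected
        # course so site distances span ~1 mm to >3 cm
        mask = unit[:, 0] > 0.8
    elif region == REGION_SVC_RA:
        mask = unit[:, 2] > 0.55
    else:
        raise ValueError(f"unknown region label: {region!r}")
    faces = f[mask]
    a, b, c = v[faces[:, 0]], v[faces[:, 1]], v[faces[:, 2]]
    area = 0.5 * np.linalg.norm(np.cross(b - a, c - a), axis=1)
    pick = rng.choice(len(faces), size=n_sites, p=area / area.sum())
    r1, r2 = rng.random(n_sites), rng.random(n_sites)
    s1 = np.sqrt(r1)
    pts = (1 - s1)[:, None] * a[pick] + (s1 * (1 - r2))[:, None] * b[pick] \
        + (s1 * r2)[:, None] * c[pick]
    d = points_to_polyline_distances(pts, anatomy.nerve_path)
    return pd.DataFrame({
        "site_id": np.arange(n_sites),
        "patient_id": _assign_patients(n_sites, n_patients, rng),
        "region": region,
        "x_mm": pts[:, 0], "y_mm": pts[:, 1], "z_mm": pts[:, 2],
        "distance_mm": d,
    })
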