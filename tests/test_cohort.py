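"""Synthetic cohorts: truncated-normal calibration, anatomy and site sampling."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from phrenicmap import (PacingProtocol, calibrate_truncated_normal,
                        generate_anatomy, generate_calibrated_cohort,
                        point_to_mesh_distance, points_to_polyline_distances,
                        sample_pacing_sites, simulate_observed_category,
                        threshold_from_distance, CaptureModelParams)
from phrenicmap.cohort import REGION_LA_SEPTAL, REGION_SVC_RA


def test_truncnorm_vanishing_truncation():
    """Bound 4+ SDs below the mean: parent moments equal the targets."""
    mu, sig = calibrate_truncated_normal(20.0, 2.0, 10.0)
    assert mu == pytest.approx(20.0, abs=1e-4)
    assert sig == pytest.approx(2.0, abs=1e-4)


@pytest.mark.parametrize("mean,sd,lower", [(19.2, 6.5, 9.4), (7.5, 3.0, 1.0)])
def test_truncnorm_monte_carlo_moments(mean, sd, lower):
    """1e6 draws from the fitted parent reproduce the target moments."""
    mu, sig = calibrate_truncated_normal(mean, sd, lower)
    a = (lower - mu) / sig
    x = sps.truncnorm.rvs(a, np.inf, loc=mu, scale=sig, size=1_000_000,
                          random_state=np.random.default_rng(5))
    assert x.mean() == pytest.approx(mean, abs=0.02)
    assert x.std(ddof=1) == pytest.approx(sd, abs=0.02)
    assert x.min() >= lower


def test_truncnorm_rejects_bad_targets():
    with pytest.raises(ValueError):
        calibrate_truncated_normal(5.0, 1.0, 5.0)
    with pytest.raises(ValueError):
        calibrate_truncated_normal(5.0, 0.0, 1.0)


def test_calibrated_cohort_structure(cohort, study):
    assert len(cohort) == 1033
    counts = cohort.groupby("category").size()
    assert list(counts) == [c.n for c in study["categories"]]
    for cat, s in enumerate(study["categories"]):
        assert cohort.loc[cohort.category == cat, "distance_mm"].min() >= s.min_mm
    assert set(cohort.region) <= {REGION_LA_SEPTAL, REGION_SVC_RA}
    assert cohort.patient_id.between(0, 44).all()
    assert (cohort.distance_mm > 0).all()


def test_calibrated_cohort_deterministic():
    a = generate_calibrated_cohort(seed=9)
    b = generate_calibrated_cohort(seed=9)
    pd.testing.assert_frame_equal(a, b)
    c = generate_calibrated_cohort(seed=10)
    assert not np.allclose(a.distance_mm, c.distance_mm)


def test_calibrated_cohort_grand_mean_lowest_category():
    """Replicate grand mean of the <=10 mA category sits at the published 7.5 mm."""
    means = [generate_calibrated_cohort(seed=s).query("category == 0").distance_mm.mean()
             for s in range(50)]
    assert np.mean(means) == pytest.approx(7.5, abs=0.15)


def test_anatomy_deterministic_and_outside_shell(anatomy):
    again = generate_anatomy(seed=7)
    assert np.array_equal(again.shell.vertices, anatomy.shell.vertices)
    assert np.array_equal(again.nerve_path.vertices, anatomy.nerve_path.vertices)
    # every nerve vertex strictly outside the closed ellipsoid shell
    q = np.sum((anatomy.nerve_path.vertices / anatomy.semi_axes_mm) ** 2, axis=1)
    assert np.all(q > 1.0)


def test_anatomy_clearance_span(anatomy):
    """Closest approach ~1-3 mm near the septum; remote ends beyond 30 mm."""
    d = np.array([point_to_mesh_distance(v, anatomy.shell)[0]
                  for v in anatomy.nerve_path.vertices])
    assert 0.8 <= d.min() <= 3.0
    assert d.max() > 25.0


def test_anatomy_infeasible_clearance_rejected():
    with pytest.raises(ValueError):
        generate_anatomy(seed=0, clearance_min_mm=5.0, clearance_max_mm=2.0)


def test_sites_on_surface_with_consistent_distances(anatomy):
    sites = sample_pacing_sites(anatomy, 50, REGION_LA_SEPTAL, seed=3)
    xyz = sites[["x_mm", "y_mm", "z_mm"]].to_numpy()
    for p in xyz[:10]:
        assert point_to_mesh_distance(p, anatomy.shell)[0] <= 1e-6
    recomputed = points_to_polyline_distances(xyz, anatomy.nerve_path)
    assert np.allclose(recomputed, sites.distance_mm)


def test_sites_region_validation(anatomy):
    with pytest.raises(ValueError, match="region"):
        sample_pacing_sites(anatomy, 5, "left ventricle", seed=0)
    svc = sample_pacing_sites(anatomy, 20, REGION_SVC_RA, seed=0)
    assert (svc.region == REGION_SVC_RA).all()


def test_geometric_threshold_distance_correlation(anatomy):
    """Geometric scenario yields a clearly positive rank correlation."""
    sites = sample_pacing_sites(anatomy, 800, seed=11)
    d = sites.distance_mm.to_numpy()
    p = CaptureModelParams()
    t = threshold_from_distance(d, p)
    cats = simulate_observed_category(t, PacingProtocol(), p.threshold_noise_sd_log,
                                      np.random.default_rng(11))
    rho = sps.spearmanr(cats, d).statistic
    assert rho > 0.5
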