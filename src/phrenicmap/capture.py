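"""Virtual-electrode capture model: site-to-nerve distance -> threshold category.

The excited tissue volume around a pacing electrode grows with output, so the
minimum current that captures the phrenic nerve encodes how far the nerve is.
We model the true capture threshold with a Weiss–Lapicque strength–duration
factor times a quadratic strength–distance term (far-field point source):

    T(d, pw) = (rheobase + k * d^2) * (1 + chronaxie / pw)

with d the shortest site-to-nerve distance (mm) and pw the pulse width (ms).
Observed thresholds get multiplicative lognormal noise and are then binned by
the clinical differential-output protocol (test at 10/20/30 mA after a 50 mA
screen, 2 ms pulses) into five categories; boundary values land in the
lower-labelled (inclusive-upper) category. ``calibrate_capture_params`` tunes
the distance coefficient and noise so simulated category-wise distance means
match a target summary.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from enum import IntEnum

import numpy as np
from scipy import optimize

__all__ = [
    "ThresholdCategory",
    "PacingProtocol",
    "CaptureModelParams",
    "threshold_from_distance",
    "distance_from_threshold",
    "simulate_observed_category",
    "calibrate_capture_params",
]


class ThresholdCategory(IntEnum):
    """Five-level ordinal capture-threshold category; higher = more remote nerve."""

    LE_10 = 0        # threshold <= 10 mA
    GT10_LE20 = 1    # > 10 and <= 20 mA
    GT20_LE30 = 2    # > 20 and <= 30 mA
    GT30_LE50 = 3    # > 30 and <= 50 mA
    NON_CAPTURE = 4  # no capture at maximum output (50 mA)

    @property
    def label(self) -> str:
        return {0: "<=10 mA", 1: ">10-<=20 mA", 2: ">20-<=30 mA",
                3: ">30-<=50 mA", 4: "non-capture at 50 mA"}[int(self)]


@dataclass(frozen=True)
class PacingProtocol:
    """Clinical pace-mapping protocol: 50 mA / 2 ms screen, then 10/20/30 mA."""

    max_output_mA: float = 50.0
    pulse_width_ms: float = 2.0
    test_levels_mA: tuple = (10.0, 20.0, 30.0)

    def __post_init__(self):
        lv = np.asarray(self.test_levels_mA, dtype=float)
        if np.any(np.diff(lv) <= 0) or lv[-1] >= self.max_output_mA:
            raise ValueError("test levels must be strictly increasing and below max output")

    @property
    def boundaries_mA(self) -> np.ndarray:
        """Upper category edges: (10, 20, 30, 50)."""
        return np.append(np.asarray(self.test_levels_mA, dtype=float), self.max_output_mA)


@dataclass
class CaptureModelParams:
    """Strength–duration / strength–distance parameters.

    rheobase_mA: asymptotic capture current at zero distance and long pulses.
    chronaxie_ms: pulse width doubling the rheobase (~1.5 ms for phrenic nerve).
    distance_coeff_mA_per_mm2: quadratic growth of threshold with distance.
    threshold_noise_sd_log: SD of multiplicative lognormal threshold noise.
    """

    rheobase_mA: float = 3.5
    chronaxie_ms: float = 1.5
    distance_coeff_mA_per_mm2: float = 0.11
    threshold_noise_sd_log: float = 0.80

    def __post_init__(self):
        if min(self.rheobase_mA, self.chronaxie_ms, self.distance_coeff_mA_per_mm2) <= 0:
            raise ValueError("rheobase, chronaxie and distance coefficient must be > 0")
        if self.threshold_noise_sd_log < 0:
            raise ValueError("noise SD must be >= 0")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "CaptureModelParams":
        with open(path) as fh:
            return cls(**json.load(fh))


def threshold_from_distance(d_mm, params: CaptureModelParams,
                            pulse_width_ms: float = 2.0):
    """Noise-free capture threshold (mA) at distance ``d_mm``; vectorized.

    Strictly increasing in distance and decreasing in pulse width.
    """
    d = np.asarray(d_mm, dtype=float)
    if np.any(d < 0):
        raise ValueError("distance must be >= 0")
    sd_factor = 1.0 + params.chronaxie_ms / pulse_width_ms
    out = (params.rheobase_mA + params.distance_coeff_mA_per_mm2 * d ** 2) * sd_factor
    return float(out) if np.isscalar(d_mm) else out


def distance_from_threshold(t_mA, params: CaptureModelParams,
                            pulse_width_ms: float = 2.0):
    """Algebraic inverse of :func:`threshold_from_distance` (noise-free)."""
    t = np.asarray(t_mA, dtype=float)
    sd_factor = 1.0 + params.chronaxie_ms / pulse_width_ms
    d2 = (t / sd_factor - params.rheobase_mA) / params.distance_coeff_mA_per_mm2
    out = np.sqrt(np.maximum(d2, 0.0))
    return float(out) if np.isscalar(t_mA) else out


def classify_threshold(t_mA, protocol: PacingProtocol = PacingProtocol()) -> np.ndarray:
    """Bin a threshold into its protocol category (upper edges inclusive)."""
    t = np.atleast_1d(np.asarray(t_mA, dtype=float))
    edges = protocol.boundaries_mA
    # side='left': t exactly on an edge stays in the lower-labelled bin
    cat = np.searchsorted(edges, t, side="left")
    return cat.astype(int)


def simulate_observed_category(true_threshold_mA, protocol: PacingProtocol,
                               noise_sd_log: float,
                               seed: int | np.random.Generator = 0) -> np.ndarray:
    """Observed categories after multiplicative lognormal threshold noise.

    Non-capture is recorded when the noisy threshold exceeds the protocol's
    maximum output; deterministic for a fixed seed.
    """
    t = np.atleast_1d(np.asarray(true_threshold_mA, dtype=float))
    if np.any(t <= 0):
        raise ValueError("true threshold must be > 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    noisy = t * np.exp(rng.normal(0.0, noise_sd_log, size=t.shape)) if noise_sd_log > 0 else t
    return classify_threshold(noisy, protocol)


def _category_means(distances, cats, n_cat=5):
    return np.array([distances[cats == k].mean() if np.any(cats == k) else np.nan
                     for k in range(n_cat)])


def calibrate_capture_params(target_summary, seed: int = 0, distances=None,
                             n_sim: int = 20000, protocol: PacingProtocol = PacingProtocol(),
                             fit_rheobase: bool = True, chronaxie_ms: float = 1.5,
                             rheobase_mA: float = 3.5):
    """Fit the capture model so simulated category distance means match targets.

    ``target_summary`` is a sequence of five (n, mean_mm) pairs — or objects
    with ``.n``/``.mean_mm`` — ordered by category. Simulated distances are
    drawn (or passed in) once, common random numbers are reused across
    objective evaluations, and Nelder–Mead minimizes the mean squared error of
    the five category-wise distance means (equal category weights). Free
    parameters are the distance coefficient, the lognormal noise SD and, by
    default, the rheobase. Returns ``(params, achieved_rmse_mm)``.
    Non-monotone target means trigger a warning but still get a best-effort fit.
    """
    import warnings

    tgt = [(getattr(c, "n", None) or c[0], getattr(c, "mean_mm", None) or c[1])
           for c in target_summary]
    if len(tgt) != 5 or any(n <= 0 for n, _ in tgt):
        raise ValueError("target summary must have 5 categories with positive n")
    tmean = np.array([m for _, m in tgt], dtype=float)
    if np.any(np.diff(tmean) < 0):
        warnings.warn("target category means are non-monotone; fitting best-effort")

    rng = np.random.default_rng(seed)
    if distances is None:
        # distance field spanning the clinical 1 mm .. >30 mm range
        distances = rng.uniform(1.0, 32.0, size=n_sim)
    distances = np.asarray(distances, dtype=float)
    z = rng.normal(size=distances.shape)  # common random numbers

    def unpack(x):
        if fit_rheobase:
            rb, k, sig = np.exp(x)
        else:
            rb = rheobase_mA
            k, sig = np.exp(x)
        return rb, k, sig

    def simulate(x):
        rb, k, sig = unpack(x)
        p = CaptureModelParams(rb, chronaxie_ms, k, sig)
        t = threshold_from_distance(distances, p, protocol.pulse_width_ms)
        return classify_threshold(t * np.exp(sig * z), protocol)

    def objective(x):
        means = _category_means(distances, simulate(x))
        err = np.where(np.isnan(means), 20.0, means - tmean)  # missing category penalty
        return float(np.mean(err ** 2))

    x0 = [np.log(0.12), np.log(0.4)]
    if fit_rheobase:
        x0 = [np.log(rheobase_mA)] + x0
    res = optimize.minimize(objective, x0=x0, method="Nelder-Mead",
                            options={"xatol": 1e-4, "fatol": 1e-9, "maxiter": 800})
    rb, k, sig = unpack(res.x)
    params = CaptureModelParams(float(rb), chronaxie_ms, float(k), float(sig))
    return params, float(np.sqrt(res.fun))
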