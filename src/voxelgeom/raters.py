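"""Simulated raters: psychometric labeling of reconstructed volumes.

A human rater deciding whether a voxel belongs to a structure is modelled as
a logistic psychometric curve in voxel intensity: the probability that an
intensity ``i`` (scaled to [0, 1]) is labeled as part of the volume is

    P(label | i) = 1 / (1 + exp(-(beta0 + beta1 * i)))

Curves can be fitted by maximum likelihood from (intensity, label) tables of
real manual labeling sessions, averaged across acquisition resolutions, and
then applied to any reconstructed volume — either stochastically (independent
Bernoulli draw per voxel) or as the deterministic expected decision
(``p >= 0.5``).  A conservative "joint" rater is the conjunction of two
raters' masks.

The *optimal* rater is different: it knows the ground-truth volume and
thresholds the image at the intensity where the suprathreshold proportion of
the FoV matches the object's proportional volume, interpolated on the
empirical survival function of the intensities.  It provides the
geometry-limited best case against which psychometric raters are compared.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy.special import expit
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .phantom import Ellipsoid, GridSpec, ImageVolume

__all__ = [
    "PsychometricCurve",
    "PsychometricFit",
    "RaterSpec",
    "LabelMask",
    "OptimalLabeling",
    "GridMismatchError",
    "DegenerateImageError",
    "DEFAULT_LIBERAL",
    "DEFAULT_JOINT",
    "logistic_probability",
    "fit_psychometric",
    "average_curves",
    "probabilistic_label",
    "conjunct_mask",
    "optimal_threshold",
    "optimal_label",
]


class GridMismatchError(ValueError):
    """Operation on masks/volumes that do not share a grid."""


class DegenerateImageError(ValueError):
    """Image has no intensity variation; a threshold cannot be interpolated."""


@dataclass(frozen=True)
class PsychometricCurve:
    """Logistic decision curve ``P(i) = expit(beta0 + beta1 * i)``."""

    beta0: float
    beta1: float

    def probability(self, intensity) -> np.ndarray:
        return expit(self.beta0 + self.beta1 * np.asarray(intensity, dtype=float))

    @property
    def midpoint(self) -> float:
        """Intensity at which the inclusion probability is 0.5."""
        if self.beta1 == 0:
            return np.nan
        return -self.beta0 / self.beta1


# Default curves for the liberal single rater and the conservative joint
# rater.  These are package placeholders with the qualitative properties of
# manually-derived curves: steep, liberal midpoint (~0.31) below the joint
# midpoint (~0.46), and a background inclusion probability P(0) small enough
# (<~1e-4) that stochastic labeling of the empty FoV does not dominate the
# labeled volume.  Any quantitative use should re-fit curves from real label
# tables via `fit_psychometric`.
DEFAULT_LIBERAL = PsychometricCurve(beta0=-9.0, beta1=29.0)  # midpoint ~0.31
DEFAULT_JOINT = PsychometricCurve(beta0=-13.0, beta1=28.0)  # midpoint ~0.46


@dataclass(frozen=True)
class PsychometricFit:
    """Result of a maximum-likelihood logistic fit.

    ``separated`` flags (quasi-)complete separation: the likelihood has no
    finite maximiser, the reported slope is capped, and standard errors are
    not meaningful.
    """

    curve: PsychometricCurve
    separated: bool
    stderr: tuple[float, float] | None
    n_obs: int


@dataclass(frozen=True)
class RaterSpec:
    """A named labeling strategy.

    ``kind`` is ``liberal``/``joint`` (psychometric; requires ``curve``) or
    ``optimal`` (threshold matching the ground-truth proportional volume; no
    curve).  ``mode`` selects stochastic Bernoulli labeling or the
    deterministic expected decision.
    """

    kind: str
    curve: PsychometricCurve | None = None
    mode: str = "stochastic"

    def __post_init__(self):
        if self.kind not in ("liberal", "joint", "optimal"):
            raise ValueError(f"unknown rater kind {self.kind!r}")
        if self.kind == "optimal":
            if self.curve is not None:
                raise ValueError("optimal rater carries no psychometric curve")
        elif self.curve is None:
            raise ValueError(f"{self.kind} rater requires a psychometric curve")
        if self.mode not in ("stochastic", "expected"):
            raise ValueError(f"unknown labeling mode {self.mode!r}")

    @property
    def name(self) -> str:
        return self.kind


def default_raters() -> list[RaterSpec]:
    return [
        RaterSpec("liberal", DEFAULT_LIBERAL),
        RaterSpec("joint", DEFAULT_JOINT),
        RaterSpec("optimal"),
    ]


@dataclass(frozen=True)
class LabelMask:
    """Binary voxel occupancy with grid metadata."""

    data: np.ndarray
    grid: GridSpec

    def __post_init__(self):
        object.__setattr__(self, "data", np.asarray(self.data, dtype=bool))
        if self.data.shape != self.grid.matrix_dims:
            raise ValueError(
                f"mask shape {self.data.shape} != matrix {self.grid.matrix_dims}"
            )

    @property
    def count(self) -> int:
        return int(self.data.sum())

    @property
    def volume(self) -> float:
        """Physical volume: occupied voxel count times voxel volume, mm^3."""
        return self.count * self.grid.voxel_volume


def logistic_probability(curve: PsychometricCurve, intensity) -> np.ndarray:
    """Inclusion probability of an intensity under a psychometric curve."""
    return curve.probability(intensity)


def fit_psychometric(
    intensity, labels, slope_cap: float = 500.0
) -> PsychometricFit:
    """Maximum-likelihood logistic fit of binary labels on intensity.

    Raises ``ValueError`` if only one label class is present.  Perfectly
    separable data (a threshold classifies all points) has no finite ML
    solution; the fit is then flagged and returned with the slope capped at
    ``slope_cap`` while preserving the separating midpoint.
    """
    intensity = np.asarray(intensity, dtype=float).ravel()
    labels = np.asarray(labels).ravel().astype(float)
    if intensity.shape != labels.shape:
        raise ValueError("intensity and labels must have the same length")
    if intensity.size == 0:
        raise ValueError("empty labeling data")
    if not set(np.unique(labels)) <= {0.0, 1.0}:
        raise ValueError("labels must be binary")
    if labels.min() == labels.max():
        raise ValueError("labeling data must contain both classes")

    exog = sm.add_constant(intensity)
    separated = False
    params = None
    stderr = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # separation + convergence warnings
        try:
            res = sm.Logit(labels, exog).fit(disp=0, maxiter=200)
            params = res.params
            stderr = res.bse
            if not res.mle_retvals.get("converged", True):
                separated = True
        except (PerfectSeparationError, np.linalg.LinAlgError):
            separated = True

    if params is None or not np.all(np.isfinite(params)):
        # Reconstruct a capped curve from the empirical separating point.
        hi0 = intensity[labels == 1].min()
        lo1 = intensity[labels == 0].max()
        mid = 0.5 * (hi0 + lo1)
        return PsychometricFit(
            curve=PsychometricCurve(beta0=-slope_cap * mid, beta1=slope_cap),
            separated=True,
            stderr=None,
            n_obs=intensity.size,
        )

    beta0, beta1 = float(params[0]), float(params[1])
    if abs(beta1) > slope_cap:
        separated = True
        mid = -beta0 / beta1
        beta1 = np.sign(beta1) * slope_cap
        beta0 = -beta1 * mid
        stderr = None
    return PsychometricFit(
        curve=PsychometricCurve(beta0=beta0, beta1=beta1),
        separated=separated,
        stderr=None if stderr is None else (float(stderr[0]), float(stderr[1])),
        n_obs=intensity.size,
    )


def average_curves(curves) -> PsychometricCurve:
    """Arithmetic mean of coefficients across curves (e.g. across resolutions)."""
    curves = list(curves)
    if not curves:
        raise ValueError("cannot average an empty list of curves")
    return PsychometricCurve(
        beta0=float(np.mean([c.beta0 for c in curves])),
        beta1=float(np.mean([c.beta1 for c in curves])),
    )


def probabilistic_label(
    img: ImageVolume,
    curve: PsychometricCurve,
    rng: np.random.Generator | int | None = None,
    mode: str = "stochastic",
) -> LabelMask:
    """Label a volume with a psychometric curve.

    ``stochastic`` draws an independent Bernoulli per voxel with probability
    ``P(i)``; ``expected`` includes a voxel iff ``P(i) >= 0.5``.  The curve
    is applied to every voxel: the logistic tails make interior voxels
    (``i ~ 1``) near-certain inclusions and background near-certain
    exclusions, so no explicit edge-voxel set is needed.
    """
    p = curve.probability(img.data)
    if mode == "expected":
        mask = p >= 0.5
    elif mode == "stochastic":
        rng = np.random.default_rng(rng)
        mask = rng.random(p.shape) < p
    else:
        raise ValueError(f"unknown labeling mode {mode!r}")
    return LabelMask(data=mask, grid=img.grid)


def conjunct_mask(a: LabelMask, b: LabelMask) -> LabelMask:
    """Voxelwise intersection: only voxels both raters agreed on."""
    if a.grid != b.grid:
        raise GridMismatchError("conjunct masks must share a grid")
    return LabelMask(data=a.data & b.data, grid=a.grid)


def optimal_threshold(img: ImageVolume, target_proportion: float) -> float:
    """Intensity whose suprathreshold proportion matches a target.

    Builds the empirical survival function S(t) = fraction of voxels with
    intensity >= t over the unique intensity levels and linearly
    interpolates the level at which S equals ``target_proportion``.
    """
    if not 0.0 < target_proportion < 1.0:
        raise ValueError("target_proportion must lie in (0, 1)")
    values, counts = np.unique(img.data.ravel(), return_counts=True)
    if values.size < 2:
        raise DegenerateImageError("constant image: no threshold exists")
    n = img.data.size
    # survival[j] = fraction of voxels >= values[j]; decreasing in j
    survival = counts[::-1].cumsum()[::-1] / n
    # np.interp needs ascending x: traverse values from high to low
    return float(np.interp(target_proportion, survival[::-1], values[::-1]))


@dataclass(frozen=True)
class OptimalLabeling:
    """Optimal-rater output.

    ``mask`` is the discrete suprathreshold mask (used for Dice);
    ``continuous_volume`` is the proportion-matched volume
    ``target_proportion * fov_volume``, the quantity the optimal threshold
    matches exactly before voxel quantization.  At coarse grids the discrete
    mask volume can only approximate it to within about one voxel.
    """

    mask: LabelMask
    threshold: float
    target_proportion: float
    continuous_volume: float


def optimal_label(
    img: ImageVolume, truth: Ellipsoid | float, fov=None
) -> OptimalLabeling:
    """Threshold a volume so its labeled proportion matches the ground truth.

    ``truth`` is the ground-truth ellipsoid (or its volume in mm^3); the
    target proportion is the fraction of the FoV cube the object occupies
    (``fov`` defaults to the image's own FoV).
    """
    truth_volume = truth.volume if isinstance(truth, Ellipsoid) else float(truth)
    if truth_volume <= 0:
        raise ValueError("truth volume must be positive")
    fov_volume = (
        img.grid.fov_volume if fov is None else float(np.prod(np.broadcast_to(fov, 3)))
    )
    target = truth_volume / fov_volume
    t = optimal_threshold(img, target)
    mask = LabelMask(data=img.data >= t, grid=img.grid)
    return OptimalLabeling(
        mask=mask,
        threshold=t,
        target_proportion=target,
        continuous_volume=target * fov_volume,
    )
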