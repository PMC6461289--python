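"""Analytic ellipsoid phantoms and their k-space reconstruction.

The phantom is a set of ellipsoids with known geometry (semi-axes, pose,
signal amplitude) in world space.  The continuous Fourier transform of an
ellipsoid indicator function has a closed form, so the MR acquisition of a
noise-free object can be simulated exactly: evaluate that closed form at the
discrete spatial frequencies of a Cartesian k-space grid and reconstruct by
inverse DFT.  The reconstruction exhibits the partial-volume ramps and Gibbs
ringing of a real acquisition at the same voxel geometry, which is the effect
under study.

Conventions
-----------
* World coordinates are in mm, with the origin at the centre of the field of
  view.  Voxel centres are cell-centred: voxel ``m`` along an axis with
  ``n`` voxels of size ``d`` sits at ``-fov/2 + (m + 0.5) * d``, symmetric
  for even and odd ``n``.
* Spatial frequencies are in cycles/mm at integer multiples of ``1/fov`` per
  axis, stored in ``numpy.fft.fftfreq`` order with the DC sample at index
  ``(0, 0, 0)``.  The forward transform uses the ``exp(-2*pi*i*k.x)`` sign.
* Rotations are intrinsic x-y-z Euler angles in degrees.  An object's own
  rotation is applied first, then the pose rotation, both about the FoV
  centre; the pose translation is applied last.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "Ellipsoid",
    "RigidTransform",
    "RigidBounds",
    "GridSpec",
    "KSpaceVolume",
    "ImageVolume",
    "GridAlignmentError",
    "ORIENTATIONS",
    "default_ellipsoid",
    "ellipsoid_volume",
    "base_orientation",
    "sample_rigid_transform",
    "analytic_kspace",
    "reconstruct",
    "rasterize_oracle",
]

#: Tags for the orientation of the ellipsoid's long axis relative to the
#: slice (z) axis.
ORIENTATIONS = ("parallel", "diagonal", "orthogonal")


class GridAlignmentError(ValueError):
    """FoV is not an integer number of voxels along some axis."""


def _as_vec3(value, name: str) -> tuple[float, float, float]:
    vec = tuple(float(v) for v in np.broadcast_to(value, (3,)))
    if not all(np.isfinite(vec)):
        raise ValueError(f"{name} must be finite, got {value!r}")
    return vec


@dataclass(frozen=True)
class Ellipsoid:
    """Geometric ground truth: a triaxial ellipsoid in world space.

    Parameters
    ----------
    semi_axes
        Semi-axis lengths (a, b, c) in mm, all positive.  The default
        phantom of this package has its long axis along z.
    center
        Centre offset from the FoV centre, mm.
    rotation
        Intrinsic x-y-z Euler angles, degrees.
    intensity
        Signal amplitude (unitless); the reconstruction is later rescaled
        to [0, 1] so only relative amplitudes matter.
    """

    semi_axes: tuple[float, float, float]
    center: tuple[float, float, float] = (0.0, 0.0, 0.0)
    rotation: tuple[float, float, float] = (0.0, 0.0, 0.0)
    intensity: float = 1.0

    def __post_init__(self):
        object.__setattr__(self, "semi_axes", _as_vec3(self.semi_axes, "semi_axes"))
        object.__setattr__(self, "center", _as_vec3(self.center, "center"))
        object.__setattr__(self, "rotation", _as_vec3(self.rotation, "rotation"))
        if min(self.semi_axes) <= 0:
            raise ValueError("semi_axes must be positive")
        if self.intensity <= 0:
            raise ValueError("intensity must be positive")

    @property
    def volume(self) -> float:
        """Exact volume (4/3)*pi*a*b*c in mm^3."""
        a, b, c = self.semi_axes
        return 4.0 / 3.0 * np.pi * a * b * c

    def rotation_matrix(self) -> np.ndarray:
        return Rotation.from_euler("xyz", self.rotation, degrees=True).as_matrix()


def default_ellipsoid() -> Ellipsoid:
    """The study's reference object: semi-axes 2.7 x 2.7 x 5.4 mm.

    Its 164.9 mm^3 volume is in the range of deep-brain-stimulation targets
    such as the subthalamic nucleus and the internal globus pallidus.
    """
    return Ellipsoid(semi_axes=(2.7, 2.7, 5.4))


def ellipsoid_volume(e: Ellipsoid) -> float:
    """Closed-form volume of an ellipsoid, mm^3."""
    return e.volume


@dataclass(frozen=True)
class RigidTransform:
    """Rigid-body motion: rotation (Euler x-y-z, degrees) then translation (mm)."""

    translation: tuple[float, float, float] = (0.0, 0.0, 0.0)
    rotation: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        object.__setattr__(
            self, "translation", _as_vec3(self.translation, "translation")
        )
        object.__setattr__(self, "rotation", _as_vec3(self.rotation, "rotation"))

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls()

    def rotation_matrix(self) -> np.ndarray:
        return Rotation.from_euler("xyz", self.rotation, degrees=True).as_matrix()

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Map object-frame points (..., 3) to world frame."""
        return points @ self.rotation_matrix().T + np.asarray(self.translation)

    def compose(self, inner: "RigidTransform") -> "RigidTransform":
        """Return ``self o inner`` (apply ``inner`` first, then ``self``)."""
        r_outer = self.rotation_matrix()
        r_total = r_outer @ inner.rotation_matrix()
        t_total = r_outer @ np.asarray(inner.translation) + np.asarray(
            self.translation
        )
        euler = Rotation.from_matrix(r_total).as_euler("xyz", degrees=True)
        return RigidTransform(translation=tuple(t_total), rotation=tuple(euler))


@dataclass(frozen=True)
class RigidBounds:
    """Uniform sampling ranges for rigid-body variation, per axis."""

    translation: tuple[float, float] = (-4.0, 4.0)  # mm
    rotation: tuple[float, float] = (-8.0, 8.0)  # degrees

    def __post_init__(self):
        for name in ("translation", "rotation"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name} bounds inverted: {lo} > {hi}")


def base_orientation(tag: str) -> RigidTransform:
    """Pure rotation placing the object's long (z) axis relative to the slice axis.

    ``parallel`` leaves the long axis on z, ``diagonal`` tilts it 45 degrees
    about x, ``orthogonal`` puts it in the imaging plane (90 degrees about x).
    """
    angles = {"parallel": 0.0, "diagonal": 45.0, "orthogonal": 90.0}
    if tag not in angles:
        raise ValueError(f"unknown orientation {tag!r}; expected one of {ORIENTATIONS}")
    return RigidTransform(rotation=(angles[tag], 0.0, 0.0))


def sample_rigid_transform(
    rng: np.random.Generator | int | None,
    bounds: RigidBounds = RigidBounds(),
) -> RigidTransform:
    """Draw a random rigid-body transform, uniform per axis within ``bounds``."""
    rng = np.random.default_rng(rng)
    t = rng.uniform(*bounds.translation, size=3)
    r = rng.uniform(*bounds.rotation, size=3)
    return RigidTransform(translation=tuple(t), rotation=tuple(r))


@dataclass(frozen=True)
class GridSpec:
    """Acquisition geometry: FoV, in-plane voxel size and slice-thickness factor.

    Voxel dimensions are ``(in_plane, in_plane, in_plane * thickness_factor)``;
    the matrix size is ``fov / voxel`` per axis and must be integral (the
    factorial design is chosen so that no interpolation is ever needed).
    """

    fov: tuple[float, float, float] = (36.0, 36.0, 36.0)
    in_plane: float = 1.0
    thickness_factor: float = 1.0

    def __post_init__(self):
        object.__setattr__(self, "fov", _as_vec3(self.fov, "fov"))
        if min(self.fov) <= 0:
            raise ValueError("fov must be positive")
        if self.in_plane <= 0 or self.thickness_factor <= 0:
            raise ValueError("voxel dimensions must be positive")
        self.matrix_dims  # validate integrality eagerly

    @classmethod
    def isotropic(cls, fov, size: float) -> "GridSpec":
        return cls(fov=_as_vec3(fov, "fov"), in_plane=size, thickness_factor=1.0)

    @property
    def voxel_dims(self) -> tuple[float, float, float]:
        return (self.in_plane, self.in_plane, self.in_plane * self.thickness_factor)

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.voxel_dims))

    @property
    def fov_volume(self) -> float:
        return float(np.prod(self.fov))

    @property
    def matrix_dims(self) -> tuple[int, int, int]:
        dims = []
        for f, d in zip(self.fov, self.voxel_dims):
            exact = f / d
            n = round(exact)
            if abs(n - exact) > 1e-6:
                raise GridAlignmentError(
                    f"FoV {f} mm is not an integer number of {d} mm voxels"
                )
            dims.append(int(n))
        if min(dims) < 1:
            raise GridAlignmentError("matrix dimensions must all be >= 1")
        return tuple(dims)

    @property
    def is_isotropic(self) -> bool:
        return self.thickness_factor == 1.0

    def axis_coords(self, axis: int) -> np.ndarray:
        """World coordinates of voxel centres along one axis (cell-centred)."""
        n = self.matrix_dims[axis]
        d = self.voxel_dims[axis]
        return -self.fov[axis] / 2.0 + (np.arange(n) + 0.5) * d

    def axis_freqs(self, axis: int) -> np.ndarray:
        """Spatial frequencies (cycles/mm) along one axis, fftfreq order."""
        return np.fft.fftfreq(self.matrix_dims[axis], d=self.voxel_dims[axis])


@dataclass(frozen=True)
class KSpaceVolume:
    """Complex k-space samples on the Cartesian grid conjugate to a GridSpec."""

    data: np.ndarray
    grid: GridSpec

    def __post_init__(self):
        if self.data.shape != self.grid.matrix_dims:
            raise ValueError(
                f"k-space shape {self.data.shape} != matrix {self.grid.matrix_dims}"
            )

    @property
    def dc_index(self) -> tuple[int, int, int]:
        return (0, 0, 0)

    @property
    def dc_value(self) -> float:
        """DC sample: the total integrated signal (sum of intensity x volume)."""
        return float(self.data[self.dc_index].real)


@dataclass(frozen=True)
class ImageVolume:
    """Real-valued reconstructed intensities on a voxel grid."""

    data: np.ndarray
    grid: GridSpec
    scaled: bool = True

    def __post_init__(self):
        if self.data.shape != self.grid.matrix_dims:
            raise ValueError(
                f"image shape {self.data.shape} != matrix {self.grid.matrix_dims}"
            )
        if self.scaled and self.data.size:
            lo, hi = float(self.data.min()), float(self.data.max())
            if lo < -1e-9 or hi > 1.0 + 1e-9:
                raise ValueError(f"scaled image outside [0, 1]: [{lo}, {hi}]")


def _sphere_form(u: np.ndarray) -> np.ndarray:
    """Radial Fourier profile of a unit ball, normalised to 1 at u=0.

    Computes ``3 * (sin u - u cos u) / u**3`` with the small-``u`` series
    ``1 - u^2/10 + u^4/280`` used below ``u = 1e-3`` to avoid cancellation.
    """
    u = np.asarray(u, dtype=float)
    out = np.empty_like(u)
    small = u < 1e-3
    us = u[small]
    out[small] = 1.0 - us**2 / 10.0 + us**4 / 280.0
    ub = u[~small]
    out[~small] = 3.0 * (np.sin(ub) - ub * np.cos(ub)) / ub**3
    return out


def _object_frame(e: Ellipsoid, pose: RigidTransform) -> tuple[np.ndarray, np.ndarray]:
    """World rotation matrix and world centre of an ellipsoid under a pose."""
    r_pose = pose.rotation_matrix()
    r = r_pose @ e.rotation_matrix()
    t = r_pose @ np.asarray(e.center) + np.asarray(pose.translation)
    return r, t


def analytic_kspace(
    objects, pose: RigidTransform = RigidTransform(), grid: GridSpec = GridSpec()
) -> KSpaceVolume:
    """Exact k-space signal of posed ellipsoids on a discrete frequency grid.

    For a unit-intensity ellipsoid with semi-axes (a, b, c), rotation R and
    world centre t, the continuous Fourier transform at frequency vector k is

        F(k) = V * f(2*pi*|K|) * exp(-2*pi*i * k.t),
        K = (a*k'_x, b*k'_y, c*k'_z),  k' = R^T k,

    where V is the ellipsoid volume and f is the unit-ball radial profile
    ``3(sin u - u cos u)/u^3`` (f(0) = 1, handled by its series).  Rotation
    acts on the frequency vector, translation is a pure phase ramp, and the
    DC sample equals intensity x volume.  Contributions of multiple objects
    add linearly.
    """
    if isinstance(objects, Ellipsoid):
        objects = [objects]
    objects = list(objects)
    if not objects:
        raise ValueError("at least one object is required")

    kx = grid.axis_freqs(0)[:, None, None]
    ky = grid.axis_freqs(1)[None, :, None]
    kz = grid.axis_freqs(2)[None, None, :]

    signal = np.zeros(grid.matrix_dims, dtype=complex)
    for e in objects:
        r, t = _object_frame(e, pose)
        a, b, c = e.semi_axes
        # k' = R^T k, component-wise; scale by semi-axes and take the norm.
        u = np.sqrt(
            (a * (r[0, 0] * kx + r[1, 0] * ky + r[2, 0] * kz)) ** 2
            + (b * (r[0, 1] * kx + r[1, 1] * ky + r[2, 1] * kz)) ** 2
            + (c * (r[0, 2] * kx + r[1, 2] * ky + r[2, 2] * kz)) ** 2
        )
        amp = (e.intensity * e.volume) * _sphere_form(2.0 * np.pi * u)
        del u
        # Separable phase ramp for the world-centre translation.
        px = np.exp(-2j * np.pi * t[0] * kx)
        py = np.exp(-2j * np.pi * t[1] * ky)
        pz = np.exp(-2j * np.pi * t[2] * kz)
        contrib = amp * px
        del amp
        contrib *= py
        contrib *= pz
        signal += contrib
        del contrib
    return KSpaceVolume(data=signal, grid=grid)


def reconstruct(ks: KSpaceVolume, scale: bool = True) -> ImageVolume:
    """Inverse DFT of a k-space volume onto its image grid.

    Takes the real part (the phantom is real-valued; the imaginary residual
    is sampling asymmetry) and divides by the voxel volume so that raw
    intensities approximate the partial-volume occupancy fraction.  With
    ``scale=True`` (default) intensities are then min-max rescaled to
    [0.0, 1.0] per volume, which also folds the negative Gibbs undershoot
    into the displayed range the way a windowed MR image would.
    """
    grid = ks.grid
    data = ks.data
    # Phase shift so samples land on cell-centred world coordinates.
    shifted = data
    for axis in range(3):
        k = grid.axis_freqs(axis)
        w0 = -grid.fov[axis] / 2.0 + grid.voxel_dims[axis] / 2.0
        phase = np.exp(2j * np.pi * k * w0)
        shape = [1, 1, 1]
        shape[axis] = -1
        shifted = shifted * phase.reshape(shape)
    img = np.fft.ifftn(shifted).real / grid.voxel_volume
    if scale:
        lo, hi = img.min(), img.max()
        if hi - lo <= 0:
            raise ValueError("constant image cannot be rescaled to [0, 1]")
        img = (img - lo) / (hi - lo)
    return ImageVolume(data=img, grid=grid, scaled=scale)


def rasterize_oracle(
    objects,
    pose: RigidTransform = RigidTransform(),
    grid: GridSpec = GridSpec(),
    subdivisions: int = 4,
) -> ImageVolume:
    """Brute-force partial-volume rasterization, for cross-checking.

    Estimates the occupancy fraction of each voxel by testing a regular
    ``subdivisions**3`` lattice of sub-voxel points against the analytic
    ellipsoid membership; converges to the exact partial volume as the
    subdivision count grows.  Independent of the Fourier pathway.
    """
    if isinstance(objects, Ellipsoid):
        objects = [objects]
    if subdivisions < 1:
        raise ValueError("subdivisions must be >= 1")
    s = int(subdivisions)
    dims = grid.matrix_dims
    vox = grid.voxel_dims
    acc = np.zeros(dims, dtype=float)
    base = [grid.axis_coords(ax) for ax in range(3)]
    offsets = (np.arange(s) + 0.5) / s - 0.5  # in voxel units
    for e in objects:
        r, t = _object_frame(e, pose)
        inv_axes = 1.0 / np.asarray(e.semi_axes)
        frac = np.zeros(dims, dtype=float)
        for ox in offsets:
            x = (base[0] + ox * vox[0] - t[0])[:, None, None]
            for oy in offsets:
                y = (base[1] + oy * vox[1] - t[1])[None, :, None]
                for oz in offsets:
                    z = (base[2] + oz * vox[2] - t[2])[None, None, :]
                    # object-frame coordinates u = R^T (x - t), scaled
                    q = (
                        ((r[0, 0] * x + r[1, 0] * y + r[2, 0] * z) * inv_axes[0]) ** 2
                        + ((r[0, 1] * x + r[1, 1] * y + r[2, 1] * z) * inv_axes[1]) ** 2
                        + ((r[0, 2] * x + r[1, 2] * y + r[2, 2] * z) * inv_axes[2]) ** 2
                    )
                    frac += q <= 1.0
        acc += e.intensity * frac / s**3
    return ImageVolume(data=acc, grid=grid, scaled=False)
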