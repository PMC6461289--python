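"""Factorial simulation experiment: voxel geometry vs. labeling accuracy.

The full design crosses random rigid-body variants of the ground-truth
ellipsoid with three orientations of its long axis relative to the slice
axis, five in-plane voxel sizes and six slice-thickness factors, labels
every reconstruction with each configured rater, and scores each labeled
mask against a per-variant reference: the optimal rater's labeling of the
same variant reconstructed at the finest (default 0.1 mm isotropic)
resolution.  Aggregation produces the per-cell accuracy surfaces, the
equal-voxel-volume isotropy comparison, the Dice-vs-deviation exponential
curve and the guideline table of acceptable voxel volumes.
"""

from __future__ import annotations

import dataclasses
import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from . import metrics
from .phantom import (
    ORIENTATIONS,
    Ellipsoid,
    GridSpec,
    RigidBounds,
    RigidTransform,
    analytic_kspace,
    base_orientation,
    default_ellipsoid,
    reconstruct,
    sample_rigid_transform,
)
from .raters import LabelMask, RaterSpec, optimal_label, probabilistic_label

__all__ = [
    "ExperimentDesign",
    "TrialRecord",
    "CurveFitError",
    "DcsDeviationFit",
    "smoke_design",
    "run_design",
    "records_to_frame",
    "summarize",
    "same_volume_comparison",
    "fit_dcs_deviation_curve",
    "guideline_table",
]

#: Field order of a trial record when written to tabular form.
TRIAL_FIELDS = (
    "variant",
    "orientation",
    "in_plane",
    "factor",
    "rater",
    "labeled_volume",
    "continuous_volume",
    "truth_volume",
    "pct_deviation",
    "dcs",
)


class CurveFitError(RuntimeError):
    """Nonlinear fit did not converge; carries optimizer diagnostics."""


@dataclass(frozen=True)
class ExperimentDesign:
    """The factorial design and everything needed to reproduce it.

    Defaults are the study conditions: 100 rigid-body variants of a
    164.9 mm^3 ellipsoid in a 36 mm cubic FoV, three orientations, in-plane
    sizes {0.1, 0.2, 0.5, 1.0, 2.0} mm and thickness factors
    {1.0, 1.2, 1.5, 1.8, 2.0, 3.0} (9000 reconstructions), with rigid-body
    variation uniform within +/-4 mm and +/-8 degrees per axis.
    """

    n_variants: int = 100
    orientations: tuple[str, ...] = ORIENTATIONS
    in_plane_sizes: tuple[float, ...] = (0.1, 0.2, 0.5, 1.0, 2.0)
    thickness_factors: tuple[float, ...] = (1.0, 1.2, 1.5, 1.8, 2.0, 3.0)
    fov: tuple[float, float, float] = (36.0, 36.0, 36.0)
    ellipsoid: Ellipsoid = field(default_factory=default_ellipsoid)
    bounds: RigidBounds = field(default_factory=RigidBounds)
    master_seed: int = 0
    reference_in_plane: float = 0.1

    def __post_init__(self):
        if self.n_variants < 1:
            raise ValueError("n_variants must be >= 1")
        for tag in self.orientations:
            base_orientation(tag)  # validates
        if min(self.in_plane_sizes) <= 0 or min(self.thickness_factors) <= 0:
            raise ValueError("sizes and factors must be positive")

    @property
    def n_cells(self) -> int:
        return (
            len(self.orientations)
            * len(self.in_plane_sizes)
            * len(self.thickness_factors)
        )

    @property
    def reference_grid(self) -> GridSpec:
        return GridSpec(self.fov, self.reference_in_plane, 1.0)

    def grid(self, in_plane: float, factor: float) -> GridSpec:
        return GridSpec(self.fov, in_plane, factor)

    def variant_pose(self, variant: int) -> RigidTransform:
        """Rigid-body variation of one variant (reproducible sub-seed)."""
        seq = np.random.SeedSequence([self.master_seed, int(variant)])
        return sample_rigid_transform(np.random.default_rng(seq), self.bounds)

    def trial_rng(self, *key: int) -> np.random.Generator:
        """Independent generator for one trial, derived from the master seed."""
        seq = np.random.SeedSequence([self.master_seed, 10_000, *map(int, key)])
        return np.random.default_rng(seq)


def smoke_design(**overrides) -> ExperimentDesign:
    """Small desk-scale design: 3 variants, the finest-useful and coarsest
    in-plane sizes, all thickness factors."""
    params = dict(n_variants=3, in_plane_sizes=(0.2, 2.0))
    params.update(overrides)
    return ExperimentDesign(**params)


@dataclass(frozen=True)
class TrialRecord:
    """One labeled reconstruction: design-cell keys plus accuracy metrics.

    ``continuous_volume`` is populated only for the optimal rater (its
    proportion-matched volume before voxel quantization); NaN otherwise.
    """

    variant: int
    orientation: str
    in_plane: float
    factor: float
    rater: str
    labeled_volume: float
    continuous_volume: float
    truth_volume: float
    pct_deviation: float
    dcs: float


def _variant_reference(
    design: ExperimentDesign,
    variant: int,
    orientation: str,
    cache: dict | None,
) -> LabelMask:
    """Optimal-rater labeling of the variant at the reference resolution.

    The cache (keyed by master seed, variant and orientation) may be shared
    across runs of designs that agree on ellipsoid, FoV, bounds and
    reference resolution.
    """
    key = (design.master_seed, variant, orientation)
    if cache is not None and key in cache:
        return cache[key]
    pose = design.variant_pose(variant).compose(base_orientation(orientation))
    grid = design.reference_grid
    img = reconstruct(analytic_kspace(design.ellipsoid, pose, grid))
    ref = optimal_label(img, design.ellipsoid).mask
    if cache is not None:
        cache[key] = ref
    return ref


def run_design(
    design: ExperimentDesign,
    raters: list[RaterSpec] | None = None,
    reference_cache: dict | None = None,
    progress: bool = False,
) -> list[TrialRecord]:
    """Run the factorial simulation and return one record per trial.

    For every (variant, orientation) the pose is sampled from the design's
    seed hierarchy and an optimal-rater reference mask is built at the
    reference resolution (cached in ``reference_cache`` if given).  Every
    (in-plane size, thickness factor) reconstruction is then labeled by
    every rater, up-sampled to the reference grid, and scored.  The record
    count is ``n_variants * |orientations| * |sizes| * |factors| * |raters|``
    and the run is bit-reproducible for a fixed master seed.
    """
    if raters is None:
        raters = [RaterSpec("optimal")]
    if not raters:
        raise ValueError("at least one rater is required")
    names = [r.name for r in raters]
    if len(set(names)) != len(names):
        raise ValueError("rater names must be unique")

    cells = list(
        itertools.product(
            range(design.n_variants),
            range(len(design.orientations)),
            range(len(design.in_plane_sizes)),
            range(len(design.thickness_factors)),
        )
    )
    if progress:
        from tqdm import tqdm

        cells = tqdm(cells, desc="cells", unit="cell")

    truth_volume = design.ellipsoid.volume
    records: list[TrialRecord] = []
    current_ref = (None, None)
    ref_mask = None
    img = None
    current_grid_key = None
    for v, oi, si, fi in cells:
        orientation = design.orientations[oi]
        if current_ref != (v, orientation):
            ref_mask = _variant_reference(design, v, orientation, reference_cache)
            current_ref = (v, orientation)
            current_grid_key = None
        in_plane = design.in_plane_sizes[si]
        factor = design.thickness_factors[fi]
        if current_grid_key != (si, fi):
            grid = design.grid(in_plane, factor)
            pose = design.variant_pose(v).compose(base_orientation(orientation))
            img = reconstruct(analytic_kspace(design.ellipsoid, pose, grid))
            current_grid_key = (si, fi)
        for ri, rater in enumerate(raters):
            continuous = np.nan
            if rater.kind == "optimal":
                res = optimal_label(img, design.ellipsoid)
                mask = res.mask
                continuous = res.continuous_volume
            else:
                rng = design.trial_rng(v, oi, si, fi, ri)
                mask = probabilistic_label(img, rater.curve, rng, mode=rater.mode)
            rec = metrics.evaluate_mask(mask, truth_volume, ref_mask)
            records.append(
                TrialRecord(
                    variant=v,
                    orientation=orientation,
                    in_plane=in_plane,
                    factor=factor,
                    rater=rater.name,
                    labeled_volume=rec.labeled_volume,
                    continuous_volume=continuous,
                    truth_volume=truth_volume,
                    pct_deviation=rec.pct_deviation,
                    dcs=rec.dcs,
                )
            )
    return records


def records_to_frame(records) -> pd.DataFrame:
    """Trial records as a tidy DataFrame (one row per trial)."""
    if isinstance(records, pd.DataFrame):
        return records
    return pd.DataFrame([dataclasses.asdict(r) for r in records], columns=TRIAL_FIELDS)


_CELL_KEYS = ["orientation", "in_plane", "factor", "rater"]


def summarize(records, truth_volume: float | None = None) -> pd.DataFrame:
    """Per-design-cell accuracy summary.

    Groups trials by (orientation, in-plane size, thickness factor, rater)
    and reports mean/SD and normal-approximation 95% confidence intervals of
    the percentage volume deviation and of the Dice score, plus the voxel
    volume as a percentage of the ground-truth volume.  Cells with a single
    trial get NaN spread statistics.
    """
    frame = records_to_frame(records)
    if frame.empty:
        raise ValueError("no records to summarize")
    if truth_volume is None:
        truth_volume = float(frame["truth_volume"].iloc[0])

    def _agg(g: pd.DataFrame) -> pd.Series:
        n = len(g)
        dev, dcs = g["pct_deviation"], g["dcs"]
        sd = dev.std(ddof=1) if n > 1 else np.nan
        half = 1.96 * sd / np.sqrt(n) if n > 1 else np.nan
        out = {
            "n": n,
            "mean_pct_deviation": dev.mean(),
            "sd_pct_deviation": sd,
            "ci95_low": dev.mean() - half,
            "ci95_high": dev.mean() + half,
            "mean_dcs": dcs.mean(),
            "sd_dcs": dcs.std(ddof=1) if n > 1 else np.nan,
            "mean_continuous_deviation": (
                100.0 * (g["continuous_volume"].mean() - truth_volume) / truth_volume
                if g["continuous_volume"].notna().all()
                else np.nan
            ),
        }
        return pd.Series(out)

    summary = (
        frame.groupby(_CELL_KEYS, sort=True).apply(_agg, include_groups=False).reset_index()
    )
    summary["voxel_volume"] = (
        summary["in_plane"] ** 2 * summary["in_plane"] * summary["factor"]
    )
    summary["relative_voxel_volume"] = 100.0 * summary["voxel_volume"] / truth_volume
    summary["n"] = summary["n"].astype(int)
    return summary


#: Equal-voxel-volume pairs: (in_plane, factor) of the anisotropic member vs
#: the isotropic member with the identical voxel volume.
SAME_VOLUME_PAIRS = (
    ((0.1, 8.0), (0.2, 1.0)),  # 0.1 x 0.1 x 0.8 == 0.2^3 mm^3
    ((0.5, 8.0), (1.0, 1.0)),  # 0.5 x 0.5 x 4.0 == 1.0^3 mm^3
)


def same_volume_comparison(
    design: ExperimentDesign,
    rater: RaterSpec | None = None,
    reference_cache: dict | None = None,
    progress: bool = False,
) -> pd.DataFrame:
    """Isotropic vs. 8x-anisotropic voxels of identical volume.

    Runs the design's variants at each member of ``SAME_VOLUME_PAIRS`` with
    a single rater (default: the optimal rater) and reports per-orientation
    mean/SD of volume deviation and Dice for each member, so that shape
    effects can be separated from voxel-volume effects.
    """
    if rater is None:
        rater = RaterSpec("optimal")
    if reference_cache is None:
        reference_cache = {}
    rows = []
    for pair_idx, pair in enumerate(SAME_VOLUME_PAIRS):
        for member, (in_plane, factor) in zip(("anisotropic", "isotropic"), pair):
            sub = dataclasses.replace(
                design, in_plane_sizes=(in_plane,), thickness_factors=(factor,)
            )
            recs = run_design(
                sub, [rater], reference_cache=reference_cache, progress=progress
            )
            frame = records_to_frame(recs)
            for orientation, g in frame.groupby("orientation"):
                rows.append(
                    {
                        "pair": pair_idx,
                        "member": member,
                        "orientation": orientation,
                        "in_plane": in_plane,
                        "factor": factor,
                        "voxel_volume": in_plane**3 * factor,
                        "n": len(g),
                        "mean_pct_deviation": g["pct_deviation"].mean(),
                        "sd_pct_deviation": g["pct_deviation"].std(ddof=1),
                        "mean_dcs": g["dcs"].mean(),
                        "sd_dcs": g["dcs"].std(ddof=1),
                    }
                )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class DcsDeviationFit:
    """Anchored exponential Dice-vs-deviation curve.

    Model: ``DCS(d) = (1 - c) * exp(-k * d) + c`` with ``d`` the absolute
    percentage volume deviation, decay rate ``k`` > 0 and floor
    ``0 <= c < 1``; the curve passes through (0, 1) by construction.
    """

    k: float
    c: float
    n_obs: int

    def dcs_at_deviation(self, deviation) -> np.ndarray:
        d = np.abs(np.asarray(deviation, dtype=float))
        return (1.0 - self.c) * np.exp(-self.k * d) + self.c

    def deviation_at_dcs(self, level: float) -> float:
        """Inverse mapping: deviation (%) at which the curve crosses a Dice level."""
        if not self.c < level < 1.0:
            raise ValueError(
                f"DCS level {level} outside the curve's range ({self.c}, 1)"
            )
        return float(-np.log((level - self.c) / (1.0 - self.c)) / self.k)


def fit_dcs_deviation_curve(records) -> DcsDeviationFit:
    """Least-squares fit of the anchored exponential to (deviation, Dice) pairs.

    Accepts trial records or a frame with ``pct_deviation`` and ``dcs``
    columns; uses absolute deviations.  Raises ``CurveFitError`` with the
    optimizer message on non-convergence.
    """
    frame = records_to_frame(records)
    dev = np.abs(frame["pct_deviation"].to_numpy(dtype=float))
    dcs = frame["dcs"].to_numpy(dtype=float)
    if dev.size < 3:
        raise ValueError("need at least 3 records to fit the curve")
    if np.ptp(dev) <= 0:
        raise ValueError("records must span a range of deviations")

    def model(d, k, c):
        return (1.0 - c) * np.exp(-k * d) + c

    try:
        popt, _ = curve_fit(
            model,
            dev,
            dcs,
            p0=(0.02, 0.1),
            bounds=([1e-8, 0.0], [np.inf, 1.0 - 1e-6]),
            maxfev=10_000,
        )
    except RuntimeError as exc:  # pragma: no cover - optimizer failure path
        raise CurveFitError(f"exponential fit did not converge: {exc}") from exc
    return DcsDeviationFit(k=float(popt[0]), c=float(popt[1]), n_obs=dev.size)


def guideline_table(
    summary: pd.DataFrame,
    acceptable: float = 0.75,
    ideal: float = 0.90,
) -> pd.DataFrame:
    """Mean Dice per relative-voxel-volume tier and anisotropy factor.

    Takes a `summarize` output, averages Dice across orientations per
    (rater, in-plane size, factor), tags each tier with the isotropic
    relative voxel volume ``100 * in_plane^3 / truth`` that identifies it,
    and flags whether the cell clears the acceptable (Dice > 0.75) and
    ideal (Dice > 0.90) levels.
    """
    required = {"rater", "in_plane", "factor", "mean_dcs", "relative_voxel_volume"}
    missing = required - set(summary.columns)
    if missing:
        raise ValueError(f"summary frame lacks columns: {sorted(missing)}")
    truth_rel = summary["relative_voxel_volume"] / summary["factor"]
    summary = summary.assign(iso_relative_voxel_volume=truth_rel)
    table = (
        summary.groupby(["rater", "in_plane", "factor"], sort=True)
        .agg(
            iso_relative_voxel_volume=("iso_relative_voxel_volume", "first"),
            relative_voxel_volume=("relative_voxel_volume", "first"),
            mean_dcs=("mean_dcs", "mean"),
            min_dcs=("mean_dcs", "min"),
        )
        .reset_index()
    )
    table["acceptable"] = table["mean_dcs"] > acceptable
    table["ideal"] = table["mean_dcs"] > ideal
    return table
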