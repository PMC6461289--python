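"""File formats and fixtures: trial-record CSV, NIfTI export, configs.

Trial tables are plain CSV (comma separator, '.' decimal, UTF-8, mandatory
header) preceded by a one-line schema stamp so that stale files from
incompatible package versions fail loudly instead of parsing wrong.
Volumes and masks can be exported as NIfTI-1 with the anisotropic voxel
dimensions in the header.  A small packaged table of published post-mortem
hemispheric volume estimates for the subthalamic nucleus (STN) and internal
globus pallidus (GPi) documents the size range the default phantom targets.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .experiment import TRIAL_FIELDS, ExperimentDesign, TrialRecord, records_to_frame
from .phantom import Ellipsoid, GridSpec, ImageVolume, RigidBounds
from .raters import (
    DEFAULT_JOINT,
    DEFAULT_LIBERAL,
    LabelMask,
    PsychometricCurve,
    RaterSpec,
)

__all__ = [
    "SCHEMA",
    "SchemaError",
    "load_fixture_table",
    "literature_summary",
    "write_results",
    "read_results",
    "save_nifti",
    "grid_affine",
    "design_from_config",
    "raters_from_config",
    "load_config",
]

SCHEMA = "voxelgeom.trials.1"


class SchemaError(ValueError):
    """Results file written by an incompatible schema version."""


def load_fixture_table() -> pd.DataFrame:
    """Packaged literature table of STN/GPi hemispheric volumes (mm^3)."""
    ref = resources.files("voxelgeom").joinpath("data/literature_volumes.csv")
    with ref.open("r", encoding="utf-8") as fh:
        table = pd.read_csv(fh)
    expected = {"structure", "author", "year", "method", "volume_mm3"}
    if set(table.columns) != expected or table.empty:
        raise SchemaError("packaged literature table is corrupted")
    if (table["volume_mm3"] <= 0).any():
        raise SchemaError("literature volumes must be positive")
    return table


def literature_summary(table: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per-structure mean and sample SD of the literature volumes."""
    if table is None:
        table = load_fixture_table()
    return (
        table.groupby("structure")["volume_mm3"]
        .agg(n="count", mean="mean", sd=lambda v: v.std(ddof=1))
        .reset_index()
    )


def write_results(records, path) -> None:
    """Write trial records as schema-stamped CSV (lossless round-trip)."""
    frame = records_to_frame(records)
    frame = frame.reindex(columns=list(TRIAL_FIELDS))
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as fh:
        fh.write(f"# schema={SCHEMA}\n")
        frame.to_csv(fh, index=False)


def read_results(path) -> list[TrialRecord]:
    """Read a schema-stamped trial CSV back into records."""
    path = Path(path)
    with path.open("r", encoding="utf-8") as fh:
        stamp = fh.readline().strip()
        if stamp != f"# schema={SCHEMA}":
            raise SchemaError(
                f"{path}:1: expected '# schema={SCHEMA}', found {stamp!r}"
            )
        frame = pd.read_csv(fh)
    missing = set(TRIAL_FIELDS) - set(frame.columns)
    if missing:
        raise SchemaError(f"{path}: missing columns {sorted(missing)}")
    records = []
    for row in frame.itertuples(index=False):
        records.append(
            TrialRecord(
                variant=int(row.variant),
                orientation=str(row.orientation),
                in_plane=float(row.in_plane),
                factor=float(row.factor),
                rater=str(row.rater),
                labeled_volume=float(row.labeled_volume),
                continuous_volume=float(row.continuous_volume),
                truth_volume=float(row.truth_volume),
                pct_deviation=float(row.pct_deviation),
                dcs=float(row.dcs),
            )
        )
    return records


def grid_affine(grid: GridSpec) -> np.ndarray:
    """Voxel-to-world affine (mm) for a grid, FoV centred on the origin."""
    affine = np.diag(list(grid.voxel_dims) + [1.0])
    for axis in range(3):
        affine[axis, 3] = -grid.fov[axis] / 2.0 + grid.voxel_dims[axis] / 2.0
    return affine


def save_nifti(volume: ImageVolume | LabelMask, path) -> None:
    """Export a volume or mask as NIfTI-1 with correct voxel dimensions.

    Masks are written as unsigned 8-bit, images as float32.
    """
    import nibabel as nib

    if isinstance(volume, LabelMask):
        data = volume.data.astype(np.uint8)
    else:
        data = volume.data.astype(np.float32)
    img = nib.Nifti1Image(data, grid_affine(volume.grid))
    img.header.set_zooms(volume.grid.voxel_dims)
    nib.save(img, str(path))


def _curve_from_config(cfg) -> PsychometricCurve:
    return PsychometricCurve(beta0=float(cfg["beta0"]), beta1=float(cfg["beta1"]))


def raters_from_config(cfg_list) -> list[RaterSpec]:
    """Build rater specs from config dicts (kind, optional curve, mode)."""
    defaults = {"liberal": DEFAULT_LIBERAL, "joint": DEFAULT_JOINT}
    raters = []
    for cfg in cfg_list:
        kind = cfg["kind"]
        curve = None
        if kind != "optimal":
            curve = (
                _curve_from_config(cfg["curve"])
                if "curve" in cfg
                else defaults[kind]
            )
        raters.append(RaterSpec(kind, curve, mode=cfg.get("mode", "stochastic")))
    return raters


def design_from_config(cfg: dict) -> ExperimentDesign:
    """Build an ExperimentDesign from a config mapping.

    Recognised keys: n_variants, orientations, in_plane_sizes,
    thickness_factors, fov, seed, reference_in_plane, bounds
    (translation/rotation ranges) and ellipsoid (semi_axes, intensity).
    """
    kwargs = {}
    simple = {
        "n_variants": int,
        "reference_in_plane": float,
    }
    for key, cast in simple.items():
        if key in cfg:
            kwargs[key] = cast(cfg[key])
    if "orientations" in cfg:
        kwargs["orientations"] = tuple(cfg["orientations"])
    if "in_plane_sizes" in cfg:
        kwargs["in_plane_sizes"] = tuple(float(v) for v in cfg["in_plane_sizes"])
    if "thickness_factors" in cfg:
        kwargs["thickness_factors"] = tuple(
            float(v) for v in cfg["thickness_factors"]
        )
    if "fov" in cfg:
        kwargs["fov"] = tuple(float(v) for v in np.broadcast_to(cfg["fov"], (3,)))
    if "seed" in cfg:
        kwargs["master_seed"] = int(cfg["seed"])
    if "bounds" in cfg:
        b = cfg["bounds"]
        kwargs["bounds"] = RigidBounds(
            translation=tuple(b.get("translation", (-4.0, 4.0))),
            rotation=tuple(b.get("rotation", (-8.0, 8.0))),
        )
    if "ellipsoid" in cfg:
        e = cfg["ellipsoid"]
        kwargs["ellipsoid"] = Ellipsoid(
            semi_axes=tuple(e["semi_axes"]),
            intensity=float(e.get("intensity", 1.0)),
        )
    return ExperimentDesign(**kwargs)


def load_config(path) -> tuple[ExperimentDesign, list[RaterSpec]]:
    """Load a YAML/JSON config with ``design`` and optional ``raters`` blocks."""
    with Path(path).open("r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    design = design_from_config(cfg.get("design", {}))
    raters = raters_from_config(cfg.get("raters", [{"kind": "optimal"}]))
    return design, raters
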