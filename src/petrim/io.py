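"""Volume, mask and table I/O.

Volumes and masks are NRRD or NIfTI-1 files read through SimpleITK; arrays
are stored in (x, y, z) index order with per-axis spacing in mm so that
``spacing[i]`` is the physical step along ``values`` axis ``i``.  Masks must
share the exact grid of their companion volume — no resampling is performed.
Cohort tables are plain CSV (comma, UTF-8, header row, "." decimal point).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import SimpleITK as sitk

logger = logging.getLogger(__name__)

_SUPPORTED_SUFFIXES = (".nrrd", ".nhdr", ".nii", ".nii.gz")


@dataclass
class SUVolume:
    """A 3D grid of standardized-uptake values.

    Parameters
    ----------
    values : ndarray, shape (nx, ny, nz)
        Non-negative, finite SUV (unitless, body-weight normalized).
    spacing : tuple of float
        Voxel spacing (dx, dy, dz) in mm, each strictly positive.
    origin : tuple of float
        Physical coordinates of the first voxel center, mm.
    """

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValueError(
                f"expected 3D volume, got {self.values.ndim}D array"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("SUV values must be finite")
        if np.any(self.values < 0):
            raise ValueError("SUV values must be >= 0")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive values, got {self.spacing}")
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def voxel_volume_ml(self) -> float:
        """Volume of one voxel in ml (mm^3 / 1000)."""
        return float(np.prod(self.spacing)) / 1000.0


@dataclass
class RegionMask:
    """Binary mask on the same grid as a companion :class:`SUVolume`.

    ``label`` names the role of the region: ``"lesion"``, ``"rim"`` or
    ``"liver"``.
    """

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    label: str = "lesion"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values) != 0
        if self.values.ndim != 3:
            raise ValueError(
                f"expected 3D mask, got {self.values.ndim}D array"
            )
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive values, got {self.spacing}")
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def n_voxels(self) -> int:
        return int(self.values.sum())

    def check_companion(self, volume: SUVolume) -> None:
        """Raise if this mask does not share ``volume``'s grid exactly."""
        if self.values.shape != volume.values.shape:
            raise ValueError(
                f"mask shape {self.values.shape} does not match volume "
                f"shape {volume.values.shape}; masks are never resampled"
            )
        if not np.allclose(self.spacing, volume.spacing):
            raise ValueError(
                f"mask spacing {self.spacing} does not match volume "
                f"spacing {volume.spacing}"
            )


def _check_path(path: str | Path) -> Path:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    name = path.name.lower()
    if not any(name.endswith(s) for s in _SUPPORTED_SUFFIXES):
        raise ValueError(
            f"unsupported volume format for {path.name}; "
            f"supported: {', '.join(_SUPPORTED_SUFFIXES)}"
        )
    return path


def _read_image(path: str | Path) -> tuple[np.ndarray, tuple, tuple]:
    image = sitk.ReadImage(str(_check_path(path)))
    if image.GetDimension() != 3:
        raise ValueError(
            f"expected 3D volume, got {image.GetDimension()}D image in {path}"
        )
    if image.GetNumberOfComponentsPerPixel() != 1:
        raise ValueError(
            f"expected scalar voxels, got "
            f"{image.GetNumberOfComponentsPerPixel()} components in {path}"
        )
    # SimpleITK arrays come back (z, y, x); transpose to (x, y, z).
    arr = np.transpose(sitk.GetArrayFromImage(image), (2, 1, 0))
    return arr, tuple(image.GetSpacing()), tuple(image.GetOrigin())


def read_volume(path: str | Path) -> SUVolume:
    """Read a 3D scalar NRRD or NIfTI-1 volume as an :class:`SUVolume`."""
    arr, spacing, origin = _read_image(path)
    return SUVolume(arr.astype(np.float64), spacing, origin)


def read_mask(path: str | Path, label: str = "lesion") -> RegionMask:
    """Read a 3D binary NRRD or NIfTI-1 mask; any nonzero voxel is set."""
    arr, spacing, origin = _read_image(path)
    return RegionMask(arr, spacing, origin, label=label)


def _write_image(values: np.ndarray, spacing, origin, path: str | Path) -> None:
    path = Path(path)
    name = path.name.lower()
    if not any(name.endswith(s) for s in _SUPPORTED_SUFFIXES):
        raise ValueError(
            f"unsupported volume format for {path.name}; "
            f"supported: {', '.join(_SUPPORTED_SUFFIXES)}"
        )
    image = sitk.GetImageFromArray(np.transpose(values, (2, 1, 0)))
    image.SetSpacing(tuple(float(s) for s in spacing))
    image.SetOrigin(tuple(float(o) for o in origin))
    sitk.WriteImage(image, str(path))


def write_volume(volume: SUVolume, path: str | Path) -> None:
    """Write an :class:`SUVolume` to NRRD or NIfTI-1 (by file suffix)."""
    _write_image(volume.values, volume.spacing, volume.origin, path)


def write_mask(mask: RegionMask, path: str | Path) -> None:
    """Write a :class:`RegionMask` as an 8-bit 0/1 volume."""
    _write_image(mask.values.astype(np.uint8), mask.spacing, mask.origin, path)


def suv_bw(
    activity_concentration: np.ndarray,
    injected_dose_bq: float,
    body_weight_kg: float,
    spacing: tuple[float, float, float],
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0),
) -> SUVolume:
    """Convert activity concentration to body-weight SUV.

    SUV = concentration [Bq/ml] x body weight [g] / injected dose [Bq].
    Decay correction is the caller's responsibility.
    """
    if injected_dose_bq <= 0:
        raise ValueError(f"injected dose must be > 0, got {injected_dose_bq}")
    if body_weight_kg <= 0:
        raise ValueError(f"body weight must be > 0, got {body_weight_kg}")
    conc = np.asarray(activity_concentration, dtype=np.float64)
    suv = conc * (body_weight_kg * 1000.0) / injected_dose_bq
    return SUVolume(suv, spacing, origin)


# --------------------------------------------------------------------------
# Cohort tables


@dataclass
class CohortTable:
    """Per-subject feature and outcome table.

    ``data`` holds one row per subject with columns ``subject_id``, ``time``
    (disease-free survival in months, > 0), ``event`` (1 = recurrence or
    death, 0 = censored) plus feature columns.  ``baseline_features`` and
    ``delta_features`` record which columns hold baseline values and
    pre-minus-post change values; change columns are NaN for subjects with a
    complete response (no residual post-treatment lesion).
    """

    data: pd.DataFrame
    baseline_features: list[str] = field(default_factory=list)
    delta_features: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for col in ("subject_id", "time", "event"):
            if col not in self.data.columns:
                raise ValueError(f"cohort table missing required column '{col}'")
        t = self.data["time"].to_numpy(dtype=float)
        if np.any(~np.isfinite(t)) or np.any(t <= 0):
            raise ValueError("DFS time must be finite and > 0 for every subject")
        ev = self.data["event"].to_numpy()
        if not np.isin(ev, (0, 1)).all():
            raise ValueError("event indicator must be 0 or 1")
        self.data = self.data.reset_index(drop=True)

    @property
    def n_subjects(self) -> int:
        return len(self.data)

    @property
    def n_events(self) -> int:
        return int(self.data["event"].sum())

    def delta_subset(self) -> pd.DataFrame:
        """Rows with complete change features (residual post-treatment lesion)."""
        if not self.delta_features:
            return self.data.iloc[0:0]
        mask = self.data[self.delta_features].notna().all(axis=1)
        return self.data.loc[mask]

    def check_delta_consistency(self, atol: float = 1e-6) -> None:
        """Verify Δf = f(t0) − f(t1) wherever all three columns exist."""
        for dcol in self.delta_features:
            base = dcol.removeprefix("Delta ")
            t0c, t1c = f"{base} t0", f"{base} t1"
            if t0c in self.data.columns and t1c in self.data.columns:
                expect = self.data[t0c] - self.data[t1c]
                got = self.data[dcol]
                ok = (got - expect).abs() <= atol
                ok |= got.isna() & (expect.isna() | True) & got.isna()
                bad = (~ok) & got.notna() & expect.notna()
                if bad.any():
                    raise ValueError(
                        f"column '{dcol}' violates delta = t0 - t1 for "
                        f"{int(bad.sum())} subject(s)"
                    )


def read_cohort_csv(
    path: str | Path,
    column_map: Mapping[str, str],
    baseline_features: Sequence[str] = (),
    delta_features: Sequence[str] = (),
) -> CohortTable:
    """Read a per-subject CSV into a :class:`CohortTable`.

    ``column_map`` maps the canonical names (``subject_id``, ``time``,
    ``event`` and any feature names) to the column headers actually present
    in the file, so externally produced tables with arbitrary headers can be
    ingested without code changes.  Rows missing time or event are dropped
    with a logged count.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    raw = pd.read_csv(path)
    for required in ("time", "event"):
        if required not in column_map:
            raise ValueError(f"column_map missing required key '{required}'")
    missing = [src for src in column_map.values() if src not in raw.columns]
    if missing:
        raise ValueError(
            f"CSV {path.name} is missing mapped column(s): {', '.join(missing)}"
        )
    df = pd.DataFrame({canon: raw[src] for canon, src in column_map.items()})
    if "subject_id" not in df.columns:
        df.insert(0, "subject_id", [f"S{i + 1:03d}" for i in range(len(df))])
    n_before = len(df)
    df = df.dropna(subset=["time", "event"])
    dropped = n_before - len(df)
    if dropped:
        logger.info("dropped %d row(s) with missing time/event from %s",
                    dropped, path.name)
    df["time"] = df["time"].astype(float)
    df["event"] = df["event"].astype(int)
    return CohortTable(
        df,
        baseline_features=list(baseline_features),
        delta_features=list(delta_features),
    )


def write_feature_table(features: Sequence, path: str | Path) -> None:
    """Write extracted feature vectors to CSV, one row per lesion-timepoint.

    Column order is fixed: ``subject_id``, ``timepoint``, the 22 panel
    features in their canonical order, then the normalization provenance
    columns.
    """
    from .features import FEATURE_NAMES  # local import avoids a cycle

    if len(features) == 0:
        raise ValueError("no feature vectors to write")
    rows = []
    for fv in features:
        row = {"subject_id": fv.subject_id, "timepoint": fv.timepoint}
        row.update({name: fv[name] for name in FEATURE_NAMES})
        row["liver_normalized"] = fv.liver_normalized
        row["liver_mean_suv"] = fv.liver_mean_suv
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)
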