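"""The 22-feature quantitative panel for a segmented PET lesion.

Five standard metrics (Max, Peak, Mean, MTV, TLG) plus seventeen
descriptive features: order statistics of the intra-lesion SUV
distribution, the four grayscale-quarter occupancy and glycolysis
features, SAM (standardized added metabolic activity) and RA (rim
average).  All functions here return *raw* values; liver normalization is
a separate pass (see :mod:`petrim.normalization`).

Conventions fixed by this implementation (the upstream tooling does not
pin them down):

* quartiles use linear interpolation between order statistics;
* Std is the population (divide-by-n) standard deviation, so
  RMS^2 = Mean^2 + Std^2 holds exactly;
* Upper Adjacent is the boxplot upper adjacent value — the largest
  observation not exceeding Q3 + 1.5 x IQR;
* grayscale quarters are the four equal bins of [Min, Max], half-open
  except the last; a degenerate range (Max == Min) puts every voxel in Q1;
* the rim is built by repeated 6-connected (face-adjacency) binary
  dilation in voxel space, clipped at the image boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .io import SUVolume, RegionMask

#: Canonical feature names, in panel order.
FEATURE_NAMES: tuple[str, ...] = (
    "Max", "Peak", "Mean", "MTV", "TLG",
    "Min", "Std", "RMS",
    "1st Quartile", "Median", "3rd Quartile", "Upper Adjacent",
    "Q1 Distribution", "Q2 Distribution", "Q3 Distribution", "Q4 Distribution",
    "Glycolysis Q1", "Glycolysis Q2", "Glycolysis Q3", "Glycolysis Q4",
    "SAM", "RA",
)

#: Whether each feature is divided by the mean liver SUV during
#: normalization.  Volume (MTV) and the dimensionless quarter-occupancy
#: percentages are not.
LIVER_NORMALIZED_FLAGS: dict[str, bool] = {
    name: name not in (
        "MTV",
        "Q1 Distribution", "Q2 Distribution",
        "Q3 Distribution", "Q4 Distribution",
    )
    for name in FEATURE_NAMES
}

#: Radius in mm of the 1 cm^3 sphere used by the Peak feature.
PEAK_SPHERE_RADIUS_MM: float = (3000.0 / (4.0 * np.pi)) ** (1.0 / 3.0)


@dataclass
class LesionSample:
    """The multiset of SUV values inside a lesion mask.

    ``voxel_volume_ml`` is the product of the spacing components divided by
    1000, so MTV = n_voxels x voxel_volume_ml.
    """

    suv_values: np.ndarray
    voxel_volume_ml: float

    def __post_init__(self) -> None:
        self.suv_values = np.asarray(self.suv_values, dtype=np.float64).ravel()
        if self.suv_values.size == 0:
            raise ValueError("lesion sample is empty")
        if self.voxel_volume_ml <= 0:
            raise ValueError(
                f"voxel volume must be > 0 ml, got {self.voxel_volume_ml}"
            )

    @property
    def n_voxels(self) -> int:
        return int(self.suv_values.size)


def lesion_sample(volume: SUVolume, lesion: RegionMask) -> LesionSample:
    """Collect the SUV values at lesion voxels."""
    lesion.check_companion(volume)
    if lesion.n_voxels == 0:
        raise ValueError("lesion mask is empty")
    return LesionSample(volume.values[lesion.values], volume.voxel_volume_ml)


def basic_statistics(sample: LesionSample) -> dict[str, float]:
    """Order statistics and moments of the intra-lesion SUV distribution.

    Returns Max, Mean, Min, Std (population), RMS, 1st Quartile, Median,
    3rd Quartile and Upper Adjacent (largest value <= Q3 + 1.5 x IQR).
    """
    v = sample.suv_values
    q1, med, q3 = np.percentile(v, [25.0, 50.0, 75.0])
    fence = q3 + 1.5 * (q3 - q1)
    upper_adjacent = float(v[v <= fence].max())
    return {
        "Max": float(v.max()),
        "Mean": float(v.mean()),
        "Min": float(v.min()),
        "Std": float(v.std(ddof=0)),
        "RMS": float(np.sqrt(np.mean(v * v))),
        "1st Quartile": float(q1),
        "Median": float(med),
        "3rd Quartile": float(q3),
        "Upper Adjacent": upper_adjacent,
    }


def mtv(sample: LesionSample) -> float:
    """Metabolic tumor volume in ml: voxel count x voxel volume."""
    return sample.n_voxels * sample.voxel_volume_ml


def tlg(sample: LesionSample) -> float:
    """Total lesion glycolysis in ml: mean SUV x MTV."""
    return float(sample.suv_values.mean()) * mtv(sample)


def _quarter_indices(v: np.ndarray) -> np.ndarray:
    """Grayscale-quarter bin index (0..3) for each value.

    Bins are [Min + k R/4, Min + (k+1) R/4) with the last bin closed,
    R = Max - Min.  R == 0 assigns every value to the first quarter.
    """
    lo, hi = v.min(), v.max()
    r = hi - lo
    if r == 0:
        return np.zeros(v.size, dtype=np.intp)
    idx = np.floor((v - lo) * 4.0 / r).astype(np.intp)
    return np.clip(idx, 0, 3)


def quarter_distribution(sample: LesionSample) -> dict[str, float]:
    """Percent of lesion voxels in each grayscale quarter; sums to 100."""
    counts = np.bincount(_quarter_indices(sample.suv_values), minlength=4)
    pct = counts * (100.0 / sample.n_voxels)
    return {f"Q{k + 1} Distribution": float(pct[k]) for k in range(4)}


def quarter_glycolysis(sample: LesionSample) -> dict[str, float]:
    """Glycolysis (ml) contributed by each grayscale quarter; sums to TLG."""
    idx = _quarter_indices(sample.suv_values)
    sums = np.bincount(idx, weights=sample.suv_values, minlength=4)
    return {
        f"Glycolysis Q{k + 1}": float(sums[k] * sample.voxel_volume_ml)
        for k in range(4)
    }


def peak(volume: SUVolume, lesion: RegionMask) -> float:
    """Peak uptake: the best mean over a 1 cm^3 sphere inside the lesion.

    Every lesion voxel center is a candidate sphere center; sphere
    membership is voxel-center-in-sphere, evaluated in physical mm; spheres
    may extend past the lesion boundary but are clipped at the image
    boundary.  Returns the maximum sphere mean over all candidates.
    """
    lesion.check_companion(volume)
    if lesion.n_voxels == 0:
        raise ValueError("lesion mask is empty")
    dx, dy, dz = volume.spacing
    r = PEAK_SPHERE_RADIUS_MM
    nx = int(np.floor(r / dx))
    ny = int(np.floor(r / dy))
    nz = int(np.floor(r / dz))
    ix, iy, iz = np.mgrid[-nx:nx + 1, -ny:ny + 1, -nz:nz + 1]
    kernel = ((ix * dx) ** 2 + (iy * dy) ** 2 + (iz * dz) ** 2) <= r * r
    kernel = kernel.astype(np.float64)
    # Sphere sums and in-grid member counts via correlation with zero
    # padding; their ratio is the boundary-clipped sphere mean.
    sums = ndimage.correlate(volume.values, kernel, mode="constant", cval=0.0)
    counts = ndimage.correlate(
        np.ones_like(volume.values), kernel, mode="constant", cval=0.0
    )
    means = sums[lesion.values] / counts[lesion.values]
    return float(means.max())


def build_rim(
    lesion: RegionMask,
    width_voxels: int = 2,
    connectivity: int = 1,
) -> RegionMask:
    """Build the background shell around a lesion.

    ``width_voxels`` iterations of binary dilation (6-connected
    face-adjacency structuring element by default; ``connectivity=3`` gives
    the full 26-neighborhood) minus the lesion itself.  The rim is clipped
    at the image boundary and is always disjoint from the lesion.
    """
    if lesion.n_voxels == 0:
        raise ValueError("lesion mask is empty")
    if width_voxels < 1:
        raise ValueError(f"rim width must be >= 1 voxel, got {width_voxels}")
    structure = ndimage.generate_binary_structure(3, connectivity)
    dilated = ndimage.binary_dilation(
        lesion.values, structure=structure, iterations=width_voxels
    )
    return RegionMask(
        dilated & ~lesion.values, lesion.spacing, lesion.origin, label="rim"
    )


def rim_average(volume: SUVolume, rim: RegionMask) -> float:
    """RA: arithmetic mean SUV over the rim voxels."""
    rim.check_companion(volume)
    if rim.n_voxels == 0:
        raise ValueError("rim mask is empty")
    return float(volume.values[rim.values].mean())


def sam(volume: SUVolume, lesion: RegionMask, rim: RegionMask) -> float:
    """Standardized added metabolic activity, in ml.

    Total activity of lesion plus rim, minus the background activity the
    same volume would hold at the rim-mean uptake:

        SAM = sum_{v in lesion ∪ rim} SUV(v) x voxel_volume
              − RA x volume(lesion ∪ rim)

    A flat field gives 0; a uniform lesion of uptake L and volume V_L over
    a uniform rim of uptake B gives (L − B) x V_L.
    """
    lesion.check_companion(volume)
    rim.check_companion(volume)
    if lesion.n_voxels == 0 or rim.n_voxels == 0:
        raise ValueError("lesion and rim masks must be non-empty")
    if (lesion.values & rim.values).any():
        raise ValueError("lesion and rim masks overlap")
    region = lesion.values | rim.values
    voxvol = volume.voxel_volume_ml
    total = float(volume.values[region].sum()) * voxvol
    ra = rim_average(volume, rim)
    return total - ra * int(region.sum()) * voxvol


@dataclass
class FeatureVector:
    """The 22 panel values for one lesion at one timepoint.

    ``liver_normalized`` records whether the SUV-based entries have been
    divided by the mean liver SUV (stored in ``liver_mean_suv``).
    """

    values: dict[str, float]
    subject_id: str = ""
    timepoint: str = "t0"
    liver_normalized: bool = False
    liver_mean_suv: float | None = None

    def __post_init__(self) -> None:
        missing = [n for n in FEATURE_NAMES if n not in self.values]
        if missing:
            raise ValueError(f"feature vector missing: {', '.join(missing)}")

    def __getitem__(self, name: str) -> float:
        return self.values[name]

    def as_series(self):
        import pandas as pd

        return pd.Series({n: self.values[n] for n in FEATURE_NAMES},
                         name=self.subject_id)


def extract_all(
    volume: SUVolume,
    lesion: RegionMask,
    rim_width: int = 2,
    connectivity: int = 1,
    subject_id: str = "",
    timepoint: str = "t0",
) -> FeatureVector:
    """Compute the full raw (un-normalized) 22-feature panel.

    The rim for RA and SAM is built internally with ``rim_width`` dilation
    iterations (default 2 voxels).
    """
    smp = lesion_sample(volume, lesion)
    rim = build_rim(lesion, width_voxels=rim_width, connectivity=connectivity)
    values = basic_statistics(smp)
    values["MTV"] = mtv(smp)
    values["TLG"] = tlg(smp)
    values["Peak"] = peak(volume, lesion)
    values.update(quarter_distribution(smp))
    values.update(quarter_glycolysis(smp))
    values["RA"] = rim_average(volume, rim)
    values["SAM"] = sam(volume, lesion, rim)
    return FeatureVector(values, subject_id=subject_id, timepoint=timepoint)
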