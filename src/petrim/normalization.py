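"""Liver-uptake normalization and pre/post-treatment change features.

PET uptake varies with metabolic baseline activity, so SUV-based features
are divided by the mean SUV of a liver reference region measured on the
same scan.  Volume (MTV) and the dimensionless quarter-occupancy
percentages are left untouched.  Change features are the pre-treatment
minus post-treatment difference, ΔQIF = QIF(t0) − QIF(t1), computed on
normalized features; subjects with a complete response (no residual
post-treatment lesion) have no change vector.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .features import FEATURE_NAMES, LIVER_NORMALIZED_FLAGS, FeatureVector
from .io import RegionMask, SUVolume


@dataclass(frozen=True)
class LiverReference:
    """Mean SUV of the liver reference region.

    ``source`` is ``"mask"`` when measured from a supplied liver mask and
    ``"scalar"`` when given directly; ``n_voxels`` is set for masks.
    """

    mean_suv: float
    source: str = "scalar"
    n_voxels: int | None = None

    def __post_init__(self) -> None:
        if self.mean_suv <= 0:
            raise ValueError(
                f"liver mean SUV must be > 0, got {self.mean_suv}"
            )
        if self.source not in ("mask", "scalar"):
            raise ValueError(f"unknown liver reference source {self.source!r}")


def liver_mean(volume: SUVolume, liver: RegionMask) -> LiverReference:
    """Arithmetic mean SUV over the liver mask."""
    liver.check_companion(volume)
    if liver.n_voxels == 0:
        raise ValueError("liver mask is empty")
    return LiverReference(
        float(volume.values[liver.values].mean()),
        source="mask",
        n_voxels=liver.n_voxels,
    )


def liver_scalar(mean_suv: float) -> LiverReference:
    """Wrap a user-supplied liver mean SUV."""
    return LiverReference(float(mean_suv), source="scalar")


def normalize(features: FeatureVector, liver: LiverReference) -> FeatureVector:
    """Divide the SUV-based features by the liver mean.

    Features flagged for normalization (everything except MTV and the
    Q1–Q4 Distribution percentages) are divided by ``liver.mean_suv``; the
    result is marked ``liver_normalized`` and re-normalizing it raises.
    """
    if features.liver_normalized:
        raise ValueError("feature vector is already liver-normalized")
    values = {
        name: (features.values[name] / liver.mean_suv
               if LIVER_NORMALIZED_FLAGS[name] else features.values[name])
        for name in FEATURE_NAMES
    }
    return replace(
        features,
        values=values,
        liver_normalized=True,
        liver_mean_suv=liver.mean_suv,
    )


@dataclass
class DeltaFeatureVector:
    """Per-feature change ΔQIF = QIF(t0) − QIF(t1) for one subject."""

    values: dict[str, float]
    subject_id: str
    t0: FeatureVector
    t1: FeatureVector

    def __getitem__(self, name: str) -> float:
        return self.values[name]


def delta(t0: FeatureVector, t1: FeatureVector) -> DeltaFeatureVector:
    """Elementwise pre-minus-post change of two feature vectors.

    Both vectors must share the same normalization state (by default the
    change analysis runs on liver-normalized features; raw-on-raw is
    permitted for sensitivity analyses, but mixing states is an error).
    """
    if t0.liver_normalized != t1.liver_normalized:
        raise ValueError(
            "cannot difference a normalized and an un-normalized feature "
            "vector; normalize both or neither"
        )
    if t0.subject_id and t1.subject_id and t0.subject_id != t1.subject_id:
        raise ValueError(
            f"subject mismatch: {t0.subject_id!r} vs {t1.subject_id!r}"
        )
    values = {
        name: t0.values[name] - t1.values[name] for name in FEATURE_NAMES
    }
    return DeltaFeatureVector(values, subject_id=t0.subject_id, t0=t0, t1=t1)
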