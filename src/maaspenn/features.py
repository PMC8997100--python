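"""Phantom VOI grid, feature registry, processing arms and extractor contract.

The phantom holds 10 texture layers; each layer is divided into 16 cubic
volumes of interest (VOIs) of 2 x 2 x 2 cm arranged in a centered 4 x 4
in-plane grid, so a scan contributes 160 VOIs.  Per VOI a fixed registry of
91 handcrafted radiomic features (HRFs) is computed: 18 first-order
intensity statistics and 73 texture features from the GLCM, GLRLM, GLSZM,
GLDM and NGTDM matrices.  Feature mathematics are delegated to an external
extractor (e.g. PyRadiomics) behind :func:`extract_features`; this package
defines the grid, the registry, the three processing arms (original,
resample-to-median-voxel, resample-to-largest-voxel) and the resampling
itself (cosine-windowed-sinc interpolation, intensities kept in HU).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Protocol, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FEATURE_FAMILIES",
    "FeatureRegistry",
    "default_registry",
    "VOIGrid",
    "build_voi_grid",
    "ProcessingArm",
    "ARMS",
    "FeatureTable",
    "FeatureExtractor",
    "resample_to_arm",
    "extract_features",
]

# PyRadiomics-style "original image" feature names, grouped by family.
# Family sizes: first-order 18, GLCM 22, GLRLM 16, GLSZM 16, GLDM 14,
# NGTDM 5 -> 91 features total.
FEATURE_FAMILIES: dict[str, tuple[str, ...]] = {
    "firstorder": (
        "10Percentile", "90Percentile", "Energy", "Entropy",
        "InterquartileRange", "Kurtosis", "Maximum", "Mean",
        "MeanAbsoluteDeviation", "Median", "Minimum", "Range",
        "RobustMeanAbsoluteDeviation", "RootMeanSquared", "Skewness",
        "TotalEnergy", "Uniformity", "Variance",
    ),
    "glcm": (
        "Autocorrelation", "ClusterProminence", "ClusterShade",
        "ClusterTendency", "Contrast", "Correlation", "DifferenceAverage",
        "DifferenceEntropy", "DifferenceVariance", "Id", "Idm", "Idmn",
        "Idn", "Imc1", "Imc2", "InverseVariance", "JointAverage",
        "JointEnergy", "JointEntropy", "MaximumProbability", "SumEntropy",
        "SumSquares",
    ),
    "glrlm": (
        "GrayLevelNonUniformity", "GrayLevelNonUniformityNormalized",
        "GrayLevelVariance", "HighGrayLevelRunEmphasis", "LongRunEmphasis",
        "LongRunHighGrayLevelEmphasis", "LongRunLowGrayLevelEmphasis",
        "LowGrayLevelRunEmphasis", "RunEntropy", "RunLengthNonUniformity",
        "RunLengthNonUniformityNormalized", "RunPercentage", "RunVariance",
        "ShortRunEmphasis", "ShortRunHighGrayLevelEmphasis",
        "ShortRunLowGrayLevelEmphasis",
    ),
    "glszm": (
        "GrayLevelNonUniformity", "GrayLevelNonUniformityNormalized",
        "GrayLevelVariance", "HighGrayLevelZoneEmphasis", "LargeAreaEmphasis",
        "LargeAreaHighGrayLevelEmphasis", "LargeAreaLowGrayLevelEmphasis",
        "LowGrayLevelZoneEmphasis", "SizeZoneNonUniformity",
        "SizeZoneNonUniformityNormalized", "SmallAreaEmphasis",
        "SmallAreaHighGrayLevelEmphasis", "SmallAreaLowGrayLevelEmphasis",
        "ZoneEntropy", "ZonePercentage", "ZoneVariance",
    ),
    "gldm": (
        "DependenceEntropy", "DependenceNonUniformity",
        "DependenceNonUniformityNormalized", "DependenceVariance",
        "GrayLevelNonUniformity", "GrayLevelVariance", "HighGrayLevelEmphasis",
        "LargeDependenceEmphasis", "LargeDependenceHighGrayLevelEmphasis",
        "LargeDependenceLowGrayLevelEmphasis", "LowGrayLevelEmphasis",
        "SmallDependenceEmphasis", "SmallDependenceHighGrayLevelEmphasis",
        "SmallDependenceLowGrayLevelEmphasis",
    ),
    "ngtdm": ("Busyness", "Coarseness", "Complexity", "Contrast", "Strength"),
}

_EXPECTED_FAMILY_SIZES = {
    "firstorder": 18, "glcm": 22, "glrlm": 16, "glszm": 16, "gldm": 14,
    "ngtdm": 5,
}


@dataclass(frozen=True)
class FeatureRegistry:
    """Ordered list of (feature_name, family); names globally unique."""

    names: tuple[str, ...]
    families: tuple[str, ...]

    def __post_init__(self):
        if len(self.names) != len(self.families):
            raise ValueError("names/families length mismatch")
        if len(set(self.names)) != len(self.names):
            raise ValueError("feature names must be unique")

    def __len__(self) -> int:
        return len(self.names)

    def family_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for fam in self.families:
            counts[fam] = counts.get(fam, 0) + 1
        return counts

    def family_of(self, name: str) -> str:
        return self.families[self.names.index(name)]


def default_registry() -> FeatureRegistry:
    """The pinned 91-feature original-image registry (18/22/16/16/14/5)."""
    names, families = [], []
    for fam, feats in FEATURE_FAMILIES.items():
        if len(feats) != _EXPECTED_FAMILY_SIZES[fam]:
            raise AssertionError(
                f"registry family {fam} has {len(feats)} features, "
                f"expected {_EXPECTED_FAMILY_SIZES[fam]}"
            )
        for f in feats:
            names.append(f"original_{fam}_{f}")
            families.append(fam)
    if len(names) != 91:
        raise AssertionError(f"registry must total 91 features, got {len(names)}")
    return FeatureRegistry(tuple(names), tuple(families))


# ---------------------------------------------------------------------------
# VOI grid


@dataclass(frozen=True)
class VOIGrid:
    """Axis-aligned VOI boxes in physical (mm) coordinates.

    Boxes are half-open intervals [start, stop) per axis, stored as
    (x0, y0, z0, x1, y1, z1); ``voi_ids`` are ``layer{L}_voi{V}``.
    """

    layers: int
    vois_per_layer: int
    voi_edge_mm: float
    boxes: tuple[tuple[float, float, float, float, float, float], ...]

    @property
    def voi_ids(self) -> list[str]:
        return [
            f"layer{l:02d}_voi{v:02d}"
            for l in range(self.layers)
            for v in range(self.vois_per_layer)
        ]

    def __len__(self) -> int:
        return len(self.boxes)


class GridExtentError(ValueError):
    """VOI grid does not fit in the image extent."""


def build_voi_grid(
    layers: int = 10,
    vois_per_layer: int = 16,
    voi_edge_cm: float = 2.0,
    *,
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0),
    extent_mm: tuple[float, float, float] | None = None,
) -> VOIGrid:
    """Lay out ``layers`` stacked planes of cubic VOIs on a centered grid.

    Default phantom configuration: 10 layers x 16 VOIs (4 x 4 in-plane) of
    edge 2 cm -> 160 VOIs.  ``extent_mm`` is the physical size of the image
    along (x, y, z) starting at ``origin_mm``; if omitted it defaults to a
    tight fit.  Raises :class:`GridExtentError` with the overflow amount
    when the grid does not fit.
    """
    side = int(round(vois_per_layer ** 0.5))
    if side * side != vois_per_layer:
        raise ValueError(
            f"vois_per_layer must be a perfect square for the in-plane grid, "
            f"got {vois_per_layer}"
        )
    edge = voi_edge_cm * 10.0  # cm -> mm
    need = (side * edge, side * edge, layers * edge)
    if extent_mm is None:
        extent_mm = need
    overflow = [max(0.0, n - e) for n, e in zip(need, extent_mm)]
    if any(o > 1e-9 for o in overflow):
        raise GridExtentError(
            f"VOI grid exceeds image extent by (x, y, z) = {tuple(overflow)} mm"
        )
    # center the in-plane 4x4 block; stack layers from the z origin
    off = [
        origin_mm[0] + (extent_mm[0] - need[0]) / 2.0,
        origin_mm[1] + (extent_mm[1] - need[1]) / 2.0,
        origin_mm[2],
    ]
    boxes = []
    for l in range(layers):
        z0 = off[2] + l * edge
        for iy in range(side):
            for ix in range(side):
                x0 = off[0] + ix * edge
                y0 = off[1] + iy * edge
                boxes.append((x0, y0, z0, x0 + edge, y0 + edge, z0 + edge))
    return VOIGrid(layers, vois_per_layer, edge, tuple(boxes))


def voi_index_ranges(
    grid: VOIGrid,
    origin_mm: Sequence[float],
    spacing_mm: Sequence[float],
) -> list[tuple[slice, slice, slice]]:
    """Map physical VOI boxes to voxel index slices (floor start, ceil end)."""
    ranges = []
    for (x0, y0, z0, x1, y1, z1) in grid.boxes:
        sl = []
        for a0, a1, o, s in (
            (x0, x1, origin_mm[0], spacing_mm[0]),
            (y0, y1, origin_mm[1], spacing_mm[1]),
            (z0, z1, origin_mm[2], spacing_mm[2]),
        ):
            start = int(np.floor((a0 - o) / s))
            stop = int(np.ceil((a1 - o) / s))
            sl.append(slice(max(start, 0), stop))
        ranges.append(tuple(sl))
    return ranges


# ---------------------------------------------------------------------------
# processing arms


@dataclass(frozen=True)
class ProcessingArm:
    """One feature-extraction condition.

    ``target_voxel_mm`` of ``None`` means extract from the native grid;
    otherwise the image is resampled to the given (x, y, z) voxel size.
    Intensities are binned with a fixed 25 HU bin width during extraction.
    """

    name: str
    target_voxel_mm: tuple[float, float, float] | None
    interpolator: str = "cosine_windowed_sinc"
    bin_width_hu: float = 25.0


#: The three study arms: native grid, median voxel and largest voxel.
ARMS: dict[str, ProcessingArm] = {
    "original": ProcessingArm("original", None),
    "median_resample": ProcessingArm("median_resample", (0.68, 0.68, 1.5)),
    "largest_resample": ProcessingArm("largest_resample", (0.98, 0.98, 3.75)),
}


def resample_to_arm(image, arm: ProcessingArm):
    """Resample a CT volume to the arm's target voxel size.

    ``image`` is a ``SimpleITK.Image`` in HU.  Interpolation uses the
    cosine-windowed-sinc kernel; the output grid keeps the input origin and
    direction, with dimensions ``ceil(extent / target)``.
    """
    import SimpleITK as sitk

    if arm.target_voxel_mm is None:
        raise ValueError(f"arm {arm.name!r} has no target voxel size")
    spacing = image.GetSpacing()
    if any(s <= 0 for s in spacing):
        raise ValueError("input image lacks valid spacing metadata")
    target = arm.target_voxel_mm
    size = [
        max(1, int(np.ceil(osz * osp / t)))
        for osz, osp, t in zip(image.GetSize(), spacing, target)
    ]
    resampler = sitk.ResampleImageFilter()
    resampler.SetOutputSpacing(tuple(float(t) for t in target))
    resampler.SetSize(size)
    resampler.SetOutputOrigin(image.GetOrigin())
    resampler.SetOutputDirection(image.GetDirection())
    resampler.SetInterpolator(sitk.sitkCosineWindowedSinc)
    resampler.SetDefaultPixelValue(-1024.0)  # air, HU
    return resampler.Execute(image)


# ---------------------------------------------------------------------------
# feature tables and the extractor contract


@dataclass
class FeatureTable:
    """VOI x HRF matrix for one scan under one processing arm."""

    scan_id: str
    arm: str
    frame: pd.DataFrame = field(repr=False)  # index: voi ids, columns: features

    def __post_init__(self):
        if not np.isfinite(self.frame.to_numpy(dtype=float)).all():
            raise ValueError(
                f"feature table for scan {self.scan_id} contains non-finite values"
            )

    @property
    def values(self) -> np.ndarray:
        return self.frame.to_numpy(dtype=float)

    def matches_registry(self, registry: FeatureRegistry) -> bool:
        return tuple(self.frame.columns) == registry.names

    def to_csv(self, path: str | Path) -> None:
        out = self.frame.copy()
        out.insert(0, "voi_id", out.index)
        out.insert(0, "arm", self.arm)
        out.insert(0, "scan_id", self.scan_id)
        out.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "FeatureTable":
        df = pd.read_csv(path)
        meta = ("scan_id", "arm", "voi_id")
        missing = [c for c in meta if c not in df.columns]
        if missing:
            raise ValueError(f"feature table CSV lacks columns {missing}")
        scan_ids = df["scan_id"].unique()
        arms = df["arm"].unique()
        if len(scan_ids) != 1 or len(arms) != 1:
            raise ValueError("feature table CSV must hold exactly one scan/arm")
        frame = df.drop(columns=["scan_id", "arm"]).set_index("voi_id")
        frame.columns.name = None
        frame.index.name = None
        return cls(str(scan_ids[0]), str(arms[0]), frame)


class FeatureExtractor(Protocol):
    """Contract for a delegated per-VOI feature extractor.

    ``extract_voi`` receives the voxel array of a single VOI (in HU, already
    cropped) plus the arm's bin width and returns ``{feature_name: value}``
    for every registry feature.  Implementations must be deterministic.
    """

    def extract_voi(
        self, voxels: np.ndarray, bin_width_hu: float, registry: FeatureRegistry
    ) -> dict[str, float]:
        ...


class ExtractionError(RuntimeError):
    """Per-VOI extractor failures, each tagged with its VOI id."""


def extract_features(
    image,
    grid: VOIGrid,
    arm: ProcessingArm,
    registry: FeatureRegistry,
    extractor: FeatureExtractor,
    *,
    scan_id: str,
) -> FeatureTable:
    """Run the delegated extractor over every VOI of a CT volume.

    ``image`` is a ``SimpleITK.Image``; the VOI grid is mapped to voxel
    index ranges via the image origin/spacing.  Produces one row per VOI and
    one column per registry feature; any per-VOI failure is collected and
    re-raised as :class:`ExtractionError` naming the offending VOIs.
    """
    import SimpleITK as sitk

    volume = sitk.GetArrayFromImage(image)  # (z, y, x)
    origin = image.GetOrigin()
    spacing = image.GetSpacing()
    ranges = voi_index_ranges(grid, origin, spacing)

    rows, failures = [], []
    for voi_id, (sx, sy, sz) in zip(grid.voi_ids, ranges):
        voxels = volume[sz, sy, sx]
        try:
            row = extractor.extract_voi(voxels, arm.bin_width_hu, registry)
            rows.append([float(row[name]) for name in registry.names])
        except Exception as exc:  # noqa: BLE001 - reported per VOI
            failures.append(f"{voi_id}: {exc}")
            rows.append([np.nan] * len(registry))
    if failures:
        raise ExtractionError(
            f"extraction failed for {len(failures)} VOI(s):\n" + "\n".join(failures)
        )
    frame = pd.DataFrame(rows, index=grid.voi_ids, columns=list(registry.names))
    return FeatureTable(scan_id=scan_id, arm=arm.name, frame=frame)
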