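"""Scan acquisition metadata and pairwise parameter encoding.

Each CT scan is described by eight acquisition/reconstruction parameters:
vendor, model, tube current (mA), exposure (mAs), exposure time (ms),
slice thickness (mm), in-plane pixel spacing (mm) and the convolution
(reconstruction) kernel.  An unordered pair of scans is encoded as an
8-vector in [0, 1] quantifying how similar the two acquisitions are:

* vendor / model: 1 if identical, 0 otherwise;
* numeric parameters: min/max ratio across the pair (1 = identical);
* kernel: min/max ratio of the two kernels' schema ranks, where the rank
  orders kernels by limiting frequency (sharper kernel = higher rank).

The encoding is symmetric in the two scans and equals the all-ones vector
iff every parameter matches.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass
from importlib import resources
from itertools import combinations
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "PARAMETERS",
    "NUMERIC_PARAMETERS",
    "ScanMetadata",
    "KernelSchema",
    "PairEncoding",
    "MetadataError",
    "load_metadata",
    "load_dicom_metadata",
    "default_kernel_schema",
    "enumerate_pairs",
    "kernel_value",
    "encode_pair",
    "encode_pairs",
    "encodings_to_frame",
]

#: Categorical hardware parameters, numeric acquisition parameters and the
#: reconstruction kernel, in canonical column order.
NUMERIC_PARAMETERS: tuple[str, ...] = (
    "tube_current",
    "exposure",
    "exposure_time",
    "slice_thickness",
    "pixel_spacing",
)
PARAMETERS: tuple[str, ...] = ("vendor", "model", *NUMERIC_PARAMETERS, "kernel")

#: DICOM attribute (keyword) for each parameter.
DICOM_KEYWORDS: Mapping[str, str] = {
    "vendor": "Manufacturer",
    "model": "ManufacturerModelName",
    "tube_current": "XRayTubeCurrent",
    "exposure": "Exposure",
    "exposure_time": "ExposureTime",
    "slice_thickness": "SliceThickness",
    "pixel_spacing": "PixelSpacing",
    "kernel": "ConvolutionKernel",
}


class MetadataError(ValueError):
    """Raised for unreadable, duplicated or invalid scan metadata."""


@dataclass(frozen=True)
class ScanMetadata:
    """Acquisition/reconstruction parameters of a single CT scan.

    Numeric fields are ``None`` when the source did not provide them (a
    recorded value of 0 for tube current / exposure / exposure time is
    treated as missing, not as a legitimate setting).
    """

    scan_id: str
    vendor: str | None = None
    model: str | None = None
    tube_current: float | None = None  # mA
    exposure: float | None = None  # mAs
    exposure_time: float | None = None  # ms
    slice_thickness: float | None = None  # mm
    pixel_spacing: float | None = None  # mm, in-plane (row/col averaged)
    kernel: str | None = None

    def missing_parameters(self) -> list[str]:
        return [p for p in PARAMETERS if getattr(self, p) is None]

    def validation_errors(self) -> list[str]:
        """Invariant violations (strictly positive numeric fields)."""
        errors = []
        for p in NUMERIC_PARAMETERS:
            v = getattr(self, p)
            if v is not None and (not math.isfinite(v) or v <= 0):
                errors.append(f"{p} must be strictly positive, got {v!r}")
        return errors


class KernelSchema:
    """Numeric ranking of convolution kernels by limiting frequency.

    Higher rank means a sharper kernel (higher limiting spatial frequency).
    Cross-vendor kernels judged equivalent may share a rank.
    """

    def __init__(self, ranks: Mapping[str, float]):
        bad = {k: v for k, v in ranks.items() if v <= 0}
        if bad:
            raise MetadataError(f"kernel ranks must be strictly positive: {bad}")
        self._ranks = {str(k): float(v) for k, v in ranks.items()}

    def __contains__(self, kernel: str) -> bool:
        return kernel in self._ranks

    def __len__(self) -> int:
        return len(self._ranks)

    def rank(self, kernel: str) -> float:
        try:
            return self._ranks[kernel]
        except KeyError:
            raise MetadataError(
                f"kernel {kernel!r} is not in the schema; add it with a rank"
            ) from None

    def as_dict(self) -> dict[str, float]:
        return dict(self._ranks)

    @classmethod
    def from_csv(cls, path: str | Path) -> "KernelSchema":
        with open(path, newline="") as fh:
            rows = list(csv.reader(fh))
        if rows and rows[0][:2] == ["kernel_name", "rank"]:
            rows = rows[1:]
        return cls({name: float(rank) for name, rank, *_ in rows if name})

    @classmethod
    def from_json(cls, path: str | Path) -> "KernelSchema":
        with open(path) as fh:
            return cls(json.load(fh))

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["kernel_name", "rank"])
            for name, rank in sorted(self._ranks.items()):
                w.writerow([name, rank])


def default_kernel_schema() -> KernelSchema:
    """Packaged default schema for common GE/Siemens/Philips/Toshiba kernels.

    The ranks order kernels by limiting frequency (soft -> sharp) and are a
    documented stand-in, not a vendor-published table; edit the CSV or supply
    your own schema for site-specific kernels.
    """
    with resources.files("maaspenn.data").joinpath("kernel_schema.csv").open() as fh:
        rows = list(csv.reader(fh))[1:]
    return KernelSchema({name: float(rank) for name, rank, *_ in rows if name})


@dataclass(frozen=True)
class PairEncoding:
    """The 8 similarity values in [0, 1] for one unordered scan pair."""

    pair_id: tuple[str, str]  # lexicographically ordered scan ids
    values: Mapping[str, float]

    def __post_init__(self):
        if tuple(sorted(self.pair_id)) != tuple(self.pair_id):
            raise MetadataError(f"pair_id must be sorted: {self.pair_id}")
        for p, v in self.values.items():
            if not (0.0 <= v <= 1.0):
                raise MetadataError(f"encoded {p}={v} outside [0, 1]")


# ---------------------------------------------------------------------------
# loading


def _is_multivalue(value) -> bool:
    # lists, tuples and pydicom MultiValue, but not strings
    return hasattr(value, "__len__") and not isinstance(value, (str, bytes))


def _coerce_numeric(value, param: str) -> float | None:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    if isinstance(value, str):
        value = value.strip()
        if not value:
            return None
        # DICOM multi-valued pixel spacing comes as "0.68\0.68"
        if "\\" in value:
            parts = [float(p) for p in value.split("\\") if p]
            value = sum(parts) / len(parts)
        else:
            value = float(value)
    elif _is_multivalue(value):
        if not len(value):
            return None
        value = sum(float(v) for v in value) / len(value)
    value = float(value)
    # zero dose-related values are scanner-header placeholders for "absent"
    if value == 0 and param in ("tube_current", "exposure", "exposure_time"):
        return None
    return value


def _coerce_str(value) -> str | None:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    if _is_multivalue(value):  # multi-valued ConvolutionKernel
        value = value[0] if len(value) else None
        if value is None:
            return None
    s = str(value).strip()
    return s or None


def load_metadata(source: str | Path | pd.DataFrame) -> list[ScanMetadata]:
    """Load scan metadata from a delimited table (CSV/TSV) or DataFrame.

    The table must carry a ``scan_id`` column plus the eight parameter
    columns named as in :data:`PARAMETERS`.  Missing cells are kept as
    ``None`` (flagged, never imputed).  Raises :class:`MetadataError` on
    duplicate scan ids or invariant violations, reporting every offending
    scan.
    """
    if isinstance(source, pd.DataFrame):
        df = source.copy()
    else:
        path = Path(source)
        if not path.exists():
            raise MetadataError(f"metadata source {path} does not exist")
        df = pd.read_csv(path, sep=None, engine="python")
    if "scan_id" not in df.columns:
        raise MetadataError("metadata table lacks a 'scan_id' column")

    scans: list[ScanMetadata] = []
    problems: list[str] = []
    for _, row in df.iterrows():
        kwargs = {"scan_id": str(row["scan_id"])}
        for p in PARAMETERS:
            raw = row.get(p)
            if p in NUMERIC_PARAMETERS:
                kwargs[p] = _coerce_numeric(raw, p)
            else:
                kwargs[p] = _coerce_str(raw)
        scan = ScanMetadata(**kwargs)
        for err in scan.validation_errors():
            problems.append(f"scan {scan.scan_id}: {err}")
        scans.append(scan)

    ids = [s.scan_id for s in scans]
    dupes = sorted({i for i in ids if ids.count(i) > 1})
    if dupes:
        problems.append(f"duplicate scan_id(s): {dupes}")
    if problems:
        raise MetadataError("invalid metadata:\n" + "\n".join(problems))
    return scans


def load_dicom_metadata(source: Iterable) -> list[ScanMetadata]:
    """Extract the eight parameters from DICOM files or pydicom datasets.

    ``source`` may be a directory, an iterable of file paths, or an iterable
    of already-read ``pydicom`` datasets (one per scan/series).  Only header
    attributes are touched; pixel data is never decoded.
    """
    import pydicom

    if isinstance(source, (str, Path)):
        source = sorted(Path(source).glob("*.dcm"))
    datasets = []
    for item in source:
        if isinstance(item, (str, Path)):
            datasets.append(pydicom.dcmread(item, stop_before_pixels=True))
        else:
            datasets.append(item)

    rows = []
    for ds in datasets:
        row = {"scan_id": str(getattr(ds, "SeriesInstanceUID", getattr(ds, "SOPInstanceUID", "")))}
        for param, keyword in DICOM_KEYWORDS.items():
            row[param] = getattr(ds, keyword, None)
        rows.append(row)

    scans = []
    problems = []
    for row in rows:
        kwargs = {"scan_id": row["scan_id"]}
        for p in PARAMETERS:
            raw = row[p]
            kwargs[p] = (
                _coerce_numeric(raw, p) if p in NUMERIC_PARAMETERS else _coerce_str(raw)
            )
        scan = ScanMetadata(**kwargs)
        for err in scan.validation_errors():
            problems.append(f"scan {scan.scan_id}: {err}")
        scans.append(scan)
    ids = [s.scan_id for s in scans]
    dupes = sorted({i for i in ids if ids.count(i) > 1})
    if dupes:
        problems.append(f"duplicate scan_id(s): {dupes}")
    if problems:
        raise MetadataError("invalid DICOM metadata:\n" + "\n".join(problems))
    return scans


# ---------------------------------------------------------------------------
# pairing and encoding


def enumerate_pairs(scans: Sequence[ScanMetadata | str]) -> list[tuple[str, str]]:
    """All unordered scan pairs, each once, as sorted (id, id) tuples.

    251 scans yield C(251, 2) = 31,375 pairs.
    """
    ids = [s.scan_id if isinstance(s, ScanMetadata) else str(s) for s in scans]
    if len(ids) < 2:
        raise MetadataError(f"need at least 2 scans to form pairs, got {len(ids)}")
    if len(set(ids)) != len(ids):
        raise MetadataError("scan ids are not unique")
    return [tuple(sorted(p)) for p in combinations(ids, 2)]


def kernel_value(k1: str, k2: str, schema: KernelSchema) -> float:
    """Similarity of two kernels: min/max ratio of their schema ranks.

    Identical kernels (or distinct names sharing a rank) encode to 1; the
    value decreases toward 0 as the limiting frequencies diverge.
    """
    r1, r2 = schema.rank(k1), schema.rank(k2)
    return min(r1, r2) / max(r1, r2)


def encode_pair(
    a: ScanMetadata, b: ScanMetadata, schema: KernelSchema
) -> PairEncoding:
    """Encode one unordered scan pair into the 8-vector in [0, 1].

    Symmetric in ``a`` and ``b``; raises :class:`MetadataError` if either
    scan is missing a parameter.
    """
    missing = [
        f"{s.scan_id}:{p}" for s in (a, b) for p in s.missing_parameters()
    ]
    if missing:
        raise MetadataError(f"cannot encode pair, missing parameters: {missing}")

    values: dict[str, float] = {}
    values["vendor"] = 1.0 if a.vendor == b.vendor else 0.0
    values["model"] = 1.0 if a.model == b.model else 0.0
    for p in NUMERIC_PARAMETERS:
        va, vb = getattr(a, p), getattr(b, p)
        values[p] = min(va, vb) / max(va, vb)
    values["kernel"] = kernel_value(a.kernel, b.kernel, schema)
    pair_id = tuple(sorted((a.scan_id, b.scan_id)))
    return PairEncoding(pair_id=pair_id, values=values)


def encode_pairs(
    scans: Sequence[ScanMetadata],
    schema: KernelSchema,
    *,
    missing_policy: str = "error",
) -> list[PairEncoding]:
    """Encode every unordered pair of ``scans``.

    ``missing_policy='error'`` (default) raises on the first pair with a
    missing parameter; ``'drop-pair'`` silently excludes affected pairs
    (their count is recoverable as C(n,2) minus the returned length).
    """
    if missing_policy not in ("error", "drop-pair"):
        raise ValueError(f"unknown missing_policy {missing_policy!r}")
    by_id = {s.scan_id: s for s in scans}
    encodings = []
    for ia, ib in enumerate_pairs(scans):
        a, b = by_id[ia], by_id[ib]
        if missing_policy == "drop-pair" and (
            a.missing_parameters() or b.missing_parameters()
        ):
            continue
        encodings.append(encode_pair(a, b, schema))
    return encodings


def encodings_to_frame(encodings: Iterable[PairEncoding]) -> pd.DataFrame:
    """Tabulate encodings: one row per pair, columns scan_a, scan_b + the 8 parameters."""
    rows = []
    for enc in encodings:
        row = {"scan_a": enc.pair_id[0], "scan_b": enc.pair_id[1]}
        row.update({p: enc.values[p] for p in PARAMETERS})
        rows.append(row)
    return pd.DataFrame(rows, columns=["scan_a", "scan_b", *PARAMETERS])
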