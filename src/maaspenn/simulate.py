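"""Synthetic phantom cohorts with acquisition-dependent feature distortions.

The generator emulates the structure of a CT phantom reproducibility study:
``n_scans`` scans of one physical phantom, each described by the eight
acquisition parameters, each yielding a 160-VOI x 91-feature table.  Every
feature has a fixed per-VOI texture signature shared by all scans (the
phantom does not change); a scan's acquisition settings multiply that
signature by a feature-specific distortion,

    value(voi, f) = base(voi, f) * (1 + sum_p beta_{f,p} d_p(scan)) + eps,

where ``d_p`` maps the scan's parameter value to a standardized offset in
[-1/2, 1/2], ``beta_{f,p} >= 0`` is the feature's sensitivity to parameter
``p``, and ``eps`` is Gaussian measurement noise.  A designated set of
features (by default the four first-order statistics that track calibrated
HU directly: mean, median, root mean squared, total energy) has all betas
zero and is therefore insensitive to every acquisition change.

Default effect sizes are ordered kernel > slice thickness > pixel spacing
>> tube current = exposure = exposure time > vendor = model = 0, i.e.
resolution parameters dominate, dose-related parameters barely matter and
hardware make not at all.  Because the distortion is a per-feature
location/scale change (shared by all VOIs), ComBat's location/scale model
can remove it; ``combat_adverse=True`` makes distortions VOI-dependent
(an interaction ComBat cannot model), for testing that harmonizability is
regime-dependent.

All randomness flows from ``cfg.seed`` through named SeedSequence spawns,
so a config is a complete, reproducible description of a cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Sequence

import numpy as np
import pandas as pd

from .features import FeatureTable, default_registry
from .metadata import (
    KernelSchema,
    ScanMetadata,
    encode_pairs,
    encodings_to_frame,
)
from .reproducibility import pairwise_reproducibility

__all__ = [
    "GeneratorConfig",
    "GroundTruth",
    "generate_metadata",
    "simulate_feature_table",
    "simulate_dataset",
    "SyntheticDataset",
    "simulate_experiment",
]

_DEFAULT_EFFECTS: tuple[tuple[str, float], ...] = (
    ("vendor", 0.0),
    ("model", 0.0),
    ("tube_current", 0.04),
    ("exposure", 0.04),
    ("exposure_time", 0.04),
    ("slice_thickness", 0.50),
    ("pixel_spacing", 0.30),
    ("kernel", 0.80),
)

_DEFAULT_INSENSITIVE: tuple[str, ...] = (
    "original_firstorder_Mean",
    "original_firstorder_Median",
    "original_firstorder_RootMeanSquared",
    "original_firstorder_TotalEnergy",
    # extras, used only when n_insensitive > 4
    "original_firstorder_Energy",
    "original_firstorder_10Percentile",
    "original_firstorder_90Percentile",
)


@dataclass(frozen=True)
class GeneratorConfig:
    """Study design of a synthetic cohort.

    ``effect_sizes`` are per-parameter distortion scales (unitless,
    multiplying the standardized parameter offset); ``noise_sd`` is the
    measurement-noise standard deviation relative to a feature's VOI
    spread; ``mean_to_spread`` is the ratio of a feature's mean magnitude
    to its across-VOI spread (5 means the texture signal is 20% of the
    mean), which controls how strongly a location shift penalizes CCC.
    """

    n_scans: int = 40
    seed: int = 0
    vendors: tuple[str, ...] = ("GE", "Siemens", "Philips", "Toshiba")
    models: tuple[tuple[str, str], ...] = (
        ("GE", "LightSpeed16"), ("GE", "Discovery690"),
        ("Siemens", "SomatomDefinition"), ("Siemens", "SensationOpen"),
        ("Philips", "Brilliance64"), ("Philips", "BigBore"),
        ("Toshiba", "Aquilion"), ("Toshiba", "AquilionONE"),
    )
    kernels: tuple[tuple[str, float], ...] = (
        ("SOFT", 1.5), ("STANDARD", 2.0), ("B30f", 2.0), ("B50f", 3.5),
        ("DETAIL", 3.5), ("FC50", 4.5), ("B70f", 5.0), ("LUNG", 5.0),
    )
    tube_currents: tuple[float, ...] = (100.0, 160.0, 200.0, 250.0, 320.0, 400.0, 500.0)
    exposures: tuple[float, ...] = (80.0, 120.0, 160.0, 200.0, 250.0, 320.0)
    exposure_times: tuple[float, ...] = (500.0, 600.0, 750.0, 1000.0)
    slice_thicknesses: tuple[float, ...] = (0.625, 1.25, 2.5, 3.75, 5.0)
    pixel_spacings: tuple[float, ...] = (0.39, 0.49, 0.59, 0.68, 0.78, 0.88, 0.98)
    effect_sizes: tuple[tuple[str, float], ...] = _DEFAULT_EFFECTS
    noise_sd: float = 0.02
    n_insensitive: int = 4
    n_voi: int = 160
    mean_to_spread: float = 5.0
    combat_adverse: bool = False
    adverse_strength: float = 1.0

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_insensitive < 4:
            raise ValueError("n_insensitive must be >= 4")
        if self.n_insensitive > len(_DEFAULT_INSENSITIVE):
            raise ValueError(
                f"n_insensitive > {len(_DEFAULT_INSENSITIVE)} is not supported"
            )
        for pool in (self.vendors, self.models, self.kernels, self.tube_currents,
                     self.exposures, self.exposure_times, self.slice_thicknesses,
                     self.pixel_spacings):
            if not pool:
                raise ValueError("parameter pools must be nonempty")

    def effects(self) -> dict[str, float]:
        return dict(self.effect_sizes)

    def kernel_schema(self) -> KernelSchema:
        return KernelSchema(dict(self.kernels))

    def with_effects(self, **overrides: float) -> "GeneratorConfig":
        eff = self.effects()
        unknown = set(overrides) - set(eff)
        if unknown:
            raise ValueError(f"unknown parameters {sorted(unknown)}")
        eff.update(overrides)
        return replace(self, effect_sizes=tuple(eff.items()))


@dataclass(frozen=True)
class GroundTruth:
    """True per-feature sensitivities and the designed-insensitive set."""

    beta: pd.DataFrame = field(repr=False)  # features x parameters
    insensitive_features: tuple[str, ...] = ()

    def to_json_dict(self) -> dict:
        return {
            "insensitive_features": list(self.insensitive_features),
            "beta": {c: self.beta[c].round(10).to_dict() for c in self.beta.columns},
        }


def _rng(cfg: GeneratorConfig, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(cfg.seed, spawn_key=key))


@lru_cache(maxsize=8)
def _design(cfg: GeneratorConfig) -> tuple[np.ndarray, np.ndarray, pd.DataFrame, tuple[str, ...], np.ndarray]:
    """Fixed phantom design: per-feature means, per-VOI texture, betas."""
    registry = default_registry()
    names = list(registry.names)
    rng = _rng(cfg, 0)
    # feature magnitudes span a few decades, like real radiomic features
    mu = np.sign(rng.uniform(-1, 1, len(names))) * 10 ** rng.uniform(0, 3, len(names))
    mu[mu == 0] = 1.0
    sigma = np.abs(mu) / cfg.mean_to_spread
    texture = rng.standard_normal((cfg.n_voi, len(names)))  # shared by all scans
    base = mu + sigma * texture  # (voi, feature)

    insensitive = _DEFAULT_INSENSITIVE[: cfg.n_insensitive]
    effects = cfg.effects()
    beta = pd.DataFrame(0.0, index=names, columns=list(effects))
    active = [p for p, s in effects.items() if s > 0]
    if active:
        scales = np.array([effects[p] for p in active])
        # each sensitive feature responds to one primary parameter, drawn
        # with probability proportional to that parameter's effect size:
        # strong parameters distort more features, and more strongly
        primary = rng.choice(len(active), size=len(names), p=scales / scales.sum())
        strength = 0.3 + np.abs(rng.standard_normal(len(names)))
        for f, (name, p_idx) in enumerate(zip(names, primary)):
            beta.iloc[f, beta.columns.get_loc(active[p_idx])] = (
                effects[active[p_idx]] * strength[f]
            )
    beta.loc[list(insensitive), :] = 0.0
    adverse = rng.standard_normal((cfg.n_voi, len(names)))  # VOI-level interaction
    return base, sigma, beta, insensitive, adverse


def _standardized_offsets(cfg: GeneratorConfig, meta: ScanMetadata) -> dict[str, float]:
    """Map a scan's parameter values to offsets in [-1/2, 1/2].

    Numeric parameters (and kernel ranks) are standardized on the log
    scale: acquisition effects act multiplicatively (halving the slice
    thickness matters the same anywhere on the scale), and the distortion
    difference between two scans is then a monotone function of their
    min/max ratio — the same similarity the pair encoding uses.
    """

    def _num(value: float, pool: Sequence[float]) -> float:
        lo, hi = min(pool), max(pool)
        if hi == lo:
            return 0.0
        lo, hi, value = np.log(lo), np.log(hi), np.log(value)
        return (value - (lo + hi) / 2.0) / (hi - lo)

    def _cat(value: str, pool: Sequence[str]) -> float:
        if len(pool) == 1:
            return 0.0
        return pool.index(value) / (len(pool) - 1) - 0.5

    ranks = dict(cfg.kernels)
    rvals = sorted(set(ranks.values()))  # log-standardized like the numerics
    model_pool = [m for _, m in cfg.models]
    return {
        "vendor": _cat(meta.vendor, list(cfg.vendors)),
        "model": _cat(meta.model, model_pool),
        "tube_current": _num(meta.tube_current, cfg.tube_currents),
        "exposure": _num(meta.exposure, cfg.exposures),
        "exposure_time": _num(meta.exposure_time, cfg.exposure_times),
        "slice_thickness": _num(meta.slice_thickness, cfg.slice_thicknesses),
        "pixel_spacing": _num(meta.pixel_spacing, cfg.pixel_spacings),
        "kernel": _num(ranks[meta.kernel], rvals),
    }


def generate_metadata(cfg: GeneratorConfig) -> list[ScanMetadata]:
    """Sample ``n_scans`` acquisition settings from the configured pools.

    Kernels are sampled independently of vendor (the rank schema makes
    kernels comparable across vendors), so hardware make carries no signal
    about the resolution parameters.
    """
    rng = _rng(cfg, 1)
    scans = []
    for i in range(cfg.n_scans):
        vendor = cfg.vendors[rng.integers(len(cfg.vendors))]
        vendor_models = [m for v, m in cfg.models if v == vendor] or [
            m for _, m in cfg.models
        ]
        scans.append(
            ScanMetadata(
                scan_id=f"scan{i:03d}",
                vendor=vendor,
                model=vendor_models[rng.integers(len(vendor_models))],
                tube_current=float(cfg.tube_currents[rng.integers(len(cfg.tube_currents))]),
                exposure=float(cfg.exposures[rng.integers(len(cfg.exposures))]),
                exposure_time=float(cfg.exposure_times[rng.integers(len(cfg.exposure_times))]),
                slice_thickness=float(cfg.slice_thicknesses[rng.integers(len(cfg.slice_thicknesses))]),
                pixel_spacing=float(cfg.pixel_spacings[rng.integers(len(cfg.pixel_spacings))]),
                kernel=cfg.kernels[rng.integers(len(cfg.kernels))][0],
            )
        )
    return scans


def ground_truth(cfg: GeneratorConfig) -> GroundTruth:
    _, _, beta, insensitive, _ = _design(cfg)
    return GroundTruth(beta=beta.copy(), insensitive_features=tuple(insensitive))


def simulate_feature_table(
    meta: ScanMetadata, cfg: GeneratorConfig, *, scan_index: int | None = None
) -> tuple[FeatureTable, GroundTruth]:
    """Feature table of one scan under the generator's distortion model.

    Deterministic given ``cfg`` and the scan: noise is seeded per scan (by
    the numeric suffix of the scan id, or an explicit ``scan_index``).
    """
    base, sigma, beta, insensitive, adverse = _design(cfg)
    registry = default_registry()
    if scan_index is None:
        digits = "".join(ch for ch in meta.scan_id if ch.isdigit())
        scan_index = int(digits) if digits else abs(hash(meta.scan_id)) % (2**31)
    offsets = _standardized_offsets(cfg, meta)
    distortion = beta.to_numpy() @ np.array([offsets[p] for p in beta.columns])
    factor = 1.0 + distortion[None, :]  # (1, feature)
    if cfg.combat_adverse:
        factor = 1.0 + distortion[None, :] * (1.0 + cfg.adverse_strength * adverse)
    noise = _rng(cfg, 2, scan_index).standard_normal(base.shape) * (
        cfg.noise_sd * sigma
    )
    values = base * factor + noise
    voi_ids = [f"voi{v:03d}" for v in range(cfg.n_voi)]
    frame = pd.DataFrame(values, index=voi_ids, columns=list(registry.names))
    table = FeatureTable(scan_id=meta.scan_id, arm="original", frame=frame)
    return table, GroundTruth(beta=beta.copy(), insensitive_features=tuple(insensitive))


@dataclass
class SyntheticDataset:
    """A full synthetic cohort: metadata, feature tables, ground truth."""

    config: GeneratorConfig
    scans: list[ScanMetadata]
    tables: dict[str, FeatureTable]
    truth: GroundTruth

    @property
    def schema(self) -> KernelSchema:
        return self.config.kernel_schema()


def simulate_dataset(cfg: GeneratorConfig) -> SyntheticDataset:
    """Generate metadata and one feature table per scan."""
    scans = generate_metadata(cfg)
    tables = {}
    for i, meta in enumerate(scans):
        table, truth = simulate_feature_table(meta, cfg, scan_index=i)
        tables[meta.scan_id] = table
    return SyntheticDataset(cfg, scans, tables, truth)


def simulate_experiment(
    cfg: GeneratorConfig, *, threshold: float = 0.9
) -> tuple[pd.DataFrame, SyntheticDataset]:
    """End-to-end scenario frame: encodings + percent reproducible per pair.

    Returns a DataFrame with one row per unordered scan pair carrying the
    eight encoded parameter similarities and the CCC-based outcome columns
    ``n_reproducible`` / ``pct_reproducible``, plus the underlying dataset.
    """
    ds = simulate_dataset(cfg)
    enc = encodings_to_frame(encode_pairs(ds.scans, ds.schema))
    out = pairwise_reproducibility(
        [ds.tables[s.scan_id] for s in ds.scans], threshold=threshold
    )
    frame = enc.merge(out, on=["scan_a", "scan_b"], validate="one_to_one")
    return frame, ds
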