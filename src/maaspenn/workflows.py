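"""Screening workflows built on the published score, plus run configuration.

Two ways to use the score in a radiomics study:

* **Prospective inclusion** (:func:`screen_scans`): score every pair of
  candidate scans and report which pairs (and which scans) fall at or
  below the cutoff — by default 0.94, the cutoff at which 70% or more of
  features are expected to be reproducible.
* **Retrospective audit** (:func:`audit_signature_dataset`): for a dataset
  a signature was trained on, the fraction of pairs scoring above the
  cutoff; a strict majority (> 1/2) is read as evidence the signature can
  generalize across the dataset's acquisition heterogeneity.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import __version__
from .metadata import (
    KernelSchema,
    ScanMetadata,
    default_kernel_schema,
    encode_pairs,
    encodings_to_frame,
)
from .score import ScoreWeights, maaspenn_score, published_weights

__all__ = ["RunConfig", "ScreenReport", "screen_scans", "audit_signature_dataset", "write_run_log"]

#: Published screening cutoff: score > 0.94 predicts >= 70% reproducible features.
DEFAULT_CUTOFF = 0.94


@dataclass
class RunConfig:
    """Paths and knobs of a CLI run, loadable from YAML."""

    metadata_path: str | None = None
    kernel_schema_path: str | None = None
    output_dir: str = "."
    thresholds: tuple[int, ...] = (10, 20, 30, 40, 50, 60, 70, 80, 90)
    cutoff: float = DEFAULT_CUTOFF
    seed: int = 0
    scoring_mode: str = "published"  # or "fitted"

    def __post_init__(self):
        bad = [t for t in self.thresholds if t not in range(10, 91)]
        if bad:
            raise ValueError(f"thresholds must lie in 10..90, got {bad}")
        if self.scoring_mode not in ("published", "fitted"):
            raise ValueError(f"unknown scoring mode {self.scoring_mode!r}")
        for p in (self.metadata_path, self.kernel_schema_path):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(p)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "thresholds" in raw:
            raw["thresholds"] = tuple(raw["thresholds"])
        return cls(**raw)

    def schema(self) -> KernelSchema:
        if self.kernel_schema_path:
            return KernelSchema.from_csv(self.kernel_schema_path)
        return default_kernel_schema()


@dataclass
class ScreenReport:
    """Pairwise scores and the pass/fail screening verdicts."""

    scores: pd.DataFrame  # scan_a, scan_b, maaspenn_score, passes
    cutoff: float

    @property
    def n_pairs(self) -> int:
        return len(self.scores)

    @property
    def fraction_above(self) -> float:
        return float(self.scores["passes"].mean())

    @property
    def failing_pairs(self) -> pd.DataFrame:
        return self.scores[~self.scores["passes"]].reset_index(drop=True)

    def per_scan_summary(self) -> pd.DataFrame:
        """Per scan: minimum pair score and number of failing pairs."""
        long = pd.concat(
            [
                self.scores.rename(columns={"scan_a": "scan_id"})[
                    ["scan_id", "maaspenn_score", "passes"]
                ],
                self.scores.rename(columns={"scan_b": "scan_id"})[
                    ["scan_id", "maaspenn_score", "passes"]
                ],
            ]
        )
        return (
            long.groupby("scan_id")
            .agg(
                min_score=("maaspenn_score", "min"),
                n_failing_pairs=("passes", lambda s: int((~s).sum())),
            )
            .reset_index()
        )


def _score_pairs(
    metadata: Sequence[ScanMetadata],
    schema: KernelSchema,
    cutoff: float,
    weights: ScoreWeights | None,
) -> ScreenReport:
    w = weights or published_weights()
    enc = encodings_to_frame(encode_pairs(metadata, schema))
    scores = enc[["scan_a", "scan_b"]].copy()
    scores["maaspenn_score"] = maaspenn_score(enc, w)
    scores["passes"] = scores["maaspenn_score"] > cutoff  # strict
    return ScreenReport(scores=scores, cutoff=cutoff)


def screen_scans(
    metadata: Sequence[ScanMetadata],
    schema: KernelSchema | None = None,
    cutoff: float = DEFAULT_CUTOFF,
    weights: ScoreWeights | None = None,
) -> ScreenReport:
    """Prospective screening: score all pairs, flag those at or below the cutoff.

    A pair passes iff its score strictly exceeds ``cutoff``.  The report's
    per-scan summary identifies scans responsible for failing pairs, the
    candidates for exclusion from a planned analysis.
    """
    return _score_pairs(metadata, schema or default_kernel_schema(), cutoff, weights)


def audit_signature_dataset(
    metadata: Sequence[ScanMetadata],
    schema: KernelSchema | None = None,
    cutoff: float = DEFAULT_CUTOFF,
    weights: ScoreWeights | None = None,
) -> tuple[float, bool, ScreenReport]:
    """Retrospective audit: fraction of pairs above the cutoff and the verdict.

    Verdict is positive iff a *strict* majority (> 50%) of pairs scores
    above the cutoff; exactly half is negative.
    """
    report = _score_pairs(metadata, schema or default_kernel_schema(), cutoff, weights)
    fraction = report.fraction_above
    return fraction, fraction > 0.5, report


def write_run_log(path: str | Path, command: str, config: dict) -> None:
    """Append one JSON line recording command, config, seeds and version."""
    record = {
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "command": command,
        "version": __version__,
        "config": config,
    }
    with open(path, "a") as fh:
        fh.write(json.dumps(record, default=str) + "\n")
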