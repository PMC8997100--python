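"""Per-feature reproducibility of radiomic features via Lin's CCC.

For a pair of scans of the same phantom, each feature yields two vectors of
160 values (one per VOI).  Lin's concordance correlation coefficient

    CCC = 2 cov(x, y) / (var(x) + var(y) + (mean(x) - mean(y))^2)

measures agreement in both value and rank: it equals the Pearson
correlation multiplied by a bias-correction factor that penalizes location
and scale shifts, so |CCC| <= |r| always.  A feature is called
*reproducible* for the pair when CCC > 0.9 (strict).  The percent of
reproducible features per pair is the scenario-level outcome used by the
scoring model.

Moments are population (1/n) by default, per Lin's original definition;
``ddof=1`` switches to sample moments (the convention of the epiR
implementation) — at n = 160 the two differ negligibly but the choice is
explicit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .features import FeatureTable

__all__ = [
    "lin_ccc",
    "ccc_per_feature",
    "ScenarioResult",
    "scenario_reproducibility",
    "intersect_reproducible",
    "summarize_scenarios",
    "pairwise_reproducibility",
]

#: Reproducibility threshold: a feature counts as reproducible iff CCC
#: strictly exceeds this value.
CCC_THRESHOLD = 0.9


def lin_ccc(x, y, *, ddof: int = 0) -> float:
    """Lin's concordance correlation coefficient of two paired vectors.

    Returns NaN when both vectors are constant (agreement is undefined).
    Symmetric in ``x`` and ``y``; bounded by [-1, 1].
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError(f"x and y must be 1-D of equal length, got {x.shape}, {y.shape}")
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 paired samples")
    mx, my = x.mean(), y.mean()
    vx = x.var(ddof=ddof)
    vy = y.var(ddof=ddof)
    if vx == 0.0 and vy == 0.0:  # agreement of two constants is undefined
        return float("nan")
    cov = ((x - mx) * (y - my)).sum() / (n - ddof)
    denom = vx + vy + (mx - my) ** 2
    return float(2.0 * cov / denom)


def ccc_per_feature(
    ta: FeatureTable, tb: FeatureTable, *, ddof: int = 0
) -> pd.Series:
    """CCC for every feature column across two aligned VOI tables."""
    _check_aligned(ta, tb)
    a = ta.values
    b = tb.values
    n = a.shape[0]
    ma, mb = a.mean(axis=0), b.mean(axis=0)
    va = a.var(axis=0, ddof=ddof)
    vb = b.var(axis=0, ddof=ddof)
    cov = ((a - ma) * (b - mb)).sum(axis=0) / (n - ddof)
    denom = va + vb + (ma - mb) ** 2
    undefined = (va == 0.0) & (vb == 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        ccc = np.where(undefined, np.nan, 2.0 * cov / np.where(undefined, 1.0, denom))
    return pd.Series(ccc, index=ta.frame.columns, name="ccc")


def _check_aligned(ta: FeatureTable, tb: FeatureTable) -> None:
    if list(ta.frame.columns) != list(tb.frame.columns):
        raise ValueError("feature registries of the two tables differ")
    if ta.arm != tb.arm:
        raise ValueError(f"processing arms differ: {ta.arm!r} vs {tb.arm!r}")
    if list(ta.frame.index) != list(tb.frame.index):
        raise ValueError("VOI rows are not aligned between the two tables")


@dataclass
class ScenarioResult:
    """Reproducibility outcome of one scan pair (a 'scenario')."""

    pair_id: tuple[str, str]
    arm: str
    harmonized: bool
    flags: pd.Series  # feature -> bool (reproducible)
    ccc: pd.Series  # feature -> CCC value (NaN where undefined)

    @property
    def n_reproducible(self) -> int:
        return int(self.flags.sum())

    @property
    def pct_reproducible(self) -> float:
        return 100.0 * self.n_reproducible / len(self.flags)

    @property
    def reproducible_features(self) -> set[str]:
        return set(self.flags.index[self.flags])


def scenario_reproducibility(
    ta: FeatureTable,
    tb: FeatureTable,
    threshold: float = CCC_THRESHOLD,
    *,
    harmonized: bool = False,
    ddof: int = 0,
) -> ScenarioResult:
    """Classify every feature of a scan pair as reproducible (CCC > threshold).

    The inequality is strict: a feature at exactly the threshold is not
    reproducible.  Features whose CCC is undefined (both columns constant)
    are flagged non-reproducible and reported via a warning.
    """
    ccc = ccc_per_feature(ta, tb, ddof=ddof)
    undefined = ccc.index[ccc.isna()]
    if len(undefined):
        warnings.warn(
            f"CCC undefined (constant in both scans) for {len(undefined)} "
            f"feature(s), counted non-reproducible: {list(undefined[:5])}...",
            stacklevel=2,
        )
    flags = (ccc > threshold).fillna(False)
    pair_id = tuple(sorted((ta.scan_id, tb.scan_id)))
    return ScenarioResult(pair_id, ta.arm, harmonized, flags, ccc)


def intersect_reproducible(results: Iterable[ScenarioResult]) -> set[str]:
    """Features reproducible in *every* scenario (the insensitive set)."""
    results = list(results)
    if not results:
        raise ValueError("need at least one scenario to intersect")
    common = results[0].reproducible_features
    for r in results[1:]:
        common &= r.reproducible_features
    return common


def summarize_scenarios(results: Iterable[ScenarioResult]) -> pd.DataFrame:
    """Per arm/harmonization condition: mean, sd and quartiles of percent reproducible.

    The sd is the sample (ddof=1) estimator; single-scenario groups report
    sd 0.  The quartile columns are the boxplot statistics for plotting the
    per-condition distributions.
    """
    results = list(results)
    if not results:
        raise ValueError("no scenarios to summarize")
    df = pd.DataFrame(
        {
            "arm": [r.arm for r in results],
            "harmonized": [r.harmonized for r in results],
            "pct_reproducible": [r.pct_reproducible for r in results],
            "n_reproducible": [r.n_reproducible for r in results],
        }
    )
    def _agg(g: pd.Series) -> pd.Series:
        return pd.Series(
            {
                "n_pairs": len(g),
                "mean_pct": g.mean(),
                "sd_pct": g.std(ddof=1) if len(g) > 1 else 0.0,
                "min_pct": g.min(),
                "q25_pct": g.quantile(0.25),
                "median_pct": g.median(),
                "q75_pct": g.quantile(0.75),
                "max_pct": g.max(),
            }
        )
    out = (
        df.groupby(["arm", "harmonized"])["pct_reproducible"]
        .apply(_agg)
        .unstack()
        .reset_index()
    )
    out["n_pairs"] = out["n_pairs"].astype(int)
    return out


def pairwise_reproducibility(
    tables: Mapping[str, FeatureTable] | Sequence[FeatureTable],
    threshold: float = CCC_THRESHOLD,
    *,
    return_flags: bool = False,
):
    """Percent-reproducible outcome for every unordered pair of scans.

    Vectorized over all pairs at once: with ``n`` scans, the per-feature
    CCCs for all C(n, 2) pairs are computed from the stacked
    (scan, VOI, feature) array via batched moment arithmetic.  Returns a
    DataFrame with columns ``scan_a, scan_b, n_reproducible,
    pct_reproducible`` (and, when ``return_flags``, also the boolean
    pair x feature flag matrix).
    """
    if isinstance(tables, Mapping):
        tables = list(tables.values())
    else:
        tables = list(tables)
    if len(tables) < 2:
        raise ValueError("need at least 2 scans")
    cols = list(tables[0].frame.columns)
    arm = tables[0].arm
    for t in tables[1:]:
        if list(t.frame.columns) != cols or t.arm != arm:
            raise ValueError("all tables must share registry and arm")
    ids = [t.scan_id for t in tables]
    X = np.stack([t.values for t in tables])  # (n_scans, n_voi, n_feat)
    n_scans, n_voi, n_feat = X.shape

    mean = X.mean(axis=1)  # (s, f)
    var = X.var(axis=1)  # population
    # cross moments for every ordered pair, then take the upper triangle
    cross = np.einsum("avf,bvf->abf", X, X) / n_voi
    cov = cross - mean[:, None, :] * mean[None, :, :]
    denom = var[:, None, :] + var[None, :, :] + (mean[:, None, :] - mean[None, :, :]) ** 2
    undefined = (var[:, None, :] == 0.0) & (var[None, :, :] == 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        ccc = np.where(undefined, np.nan, 2.0 * cov / np.where(undefined, 1.0, denom))

    ia, ib = np.triu_indices(n_scans, k=1)
    flags = np.nan_to_num(ccc[ia, ib, :], nan=-np.inf) > threshold
    n_rep = flags.sum(axis=1)
    rows = []
    for k in range(len(ia)):
        a, b = sorted((ids[ia[k]], ids[ib[k]]))
        rows.append((a, b, int(n_rep[k]), 100.0 * n_rep[k] / n_feat))
    out = pd.DataFrame(
        rows, columns=["scan_a", "scan_b", "n_reproducible", "pct_reproducible"]
    )
    if return_flags:
        flag_df = pd.DataFrame(flags, columns=cols)
        flag_df.insert(0, "scan_b", out["scan_b"])
        flag_df.insert(0, "scan_a", out["scan_a"])
        return out, flag_df
    return out
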