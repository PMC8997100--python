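"""The MaasPenn reproducibility score and its supporting analyses.

A regression random forest is trained on the pairwise parameter encodings
(8 predictors) against the percent of reproducible features per pair.  The
top-k (default 3) parameters by importance are kept and their importances
normalized to sum to 1; the score of a pair is then the importance-weighted
sum of its encoded parameter similarities, a number in (0, 1] that is 1
exactly when the retained parameters match.

The published weights — convolution kernel 0.48, slice thickness 0.33,
pixel spacing 0.19 — are the packaged default scoring mode; refitting on
your own cohort produces dataset-specific weights labelled ``fitted``.

ROC analyses turn the score into a screening rule: for a percent-
reproducible threshold t, pairs are labelled 1 iff their percent exceeds t,
and the score cutoff maximizing Youden's J is selected.  The packaged
cutoff table (including the 0.94 cutoff at the 70% threshold used for scan
screening) ships alongside the weights.  A robustness harness repeats the
cutoff selection over random 80/20 train/validation splits.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestRegressor
from sklearn.inspection import permutation_importance
from sklearn.metrics import roc_curve

from .metadata import PARAMETERS, PairEncoding

__all__ = [
    "RFConfig",
    "ScoreWeights",
    "published_weights",
    "published_cutoffs",
    "RFFit",
    "fit_rf",
    "derive_weights",
    "maaspenn_score",
    "score_outcome_correlation",
    "ThresholdRule",
    "roc_select_cutoff",
    "robustness_runs",
]

DEFAULT_THRESHOLDS: tuple[int, ...] = (10, 20, 30, 40, 50, 60, 70, 80, 90)


@dataclass(frozen=True)
class RFConfig:
    """Random-forest settings: 500 trees, 3 candidate variables per split."""

    n_trees: int = 500
    vars_per_split: int = 3
    seed: int = 0
    importance_method: str = "permutation"  # or "impurity"

    def __post_init__(self):
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if not (1 <= self.vars_per_split <= len(PARAMETERS)):
            raise ValueError(f"vars_per_split must be in [1, {len(PARAMETERS)}]")
        if self.importance_method not in ("permutation", "impurity"):
            raise ValueError(f"unknown importance method {self.importance_method!r}")


@dataclass(frozen=True)
class ScoreWeights:
    """Normalized importance weights of the retained parameters."""

    weights: Mapping[str, float]
    provenance: str  # "published" or "fitted"

    def __post_init__(self):
        unknown = set(self.weights) - set(PARAMETERS)
        if unknown:
            raise ValueError(f"unknown parameters in weights: {sorted(unknown)}")
        total = sum(self.weights.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"weights must sum to 1, got {total}")
        if any(w < 0 for w in self.weights.values()):
            raise ValueError("weights must be non-negative")

    @property
    def retained(self) -> tuple[str, ...]:
        return tuple(self.weights)


def published_weights() -> ScoreWeights:
    """The published score weights: kernel 0.48, slice 0.33, pixel spacing 0.19."""
    return ScoreWeights(
        {"kernel": 0.48, "slice_thickness": 0.33, "pixel_spacing": 0.19},
        provenance="published",
    )


def published_cutoffs() -> pd.DataFrame:
    """Packaged score-cutoff table per percent-reproducible threshold.

    Columns: pct_threshold, score_cutoff, auc, ci95_lower/upper,
    specificity, sensitivity, false_alarm.  The 70% row (cutoff 0.94) backs
    the default screening workflows.
    """
    with resources.files("maaspenn.data").joinpath("published_cutoffs.csv").open() as fh:
        return pd.read_csv(fh)


# ---------------------------------------------------------------------------
# random forest and weights


@dataclass
class RFFit:
    """Fitted forest plus its variance explained and importances."""

    model: RandomForestRegressor
    variance_explained_pct: float  # out-of-bag R^2, percent
    importances: pd.Series  # parameter -> importance
    config: RFConfig


def _encoding_matrix(encodings) -> pd.DataFrame:
    if isinstance(encodings, pd.DataFrame):
        df = encodings
        missing = [p for p in PARAMETERS if p not in df.columns]
        if missing:
            raise ValueError(f"encoding frame lacks parameter columns {missing}")
        return df[list(PARAMETERS)].astype(float)
    rows = []
    for enc in encodings:
        rows.append([enc.values[p] for p in PARAMETERS])
    return pd.DataFrame(rows, columns=list(PARAMETERS))


def fit_rf(
    encodings,
    outcomes: Sequence[float],
    cfg: RFConfig = RFConfig(),
) -> RFFit:
    """Train the regression forest of pct-reproducible on the 8 encodings.

    ``encodings`` is a DataFrame with the 8 parameter columns or a sequence
    of :class:`PairEncoding`.  Variance explained is the out-of-bag R^2 (as
    a percent), matching the convention of R's randomForest.  Importances
    are permutation importances (mean decrease in MSE) by default;
    ``importance_method='impurity'`` switches to Gini-style impurity
    importance.  Deterministic for a fixed config seed.
    """
    X = _encoding_matrix(encodings)
    y = np.asarray(outcomes, dtype=float)
    if len(X) != len(y):
        raise ValueError(f"{len(X)} encodings vs {len(y)} outcomes")
    if len(X) < 50:
        raise ValueError(f"need at least 50 pairs to fit the forest, got {len(X)}")
    if np.all(y == y[0]):
        raise ValueError("outcome is constant; nothing to model")
    if y.min() < 0 or y.max() > 100:
        raise ValueError("outcomes must be percentages in [0, 100]")

    model = RandomForestRegressor(
        n_estimators=cfg.n_trees,
        max_features=cfg.vars_per_split,
        oob_score=True,
        random_state=cfg.seed,
        n_jobs=1,
    )
    model.fit(X.to_numpy(), y)
    var_explained = 100.0 * model.oob_score_

    if cfg.importance_method == "permutation":
        perm = permutation_importance(
            model,
            X.to_numpy(),
            y,
            n_repeats=5,
            random_state=cfg.seed + 1,
            scoring="neg_mean_squared_error",
        )
        imp = pd.Series(perm.importances_mean, index=X.columns)
    else:
        imp = pd.Series(model.feature_importances_, index=X.columns)
    return RFFit(model, float(var_explained), imp, cfg)


def derive_weights(importances: Mapping[str, float], k: int = 3) -> ScoreWeights:
    """Retain the top-k parameters by importance; normalize to sum to 1.

    Negative (noise-level) permutation importances are clipped to zero
    before normalization.  Invariant under uniform scaling of the
    importances.
    """
    imp = pd.Series(dict(importances), dtype=float)
    if k > len(imp):
        raise ValueError(f"k={k} exceeds the {len(imp)} scored parameters")
    if (imp.dropna() < 0).all():
        raise ValueError("all importances negative; forest carries no signal")
    top = imp.sort_values(ascending=False, kind="stable").iloc[:k].clip(lower=0.0)
    total = top.sum()
    if total <= 0:
        raise ValueError("top-k importances sum to zero; cannot derive weights")
    return ScoreWeights((top / total).to_dict(), provenance="fitted")


def maaspenn_score(
    enc: PairEncoding | Mapping[str, float] | pd.DataFrame,
    weights: ScoreWeights | None = None,
):
    """Importance-weighted parameter-similarity score of a scan pair.

    ``sum_p w_p * enc[p]`` over the retained parameters; in [0, 1], equal
    to 1 iff every retained component is 1 (all weights positive), and
    monotone non-decreasing in each component.  Accepts one encoding (->
    float) or a DataFrame of encodings (-> Series).
    """
    w = weights or published_weights()
    if isinstance(enc, pd.DataFrame):
        missing = [p for p in w.retained if p not in enc.columns]
        if missing:
            raise ValueError(f"encodings lack retained parameter(s) {missing}")
        out = sum(w.weights[p] * enc[p].astype(float) for p in w.retained)
        out.name = "maaspenn_score"
        return out
    values = enc.values if isinstance(enc, PairEncoding) else enc
    missing = [p for p in w.retained if p not in values]
    if missing:
        raise ValueError(f"encoding lacks retained parameter(s) {missing}")
    return float(sum(w.weights[p] * values[p] for p in w.retained))


def score_outcome_correlation(scores, outcomes) -> float:
    """Spearman rank correlation between scores and percent reproducible."""
    scores = np.asarray(scores, dtype=float)
    outcomes = np.asarray(outcomes, dtype=float)
    if scores.shape != outcomes.shape or scores.ndim != 1:
        raise ValueError("scores and outcomes must be 1-D of equal length")
    if scores.size < 3:
        raise ValueError("need at least 3 pairs")
    if np.all(scores == scores[0]) or np.all(outcomes == outcomes[0]):
        return float("nan")
    rho, _ = stats.spearmanr(scores, outcomes)
    return float(rho)


# ---------------------------------------------------------------------------
# ROC threshold analysis


@dataclass(frozen=True)
class ThresholdRule:
    """Score cutoff and its operating characteristics at one threshold."""

    pct_threshold: float
    score_cutoff: float
    auc: float
    sensitivity: float
    specificity: float

    @property
    def false_alarm(self) -> float:
        return 1.0 - self.specificity


def _auc_rank(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC via the rank statistic (Mann-Whitney), ties shared."""
    ranks = stats.rankdata(scores)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    auc = (ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
    return float(auc)


def roc_select_cutoff(
    scores,
    labels,
    pct_threshold: float = float("nan"),
) -> ThresholdRule:
    """Pick the score cutoff maximizing Youden's J (sens + spec - 1).

    ``labels`` are 1 when the pair's percent reproducible exceeded the
    threshold.  AUC is the rank statistic; sensitivity and specificity are
    evaluated at the selected cutoff (predicted positive iff score >=
    cutoff).  Requires both classes present.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must align")
    if labels.min() == labels.max():
        raise ValueError("labels contain a single class; ROC undefined")
    auc = _auc_rank(scores, labels)
    fpr, tpr, thresholds = roc_curve(labels, scores)
    j = tpr - fpr
    best = int(np.argmax(j))
    return ThresholdRule(
        pct_threshold=float(pct_threshold),
        score_cutoff=float(thresholds[best]),
        auc=auc,
        sensitivity=float(tpr[best]),
        specificity=float(1.0 - fpr[best]),
    )


def threshold_table(
    scores, outcomes_pct, thresholds: Sequence[float] = DEFAULT_THRESHOLDS
) -> pd.DataFrame:
    """ROC cutoff selection at every percent threshold; one row each."""
    scores = np.asarray(scores, dtype=float)
    pct = np.asarray(outcomes_pct, dtype=float)
    rows = []
    for t in thresholds:
        labels = (pct > t).astype(int)
        if labels.min() == labels.max():
            rows.append((t, np.nan, np.nan, np.nan, np.nan, np.nan))
            continue
        rule = roc_select_cutoff(scores, labels, pct_threshold=t)
        rows.append(
            (t, rule.score_cutoff, rule.auc, rule.sensitivity,
             rule.specificity, rule.false_alarm)
        )
    return pd.DataFrame(
        rows,
        columns=["pct_threshold", "score_cutoff", "auc", "sensitivity",
                 "specificity", "false_alarm"],
    )


# ---------------------------------------------------------------------------
# robustness harness


def robustness_runs(
    encodings,
    outcomes_pct: Sequence[float],
    *,
    weights: ScoreWeights | None = None,
    cfg: RFConfig | None = None,
    refit_weights: bool = False,
    n_runs: int = 100,
    train_frac: float = 0.8,
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
    seed: int = 0,
) -> pd.DataFrame:
    """Repeat the threshold analysis over random 80/20 train/validation splits.

    Per run and threshold, the score cutoff is selected on the training
    split (Youden's J) and AUC/sensitivity/specificity are evaluated on
    both splits.  With ``refit_weights=True`` the forest and score weights
    are refit on each training split (``cfg`` required); by default the
    supplied (published) weights stay fixed and only the cutoff is
    re-selected.  Runs where a split lacks both classes at a threshold are
    recorded as NaN.  One master ``seed`` fans out to per-run seeds through
    ``np.random.SeedSequence(seed, spawn_key=(run,))``; the per-run seed is
    recorded in the output.
    """
    X = _encoding_matrix(encodings)
    pct = np.asarray(outcomes_pct, dtype=float)
    if len(X) != len(pct):
        raise ValueError("encodings and outcomes must align")
    n = len(X)
    n_train = int(round(train_frac * n))
    if not (0 < n_train < n):
        raise ValueError("train fraction leaves an empty split")
    w = weights or published_weights()

    rows = []
    for run in range(n_runs):
        run_seed = int(np.random.SeedSequence(seed, spawn_key=(run,)).generate_state(1)[0] % (2**31))
        rng = np.random.default_rng(run_seed)
        idx = rng.permutation(n)
        tr, va = idx[:n_train], idx[n_train:]
        if refit_weights:
            if cfg is None:
                raise ValueError("refit_weights=True requires an RFConfig")
            fit = fit_rf(X.iloc[tr], pct[tr], RFConfig(
                n_trees=cfg.n_trees, vars_per_split=cfg.vars_per_split,
                seed=run_seed, importance_method=cfg.importance_method))
            w_run = derive_weights(fit.importances.to_dict(), k=3)
        else:
            w_run = w
        s = maaspenn_score(X, w_run).to_numpy()
        for t in thresholds:
            lab = (pct > t).astype(int)
            for split, ids in (("training", tr), ("validation", va)):
                if lab[ids].min() == lab[ids].max() or lab[tr].min() == lab[tr].max():
                    rows.append((run, run_seed, t, split, np.nan, np.nan, np.nan, np.nan))
                    continue
                rule = roc_select_cutoff(s[tr], lab[tr], pct_threshold=t)
                pred = s[ids] >= rule.score_cutoff
                pos = lab[ids] == 1
                sens = float(pred[pos].mean())
                spec = float((~pred[~pos]).mean())
                auc = _auc_rank(s[ids], lab[ids])
                rows.append((run, run_seed, t, split, rule.score_cutoff, auc, sens, spec))
    return pd.DataFrame(
        rows,
        columns=["run", "run_seed", "pct_threshold", "split", "score_cutoff",
                 "auc", "sensitivity", "specificity"],
    )
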