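"""Feature selection and ranking.

Two stages mirror the discovery workflow: an L1-penalized linear support
vector classifier prunes the descriptor matrix to the features with
non-zero coefficients (sparsity controlled by ``C``; smaller ``C``,
fewer features), then a gradient-boosted tree ensemble ranks the
survivors by how often each is used to split the data across all trees,
reported as raw split counts with normalized and cumulative scores.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from lightgbm import LGBMClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.svm import LinearSVC


@dataclass(frozen=True)
class SelectionConfig:
    """Parameters of the SVC-L1 selection stage.

    ``svc_C`` is the inverse regularization strength (default 0.01, a
    deliberately sparse setting); features are standardized to zero mean
    and unit variance before the fit because L1 selection is
    scale-sensitive across descriptor families on different scales.
    """

    svc_C: float = 0.01
    standardize: bool = True
    seed: int = 0
    max_iter: int = 5000

    def __post_init__(self):
        if self.svc_C <= 0:
            raise ValueError("svc_C must be > 0")


@dataclass
class RankedFeature:
    name: str
    split_count: float
    normalized_score: float
    cumulative_score: float


@dataclass
class SelectionResult:
    """Selected feature names, their linear coefficients, and (once
    :func:`rank_features` has run) the GBM ranking."""

    selected: list[str]
    coefficients: dict[str, float]
    ranking: list[RankedFeature] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    @property
    def ranked_names(self) -> list[str]:
        return [r.name for r in self.ranking]

    def ranking_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(r.name, r.split_count, r.normalized_score, r.cumulative_score)
             for r in self.ranking],
            columns=["feature", "split_count", "normalized_score", "cumulative_score"],
        )


def _as_binary(y: Sequence) -> np.ndarray:
    arr = np.asarray(y)
    if arr.dtype.kind in "UO":
        arr = (arr == "positive").astype(int)
    arr = arr.astype(int)
    if set(np.unique(arr)) - {0, 1}:
        raise ValueError("labels must be binary (0/1 or positive/negative)")
    return arr


def select_svc_l1(
    X: pd.DataFrame, y: Sequence, cfg: SelectionConfig = SelectionConfig()
) -> SelectionResult:
    """Fit a linear SVC with L1 penalty and keep features with non-zero
    coefficients (strict non-zero, no epsilon threshold).

    Raises on single-class labels; an all-constant matrix yields an empty
    selection with a warning.
    """
    yb = _as_binary(y)
    if len(np.unique(yb)) < 2:
        raise ValueError("selection requires both classes present")
    if np.bincount(yb).min() < 2:
        raise ValueError("selection requires >= 2 samples per class")
    values = X.to_numpy()
    if cfg.standardize:
        scaler = StandardScaler()
        values = scaler.fit_transform(values)
    clf = LinearSVC(
        penalty="l1",
        loss="squared_hinge",
        dual=False,
        C=cfg.svc_C,
        max_iter=cfg.max_iter,
        random_state=cfg.seed,
    )
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*max_iter.*")
        clf.fit(values, yb)
    coefs = clf.coef_.ravel()
    mask = coefs != 0.0
    selected = [n for n, m in zip(X.columns, mask) if m]
    if not selected:
        warnings.warn("SVC-L1 selected no features (all coefficients zero)")
    return SelectionResult(
        selected=selected,
        coefficients={n: float(c) for n, c in zip(X.columns, coefs) if c != 0.0},
        provenance={
            "svc_C": cfg.svc_C,
            "standardize": cfg.standardize,
            "seed": cfg.seed,
            "n_input_features": X.shape[1],
            "n_selected": len(selected),
        },
    )


def rank_features(
    X: pd.DataFrame,
    y: Sequence,
    seed: int = 0,
    n_estimators: int = 100,
    num_leaves: int = 31,
) -> list[RankedFeature]:
    """Rank features by gradient-boosting split counts.

    Features are sorted by the number of times they are used to split the
    data across all trees (descending; ties broken lexicographically by
    name).  ``normalized_score`` is the split count over the total;
    ``cumulative_score`` accumulates over the sorted order and ends at 1.
    A degenerate fit with no splits at all yields uniform scores and a
    warning.
    """
    if X.shape[1] < 1:
        raise ValueError("ranking requires at least one feature")
    yb = _as_binary(y)
    gbm = LGBMClassifier(
        n_estimators=n_estimators,
        num_leaves=num_leaves,
        random_state=seed,
        n_jobs=1,
        verbose=-1,
    )
    gbm.fit(X.to_numpy(), yb)
    counts = gbm.booster_.feature_importance(importance_type="split").astype(float)
    if counts.sum() == 0:
        warnings.warn("no splits made; returning uniform feature scores")
        counts = np.ones_like(counts)
    order = sorted(zip(X.columns, counts), key=lambda t: (-t[1], t[0]))
    total = sum(c for _, c in order)
    ranking, cum = [], 0.0
    for name, count in order:
        norm = count / total
        cum += norm
        ranking.append(RankedFeature(name, count, norm, cum))
    return ranking


def take_top_k(ranking: Sequence[RankedFeature], k: int) -> list[str]:
    """First ``k`` feature names in ranked order (prefix of the ranking)."""
    if not (1 <= k <= len(ranking)):
        raise ValueError(f"k={k} out of range 1..{len(ranking)}")
    return [r.name for r in ranking[:k]]


def select_and_rank(
    X: pd.DataFrame, y: Sequence, cfg: SelectionConfig = SelectionConfig()
) -> SelectionResult:
    """Full selection stage: SVC-L1 pruning followed by GBM ranking."""
    result = select_svc_l1(X, y, cfg)
    if result.selected:
        result.ranking = rank_features(X[result.selected], y, seed=cfg.seed)
    result.provenance["gbm"] = {"n_estimators": 100, "num_leaves": 31, "seed": cfg.seed}
    return result
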