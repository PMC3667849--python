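"""Super-learner prediction of the poly-3 target from pathway z features.

The model fits continuous carcinogenicity targets (capped poly-3 z per
chemical) on a chemicals x pathways matrix of enrichment z features.  A
small learner library (random forest, support-vector regression, ridge) is
compared by 5-fold cross-validated risk (MSE); the discrete super learner
picks the argmin, the continuous variant forms a non-negative MSE-optimal
weighting of the learners.  "Honest" predictions come from two nested
levels of 5-fold cross-validation: learner selection for each outer test
fold uses only that fold's training complement.

Exposed statsmodels-style: ``PathwayCarcinogenicityModel(X, y).fit()``
returns a ``PathwayCarcinogenicityResults`` with risks, honest predictions,
permutation importances and a ``summary()`` table.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import nnls
from sklearn.ensemble import RandomForestRegressor
from sklearn.linear_model import Ridge
from sklearn.svm import SVR

__all__ = [
    "Learner",
    "FoldAssignment",
    "default_library",
    "make_folds",
    "cross_validated_predictions",
    "cv_risk",
    "discrete_super_learner",
    "continuous_super_learner",
    "honest_predictions",
    "fit_final",
    "predict_panel",
    "PathwayCarcinogenicityModel",
    "PathwayCarcinogenicityResults",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Learner:
    """A named regression learner: ``factory(seed)`` builds a fresh estimator."""

    name: str
    factory: Callable[[int], object]


def default_library(n_trees: int = 500) -> list:
    """Random forest (the final-model learner), SVR and ridge.

    Forest defaults: ``n_trees`` trees, sqrt(N_p) features per split.
    """
    return [
        Learner(
            "random_forest",
            lambda seed, n=n_trees: RandomForestRegressor(
                n_estimators=n, max_features="sqrt", random_state=seed
            ),
        ),
        Learner("svr", lambda seed: SVR()),
        Learner("ridge", lambda seed: Ridge(alpha=1.0)),
    ]


@dataclass
class FoldAssignment:
    """Mapping chemical id -> fold index in 1..n_folds."""

    folds: Mapping[str, int]
    n_folds: int = 5

    def __post_init__(self):
        sizes = self.sizes()
        if len(sizes) != self.n_folds or min(sizes.values()) == 0:
            raise ValueError(f"expected {self.n_folds} non-empty folds, got sizes {sizes}")
        if max(sizes.values()) - min(sizes.values()) > 1:
            raise ValueError(f"fold sizes differ by more than 1: {sizes}")

    def sizes(self) -> dict:
        out = {f: 0 for f in range(1, self.n_folds + 1)}
        for f in self.folds.values():
            out[f] = out.get(f, 0) + 1
        return out

    def members(self, fold: int) -> list:
        return [c for c, f in self.folds.items() if f == fold]

    def complement(self, fold: int) -> list:
        return [c for c, f in self.folds.items() if f != fold]


def make_folds(targets: Mapping[str, float], n_folds: int = 5, seed: int = 0) -> FoldAssignment:
    """Target-balanced fold assignment.

    Chemicals are sorted by target value, cut into strata of ``n_folds``
    consecutive chemicals, and each stratum deals its members to distinct
    folds (serpentine base order, then a seeded shuffle within the stratum).
    Every fold then spans the target range and sizes differ by at most 1.
    """
    items = sorted(targets.items(), key=lambda kv: (-kv[1], kv[0]))
    if len(items) < n_folds:
        raise ValueError(f"need >= {n_folds} chemicals, got {len(items)}")
    rng = np.random.default_rng(seed)
    assignment = {}
    base = list(range(1, n_folds + 1))
    for k, s in enumerate(range(0, len(items), n_folds)):
        stratum = items[s : s + n_folds]
        if k % 2 == 0:
            base = [int(f) for f in rng.permutation(n_folds) + 1]
        else:
            # serpentine: pair each stratum with the reverse of the previous
            # deal so adjacent high/low targets land in the same fold
            base = base[::-1]
        for (chem, _), fold in zip(stratum, base):
            assignment[chem] = fold
    return FoldAssignment(assignment, n_folds)


def _derive_seed(seed: int, *tokens) -> int:
    ss = np.random.SeedSequence([seed] + [abs(hash(str(t))) % (2**31) for t in tokens])
    return int(ss.generate_state(1)[0] % (2**31))


def cross_validated_predictions(
    library: Sequence[Learner],
    X: pd.DataFrame,
    y: pd.Series,
    folds: FoldAssignment,
    seed: int = 0,
) -> tuple:
    """Out-of-fold predictions per learner.

    Returns (DataFrame rows=chemicals, cols=learner names; list of failed
    learner names).  A learner that raises on any fold is excluded whole.
    """
    if not len(library):
        raise ValueError("empty learner library")
    preds = pd.DataFrame(index=X.index, columns=[l.name for l in library], dtype=float)
    failed = []
    for learner in library:
        try:
            for fold in range(1, folds.n_folds + 1):
                train = folds.complement(fold)
                test = folds.members(fold)
                est = learner.factory(_derive_seed(seed, learner.name, fold))
                est.fit(X.loc[train].to_numpy(), y.loc[train].to_numpy())
                preds.loc[test, learner.name] = est.predict(X.loc[test].to_numpy())
        except Exception as exc:  # noqa: BLE001 - learner failures are recoverable
            logger.warning("learner %s failed and is excluded: %s", learner.name, exc)
            failed.append(learner.name)
    return preds.drop(columns=failed), failed


def cv_risk(
    library: Sequence[Learner],
    X: pd.DataFrame,
    y: pd.Series,
    folds: FoldAssignment,
    seed: int = 0,
) -> pd.Series:
    """Cross-validated risk (out-of-fold MSE) per non-failed learner."""
    preds, _failed = cross_validated_predictions(library, X, y, folds, seed)
    if preds.shape[1] == 0:
        raise RuntimeError("all learners failed")
    return ((preds.sub(y, axis=0)) ** 2).mean(axis=0)


def discrete_super_learner(risks: pd.Series, library_order: Sequence[str] | None = None) -> str:
    """Name of the minimum-risk learner; ties break by library order."""
    if len(risks) == 0:
        raise ValueError("no learner risks available")
    order = list(library_order) if library_order is not None else list(risks.index)
    best = min((r for r in order if r in risks.index), key=lambda name: risks[name])
    return best


def continuous_super_learner(oof_predictions: pd.DataFrame, y: pd.Series) -> pd.Series:
    """Non-negative learner weights (summing to 1) minimizing combined MSE.

    Solved by non-negative least squares on the out-of-fold prediction
    matrix; if every learner's predictions are constant the weights are
    uniform (with a warning).
    """
    A = oof_predictions.to_numpy(dtype=float)
    b = y.loc[oof_predictions.index].to_numpy(dtype=float)
    if np.all(A.std(axis=0) == 0):
        warnings.warn("all learner predictions constant; using uniform weights")
        w = np.ones(A.shape[1])
    else:
        w, _ = nnls(A, b)
        if w.sum() == 0:
            warnings.warn("degenerate NNLS solution; using uniform weights")
            w = np.ones(A.shape[1])
    return pd.Series(w / w.sum(), index=oof_predictions.columns)


def _fit_on(library, names, X, y, seed, fold_token):
    fitted = {}
    for learner in library:
        if learner.name in names:
            est = learner.factory(_derive_seed(seed, "refit", learner.name, fold_token))
            est.fit(X.to_numpy(), y.to_numpy())
            fitted[learner.name] = est
    return fitted


def honest_predictions(
    library: Sequence[Learner],
    X: pd.DataFrame,
    y: pd.Series,
    folds: FoldAssignment,
    seed: int = 0,
    selector: str = "discrete",
) -> pd.Series:
    """Nested-CV predictions in which selection never sees the test fold.

    For each outer fold: an inner 5-fold CV on the training complement
    selects the learner (``selector='discrete'``) or the learner weights
    (``'continuous'``); the selection is refit on the whole complement and
    predicts the held-out fold.  A chemical's own target value therefore
    never influences its prediction.
    """
    if selector not in ("discrete", "continuous"):
        raise ValueError(f"unknown selector {selector!r}")
    out = pd.Series(index=X.index, dtype=float)
    for fold in range(1, folds.n_folds + 1):
        train = folds.complement(fold)
        test = folds.members(fold)
        X_tr, y_tr = X.loc[train], y.loc[train]
        inner_seed = _derive_seed(seed, "inner", fold)
        inner_folds = make_folds(dict(y_tr), folds.n_folds, inner_seed)
        oof, failed = cross_validated_predictions(library, X_tr, y_tr, inner_folds, inner_seed)
        if oof.shape[1] == 0:
            raise RuntimeError(f"all learners failed on outer fold {fold}")
        if selector == "discrete":
            risks = ((oof.sub(y_tr, axis=0)) ** 2).mean(axis=0)
            name = discrete_super_learner(risks, [l.name for l in library])
            fitted = _fit_on(library, {name}, X_tr, y_tr, seed, fold)
            out.loc[test] = fitted[name].predict(X.loc[test].to_numpy())
        else:
            weights = continuous_super_learner(oof, y_tr)
            active = weights[weights > 0]
            fitted = _fit_on(library, set(active.index), X_tr, y_tr, seed, fold)
            combo = np.zeros(len(test))
            for name, w in active.items():
                combo += w * fitted[name].predict(X.loc[test].to_numpy())
            out.loc[test] = combo
    return out


def permutation_importances(
    model,
    X: np.ndarray,
    y: np.ndarray,
    n_repeats: int = 10,
    seed: int = 0,
) -> np.ndarray:
    """Mean increase in MSE when each feature column is permuted.

    All permuted copies are scored in a single predict call, which keeps a
    200-feature x 10-repeat sweep fast on small chemical panels.
    """
    rng = np.random.default_rng(seed)
    n, p = X.shape
    base_mse = float(np.mean((y - model.predict(X)) ** 2))
    stacked = np.tile(X, (p * n_repeats, 1)).reshape(p, n_repeats, n, p)
    for j in range(p):
        for r in range(n_repeats):
            stacked[j, r, :, j] = X[rng.permutation(n), j]
    preds = model.predict(stacked.reshape(p * n_repeats * n, p)).reshape(p, n_repeats, n)
    mses = ((preds - y) ** 2).mean(axis=2)  # (p, n_repeats)
    return mses.mean(axis=1) - base_mse


def fit_final(
    X: pd.DataFrame,
    y: pd.Series,
    seed: int = 0,
    n_trees: int = 500,
    n_repeats: int = 10,
) -> tuple:
    """Fit the final random forest on all rows and rank pathway importances.

    Importance is permutation importance: the mean increase in squared
    error when one feature column is permuted, repeated ``n_repeats`` times.
    Returned as (fitted forest, Series sorted descending by importance).
    """
    forest = RandomForestRegressor(
        n_estimators=n_trees, max_features="sqrt", random_state=_derive_seed(seed, "final")
    )
    forest.fit(X.to_numpy(), y.to_numpy())
    imp = permutation_importances(
        forest,
        X.to_numpy(),
        y.to_numpy(),
        n_repeats=n_repeats,
        seed=_derive_seed(seed, "importance"),
    )
    importance = pd.Series(imp, index=X.columns).sort_values(ascending=False)
    return forest, importance


def predict_panel(model, X_new: pd.DataFrame, train_columns: Sequence[str]) -> pd.Series:
    """Predict new rows after verifying exact panel-column agreement."""
    train_cols = list(train_columns)
    new_cols = list(X_new.columns)
    if new_cols != train_cols:
        missing = [c for c in train_cols if c not in new_cols]
        extra = [c for c in new_cols if c not in train_cols]
        raise ValueError(
            f"feature panel mismatch: missing={missing[:10]}, extra={extra[:10]}"
            + ("" if missing or extra else " (column order differs)")
        )
    return pd.Series(model.predict(X_new.to_numpy()), index=X_new.index)


class PathwayCarcinogenicityModel:
    """Continuous carcinogenicity model on pathway enrichment features.

    Parameters
    ----------
    X : DataFrame
        Chemicals x pathways matrix of enrichment z features (panel order).
    y : Series
        Capped poly-3 z target per chemical, aligned with ``X.index``.
    library : list of Learner, optional
        Candidate learners; defaults to random forest + SVR + ridge.
    n_folds, seed : CV structure and the master random seed.
    """

    def __init__(
        self,
        X: pd.DataFrame,
        y: pd.Series,
        library: Sequence[Learner] | None = None,
        n_folds: int = 5,
        seed: int = 0,
    ):
        if not X.index.equals(y.index):
            y = y.reindex(X.index)
        if y.isna().any():
            raise ValueError("targets missing for some chemicals")
        if not np.isfinite(X.to_numpy(dtype=float)).all():
            raise ValueError("feature matrix must be finite")
        self.X = X
        self.y = y.astype(float)
        self.library = list(library) if library is not None else default_library()
        self.n_folds = n_folds
        self.seed = seed

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, target_col: str = "z_capped", **kwargs):
        """Build from a single table whose non-target columns are features."""
        y = df[target_col]
        X = df.drop(columns=[target_col])
        return cls(X, y, **kwargs)

    def fit(self, selector: str = "discrete") -> "PathwayCarcinogenicityResults":
        folds = make_folds(dict(self.y), self.n_folds, self.seed)
        oof, failed = cross_validated_predictions(
            self.library, self.X, self.y, folds, self.seed
        )
        if oof.shape[1] == 0:
            raise RuntimeError("all learners failed")
        risks = ((oof.sub(self.y, axis=0)) ** 2).mean(axis=0)
        selected = discrete_super_learner(risks, [l.name for l in self.library])
        weights = continuous_super_learner(oof, self.y)
        honest = honest_predictions(
            self.library, self.X, self.y, folds, self.seed, selector
        )
        forest, importance = fit_final(self.X, self.y, self.seed)
        return PathwayCarcinogenicityResults(
            model=self,
            folds=folds,
            cv_risks=risks,
            selected_learner=selected,
            learner_weights=weights,
            honest=honest,
            final_estimator=forest,
            importance=importance,
            failed_learners=failed,
            selector=selector,
        )


@dataclass
class PathwayCarcinogenicityResults:
    """Fit artifacts: risks, selection, honest predictions, importances."""

    model: PathwayCarcinogenicityModel
    folds: FoldAssignment
    cv_risks: pd.Series
    selected_learner: str
    learner_weights: pd.Series
    honest: pd.Series
    final_estimator: object
    importance: pd.Series
    failed_learners: list = field(default_factory=list)
    selector: str = "discrete"

    @property
    def honest_predictions(self) -> pd.Series:
        return self.honest

    def predict(self, X_new: pd.DataFrame) -> pd.Series:
        """Continuous predictions for a new panel-aligned feature matrix."""
        return predict_panel(self.final_estimator, X_new, self.model.X.columns)

    def top_pathways(self, n: int = 15) -> pd.Series:
        return self.importance.head(n)

    def summary(self) -> str:
        lines = [
            "Pathway carcinogenicity model",
            "=" * 48,
            f"chemicals: {len(self.model.y)}   pathways: {self.model.X.shape[1]}",
            f"folds: {self.folds.n_folds}   selector: {self.selector}",
            "",
            "Cross-validated risk (MSE):",
        ]
        for name, risk in self.cv_risks.items():
            marker = " <- selected" if name == self.selected_learner else ""
            lines.append(f"  {name:<16} {risk:8.4f}{marker}")
        if self.failed_learners:
            lines.append(f"failed learners: {', '.join(self.failed_learners)}")
        lines += ["", "Continuous super-learner weights:"]
        for name, w in self.learner_weights.items():
            lines.append(f"  {name:<16} {w:8.4f}")
        lines += ["", "Top pathways by permutation importance:"]
        for pid, imp in self.top_pathways(10).items():
            lines.append(f"  {pid:<24} {imp:8.4f}")
        return "\n".join(lines)
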