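"""Diagnostic models: MDS composites, feature selection, random forests.

The modelling layer follows scikit-learn conventions: estimators expose
``fit`` / ``transform`` or ``fit`` / ``predict_proba``, validate their
inputs, and store fitted state in trailing-underscore attributes.  The
module-level functions (``mds_embed``, ``train_rf_cv``, ...) are thin
wrappers kept for pipeline scripting.

Three model modes are supported:

* ``meth``      — malignant ratios of the selected DMR panel;
* ``meth_cnv``  — DMR panel + 2 MDS composite coordinates of the CNV
  event matrix;
* ``full``      — DMR panel + 2 CNV-MDS + 2 FSR-MDS coordinates.

Class-probability scores are raw forest vote fractions (no
recalibration), so a 0.5 cutoff keeps its natural semantics.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.spatial.distance import cdist, pdist, squareform
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

MODES = ("meth", "meth_cnv", "full")


# ---------------------------------------------------------------------------
# Multidimensional scaling
# ---------------------------------------------------------------------------

class MDSEmbedder(BaseEstimator, TransformerMixin):
    """Metric MDS to 2-D by stress majorisation (SMACOF).

    Deterministic: initialised from classical (Torgerson) scaling with a
    fixed sign convention, then Guttman-transform iterations until the
    raw stress decreases by less than ``tol``.

    Attributes
    ----------
    embedding_ : (n, 2) training coordinates
    stress_ : raw stress, sum over pairs of squared distance residuals
    normalized_stress_ : sqrt(raw / sum of squared dissimilarities)
    """

    def __init__(self, n_components: int = 2, max_iter: int = 300,
                 tol: float = 1e-12, random_state: int = 0):
        self.n_components = n_components
        self.max_iter = max_iter
        self.tol = tol
        self.random_state = random_state

    @staticmethod
    def _classical_init(d: np.ndarray, k: int) -> np.ndarray:
        n = d.shape[0]
        j = np.eye(n) - np.ones((n, n)) / n
        b = -0.5 * j @ (d ** 2) @ j
        vals, vecs = np.linalg.eigh(b)
        idx = np.argsort(vals)[::-1][:k]
        vals = np.clip(vals[idx], 0.0, None)
        coords = vecs[:, idx] * np.sqrt(vals)
        for c in range(coords.shape[1]):  # fix eigenvector sign
            col = coords[:, c]
            if len(col) and col[np.argmax(np.abs(col))] < 0:
                coords[:, c] = -col
        return coords

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or len(X) < 1:
            raise ValueError("X must be a 2-D sample matrix")
        if np.isnan(X).any():
            raise ValueError("impute missing values before embedding")
        self.X_fit_ = X
        self.n_features_in_ = X.shape[1]
        d = squareform(pdist(X))
        n = len(X)
        if n < 2 or np.allclose(d, 0.0):
            # zero-variance (or single-point) input: all-equal coordinates
            self.embedding_ = np.zeros((n, self.n_components))
            self.stress_ = 0.0
            self.normalized_stress_ = 0.0
            return self
        z = self._classical_init(d, self.n_components)
        prev = np.inf
        for _ in range(self.max_iter):
            dz = squareform(pdist(z))
            with np.errstate(divide="ignore", invalid="ignore"):
                ratio = np.where(dz > 0, d / dz, 0.0)
            b = -ratio
            np.fill_diagonal(b, 0.0)
            np.fill_diagonal(b, -b.sum(axis=1))
            z = b @ z / n
            dz = squareform(pdist(z))
            stress = float(np.sum((squareform(d) - squareform(dz)) ** 2))
            if prev - stress < self.tol:
                prev = stress
                break
            prev = stress
        self.embedding_ = z
        self.stress_ = prev if np.isfinite(prev) else 0.0
        denom = float(np.sum(squareform(d) ** 2))
        self.normalized_stress_ = float(np.sqrt(self.stress_ / denom)) if denom else 0.0
        return self

    def fit_transform(self, X, y=None):
        return self.fit(X).embedding_

    def transform(self, X):
        """Out-of-sample placement: each new point minimises its stress
        against the fixed training coordinates."""
        X = np.asarray(X, dtype=float)
        if not hasattr(self, "embedding_"):
            raise RuntimeError("fit the embedder first")
        d_new = cdist(X, self.X_fit_)
        out = np.empty((len(X), self.n_components))
        emb = self.embedding_
        for i in range(len(X)):
            target = d_new[i]

            def objective(zi):
                dd = np.sqrt(((emb - zi) ** 2).sum(axis=1))
                return float(((dd - target) ** 2).sum())

            z0 = emb[np.argmin(target)]
            res = minimize(objective, z0, method="Nelder-Mead",
                           options={"xatol": 1e-8, "fatol": 1e-12, "maxiter": 2000})
            out[i] = res.x
        return out


def mds_embed(X, seed: int = 0) -> MDSEmbedder:
    """Fit a 2-D stress-majorisation embedding; returns the fitted embedder."""
    return MDSEmbedder(random_state=seed).fit(X)


# ---------------------------------------------------------------------------
# Random forest with out-of-fold scoring
# ---------------------------------------------------------------------------

class RandomForestCV(BaseEstimator, ClassifierMixin):
    """Random forest with stratified k-fold out-of-fold probabilities.

    ``fit`` derives per-sample out-of-fold scores (``oof_scores_``) by
    refitting the forest on each k-1 fold split, then refits the final
    forest on all data.  Defaults mirror common practice for this kind of
    panel: 500 trees, 2 candidate features per split, 10 folds.
    """

    def __init__(self, n_trees: int = 500, mtry: int = 2, k_folds: int = 10,
                 seed: int = 0, cutoff: float = 0.5):
        self.n_trees = n_trees
        self.mtry = mtry
        self.k_folds = k_folds
        self.seed = seed
        self.cutoff = cutoff

    def _forest(self) -> RandomForestClassifier:
        return RandomForestClassifier(n_estimators=self.n_trees,
                                      max_features=self.mtry,
                                      random_state=self.seed, n_jobs=1)

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y).astype(int)
        if np.isnan(X).any():
            raise ValueError("impute missing values before fitting")
        classes, counts = np.unique(y, return_counts=True)
        if len(classes) != 2:
            raise ValueError("binary labels required")
        if counts.min() < self.k_folds:
            raise ValueError(
                f"minority class ({counts.min()}) smaller than k_folds "
                f"({self.k_folds}); stratified folds would lose a class")
        skf = StratifiedKFold(n_splits=self.k_folds, shuffle=True,
                              random_state=self.seed)
        oof = np.full(len(y), np.nan)
        folds = np.full(len(y), -1, dtype=int)
        for f, (tr, te) in enumerate(skf.split(X, y)):
            clf = self._forest().fit(X[tr], y[tr])
            oof[te] = clf.predict_proba(X[te])[:, 1]
            folds[te] = f
        self.oof_scores_ = oof
        self.folds_ = folds
        self.oof_auc_ = float(roc_auc_score(y, oof))
        self.forest_ = self._forest().fit(X, y)
        self.classes_ = self.forest_.classes_
        self.n_features_in_ = X.shape[1]
        return self

    def predict_proba(self, X):
        return self.forest_.predict_proba(np.asarray(X, dtype=float))

    def decision_scores(self, X):
        return self.predict_proba(X)[:, 1]

    def predict(self, X):
        return (self.decision_scores(X) >= self.cutoff).astype(int)


# ---------------------------------------------------------------------------
# Recursive feature elimination
# ---------------------------------------------------------------------------

def rfe_select(matrix: pd.DataFrame, labels, subset_sizes, cv_folds: int = 5,
               seed: int = 0, n_trees: int = 500, n_select: int | None = None,
               ) -> tuple[list[str], pd.DataFrame]:
    """Backward elimination ranked by forest importance.

    Starting from all columns, repeatedly drops the least-important
    features down to each declared subset size (descending), scoring each
    size by stratified cross-validated out-of-fold ROC-AUC.  Returns the
    selected feature list (at ``n_select`` if given, else at the smallest
    size within one standard error of the best) and the accuracy curve.
    """
    y = np.asarray(labels).astype(int)
    sizes = sorted(set(int(s) for s in subset_sizes), reverse=True)
    if sizes[0] > matrix.shape[1]:
        raise ValueError("subset size exceeds number of candidate features")
    current = list(matrix.columns)
    curve_rows = []
    kept: dict[int, list[str]] = {}
    skf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    for size in sizes:
        while len(current) > size:
            clf = RandomForestClassifier(n_estimators=n_trees, max_features="sqrt",
                                         random_state=seed, n_jobs=1)
            clf.fit(matrix[current].to_numpy(), y)
            order = np.argsort(clf.feature_importances_)
            drop = max(1, (len(current) - size) // 2)
            current = [current[i] for i in sorted(order[drop:])]
        kept[size] = list(current)
        X = matrix[current].to_numpy()
        oof = np.full(len(y), np.nan)
        for tr, te in skf.split(X, y):
            clf = RandomForestClassifier(n_estimators=n_trees, max_features="sqrt",
                                         random_state=seed, n_jobs=1)
            oof[te] = clf.fit(X[tr], y[tr]).predict_proba(X[te])[:, 1]
        auc = float(roc_auc_score(y, oof))
        se = float(np.sqrt(auc * (1 - auc) / len(y)))  # coarse binomial SE
        curve_rows.append((size, auc, se))
    curve = pd.DataFrame(curve_rows, columns=["size", "auc", "se"])
    if n_select is not None:
        if n_select not in kept:
            raise ValueError("n_select must be one of the evaluated subset sizes")
        chosen = n_select
    else:
        best = curve.loc[curve["auc"].idxmax()]
        ok = curve[curve["auc"] >= best["auc"] - best["se"]]
        chosen = int(ok["size"].min())
    return kept[chosen], curve


# ---------------------------------------------------------------------------
# Feature assembly
# ---------------------------------------------------------------------------

class ModelInputBuilder(BaseEstimator, TransformerMixin):
    """Assemble the per-mode feature matrix from modality tables.

    * DMR malignant ratios: missing cells imputed with the training
      control-cohort median (fitted on training data only).
    * CNV events / FSR bins: reduced to 2 MDS coordinates fitted on the
      training cohort; new cohorts are projected out-of-sample.

    Column provenance is encoded in the column-name prefixes ``dmr:``,
    ``cnvmds:`` and ``fsrmds:``.
    """

    def __init__(self, mode: str = "full", seed: int = 0):
        if mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")
        self.mode = mode
        self.seed = seed

    def fit(self, dmr_matrix: pd.DataFrame, labels,
            cnv_events: pd.DataFrame | None = None,
            fsr_matrix: pd.DataFrame | None = None):
        labels = np.asarray(labels).astype(bool)
        if len(labels) != len(dmr_matrix):
            raise ValueError("labels length must match the sample count")
        ctrl = dmr_matrix.loc[~labels]
        med = ctrl.median(axis=0, skipna=True).fillna(0.0)
        self.dmr_columns_ = list(dmr_matrix.columns)
        self.control_medians_ = med
        if self.mode in ("meth_cnv", "full"):
            if cnv_events is None or cnv_events.shape[1] == 0:
                raise ValueError(
                    "mode %r needs a non-empty CNV event matrix; pass the "
                    "samples x regions indicator table (or use mode='meth')"
                    % self.mode)
            self.cnv_columns_ = list(cnv_events.columns)
            self.cnv_mds_ = MDSEmbedder(random_state=self.seed).fit(
                cnv_events.to_numpy(dtype=float))
        if self.mode == "full":
            if fsr_matrix is None or fsr_matrix.shape[1] == 0:
                raise ValueError("mode 'full' needs a non-empty FSR matrix")
            self.fsr_columns_ = list(fsr_matrix.columns)
            filled = fsr_matrix.fillna(fsr_matrix.loc[~labels].median(axis=0))
            self.fsr_medians_ = fsr_matrix.loc[~labels].median(axis=0).fillna(0.0)
            self.fsr_mds_ = MDSEmbedder(random_state=self.seed).fit(
                filled.to_numpy(dtype=float))
            self._fsr_train_index = list(fsr_matrix.index)
        self._train_index = list(dmr_matrix.index)
        return self

    def transform(self, dmr_matrix: pd.DataFrame,
                  cnv_events: pd.DataFrame | None = None,
                  fsr_matrix: pd.DataFrame | None = None) -> pd.DataFrame:
        X = dmr_matrix[self.dmr_columns_].fillna(self.control_medians_)
        out = X.copy()
        out.columns = [f"dmr:{c}" for c in self.dmr_columns_]
        is_train = list(dmr_matrix.index) == self._train_index
        if self.mode in ("meth_cnv", "full"):
            if cnv_events is None:
                raise ValueError("CNV event matrix required in mode %r" % self.mode)
            if len(cnv_events) != len(dmr_matrix):
                raise ValueError("sample sets of the modality tables must align")
            arr = cnv_events[self.cnv_columns_].to_numpy(dtype=float)
            coords = (self.cnv_mds_.embedding_ if is_train
                      else self.cnv_mds_.transform(arr))
            out[["cnvmds:1", "cnvmds:2"]] = coords
        if self.mode == "full":
            if fsr_matrix is None:
                raise ValueError("FSR matrix required in mode 'full'")
            if len(fsr_matrix) != len(dmr_matrix):
                raise ValueError("sample sets of the modality tables must align")
            arr = fsr_matrix[self.fsr_columns_].fillna(
                self.fsr_medians_).to_numpy(dtype=float)
            coords = (self.fsr_mds_.embedding_ if is_train
                      else self.fsr_mds_.transform(arr))
            out[["fsrmds:1", "fsrmds:2"]] = coords
        return out


def build_model_inputs(dmr_matrix: pd.DataFrame, labels,
                       cnv_events: pd.DataFrame | None = None,
                       fsr_matrix: pd.DataFrame | None = None,
                       mode: str = "full", seed: int = 0,
                       ) -> tuple[pd.DataFrame, ModelInputBuilder]:
    """Fit a :class:`ModelInputBuilder` on a training cohort and return its
    feature matrix together with the fitted builder."""
    builder = ModelInputBuilder(mode=mode, seed=seed)
    builder.fit(dmr_matrix, labels, cnv_events=cnv_events, fsr_matrix=fsr_matrix)
    X = builder.transform(dmr_matrix, cnv_events=cnv_events, fsr_matrix=fsr_matrix)
    return X, builder


# ---------------------------------------------------------------------------
# Thresholding & evaluation
# ---------------------------------------------------------------------------

def classify_at_cutoff(scores, cutoff: float = 0.5) -> np.ndarray:
    """Positive (1) iff score >= cutoff."""
    return (np.asarray(scores, dtype=float) >= cutoff).astype(int)


def threshold_at_specificity(scores, labels, target_specificity: float = 0.95,
                             ) -> float:
    """Smallest cutoff achieving the target specificity on training controls.

    Specificity at cutoff c is the fraction of control scores < c (a
    sample is positive iff its score >= c).  Among achieving cutoffs the
    smallest is returned, which also maximises sensitivity.  If no finite
    cutoff achieves the target (all scores tied), returns a cutoff just
    above the maximum control score and warns.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    ctrl = scores[~labels]
    if len(ctrl) == 0:
        raise ValueError("controls required to set a specificity threshold")
    eps = max(1e-9, np.abs(ctrl).max() * 1e-9)
    candidates = np.sort(np.unique(np.append(scores, ctrl.max() + eps)))
    for c in candidates:
        if np.mean(ctrl < c) >= target_specificity:
            if c > scores.max():
                warnings.warn("specificity target only met above every score "
                              "(zero training sensitivity); returning a cutoff "
                              "just above the maximum control score")
            return float(c)
    warnings.warn("target specificity unattainable; returning a cutoff above "
                  "the maximum control score")
    return float(ctrl.max() + eps)


def _auc_pair_count(scores: np.ndarray, labels: np.ndarray) -> float:
    # probability a random case outscores a random control; ties count 1/2
    case = scores[labels]
    ctrl = scores[~labels]
    gt = (case[:, None] > ctrl[None, :]).sum()
    eq = (case[:, None] == ctrl[None, :]).sum()
    return float((gt + 0.5 * eq) / (len(case) * len(ctrl)))


def evaluate(scores, labels, cutoff: float = 0.5, n_boot: int = 2000,
             seed: int = 0) -> dict:
    """AUC with stratified-bootstrap 95% CI plus confusion metrics at ``cutoff``.

    Returns a dict with ``auc, auc_ci, sensitivity, specificity, ppv, npv,
    accuracy, cutoff``.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    if labels.all() or not labels.any():
        raise ValueError("both classes must be present")
    auc = _auc_pair_count(scores, labels)

    rng = np.random.default_rng(seed)
    case_idx = np.flatnonzero(labels)
    ctrl_idx = np.flatnonzero(~labels)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        ci = rng.choice(case_idx, size=len(case_idx), replace=True)
        ni = rng.choice(ctrl_idx, size=len(ctrl_idx), replace=True)
        idx = np.concatenate([ci, ni])
        boots[b] = _auc_pair_count(scores[idx], labels[idx])
    lo, hi = np.quantile(boots, [0.025, 0.975])

    pred = classify_at_cutoff(scores, cutoff).astype(bool)
    tp = int((pred & labels).sum())
    tn = int((~pred & ~labels).sum())
    fp = int((pred & ~labels).sum())
    fn = int((~pred & labels).sum())
    return {
        "auc": auc, "auc_ci": (float(lo), float(hi)),
        "sensitivity": tp / (tp + fn) if tp + fn else float("nan"),
        "specificity": tn / (tn + fp) if tn + fp else float("nan"),
        "ppv": tp / (tp + fp) if tp + fp else float("nan"),
        "npv": tn / (tn + fn) if tn + fn else float("nan"),
        "accuracy": (tp + tn) / len(labels),
        "cutoff": float(cutoff),
    }


# ---------------------------------------------------------------------------
# Bundles
# ---------------------------------------------------------------------------

@dataclass
class ModelBundle:
    """A trained diagnostic model with its full provenance."""

    model: RandomForestCV
    feature_names: list[str]
    folds: np.ndarray
    oof_scores: np.ndarray
    threshold: float
    seed: int
    mode: str = "full"
    builder: ModelInputBuilder | None = field(default=None, repr=False)

    def save(self, path: str | Path) -> None:
        import joblib

        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        manifest = {"version": 1, "feature_names": self.feature_names,
                    "threshold": self.threshold, "seed": self.seed,
                    "mode": self.mode}
        (path / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                       sort_keys=True))
        np.save(path / "oof_scores.npy", self.oof_scores)
        np.save(path / "folds.npy", self.folds)
        joblib.dump({"model": self.model, "builder": self.builder},
                    path / "model.joblib")

    @classmethod
    def load(cls, path: str | Path) -> "ModelBundle":
        import joblib

        path = Path(path)
        manifest = json.loads((path / "manifest.json").read_text())
        payload = joblib.load(path / "model.joblib")
        return cls(model=payload["model"], builder=payload.get("builder"),
                   feature_names=manifest["feature_names"],
                   folds=np.load(path / "folds.npy"),
                   oof_scores=np.load(path / "oof_scores.npy"),
                   threshold=manifest["threshold"], seed=manifest["seed"],
                   mode=manifest["mode"])


def train_rf_cv(X: pd.DataFrame, labels, n_trees: int = 500, mtry: int = 2,
                k_folds: int = 10, seed: int = 0, threshold: float = 0.5,
                mode: str = "full",
                builder: ModelInputBuilder | None = None) -> ModelBundle:
    """Fit the cross-validated forest and package it as a bundle."""
    clf = RandomForestCV(n_trees=n_trees, mtry=mtry, k_folds=k_folds, seed=seed,
                         cutoff=threshold)
    clf.fit(X.to_numpy(dtype=float), np.asarray(labels).astype(int))
    return ModelBundle(model=clf, feature_names=list(X.columns),
                       folds=clf.folds_, oof_scores=clf.oof_scores_,
                       threshold=threshold, seed=seed, mode=mode, builder=builder)
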