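"""Supervised pipeline: collinearity filtering, standardization, stratified
splitting, floating forward feature selection with fold-internal minority
oversampling, randomized hyperparameter search, and the six classifier
families.

Leakage discipline: every fitted statistic (collinearity mask, imputation
medians, z-score parameters, oversampling, selection, tuning) is derived
from training rows only and replayed on unseen rows.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier, NearestNeighbors
from sklearn.svm import SVC

from .ensemble import roc_auc

CLASSIFIER_KINDS = ("gnb", "knn", "lr", "rfc", "svm", "xgb")

#: Covariate typing for the standard clinical table.
CLINICAL_TYPES = {
    "age": "continuous",
    "menopausal_status": "nominal",
    "laterality": "binary",
    "regimen": "nominal",
    "anti_her2_therapy": "binary",
    "er_status": "binary",
    "pr_status": "binary",
    "her2_status": "binary",
    "tumor_size_mm": "continuous",
    "clinical_t_stage": "ordinal",
    "clinical_n_stage": "ordinal",
    "node_status": "binary",
    "inflammatory_status": "binary",
    "nottingham_grade": "ordinal",
    "histology": "nominal",
    "brca_status": "binary",
}


def make_classifier(kind: str, params: dict | None = None, seed: int = 0):
    """Instantiate one of the six classifier families with probability output.

    The boosted-trees family is backed by scikit-learn's gradient boosting.
    """
    params = dict(params or {})
    kind = kind.lower()
    if kind == "gnb":
        return GaussianNB(**params)
    if kind == "knn":
        params.setdefault("n_neighbors", 5)
        return KNeighborsClassifier(**params)
    if kind == "lr":
        params.setdefault("max_iter", 2000)
        return LogisticRegression(random_state=seed, **params)
    if kind == "rfc":
        params.setdefault("n_estimators", 100)
        return RandomForestClassifier(random_state=seed, **params)
    if kind == "svm":
        params.setdefault("probability", True)
        return SVC(random_state=seed, **params)
    if kind in ("xgb", "xgboost"):
        return GradientBoostingClassifier(random_state=seed, **params)
    raise ValueError(f"unknown classifier kind: {kind}")


# ---------------------------------------------------------------------------
# Association measures and collinearity filtering
# ---------------------------------------------------------------------------

def theils_u(x, y) -> float:
    """Uncertainty coefficient U(x|y) = (H(x) - H(x|y)) / H(x).

    Asymmetric; 0 when independent, 1 when y determines x. Defined as 1 when
    H(x) = 0 (a constant is trivially determined). Natural-log entropies.
    """
    x = np.asarray(x)
    y = np.asarray(y)
    if len(x) == 0 or len(x) != len(y):
        raise ValueError("need non-empty columns of equal length")
    hx = _entropy(x)
    if hx == 0:
        return 1.0
    # H(x|y) = sum_y p(y) H(x | Y=y)
    hxy = 0.0
    n = len(x)
    for level in np.unique(y):
        mask = y == level
        hxy += mask.sum() / n * _entropy(x[mask])
    return float((hx - hxy) / hx)


def _entropy(x) -> float:
    _, counts = np.unique(x, return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log(p)).sum())


def _pearson(a, b) -> float:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.std() == 0 or b.std() == 0:
        return np.nan
    return float(np.corrcoef(a, b)[0, 1])


def target_association(column, y, col_type: str) -> float:
    """|point-biserial| for numeric columns, U(target|column) for nominal."""
    if col_type == "nominal":
        return theils_u(np.asarray(y), np.asarray(column))
    r = _pearson(column, np.asarray(y, dtype=float))
    return abs(r) if np.isfinite(r) else 0.0


def collinearity_filter(features: pd.DataFrame, target, types: dict | None = None,
                        threshold: float = 0.90) -> np.ndarray:
    """Boolean retained-column mask.

    For each pair with association above ``threshold`` — Pearson for
    numeric-numeric (point-biserial when one side is dichotomous), Theil's U
    (larger direction) for nominal-nominal — the member less associated with
    the target is dropped. Numeric-nominal pairs are not comparable and are
    never filtered against each other. Constant columns are dropped.
    """
    cols = list(features.columns)
    types = types or {c: "continuous" for c in cols}
    y = np.asarray(target)
    numeric = {c for c in cols if types.get(c, "continuous") != "nominal"}

    keep = np.ones(len(cols), dtype=bool)
    for i, c in enumerate(cols):
        col = features[c]
        if col.nunique(dropna=False) <= 1:
            warnings.warn(f"constant column dropped: {c}", stacklevel=2)
            keep[i] = False

    relevance = {}
    for c in cols:
        ctype = "continuous" if c in numeric else "nominal"
        relevance[c] = target_association(features[c], y, ctype)

    num_cols = [c for c in cols if c in numeric and keep[cols.index(c)]]
    if num_cols:
        mat = features[num_cols].to_numpy(dtype=float)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            corr = np.corrcoef(mat, rowvar=False)
        corr = np.atleast_2d(corr)

    for i, ci in enumerate(cols):
        if not keep[i]:
            continue
        for j in range(i + 1, len(cols)):
            cj = cols[j]
            if not keep[j] or not keep[i]:
                continue
            if ci in numeric and cj in numeric:
                a = abs(corr[num_cols.index(ci), num_cols.index(cj)])
            elif ci not in numeric and cj not in numeric:
                a = max(theils_u(features[ci], features[cj]),
                        theils_u(features[cj], features[ci]))
            else:
                continue
            if np.isfinite(a) and a > threshold:
                drop = j if relevance[cj] <= relevance[ci] else i
                keep[drop] = False
    return keep


# ---------------------------------------------------------------------------
# Standardization, splitting, capping, oversampling
# ---------------------------------------------------------------------------

def zscore_fit(train: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-column mean and population standard deviation from training rows.
    Zero-variance columns get sigma 1 (pass-through centering) with a warning."""
    x = np.asarray(train, dtype=float)
    mu = np.nanmean(x, axis=0)
    sigma = np.nanstd(x, axis=0, ddof=0)
    if np.any(sigma == 0):
        warnings.warn("zero-variance column(s): centered only", stacklevel=2)
        sigma = np.where(sigma == 0, 1.0, sigma)
    return mu, sigma


def zscore_apply(matrix: np.ndarray, mu: np.ndarray, sigma: np.ndarray) -> np.ndarray:
    return (np.asarray(matrix, dtype=float) - mu) / sigma


def stratified_split(labels, train_fraction: float = 0.80, seed: int = 0):
    """Index split with test size = ceil((1 - train_fraction) * n), stratified.

    Reproduces 85 -> 68/17 and 56 -> 44/12.
    """
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2 or counts.min() < 2:
        raise ValueError("need both classes with at least 2 members each")
    n_test = math.ceil((1.0 - train_fraction) * len(y))
    idx = np.arange(len(y))
    train_idx, test_idx = train_test_split(
        idx, test_size=n_test, stratify=y, random_state=seed)
    return np.sort(train_idx), np.sort(test_idx)


def feature_cap(n_train: int) -> int:
    """One feature per 10 training samples, rounded half-up; at least 1."""
    if n_train < 10:
        return 1
    return int(math.floor(n_train / 10.0 + 0.5))


def smote_oversample(features: np.ndarray, labels, k_neighbors: int = 5,
                     seed: int = 0):
    """Balance classes by interpolating synthetic minority samples between
    minority nearest neighbors. Returns (features, labels) with the minority
    class upsampled to the majority count."""
    x = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2 or counts[0] == counts[1]:
        return x, y
    minority = classes[np.argmin(counts)]
    x_min = x[y == minority]
    n_needed = int(counts.max() - counts.min())
    if len(x_min) < 2:
        warnings.warn("minority class too small for oversampling", stacklevel=2)
        return x, y
    k = min(k_neighbors, len(x_min) - 1)
    if k < k_neighbors:
        warnings.warn(f"k_neighbors reduced to {k}", stacklevel=2)
    rng = np.random.default_rng(seed)
    if len(x_min) <= 1000:
        from scipy.spatial.distance import cdist

        d = cdist(x_min, x_min)
        np.fill_diagonal(d, np.inf)
        neighbors = np.argsort(d, axis=1, kind="stable")[:, :k]
    else:
        nn = NearestNeighbors(n_neighbors=k + 1).fit(x_min)
        neighbors = nn.kneighbors(x_min, return_distance=False)[:, 1:]
    base = rng.integers(0, len(x_min), size=n_needed)
    pick = neighbors[base, rng.integers(0, k, size=n_needed)]
    gap = rng.uniform(0, 1, size=(n_needed, 1))
    synthetic = x_min[base] + gap * (x_min[pick] - x_min[base])
    return (np.vstack([x, synthetic]),
            np.concatenate([y, np.full(n_needed, minority)]))


# ---------------------------------------------------------------------------
# Cross-validated AUC with fold-internal oversampling
# ---------------------------------------------------------------------------

def cv_auc(features: np.ndarray, labels, kind: str, params: dict | None = None,
           folds: int = 10, seed: int = 0, use_smote: bool = True) -> float:
    """Mean stratified k-fold CV AUC; oversampling applied inside each
    training fold only. Single-class validation folds are skipped."""
    x = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    folds = min(folds, int(np.unique(y, return_counts=True)[1].min()))
    if folds < 2:
        raise ValueError("not enough samples per class for cross-validation")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    aucs = []
    for f, (tr, va) in enumerate(skf.split(x, y)):
        if len(np.unique(y[va])) < 2:
            warnings.warn("single-class validation fold skipped", stacklevel=2)
            continue
        xt, yt = (smote_oversample(x[tr], y[tr], seed=seed * 1000 + f)
                  if use_smote else (x[tr], y[tr]))
        clf = make_classifier(kind, params, seed=seed)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            clf.fit(xt, yt)
            scores = clf.predict_proba(x[va])[:, list(clf.classes_).index(1)]
        # a degenerate fit (e.g. zero within-class variance) is uninformative
        scores = np.nan_to_num(scores, nan=0.5)
        aucs.append(roc_auc(scores, y[va]))
    if not aucs:
        raise ValueError("no valid folds")
    return float(np.mean(aucs))


# ---------------------------------------------------------------------------
# Sequential forward floating selection
# ---------------------------------------------------------------------------

@dataclass
class SelectionResult:
    candidate_frequencies: dict
    selected: list
    cap: int
    iterations: int


def _sffs_once(x, y, kind, cap, folds, seed):
    """One SFFS pass: greedy add maximizing CV AUC with conditional removal."""
    n_feat = x.shape[1]
    current: list[int] = []
    best_at_size: dict[int, float] = {0: 0.5}

    def score(subset):
        return cv_auc(x[:, subset], y, kind, folds=folds, seed=seed)

    while len(current) < cap:
        candidates = [j for j in range(n_feat) if j not in current]
        if not candidates:
            break
        scores = [score(current + [j]) for j in candidates]
        best = int(np.argmax(scores))
        current.append(candidates[best])
        best_at_size[len(current)] = scores[best]
        # floating step: drop a feature if a smaller subset improves
        while len(current) > 2:
            drop_scores = [score([f for f in current if f != j]) for j in current[:-1]]
            k = int(np.argmax(drop_scores))
            if drop_scores[k] > best_at_size.get(len(current) - 1, -np.inf):
                current.pop(k)
                best_at_size[len(current)] = drop_scores[k]
            else:
                break
    return current, best_at_size.get(len(current), 0.5)


def sffs_select(features, labels, kind: str = "gnb", cap: int = 5,
                folds: int = 10, iterations: int = 100, seed: int = 0,
                column_names=None) -> SelectionResult:
    """Repeat SFFS over re-shuffled stratified folds and rank features by
    selection frequency; ties break by accumulated CV AUC, then column order."""
    x = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    if x.shape[1] < 2:
        raise ValueError("need at least 2 candidate features")
    names = list(column_names) if column_names is not None else list(range(x.shape[1]))

    freq = np.zeros(x.shape[1], dtype=int)
    gain = np.zeros(x.shape[1], dtype=float)
    for it in range(iterations):
        chosen, final_auc = _sffs_once(x, y, kind, cap, folds, seed=seed + it)
        freq[chosen] += 1
        gain[chosen] += final_auc
    order = sorted(range(x.shape[1]), key=lambda j: (-freq[j], -gain[j], j))
    selected = [names[j] for j in order[:cap] if freq[j] > 0]
    return SelectionResult(
        candidate_frequencies={names[j]: int(freq[j]) for j in range(x.shape[1])},
        selected=selected, cap=cap, iterations=iterations)


# ---------------------------------------------------------------------------
# Hyperparameter search
# ---------------------------------------------------------------------------

def _sample_params(kind: str, rng: np.random.Generator) -> dict:
    log = lambda lo, hi: float(10 ** rng.uniform(np.log10(lo), np.log10(hi)))
    if kind == "gnb":
        return {"var_smoothing": log(1e-12, 1e-6)}
    if kind == "knn":
        return {"n_neighbors": int(rng.integers(1, 26)),
                "weights": str(rng.choice(["uniform", "distance"])),
                "p": int(rng.integers(1, 3))}
    if kind == "lr":
        return {"C": log(1e-3, 1e3)}
    if kind == "rfc":
        return {"n_estimators": int(rng.integers(50, 301)),
                "max_depth": int(rng.integers(2, 11)),
                "max_features": str(rng.choice(["sqrt", "log2"]))}
    if kind == "svm":
        return {"C": log(1e-2, 1e3),
                "gamma": log(1e-4, 1.0),
                "kernel": str(rng.choice(["rbf", "linear"]))}
    if kind in ("xgb", "xgboost"):
        return {"n_estimators": int(rng.integers(50, 301)),
                "learning_rate": log(0.01, 0.3),
                "max_depth": int(rng.integers(1, 6)),
                "subsample": float(rng.uniform(0.6, 1.0))}
    raise ValueError(kind)


def tune_hyperparameters(features, labels, kind: str, budget: int = 25,
                         folds: int = 10, seed: int = 0) -> dict:
    """Uniform random search over the per-classifier space, scored by
    stratified CV AUC with fold-internal oversampling. Budget 0 returns
    the classifier defaults."""
    if budget <= 0:
        return {}
    rng = np.random.default_rng(seed)
    x = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    best_params, best_score = {}, -np.inf
    for b in range(budget):
        params = _sample_params(kind, rng)
        try:
            score = cv_auc(x, y, kind, params, folds=folds, seed=seed)
        except ValueError:
            continue
        if score > best_score:
            best_params, best_score = params, score
    return best_params


# ---------------------------------------------------------------------------
# Clinical encoding
# ---------------------------------------------------------------------------

class ClinicalEncoder:
    """Numeric encoding of the clinical table: binary covariates to 0/1,
    multi-level nominals one-hot against the first (reference) level, ordinal
    stage/grade as integers. Unseen levels map to the reference with a
    warning."""

    def __init__(self, types: dict | None = None):
        self.types = dict(types or CLINICAL_TYPES)
        self.levels_: dict[str, list] = {}
        self.columns_: list[str] = []

    def fit(self, df: pd.DataFrame) -> "ClinicalEncoder":
        self.levels_ = {}
        cols = []
        for c in df.columns:
            t = self.types.get(c, "continuous")
            if t in ("continuous", "ordinal"):
                cols.append(c)
            else:
                levels = sorted(map(str, df[c].astype(str).unique()))
                self.levels_[c] = levels
                if t == "binary" or len(levels) <= 2:
                    cols.append(c)
                else:
                    cols.extend(f"{c}={lv}" for lv in levels[1:])
        self.columns_ = cols
        return self

    def transform(self, df: pd.DataFrame) -> pd.DataFrame:
        out = {}
        for c in df.columns:
            t = self.types.get(c, "continuous")
            if t in ("continuous", "ordinal"):
                out[c] = pd.to_numeric(df[c])
                continue
            levels = self.levels_[c]
            vals = df[c].astype(str)
            unseen = set(vals) - set(levels)
            if unseen:
                warnings.warn(f"{c}: unseen level(s) {sorted(unseen)} -> reference",
                              stacklevel=2)
                vals = vals.where(vals.isin(levels), levels[0])
            if t == "binary" or len(levels) <= 2:
                out[c] = (vals == levels[-1]).astype(int) if len(levels) > 1 else 0
            else:
                for lv in levels[1:]:
                    out[f"{c}={lv}"] = (vals == lv).astype(int)
        return pd.DataFrame(out, index=df.index)[self.columns_]

    def column_types(self) -> dict:
        """Per encoded column typing for the collinearity filter."""
        out = {}
        for c in self.columns_:
            base = c.split("=")[0]
            t = self.types.get(base, "continuous")
            out[c] = "continuous" if t in ("continuous", "ordinal") else "binary"
        return out


# ---------------------------------------------------------------------------
# Model bundle
# ---------------------------------------------------------------------------

@dataclass
class ModelBundle:
    """Everything needed to score unseen rows exactly as at training time."""

    classifier_kind: str
    columns: list                  # input columns after encoding
    keep_mask: np.ndarray          # collinearity mask over columns
    medians: np.ndarray            # imputation medians (retained columns)
    mu: np.ndarray
    sigma: np.ndarray
    selected: list                 # names of selected (retained) columns
    hyperparameters: dict
    classifier: object
    aggregation: str = "mean"
    encoder: ClinicalEncoder | None = None
    selection: SelectionResult | None = None

    def _design(self, df: pd.DataFrame) -> np.ndarray:
        if self.encoder is not None:
            df = self.encoder.transform(df)
        x = df[self.columns].to_numpy(dtype=float)[:, self.keep_mask]
        x = np.where(np.isnan(x), self.medians, x)
        x = zscore_apply(x, self.mu, self.sigma)
        kept = [c for c, k in zip(self.columns, self.keep_mask) if k]
        sel_idx = [kept.index(s) for s in self.selected]
        return x[:, sel_idx]

    def predict_proba(self, df: pd.DataFrame) -> np.ndarray:
        """P(responder) for each row."""
        x = self._design(df)
        proba = self.classifier.predict_proba(x)
        return proba[:, list(self.classifier.classes_).index(1)]

    def save(self, path) -> None:
        import joblib

        joblib.dump(self, path)
        meta = {"classifier_kind": self.classifier_kind,
                "aggregation": self.aggregation,
                "selected": list(map(str, self.selected)),
                "hyperparameters": self.hyperparameters,
                "n_input_columns": len(self.columns)}
        with open(str(path) + ".json", "w") as fh:
            json.dump(meta, fh, indent=1)

    @staticmethod
    def load(path) -> "ModelBundle":
        import joblib

        return joblib.load(path)


def train_model(features: pd.DataFrame, labels, classifier_kind: str = "gnb",
                types: dict | None = None, encoder: ClinicalEncoder | None = None,
                cap: int | None = None, folds: int = 10,
                selection_iterations: int = 100, tuning_budget: int = 25,
                collinearity_threshold: float = 0.90, seed: int = 0,
                aggregation: str = "mean") -> ModelBundle:
    """Fit the full chain on training rows and return a reusable bundle.

    ``features`` must contain training rows only; pass an encoder fitted on
    the same rows when the frame holds raw clinical covariates.
    """
    y = np.asarray(labels)
    if encoder is not None:
        df = encoder.transform(features)
        types = encoder.column_types()
    else:
        df = features
    columns = list(df.columns)

    keep = collinearity_filter(df, y, types=types, threshold=collinearity_threshold)
    kept_cols = [c for c, k in zip(columns, keep) if k]
    x = df[kept_cols].to_numpy(dtype=float)

    medians = np.nanmedian(x, axis=0)
    medians = np.where(np.isnan(medians), 0.0, medians)
    x = np.where(np.isnan(x), medians, x)

    # columns constant after imputation (e.g. a single observed value) carry
    # no information and break variance-based classifiers
    informative = x.std(axis=0) > 0
    if not informative.any():
        raise ValueError("no informative feature columns after preprocessing")
    if not informative.all():
        for c, ok in zip(kept_cols, informative):
            if not ok:
                keep[columns.index(c)] = False
        kept_cols = [c for c, ok in zip(kept_cols, informative) if ok]
        medians = medians[informative]
        x = x[:, informative]
    mu, sigma = zscore_fit(x)
    xz = zscore_apply(x, mu, sigma)

    if cap is None:
        cap = feature_cap(len(y))
    if len(kept_cols) < 2:
        selection = SelectionResult({c: selection_iterations for c in kept_cols},
                                    list(kept_cols), cap, selection_iterations)
    else:
        selection = sffs_select(xz, y, kind=classifier_kind, cap=cap, folds=folds,
                                iterations=selection_iterations, seed=seed,
                                column_names=kept_cols)
    sel_idx = [kept_cols.index(s) for s in selection.selected]
    xs = xz[:, sel_idx]

    params = tune_hyperparameters(xs, y, classifier_kind, budget=tuning_budget,
                                  folds=folds, seed=seed)
    xb, yb = smote_oversample(xs, y, seed=seed)
    clf = make_classifier(classifier_kind, params, seed=seed)
    clf.fit(xb, yb)

    return ModelBundle(classifier_kind=classifier_kind, columns=columns,
                       keep_mask=keep, medians=medians, mu=mu, sigma=sigma,
                       selected=list(selection.selected), hyperparameters=params,
                       classifier=clf, aggregation=aggregation, encoder=encoder,
                       selection=selection)
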