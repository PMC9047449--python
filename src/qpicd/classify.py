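"""Screening and classification of sigmoid parameters by cell-death type.

For every feature the fitted ``Amplitude``, ``Gain`` and their product are
candidate discriminators (33 columns per cell).  A two-sided Wilcoxon
rank-sum test screens them for apoptosis-vs-necrosis differences; selected
columns feed a radial-basis SVM evaluated over repeated stratified
train/validation/test splits (2:1:2), with min-max scaling and a gamma
(power-law) correction whose exponent — like the SVM hyperparameters — is
chosen on the validation split only.  A Fisher linear discriminant
projection of the same columns visualizes how the classes separate.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.svm import SVC

from .synthetic import FEATURE_NAMES

__all__ = [
    "ClassifierReport",
    "rank_sum_test",
    "ranksum_screen",
    "build_parameter_table",
    "MinMaxGamma",
    "train_eval_svm",
    "two_class_death_classifier",
    "lda_project",
    "THREE_CLASS_COLUMNS",
    "TWO_CLASS_COLUMNS",
]

#: Default parameter sets (amplitude `_A`, amplitude x gain `_AxG`).
THREE_CLASS_COLUMNS = (
    "cell_area_A",
    "mean_central_phase_A",
    "fried_egg_score_A",
    "circularity_AxG",
    "nuclear_edge_score_AxG",
)
TWO_CLASS_COLUMNS = (
    "cell_area_A",
    "mean_peripheral_phase_A",
    "mean_central_phase_A",
    "fried_egg_score_A",
    "nuclear_edge_score_AxG",
)

GAMMA_GRID = (1.0 / 3.0, 0.5, 1.0, 2.0, 3.0)
SVM_C_GRID = (1.0, 10.0, 100.0)
SVM_GAMMA_GRID = ("scale", 0.1, 1.0)

EXACT_LIMIT = 8


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum
# ---------------------------------------------------------------------------


def _rank_sum_statistic(pooled_ranks: np.ndarray, idx: tuple[int, ...]) -> float:
    return float(pooled_ranks[list(idx)].sum())


def rank_sum_test(x, y, exact_limit: int = EXACT_LIMIT) -> float:
    """Two-sided Wilcoxon rank-sum p-value for two independent samples.

    Small samples (both sizes <= ``exact_limit``) are handled by exhaustive
    enumeration of all group assignments conditional on the pooled values
    (exact even with ties); larger samples use the normal approximation
    with midranks, tie correction and a 0.5 continuity correction.  Two
    identical constant samples give p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 < 1 or n2 < 1:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return 1.0
    ranks = stats.rankdata(pooled)
    w_obs = float(ranks[:n1].sum())
    mean_w = n1 * (n1 + n2 + 1) / 2.0
    if n1 <= exact_limit and n2 <= exact_limit:
        count = 0
        total = 0
        dev = abs(w_obs - mean_w)
        for idx in itertools.combinations(range(n1 + n2), n1):
            total += 1
            if abs(_rank_sum_statistic(ranks, idx) - mean_w) >= dev - 1e-9:
                count += 1
        return count / total
    # normal approximation with tie correction
    n = n1 + n2
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts)
    var_w = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var_w <= 0:
        return 1.0
    z = (abs(w_obs - mean_w) - 0.5) / math.sqrt(var_w)
    return float(2.0 * stats.norm.sf(max(z, 0.0)))


def significance_stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def build_parameter_table(fits: pd.DataFrame, labels: pd.DataFrame) -> pd.DataFrame:
    """Wide per-cell parameter table from a tidy fits table.

    Columns ``{feature}_A``, ``{feature}_G`` and ``{feature}_AxG`` for each
    of the 11 features, plus ``class_label``; the product column is exactly
    the row-wise product of its parents.  ``labels`` maps ``cell_id`` (or
    ``track_id``) to ``class_label``.
    """
    amp = fits.pivot(index="track_id", columns="feature", values="amplitude")
    gain = fits.pivot(index="track_id", columns="feature", values="gain")
    out = pd.DataFrame(index=amp.index)
    for feature in FEATURE_NAMES:
        out[f"{feature}_A"] = amp[feature]
        out[f"{feature}_G"] = gain[feature]
        out[f"{feature}_AxG"] = amp[feature] * gain[feature]
    lab = labels.copy()
    if "cell_id" in lab.columns and "track_id" not in lab.columns:
        lab = lab.rename(columns={"cell_id": "track_id"})
    lab = lab.set_index("track_id")["class_label"]
    out["class_label"] = lab.reindex(out.index)
    return out.reset_index()


def ranksum_screen(table: pd.DataFrame) -> pd.DataFrame:
    """Rank-sum screen of every parameter column, apoptotic vs necrotic.

    Returns one row per column with the two-sided p-value and Fig.-style
    significance stars.  Requires at least two cells per class.
    """
    apo = table[table["class_label"] == "apoptotic"]
    nec = table[table["class_label"] == "necrotic"]
    if len(apo) < 2 or len(nec) < 2:
        raise ValueError("need >= 2 apoptotic and >= 2 necrotic cells")
    rows = []
    for col in table.columns:
        if col in ("track_id", "class_label"):
            continue
        p = rank_sum_test(apo[col].to_numpy(), nec[col].to_numpy())
        rows.append({"column": col, "p_value": p, "stars": significance_stars(p)})
    return pd.DataFrame(rows).sort_values("p_value").reset_index(drop=True)


# ---------------------------------------------------------------------------
# Preprocessing: min-max scaling + gamma correction
# ---------------------------------------------------------------------------


@dataclass
class MinMaxGamma:
    """Column-wise min-max rescale to [0, 1] followed by a power transform.

    Statistics come from the training split only; out-of-range test values
    are clipped to [0, 1] before the power, so the transform is monotone
    for any gamma > 0.  Zero-range columns map to a constant 0.5.
    """

    gamma: float = 1.0
    mins: np.ndarray | None = None
    ranges: np.ndarray | None = None

    def fit(self, X: np.ndarray) -> "MinMaxGamma":
        X = np.asarray(X, dtype=float)
        self.mins = X.min(axis=0)
        self.ranges = X.max(axis=0) - self.mins
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        if self.mins is None:
            raise RuntimeError("fit before transform")
        X = np.asarray(X, dtype=float)
        out = np.empty_like(X)
        for j in range(X.shape[1]):
            if self.ranges[j] == 0:
                out[:, j] = 0.5
            else:
                scaled = np.clip((X[:, j] - self.mins[j]) / self.ranges[j], 0.0, 1.0)
                out[:, j] = scaled**self.gamma
        return out


# ---------------------------------------------------------------------------
# SVM evaluation over repeated stratified splits
# ---------------------------------------------------------------------------


@dataclass
class ClassifierReport:
    """Aggregate performance over repeated random splits."""

    classes: list[str]
    n_splits: int
    accuracies: np.ndarray
    confusion: np.ndarray  # averaged counts, rows = true class
    per_cell_error_rate: np.ndarray
    columns: list[str] = field(default_factory=list)

    @property
    def overall_accuracy(self) -> float:
        return float(np.mean(self.accuracies))

    def collapsed_accuracy(self, groups: dict[str, str]) -> float:
        """Accuracy after merging classes (e.g. both death types as 'dead')."""
        mapped = [groups.get(c, c) for c in self.classes]
        uniq = sorted(set(mapped))
        m = np.zeros((len(uniq), len(uniq)))
        for i, gi in enumerate(mapped):
            for j, gj in enumerate(mapped):
                m[uniq.index(gi), uniq.index(gj)] += self.confusion[i, j]
        return float(np.trace(m) / m.sum())

    def to_dict(self) -> dict:
        return {
            "classes": self.classes,
            "n_splits": self.n_splits,
            "overall_accuracy": self.overall_accuracy,
            "accuracy_sd": float(np.std(self.accuracies)),
            "confusion_matrix": self.confusion.tolist(),
            "columns": list(self.columns),
        }


def _stratified_split(y: np.ndarray, rng: np.random.Generator):
    """Random 2:1:2 train/validation/test split, stratified per class."""
    train, val, test = [], [], []
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        rng.shuffle(idx)
        n = len(idx)
        n_tr = max(int(round(0.4 * n)), 1)
        n_va = max(int(round(0.2 * n)), 1)
        train.extend(idx[:n_tr])
        val.extend(idx[n_tr : n_tr + n_va])
        test.extend(idx[n_tr + n_va :])
    return np.array(train), np.array(val), np.array(test)


def train_eval_svm(
    X: np.ndarray,
    y,
    n_splits: int = 500,
    seed: int = 0,
    gamma_grid=GAMMA_GRID,
    c_grid=SVM_C_GRID,
    kernel_gamma_grid=SVM_GAMMA_GRID,
    columns: list[str] | None = None,
) -> ClassifierReport:
    """RBF-SVM performance averaged over repeated stratified 2:1:2 splits.

    Per split, the preprocessing exponent and the SVM (C, kernel width)
    are selected by validation accuracy; preprocessing statistics come
    from the training split only, so no test information leaks into the
    model.  The averaged confusion matrix, per-split accuracies and each
    cell's test-set error rate are returned; everything is reproducible
    from ``seed``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = sorted(np.unique(y).tolist())
    counts = {c: int(np.sum(y == c)) for c in classes}
    if min(counts.values()) < 5:
        raise ValueError(f"every class needs >= 5 cells, got {counts}")
    rng = np.random.default_rng(seed)
    class_index = {c: i for i, c in enumerate(classes)}
    y_idx = np.array([class_index[v] for v in y])
    confusion = np.zeros((len(classes), len(classes)))
    accuracies = np.empty(n_splits)
    err_counts = np.zeros(len(y))
    test_counts = np.zeros(len(y))
    for split in range(n_splits):
        tr, va, te = _stratified_split(y, rng)
        best = None
        for g in gamma_grid:
            prep = MinMaxGamma(gamma=g).fit(X[tr])
            Xtr, Xva = prep.transform(X[tr]), prep.transform(X[va])
            for C in c_grid:
                for kg in kernel_gamma_grid:
                    clf = SVC(C=C, kernel="rbf", gamma=kg)
                    clf.fit(Xtr, y_idx[tr])
                    acc = float(np.mean(clf.predict(Xva) == y_idx[va]))
                    if best is None or acc > best[0]:
                        best = (acc, g, C, kg)
        _, g, C, kg = best
        prep = MinMaxGamma(gamma=g).fit(X[tr])
        clf = SVC(C=C, kernel="rbf", gamma=kg)
        clf.fit(prep.transform(X[tr]), y_idx[tr])
        pred = clf.predict(prep.transform(X[te]))
        accuracies[split] = float(np.mean(pred == y_idx[te]))
        for true_i, pred_i in zip(y_idx[te], pred):
            confusion[true_i, pred_i] += 1
        err_counts[te] += pred != y_idx[te]
        test_counts[te] += 1
    confusion /= n_splits
    with np.errstate(invalid="ignore"):
        err_rate = np.where(test_counts > 0, err_counts / test_counts, np.nan)
    return ClassifierReport(
        classes=classes,
        n_splits=n_splits,
        accuracies=accuracies,
        confusion=confusion,
        per_cell_error_rate=err_rate,
        columns=list(columns or []),
    )


def two_class_death_classifier(
    table: pd.DataFrame,
    columns=TWO_CLASS_COLUMNS,
    n_splits: int = 500,
    seed: int = 0,
) -> ClassifierReport:
    """Apoptosis-vs-necrosis SVM on the dedicated five-parameter set."""
    sub = table[table["class_label"].isin(["apoptotic", "necrotic"])]
    X = sub[list(columns)].to_numpy(dtype=float)
    return train_eval_svm(
        X, sub["class_label"].to_numpy(), n_splits=n_splits, seed=seed,
        columns=list(columns),
    )


# ---------------------------------------------------------------------------
# Linear discriminant projection
# ---------------------------------------------------------------------------


def lda_project(
    X: np.ndarray, y, n_components: int | None = None, ridge: float = 1e-6
):
    """Fisher discriminant projection of the classifier inputs.

    Solves the generalized eigenproblem of the between- and within-class
    scatter matrices (the within-class scatter is ridge-regularized by
    ``ridge x trace / d`` for robustness) and returns the per-cell
    coordinates and the per-column loadings of the leading axes
    (at most ``n_classes - 1``).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = sorted(np.unique(y).tolist())
    if len(classes) < 2:
        raise ValueError("need at least two classes")
    d = X.shape[1]
    overall = X.mean(axis=0)
    sw = np.zeros((d, d))
    sb = np.zeros((d, d))
    for c in classes:
        Xc = X[y == c]
        mu = Xc.mean(axis=0)
        dev = Xc - mu
        sw += dev.T @ dev
        diff = (mu - overall)[:, None]
        sb += len(Xc) * (diff @ diff.T)
    sw += np.eye(d) * ridge * max(np.trace(sw), 1e-30) / d
    evals, evecs = np.linalg.eig(np.linalg.solve(sw, sb))
    order = np.argsort(evals.real)[::-1]
    max_axes = min(len(classes) - 1, d)
    k = max_axes if n_components is None else min(n_components, max_axes)
    loadings = evecs[:, order[:k]].real
    # deterministic sign: largest-magnitude loading positive
    for j in range(loadings.shape[1]):
        i = np.argmax(np.abs(loadings[:, j]))
        if loadings[i, j] < 0:
            loadings[:, j] = -loadings[:, j]
    coords = (X - overall) @ loadings
    return coords, loadings
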