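"""Multivariate core: autoscaling, PCA, two-class PLS-DA, repeated double
cross-validation (DCV) and sign-stability variable selection.

The classifier is PLS1 regression (NIPALS) against ±1 class codes
(+1 = Exposed, -1 = CTRL). Validation is a repeated, nested resampling
scheme: an inner cross-validation loop over each outer-training set picks
the number of latent variables by minimum misclassification, the model is
refit on the full outer-training set (autoscaling fitted there only) and
applied to the untouched outer fold, and the whole scheme is repeated with
reshuffled stratified splits. Every outer-fold model contributes one
sample of the discriminant-direction weights; a variable is called
significant only when all those weight samples share one sign and their
percentile confidence interval excludes zero.

For a two-class model the discriminant subspace is one-dimensional; the
canonical direction ("CV1") is represented here by the PLS regression
coefficient vector b, normalised to unit length with its sign fixed so the
exposed-class centroid projects positive. The first weight vector w1 is
available as an alternative via ``DcvConfig.cv1_mode``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Figures of merit are reported on the 0-100 percent scale.
FOM_COLUMNS = ("sensitivity", "specificity", "accuracy", "percent_correct")


# --------------------------------------------------------------------------
# scaling and PCA

@dataclass
class ScaledMatrix:
    """Autoscaled data plus the training statistics that produced it."""

    X: np.ndarray
    column_means: np.ndarray
    column_sds: np.ndarray


def autoscale(
    X: np.ndarray | pd.DataFrame,
    reference_means: np.ndarray | None = None,
    reference_sds: np.ndarray | None = None,
) -> ScaledMatrix:
    """Column-wise standardisation to zero mean, unit variance.

    Fit mode (no reference statistics): means/sds (ddof=1) are estimated
    from X; a zero-variance column is an error. Transform mode: the
    supplied training statistics are applied unchanged — the contract for
    scaling held-out data.
    """
    cols = list(X.columns) if isinstance(X, pd.DataFrame) else None
    X = np.asarray(X, dtype=float)
    if X.size == 0:
        raise ValueError("empty matrix")
    if (reference_means is None) != (reference_sds is None):
        raise ValueError("supply both reference means and sds, or neither")
    if reference_means is None:
        means = X.mean(axis=0)
        sds = X.std(axis=0, ddof=1)
        zero = np.flatnonzero(sds == 0)
        if zero.size:
            names = [cols[i] for i in zero] if cols else list(zero)
            raise ValueError(f"zero-variance column(s) during fit: {names}")
    else:
        means = np.asarray(reference_means, dtype=float)
        sds = np.asarray(reference_sds, dtype=float)
    return ScaledMatrix(X=(X - means) / sds, column_means=means, column_sds=sds)


@dataclass
class PcaResult:
    scores: np.ndarray                 # n x k
    loadings: np.ndarray               # p x k
    explained_variance_ratio: np.ndarray


def pca(X_scaled: np.ndarray) -> PcaResult:
    """PCA of a centered (typically autoscaled) matrix via SVD.

    Returns min(n-1, p) components; explained-variance fractions sum to 1
    over that set and scores equal X @ loadings.
    """
    X = np.asarray(X_scaled, dtype=float)
    if X.size == 0:
        raise ValueError("empty matrix")
    n, p = X.shape
    k = min(n - 1, p)
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    var = s[:k] ** 2
    return PcaResult(
        scores=(U[:, :k] * s[:k]),
        loadings=Vt[:k].T,
        explained_variance_ratio=var / var.sum(),
    )


# --------------------------------------------------------------------------
# PLS-DA (NIPALS PLS1)

@dataclass
class PlsDaModel:
    """A fitted two-class PLS-DA model.

    ``coef_path`` holds the regression coefficient vector for every
    truncation 1..n_lv of the latent-variable sequence, which lets nested
    cross-validation evaluate all model complexities from one fit.
    """

    n_lv: int
    weights: np.ndarray        # W, p x A
    loadings: np.ndarray       # P, p x A
    scores: np.ndarray         # T, n x A (training scores)
    y_loadings: np.ndarray     # q, A
    coef: np.ndarray           # b for the full n_lv model, p
    coef_path: np.ndarray      # p x A, column a-1 = b using a latent variables
    y_mean: float
    cv1_weights: np.ndarray    # unit-norm discriminant direction, p
    class_threshold: float = 0.0
    scaler: ScaledMatrix | None = None
    variable_names: list[str] | None = None

    def predict_continuous(self, X_new: np.ndarray, n_lv: int | None = None) -> np.ndarray:
        """Continuous ŷ for data already scaled with the training stats."""
        X_new = np.asarray(X_new, dtype=float)
        if X_new.shape[1] != self.coef.shape[0]:
            raise ValueError(
                f"expected {self.coef.shape[0]} columns, got {X_new.shape[1]}")
        b = self.coef if n_lv is None else self.coef_path[:, n_lv - 1]
        return self.y_mean + X_new @ b


def pls_da_fit(
    X_scaled: np.ndarray,
    y: np.ndarray,
    n_lv: int,
    variable_names: list[str] | None = None,
    cv1_mode: str = "coefficients",
) -> PlsDaModel:
    """Fit PLS1 by NIPALS on autoscaled X against ±1 class codes.

    y is centered internally (with column-centered X this leaves the first
    weight vector proportional to Xᵀy). Deflation of X follows NIPALS; the
    coefficient vector is recovered as b = W (PᵀW)⁻¹ q. Components whose
    weight norm or score norm underflows terminate the sequence early.
    """
    X = np.asarray(X_scaled, dtype=float).copy()
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("both classes must be present")
    if not 1 <= n_lv <= min(n - 1, p):
        raise ValueError(f"n_lv must be in [1, {min(n - 1, p)}], got {n_lv}")

    y_mean = float(y.mean())
    f = y - y_mean
    W = np.zeros((p, n_lv))
    P = np.zeros((p, n_lv))
    T = np.zeros((n, n_lv))
    q = np.zeros(n_lv)
    a_used = 0
    for a in range(n_lv):
        w = X.T @ f
        wn = np.linalg.norm(w)
        if wn < 1e-12:
            break
        w /= wn
        t = X @ w
        tt = t @ t
        if tt < 1e-12:
            break
        pvec = X.T @ t / tt
        qa = f @ t / tt
        X -= np.outer(t, pvec)
        f = f - qa * t
        W[:, a], P[:, a], T[:, a], q[a] = w, pvec, t, qa
        a_used += 1
    if a_used == 0:
        raise ValueError("no latent variable could be extracted (Xᵀy ≈ 0)")
    W, P, T, q = W[:, :a_used], P[:, :a_used], T[:, :a_used], q[:a_used]

    coef_path = np.zeros((p, a_used))
    for a in range(1, a_used + 1):
        R = np.linalg.solve((P[:, :a].T @ W[:, :a]).T, W[:, :a].T).T
        coef_path[:, a - 1] = R @ q[:a]
    b = coef_path[:, -1]

    direction = b if cv1_mode == "coefficients" else W[:, 0]
    nrm = np.linalg.norm(direction)
    cv1 = direction / nrm if nrm > 0 else direction
    # orient so the exposed (+1) centroid projects positive
    Xs = np.asarray(X_scaled, dtype=float)
    gap = Xs[y > 0].mean(axis=0) @ cv1 - Xs[y < 0].mean(axis=0) @ cv1
    if gap < 0:
        cv1 = -cv1

    return PlsDaModel(n_lv=a_used, weights=W, loadings=P, scores=T,
                      y_loadings=q, coef=b, coef_path=coef_path,
                      y_mean=y_mean, cv1_weights=cv1,
                      variable_names=variable_names)


def classify(model: PlsDaModel, X_new: np.ndarray,
             n_lv: int | None = None) -> np.ndarray:
    """±1 labels from continuous predictions; ŷ exactly at the threshold
    goes to the positive (Exposed) class."""
    yc = model.predict_continuous(X_new, n_lv=n_lv)
    return np.where(yc >= model.class_threshold, 1.0, -1.0)


# --------------------------------------------------------------------------
# repeated double cross-validation

@dataclass
class DcvConfig:
    """Geometry and knobs of the repeated double cross-validation."""

    n_repetitions: int = 20
    outer_folds: int = 5
    inner_folds: int = 5
    max_lv: int = 5
    seed: int = 0
    stratified: bool = True
    cv1_mode: str = "coefficients"     # or "w1"
    global_scaling: bool = False       # scale once on all data (diagnostic)

    def __post_init__(self) -> None:
        if self.outer_folds < 2 or self.inner_folds < 2:
            raise ValueError("fold counts must be >= 2")
        if self.max_lv < 1:
            raise ValueError("max_lv must be >= 1")
        if self.n_repetitions < 1:
            raise ValueError("n_repetitions must be >= 1")


@dataclass
class FoldRecord:
    """Bookkeeping for one outer-fold model (enables leakage audits)."""

    repetition: int
    fold: int
    test_indices: np.ndarray
    chosen_n_lv: int
    scaler_means: np.ndarray
    scaler_sds: np.ndarray
    cv1_weights: np.ndarray
    predictions: np.ndarray            # ±1 for the held-out subjects


@dataclass
class DcvResult:
    per_repetition: pd.DataFrame       # one row per repetition, FOM_COLUMNS
    cv1_weight_samples: np.ndarray     # (n_rep * outer_folds) x p
    chosen_n_lv: np.ndarray            # n_rep x outer_folds
    confusion: dict[str, int]          # pooled TP/TN/FP/FN over everything
    fold_records: list[FoldRecord]
    variable_names: list[str]

    def summary(self) -> dict[str, dict[str, float]]:
        """Mean ± sd of each figure of merit across repetitions (percent)."""
        return {c: {"mean": float(self.per_repetition[c].mean()),
                    "sd": float(self.per_repetition[c].std(ddof=1))}
                for c in FOM_COLUMNS}


def figures_of_merit(tp: int, tn: int, fp: int, fn: int) -> dict[str, float]:
    """Sensitivity, specificity, accuracy, percent correct — in percent.

    Positive class = Exposed. Percent correct classification equals
    accuracy for a two-class pooled confusion table; both are reported
    because both are conventional."""
    total = tp + tn + fp + fn
    if total == 0:
        raise ValueError("empty confusion table")
    acc = 100.0 * (tp + tn) / total
    return {
        "sensitivity": 100.0 * tp / (tp + fn) if tp + fn else np.nan,
        "specificity": 100.0 * tn / (tn + fp) if tn + fp else np.nan,
        "accuracy": acc,
        "percent_correct": acc,
    }


def _stratified_folds(y: np.ndarray, k: int,
                      rng: np.random.Generator,
                      stratified: bool) -> list[np.ndarray]:
    """Deterministic shuffled (stratified) partition into k folds."""
    n = y.shape[0]
    if stratified:
        folds: list[list[int]] = [[] for _ in range(k)]
        for cls in np.unique(y):
            idx = rng.permutation(np.flatnonzero(y == cls))
            for pos, i in enumerate(idx):
                folds[pos % k].append(int(i))
        return [np.sort(np.array(f, dtype=int)) for f in folds]
    perm = rng.permutation(n)
    return [np.sort(part) for part in np.array_split(perm, k)]


def _choose_n_lv(X_tr: np.ndarray, y_tr: np.ndarray, config: DcvConfig,
                 rng: np.random.Generator) -> int:
    """Inner CV over the outer-training set: minimum mean misclassification
    rate across inner folds; ties go to the smaller model."""
    folds = _stratified_folds(y_tr, config.inner_folds, rng, config.stratified)
    n = X_tr.shape[0]
    cap = min(config.max_lv, X_tr.shape[1],
              min(n - f.size for f in folds) - 1)
    cap = max(cap, 1)
    errors = np.zeros(cap)
    counts = np.zeros(cap)
    for test_idx in folds:
        train_idx = np.setdiff1d(np.arange(n), test_idx)
        if np.unique(y_tr[train_idx]).size < 2 or test_idx.size == 0:
            continue
        scaler = autoscale(X_tr[train_idx])
        model = pls_da_fit(scaler.X, y_tr[train_idx],
                           min(cap, train_idx.size - 1, X_tr.shape[1]))
        X_te = (X_tr[test_idx] - scaler.column_means) / scaler.column_sds
        for a in range(1, model.n_lv + 1):
            pred = classify(model, X_te, n_lv=a)
            errors[a - 1] += np.sum(pred != y_tr[test_idx])
            counts[a - 1] += test_idx.size
        # complexities beyond what this fold supported inherit its best error
        for a in range(model.n_lv + 1, cap + 1):
            errors[a - 1] += np.sum(classify(model, X_te) != y_tr[test_idx])
            counts[a - 1] += test_idx.size
    rates = np.where(counts > 0, errors / np.maximum(counts, 1), np.inf)
    return int(np.argmin(rates)) + 1    # argmin takes the first (smallest) tie


def double_cross_validate(
    X: np.ndarray | pd.DataFrame,
    y: np.ndarray,
    config: DcvConfig | None = None,
) -> DcvResult:
    """Repeated double cross-validation of a two-class PLS-DA model.

    Per repetition: a fresh stratified outer split; per outer fold, inner
    CV on the outer-training set selects the latent-variable count,
    autoscaling is fitted on the outer-training set only, the refit model
    predicts the untouched fold, and its discriminant weights are
    collected. Figures of merit are computed from the pooled outer
    predictions of each repetition. Fully reproducible from the seed.
    """
    config = config or DcvConfig()
    names = (list(X.columns) if isinstance(X, pd.DataFrame)
             else [f"var{i}" for i in range(np.asarray(X).shape[1])])
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = X.shape[0]
    for cls in (1.0, -1.0):
        if np.sum(y == cls) < config.outer_folds:
            raise ValueError(
                f"class {cls:+g} has fewer subjects than outer_folds")

    global_scaler = autoscale(X) if config.global_scaling else None

    rep_rows = []
    fold_records: list[FoldRecord] = []
    chosen = np.zeros((config.n_repetitions, config.outer_folds), dtype=int)
    pooled = {"TP": 0, "TN": 0, "FP": 0, "FN": 0}

    for rep in range(config.n_repetitions):
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, rep]))
        outer = _stratified_folds(y, config.outer_folds, rng, config.stratified)
        y_pred = np.zeros(n)
        for k, test_idx in enumerate(outer):
            train_idx = np.setdiff1d(np.arange(n), test_idx)
            inner_rng = np.random.default_rng(
                np.random.SeedSequence([config.seed, rep, k]))
            n_lv = _choose_n_lv(X[train_idx], y[train_idx], config, inner_rng)
            if global_scaler is not None:
                scaler = ScaledMatrix(
                    X=(X[train_idx] - global_scaler.column_means)
                      / global_scaler.column_sds,
                    column_means=global_scaler.column_means,
                    column_sds=global_scaler.column_sds)
            else:
                scaler = autoscale(X[train_idx])
            n_lv = min(n_lv, train_idx.size - 1, X.shape[1])
            model = pls_da_fit(scaler.X, y[train_idx], n_lv,
                               variable_names=names, cv1_mode=config.cv1_mode)
            X_te = (X[test_idx] - scaler.column_means) / scaler.column_sds
            pred = classify(model, X_te)
            y_pred[test_idx] = pred
            chosen[rep, k] = model.n_lv
            fold_records.append(FoldRecord(
                repetition=rep, fold=k, test_indices=test_idx,
                chosen_n_lv=model.n_lv, scaler_means=scaler.column_means,
                scaler_sds=scaler.column_sds, cv1_weights=model.cv1_weights,
                predictions=pred))
        tp = int(np.sum((y_pred > 0) & (y > 0)))
        tn = int(np.sum((y_pred < 0) & (y < 0)))
        fp = int(np.sum((y_pred > 0) & (y < 0)))
        fn = int(np.sum((y_pred < 0) & (y > 0)))
        pooled["TP"] += tp
        pooled["TN"] += tn
        pooled["FP"] += fp
        pooled["FN"] += fn
        rep_rows.append(figures_of_merit(tp, tn, fp, fn))

    return DcvResult(
        per_repetition=pd.DataFrame(rep_rows, columns=list(FOM_COLUMNS)),
        cv1_weight_samples=np.vstack([r.cv1_weights for r in fold_records]),
        chosen_n_lv=chosen,
        confusion=pooled,
        fold_records=fold_records,
        variable_names=names,
    )


# --------------------------------------------------------------------------
# sign-stability variable selection

@dataclass
class SelectionReport:
    """Per-variable stability of the discriminant-direction weights."""

    table: pd.DataFrame    # median_weight, ci_lo, ci_hi, sign_consistency,
                           # selected, group
    ci_level: float

    @property
    def selected(self) -> list[str]:
        return list(self.table.index[self.table["selected"]])

    def to_csv(self, path) -> None:
        out = self.table.copy()
        out.index.name = "metabolite"
        out.to_csv(path)


def select_significant_variables(result: DcvResult,
                                 ci_level: float = 0.95) -> SelectionReport:
    """Call a variable significant when every cross-validated model agrees
    on its weight's sign and the percentile confidence interval of the
    weight samples excludes zero.

    Group assignment follows the sign convention: positive weights point
    to the Exposed class (+1 coding), negative to CTRL.
    """
    samples = result.cv1_weight_samples
    if samples.shape[0] < 2:
        raise ValueError("need at least 2 weight samples per variable")
    alpha = 1.0 - ci_level
    lo, hi = np.percentile(samples, [100 * alpha / 2, 100 * (1 - alpha / 2)],
                           axis=0)
    median = np.median(samples, axis=0)
    pos_frac = np.mean(samples > 0, axis=0)
    neg_frac = np.mean(samples < 0, axis=0)
    sign_consistency = np.maximum(pos_frac, neg_frac)
    all_same_sign = (pos_frac == 1.0) | (neg_frac == 1.0)
    ci_excludes_zero = (lo > 0) | (hi < 0)
    selected = all_same_sign & ci_excludes_zero
    table = pd.DataFrame({
        "median_weight": median,
        "ci_lo": lo,
        "ci_hi": hi,
        "sign_consistency": sign_consistency,
        "selected": selected,
        "group": np.where(median > 0, "Exposed", "CTRL"),
    }, index=result.variable_names)
    return SelectionReport(table=table, ci_level=ci_level)
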