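"""Brain-behavior prediction: PLS regression with Q²-based model selection.

Nodal network metrics (strength, degree) form a regions x subjects predictor
matrix; age, sex, and their interaction are regressed out of every node (but
not out of the cognitive outcome, which is assumed already age-adjusted).  A
univariate-response PLS (PLS1, NIPALS) relates the predictors to the outcome.
The number of PLS components is chosen by cross-validated R², the Q²
statistic,

    Q² = 1 - PRESS / TSS,

computed from pooled out-of-fold predictions over repeated k-fold
cross-validation.  Zero components — predicting each held-out fold with the
training-fold mean — is a first-class candidate, so "retain no components"
(no model is built) is a possible, meaningful outcome.  When a model is
retained, predictor weights are reported with bias-corrected and accelerated
(BCa) bootstrap confidence intervals.

The executive-function summary score is the first principal component of the
three EF subtests (correlation scale), retained only if its eigenvalue
exceeds 1 and all three loadings share a sign.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PLSModel",
    "PLSSelectionResult",
    "ef_summary",
    "residualize_confounds",
    "q_squared",
    "pls1_fit",
    "pls_cv_select",
    "bootstrap_weights",
    "bca_interval",
]


def ef_summary(ef_scores: np.ndarray) -> np.ndarray:
    """Summarize three executive-function subtests by their first PC.

    PCA is on the correlation scale (columns standardized).  The component is
    retained only if its eigenvalue exceeds 1 and all three loadings share a
    sign (flipped so loadings are positive); otherwise an error explains which
    retention rule failed.  Returns standardized component scores.
    """
    X = np.asarray(ef_scores, dtype=float)
    if X.ndim != 2 or X.shape[1] != 3:
        raise ValueError(f"expected an N x 3 subtest matrix, got shape {X.shape}")
    if np.isnan(X).any():
        raise ValueError("missing values in EF subtests")
    sd = X.std(axis=0, ddof=1)
    if np.any(sd == 0):
        raise ValueError("an EF subtest has zero variance")
    Z = (X - X.mean(axis=0)) / sd
    corr = np.corrcoef(Z, rowvar=False)
    eigvals, eigvecs = np.linalg.eigh(corr)
    lam1 = eigvals[-1]
    v1 = eigvecs[:, -1]
    if lam1 <= 1:
        raise ValueError(
            f"first principal component eigenvalue {lam1:.3f} <= 1; "
            "retention rule not met, no EF summary score available"
        )
    if v1.sum() < 0:
        v1 = -v1
    if not (np.all(v1 > 0) or np.all(v1 < 0)):
        raise ValueError(
            "EF subtest loadings do not share a sign; no common EF component"
        )
    scores = Z @ v1
    return (scores - scores.mean()) / scores.std(ddof=1)


def residualize_confounds(
    metric: np.ndarray, age: np.ndarray, sex: np.ndarray
) -> np.ndarray:
    """OLS-residualize each node's metric on intercept + age + sex + age x sex.

    ``metric`` is subjects x nodes; ``sex`` may be {"F","M"} strings or 0/1
    codes.  The cognitive outcome is deliberately never passed through here.
    """
    Y = np.asarray(metric, dtype=float)
    age = np.asarray(age, dtype=float)
    sex = np.asarray(sex)
    if sex.dtype.kind in "UO":
        sex = (sex == "M").astype(float)
    sex = sex.astype(float)
    n = Y.shape[0]
    if age.shape != (n,) or sex.shape != (n,):
        raise ValueError("age/sex must have one entry per subject row of the metric matrix")
    design = np.column_stack([np.ones(n), age, sex, age * sex])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError(
            "confound design matrix (intercept, age, sex, age x sex) is rank deficient"
        )
    beta, *_ = np.linalg.lstsq(design, Y, rcond=None)
    return Y - design @ beta


def q_squared(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Cross-validated R²: Q² = 1 - PRESS/TSS from pooled out-of-fold predictions.

    PRESS = sum (yhat_i - y_i)²; TSS = sum (y_i - ybar)² with ybar the grand
    mean of the observed outcomes.  Q² can be negative (worse than predicting
    the mean) and is 1 only for perfect prediction.
    """
    y = np.asarray(y_true, dtype=float)
    yhat = np.asarray(y_pred, dtype=float)
    if y.shape != yhat.shape:
        raise ValueError("y_true and y_pred must have the same shape")
    tss = float(np.sum((y - y.mean()) ** 2))
    if tss == 0:
        raise ValueError("zero total sum of squares; outcome is constant")
    press = float(np.sum((yhat - y) ** 2))
    return 1.0 - press / tss


@dataclass
class PLSModel:
    """A fitted PLS1 model with nested coefficients for 1..n_components."""

    x_mean: np.ndarray
    x_sd: np.ndarray
    y_mean: float
    weights: np.ndarray  # p x A weight vectors (on the standardized scale)
    loadings: np.ndarray  # p x A predictor loadings
    y_loadings: np.ndarray  # A
    n_components: int

    def coef(self, c: int | None = None) -> np.ndarray:
        """Regression coefficients on the original predictor scale, c components."""
        c = self.n_components if c is None else c
        if not (1 <= c <= self.n_components):
            raise ValueError(f"components must be in [1, {self.n_components}], got {c}")
        W, P, q = self.weights[:, :c], self.loadings[:, :c], self.y_loadings[:c]
        B = W @ np.linalg.solve(P.T @ W, q)
        return B / self.x_sd

    def predict(self, X: np.ndarray, c: int | None = None) -> np.ndarray:
        b = self.coef(c)
        return (np.asarray(X, float) - self.x_mean) @ b + self.y_mean


def pls1_fit(
    X: np.ndarray, y: np.ndarray, n_components: int, scale: bool = True
) -> PLSModel:
    """Fit univariate-response PLS by NIPALS deflation.

    Predictors are standardized (sample SD) by default; the response is
    centered.  Components maximize predictor-response covariance; coefficients
    for any truncation c <= n_components are recoverable from one fit.  If the
    residual covariance vanishes early the component count is truncated.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite values in predictor matrix")
    n, p = X.shape
    if y.shape != (n,):
        raise ValueError("y must be 1-D with one entry per predictor row")
    x_mean = X.mean(axis=0)
    x_sd = X.std(axis=0, ddof=1) if scale else np.ones(p)
    x_sd = np.where(x_sd == 0, 1.0, x_sd)
    E = (X - x_mean) / x_sd
    y_mean = float(y.mean())
    f = y - y_mean

    max_c = min(n_components, n - 1, p)
    W = np.zeros((p, max_c))
    P = np.zeros((p, max_c))
    q = np.zeros(max_c)
    a = 0
    for _ in range(max_c):
        w = E.T @ f
        norm = np.linalg.norm(w)
        if norm < 1e-12:
            break
        w /= norm
        t = E @ w
        tt = float(t @ t)
        if tt < 1e-12:
            break
        p_a = E.T @ t / tt
        q_a = float(f @ t) / tt
        E = E - np.outer(t, p_a)
        f = f - q_a * t
        W[:, a], P[:, a], q[a] = w, p_a, q_a
        a += 1
    if a == 0:
        raise ValueError("no PLS component could be extracted (zero covariance)")
    return PLSModel(
        x_mean=x_mean,
        x_sd=x_sd,
        y_mean=y_mean,
        weights=W[:, :a],
        loadings=P[:, :a],
        y_loadings=q[:a],
        n_components=a,
    )


@dataclass
class PLSSelectionResult:
    """Outcome of repeated cross-validated PLS component selection."""

    selection_counts: dict[int, int]
    chosen_c: int
    q2_curve: np.ndarray  # mean Q² per candidate c over instances
    q2_at_chosen: float  # mean pooled Q² at chosen_c
    n_instances: int
    k_folds: int
    c_max: int
    stratified: bool = False
    weights: pd.DataFrame | None = None  # set by bootstrap_weights


def _kfold_indices(n: int, k: int, rng: np.random.Generator) -> list[np.ndarray]:
    perm = rng.permutation(n)
    return [fold for fold in np.array_split(perm, k)]


def _stratified_train(
    train_idx: np.ndarray, bins: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Equal-sized random samples per outcome bin from the training candidates."""
    groups = [train_idx[bins[train_idx] == b] for b in np.unique(bins)]
    m = min(len(g) for g in groups)
    if m < 1:
        raise ValueError("a stratification bin has no training subjects")
    picks = [rng.choice(g, size=m, replace=False) for g in groups]
    return np.sort(np.concatenate(picks))


def pls_cv_select(
    X: np.ndarray,
    y: np.ndarray,
    c_max: int = 10,
    n_instances: int = 100,
    k: int = 9,
    seed: int = 0,
    stratified: bool = False,
    n_bins: int = 4,
) -> PLSSelectionResult:
    """Select the PLS component count by repeated k-fold cross-validated Q².

    Per CV instance: a fresh random k-fold partition; for each candidate
    c = 0..c_max the held-out folds are predicted (c = 0 predicts the
    training-fold mean) and one pooled Q²(c) is computed; the argmax c is
    recorded.  The chosen count is the modal argmax over instances (ties go to
    the smaller c).  With ``stratified=True`` the outcome is discretized into
    ``n_bins`` equal-count bins and each training set is an equal-sized random
    sample per bin.  Deterministic under ``seed``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite values in predictor matrix")
    n = X.shape[0]
    if n < 2 * k:
        raise ValueError(f"need at least {2 * k} subjects for {k}-fold CV, got {n}")
    if c_max < 1:
        raise ValueError(f"c_max must be >= 1, got {c_max}")
    rng = np.random.default_rng(seed)

    bins = None
    if stratified:
        order = np.argsort(y, kind="stable")
        bins = np.empty(n, dtype=int)
        for b, chunk in enumerate(np.array_split(order, n_bins)):
            bins[chunk] = b

    counts = {c: 0 for c in range(c_max + 1)}
    q2_sum = np.zeros(c_max + 1)
    for _ in range(n_instances):
        folds = _kfold_indices(n, k, rng)
        preds = np.zeros((c_max + 1, n))
        for fold in folds:
            if fold.size < 1:
                raise ValueError("empty cross-validation fold")
            test_mask = np.zeros(n, dtype=bool)
            test_mask[fold] = True
            train_idx = np.flatnonzero(~test_mask)
            if train_idx.size < 2:
                raise ValueError("fewer than 2 training subjects in a fold")
            if stratified:
                train_idx = _stratified_train(train_idx, bins, rng)
            preds[0, fold] = y[train_idx].mean()
            model = pls1_fit(X[train_idx], y[train_idx], n_components=c_max)
            for c in range(1, c_max + 1):
                cc = min(c, model.n_components)
                preds[c, fold] = model.predict(X[fold], cc)
        q2 = np.array([q_squared(y, preds[c]) for c in range(c_max + 1)])
        q2_sum += q2
        counts[int(np.argmax(q2))] += 1  # argmax ties -> smaller c

    best = max(counts.values())
    chosen_c = min(c for c, v in counts.items() if v == best)
    q2_curve = q2_sum / n_instances
    return PLSSelectionResult(
        selection_counts=counts,
        chosen_c=chosen_c,
        q2_curve=q2_curve,
        q2_at_chosen=float(q2_curve[chosen_c]),
        n_instances=n_instances,
        k_folds=k,
        c_max=c_max,
        stratified=stratified,
    )


def bca_interval(
    boot: np.ndarray, point: float, jackknife: np.ndarray, alpha: float = 0.05
) -> tuple[float, float]:
    """Bias-corrected and accelerated bootstrap interval for one statistic.

    z0 comes from the fraction of bootstrap replicates below the point
    estimate; the acceleration a from the jackknife skewness.  With z0 = 0 and
    a = 0 this reduces to the percentile interval.
    """
    boot = np.asarray(boot, dtype=float)
    if boot.size == 0:
        raise ValueError("empty bootstrap distribution")
    if np.allclose(boot, boot[0]):
        return float(boot[0]), float(boot[0])
    prop = np.mean(boot < point)
    prop = min(max(prop, 1.0 / (boot.size + 1)), boot.size / (boot.size + 1.0))
    z0 = stats.norm.ppf(prop)
    jk = np.asarray(jackknife, dtype=float)
    diffs = jk.mean() - jk
    denom = np.sum(diffs**2) ** 1.5
    a = float(np.sum(diffs**3) / (6 * denom)) if denom > 0 else 0.0
    out = []
    for z in (stats.norm.ppf(alpha / 2), stats.norm.ppf(1 - alpha / 2)):
        adj = z0 + (z0 + z) / (1 - a * (z0 + z))
        out.append(float(np.percentile(boot, 100 * stats.norm.cdf(adj))))
    return out[0], out[1]


def bootstrap_weights(
    X: np.ndarray,
    y: np.ndarray,
    chosen_c: int,
    n_boot: int = 500,
    seed: int = 0,
    alpha: float = 0.05,
    region_labels: list[str] | None = None,
    resample: bool = True,
) -> pd.DataFrame:
    """Per-predictor PLS weights with BCa bootstrap confidence intervals.

    Subjects are resampled with replacement and the PLS refit with
    ``chosen_c`` components; each replicate's coefficient vector is
    sign-aligned to the point estimate (dot-product convention) before the
    intervals are formed.  ``resample=False`` degenerately refits the original
    sample every time (all intervals collapse to the point estimate).
    """
    if chosen_c < 1:
        raise ValueError("chosen_c = 0: no model was retained, nothing to bootstrap")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    rng = np.random.default_rng(seed)
    point = pls1_fit(X, y, chosen_c).coef()

    boots = np.empty((n_boot, p))
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n) if resample else np.arange(n)
        coef = pls1_fit(X[idx], y[idx], chosen_c).coef()
        if coef @ point < 0:
            coef = -coef
        boots[b] = coef

    jack = np.empty((n, p))
    for i in range(n):
        idx = np.delete(np.arange(n), i)
        coef = pls1_fit(X[idx], y[idx], chosen_c).coef()
        if coef @ point < 0:
            coef = -coef
        jack[i] = coef

    rows = []
    labels = region_labels or [f"node_{i:02d}" for i in range(p)]
    for j in range(p):
        lo, hi = bca_interval(boots[:, j], float(point[j]), jack[:, j], alpha=alpha)
        rows.append({"region": labels[j], "weight": float(point[j]), "ci_low": lo, "ci_high": hi})
    return pd.DataFrame(rows)
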