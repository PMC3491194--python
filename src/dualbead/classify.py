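"""Double cross-validated class probabilities and prediction-level fusion.

The base diagnostic rule per platform is linear discriminant analysis on
a principal-component reduction of the standardized peak matrix (the
standard regularization for p ≈ n spectra).  A nested (double)
cross-validation produces one held-out class probability per sample:

* the **outer** loop (leave-one-out or stratified k-fold) holds out each
  fold purely for assessment;
* for each outer training set the **inner** loop selects the number of
  principal components from a grid by minimum cross-validated deviance;
* a model with the selected dimension, fit on the full outer training
  set, scores the held-out samples.

No model ever sees the sample it scores — the resulting probability
vectors p¹ (WCX) and p² (RPC18) are honest inputs for the second level,
where the two platforms are fused *at the prediction level*:

* ``combine_mix`` — the linear mixture ``α·p¹ + (1−α)·p²`` with α chosen
  on a grid by minimum cross-validated deviance (its own CV layer over
  samples, so the reported combined probabilities are held-out too);
* ``combine_rf`` / ``combine_lg`` — a random forest, respectively a
  logistic regression, trained on the two probabilities under the same
  cross-validated scheme, as confirmatory combiners.

Standardization (and the optional log transform's companion statistics)
is always computed on training folds only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "CvConfig",
    "LdaModel",
    "CvProbabilityVector",
    "fit_lda",
    "double_cv_probabilities",
    "combine_mix",
    "combine_rf",
    "combine_lg",
    "deviance",
    "clip_probabilities",
]

log = logging.getLogger(__name__)

#: Probabilities are clipped into [eps, 1−eps] before any log-loss.
PROB_EPS = 1e-6


@dataclass(frozen=True)
class CvConfig:
    """Settings of the double-CV classifier and the combiners.

    ``outer_scheme`` is ``"loo"`` (leave-one-out) or ``"kfold"`` with
    ``outer_folds`` stratified folds; with ``outer_repeats`` > 1 the
    k-fold outer loop is repeated over fresh fold partitions and the
    held-out probabilities averaged per sample, which damps the
    fold-assignment noise that makes pooled cross-validated probabilities
    pessimistically ranked on weak signals.  ``component_grid`` lists the
    PCA dimensions the inner loop may pick; the entry 0 is the
    intercept-only null model (prior probabilities), so on uninformative
    data the rule can honestly decline to discriminate instead of chasing
    chance structure.  ``alpha_grid_size`` is the
    resolution of the mixture-weight grid on [0, 1].  ``priors`` is
    ``"cohort"`` (class proportions of the whole cohort — the study-design
    prevalence, constant across folds), ``"train"`` (proportions of each
    training fold) or ``"equal"``.  Cohort priors are the default: a
    training fold's prevalence is mechanically anti-correlated with its
    held-out fold's composition, which skews cross-validated
    probabilities against the minority class.
    """

    outer_scheme: str = "loo"
    outer_folds: int = 10
    outer_repeats: int = 1
    inner_folds: int = 5
    component_grid: tuple = (0, 1, 2, 5, 10)
    alpha_grid_size: int = 101
    combiner_folds: int = 10
    combiner_repeats: int = 1
    seed: int = 0
    log_transform: bool = True
    priors: str = "cohort"
    inner_criterion: str = "deviance"  # or "accuracy"
    inner_rule: str = "min"  # or "1se" (most parsimonious within one SE)

    def __post_init__(self):
        if self.inner_folds < 2:
            raise ValueError("inner_folds must be >= 2")
        if not self.component_grid:
            raise ValueError("component_grid must be non-empty")
        if self.outer_scheme not in ("loo", "kfold"):
            raise ValueError("outer_scheme must be 'loo' or 'kfold'")
        if self.priors not in ("cohort", "train", "equal"):
            raise ValueError("priors must be 'cohort', 'train' or 'equal'")


@dataclass
class CvProbabilityVector:
    """Per-sample held-out probabilities of class 'case'."""

    sample_ids: pd.Index
    p: np.ndarray
    platform_id: str = ""
    chosen_components: list = field(default_factory=list)

    def __post_init__(self):
        self.p = np.asarray(self.p, float)
        if np.any((self.p < 0) | (self.p > 1)):
            raise ValueError("probabilities must lie in [0, 1]")

    def __len__(self):
        return len(self.p)

    def series(self) -> pd.Series:
        return pd.Series(self.p, index=self.sample_ids, name=self.platform_id)


def clip_probabilities(p, eps: float = PROB_EPS) -> np.ndarray:
    return np.clip(np.asarray(p, float), eps, 1.0 - eps)


def deviance(p, y, eps: float = PROB_EPS) -> float:
    """−2 × log-likelihood of 0/1 labels under clipped probabilities."""
    p = clip_probabilities(p, eps)
    y = np.asarray(y, float)
    return float(-2.0 * np.sum(y * np.log(p) + (1.0 - y) * np.log1p(-p)))


# --------------------------------------------------------------------------
# Base classifier: standardization + PCA + Fisher LDA with Gaussian posteriors


@dataclass
class PriorModel:
    """Intercept-only rule: every sample receives the training prevalence."""

    p_case: float
    n_components: int = 0

    def predict_proba(self, X) -> np.ndarray:
        return np.full(np.atleast_2d(X).shape[0], self.p_case)

    def discriminant_direction(self) -> np.ndarray:
        return np.zeros(0)


@dataclass
class LdaModel:
    """PCA-reduced LDA fit: everything needed to score new samples."""

    feature_mean: np.ndarray
    feature_scale: np.ndarray
    components: np.ndarray  # (k, p) principal axes in standardized space
    class_means: np.ndarray  # (2, k) component-space class centroids
    cov_chol: tuple  # Cholesky factorization of the pooled covariance
    log_priors: np.ndarray  # (2,)
    n_components: int

    def transform(self, X) -> np.ndarray:
        Z = (np.asarray(X, float) - self.feature_mean) / self.feature_scale
        return Z @ self.components.T

    def predict_proba(self, X) -> np.ndarray:
        """Posterior probability of class 1 via Gaussian class-conditionals."""
        T = self.transform(np.atleast_2d(X))
        logp = np.empty((T.shape[0], 2))
        for c in (0, 1):
            d = T - self.class_means[c]
            q = np.sum(d * cho_solve(self.cov_chol, d.T).T, axis=1)
            logp[:, c] = self.log_priors[c] - 0.5 * q
        logp -= logp.max(axis=1, keepdims=True)
        w = np.exp(logp)
        return w[:, 1] / w.sum(axis=1)

    def discriminant_direction(self) -> np.ndarray:
        """Canonical discriminant direction in component space.

        ``Σ⁻¹(μ₁−μ₀)`` scaled to unit pooled within-class variance of the
        discriminant score; oriented so cases project higher.
        """
        delta = self.class_means[1] - self.class_means[0]
        w = cho_solve(self.cov_chol, delta)
        scale = float(np.sqrt(delta @ w))
        if scale > 0:
            w = w / scale
        return w


def fit_lda(X_train, y_train, n_components: int, priors="train",
            ridge: float = 1e-8) -> LdaModel:
    """Fit the standardized PCA + LDA model.

    ``priors`` is ``"train"`` (training proportions), ``"equal"``, or an
    explicit ``(p_control, p_case)`` pair (e.g. a fixed cohort
    prevalence).  The pooled within-class covariance on the components is
    the maximum likelihood (n-normalized) estimator, which makes the fit
    invariant to duplicating the training set.  A singular pooled
    covariance receives a logged ridge jitter of ``ridge × trace``.
    """
    X = np.asarray(X_train, float)
    y = np.asarray(y_train, int)
    n, p = X.shape
    n1 = int(y.sum())
    n0 = n - n1
    if n0 < 2 or n1 < 2:
        raise ValueError("each class needs at least two training samples")
    k = int(n_components)
    if not 1 <= k <= min(n - 2, p):
        raise ValueError(f"n_components must lie in [1, {min(n - 2, p)}]")

    mean = X.mean(axis=0)
    # standardize by the pooled *within-class* SD: scaling by the total SD
    # would normalize away exactly the between-class variance the principal
    # components must retain for a displaced peak to stay visible
    c0 = X[y == 0] - X[y == 0].mean(axis=0)
    c1 = X[y == 1] - X[y == 1].mean(axis=0)
    scale = np.sqrt((np.sum(c0 ** 2, axis=0) + np.sum(c1 ** 2, axis=0)) / n)
    scale[scale == 0] = 1.0
    Z = (X - mean) / scale
    _, _, Vt = np.linalg.svd(Z, full_matrices=False)
    comps = Vt[:k].copy()
    # deterministic sign convention: largest-magnitude loading positive
    lead = np.argmax(np.abs(comps), axis=1)
    signs = np.sign(comps[np.arange(k), lead])
    signs[signs == 0] = 1.0
    comps *= signs[:, None]

    T = Z @ comps.T
    m0 = T[y == 0].mean(axis=0)
    m1 = T[y == 1].mean(axis=0)
    d0 = T[y == 0] - m0
    d1 = T[y == 1] - m1
    S = (d0.T @ d0 + d1.T @ d1) / n  # pooled MLE covariance
    S = np.atleast_2d(S)
    try:
        chol = cho_factor(S, lower=True)
    except np.linalg.LinAlgError:
        jitter = ridge * np.trace(S)
        log.info("singular pooled covariance; adding ridge jitter %.3g", jitter)
        chol = cho_factor(S + jitter * np.eye(k), lower=True)
    if isinstance(priors, str):
        pri = np.array([0.5, 0.5]) if priors == "equal" \
            else np.array([n0 / n, n1 / n])
    else:
        pri = np.asarray(priors, float)
        if pri.shape != (2,) or not np.isclose(pri.sum(), 1.0):
            raise ValueError("explicit priors must be two probabilities summing to 1")
    return LdaModel(feature_mean=mean, feature_scale=scale, components=comps,
                    class_means=np.vstack([m0, m1]), cov_chol=chol,
                    log_priors=np.log(pri), n_components=k)


# --------------------------------------------------------------------------
# Fold machinery


def _as_matrix(X):
    """Accept a PeakMatrix, DataFrame or ndarray; return (ids, values)."""
    values = getattr(X, "values", None)
    if isinstance(values, pd.DataFrame):  # PeakMatrix
        return values.index, values.to_numpy(float)
    if isinstance(X, pd.DataFrame):
        return X.index, X.to_numpy(float)
    X = np.asarray(X, float)
    return pd.RangeIndex(X.shape[0]), X


def _derived_seed(rng) -> int:
    return int(rng.integers(0, 2 ** 31 - 1))


def _stratified_folds(y, n_folds, rng, max_attempts: int = 100):
    """Stratified folds whose training sides always hold both classes."""
    n_folds = min(n_folds, int(np.bincount(y, minlength=2).min()))
    if n_folds < 2:
        raise ValueError("too few samples per class for cross-validation")
    for _ in range(max_attempts):
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True,
                              random_state=_derived_seed(rng))
        folds = list(skf.split(np.zeros(len(y)), y))
        if all(len(np.unique(y[tr])) == 2 for tr, _ in folds):
            return folds
    raise RuntimeError("could not draw folds keeping both classes present")


def _outer_folds(y, cfg: CvConfig, rng):
    if cfg.outer_scheme == "loo":
        n = len(y)
        idx = np.arange(n)
        return [(np.delete(idx, i), np.array([i])) for i in range(n)]
    return _stratified_folds(y, cfg.outer_folds, rng)


def _fit_rule(X, y, k: int, priors):
    """Fit the k-component LDA rule; k = 0 is the prior-only null model."""
    if k == 0:
        if isinstance(priors, str):
            p_case = 0.5 if priors == "equal" else float(np.mean(np.asarray(y, int)))
        else:
            p_case = float(priors[1])
        return PriorModel(p_case)
    return fit_lda(X, y, k, priors=priors)


def _resolve_priors(cfg: CvConfig, y_full):
    """Turn the config's prior policy into what the fold fits receive."""
    if cfg.priors == "cohort":
        pi = float(np.mean(np.asarray(y_full, int)))
        return (1.0 - pi, pi)
    return cfg.priors


def _select_components(X, y, cfg: CvConfig, rng, priors=None) -> int:
    """Inner-CV choice of the PCA dimension (minimum deviance, ties → smaller)."""
    if priors is None:
        priors = _resolve_priors(cfg, y)
    n = X.shape[0]
    folds = _stratified_folds(y, cfg.inner_folds, rng)
    k_inner_max = min(len(tr) for tr, _ in folds) - 2
    kmax = min(k_inner_max, X.shape[1])
    ks = sorted({min(int(k), kmax) for k in cfg.component_grid if k >= 0})
    if not ks or (len(ks) == 1 and ks[0] == 0):
        raise ValueError("component grid empty after clipping to training size")
    if len(ks) == 1:
        return ks[0]
    # per-fold mean losses so the one-standard-error rule has a spread
    fold_loss = np.empty((len(ks), len(folds)))
    for i, k in enumerate(ks):
        for f, (tr, te) in enumerate(folds):
            model = _fit_rule(X[tr], y[tr], k, priors)
            p_hat = model.predict_proba(X[te])
            if cfg.inner_criterion == "accuracy":
                fold_loss[i, f] = float(np.mean((p_hat >= 0.5) != y[te]))
            else:
                fold_loss[i, f] = deviance(p_hat, y[te]) / len(te)
    mean_loss = fold_loss.mean(axis=1)
    best = int(np.argmin(mean_loss))  # first minimum → smallest k on ties
    if cfg.inner_rule == "min":
        return ks[best]
    # 1-SE rule: the most parsimonious model within one standard error of
    # the minimum — on uninformative data this settles on the null model
    # instead of chasing chance structure
    se = float(np.std(fold_loss[best], ddof=1) / np.sqrt(len(folds)))
    for i, k in enumerate(ks):
        if mean_loss[i] <= mean_loss[best] + se:
            return k
    return ks[best]


# --------------------------------------------------------------------------
# Double CV per platform


def double_cv_probabilities(X, y, cfg: CvConfig,
                            platform_id: str | None = None) -> CvProbabilityVector:
    """One honest held-out class probability per sample.

    ``X`` may be a :class:`~dualbead.quantify.PeakMatrix`, a DataFrame or
    an array (samples × peaks, no missing values); ``y`` holds 0/1 labels.
    Identical inputs and seed reproduce identical probabilities.
    """
    ids, Xv = _as_matrix(X)
    y = np.asarray(y, int)
    if Xv.shape[0] != len(y):
        raise ValueError("X and y sample counts differ")
    if np.isnan(Xv).any():
        raise ValueError("peak matrix contains missing values")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    if cfg.log_transform:
        if np.any(Xv < 0):
            raise ValueError("log_transform requires non-negative "
                             "intensities; disable it for general features")
        Xv = np.log1p(Xv)
    if platform_id is None:
        platform_id = getattr(X, "platform_id", "") or ""

    rng = np.random.default_rng(cfg.seed)
    priors = _resolve_priors(cfg, y)
    repeats = cfg.outer_repeats if cfg.outer_scheme == "kfold" else 1
    p_sum = np.zeros(len(y))
    chosen = []
    for _ in range(max(1, repeats)):
        folds = _outer_folds(y, cfg, rng)
        p = np.full(len(y), np.nan)
        for tr, te in folds:
            k = _select_components(Xv[tr], y[tr], cfg, rng, priors)
            model = _fit_rule(Xv[tr], y[tr], k, priors)
            p[te] = model.predict_proba(Xv[te])
            chosen.append(k)
        assert not np.isnan(p).any()
        p_sum += p
    p = p_sum / max(1, repeats)
    return CvProbabilityVector(sample_ids=ids, p=p, platform_id=platform_id,
                               chosen_components=chosen)


# --------------------------------------------------------------------------
# Prediction-level combiners


def _check_aligned(p1: CvProbabilityVector, p2: CvProbabilityVector):
    if list(p1.sample_ids) != list(p2.sample_ids):
        only1 = set(p1.sample_ids) - set(p2.sample_ids)
        only2 = set(p2.sample_ids) - set(p1.sample_ids)
        raise ValueError(
            "probability vectors are not aligned on the same samples; "
            f"only in first: {sorted(only1)}; only in second: {sorted(only2)}")


def _pick_alpha(devs, alphas) -> float:
    devs = np.asarray(devs, float)
    m = devs.min()
    cand = np.flatnonzero(devs <= m + 1e-9)
    best = cand[np.argmin(np.abs(alphas[cand] - 0.5))]
    return float(alphas[best])


def _combiner_partitions(y, cfg: CvConfig, tag: int):
    """Fold partitions for a combiner's own CV layer (repeated, seeded)."""
    ss = np.random.SeedSequence([cfg.seed, tag])
    rng = np.random.default_rng(ss)
    return [_stratified_folds(y, cfg.combiner_folds, rng)
            for _ in range(max(1, cfg.combiner_repeats))]


def combine_mix(p1: CvProbabilityVector, p2: CvProbabilityVector, y,
                cfg: CvConfig, alphas=None):
    """Linear mixture of the two platforms' probability vectors.

    ``p_mix(α) = α·p¹ + (1−α)·p²`` with α selected by minimum deviance on
    a grid, inside its own stratified CV layer over samples: each fold's α
    is chosen on the training part and applied to the held-out part, so
    the reported combined probabilities are cross-validated.  Ties in the
    grid argmin break toward α = 0.5 (the most even blend).

    Each fold's candidate set also contains the prior-only constant; the
    fitted mixture is used only when it beats that constant on the
    training part by at least one standard error of the paired per-sample
    deviance difference.  Two uninformative inputs therefore combine to an
    honestly flat prediction instead of re-fitted noise; with any real
    signal the constant never wins.

    Returns ``(combined, alpha)`` where ``alpha`` is the tie-broken argmin
    over the full sample set (the reportable mixing weight).
    """
    _check_aligned(p1, p2)
    y = np.asarray(y, int)
    if alphas is None:
        alphas = np.linspace(0.0, 1.0, cfg.alpha_grid_size)
    else:
        alphas = np.asarray(alphas, float)
    a1, a2 = p1.p, p2.p
    prior = float(np.mean(y))

    def devs_on(idx):
        mix = alphas[:, None] * a1[idx] + (1 - alphas[:, None]) * a2[idx]
        pm = clip_probabilities(mix)
        yy = y[idx]
        return -2.0 * np.sum(yy * np.log(pm) + (1 - yy) * np.log1p(-pm), axis=1)

    def sample_dev(p, yy):
        p = clip_probabilities(p)
        return -2.0 * (yy * np.log(p) + (1 - yy) * np.log1p(-p))

    if len(alphas) == 1:
        alpha_full = float(alphas[0])
        p_out = alpha_full * a1 + (1 - alpha_full) * a2
    else:
        partitions = _combiner_partitions(y, cfg, tag=101)
        p_sum = np.zeros(len(y))
        for folds in partitions:
            p_rep = np.empty(len(y))
            for tr, te in folds:
                a = _pick_alpha(devs_on(tr), alphas)
                d_mix = sample_dev(a * a1[tr] + (1 - a) * a2[tr], y[tr])
                d_pri = sample_dev(np.full(len(tr), prior), y[tr])
                diff = d_mix - d_pri
                se = float(np.std(diff, ddof=1)) * np.sqrt(len(tr))
                if diff.sum() <= -se:
                    p_rep[te] = a * a1[te] + (1 - a) * a2[te]
                else:
                    p_rep[te] = prior
            p_sum += p_rep
        p_out = p_sum / len(partitions)
        alpha_full = _pick_alpha(devs_on(np.arange(len(y))), alphas)
    combined = CvProbabilityVector(sample_ids=p1.sample_ids, p=p_out,
                                   platform_id="MIX")
    return combined, alpha_full


def _combine_sklearn(p1, p2, y, cfg, estimator_factory, tag, label):
    _check_aligned(p1, p2)
    y = np.asarray(y, int)
    F = np.column_stack([p1.p, p2.p])
    partitions = _combiner_partitions(y, cfg, tag=tag)
    p_sum = np.zeros(len(y))
    for folds in partitions:
        p_rep = np.empty(len(y))
        for tr, te in folds:
            est = estimator_factory()
            est.fit(F[tr], y[tr])
            p_rep[te] = est.predict_proba(F[te])[:, 1]
        p_sum += p_rep
    return CvProbabilityVector(sample_ids=p1.sample_ids, p=p_sum / len(partitions),
                               platform_id=label)


def combine_rf(p1: CvProbabilityVector, p2: CvProbabilityVector, y,
               cfg: CvConfig) -> CvProbabilityVector:
    """Random-forest combination of the two probability vectors (seeded)."""
    seed = int(np.random.SeedSequence([cfg.seed, 202]).generate_state(1)[0]
               % (2 ** 31))
    return _combine_sklearn(
        p1, p2, y, cfg,
        lambda: RandomForestClassifier(n_estimators=300, min_samples_leaf=5,
                                       random_state=seed),
        tag=102, label="RF")


def combine_lg(p1: CvProbabilityVector, p2: CvProbabilityVector, y,
               cfg: CvConfig) -> CvProbabilityVector:
    """Logistic-regression calibration on the two probability vectors.

    Essentially unregularized (C = 1e6): the two features are themselves
    probabilities, so shrinkage is unnecessary and would blunt calibration.
    """
    return _combine_sklearn(
        p1, p2, y, cfg,
        lambda: LogisticRegression(C=1e6, max_iter=10000),
        tag=103, label="LG")
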