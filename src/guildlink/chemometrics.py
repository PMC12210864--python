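"""From-scratch PLS-DA and OPLS-DA with VIP scores and permutation validation.

Two-class discriminant models fitted by NIPALS on a single centred {0,1}
response (PLS1). OPLS-DA follows the orthogonal-signal-correction scheme of
Trygg & Wold: variation in X orthogonal to y is peeled off into dedicated
components before a single predictive component is extracted, so class
separation concentrates on the first (predictive) score axis.

Model quality is reported as R²X/R²Y (explained variation) and Q²
(cross-validated predictive ability, venetian-blinds folds), and model
validity is assessed by refitting under random label permutations.

Sign convention: within each component the loading entry of largest
magnitude is made positive, so fits are bit-reproducible across runs.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np

logger = logging.getLogger("guildlink")

_EPS = 1e-12


@dataclasses.dataclass
class ModelSpec:
    """Frozen description of a model structure, used for CV and permutations."""

    kind: str = "plsda"          # plsda | oplsda
    n_components: int = 1        # predictive components (plsda); oplsda has 1
    n_orth: int = 0              # orthogonal components (oplsda only)
    cv_folds: int = 7
    cv_seed: int = 0
    scale: bool = False          # unit-variance scale X internally


@dataclasses.dataclass
class FitModel:
    """Fitted PLS-DA / OPLS-DA state."""

    model_kind: str
    n: int
    p: int
    weights: np.ndarray          # (A_pred, p), rows unit norm
    x_loadings: np.ndarray       # (A_pred, p)
    y_loadings: np.ndarray       # (A_pred,)
    scores: np.ndarray           # (A_pred, n)
    orth_weights: np.ndarray     # (A_orth, p)
    orth_loadings: np.ndarray    # (A_orth, p)
    orth_scores: np.ndarray      # (A_orth, n)
    x_mean: np.ndarray
    x_scale: np.ndarray
    y_mean: float
    r2x: float
    r2y: float
    q2: float
    r2y_per_component: np.ndarray
    vip: np.ndarray

    @property
    def n_predictive(self) -> int:
        return self.weights.shape[0]

    @property
    def n_orthogonal(self) -> int:
        return self.orth_weights.shape[0]

    def transform(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Predictive and orthogonal scores for new observations."""
        Xc = (np.asarray(X, float) - self.x_mean) / self.x_scale
        t_orth = np.empty((self.n_orthogonal, Xc.shape[0]))
        for k in range(self.n_orthogonal):
            t_o = Xc @ self.orth_weights[k]
            t_orth[k] = t_o
            Xc = Xc - np.outer(t_o, self.orth_loadings[k])
        t_pred = np.empty((self.n_predictive, Xc.shape[0]))
        for a in range(self.n_predictive):
            t = Xc @ self.weights[a]
            t_pred[a] = t
            Xc = Xc - np.outer(t, self.x_loadings[a])
        return t_pred, t_orth

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Continuous prediction of the centred-{0,1} response plus its mean."""
        t_pred, _ = self.transform(X)
        return self.y_mean + self.y_loadings @ t_pred


def encode_labels(y) -> np.ndarray:
    """Map a two-class label vector to {0,1} floats (case=1 if labels are
    case/control; otherwise the lexicographically larger label is 1)."""
    y = np.asarray(y)
    if y.dtype.kind in "fiub":
        vals = np.unique(y)
        if not set(vals.tolist()) <= {0, 1, 0.0, 1.0, True, False}:
            raise ValueError("numeric labels must be 0/1")
        return y.astype(float)
    classes = sorted(np.unique(y).tolist())
    if len(classes) != 2:
        raise ValueError(f"need exactly two classes, got {classes}")
    if set(classes) == {"case", "control"}:
        positive = "case"
    else:
        positive = classes[1]
    return (y == positive).astype(float)


def _check_xy(X, y):
    X = np.asarray(X, dtype=float)
    y = encode_labels(y)
    if X.ndim != 2:
        raise ValueError("X must be a 2-D matrix (samples × features)")
    if X.shape[0] != y.shape[0]:
        raise ValueError("X and y disagree on the number of samples")
    if X.shape[1] == 0:
        raise ValueError("X has no features")
    if len(np.unique(y)) < 2:
        raise ValueError("only one class present")
    return X, y


def _center_scale(X, scale: bool):
    mean = X.mean(axis=0)
    if scale:
        sd = X.std(axis=0, ddof=1)
        sd = np.where(sd == 0, 1.0, sd)
    else:
        sd = np.ones(X.shape[1])
    return (X - mean) / sd, mean, sd


def _fix_sign(w, t, p_load, q=None):
    j = int(np.argmax(np.abs(p_load)))
    if p_load[j] < 0:
        w, t, p_load = -w, -t, -p_load
        if q is not None:
            q = -q
    return w, t, p_load, q


def _nipals_sweep(Xc, yc, n_comp):
    """Extract up to n_comp PLS1 components from centred data."""
    X = Xc.copy()
    y = yc.copy()
    W, P, Q, T = [], [], [], []
    for _ in range(n_comp):
        w = X.T @ y
        nw = np.linalg.norm(w)
        if nw < _EPS:
            break
        w = w / nw
        t = X @ w
        tt = t @ t
        if tt < _EPS:
            break
        p_load = X.T @ t / tt
        q = (y @ t) / tt
        w, t, p_load, q = _fix_sign(w, t, p_load, q)
        X = X - np.outer(t, p_load)
        y = y - q * t
        W.append(w); P.append(p_load); Q.append(q); T.append(t)
    return (np.array(W), np.array(P), np.array(Q), np.array(T), X, y)


def _opls_orth_sweep(Xc, yc, n_orth):
    """Peel off up to n_orth y-orthogonal components (Trygg–Wold OSC)."""
    X = Xc.copy()
    Wo, Po, To = [], [], []
    for _ in range(n_orth):
        w = X.T @ yc
        nw = np.linalg.norm(w)
        if nw < _EPS:
            break
        w = w / nw
        t = X @ w
        tt = t @ t
        if tt < _EPS:
            break
        p_load = X.T @ t / tt
        w_o = p_load - (w @ p_load) * w
        n_wo = np.linalg.norm(w_o)
        if n_wo < _EPS:
            break   # no structured orthogonal variation left
        w_o = w_o / n_wo
        t_o = X @ w_o
        p_o = X.T @ t_o / (t_o @ t_o)
        w_o, t_o, p_o, _ = _fix_sign(w_o, t_o, p_o)
        X = X - np.outer(t_o, p_o)
        Wo.append(w_o); Po.append(p_o); To.append(t_o)
    return np.array(Wo), np.array(Po), np.array(To), X


def _fit_fixed(X, y, spec: ModelSpec) -> FitModel:
    """Fit with a fixed component structure (no CV-driven selection)."""
    X, y = _check_xy(X, y)
    n, p = X.shape
    Xc, x_mean, x_scale = _center_scale(X, spec.scale)
    y_mean = y.mean()
    yc = y - y_mean
    ss_y = yc @ yc
    ss_x = (Xc ** 2).sum()

    if spec.kind == "oplsda":
        Wo, Po, To, Xf = _opls_orth_sweep(Xc, yc, spec.n_orth)
        W, P, Q, T, X_res, y_res = _nipals_sweep(Xf, yc, 1)
    elif spec.kind == "plsda":
        Wo = np.empty((0, p)); Po = np.empty((0, p)); To = np.empty((0, n))
        W, P, Q, T, X_res, y_res = _nipals_sweep(Xc, yc, spec.n_components)
    else:
        raise ValueError(f"unknown model kind {spec.kind!r}")
    if W.shape[0] == 0:
        raise ValueError("no predictive component could be extracted (X'y ~ 0)")

    r2y_cum = []
    resid = yc.copy()
    for a in range(W.shape[0]):
        resid = resid - Q[a] * T[a]
        r2y_cum.append(1.0 - (resid @ resid) / ss_y if ss_y > 0 else 0.0)
    r2y = r2y_cum[-1]
    explained_x = ss_x - (X_res ** 2).sum()
    r2x = explained_x / ss_x if ss_x > 0 else 0.0

    model = FitModel(
        model_kind=spec.kind, n=n, p=p,
        weights=W, x_loadings=P, y_loadings=Q, scores=T,
        orth_weights=Wo, orth_loadings=Po, orth_scores=To,
        x_mean=x_mean, x_scale=x_scale, y_mean=float(y_mean),
        r2x=float(r2x), r2y=float(r2y), q2=np.nan,
        r2y_per_component=np.array(r2y_cum),
        vip=np.empty(0),
    )
    model.vip = vip_scores(model)
    return model


def vip_scores(model: FitModel) -> np.ndarray:
    """Variable importance in projection over the predictive components.

    VIP_j = sqrt( p * sum_a SS_a w_ja^2 / sum_a SS_a ) with
    SS_a = q_a^2 t_a' t_a; the mean of VIP^2 over features is 1 by
    construction.
    """
    if model.weights.size == 0:
        raise ValueError("model has no fitted components")
    ss = model.y_loadings ** 2 * np.einsum("an,an->a", model.scores, model.scores)
    total = ss.sum()
    if total < _EPS:
        return np.zeros(model.p)
    contrib = (ss[:, None] * model.weights ** 2).sum(axis=0) / total
    return np.sqrt(model.p * contrib)


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------

def _venetian_folds(y: np.ndarray, cv_folds: int, seed: int) -> np.ndarray:
    """Deterministic interleaved fold assignment; every fold must hold both
    classes (refolds with a shifted seed and a warning if not)."""
    n = len(y)
    folds_n = min(cv_folds, n)
    fallback = None
    for attempt in range(50):
        rng = np.random.default_rng(seed + 1000 * attempt)
        order = rng.permutation(n)
        fold = np.empty(n, dtype=int)
        fold[order] = np.arange(n) % folds_n
        trains_ok = all(len(np.unique(y[fold != f])) == 2 for f in range(folds_n))
        if not trains_ok:
            continue
        if all(len(np.unique(y[fold == f])) == 2 for f in range(folds_n)):
            if attempt > 0:
                logger.warning("refolded CV %d times to get both classes per fold",
                               attempt)
            return fold
        if fallback is None:
            fallback = fold
    if fallback is not None:
        # tiny folds cannot always hold both classes; training sets do
        logger.warning("CV folds are single-class in places; training sets "
                       "retain both classes")
        return fallback
    raise ValueError("could not build CV folds whose training sets contain "
                     "both classes")


def cross_validated_q2(X, y, spec: ModelSpec | None = None,
                       cv_folds: int | None = None) -> float:
    """Q² = 1 - PRESS/SS with SS about the centred response.

    Folds are interleaved ("venetian blinds") over a seeded shuffle of the
    sample order; each held-out fold is predicted from a model refitted on
    the remainder.
    """
    spec = spec or ModelSpec()
    if cv_folds is not None:
        spec = dataclasses.replace(spec, cv_folds=cv_folds)
    X, y = _check_xy(X, y)
    fold = _venetian_folds(y, spec.cv_folds, spec.cv_seed)
    press = 0.0
    for f in np.unique(fold):
        train = fold != f
        test = ~train
        m = _fit_fixed(X[train], y[train], spec)
        yhat = m.predict(X[test])
        press += ((y[test] - yhat) ** 2).sum()
    ss = ((y - y.mean()) ** 2).sum()
    return float(1.0 - press / ss)


# ---------------------------------------------------------------------------
# public fitting interfaces (CV-driven structure selection)
# ---------------------------------------------------------------------------

def fit_plsda(X, y, max_components: int = 5, cv_folds: int = 7,
              scale: bool = False, q2_gain: float = 0.01,
              cv_seed: int = 0) -> FitModel:
    """PLS-DA on a centred {0,1} response.

    Components are added while the cross-validated Q² improves by more than
    ``q2_gain``, up to ``max_components``; at least one component is always
    fitted. Deterministic for fixed inputs and ``cv_seed``.
    """
    X, y = _check_xy(X, y)
    best_a, best_q2 = 1, cross_validated_q2(
        X, y, ModelSpec("plsda", 1, cv_folds=cv_folds, cv_seed=cv_seed, scale=scale))
    for a in range(2, max_components + 1):
        q2 = cross_validated_q2(
            X, y, ModelSpec("plsda", a, cv_folds=cv_folds, cv_seed=cv_seed, scale=scale))
        if q2 - best_q2 > q2_gain:
            best_a, best_q2 = a, q2
        else:
            break
    spec = ModelSpec("plsda", best_a, cv_folds=cv_folds, cv_seed=cv_seed, scale=scale)
    model = _fit_fixed(X, y, spec)
    model.q2 = best_q2
    return model


def fit_oplsda(X, y, n_orth: int | str = "auto", max_orth: int = 5,
               cv_folds: int = 7, scale: bool = False, q2_gain: float = 0.01,
               cv_seed: int = 0) -> FitModel:
    """OPLS-DA: orthogonal components then a single predictive component.

    With ``n_orth="auto"`` orthogonal components are added while the
    cross-validated Q² improves by more than ``q2_gain``.
    """
    X, y = _check_xy(X, y)
    if n_orth == "auto":
        best_k, best_q2 = 0, cross_validated_q2(
            X, y, ModelSpec("oplsda", 1, 0, cv_folds, cv_seed, scale))
        for k in range(1, max_orth + 1):
            q2 = cross_validated_q2(
                X, y, ModelSpec("oplsda", 1, k, cv_folds, cv_seed, scale))
            if q2 - best_q2 > q2_gain:
                best_k, best_q2 = k, q2
            else:
                break
        chosen, q2 = best_k, best_q2
    else:
        chosen = int(n_orth)
        q2 = cross_validated_q2(
            X, y, ModelSpec("oplsda", 1, chosen, cv_folds, cv_seed, scale))
    spec = ModelSpec("oplsda", 1, chosen, cv_folds, cv_seed, scale)
    model = _fit_fixed(X, y, spec)
    model.q2 = q2
    return model


def fit_from_spec(X, y, spec: ModelSpec) -> FitModel:
    """Fit with the exact structure in ``spec`` and attach its CV Q²."""
    model = _fit_fixed(X, y, spec)
    model.q2 = cross_validated_q2(X, y, spec)
    return model


# ---------------------------------------------------------------------------
# permutation validation
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class PermutationReport:
    """Label-permutation validation of a discriminant model."""

    n_perm: int
    r2y_orig: float
    q2_orig: float
    correlations: np.ndarray   # Pearson r between permuted and original y
    r2y_perm: np.ndarray
    q2_perm: np.ndarray
    p_q2: float                # (count(Q2_perm >= Q2_orig)+1)/(n_perm+1)
    all_perm_below: bool
    q2_intercept: float        # Q2 regression value at label-correlation 0
    valid: bool


def permutation_test(X, y, spec: ModelSpec | None = None, n_perm: int = 99,
                     seed: int = 0) -> PermutationReport:
    """Refit under ``n_perm`` random label permutations.

    Validity requires every permuted Q² to fall below the original and the
    regression of Q² on label correlation to intercept at or below 0.05.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    spec = spec or ModelSpec()
    X, y = _check_xy(X, y)
    orig = fit_from_spec(X, y, spec)
    rng = np.random.default_rng(seed)
    yc = y - y.mean()
    denom = yc @ yc
    corrs = np.empty(n_perm)
    r2s = np.empty(n_perm)
    q2s = np.empty(n_perm)
    for i in range(n_perm):
        yp = rng.permutation(y)
        ypc = yp - yp.mean()
        corrs[i] = (ypc @ yc) / denom if denom > 0 else 0.0
        m = fit_from_spec(X, yp, spec)
        r2s[i] = m.r2y
        q2s[i] = m.q2
    p_q2 = (int((q2s >= orig.q2).sum()) + 1) / (n_perm + 1)
    all_below = bool((q2s < orig.q2).all())
    xs = np.concatenate([np.abs(corrs), [1.0]])
    ys = np.concatenate([q2s, [orig.q2]])
    slope, intercept = np.polyfit(xs, ys, 1)
    valid = all_below and intercept <= 0.05
    return PermutationReport(
        n_perm=n_perm, r2y_orig=orig.r2y, q2_orig=orig.q2,
        correlations=corrs, r2y_perm=r2s, q2_perm=q2s,
        p_q2=float(p_q2), all_perm_below=all_below,
        q2_intercept=float(intercept), valid=valid,
    )
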