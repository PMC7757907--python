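"""Presence-background maximum-entropy niche model.

The model estimates a Gibbs density over environmental feature space,

    q_lambda(x) = exp(lambda . f(x)) / Z,

normalized over a finite point universe (background sample plus the
presence points), by maximizing the L1-penalized average presence
log-likelihood

    (1/m) sum_presences log q_lambda(x_i)  -  sum_j beta_j |lambda_j|.

Features f are the linear, quadratic and hinge transforms of the
covariates, each rescaled to [0, 1]. The optimizer is cyclic coordinate
descent with a Newton step per coordinate, soft-thresholding for the L1
term, and backtracking so the penalized objective never decreases; the
per-coordinate objective gains double as the bookkeeping behind
percent-contribution scores. Predictions use the logistic output
p = e^H q / (1 + e^H q), with H the entropy of the fitted raw
distribution, so that a completely uninformative model scores 0.5
everywhere.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .occurrences import OccurrenceSet
from .raster import PredictorStack, RasterGrid

logger = logging.getLogger(__name__)

FEATURE_CLASSES = ("linear", "quadratic", "hinge")

# Base L1 penalty per feature class. The per-feature penalty is
# beta_j = base_class * reg_multiplier * s_j / sqrt(m), where s_j is the
# feature's standard deviation over the presence sample (floored so that
# features absent from every presence stay penalized) and m the presence
# count — an error-bound-style scaling: coefficients move only when the
# presence mean of a feature differs from its background expectation by
# more than roughly its standard error.
BASE_BETA = {"linear": 1.0, "quadratic": 1.0, "hinge": 0.5}
MIN_FEATURE_SD = 0.05


@dataclass(frozen=True)
class FeatureSpec:
    """Which response-curve shapes to allow, and the covariate scaling.

    ``var_min``/``var_max`` (filled at fit time from the training universe)
    rescale each covariate to [0, 1] before feature expansion; prediction
    inputs outside the training range are clamped.
    """

    classes: tuple[str, ...] = ("linear", "quadratic", "hinge")
    hinge_knots: int = 20
    var_names: tuple[str, ...] = ()
    var_min: tuple[float, ...] = ()
    var_max: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if not self.classes:
            raise ValueError("at least one feature class is required")
        bad = [c for c in self.classes if c not in FEATURE_CLASSES]
        if bad:
            raise ValueError(f"unknown feature classes: {bad}")
        if "hinge" in self.classes and self.hinge_knots < 1:
            raise ValueError("hinge_knots must be >= 1 when hinge features are enabled")

    def with_scaling(self, names, mins, maxs) -> "FeatureSpec":
        return replace(
            self,
            var_names=tuple(names),
            var_min=tuple(float(v) for v in mins),
            var_max=tuple(float(v) for v in maxs),
        )


def fit_scaling(X: np.ndarray, names: list[str], spec: FeatureSpec) -> FeatureSpec:
    """Record per-variable min/max from the training universe."""
    X = np.asarray(X, dtype=float)
    return spec.with_scaling(names, X.min(axis=0), X.max(axis=0))


def build_features(X: np.ndarray, spec: FeatureSpec, clamp_warn: bool = False):
    """Expand raw covariates into the model's feature matrix.

    Columns, per variable: ``linear`` x, ``quadratic`` x^2, forward hinges
    max(0, (x-k)/(1-k)) and reverse hinges max(0, (k-x)/k) at
    ``hinge_knots`` evenly spaced interior knots. All features live in
    [0, 1]. Variables that were constant on the training universe
    (min == max) contribute no features (warned).

    Returns ``(F, feature_var, feature_names)`` where ``feature_var[j]``
    is the index of the variable owning column j.
    """
    if not spec.var_names:
        raise ValueError("FeatureSpec has no scaling; call fit_scaling first")
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != len(spec.var_names):
        raise ValueError(f"X must be (n, {len(spec.var_names)}), got {X.shape}")

    knots = np.arange(1, spec.hinge_knots + 1) / (spec.hinge_knots + 1)
    cols, owners, names = [], [], []
    for v, name in enumerate(spec.var_names):
        lo, hi = spec.var_min[v], spec.var_max[v]
        if hi <= lo:
            warnings.warn(f"variable {name!r} constant on training data; features dropped")
            continue
        x = (X[:, v] - lo) / (hi - lo)
        out_of_range = (x < 0) | (x > 1)
        if clamp_warn and out_of_range.any():
            logger.info("variable %r: %d values outside the training range, clamped",
                        name, int(out_of_range.sum()))
        x = np.clip(x, 0.0, 1.0)
        if "linear" in spec.classes:
            cols.append(x)
            owners.append(v)
            names.append(f"{name}:linear")
        if "quadratic" in spec.classes:
            cols.append(x**2)
            owners.append(v)
            names.append(f"{name}:quadratic")
        if "hinge" in spec.classes:
            for k in knots:
                cols.append(np.maximum(0.0, (x - k) / (1.0 - k)))
                owners.append(v)
                names.append(f"{name}:hinge_fwd@{k:.3f}")
            for k in knots:
                cols.append(np.maximum(0.0, (k - x) / k))
                owners.append(v)
                names.append(f"{name}:hinge_rev@{k:.3f}")
    if not cols:
        raise ValueError("no usable features (all variables constant)")
    return np.column_stack(cols), np.asarray(owners), names


@dataclass
class EnmModel:
    """A fitted maximum-entropy niche model."""

    spec: FeatureSpec
    lambdas: np.ndarray
    betas: np.ndarray
    feature_var: np.ndarray
    feature_names: list[str]
    reg_multiplier: float
    log_z: float  # log normalizer over the training universe
    entropy: float  # H of the fitted raw distribution, in nats
    n_universe: int
    n_presence: int
    gain_trace: np.ndarray  # penalized objective after each sweep
    var_credit: np.ndarray  # per-variable objective-improvement credit
    converged: bool
    background_X: np.ndarray  # raw covariates of the background sample
    presence_X: np.ndarray  # raw covariates of the training presences

    def raw_scores(self, X: np.ndarray) -> np.ndarray:
        """Unnormalized log-density lambda . f(x) at raw covariate rows."""
        F, _, _ = build_features(X, self.spec, clamp_warn=True)
        return F @ self.lambdas

    def raw_density(self, X: np.ndarray) -> np.ndarray:
        """Gibbs density relative to the training universe (sums to 1 there)."""
        return np.exp(self.raw_scores(X) - self.log_z)

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Logistic output p = e^H q / (1 + e^H q) at raw covariate rows."""
        # work in logs: logit(p) = H + log q
        logit = self.entropy + self.raw_scores(X) - self.log_z
        return 1.0 / (1.0 + np.exp(-logit))


def sample_background(stack: PredictorStack, n: int = 10_000, seed: int | None = None) -> pd.DataFrame:
    """Uniform seeded sample of valid cells (without replacement).

    Returns a frame with the cell-center ``lon``/``lat`` and one column per
    stack layer. If fewer than ``n`` valid cells exist, all are returned.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rows, cols = np.nonzero(stack.valid)
    if rows.size == 0:
        raise ValueError("stack has no valid cells to sample")
    rng = np.random.default_rng(seed)
    if rows.size > n:
        pick = rng.choice(rows.size, size=n, replace=False)
        rows, cols = rows[pick], cols[pick]
    lon, lat = stack.transform.cell_center(rows, cols)
    out = pd.DataFrame({"lon": lon, "lat": lat})
    X = stack.table(rows, cols)
    for k, name in enumerate(stack.names):
        out[name] = X[:, k]
    return out


def extract_at_points(stack: PredictorStack, occ: OccurrenceSet) -> pd.DataFrame:
    """Layer values at the cells containing each occurrence (invalid cells dropped)."""
    lon, lat = occ.lon, occ.lat
    inside = stack.transform.contains(lon, lat)
    rows, cols = stack.transform.index_of(lon[inside], lat[inside])
    ok = stack.valid[rows, cols]
    if not np.all(inside) or not np.all(ok):
        n_bad = int((~inside).sum() + (~ok).sum())
        logger.warning("%d occurrences fall outside the valid grid and are dropped", n_bad)
    rows, cols = rows[ok], cols[ok]
    lon_in, lat_in = lon[inside][ok], lat[inside][ok]
    out = pd.DataFrame({"lon": lon_in, "lat": lat_in})
    X = stack.table(rows, cols)
    for k, name in enumerate(stack.names):
        out[name] = X[:, k]
    return out


def split_presences(occ: OccurrenceSet, train_frac: float = 0.75, seed: int | None = None):
    """Seeded random 75/25-style partition of an occurrence set."""
    n = len(occ)
    if n < 4:
        raise ValueError(f"need >= 4 records to split, got {n}")
    rng = np.random.default_rng(seed)
    n_train = int(round(train_frac * n))
    perm = rng.permutation(n)
    train_idx, test_idx = np.sort(perm[:n_train]), np.sort(perm[n_train:])
    train = OccurrenceSet(records=occ.records.iloc[train_idx].reset_index(drop=True),
                          provenance=[*occ.provenance])
    test = OccurrenceSet(records=occ.records.iloc[test_idx].reset_index(drop=True),
                         provenance=[*occ.provenance])
    return train, test


def auc(scores_presence, scores_background) -> float:
    """Rank-sum (Mann–Whitney) AUC with half credit for ties."""
    sp = np.asarray(scores_presence, dtype=float)
    sb = np.asarray(scores_background, dtype=float)
    if sp.size == 0 or sb.size == 0:
        raise ValueError("both score sets must be non-empty")
    from scipy.stats import rankdata

    ranks = rankdata(np.concatenate([sp, sb]))
    r_pres = ranks[: sp.size].sum()
    u = r_pres - sp.size * (sp.size + 1) / 2.0
    return float(u / (sp.size * sb.size))


def _objective(lam_f_pres_mean: float, log_z: float, penalty: float) -> float:
    return lam_f_pres_mean - log_z - penalty


def fit_maxent(
    presence_X: np.ndarray,
    background_X: np.ndarray,
    spec: FeatureSpec,
    var_names: list[str] | None = None,
    reg_multiplier: float = 2.0,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> EnmModel:
    """Fit the Gibbs model by penalized cyclic coordinate descent.

    ``presence_X`` and ``background_X`` are raw covariate matrices sharing
    column order (and ``var_names``). The normalization universe is the
    background plus the presences. Per-feature penalties are
    ``BASE_BETA[class] * reg_multiplier / sqrt(m)``.

    Returns the model even when ``max_iter`` is reached without meeting
    ``tol``; ``converged`` records which happened.
    """
    P = np.asarray(presence_X, dtype=float)
    B = np.asarray(background_X, dtype=float)
    if P.ndim != 2 or B.ndim != 2 or P.shape[1] != B.shape[1]:
        raise ValueError("presence and background must share one covariate space")
    m = P.shape[0]
    if m < 2:
        raise ValueError("need at least 2 presences")
    if var_names is None:
        var_names = [f"x{k}" for k in range(P.shape[1])]

    U = np.vstack([B, P])  # normalization universe
    spec = fit_scaling(U, list(var_names), spec)
    F_u, feature_var, feature_names = build_features(U, spec)
    F_p, _, _ = build_features(P, spec)
    n_feat = F_u.shape[1]
    n_u = F_u.shape[0]

    beta_class = np.array(
        [BASE_BETA["hinge" if "hinge" in nm else ("quadratic" if "quadratic" in nm else "linear")]
         for nm in feature_names]
    )
    feature_sd = np.maximum(F_p.std(axis=0), MIN_FEATURE_SD)
    betas = beta_class * reg_multiplier * feature_sd / np.sqrt(m)

    lam = np.zeros(n_feat)
    f_pres_mean = F_p.mean(axis=0)
    s = np.zeros(n_u)  # lambda . f over the universe
    log_z = np.log(n_u)  # logsumexp of zeros
    n_vars = len(spec.var_names)
    var_credit = np.zeros(n_vars)
    obj = _objective(0.0, log_z, 0.0)
    trace = [obj]
    converged = False

    for sweep in range(max_iter):
        obj_start = obj
        for j in range(n_feat):
            fj = F_u[:, j]
            w = np.exp(s - log_z)
            e_fj = w @ fj
            var_fj = w @ (fj - e_fj) ** 2
            if var_fj < 1e-12:
                continue
            g = f_pres_mean[j] - e_fj
            z_new = lam[j] + g / var_fj
            lam_new = np.sign(z_new) * max(0.0, abs(z_new) - betas[j] / var_fj)
            delta = lam_new - lam[j]
            if delta == 0.0:
                continue
            # backtrack until the penalized objective does not decrease
            for _ in range(30):
                lam_j_try = lam[j] + delta
                s_try = s + delta * fj
                log_z_try = logsumexp(s_try)
                pen_try = betas @ np.abs(lam) - betas[j] * abs(lam[j]) + betas[j] * abs(lam_j_try)
                obj_try = _objective(
                    float(f_pres_mean @ lam) + delta * f_pres_mean[j], log_z_try, pen_try
                )
                if obj_try >= obj - 1e-15:
                    break
                delta *= 0.5
            else:
                continue
            if obj_try <= obj:
                continue
            var_credit[feature_var[j]] += obj_try - obj
            lam[j] += delta
            s = s_try
            log_z = log_z_try
            obj = obj_try
        trace.append(obj)
        if obj - obj_start < tol:
            converged = True
            break

    if not converged:
        warnings.warn(f"coordinate descent did not reach tol={tol} in {max_iter} sweeps")

    q = np.exp(s - log_z)
    entropy = float(-(q * (s - log_z)).sum())
    model = EnmModel(
        spec=spec,
        lambdas=lam,
        betas=betas,
        feature_var=feature_var,
        feature_names=feature_names,
        reg_multiplier=reg_multiplier,
        log_z=float(log_z),
        entropy=entropy,
        n_universe=n_u,
        n_presence=m,
        gain_trace=np.asarray(trace),
        var_credit=var_credit,
        converged=converged,
        background_X=B,
        presence_X=P,
    )
    logger.info("fit: %d features, %d sweeps, objective %.6f, H=%.4f, converged=%s",
                n_feat, len(trace) - 1, obj, entropy, converged)
    return model


def predict_logistic(model: EnmModel, stack: PredictorStack) -> RasterGrid:
    """Logistic suitability surface over every valid cell of a stack.

    The stack must contain the model's variables (by name); extra layers
    are ignored. Values outside the training range are clamped into the
    [0, 1] feature scale (logged).
    """
    missing = [v for v in model.spec.var_names if v not in stack]
    if missing:
        raise ValueError(f"stack lacks model variables: {missing}")
    sub = stack.subset(list(model.spec.var_names))
    valid = sub.valid
    rows, cols = np.nonzero(valid)
    X = sub.table(rows, cols)
    p = model.predict(X)
    out = np.full(sub.transform.shape, np.nan)
    out[rows, cols] = p
    return RasterGrid(values=out, transform=sub.transform, mask=~valid, units="probability")


def percent_contribution(model: EnmModel) -> pd.Series:
    """Percent of the accumulated training gain credited to each variable.

    Every accepted coordinate-descent update's objective improvement is
    credited to the variable owning the updated feature; credits are
    normalized to sum to 100.
    """
    credit = model.var_credit
    total = credit.sum()
    if total <= 0:
        warnings.warn("no training gain; contributions reported as uniform")
        vals = np.full(len(credit), 100.0 / len(credit))
    else:
        vals = 100.0 * credit / total
    return pd.Series(vals, index=list(model.spec.var_names), name="percent_contribution")


def training_gain(model: EnmModel, presence_X: np.ndarray) -> float:
    """Unpenalized mean presence log-density relative to the uniform model."""
    F_p, _, _ = build_features(np.asarray(presence_X, dtype=float), model.spec)
    return float((F_p @ model.lambdas).mean() - model.log_z + np.log(model.n_universe))


def threshold_10pct(model: EnmModel, training_presence_X: np.ndarray) -> float:
    """10th percentile (linear interpolation) of training-presence predictions.

    The conventional conservative cutoff below which predictions are
    treated as unsuitable; computed and reported, applied only on request.
    """
    preds = model.predict(np.asarray(training_presence_X, dtype=float))
    return float(np.percentile(preds, 10.0, method="linear"))


def apply_threshold(surface: RasterGrid, threshold: float) -> RasterGrid:
    """Zero out cells strictly below the threshold (mask unchanged)."""
    vals = np.where(surface.values < threshold, 0.0, surface.values)
    return surface.with_values(vals)


def jackknife(
    presence_X: np.ndarray,
    background_X: np.ndarray,
    spec: FeatureSpec,
    var_names: list[str],
    reg_multiplier: float = 2.0,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> pd.DataFrame:
    """Leave-one-variable-out and single-variable importance sweep.

    For each variable, two reduced models are fitted: without the variable
    and with that variable only. Each reports its training gain and the AUC
    of the presences against the background. A sub-model failure is
    recorded as NaN without aborting the remaining fits.
    """
    if len(var_names) < 2:
        raise ValueError("jackknife needs >= 2 variables")
    P = np.asarray(presence_X, dtype=float)
    B = np.asarray(background_X, dtype=float)
    rows = []
    for v, name in enumerate(var_names):
        row: dict[str, float | str] = {"variable": name}
        for mode, keep in (("without", [k for k in range(len(var_names)) if k != v]),
                           ("only", [v])):
            try:
                sub = fit_maxent(P[:, keep], B[:, keep], spec,
                                 var_names=[var_names[k] for k in keep],
                                 reg_multiplier=reg_multiplier, tol=tol, max_iter=max_iter)
                row[f"gain_{mode}"] = training_gain(sub, P[:, keep])
                row[f"auc_{mode}"] = auc(sub.predict(P[:, keep]), sub.predict(B[:, keep]))
            except Exception as exc:  # pragma: no cover - defensive
                logger.error("jackknife %s/%s failed: %s", name, mode, exc)
                row[f"gain_{mode}"] = np.nan
                row[f"auc_{mode}"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows).set_index("variable")
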