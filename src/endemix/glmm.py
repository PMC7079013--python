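"""Binomial mixed model for native/nonnative categorization.

The response is the known biogeographic status of a training species
(endemic = 1, introduced = 0).  Fixed effects are the two per-species
diversity statistics — average within-species distance ("sim") and
mean-linkage nearest-neighbor distance ("dist") — and a Gaussian random
intercept per arthropod order absorbs order-level differences in fit.
Four candidate formulas are compared by AICc:

=============  =========================================  ===
formula_id     linear predictor                             K
=============  =========================================  ===
``sim+dist``   b0 + b1*sim + b2*dist + u_order              4
``sim*dist``   b0 + b1*sim + b2*dist + b3*sim*dist + u      5
``dist``       b0 + b2*dist + u_order                       3
``sim``        b0 + b1*sim + u_order                        3
=============  =========================================  ===

K counts the fixed effects (incl. intercept) plus the random-intercept
variance.  The marginal likelihood is maximized under a Laplace
approximation with deterministic starting values, so refitting identical
data reproduces identical estimates.  Scores for all species are posterior
predictions on the probability scale; a species is called likely native
when its score reaches the lower 95% confidence bound of the endemic
training scores, likely nonnative when it does not exceed the upper bound
of the introduced training scores, undetermined in between, and NA when no
score exists (singleton species).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .records import SpeciesStats

log = logging.getLogger(__name__)

FORMULAS = ("sim+dist", "sim*dist", "dist", "sim")

LABEL_NATIVE = "GLMM-Native"
LABEL_NONNATIVE = "GLMM-Nonnative"
LABEL_UNDET = "GLMM-Undet"
LABEL_NA = "NA"
LABELS = (LABEL_NATIVE, LABEL_NONNATIVE, LABEL_UNDET, LABEL_NA)


# --------------------------------------------------------------------------
# Welch's t test

@dataclass
class TestResult:
    statistic: float
    df: float
    p_value: float


def welch_t(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Welch's two-sample t test with Satterthwaite degrees of freedom."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs at least 2 observations")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0 and vy == 0:
        if x.mean() == y.mean():
            return TestResult(0.0, float(len(x) + len(y) - 2), 1.0)
        raise ValueError("zero variance with unequal means: t undefined")
    t, p = stats.ttest_ind(x, y, equal_var=False)
    se2x, se2y = vx / len(x), vy / len(y)
    df = (se2x + se2y) ** 2 / (
        se2x**2 / (len(x) - 1) + se2y**2 / (len(y) - 1)
    )
    return TestResult(float(t), float(df), float(p))


# --------------------------------------------------------------------------
# Model fitting

@dataclass
class GLMMFit:
    formula_id: str
    beta: np.ndarray  # fixed effects, order per design()
    beta_names: list[str]
    sigma2_order: float
    u: dict[str, float]  # order -> conditional mode (BLUP)
    LL: float
    K: int
    AICc: float
    n: int
    converged: bool = True
    beta_se: Optional[np.ndarray] = field(default=None, repr=False)


def aicc(LL: float, K: int, n: int) -> float:
    """Small-sample corrected Akaike information criterion."""
    if n - K - 1 <= 0:
        return np.inf
    return -2.0 * LL + 2.0 * K + 2.0 * K * (K + 1) / (n - K - 1)


def design(formula_id: str, sim: np.ndarray, dist: np.ndarray):
    """Design matrix and coefficient names for one candidate formula."""
    ones = np.ones_like(sim)
    if formula_id == "sim+dist":
        return np.column_stack([ones, sim, dist]), ["intercept", "avg_within", "nn_distance"]
    if formula_id == "sim*dist":
        return (
            np.column_stack([ones, sim, dist, sim * dist]),
            ["intercept", "avg_within", "nn_distance", "avg_within:nn_distance"],
        )
    if formula_id == "dist":
        return np.column_stack([ones, dist]), ["intercept", "nn_distance"]
    if formula_id == "sim":
        return np.column_stack([ones, sim]), ["intercept", "avg_within"]
    raise ValueError(f"unknown formula {formula_id!r}")


def _training_frame(training: Sequence[SpeciesStats] | pd.DataFrame) -> pd.DataFrame:
    if isinstance(training, pd.DataFrame):
        df = training.copy()
    else:
        df = pd.DataFrame(
            {
                "species_id": [s.species_id for s in training],
                "order": [s.order for s in training],
                "avg_within": [s.avg_within for s in training],
                "nn_distance": [s.nn_distance for s in training],
                "status": [s.training_status for s in training],
            }
        )
    bad = ~df["status"].isin(["endemic", "introduced"])
    if bad.any():
        raise ValueError("training species must all be endemic or introduced")
    if df[["avg_within", "nn_distance"]].isna().any().any():
        raise ValueError("training species must have defined avg_within and nn_distance")
    return df


def _group_loglik(eta: np.ndarray, y: np.ndarray) -> float:
    # Bernoulli log-likelihood with logit link, numerically safe
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def _laplace_group(Xb: np.ndarray, y: np.ndarray, sigma2: float):
    """Conditional mode u* and Laplace log-likelihood contribution for one
    order.  Newton iterations on the penalized log-likelihood."""
    u = 0.0
    for _ in range(50):
        eta = Xb + u
        p = special.expit(eta)
        grad = np.sum(y - p) - u / sigma2
        hess = -np.sum(p * (1 - p)) - 1.0 / sigma2
        step = grad / hess
        u -= step
        if abs(step) < 1e-12:
            break
    eta = Xb + u
    p = special.expit(eta)
    W = np.sum(p * (1 - p))
    ll = (
        _group_loglik(eta, y)
        - u * u / (2.0 * sigma2)
        - 0.5 * np.log(sigma2)
        - 0.5 * np.log(W + 1.0 / sigma2)
    )
    return u, ll


def _marginal_nll(params, X, y, groups, fix_sigma2):
    k = X.shape[1]
    beta = params[:k]
    sigma2 = fix_sigma2 if fix_sigma2 is not None else np.exp(params[k]) ** 2
    Xbeta = X @ beta
    total = 0.0
    if fix_sigma2 == 0 or sigma2 < 1e-12:
        total = _group_loglik(Xbeta, y)
    else:
        for idx in groups.values():
            _, ll = _laplace_group(Xbeta[idx], y[idx], sigma2)
            total += ll
    return -total


def _numerical_hessian(f, x: np.ndarray, h: float = 1e-4) -> np.ndarray:
    """Central-difference Hessian; step scaled per coordinate."""
    m = len(x)
    H = np.empty((m, m))
    steps = h * np.maximum(1.0, np.abs(x))
    for i in range(m):
        for j in range(i, m):
            ei = np.zeros(m)
            ej = np.zeros(m)
            ei[i] = steps[i]
            ej[j] = steps[j]
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4.0 * steps[i] * steps[j])
    return H


def fit_glmm(
    training: Sequence[SpeciesStats] | pd.DataFrame,
    formula_id: str = "sim+dist",
    fix_sigma2: Optional[float] = None,
    tol: float = 1e-8,
) -> GLMMFit:
    """Fit one candidate binomial mixed model on the training species.

    ``training`` rows need species_id, order, avg_within, nn_distance and
    status (endemic/introduced).  ``fix_sigma2=0`` collapses the model to
    ordinary logistic regression (used for validation).  Optimization uses
    deterministic zero starting values, so results are reproducible.
    """
    df = _training_frame(training)
    if fix_sigma2 is None and df["order"].nunique() < 2:
        raise ValueError("random-intercept model needs at least 2 orders")
    y = (df["status"] == "endemic").to_numpy(dtype=float)
    X, names = design(
        formula_id,
        df["avg_within"].to_numpy(dtype=float),
        df["nn_distance"].to_numpy(dtype=float),
    )
    groups = {
        o: np.where((df["order"] == o).to_numpy())[0]
        for o in sorted(df["order"].unique())
    }
    k = X.shape[1]
    n = len(df)

    # optimize on column-standardized covariates: the raw distance statistics
    # live on a ~0.01 scale, which conditions the likelihood badly
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    mu[0], sd[0] = 0.0, 1.0
    sd[sd == 0] = 1.0
    Xs = (X - mu) / sd

    x0 = np.zeros(k + (0 if fix_sigma2 is not None else 1))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        res = optimize.minimize(
            _marginal_nll,
            x0,
            args=(Xs, y, groups, fix_sigma2),
            method="BFGS",
            options={"gtol": tol, "maxiter": 2000},
        )
    beta_s = res.x[:k]
    beta = beta_s / sd
    beta[0] = beta_s[0] - float(np.sum(beta_s[1:] * mu[1:] / sd[1:]))
    sigma2 = fix_sigma2 if fix_sigma2 is not None else float(np.exp(res.x[k]) ** 2)
    LL = -float(res.fun)
    converged = bool(res.success) or float(np.max(np.abs(res.jac))) < 1e-4
    if np.max(np.abs(beta_s)) > 50:
        log.warning(
            "%s: |beta| > 50 suggests (quasi-)separation in the training data",
            formula_id,
        )
        converged = False

    # conditional modes at the optimum
    u: dict[str, float] = {}
    Xbeta = X @ beta
    for o, idx in groups.items():
        if sigma2 < 1e-12:
            u[o] = 0.0
        else:
            u[o], _ = _laplace_group(Xbeta[idx], y[idx], sigma2)

    K = k + 1  # fixed effects + random-intercept variance
    if fix_sigma2 is not None:
        K = k + (0 if fix_sigma2 == 0 else 1)

    # standard errors from a central-difference Hessian of the marginal
    # negative log-likelihood in the original parametrization
    beta_se = None
    try:
        theta = np.concatenate([beta, [] if fix_sigma2 is not None else [res.x[k]]])
        H = _numerical_hessian(
            lambda t: _marginal_nll(t, X, y, groups, fix_sigma2), theta
        )
        cov = np.linalg.inv(H)
        beta_se = np.sqrt(np.clip(np.diag(cov)[:k], 0, None))
    except np.linalg.LinAlgError:
        pass

    return GLMMFit(
        formula_id=formula_id,
        beta=beta,
        beta_names=names,
        sigma2_order=float(sigma2),
        u=u,
        LL=LL,
        K=K,
        AICc=aicc(LL, K, n),
        n=n,
        converged=converged,
        beta_se=beta_se,
    )


def compare_models(fits: Sequence[GLMMFit] | Sequence[float]) -> pd.DataFrame:
    """Rank candidate fits by AICc with differences and Akaike weights.

    Accepts either fitted models or bare AICc values (useful for checking
    published model-selection tables).
    """
    if len(fits) == 0:
        raise ValueError("no fits to compare")
    if isinstance(fits[0], GLMMFit):
        rows = [
            {"formula_id": f.formula_id, "LL": f.LL, "K": f.K, "AICc": f.AICc}
            for f in fits
        ]
    else:
        rows = [
            {"formula_id": f"model{i}", "LL": np.nan, "K": np.nan, "AICc": float(a)}
            for i, a in enumerate(fits)
        ]
    df = pd.DataFrame(rows).sort_values("AICc", kind="stable").reset_index(drop=True)
    df["dAICc"] = df["AICc"] - df["AICc"].iloc[0]
    rel = np.exp(-0.5 * df["dAICc"].to_numpy())
    df["weight"] = rel / rel.sum()
    return df


def predict_scores(
    fit: GLMMFit, species: Sequence[SpeciesStats] | pd.DataFrame
) -> pd.DataFrame:
    """Score every species on the 0-1 endemic-likelihood scale.

    Species from orders seen in training are predicted conditionally on the
    order's BLUP; unseen orders use the population level (u = 0).  Species
    with an undefined statistic (singletons, single-species orders) get no
    score.
    """
    if isinstance(species, pd.DataFrame):
        df = species.copy()
    else:
        df = pd.DataFrame(
            {
                "species_id": [s.species_id for s in species],
                "order": [s.order for s in species],
                "avg_within": [s.avg_within for s in species],
                "nn_distance": [s.nn_distance for s in species],
            }
        )
    scores = np.full(len(df), np.nan)
    defined = df["avg_within"].notna() & df["nn_distance"].notna()
    if defined.any():
        X, _ = design(
            fit.formula_id,
            df.loc[defined, "avg_within"].to_numpy(dtype=float),
            df.loc[defined, "nn_distance"].to_numpy(dtype=float),
        )
        u = df.loc[defined, "order"].map(lambda o: fit.u.get(o, 0.0)).to_numpy()
        scores[defined.to_numpy()] = special.expit(X @ fit.beta + u)
    out = df[["species_id", "order"]].copy()
    out["glmm_score"] = scores
    return out


# --------------------------------------------------------------------------
# Categorization

@dataclass
class CategoryThresholds:
    intro_mean: float
    intro_ci: tuple[float, float]
    endemic_mean: float
    endemic_ci: tuple[float, float]
    level: float = 0.95


def thresholds_from_training(
    scores: Sequence[float], statuses: Sequence[str], level: float = 0.95
) -> CategoryThresholds:
    """Per-category mean and mean +/- z*SE of the training scores, with SE
    the sample standard deviation (n-1) over the square root of n."""
    scores = np.asarray(scores, dtype=float)
    statuses = np.asarray(statuses)
    z = float(stats.norm.ppf(0.5 + level / 2.0))
    out = {}
    for cat in ("introduced", "endemic"):
        vals = scores[(statuses == cat) & ~np.isnan(scores)]
        if len(vals) < 2:
            raise ValueError(f"need at least 2 scored {cat} training species")
        m = float(vals.mean())
        se = float(vals.std(ddof=1) / np.sqrt(len(vals)))
        out[cat] = (m, (m - z * se, m + z * se))
    return CategoryThresholds(
        intro_mean=out["introduced"][0],
        intro_ci=out["introduced"][1],
        endemic_mean=out["endemic"][0],
        endemic_ci=out["endemic"][1],
        level=level,
    )


def categorize(score: Optional[float], thresholds: CategoryThresholds) -> str:
    """Map one score to a categorization label.

    No score -> NA; otherwise compare against the introduced upper and
    endemic lower confidence bounds.  If the two intervals overlap and a
    score satisfies both rules the species is left undetermined.
    """
    if score is None or (isinstance(score, float) and np.isnan(score)):
        return LABEL_NA
    intro_hi = thresholds.intro_ci[1]
    endemic_lo = thresholds.endemic_ci[0]
    is_nonnative = score <= intro_hi
    is_native = score >= endemic_lo
    if is_nonnative and is_native:
        log.warning(
            "confidence intervals overlap (intro hi %.4f >= endemic lo %.4f); "
            "score %.4f left undetermined",
            intro_hi,
            endemic_lo,
            score,
        )
        return LABEL_UNDET
    if is_nonnative:
        return LABEL_NONNATIVE
    if is_native:
        return LABEL_NATIVE
    return LABEL_UNDET


# --------------------------------------------------------------------------
# Error reporting

@dataclass
class ErrorReport:
    """Contingency counts of predicted labels within each true category,
    per order and grand total, with directional error rates.

    The error rate for a true category is the percentage of its species
    assigned the *opposite* label (likely native for introduced species,
    likely nonnative for endemic species), over all species in the category
    including the undetermined and NA ones.
    """

    counts: pd.DataFrame  # index (order), columns MultiIndex (status, label)

    GRAND_TOTAL = "Grand total"

    @staticmethod
    def _error_pct(row, status: str) -> float:
        total = sum(row[(status, lab)] for lab in LABELS)
        if total == 0:
            return np.nan
        wrong = row[(status, LABEL_NATIVE if status == "introduced" else LABEL_NONNATIVE)]
        return 100.0 * wrong / total

    def error_rate(self, status: str, order: str = GRAND_TOTAL) -> float:
        return self._error_pct(self.counts.loc[order], status)

    def error_table(self) -> pd.DataFrame:
        rows = {}
        for order in self.counts.index:
            rows[order] = {
                s: self._error_pct(self.counts.loc[order], s)
                for s in ("introduced", "endemic")
            }
        return pd.DataFrame(rows).T

    def accuracy(self) -> float:
        """100 minus the mean of the two grand-total directional error
        rates — the headline accuracy of the categorization."""
        errs = [
            self.error_rate(s) for s in ("introduced", "endemic")
        ]
        return 100.0 - float(np.nanmean(errs))


def error_report_from_counts(counts: pd.DataFrame) -> ErrorReport:
    """Build a report from a ready-made per-order contingency table.

    ``counts`` has one row per order and a (status, label) column
    MultiIndex over statuses {introduced, endemic, unknown} and the four
    labels.  A grand-total row is appended if absent.
    """
    df = counts.copy()
    for status in ("introduced", "endemic", "unknown"):
        for lab in LABELS:
            if (status, lab) not in df.columns:
                df[(status, lab)] = 0
    df = df.sort_index(axis=1)
    if ErrorReport.GRAND_TOTAL not in df.index:
        df.loc[ErrorReport.GRAND_TOTAL] = df.sum(axis=0)
    return ErrorReport(counts=df)


def error_report(
    categories: Sequence[str],
    true_statuses: Sequence[str],
    orders: Sequence[str],
) -> ErrorReport:
    """Tabulate predicted labels against known statuses, per order."""
    df = pd.DataFrame(
        {"category": categories, "status": true_statuses, "order": orders}
    )
    table = (
        df.groupby(["order", "status", "category"]).size().unstack([1, 2], fill_value=0)
    )
    table.columns = pd.MultiIndex.from_tuples(table.columns)
    return error_report_from_counts(table)
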