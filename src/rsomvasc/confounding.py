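"""Confounding analysis: nested logistic GLM triplets and the multivariate
linear (probability) regression.

For each candidate confounder three nested logistic models of disease status
are compared: M1 uses the confounder alone, M2 adds the feature-based index,
M3 adds their interaction.  "Residuals" are residual deviances
(-2 log-likelihood at the MLE; the Bernoulli saturated likelihood is 1), and
each added term is tested by a 1-df likelihood-ratio chi-square (Wald
optional).  The multivariate block is ordinary least squares on the 0/1
outcome — a linear probability model, which is what puts coefficients on a
probability scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .core import ValidationError, logger

_SEPARATION_COEF = 30.0


# ---------------------------------------------------------------------------
# Logistic fit (IRLS)
# ---------------------------------------------------------------------------

@dataclass
class LogisticFit:
    coef: np.ndarray
    deviance: float
    converged: bool
    separated: bool
    n_iter: int


def _check_full_rank(X: np.ndarray, columns) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify offending columns via QR pivoting on the gram matrix
        _, R = np.linalg.qr(X)
        bad = [str(columns[i]) for i in range(X.shape[1]) if abs(R[i, i]) < 1e-8 * max(1.0, abs(R[0, 0]))]
        raise ValidationError(f"design matrix is rank deficient (collinear columns: {bad or 'unknown'})")


def fit_logistic(
    X: np.ndarray | pd.DataFrame,
    y: np.ndarray,
    max_iter: int = 100,
    tol: float = 1e-10,
    start: np.ndarray | None = None,
) -> LogisticFit:
    """Maximum-likelihood logistic regression by IRLS with step halving.

    ``X`` is the full design matrix (add an intercept column yourself or use
    :func:`nested_triplet`).  Step halving makes every iteration decrease the
    deviance, so a fit warm-started from a nested model's MLE can never end
    above it.  Quasi-separation is flagged (coefficients still reported at
    the last iterate).
    """
    columns = list(X.columns) if isinstance(X, pd.DataFrame) else list(range(np.asarray(X).shape[1]))
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValidationError("outcome must be binary 0/1")
    _check_full_rank(X, columns)

    def deviance_of(beta):
        eta = X @ beta
        # numerically stable -2 loglik: log(1+exp(eta)) - y*eta
        return 2.0 * np.sum(np.logaddexp(0.0, eta) - y * eta)

    beta = np.zeros(X.shape[1]) if start is None else np.asarray(start, dtype=float).copy()
    dev = deviance_of(beta)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -500, 500)))
        w = np.clip(mu * (1.0 - mu), 1e-10, None)
        z = eta + (y - mu) / w
        WX = X * w[:, None]
        try:
            step_target = np.linalg.solve(X.T @ WX, X.T @ (w * z))
        except np.linalg.LinAlgError:
            break
        direction = step_target - beta
        scale = 1.0
        new_dev = deviance_of(beta + direction)
        while new_dev > dev + 1e-12 and scale > 1e-8:
            scale *= 0.5
            new_dev = deviance_of(beta + scale * direction)
        if new_dev > dev + 1e-12:
            converged = True  # cannot improve further
            break
        improved = dev - new_dev
        beta = beta + scale * direction
        dev = new_dev
        if improved < tol:
            converged = True
            break
    separated = bool(np.abs(beta).max() > _SEPARATION_COEF or dev < 1e-6)
    if separated:
        converged = False
        logger.warning("fit_logistic: quasi-separation detected (|coef| max %.1f)",
                       float(np.abs(beta).max()))
    return LogisticFit(coef=beta, deviance=float(dev), converged=converged,
                       separated=separated, n_iter=it)


# ---------------------------------------------------------------------------
# Nested GLM triplets
# ---------------------------------------------------------------------------

@dataclass
class TripletResult:
    confounder: str
    deviance_m1: float
    deviance_m2: float
    deviance_m3: float
    p_index: float          # LRT of the index term added in M2
    p_interaction: float    # LRT of the interaction term added in M3
    sparse: bool            # empty confounder x outcome cell (binary confounders)
    separated: bool


def nested_triplet(
    confounder: np.ndarray,
    index: np.ndarray,
    outcome: np.ndarray,
    name: str = "confounder",
    test: str = "lrt",
) -> TripletResult:
    """Fit the three nested logistic models for one confounder.

    M1: outcome ~ confounder; M2: + index; M3: + confounder x index.
    Added-term p-values are 1-df likelihood-ratio chi-square by default
    (``test="wald"`` uses the Wald z of the added coefficient).
    """
    c = np.asarray(confounder, dtype=float)
    ix = np.asarray(index, dtype=float)
    y = np.asarray(outcome, dtype=float)
    if len(c) < 10:
        raise ValidationError("need n >= 10 for the nested GLM analysis")
    if np.ptp(c) == 0 or np.ptp(ix) == 0:
        raise ValidationError("confounder and index must vary")
    sparse = False
    uniq = np.unique(c)
    if len(uniq) == 2:
        cells = [((c == a) & (y == b)).sum() for a in uniq for b in (0, 1)]
        if min(cells) == 0:
            sparse = True
            logger.warning("confounder %s: empty cell against outcome; "
                           "interpret with caution", name)
    ones = np.ones_like(c)
    X1 = np.column_stack([ones, c])
    X2 = np.column_stack([ones, c, ix])
    X3 = np.column_stack([ones, c, ix, c * ix])
    m1 = fit_logistic(X1, y)
    m2 = fit_logistic(X2, y, start=np.append(m1.coef, 0.0))
    m3 = fit_logistic(X3, y, start=np.append(m2.coef, 0.0))

    def lrt_p(dev_small, dev_big):
        return float(stats.chi2.sf(max(dev_small - dev_big, 0.0), df=1))

    if test == "lrt":
        p2 = lrt_p(m1.deviance, m2.deviance)
        p3 = lrt_p(m2.deviance, m3.deviance)
    elif test == "wald":
        p2 = _wald_p(X2, m2)
        p3 = _wald_p(X3, m3)
    else:
        raise ValidationError(f"unknown test {test!r}")
    return TripletResult(
        confounder=name,
        deviance_m1=m1.deviance, deviance_m2=m2.deviance, deviance_m3=m3.deviance,
        p_index=p2, p_interaction=p3,
        sparse=sparse,
        separated=m1.separated or m2.separated or m3.separated,
    )


def _wald_p(X: np.ndarray, fit: LogisticFit) -> float:
    eta = X @ fit.coef
    mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -500, 500)))
    w = np.clip(mu * (1 - mu), 1e-10, None)
    cov = np.linalg.inv(X.T @ (X * w[:, None]))
    z = fit.coef[-1] / np.sqrt(cov[-1, -1])
    return float(2 * stats.norm.sf(abs(z)))


# ---------------------------------------------------------------------------
# Multivariate linear probability model
# ---------------------------------------------------------------------------

def multivariate_linear(covariates: pd.DataFrame, outcome) -> pd.DataFrame:
    """OLS of the 0/1 outcome on covariates plus the feature-based index.

    A linear probability model: coefficients live on the probability scale.
    Returns a table of coefficient, standard error and two-sided t-test
    p-value per variable (plus the intercept).
    """
    y = np.asarray(outcome, dtype=float)
    X = covariates.astype(float)
    if len(y) <= X.shape[1] + 1:
        raise ValidationError("need n > number of parameters")
    design = sm.add_constant(X, has_constant="add")
    _check_full_rank(design.to_numpy(), list(design.columns))
    fit = sm.OLS(y, design).fit()
    return pd.DataFrame(
        {"coef": fit.params, "se": fit.bse, "p": fit.pvalues}
    )


# ---------------------------------------------------------------------------
# Full analysis
# ---------------------------------------------------------------------------

#: Binary confounders are excluded from the multivariate block when any
#: confounder x outcome cell holds fewer than this many subjects.
SPARSE_CELL_MIN = 3


def confounding_analysis(
    covariates: pd.DataFrame,
    index: pd.Series,
    outcome: pd.Series,
    confounders: tuple[str, ...] = (
        "age", "sex", "bmi", "hypertension", "smoking", "hyperlipidemia", "diabetes",
    ),
    test: str = "lrt",
):
    """Run the GLM triplets for every confounder plus the multivariate model.

    Binary confounders with any confounder-by-outcome cell below
    :data:`SPARSE_CELL_MIN` stay in the triplet panel but are dropped from
    the multivariate regression (with a logged note).  Returns
    ``(triplet_table, multivariate_table)``.
    """
    idx = index.loc[covariates.index].to_numpy(dtype=float)
    y = outcome.loc[covariates.index].to_numpy(dtype=float)
    rows = []
    multivariate_vars = []
    for name in confounders:
        c = covariates[name].to_numpy(dtype=float)
        res = nested_triplet(c, idx, y, name=name, test=test)
        rows.append(res)
        uniq = np.unique(c)
        if len(uniq) == 2:
            cells = [((c == a) & (y == b)).sum() for a in uniq for b in (0, 1)]
            if min(cells) < SPARSE_CELL_MIN:
                logger.info("excluding sparse confounder %r from the multivariate model", name)
                continue
        multivariate_vars.append(name)
    triplets = pd.DataFrame(
        [
            {
                "confounder": r.confounder,
                "deviance_m1": r.deviance_m1,
                "deviance_m2": r.deviance_m2,
                "deviance_m3": r.deviance_m3,
                "p_index": r.p_index,
                "p_interaction": r.p_interaction,
                "sparse": r.sparse,
                "separated": r.separated,
            }
            for r in rows
        ]
    ).set_index("confounder")
    design = covariates[multivariate_vars].copy()
    design["feature_based_index"] = idx
    multivariate = multivariate_linear(design, y)
    return triplets, multivariate
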