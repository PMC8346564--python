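"""Binomial GLM of myelination probability: P(myelinated) ~ 1 + diameter + subtype.

The model is a logit-link binomial regression in which the probability of an
axon being myelinated is predicted by its mean diameter (μm) and its neuronal
subtype, with treatment (dummy) coding relative to a reference subtype
(PV by default).  Responses may be fractional site-myelination values
(k myelinated of n sites), handled as binomial proportions with the site
count as weight.

The fit is plain iteratively reweighted least squares (IRLS) with a fixed
iteration budget.  When a subtype level perfectly predicts the outcome
(e.g. a subtype with zero myelinated axons), the maximum-likelihood
coefficient diverges; such terms are detected after the iteration budget by
their magnitude or standard error and recorded in ``separation_flags``
rather than regularized away, so the divergent estimate is reported as-is.

From a fit, ``d50`` gives the diameter at which a subtype's modeled
myelination probability reaches 50%:  d50 = −(β0 + βtype)/βd, with a delta-
method confidence interval from the fit covariance.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .traces import SUBTYPES

__all__ = [
    "LogisticFit",
    "D50Estimate",
    "SeparationError",
    "NoInformationError",
    "LAYER1_GLM_COEFFICIENTS",
    "reference_fit",
    "irls_logistic",
    "fit_myelination_glm",
    "d50",
    "predict_probability",
]

#: Published coefficient estimates (value, standard error) for the
#: diameter+subtype myelination model of layer I somatosensory cortex axons,
#: treatment-coded relative to PV.  The divergent NTSR1 row reflects complete
#: separation: no NTSR1 axon in the study was myelinated.
LAYER1_GLM_COEFFICIENTS: dict[str, tuple[float, float]] = {
    "(Intercept)": (-3.044, 0.581),
    "diam": (5.836, 1.034),
    "type_NTSR1": (-15.215, 2573735.335),
    "type_NXPH4": (-1.470, 0.650),
    "type_RBP4": (-1.014, 0.457),
    "type_PO": (-0.481, 0.389),
    "type_VM": (0.047, 0.367),
}

#: divergence thresholds used to flag separated terms after the fit
SEPARATION_COEF_THRESHOLD = 10.0
SEPARATION_SE_THRESHOLD = 100.0


class SeparationError(ValueError):
    """Requested quantity is undefined for a separation-flagged term."""


class NoInformationError(ValueError):
    """The response carries a single class overall; no model can be fit."""


@dataclass(frozen=True)
class LogisticFit:
    """Coefficients and covariance of a fitted myelination GLM."""

    coefficients: Mapping[str, float]
    standard_errors: Mapping[str, float]
    covariance: np.ndarray  # ordered as `terms`
    terms: tuple[str, ...]
    reference: str
    loglik: float
    converged: bool
    separation_flags: frozenset[str] = field(default_factory=frozenset)

    def term_for(self, subtype: str) -> str | None:
        """Dummy-coded term name for a subtype (None for the reference)."""
        if subtype == self.reference:
            return None
        return f"type_{subtype}"


@dataclass(frozen=True)
class D50Estimate:
    """Diameter at 50% modeled myelination probability for one subtype."""

    subtype: str
    d50: float
    interval: tuple[float, float] | None = None


def reference_fit(
    coefficients: Mapping[str, tuple[float, float]] | None = None,
    reference: str = "PV",
) -> LogisticFit:
    """Wrap published (coefficient, SE) pairs as a :class:`LogisticFit`.

    The covariance is diagonal (squared SEs): published tables report no
    cross-covariances, so delta-method intervals from this fit are
    approximate and d50 point estimates are exact.
    """
    coefficients = dict(coefficients or LAYER1_GLM_COEFFICIENTS)
    terms = tuple(coefficients)
    coefs = {t: v[0] for t, v in coefficients.items()}
    ses = {t: v[1] for t, v in coefficients.items()}
    flags = frozenset(
        t
        for t in terms
        if abs(coefs[t]) > SEPARATION_COEF_THRESHOLD or ses[t] > SEPARATION_SE_THRESHOLD
    )
    return LogisticFit(
        coefficients=coefs,
        standard_errors=ses,
        covariance=np.diag([ses[t] ** 2 for t in terms]),
        terms=terms,
        reference=reference,
        loglik=float("nan"),
        converged=True,
        separation_flags=flags,
    )


def irls_logistic(
    X: np.ndarray,
    y: np.ndarray,
    w: np.ndarray,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float, bool]:
    """Iteratively reweighted least squares for a weighted binomial logit fit.

    Returns (beta, covariance, standard errors, log likelihood up to the
    combinatorial constant, converged).  Under separation the working
    weights collapse and the loop stops at the budget (or on a singular
    information matrix), leaving the divergent estimate in place.
    """
    beta = np.zeros(X.shape[1])
    converged = False
    for _ in range(max_iter):
        eta = X @ beta
        mu = np.clip(1.0 / (1.0 + np.exp(-eta)), 1e-12, 1.0 - 1e-12)
        wt = w * mu * (1.0 - mu)
        z = eta + (y - mu) / (mu * (1.0 - mu))
        XtW = X.T * wt
        try:
            new_beta = np.linalg.solve(XtW @ X, XtW @ z)
        except np.linalg.LinAlgError:
            break
        step = new_beta - beta
        beta = new_beta
        if np.max(np.abs(step)) < tol:
            converged = True
            break

    eta = X @ beta
    mu = np.clip(1.0 / (1.0 + np.exp(-eta)), 1e-12, 1.0 - 1e-12)
    wt = w * mu * (1.0 - mu)
    cov = np.linalg.pinv((X.T * wt) @ X)
    ses = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    loglik = float(np.sum(w * (y * np.log(mu) + (1.0 - y) * np.log(1.0 - mu))))
    return beta, cov, ses, loglik, converged


def _design_matrix(
    diameters: np.ndarray, subtypes: Sequence[str], reference: str
) -> tuple[np.ndarray, tuple[str, ...]]:
    present = [s for s in SUBTYPES if s in set(subtypes) and s != reference]
    terms = ("(Intercept)", "diam") + tuple(f"type_{s}" for s in present)
    X = np.zeros((len(subtypes), len(terms)))
    X[:, 0] = 1.0
    X[:, 1] = diameters
    for j, s in enumerate(present):
        X[:, 2 + j] = [1.0 if st == s else 0.0 for st in subtypes]
    return X, terms


def fit_myelination_glm(
    data: Sequence[tuple[float, str, float]],
    reference: str = "PV",
    weights: Sequence[float] | None = None,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> LogisticFit:
    """Maximum-likelihood logit fit of P(myelinated) ~ 1 + diameter + subtype.

    Parameters
    ----------
    data
        Triples ``(mean_diameter_um, subtype, response)`` with responses in
        [0, 1]; fractional responses are site-myelination fractions.
    reference
        Subtype absorbed into the intercept (treatment coding).
    weights
        Binomial weights (site counts) per observation; default 1.
    max_iter, tol
        IRLS iteration budget and convergence tolerance on the coefficient
        update.  A fit that exhausts the budget is returned unconverged with
        divergent terms recorded in ``separation_flags``.
    """
    diam = np.array([d for d, _, _ in data], dtype=float)
    subs = [s for _, s, _ in data]
    y = np.array([r for _, _, r in data], dtype=float)
    w = np.ones_like(y) if weights is None else np.asarray(weights, dtype=float)
    if np.any(diam <= 0):
        raise ValueError("diameters must be positive")
    if np.any((y < 0) | (y > 1)):
        raise ValueError("responses must lie in [0, 1]")
    unknown = set(subs) - set(SUBTYPES)
    if unknown:
        raise ValueError(f"unknown subtypes {sorted(unknown)}")
    if len(set(subs)) < 2:
        raise ValueError("need at least 2 subtypes")
    if reference not in set(subs):
        raise ValueError(f"reference subtype {reference!r} absent from data")
    if np.all(y == 0) or np.all(y == 1):
        raise NoInformationError("response takes a single class overall")

    X, terms = _design_matrix(diam, subs, reference)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise np.linalg.LinAlgError("design matrix is rank deficient")

    beta, cov, ses, loglik, converged = irls_logistic(X, y, w, max_iter=max_iter, tol=tol)

    flags = frozenset(
        t
        for t, b, se in zip(terms, beta, ses)
        if abs(b) > SEPARATION_COEF_THRESHOLD or se > SEPARATION_SE_THRESHOLD
    )
    return LogisticFit(
        coefficients=dict(zip(terms, (float(b) for b in beta))),
        standard_errors=dict(zip(terms, (float(s) for s in ses))),
        covariance=cov,
        terms=terms,
        reference=reference,
        loglik=loglik,
        converged=converged or bool(flags),
        separation_flags=flags,
    )


def d50(fit: LogisticFit, subtype: str, confidence: float = 0.95) -> D50Estimate:
    """Diameter at which the modeled myelination probability is 50%.

    d50 = −(β0 + βtype)/βd with βtype = 0 for the reference subtype.  The
    interval is a delta-method normal interval on the coefficient ratio
    using the fit covariance.
    """
    if not fit.converged:
        raise ValueError("fit did not converge; d50 undefined")
    term = fit.term_for(subtype)
    flagged = {"(Intercept)", "diam"} | ({term} if term else set())
    hit = flagged & fit.separation_flags
    if hit:
        raise SeparationError(
            f"d50 undefined for {subtype}: separation-flagged terms {sorted(hit)}"
        )
    b0 = fit.coefficients["(Intercept)"]
    bd = fit.coefficients["diam"]
    bt = fit.coefficients[term] if term else 0.0
    if bd == 0:
        raise ZeroDivisionError("diameter coefficient is zero; d50 undefined")
    if bd < 0:
        warnings.warn(
            "diameter coefficient is negative: myelination probability "
            "decreases with diameter and d50 is a 50%-downcrossing",
            RuntimeWarning,
        )
    value = -(b0 + bt) / bd

    # delta method: gradient of -(b0+bt)/bd w.r.t. (terms order)
    grad = np.zeros(len(fit.terms))
    idx = {t: i for i, t in enumerate(fit.terms)}
    grad[idx["(Intercept)"]] = -1.0 / bd
    if term:
        grad[idx[term]] = -1.0 / bd
    grad[idx["diam"]] = (b0 + bt) / bd**2
    var = float(grad @ fit.covariance @ grad)
    interval = None
    if math.isfinite(var) and var >= 0:
        from scipy.stats import norm

        half = norm.ppf(0.5 + confidence / 2.0) * math.sqrt(var)
        interval = (value - half, value + half)
    return D50Estimate(subtype=subtype, d50=float(value), interval=interval)


def predict_probability(fit: LogisticFit, diameter: float, subtype: str) -> float:
    """Modeled myelination probability logistic(β0 + βd·diameter + βtype)."""
    term = fit.term_for(subtype)
    if term is not None and term not in fit.coefficients:
        raise KeyError(f"subtype {subtype!r} not in fit terms")
    eta = (
        fit.coefficients["(Intercept)"]
        + fit.coefficients["diam"] * diameter
        + (fit.coefficients[term] if term else 0.0)
    )
    return 1.0 / (1.0 + math.exp(-eta))
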