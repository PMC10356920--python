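"""Conditional logistic regression for 1:M matched sets.

For a matched set with case covariate row :math:`x_0` and control rows
:math:`x_1 \\dots x_M`, the conditional likelihood contribution is

.. math::

    \\ell_i(\\beta) = x_0'\\beta - \\log \\sum_{j=0}^{M} \\exp(x_j'\\beta),

the probability that, given the set and that exactly one member is the
case, it is the observed one.  The total log-likelihood is concave; its
gradient per set is :math:`x_0 - \\bar x_p` (the softmax-weighted mean) and
its Hessian the negative softmax covariance, so a Newton–Raphson with
step-halving converges in a handful of iterations for the small parameter
counts used here.  Within-set computations are log-sum-exp stabilized.

Terms with no within-set variation anywhere carry no information: they are
excluded from the optimization and reported with an infinite-variance flag.
Complete or quasi-separation (a coefficient diverging past ±15, with the
likelihood still improving) raises :class:`SeparationError` rather than
returning silently absurd estimates.

Also provides the marginal (unmatched) 2x2 odds ratio with its Woolf
confidence interval, used to reproduce published crude odds ratios from
marginal exposure counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

Z975 = float(stats.norm.ppf(0.975))  # 1.959964...

BETA_BOUND = 15.0


class SeparationError(RuntimeError):
    """The conditional likelihood has no finite maximizer for some term."""


class ZeroCellError(ValueError):
    """A 2x2 margin contains an empty cell."""


@dataclass(frozen=True)
class SetDesign:
    """Design rows of one matched set; the case row first."""

    set_id: int
    case_row: np.ndarray
    control_rows: np.ndarray  # (M, p)

    def stacked(self) -> np.ndarray:
        return np.vstack([self.case_row[None, :], self.control_rows])


@dataclass(frozen=True)
class TermResult:
    name: str
    beta: float
    se: float
    or_point: float
    ci_low: float
    ci_high: float
    p: float
    informative: bool  # False: no within-set variation, variance infinite


@dataclass
class ClogitResult:
    terms: list[TermResult]
    loglik: float
    iterations: int
    converged: bool
    n_sets: int
    n_informative_sets: int

    def term(self, name: str) -> TermResult:
        for t in self.terms:
            if t.name == name:
                return t
        raise KeyError(name)


def _pack(sets: Sequence[SetDesign] | Sequence[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    """Stack set matrices; returns (X, offsets) with case rows first per set."""
    mats = []
    for s in sets:
        m = s.stacked() if isinstance(s, SetDesign) else np.asarray(s, dtype=float)
        if m.ndim != 2 or m.shape[0] < 2:
            raise ValueError("each set needs a case row and at least one control row")
        mats.append(m)
    sizes = np.array([m.shape[0] for m in mats])
    X = np.vstack(mats).astype(float)
    if not np.isfinite(X).all():
        raise ValueError("non-finite covariate values")
    offsets = np.concatenate([[0], np.cumsum(sizes)])
    return X, offsets


def conditional_loglik(
    beta: np.ndarray, sets: Sequence[SetDesign] | Sequence[np.ndarray]
) -> tuple[float, np.ndarray, np.ndarray]:
    """Exact value, gradient and Hessian of the conditional log-likelihood."""
    X, offsets = _pack(sets)
    return _loglik_packed(np.asarray(beta, dtype=float), X, offsets)


def _loglik_packed(
    beta: np.ndarray, X: np.ndarray, offsets: np.ndarray
) -> tuple[float, np.ndarray, np.ndarray]:
    eta = X @ beta
    p = X.shape[1]
    ll = 0.0
    grad = np.zeros(p)
    hess = np.zeros((p, p))
    for a, b in zip(offsets[:-1], offsets[1:]):
        e = eta[a:b]
        m = e.max()
        w = np.exp(e - m)
        denom = w.sum()
        probs = w / denom
        rows = X[a:b]
        xbar = probs @ rows
        ll += e[0] - (m + np.log(denom))
        grad += rows[0] - xbar
        hess -= (rows.T * probs) @ rows - np.outer(xbar, xbar)
    return float(ll), grad, hess


def _informative_columns(X: np.ndarray, offsets: np.ndarray) -> np.ndarray:
    """Columns with within-set variation in at least one set."""
    p = X.shape[1]
    varying = np.zeros(p, dtype=bool)
    for a, b in zip(offsets[:-1], offsets[1:]):
        rows = X[a:b]
        varying |= np.any(rows != rows[0], axis=0)
        if varying.all():
            break
    return varying


def fit_clogit(
    sets: Sequence[SetDesign] | Sequence[np.ndarray],
    term_names: Sequence[str],
    max_iter: int = 50,
    tol: float = 1e-8,
) -> ClogitResult:
    """Newton–Raphson fit of the matched-set conditional likelihood.

    Convergence is declared at infinity-norm of the gradient below ``tol``.
    Raises :class:`SeparationError` when a coefficient diverges past the
    ±15 bound while the likelihood is still increasing.
    """
    X, offsets = _pack(sets)
    p = X.shape[1]
    if len(term_names) != p:
        raise ValueError("term_names length must match design columns")
    n_sets = len(offsets) - 1
    informative_sets = sum(
        int(np.any(X[a:b] != X[a])) for a, b in zip(offsets[:-1], offsets[1:])
    )
    active = _informative_columns(X, offsets)
    Xa = X[:, active]
    beta_a = np.zeros(int(active.sum()))

    ll, grad, hess = _loglik_packed(beta_a, Xa, offsets)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        if np.max(np.abs(grad), initial=0.0) < tol:
            converged = True
            it -= 1
            break
        try:
            step = np.linalg.solve(-hess, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(-hess, grad, rcond=None)[0]
        # step-halving on likelihood decrease
        scale = 1.0
        for _ in range(30):
            cand = beta_a + scale * step
            ll_new, grad_new, hess_new = _loglik_packed(cand, Xa, offsets)
            if ll_new >= ll - 1e-12:
                break
            scale *= 0.5
        beta_a, ll, grad, hess = cand, ll_new, grad_new, hess_new
        if np.max(np.abs(beta_a), initial=0.0) > BETA_BOUND:
            active_names = [n for n, a in zip(term_names, active) if a]
            worst = active_names[int(np.argmax(np.abs(beta_a)))]
            raise SeparationError(
                f"coefficient for {worst!r} diverged past ±15: "
                "complete or quasi-separation"
            )
    else:
        if np.max(np.abs(grad), initial=0.0) < tol:
            converged = True

    # standard errors from the observed information at the optimum
    se_a = np.full(len(beta_a), np.nan)
    if len(beta_a):
        info = -hess
        try:
            cov = np.linalg.inv(info)
            d = np.diag(cov)
            se_a = np.sqrt(np.where(d > 0, d, np.nan))
        except np.linalg.LinAlgError:
            pass

    terms: list[TermResult] = []
    ai = 0
    for k, name in enumerate(term_names):
        if active[k]:
            b, s = float(beta_a[ai]), float(se_a[ai])
            ai += 1
            lo, hi = wald_interval(b, s) if np.isfinite(s) and s > 0 else (np.nan, np.nan)
            pval = (
                float(2 * stats.norm.sf(abs(b / s)))
                if np.isfinite(s) and s > 0
                else np.nan
            )
            terms.append(
                TermResult(name, b, s, float(np.exp(b)), lo, hi, pval, True)
            )
        else:
            terms.append(
                TermResult(name, 0.0, np.inf, 1.0, np.nan, np.nan, np.nan, False)
            )
    return ClogitResult(
        terms=terms,
        loglik=ll,
        iterations=it,
        converged=converged,
        n_sets=n_sets,
        n_informative_sets=informative_sets,
    )


def wald_interval(beta: float, se: float, level: float = 0.95) -> tuple[float, float]:
    """Odds-ratio Wald interval exp(beta ± z * se)."""
    if se <= 0:
        raise ValueError("se must be > 0")
    z = float(stats.norm.ppf(0.5 + level / 2))
    return float(np.exp(beta - z * se)), float(np.exp(beta + z * se))


def marginal_or(
    a: int, b: int, c: int, d: int, haldane: bool = False
) -> tuple[float, tuple[float, float]]:
    """Marginal 2x2 odds ratio (a·d)/(b·c) with the Woolf 95% CI.

    a = exposed cases, b = unexposed cases, c = exposed controls,
    d = unexposed controls.  Zero cells raise unless ``haldane`` adds the
    +0.5 Haldane–Anscombe correction.
    """
    cells = [a, b, c, d]
    if any(x < 0 for x in cells):
        raise ValueError("cell counts must be non-negative")
    if any(x == 0 for x in cells):
        if not haldane:
            raise ZeroCellError("zero cell in 2x2 table; pass haldane=True to correct")
        a, b, c, d = (x + 0.5 for x in cells)
    or_ = (a * d) / (b * c)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    log_or = np.log(or_)
    return float(or_), (
        float(np.exp(log_or - Z975 * se)),
        float(np.exp(log_or + Z975 * se)),
    )
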