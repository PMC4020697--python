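"""Restricted maximum likelihood estimation of additive + dominance variance.

The mixed model is

    y = X b + a + d + e,   var(a) = sigma2_a A_g,  var(d) = sigma2_d D_g,
                           var(e) = sigma2_e I,

with ``X`` the fixed-effects design (intercept plus sex levels) and A_g, D_g
the genomic relationship matrices. The restricted log-likelihood is, up to an
additive constant,

    l(theta) = -1/2 [ log|V| + log|X' V^-1 X| + y' P y ],
    V = sigma2_a A_g + sigma2_d D_g + sigma2_e I,
    P = V^-1 - V^-1 X (X' V^-1 X)^-1 X' V^-1.

Two maximisers are provided. EM-REML iterates

    sigma2_i <- sigma2_i + sigma2_i**2 (y'P G_i P y - tr(P G_i)) / n

for G_a = A_g, G_d = D_g, G_e = I; it increases the likelihood monotonically
and approaches boundary components multiplicatively without ever producing a
negative value, which is why near-zero components appear as extremely small
positive numbers rather than exact zeros. A bounded quasi-Newton maximiser
(L-BFGS-B on log-variances with the analytic gradient) converges much faster
on large problems and serves both as a cross-check on EM and as the
recommended optimizer for simulation studies at n of several hundred.

Heritabilities are variance fractions on the observed scale:
h2_a = sigma2_a / sigma2_p, h2_d = sigma2_d / sigma2_p, H2 = h2_a + h2_d with
sigma2_p the component sum. For a binary trait analysed as 0/1, the
observed-scale narrow heritability converts to the liability scale by the
probit (threshold-model) adjustment

    h2_liability = h2_observed * P1 (1 - P1) / z**2,

with P1 the trait prevalence and z the standard normal density at the
liability threshold. The conversion factor P(1-P)/z^2 is minimised at
P = 0.5 where it equals pi/2, so the liability-scale estimate exceeds 1 for
every prevalence exactly when the observed-scale estimate exceeds 2/pi
(about 0.64); results above 1 are reported unclamped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats
from scipy.linalg import cho_factor, cho_solve
from sklearn.base import BaseEstimator

from .datatypes import CohortTable
from .grm import GrmPair, additive_model_matrix, dominance_model_matrix
from .io import allele_frequencies

_VARIANCE_FLOOR_REL = 1e-12  # relative to initial phenotypic variance


class NumericalRankError(np.linalg.LinAlgError):
    """V or X'V^-1X is numerically singular."""


def sex_design(sex: np.ndarray | list[str] | None, n: int) -> np.ndarray:
    """Fixed-effects design: intercept plus dummies for observed sex levels.

    Sex is a three-level factor (F, M, NA-unknown); only levels actually
    present get a column, and the first present level is the reference, so
    the design always has full column rank.
    """
    X = np.ones((n, 1))
    if sex is None:
        return X
    sex = np.asarray(sex, dtype=object)
    levels = sorted(set(sex))
    for lev in levels[1:]:
        X = np.column_stack([X, (sex == lev).astype(float)])
    return X


@dataclass
class MixedModelSpec:
    """Aligned inputs for one GREML fit."""

    y: np.ndarray
    X: np.ndarray
    A: np.ndarray
    D: np.ndarray | None = None
    include_dominance: bool = True

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float).ravel()
        self.X = np.asarray(self.X, dtype=float)
        n = self.y.size
        if self.X.shape[0] != n or self.A.shape != (n, n):
            raise ValueError("y, X and A_g are not aligned on the same individuals")
        if np.linalg.matrix_rank(self.X) < self.X.shape[1]:
            raise ValueError("fixed-effects design is rank deficient")
        if self.include_dominance:
            if self.D is None or self.D.shape != (n, n):
                raise ValueError("include_dominance=True requires an aligned D_g")
        elif self.D is None:
            self.D = np.zeros((n, n))

    @property
    def n(self) -> int:
        return self.y.size

    @classmethod
    def from_cohort(cls, grm: GrmPair, cohort: CohortTable,
                    y: np.ndarray | None = None,
                    include_dominance: bool = True) -> "MixedModelSpec":
        """Build a spec from a GRM pair and cohort; default phenotype is the
        binary trait recoded 0/1 (1 = migratory)."""
        tab = cohort.table.set_index("id").loc[grm.individual_ids].reset_index()
        if y is None:
            y = (tab["smolt"].to_numpy() == 1).astype(float)
        X = sex_design(tab["sex"].to_numpy(), len(tab))
        return cls(y=y, X=X, A=grm.A, D=grm.D, include_dominance=include_dominance)


def _reml_parts(theta, spec: MixedModelSpec):
    """Log-likelihood, gradient pieces and P y at theta = (s_a, s_d, s_e)."""
    sa, sd, se = (float(t) for t in theta)
    n = spec.n
    V = sa * spec.A + se * np.eye(n)
    if spec.include_dominance or sd != 0.0:
        V = V + sd * spec.D
    try:
        c, low = cho_factor(V, lower=True, check_finite=False)
    except np.linalg.LinAlgError as err:
        raise NumericalRankError(f"V not positive definite at theta={theta}") from err
    logdet_V = 2.0 * float(np.sum(np.log(np.diag(c))))
    Vinv = cho_solve((c, low), np.eye(n), check_finite=False)
    VX = Vinv @ spec.X
    XtVX = spec.X.T @ VX
    sign, logdet_XtVX = np.linalg.slogdet(XtVX)
    if sign <= 0:
        raise NumericalRankError("X'V^-1X is singular")
    B = np.linalg.solve(XtVX, VX.T)
    P = Vinv - VX @ B
    Py = P @ spec.y
    ll = -0.5 * (logdet_V + logdet_XtVX + float(spec.y @ Py))
    return ll, P, Py


def reml_loglik(theta, spec: MixedModelSpec) -> float:
    """Restricted log-likelihood at variance components ``theta`` (constant
    convention: the -((n-f)/2) log 2pi term is omitted)."""
    return _reml_parts(theta, spec)[0]


def reml_gradient(theta, spec: MixedModelSpec) -> np.ndarray:
    """dl/d sigma2_i = (y'P G_i P y - tr(P G_i)) / 2 for G = (A, D, I)."""
    _, P, Py = _reml_parts(theta, spec)
    grads = []
    for G in (spec.A, spec.D, np.eye(spec.n)):
        yPGPy = float(Py @ (G @ Py))
        trPG = float(np.sum(P * G))
        grads.append(0.5 * (yPGPy - trPG))
    return np.array(grads)


@dataclass
class VarianceEstimate:
    sigma2_a: float
    sigma2_d: float
    sigma2_e: float
    h2_a: float
    h2_d: float
    H2: float
    loglik: float
    n_iter: int
    converged: bool
    trace: np.ndarray = field(repr=False)  # columns: sigma2_a, sigma2_d, sigma2_e, loglik

    def components(self) -> tuple[float, float, float]:
        return (self.sigma2_a, self.sigma2_d, self.sigma2_e)


def heritabilities(est) -> tuple[float, float, float]:
    """(h2_a, h2_d, H2) from a VarianceEstimate or a component triple."""
    sa, sd, se = est.components() if hasattr(est, "components") else (float(v) for v in est)
    tot = sa + sd + se
    if tot <= 0:
        raise ValueError("total variance is zero; heritability undefined")
    return (sa / tot, sd / tot, (sa + sd) / tot)


def _default_init(spec: MixedModelSpec) -> np.ndarray:
    """Equal split of the phenotypic variance over the active components."""
    vy = float(np.var(spec.y, ddof=1))
    if vy <= 0:
        vy = 1.0
    if spec.include_dominance:
        return np.array([vy / 3, vy / 3, vy / 3])
    return np.array([vy / 2, 0.0, vy / 2])


def _fit_em(spec, init, max_iter, tol, floor):
    theta = np.array(init, dtype=float)
    active = [0, 1, 2] if spec.include_dominance else [0, 2]
    Gs = {0: spec.A, 1: spec.D, 2: np.eye(spec.n)}
    trace = []
    converged = False
    it = 0
    ll = -np.inf
    for it in range(1, max_iter + 1):
        ll_new, P, Py = _reml_parts(theta, spec)
        trace.append([*theta, ll_new])
        new = theta.copy()
        for i in active:
            G = Gs[i]
            yPGPy = float(Py @ (G @ Py))
            trPG = float(np.sum(P * G))
            step = theta[i] ** 2 * (yPGPy - trPG) / spec.n
            cand = theta[i] + step
            # EM cannot overshoot below 0 in exact arithmetic; guard roundoff
            new[i] = cand if cand > 0 else theta[i] / 10.0
        # convergence: relative change of every non-negligible component
        denom = np.maximum(np.abs(theta), floor)
        rel = np.abs(new - theta) / denom
        rel[np.abs(new) < floor] = 0.0
        param_ok = bool(np.all(rel[active] < tol))
        ll_stalled = np.isfinite(ll) and abs(ll_new - ll) < 1e-12 * (1.0 + abs(ll_new))
        theta, ll = new, ll_new
        if param_ok or ll_stalled:
            converged = True
            break
    ll_final = reml_loglik(theta, spec)
    trace.append([*theta, ll_final])
    return theta, ll_final, it, converged, np.array(trace)


def _fit_bounded(spec, init, max_iter, tol, floor):
    active = [0, 1, 2] if spec.include_dominance else [0, 2]
    vy = max(float(np.var(spec.y, ddof=1)), floor / _VARIANCE_FLOOR_REL)
    lo, hi = np.log(floor), np.log(100.0 * vy)
    s0 = np.log(np.clip(np.asarray(init, dtype=float)[active], floor, None))

    def negloglik_and_grad(s):
        theta = np.zeros(3)
        theta[active] = np.exp(s)
        ll, P, Py = _reml_parts(theta, spec)
        g = []
        for i in active:
            G = (spec.A, spec.D, np.eye(spec.n))[i]
            dldsig = 0.5 * (float(Py @ (G @ Py)) - float(np.sum(P * G)))
            g.append(dldsig * theta[i])  # chain rule onto log scale
        return -ll, -np.array(g)

    res = optimize.minimize(
        negloglik_and_grad, s0, jac=True, method="L-BFGS-B",
        bounds=[(lo, hi)] * len(active),
        options={"maxiter": max_iter, "ftol": 1e-14, "gtol": 1e-9},
    )
    theta = np.zeros(3)
    theta[active] = np.exp(res.x)
    ll = -res.fun
    trace = np.array([[*theta, ll]])
    return theta, ll, int(res.nit), bool(res.success), trace


def _restart_inits(spec: MixedModelSpec, n: int) -> list[np.ndarray]:
    """Deterministic corner-biased starts for multimodal small-n surfaces."""
    vy = max(float(np.var(spec.y, ddof=1)), 1e-12)
    fracs = [(1 / 3, 1 / 3, 1 / 3), (0.9, 0.05, 0.05), (0.05, 0.9, 0.05),
             (0.05, 0.05, 0.9), (0.45, 0.45, 0.1)]
    if not spec.include_dominance:
        fracs = [(0.5, 0.0, 0.5), (0.9, 0.0, 0.1), (0.1, 0.0, 0.9),
                 (0.99, 0.0, 0.01), (0.01, 0.0, 0.99)]
    return [vy * np.array(f) for f in fracs[:n]]


def fit_greml(spec: MixedModelSpec, init=None, max_iter: int = 5000,
              tol: float = 1e-8, optimizer: str = "em",
              cross_check: bool = True, restarts: int = 1) -> VarianceEstimate:
    """Maximise the restricted likelihood over nonnegative variance components.

    Parameters
    ----------
    init : component triple, optional
        Strictly positive starting values for the active components; the
        default splits the phenotypic variance equally.
    optimizer : {"em", "bounded"}
        "em" runs the EM-REML recursion (boundary components decay toward 0
        without being clamped); "bounded" runs L-BFGS-B on log-variances
        with the analytic gradient — much faster at large n.
    cross_check : bool
        Re-maximise with the other optimizer and warn if any heritability
        disagrees by more than 1e-4.
    restarts : int
        Number of deterministic corner-biased starting points (max 5); the
        fit with the best restricted likelihood wins. Small-n likelihood
        surfaces can be multimodal, so use several restarts on toy data.
    """
    if init is None:
        init = _default_init(spec)
    init = np.asarray(init, dtype=float)
    if spec.include_dominance and not np.all(init > 0):
        raise ValueError("initial components must be strictly positive")
    floor = _VARIANCE_FLOOR_REL * max(float(np.var(spec.y, ddof=1)), 1e-300)
    runner = {"em": _fit_em, "bounded": _fit_bounded}.get(optimizer)
    if runner is None:
        raise ValueError(f"optimizer must be 'em' or 'bounded', got {optimizer!r}")
    inits = [init] if restarts <= 1 else _restart_inits(spec, restarts)
    theta = ll = n_iter = converged = trace = None
    for start in inits:
        fit = runner(spec, start, max_iter, tol, floor)
        if ll is None or fit[1] > ll:
            theta, ll, n_iter, converged, trace = fit
    if not converged:
        warnings.warn(
            f"GREML did not converge in {n_iter} iterations (optimizer={optimizer})",
            RuntimeWarning, stacklevel=2,
        )
    h2a, h2d, H2 = heritabilities(theta)
    if cross_check:
        other = "bounded" if optimizer == "em" else "em"
        theta2, *_ = {"em": _fit_em, "bounded": _fit_bounded}[other](
            spec, init, max_iter, tol, floor)
        h2 = np.array([h2a, h2d, H2])
        h2_other = np.array(heritabilities(theta2))
        if np.max(np.abs(h2 - h2_other)) > 1e-4:
            warnings.warn(
                f"EM-REML and quasi-Newton heritabilities disagree by "
                f"{np.max(np.abs(h2 - h2_other)):.2e}; the likelihood surface "
                "may be flat or multimodal", RuntimeWarning, stacklevel=2,
            )
    return VarianceEstimate(
        sigma2_a=float(theta[0]), sigma2_d=float(theta[1]), sigma2_e=float(theta[2]),
        h2_a=h2a, h2_d=h2d, H2=H2, loglik=float(ll),
        n_iter=n_iter, converged=converged, trace=trace,
    )


def liability_transform(h2_obs: float, prevalence: float) -> float:
    """Probit (threshold-model) conversion of observed-scale heritability.

    ``prevalence`` is the proportion of the case class (migratory fish).
    The result is reported unclamped and exceeds 1 whenever
    h2_obs > z^2 / (P (1-P)); over all prevalences that happens exactly when
    h2_obs > 2/pi.
    """
    if not (0.0 < prevalence < 1.0):
        raise ValueError("prevalence must lie strictly inside (0, 1)")
    if h2_obs < 0:
        raise ValueError("observed-scale heritability must be nonnegative")
    t = stats.norm.isf(prevalence)  # threshold with upper-tail mass = prevalence
    z = stats.norm.pdf(t)
    return h2_obs * prevalence * (1.0 - prevalence) / z**2


def liability_boundary() -> float:
    """Observed-scale heritability above which the liability conversion
    exceeds 1 for every prevalence: the reciprocal of min_P P(1-P)/z(P)^2."""
    res = optimize.minimize_scalar(
        lambda p: p * (1.0 - p) / stats.norm.pdf(stats.norm.isf(p)) ** 2,
        bounds=(1e-6, 1.0 - 1e-6), method="bounded",
        options={"xatol": 1e-12},
    )
    return 1.0 / res.fun


class GREML(BaseEstimator):
    """sklearn-style estimator for the additive + dominance mixed model.

    ``fit(X, y, sex=...)`` accepts either a raw dosage matrix (n x m, NaN for
    missing; relationship matrices are built internally with frequencies from
    X itself) or, with ``precomputed=True``, a tuple ``(A_g, D_g)``. Fitted
    attributes follow sklearn conventions (trailing underscore).

    Attributes
    ----------
    sigma2_a_, sigma2_d_, sigma2_e_ : float
    h2_a_, h2_d_, H2_ : float
    loglik_, n_iter_, converged_ : fit diagnostics
    gblup_a_, gblup_d_, gblup_g_ : in-sample genomic predictions
    """

    def __init__(self, include_dominance: bool = True, optimizer: str = "em",
                 max_iter: int = 5000, tol: float = 1e-8,
                 cross_check: bool = False, precomputed: bool = False):
        self.include_dominance = include_dominance
        self.optimizer = optimizer
        self.max_iter = max_iter
        self.tol = tol
        self.cross_check = cross_check
        self.precomputed = precomputed

    def fit(self, X, y, sex=None):
        y = np.asarray(y, dtype=float).ravel()
        if self.precomputed:
            A, D = X if isinstance(X, tuple) else (X, None)
        else:
            X = np.asarray(X, dtype=float)
            self.freqs_ = allele_frequencies(X)
            pq2 = 2.0 * self.freqs_ * (1.0 - self.freqs_)
            self.k_alpha_, self.k_delta_ = float(pq2.sum()), float((pq2**2).sum())
            Ta = additive_model_matrix(X, self.freqs_)
            Td = dominance_model_matrix(X, self.freqs_)
            A = Ta @ Ta.T / self.k_alpha_
            D = Td @ Td.T / self.k_delta_
            self._Ta, self._Td = Ta, Td
        design = sex_design(sex, y.size)
        spec = MixedModelSpec(y=y, X=design, A=A, D=D,
                              include_dominance=self.include_dominance)
        est = fit_greml(spec, max_iter=self.max_iter, tol=self.tol,
                        optimizer=self.optimizer, cross_check=self.cross_check)
        self.spec_ = spec
        self.estimate_ = est
        self.sigma2_a_, self.sigma2_d_, self.sigma2_e_ = est.components()
        self.h2_a_, self.h2_d_, self.H2_ = est.h2_a, est.h2_d, est.H2
        self.loglik_, self.n_iter_, self.converged_ = est.loglik, est.n_iter, est.converged
        _, _, Py = _reml_parts(est.components(), spec)
        self._Py = Py
        self.gblup_a_ = self.sigma2_a_ * (A @ Py)
        self.gblup_d_ = self.sigma2_d_ * (D @ Py)
        self.gblup_g_ = self.gblup_a_ + self.gblup_d_
        return self

    def predict(self, X=None):
        """Total genetic values; for new dosage rows ``X`` (non-precomputed
        fits only) the cross-relationship blocks extend the BLUP."""
        if X is None:
            return self.gblup_g_
        if self.precomputed:
            raise ValueError("cannot predict new individuals from a precomputed-kernel fit")
        X = np.asarray(X, dtype=float)
        A_cross = additive_model_matrix(X, self.freqs_) @ self._Ta.T / self.k_alpha_
        D_cross = dominance_model_matrix(X, self.freqs_) @ self._Td.T / self.k_delta_
        return self.sigma2_a_ * (A_cross @ self._Py) + self.sigma2_d_ * (D_cross @ self._Py)
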