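"""Residual maximum likelihood estimation of the five variance components.

The marginal covariance of one subject's measurement vector is

    V_i = s_subj * 11' + s_sess * (session blocks) + s_side * (side blocks)
        + s_sss * (session-side cell blocks) + s_reps * I

and subjects are independent, so the REML criterion decomposes over
per-subject blocks.  The criterion implemented here is the log-density of
an orthonormal error-contrast vector (the basis-invariant form of the REML
log-likelihood, including all constants), which makes it directly
comparable against a brute-force multivariate-normal evaluation on the
contrast space.

Two evaluation paths share one optimizer:

* balanced data (every subject observed on the full J x K x L grid):
  the per-subject covariance is a sum of Kronecker products of averaging
  projectors, so it diagonalises in closed form.  The criterion reduces to
  five eigenvalues and five pooled sums of squares (the classic nested
  mean squares) — evaluation is O(1) after one pass over the data.
* unbalanced data: per-subject dense covariance with Cholesky
  factorisation.

The optimizer works on log(sigma2) for components kept in the interior
(no negative variances by construction) with a deterministic multi-start
— ANOVA moment estimates plus fixed proportion splits of the sample
variance — followed by an explicit profile comparison that pins small
components to exactly zero when doing so does not reduce the criterion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .io import validate_ppt_frame
from .types import COMPONENT_NAMES, Design, VarianceComponents

__all__ = ["FitResult", "reml_criterion", "fit_reml", "fit_reml_values",
           "variance_percentages", "NotEstimableError", "SingularCovarianceError"]

_LOG2PI = math.log(2.0 * math.pi)
# below this fraction of the sample variance an estimate counts as "at zero"
_REL_FLOOR = 1e-12


class NotEstimableError(ValueError):
    """Raised when the requested model cannot be identified from the data."""


class SingularCovarianceError(ValueError):
    """Marginal covariance is singular (e.g. zero residual variance with replicates)."""


# ---------------------------------------------------------------------------
# data preparation


@dataclass
class _BalancedStats:
    """Sufficient statistics of a balanced I x J x K x L layout.

    ``ss`` holds the pooled sums of squares of the five orthogonal strata
    (between subjects, sessions within subject, sides within subject,
    session x side interaction, within-cell residual) and ``df`` their
    degrees of freedom.  Together with the stratum eigenvalues of V they
    determine the REML criterion exactly.
    """

    I: int
    J: int
    K: int
    L: int
    grand_mean: float
    ss: np.ndarray
    df: np.ndarray

    @classmethod
    def from_values(cls, values: np.ndarray) -> "_BalancedStats":
        I, J, K, L = values.shape
        m_cell = values.mean(axis=3)            # (I, J, K)
        m_sess = m_cell.mean(axis=2)            # (I, J)
        m_side = m_cell.mean(axis=1)            # (I, K)
        m_subj = m_sess.mean(axis=1)            # (I,)
        grand = float(m_subj.mean())
        ss1 = J * K * L * float(((m_subj - grand) ** 2).sum())
        ss2 = K * L * float(((m_sess - m_subj[:, None]) ** 2).sum())
        ss3 = J * L * float(((m_side - m_subj[:, None]) ** 2).sum())
        inter = (m_cell - m_sess[:, :, None] - m_side[:, None, :]
                 + m_subj[:, None, None])
        ss4 = L * float((inter ** 2).sum())
        ss5 = float(((values - m_cell[:, :, :, None]) ** 2).sum())
        df = np.array([I - 1, I * (J - 1), I * (K - 1),
                       I * (J - 1) * (K - 1), I * J * K * (L - 1)], dtype=float)
        return cls(I, J, K, L, grand,
                   np.array([ss1, ss2, ss3, ss4, ss5]), df)

    @property
    def n_obs(self) -> int:
        return self.I * self.J * self.K * self.L

    def sample_variance(self) -> float:
        return float(self.ss.sum() / max(self.n_obs - 1, 1))

    def _eigenvalues(self, v: np.ndarray) -> np.ndarray:
        J, K, L = self.J, self.K, self.L
        s_subj, s_sess, s_side, s_sss, s_reps = v
        return np.array([
            s_reps + L * s_sss + J * L * s_side + K * L * s_sess + J * K * L * s_subj,
            s_reps + L * s_sss + K * L * s_sess,
            s_reps + L * s_sss + J * L * s_side,
            s_reps + L * s_sss,
            s_reps,
        ])

    def _lam_jacobian(self) -> np.ndarray:
        J, K, L = self.J, self.K, self.L
        return np.array([
            [J * K * L, K * L, J * L, L, 1.0],
            [0.0, K * L, 0.0, L, 1.0],
            [0.0, 0.0, J * L, L, 1.0],
            [0.0, 0.0, 0.0, L, 1.0],
            [0.0, 0.0, 0.0, 0.0, 1.0],
        ])

    def loglik(self, v: np.ndarray) -> float:
        """REML criterion at variances v = (subj, sess, side, sss, reps).

        The intercept's log-information and the -log|X'X| contrast
        correction cancel exactly in the balanced case, leaving degrees of
        freedom I-1 in the between-subject stratum.
        """
        lam = self._eigenvalues(v)
        relevant = (self.df > 0)
        relevant[0] = True  # between-subject eigenvalue always enters
        if np.any(relevant & (lam <= 0)):
            return -math.inf
        safe = np.where(lam > 0, lam, 1.0)
        val = ((self.n_obs - 1) * _LOG2PI
               + float(self.df @ np.log(safe))
               + float((self.ss / safe).sum()))
        return -0.5 * val

    def loglik_grad(self, v: np.ndarray) -> tuple[float, np.ndarray]:
        """Criterion and its analytic gradient with respect to the variances."""
        lam = self._eigenvalues(v)
        relevant = (self.df > 0)
        relevant[0] = True
        if np.any(relevant & (lam <= 0)):
            return -math.inf, np.zeros(5)
        safe = np.where(lam > 0, lam, 1.0)
        val = ((self.n_obs - 1) * _LOG2PI
               + float(self.df @ np.log(safe))
               + float((self.ss / safe).sum()))
        g_lam = np.where(lam > 0, self.df / safe - self.ss / safe ** 2, 0.0)
        grad = -0.5 * (self._lam_jacobian().T @ g_lam)
        return -0.5 * val, grad

    def gls_mean(self, v: np.ndarray) -> float:
        # balanced blocks: GLS intercept reduces to the grand mean
        return self.grand_mean

    def moment_estimates(self) -> np.ndarray:
        """Henderson/ANOVA estimators from expected mean squares (may be negative)."""
        J, K, L = self.J, self.K, self.L
        df = self.df
        msq = np.where(df > 0, self.ss / np.where(df > 0, df, 1.0), np.nan)
        ms1, ms2, ms3, ms4, ms5 = msq
        out = np.full(5, np.nan)
        if df[4] > 0:
            out[4] = ms5
            if df[3] > 0:
                out[3] = (ms4 - ms5) / L
        if df[1] > 0 and df[3] > 0:
            out[1] = (ms2 - ms4) / (K * L)
        if df[2] > 0 and df[3] > 0:
            out[2] = (ms3 - ms4) / (J * L)
        if df[1] > 0 and df[2] > 0 and df[3] > 0:
            out[0] = (ms1 - ms2 - ms3 + ms4) / (J * K * L)
        return out


@dataclass
class _SubjectBlocks:
    """Per-subject data and random-effect match matrices for unbalanced layouts."""

    ys: list[np.ndarray]
    match_sess: list[np.ndarray]
    match_side: list[np.ndarray]
    match_cell: list[np.ndarray]
    n_obs: int

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "_SubjectBlocks":
        ys, m1, m2, m3 = [], [], [], []
        for _, g in df.groupby("subject", sort=True):
            y = g["ppt_n"].to_numpy(dtype=float)
            sess = g["session"].to_numpy()
            side = g["side"].to_numpy()
            ys.append(y)
            m1.append(sess[:, None] == sess[None, :])
            m2.append(side[:, None] == side[None, :])
            m3.append(m1[-1] & m2[-1])
        return cls(ys, m1, m2, m3, sum(len(y) for y in ys))

    def sample_variance(self) -> float:
        y = np.concatenate(self.ys)
        return float(y.var(ddof=1)) if len(y) > 1 else 0.0

    def has_replicates(self) -> bool:
        return any(m.sum() > len(y) for y, m in zip(self.ys, self.match_cell))

    def _accumulate(self, v: np.ndarray) -> tuple[float, float, float, float]:
        s_subj, s_sess, s_side, s_sss, s_reps = v
        logdet = 0.0
        A = B = C = 0.0
        for y, ms, md, mc in zip(self.ys, self.match_sess, self.match_side,
                                 self.match_cell):
            n_i = len(y)
            V = (s_subj
                 + s_sess * ms + s_side * md + s_sss * mc
                 + s_reps * np.eye(n_i))
            try:
                Lf = np.linalg.cholesky(V)
            except np.linalg.LinAlgError as exc:
                raise SingularCovarianceError(
                    "singular marginal covariance at the supplied components"
                ) from exc
            logdet += 2.0 * float(np.log(np.diag(Lf)).sum())
            sol = np.linalg.solve(Lf, np.column_stack([np.ones(n_i), y]))
            g = sol.T @ sol                 # [1 y]' V^-1 [1 y]
            A += g[0, 0]
            B += g[0, 1]
            C += g[1, 1]
        return logdet, A, B, C

    def loglik(self, v: np.ndarray) -> float:
        n = self.n_obs
        try:
            logdet, A, B, C = self._accumulate(v)
        except SingularCovarianceError:
            return -math.inf
        quad = C - B * B / A
        return -0.5 * ((n - 1) * _LOG2PI + logdet + math.log(A)
                       - math.log(n) + quad)

    def gls_mean(self, v: np.ndarray) -> float:
        _, A, B, _ = self._accumulate(v)
        return B / A

    def moment_estimates(self) -> np.ndarray:
        return np.full(5, np.nan)


def _is_balanced(df: pd.DataFrame) -> bool:
    counts = df.groupby(["subject", "session", "side"], sort=False)["ppt_n"].count()
    if counts.nunique() != 1:
        return False
    J = df["session"].nunique()
    K = df["side"].nunique()
    L = int(counts.iloc[0])
    per_subject = df.groupby("subject", sort=False).agg(
        j=("session", "nunique"), k=("side", "nunique"), n=("ppt_n", "count"))
    return bool(((per_subject["j"] == J) & (per_subject["k"] == K)
                 & (per_subject["n"] == J * K * L)).all())


def _to_array(df: pd.DataFrame) -> np.ndarray:
    """Reshape a balanced frame into an (I, J, K, L) value array."""
    d = df.sort_values(["subject", "session", "side", "repetition"], kind="stable")
    I = d["subject"].nunique()
    J = d["session"].nunique()
    K = d["side"].nunique()
    L = len(d) // (I * J * K)
    return d["ppt_n"].to_numpy(dtype=float).reshape(I, J, K, L)


def _prepare(df: pd.DataFrame):
    if _is_balanced(df):
        return _BalancedStats.from_values(_to_array(df))
    return _SubjectBlocks.from_frame(df)


# ---------------------------------------------------------------------------
# public criterion


def reml_criterion(components: VarianceComponents, data: pd.DataFrame) -> float:
    """REML log-likelihood of the nested model at the given variances.

    The grand mean is profiled out by generalised least squares; the value
    is the log-density of orthonormal error contrasts, so it includes all
    constants and is invariant to subject relabelling and row order.
    ``sigma2_reps`` must be positive whenever cells hold replicate
    measurements, otherwise the covariance is singular and
    :class:`SingularCovarianceError` is raised.
    """
    df = validate_ppt_frame(data)
    if df["subject"].nunique() < 2:
        raise NotEstimableError("need at least 2 subjects to evaluate the criterion")
    v = np.asarray(components.variances(), dtype=float)
    prep = _prepare(df)
    if v[4] <= 0:
        replicated = (prep.L > 1 if isinstance(prep, _BalancedStats)
                      else prep.has_replicates())
        if replicated:
            raise SingularCovarianceError(
                "sigma2_reps = 0 with replicated cells gives a singular covariance")
    val = prep.loglik(v)
    if not math.isfinite(val):
        raise SingularCovarianceError(
            "REML criterion is not finite at the supplied components")
    return val


# ---------------------------------------------------------------------------
# fitting


@dataclass
class FitResult:
    """Outcome of a REML fit.

    ``boundary_flags[name]`` is True exactly when that variance estimate is
    pinned at zero; ``not_estimable[name]`` marks components the observed
    design cannot identify at all (reported as zero, excluded from
    optimisation).  ``reml_loglik`` is finite whenever the data carry any
    variation; for exactly constant data the Gaussian criterion degenerates
    and is reported as +inf.
    """

    components: VarianceComponents
    reml_loglik: float
    converged: bool
    n_obs: int
    design_summary: Design
    boundary_flags: dict[str, bool] = field(default_factory=dict)
    not_estimable: dict[str, bool] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            **self.components.to_dict(),
            "reml_loglik": self.reml_loglik,
            "converged": self.converged,
            "n_obs": self.n_obs,
            "design_summary": {
                "n_subjects": self.design_summary.n_subjects,
                "n_sessions": self.design_summary.n_sessions,
                "n_sides": self.design_summary.n_sides,
                "n_repetitions": self.design_summary.n_repetitions,
            },
            "boundary_flags": dict(self.boundary_flags),
            "not_estimable": dict(self.not_estimable),
        }


def _estimability(design: Design) -> dict[str, bool]:
    flags = {name: False for name in COMPONENT_NAMES}
    if design.n_sessions < 2:
        flags["sigma2_sess"] = True
        flags["sigma2_sss"] = True
    if design.n_sides < 2:
        flags["sigma2_side"] = True
        flags["sigma2_sss"] = True
    if design.n_repetitions < 2:
        # single replicates: interaction indistinguishable from residual
        flags["sigma2_sss"] = True
    return flags


def _start_points(prep, active: np.ndarray, s2: float) -> list[np.ndarray]:
    """Deterministic multi-start values on the variance scale (length 5 each).

    The ANOVA moment estimator is an excellent start on balanced data; when
    it exists and is cleanly interior (all active components positive) one
    grid start suffices as insurance, otherwise the full coarse grid runs.
    """
    floor = max(s2, 1e-12) * 1e-4
    grid = [np.maximum(np.asarray(split) * max(s2, 1e-8), floor)
            for split in ((0.60, 0.05, 0.05, 0.10, 0.20),
                          (0.20, 0.20, 0.20, 0.20, 0.20),
                          (0.05, 0.05, 0.05, 0.05, 0.80))]
    mom = prep.moment_estimates()
    if np.isfinite(mom[active]).all():
        clipped = np.clip(np.where(np.isfinite(mom), mom, 0.0), floor, None)
        if (mom[active] > floor).all():
            return [clipped, grid[0]]
        return [clipped] + grid
    return grid


def _optimize(prep, active: np.ndarray, starts: list[np.ndarray],
              tol_criterion: float, tol_params: float,
              maxiter: int) -> tuple[np.ndarray, float, bool]:
    """Maximise the criterion over log(sigma2) of the active components.

    Balanced layouts carry an analytic gradient, so L-BFGS-B does the work
    (with a Nelder-Mead polish if line search stalls); the dense unbalanced
    path is derivative-free Nelder-Mead throughout.  Both are deterministic.
    """
    idx = np.flatnonzero(active)
    has_grad = hasattr(prep, "loglik_grad")

    def neg(x: np.ndarray) -> float:
        v = np.zeros(5)
        v[idx] = np.exp(x)
        return -prep.loglik(v)

    def neg_grad(x: np.ndarray) -> tuple[float, np.ndarray]:
        v = np.zeros(5)
        v[idx] = np.exp(x)
        val, grad = prep.loglik_grad(v)
        # chain rule through v = exp(x)
        return -val, -grad[idx] * v[idx]

    s2 = max(prep.sample_variance(), 1e-300)
    lo, hi = math.log(s2) - 35.0, math.log(s2) + 12.0
    nm_opts = {"xatol": tol_params, "fatol": tol_criterion,
               "maxiter": maxiter, "maxfev": 2 * maxiter}

    best = None
    for s in starts:
        x0 = np.clip(np.log(np.maximum(s[idx], 1e-300)), lo, hi)
        if has_grad:
            res = minimize(neg_grad, x0, method="L-BFGS-B", jac=True,
                           bounds=[(lo, hi)] * len(idx),
                           options={"ftol": 1e-13, "gtol": 1e-9,
                                    "maxiter": maxiter})
            if not res.success:
                res = minimize(neg, res.x, method="Nelder-Mead", options=nm_opts)
        else:
            res = minimize(neg, x0, method="Nelder-Mead", options=nm_opts)
        if best is None or res.fun < best.fun:
            best = res
    v = np.zeros(5)
    v[idx] = np.exp(best.x)
    return v, -float(best.fun), bool(best.success)


def _fit_core(prep, design: Design, n_obs: int, first_value: float,
              tol_criterion: float, tol_params: float,
              maxiter: int) -> FitResult:
    not_estimable = _estimability(design)
    active = np.array([not not_estimable[n] for n in COMPONENT_NAMES])

    s2 = prep.sample_variance()
    mu0 = prep.gls_mean(np.array([0.0, 0.0, 0.0, 0.0, 1.0]))
    if s2 <= 1e-12 * max(1.0, mu0 * mu0):
        comps = VarianceComponents(grand_mean=float(first_value),
                                   **{n: 0.0 for n in COMPONENT_NAMES})
        return FitResult(comps, math.inf, True, n_obs, design,
                         {n: True for n in COMPONENT_NAMES}, not_estimable)

    starts = _start_points(prep, active, s2)
    v_hat, ll_hat, ok = _optimize(prep, active, starts,
                                  tol_criterion, tol_params, maxiter)

    # zero-boundary profile comparison: each component driven to a small
    # fraction of the sample variance is refitted pinned at exactly zero,
    # one at a time (smallest first), and kept there when the profiled
    # criterion does not drop
    work = active.copy()
    while True:
        candidates = sorted(
            (i for i in range(4) if work[i] and v_hat[i] < 1e-3 * s2),
            key=lambda i: v_hat[i])
        accepted = False
        for i in candidates:
            trial = work.copy()
            trial[i] = False
            starts_t = [np.where(trial, s, 0.0) for s in starts]
            v0, ll0, ok0 = _optimize(prep, trial, starts_t,
                                     tol_criterion, tol_params, maxiter)
            if ll0 >= ll_hat - 10.0 * tol_criterion:
                work, v_hat, ll_hat, ok = trial, v0, ll0, ok0
                accepted = True
                break
        if not accepted:
            break
    v_hat[:4] = np.where(v_hat[:4] < _REL_FLOOR * s2, 0.0, v_hat[:4])

    comps = VarianceComponents(grand_mean=float(prep.gls_mean(v_hat)),
                               **dict(zip(COMPONENT_NAMES, map(float, v_hat))))
    boundary = {n: bool(getattr(comps, n) == 0.0) for n in COMPONENT_NAMES}
    return FitResult(comps, float(ll_hat), bool(ok), n_obs, design,
                     boundary, not_estimable)


def fit_reml(
    data: pd.DataFrame,
    tol_criterion: float = 1e-8,
    tol_params: float = 1e-6,
    maxiter: int = 4000,
) -> FitResult:
    """Fit the five-component nested model by REML.

    Deterministic given the data: the multi-start is a fixed grid plus
    moment estimates, with no randomness.  Estimates are constrained
    non-negative; components the optimiser drives to the boundary are
    reported as exact zeros with ``boundary_flags`` set.  Unbalanced data
    are accepted; the design summary then tallies observed levels.
    """
    df = validate_ppt_frame(data)
    if df["subject"].nunique() < 2:
        raise NotEstimableError(
            "inter-subject variance not estimable: need at least 2 subjects")
    design = Design(
        n_subjects=df["subject"].nunique(),
        n_sessions=df["session"].nunique(),
        n_sides=df["side"].nunique(),
        n_repetitions=int(df.groupby(["subject", "session", "side"])["ppt_n"]
                          .count().max()),
    )
    return _fit_core(_prepare(df), design, len(df), float(df["ppt_n"].iloc[0]),
                     tol_criterion, tol_params, maxiter)


def fit_reml_values(values: np.ndarray, **kwargs) -> FitResult:
    """Fit from a balanced (I, J, K, L) value array, bypassing DataFrame I/O.

    Fast path used by the parametric bootstrap; results are identical to
    :func:`fit_reml` on the equivalent long-format frame.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 4:
        raise ValueError("expected a 4-d (subjects, sessions, sides, reps) array")
    I, J, K, L = values.shape
    if I < 2:
        raise NotEstimableError(
            "inter-subject variance not estimable: need at least 2 subjects")
    return _fit_core(_BalancedStats.from_values(values), Design(I, J, K, L),
                     values.size, float(values.flat[0]),
                     kwargs.get("tol_criterion", 1e-8),
                     kwargs.get("tol_params", 1e-6),
                     kwargs.get("maxiter", 4000))


def variance_percentages(components: VarianceComponents) -> dict[str, float]:
    """Each component's share of the total variance, in percent.

    Shares sum to exactly 100 before any rounding.
    """
    total = components.total_variance
    if total <= 0:
        raise ValueError("variance percentages undefined: total variance is zero")
    return {name: 100.0 * value / total for name, value in components.items()}
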