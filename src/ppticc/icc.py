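"""Intraclass correlation coefficients built from variance components.

Every ICC here is the correlation between two measurements of the same
subject that differ in a declared set of factors (session, side,
repetition).  Under the nested random-effects model that correlation is a
ratio of variance components: the denominator is always the total
variance, and the numerator collects exactly those components whose
defining factors are shared between the two measurements:

* ``sigma2_subj`` is always shared (same subject);
* ``sigma2_sess`` is shared iff the session is the same;
* ``sigma2_side`` is shared iff the side is the same;
* ``sigma2_sss`` is shared iff both session and side are the same;
* ``sigma2_reps`` is shared iff the repetition is the same.

One rule therefore generates the whole family: the classic inter-session
ICC (only the session differs), the more conservative
inter-session-repetition ICC (session and repetition differ — two
measurements at different sessions can never be the same press of the
algometer), and the fully conservative variant where session, side and
repetition all differ.

A separate average-measures form, :func:`icck_session`, gives the
inter-session reliability of the mean over K sides x L repetitions per
session; its numerator is the subject variance alone while the averaged
factors shrink in the denominator by 1/K and 1/(K*L).  Increasing L along
this curve is the design lever for meeting a reliability target.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .types import VarianceComponents

__all__ = ["ICCSpec", "ICCResult", "construct_icc", "icc_two_component",
           "icck_session", "repetition_curve", "minimal_repetitions"]

_FACTORS = frozenset({"session", "side", "repetition"})


@dataclass(frozen=True)
class ICCSpec:
    """Which factors differ between the two correlated measurements.

    ``k_avg``/``l_avg`` declare averaging over sides/repetitions and are
    only meaningful for the average-measures inter-session form, i.e.
    together with ``differing_factors == {"session"}``.
    """

    differing_factors: frozenset = field(default_factory=frozenset)
    k_avg: int = 1
    l_avg: int = 1

    def __post_init__(self) -> None:
        diff = frozenset(self.differing_factors)
        object.__setattr__(self, "differing_factors", diff)
        unknown = diff - _FACTORS
        if unknown:
            raise ValueError(f"unknown factor(s): {sorted(unknown)}; "
                             f"valid factors are {sorted(_FACTORS)}")
        if self.k_avg < 1 or self.l_avg < 1:
            raise ValueError("k_avg and l_avg must be >= 1")
        if (self.k_avg > 1 or self.l_avg > 1) and diff != {"session"}:
            raise ValueError(
                "averaging over sides/repetitions is defined only for the "
                "inter-session ICC (differing_factors={'session'})")

    @property
    def name(self) -> str:
        if self.k_avg > 1 or self.l_avg > 1:
            return f"ICCk(session, K={self.k_avg}, L={self.l_avg})"
        if not self.differing_factors:
            return "ICC(identity)"
        order = ["session", "side", "repetition"]
        inside = ", ".join("reps" if f == "repetition" else f
                           for f in order if f in self.differing_factors)
        return f"ICC({inside})"


@dataclass(frozen=True)
class ICCResult:
    """An ICC value together with the exact ratio that produced it."""

    value: float
    spec: ICCSpec
    numerator: float
    denominator: float


def _require_total(components: VarianceComponents) -> float:
    total = components.total_variance
    if total <= 0:
        raise ValueError("ICC undefined: total variance is zero")
    return total


def construct_icc(components: VarianceComponents, spec: ICCSpec) -> ICCResult:
    """Single-measurement ICC for the factor set declared in ``spec``.

    The shared-component rule in the module docstring decides the
    numerator; the denominator is the total variance.  With an empty
    ``differing_factors`` the two measurements are identical and the ICC
    is exactly 1.
    """
    if spec.k_avg != 1 or spec.l_avg != 1:
        raise ValueError("construct_icc handles single measurements only; "
                         "use icck_session for averaged measurements")
    total = _require_total(components)
    diff = spec.differing_factors
    num = components.sigma2_subj
    if "session" not in diff:
        num += components.sigma2_sess
    if "side" not in diff:
        num += components.sigma2_side
    if "session" not in diff and "side" not in diff:
        num += components.sigma2_sss
    if "repetition" not in diff:
        num += components.sigma2_reps
    return ICCResult(value=num / total, spec=spec, numerator=num, denominator=total)


def icc_two_component(sigma2_subj: float, sigma2_sess: float) -> float:
    """Naive two-source inter-session ICC: subj / (subj + sess).

    This is the form traditional two-way software reports after collapsing
    the data to subjects x sessions.  It ignores side, interaction and
    repetition variability and therefore overstates reliability whenever
    those sources are non-trivial; it is kept separate precisely to make
    that comparison.
    """
    if sigma2_subj < 0 or sigma2_sess < 0:
        raise ValueError("variances must be non-negative")
    denom = sigma2_subj + sigma2_sess
    if denom <= 0:
        raise ValueError("two-component ICC undefined: both variances are zero")
    return sigma2_subj / denom


def icck_session(components: VarianceComponents, k_avg: int, l_avg: int) -> ICCResult:
    """Inter-session reliability of the session mean over K sides x L repetitions.

        ICCk = s_subj / (s_subj + s_sess + s_side/K + s_sss/K + s_reps/(K*L))

    Averaging shrinks the side, interaction and residual contributions but
    cannot touch the session variance, so as K, L grow the value rises to
    the two-component ceiling s_subj / (s_subj + s_sess).
    """
    if k_avg < 1 or l_avg < 1:
        raise ValueError("k_avg and l_avg must be >= 1")
    _require_total(components)
    num = components.sigma2_subj
    denom = (components.sigma2_subj + components.sigma2_sess
             + components.sigma2_side / k_avg
             + components.sigma2_sss / k_avg
             + components.sigma2_reps / (k_avg * l_avg))
    if denom <= 0:
        raise ValueError("ICCk undefined: denominator is zero")
    spec = ICCSpec(frozenset({"session"}), k_avg=k_avg, l_avg=l_avg)
    return ICCResult(value=num / denom, spec=spec, numerator=num, denominator=denom)


def repetition_curve(components: VarianceComponents, k_avg: int,
                     l_range) -> list[tuple[int, ICCResult]]:
    """ICCk(session) for each repetition count L in ``l_range``.

    The curve is non-decreasing in L (strictly increasing while
    ``sigma2_reps > 0``).
    """
    l_values = list(l_range)
    if not l_values:
        raise ValueError("l_range must be non-empty")
    return [(int(L), icck_session(components, k_avg, int(L))) for L in l_values]


def minimal_repetitions(components: VarianceComponents, k_avg: int,
                        threshold: float) -> int | None:
    """Smallest repetition count L with ICCk(session) >= threshold.

    Returns ``None`` ("unreachable") when even infinitely many repetitions
    on the given K sides cannot reach the threshold, i.e. when the L->inf
    limit  s_subj / (s_subj + s_sess + (s_side + s_sss)/K)  falls short.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie strictly between 0 and 1")
    _require_total(components)
    limit_denom = (components.sigma2_subj + components.sigma2_sess
                   + (components.sigma2_side + components.sigma2_sss) / k_avg)
    limit = components.sigma2_subj / limit_denom if limit_denom > 0 else 1.0
    if limit < threshold:
        return None
    L = 1
    while icck_session(components, k_avg, L).value < threshold:
        L += 1
        if L > 10 ** 9:  # unreachable in exact arithmetic; guard rounding
            return None
    return L
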