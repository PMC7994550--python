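"""Core domain types: the factorial measurement design and the variance components.

A pressure pain threshold (PPT) study measures each subject at several
sessions, on several sides (lateralities), with several repeated stimuli
per subject-session-side cell.  The random-effects model decomposes a
measurement into a fixed grand mean plus Gaussian deviations at five
levels:

    PPT[i,j,k,l] = mu + subject[i] + session[i,j] + side[i,k]
                      + session_x_side[i,j,k] + residual[i,j,k,l]

with independent zero-mean normal effects of variances sigma2_subj,
sigma2_sess, sigma2_side, sigma2_sss and sigma2_reps (all in N^2, forces
in newtons).  Sessions and sides are nested within subject; the residual
is i.i.d. per repetition.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Iterator

__all__ = ["Design", "VarianceComponents", "COMPONENT_NAMES"]

#: canonical ordering of the five variance components, used everywhere
COMPONENT_NAMES = ("sigma2_subj", "sigma2_sess", "sigma2_side", "sigma2_sss", "sigma2_reps")


@dataclass(frozen=True)
class Design:
    """Balanced factorial layout: I subjects x J sessions x K sides x L repetitions."""

    n_subjects: int
    n_sessions: int = 2
    n_sides: int = 2
    n_repetitions: int = 10

    def __post_init__(self) -> None:
        for name in ("n_subjects", "n_sessions", "n_sides", "n_repetitions"):
            v = getattr(self, name)
            if not isinstance(v, (int,)) or isinstance(v, bool):
                raise TypeError(f"{name} must be an integer, got {v!r}")
            if v < 1:
                raise ValueError(f"{name} must be >= 1, got {v}")

    @property
    def n_obs(self) -> int:
        """Total observations in the balanced design (I*J*K*L)."""
        return self.n_subjects * self.n_sessions * self.n_sides * self.n_repetitions


@dataclass(frozen=True)
class VarianceComponents:
    """The five variance components of the nested model plus the fixed grand mean.

    Units: grand_mean in newtons, variances in newtons squared.
    """

    grand_mean: float
    sigma2_subj: float
    sigma2_sess: float
    sigma2_side: float
    sigma2_sss: float
    sigma2_reps: float

    def __post_init__(self) -> None:
        for name in COMPONENT_NAMES:
            v = getattr(self, name)
            if not (v >= 0):  # also catches NaN
                raise ValueError(f"variance component {name} must be >= 0, got {v!r}")

    @property
    def total_variance(self) -> float:
        """Marginal variance of a single observation: the sum of all five components."""
        return sum(self.variances())

    def variances(self) -> tuple[float, float, float, float, float]:
        """The five components in canonical order (subj, sess, side, sss, reps)."""
        return (self.sigma2_subj, self.sigma2_sess, self.sigma2_side,
                self.sigma2_sss, self.sigma2_reps)

    def items(self) -> Iterator[tuple[str, float]]:
        for name in COMPONENT_NAMES:
            yield name, getattr(self, name)

    def replace(self, **kwargs: float) -> "VarianceComponents":
        d = asdict(self)
        d.update(kwargs)
        return VarianceComponents(**d)

    def to_dict(self) -> dict[str, float]:
        return asdict(self)


#: fitted components reported by the motivating lumbar-region PPT study
#: (20 subjects, 2 sessions, 2 sides, 10 repetitions); handy defaults for
#: simulation and worked examples.  grand_mean 50 N is a typical lumbar PPT.
REFERENCE_COMPONENTS = VarianceComponents(
    grand_mean=50.0,
    sigma2_subj=222.28,
    sigma2_sess=4.83,
    sigma2_side=9.72,
    sigma2_sss=34.63,
    sigma2_reps=45.77,
)

REFERENCE_DESIGN = Design(n_subjects=20, n_sessions=2, n_sides=2, n_repetitions=10)
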