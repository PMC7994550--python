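"""Synthetic PPT datasets with the exact nested random-effects structure.

The generator draws one Gaussian deviate per subject, per subject-session,
per subject-side, per subject-session-side cell, and one residual per
observation, then sums them onto the grand mean.  It exists so that every
downstream stage — REML fitting, ICC construction, bootstrap intervals —
is testable without access to any real algometer data.

Seeding contract: the master seed spawns one independent substream per
random effect, so changing the number of repetitions L leaves the subject,
session, side and interaction deviates untouched.  This makes designs with
different L directly comparable pair-by-pair.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd

from .io import COLUMNS
from .types import Design, VarianceComponents

__all__ = ["simulate_dataset", "drop_cells"]

# fixed spawn order of the per-effect substreams; do not reorder
_STREAMS = ("subject", "session", "side", "sss", "residual")


def _effect_rngs(seed) -> dict[str, np.random.Generator]:
    seq = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = seq.spawn(len(_STREAMS))
    return {name: np.random.default_rng(ss) for name, ss in zip(_STREAMS, children)}


def _simulate_parts(design: Design, components: VarianceComponents, seed):
    """Mean structure, residual draw and the residual stream (for resampling)."""
    I, J, K, L = (design.n_subjects, design.n_sessions,
                  design.n_sides, design.n_repetitions)
    rngs = _effect_rngs(seed)
    subj = rngs["subject"].normal(0.0, math.sqrt(components.sigma2_subj), size=I)
    sess = rngs["session"].normal(0.0, math.sqrt(components.sigma2_sess), size=(I, J))
    side = rngs["side"].normal(0.0, math.sqrt(components.sigma2_side), size=(I, K))
    sss = rngs["sss"].normal(0.0, math.sqrt(components.sigma2_sss), size=(I, J, K))
    resid = rngs["residual"].normal(0.0, math.sqrt(components.sigma2_reps),
                                    size=(I, J, K, L))
    mean_part = (components.grand_mean
                 + subj[:, None, None, None]
                 + sess[:, :, None, None]
                 + side[:, None, :, None]
                 + sss[:, :, :, None])
    return np.broadcast_to(mean_part, (I, J, K, L)).copy(), resid, rngs["residual"]


def simulate_values(design: Design, components: VarianceComponents, seed) -> np.ndarray:
    """Draw a balanced (I, J, K, L) value array from the nested model.

    Array-shaped core of :func:`simulate_dataset`; ``seed`` may be an
    integer or a ``numpy.random.SeedSequence`` (used by the bootstrap to
    hand each iteration its own substream).
    """
    mean_part, resid, _ = _simulate_parts(design, components, seed)
    return mean_part + resid


def simulate_dataset(
    design: Design,
    components: VarianceComponents,
    seed: int,
    resample_negative: bool = False,
) -> pd.DataFrame:
    """Simulate a balanced PPT dataset under the nested variance-component model.

    Parameters
    ----------
    design
        Factorial layout (I subjects, J sessions, K sides, L repetitions).
    components
        Grand mean (N) and the five variances (N^2); all variances must be
        non-negative (enforced by :class:`VarianceComponents`).
    seed
        Master seed; identical seeds give bit-identical datasets.
    resample_negative
        If True, redraw the residual of any observation whose value comes
        out negative (a physical force cannot be).  Off by default: with
        realistic components the mean is many standard deviations above
        zero, so negatives are vanishingly rare, and redrawing perturbs the
        Gaussian model.  Use of the flag is logged via a warning.

    Returns
    -------
    DataFrame in the package dialect, ordered by (subject, session, side,
    repetition), subjects labelled ``S01, S02, ...``.
    """
    if not isinstance(design, Design):
        raise TypeError("design must be a Design instance")
    I, J, K, L = (design.n_subjects, design.n_sessions,
                  design.n_sides, design.n_repetitions)
    mean_part, resid, rng = _simulate_parts(design, components, seed)
    values = mean_part + resid

    if resample_negative:
        warnings.warn(
            "resample_negative is active: negative simulated forces are being "
            "redrawn, which truncates the Gaussian residual distribution",
            stacklevel=2,
        )
        sd = math.sqrt(components.sigma2_reps)
        for _ in range(100):
            neg = values < 0
            if not neg.any():
                break
            values[neg] = mean_part[neg] + rng.normal(0.0, sd, size=int(neg.sum()))
        else:
            raise RuntimeError(
                "could not obtain non-negative forces by residual resampling; "
                "the mean structure itself is negative for some cells"
            )

    width = max(2, len(str(I)))
    subjects = np.array([f"S{i + 1:0{width}d}" for i in range(I)])
    idx = np.indices((I, J, K, L)).reshape(4, -1)
    return pd.DataFrame(
        {
            "subject": subjects[idx[0]],
            "session": idx[1] + 1,
            "side": idx[2] + 1,
            "repetition": idx[3] + 1,
            "ppt_n": values.ravel(),
        },
        columns=COLUMNS,
    )


def drop_cells(data: pd.DataFrame, fraction: float, seed: int) -> pd.DataFrame:
    """Randomly delete ``floor(fraction * n)`` rows, keeping every subject represented.

    Produces deliberately unbalanced data for exercising the REML fitter.
    Raises ``ValueError`` if the requested fraction cannot be met while
    leaving at least one observation per subject.
    """
    if not 0 <= fraction < 1:
        raise ValueError(f"fraction must be in [0, 1), got {fraction}")
    n = len(data)
    n_drop = math.floor(fraction * n)
    if n_drop == 0:
        return data.copy()
    n_subjects = data["subject"].nunique()
    if n_drop > n - n_subjects:
        raise ValueError(
            f"dropping {n_drop} of {n} rows would leave some subject with no "
            f"observations ({n_subjects} subjects present)"
        )
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    remaining = data["subject"].value_counts().to_dict()
    subjects = data["subject"].to_numpy()
    dropped: list[int] = []
    for pos in order:
        if len(dropped) == n_drop:
            break
        s = subjects[pos]
        if remaining[s] > 1:
            remaining[s] -= 1
            dropped.append(pos)
    keep = np.setdiff1d(np.arange(n), np.array(dropped))
    return data.iloc[keep].reset_index(drop=True)
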