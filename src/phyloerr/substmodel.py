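"""Kimura two-parameter (K2P) substitution model.

The model has uniform stationary base frequencies (1/4 each) and two rate
classes: transitions (A<->G, C<->T) at per-site rate ``alpha`` and each of the
two transversion targets at rate ``beta``.  Rates are normalized so that one
unit of branch length equals one expected substitution per site:
``alpha + 2*beta = 1``.  The single free parameter is the
transition/transversion ratio ``R = alpha / (2*beta)``; ``R = 0.5`` recovers
Jukes-Cantor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

#: index order of the nucleotide states everywhere in this package
BASES = "ACGT"

#: transition partner of each state index (A<->G, C<->T)
TRANSITION_PARTNER = (2, 3, 0, 1)


@dataclass(frozen=True)
class SubstModel:
    """Normalized K2P parameterization.

    Attributes
    ----------
    ts_tv_ratio : float
        R, the ratio of the total transition rate to the total transversion
        rate at equilibrium.
    alpha : float
        Per-site transition rate, ``R / (R + 1)``.
    beta : float
        Per-site rate toward each single transversion target,
        ``1 / (2 * (R + 1))``.
    """

    ts_tv_ratio: float
    alpha: float
    beta: float


def build_model(ts_tv_ratio: float) -> SubstModel:
    """Build a normalized K2P model from the transition/transversion ratio.

    Raises
    ------
    ValueError
        If ``ts_tv_ratio`` is not a positive finite number.
    """
    r = float(ts_tv_ratio)
    if not math.isfinite(r) or r <= 0.0:
        raise ValueError(f"ts_tv_ratio must be a positive finite number, got {ts_tv_ratio!r}")
    alpha = r / (r + 1.0)
    beta = 1.0 / (2.0 * (r + 1.0))
    return SubstModel(ts_tv_ratio=r, alpha=alpha, beta=beta)


def rate_matrix(model: SubstModel) -> np.ndarray:
    """Instantaneous generator Q (rows sum to zero, -sum_x pi_x Q_xx = 1)."""
    q = np.full((4, 4), model.beta)
    for x in range(4):
        q[x, TRANSITION_PARTNER[x]] = model.alpha
        q[x, x] = 0.0
        q[x, x] = -q[x].sum()
    return q


def transition_matrix(model: SubstModel, branch_length: float) -> np.ndarray:
    """4x4 matrix ``P[x, y] = Pr(end base y | start base x, length b)``.

    Uses the K2P closed form; rows sum to 1 and the matrix is symmetric
    (detailed balance under the uniform stationary distribution).

    Raises
    ------
    ValueError
        If ``branch_length`` is negative or not finite.
    """
    b = float(branch_length)
    if not math.isfinite(b) or b < 0.0:
        raise ValueError(f"branch length must be finite and >= 0, got {branch_length!r}")
    return _matrix_from_probs(*transition_probs(model.alpha, model.beta, b))


def transition_probs(alpha: float, beta: float, b: float) -> tuple[float, float]:
    """(transition probability, per-target transversion probability) at length b."""
    e1 = math.exp(-4.0 * beta * b)
    e2 = math.exp(-2.0 * (alpha + beta) * b)
    p_ts = 0.25 + 0.25 * e1 - 0.5 * e2
    p_tv = 0.25 - 0.25 * e1
    return p_ts, p_tv


def _matrix_from_probs(p_ts: float, p_tv: float) -> np.ndarray:
    p = np.full((4, 4), p_tv)
    for x in range(4):
        p[x, TRANSITION_PARTNER[x]] = p_ts
        p[x, x] = 1.0 - p_ts - 2.0 * p_tv
    return p
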