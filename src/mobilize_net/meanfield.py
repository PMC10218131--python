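"""Well-mixed (mean-field) replicator analysis of the game.

Let ``m`` be the fraction of SRSs participating positively and ``r`` the
fraction of GRSs mobilizing positively.  Averaging the payoff matrix over
the opposite population gives the expected gains

    He1 = r(pi_e - c_e + gamma) + (1-r)(pi_e - c_e)      (positive SRS)
    He2 = r(pi_e - delta)       + (1-r) pi_e             (negative SRS)
    Hg1 = m(pi_g - c_g) + (1-m)(pi_g - c_g + beta*delta) (positive GRS)
    Hg2 = m(-c_v)       + (1-m)(-c_v - c_s)              (negative GRS)

with population means ``He = m He1 + (1-m) He2`` and
``Hg = r Hg1 + (1-r) Hg2``.  The replicator dynamics reduce to

    dm/dt = m(1-m) [ r(gamma+delta) - c_e ]
    dr/dt = r(1-r) [ A - m B ],   A = pi_g - c_g + beta*delta + c_s + c_v,
                                  B = c_s + beta*delta.

Five fixed-point candidates exist: the four corners of the unit square and
the interior point ``m* = A/B``, ``r* = c_e/(gamma+delta)`` (when both lie
in [0, 1]).  Stability is read off the 2x2 Jacobian: stable iff Det > 0 and
Tr < 0, saddle iff Det < 0, unstable iff Det > 0 and Tr > 0, and
non-hyperbolic when Det = 0 or Tr = 0 with Det > 0 (the interior point
always has Tr = 0, so it is never asymptotically stable here).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, replace
from typing import List, Optional, Tuple

import numpy as np

from mobilize_net.payoff_core import GameParameters

__all__ = [
    "ReplicatorState",
    "ExpectedGains",
    "Stability",
    "FixedPointReport",
    "expected_gains",
    "replicator_rhs",
    "jacobian",
    "find_fixed_points",
    "classify_stability",
    "integrate_trajectory",
]

#: tolerance for the Det/Tr sign tests in stability classification
SIGN_TOL = 1e-9


@dataclass(frozen=True)
class ReplicatorState:
    """A mean-field point: positive fractions of the two populations."""

    m: float  # fraction of SRSs playing POSITIVE
    r: float  # fraction of GRSs playing POSITIVE

    def __post_init__(self) -> None:
        if not (0.0 <= self.m <= 1.0 and 0.0 <= self.r <= 1.0):
            raise ValueError(
                f"state must lie in the unit square, got (m={self.m}, r={self.r})"
            )


@dataclass(frozen=True)
class ExpectedGains:
    """Strategy-conditional and population-mean expected gains."""

    He1: float
    He2: float
    He: float
    Hg1: float
    Hg2: float
    Hg: float


class Stability(enum.Enum):
    STABLE = "stable"
    UNSTABLE = "unstable"
    SADDLE = "saddle"
    NONHYPERBOLIC = "nonhyperbolic"


@dataclass(frozen=True)
class FixedPointReport:
    """A fixed-point candidate with its Jacobian invariants.

    ``exists`` is False only for an interior candidate whose coordinates
    fall outside the unit square or that is undefined (``gamma+delta=0``);
    corner candidates always exist.  ``det_j``/``tr_j``/``stability`` are
    filled by :func:`classify_stability` and are None for a non-existing
    interior point.
    """

    point: Optional[ReplicatorState]
    interior: bool = False
    exists: bool = True
    det_j: Optional[float] = None
    tr_j: Optional[float] = None
    stability: Optional[Stability] = None


def expected_gains(state: ReplicatorState, params: GameParameters) -> ExpectedGains:
    """Expected gains of each strategy and the population means at ``state``."""
    p, m, r = params, state.m, state.r
    He1 = r * (p.pi_e - p.c_e + p.gamma) + (1 - r) * (p.pi_e - p.c_e)
    He2 = r * (p.pi_e - p.delta) + (1 - r) * p.pi_e
    Hg1 = m * (p.pi_g - p.c_g) + (1 - m) * (p.pi_g - p.c_g + p.beta * p.delta)
    Hg2 = m * (-p.c_v) + (1 - m) * (-p.c_v - p.c_s)
    return ExpectedGains(
        He1=He1,
        He2=He2,
        He=m * He1 + (1 - m) * He2,
        Hg1=Hg1,
        Hg2=Hg2,
        Hg=r * Hg1 + (1 - r) * Hg2,
    )


def _brackets(params: GameParameters) -> Tuple[float, float, float]:
    """Constants of the closed-form right-hand sides: (gamma+delta, A, B)."""
    p = params
    A = p.pi_g - p.c_g + p.beta * p.delta + p.c_s + p.c_v
    B = p.c_s + p.beta * p.delta
    return p.gamma + p.delta, A, B


def replicator_rhs(
    state: ReplicatorState, params: GameParameters
) -> Tuple[float, float]:
    """Time derivatives (dm/dt, dr/dt) of the replicator dynamics."""
    gd, A, B = _brackets(params)
    m, r = state.m, state.r
    dm = m * (1 - m) * (r * gd - params.c_e)
    dr = r * (1 - r) * (A - m * B)
    return dm, dr


def jacobian(state: ReplicatorState, params: GameParameters) -> np.ndarray:
    """Analytic 2x2 Jacobian of :func:`replicator_rhs` at ``state``."""
    gd, A, B = _brackets(params)
    m, r = state.m, state.r
    return np.array(
        [
            [(1 - 2 * m) * (r * gd - params.c_e), m * (1 - m) * gd],
            [-r * (1 - r) * B, (1 - 2 * r) * (A - m * B)],
        ]
    )


def find_fixed_points(params: GameParameters) -> List[FixedPointReport]:
    """Enumerate the five fixed-point candidates, classified for stability.

    Always returns five reports: the four corners (in the order (0,0),
    (0,1), (1,0), (1,1)) followed by the interior candidate.  The interior
    point is flagged ``exists=False`` when ``gamma+delta=0`` (its r-
    coordinate is undefined) or when either coordinate falls outside
    [0, 1].
    """
    gd, A, B = _brackets(params)
    reports = [
        FixedPointReport(point=ReplicatorState(m, r))
        for m, r in ((0.0, 0.0), (0.0, 1.0), (1.0, 0.0), (1.0, 1.0))
    ]
    interior = FixedPointReport(point=None, interior=True, exists=False)
    if gd > 0 and B > 0:
        m_star, r_star = A / B, params.c_e / gd
        if 0.0 <= m_star <= 1.0 and 0.0 <= r_star <= 1.0:
            interior = FixedPointReport(
                point=ReplicatorState(m_star, r_star), interior=True, exists=True
            )
    reports.append(interior)
    return [classify_stability(fp, params) for fp in reports]


def classify_stability(
    fp: FixedPointReport, params: GameParameters
) -> FixedPointReport:
    """Fill in Det(J), Tr(J) and the stability class of a candidate.

    Uses the analytic Jacobian; sign tests carry tolerance ``SIGN_TOL``.
    A non-existing interior candidate is returned unchanged.
    """
    if not fp.exists or fp.point is None:
        return fp
    J = jacobian(fp.point, params)
    det = float(np.linalg.det(J))
    tr = float(np.trace(J))
    if det < -SIGN_TOL:
        stab = Stability.SADDLE
    elif det > SIGN_TOL and tr < -SIGN_TOL:
        stab = Stability.STABLE
    elif det > SIGN_TOL and tr > SIGN_TOL:
        stab = Stability.UNSTABLE
    else:
        stab = Stability.NONHYPERBOLIC
    return replace(fp, det_j=det, tr_j=tr, stability=stab)


def integrate_trajectory(
    state0: ReplicatorState,
    params: GameParameters,
    horizon: float,
    step: float = 0.01,
) -> List[ReplicatorState]:
    """Integrate the replicator ODEs with fixed-step RK4.

    The system is smooth and confined to the unit square, so a fixed-step
    explicit scheme suffices; the state is clipped to [0, 1] only within
    numerical round-off.  Returns the states at t = 0, step, 2*step, ...
    up to ``horizon``.
    """
    if horizon <= 0 or step <= 0:
        raise ValueError("horizon and step must be positive")

    def f(y: np.ndarray) -> np.ndarray:
        m, r = y
        gd, A, B = _brackets(params)
        return np.array(
            [m * (1 - m) * (r * gd - params.c_e), r * (1 - r) * (A - m * B)]
        )

    y = np.array([state0.m, state0.r], dtype=float)
    out = [state0]
    n_steps = int(round(horizon / step))
    for _ in range(n_steps):
        k1 = f(y)
        k2 = f(y + 0.5 * step * k1)
        k3 = f(y + 0.5 * step * k2)
        k4 = f(y + step * k3)
        y = y + (step / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        if not np.all(np.isfinite(y)):
            raise FloatingPointError(
                f"non-finite state encountered during integration: {y}"
            )
        # replicator flow cannot leave the unit square; clip round-off only
        y = np.clip(y, 0.0, 1.0)
        out.append(ReplicatorState(float(y[0]), float(y[1])))
    return out
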