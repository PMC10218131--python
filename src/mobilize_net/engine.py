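"""Networked evolutionary game engine.

Each round every node plays the stage game with each of its cross-role
neighbors and accumulates the round gain ``u_i`` (same-role ties carry no
game payoff but remain learning channels).  Every node then selects one
neighbor ``j`` as a learning object with Boltzmann (softmax) probability

    B_j = exp((u_j + alpha_j) / lambda) / sum_{k in J_i} exp((u_k + alpha_k) / lambda)

and adopts j's current strategy with the Fermi probability

    omega(s_i -> s_j) = 1 / (1 + exp((u_i - u_j) / xi)).

Updates are synchronous.  ``lambda`` is an information-cost parameter
(large lambda -> near-uniform neighbor choice), ``xi`` a noise parameter
(xi -> 0 gives deterministic imitation of strictly better-off neighbors),
and ``alpha_j`` an adjusting weight, zero by default.  Strategy labels
transfer across roles by default: a GRS may copy POSITIVE/NEGATIVE from an
SRS neighbor and vice versa, which is how the network dynamics can leave
the mean-field prediction (e.g. all nodes turning negative even though the
well-mixed analysis sends GRSs positive).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Union

import numpy as np
import pandas as pd

from mobilize_net.network import GeneratorConfig, Role, TypedNetwork, generate_network
from mobilize_net.payoff_core import GameParameters, Strategy, pair_payoff

__all__ = [
    "LearningParameters",
    "SimulationConfig",
    "RoundPayoffs",
    "Trajectory",
    "initialize_strategies",
    "play_round",
    "selection_probabilities",
    "select_learning_target",
    "adoption_probability",
    "step",
    "run_simulation",
]

StrategyMap = Dict[str, Strategy]


@dataclass(frozen=True)
class LearningParameters:
    """Learning-rule parameters: information cost, noise, adjusting weight."""

    lam: float = 1.0  # information-cost parameter of the softmax selection
    xi: float = 1.0  # noise parameter of the Fermi adoption rule
    alpha: float = 0.0  # adjusting weight added to every neighbor's gain

    def __post_init__(self) -> None:
        if not self.lam > 0:
            raise ValueError(f"lam must be positive, got {self.lam}")
        if not self.xi > 0:
            raise ValueError(f"xi must be positive, got {self.xi}")


@dataclass(frozen=True)
class RoundPayoffs:
    """Accumulated round gains u_i(t), one entry per node (0 if isolated)."""

    u: Dict[str, float]


@dataclass
class SimulationConfig:
    """Full configuration of one simulation experiment."""

    params: GameParameters = field(default_factory=GameParameters)
    learning: LearningParameters = field(default_factory=LearningParameters)
    network: Union[TypedNetwork, GeneratorConfig] = field(
        default_factory=GeneratorConfig
    )
    m0: float = 0.1  # initial positive fraction among SRSs
    r0: float = 0.4  # initial positive fraction among GRSs
    rounds: int = 100
    reps: int = 20
    seed: int = 0
    quiescence_window: int = 20  # unchanged rounds that trigger early stop
    cross_role_learning: bool = True

    def __post_init__(self) -> None:
        if not (0.0 <= self.m0 <= 1.0 and 0.0 <= self.r0 <= 1.0):
            raise ValueError("m0 and r0 must lie in [0, 1]")
        if self.rounds < 1 or self.reps < 1:
            raise ValueError("rounds and reps must each be at least 1")

    def resolve_network(self) -> TypedNetwork:
        if isinstance(self.network, TypedNetwork):
            return self.network
        return generate_network(self.network)


@dataclass
class Trajectory:
    """Per-round, per-replicate observables of one simulation.

    Arrays have shape (reps, rounds+1); index 0 is the initial state.
    ``pps_*`` are proportions of positive strategies (overall / GRS-only /
    SRS-only); ``mean_gain`` is the per-node average round gain.
    Replicates that absorb early are padded with their final values so the
    series align; ``absorption_round[k]`` records when replicate k last
    changed (-1 if it never went quiescent).
    """

    pps_all: np.ndarray
    pps_grs: np.ndarray
    pps_srs: np.ndarray
    mean_gain: np.ndarray
    absorption_round: np.ndarray
    n_grs: int
    n_srs: int

    @property
    def reps(self) -> int:
        return self.pps_all.shape[0]

    @property
    def rounds(self) -> int:
        return self.pps_all.shape[1] - 1

    def mean_series(self, name: str = "pps_all") -> np.ndarray:
        """Replicate-averaged series of one observable."""
        return getattr(self, name).mean(axis=0)

    def final_statistic(self, name: str = "pps_all", window: int = 20) -> float:
        """Replicate-mean of the observable averaged over the last ``window`` rounds."""
        arr = getattr(self, name)
        return float(arr[:, -window:].mean())

    def to_dataframe(self) -> pd.DataFrame:
        """Long-format table with columns (rep, round, pps_all, pps_grs, pps_srs, mean_gain)."""
        reps, cols = self.pps_all.shape
        idx = pd.MultiIndex.from_product(
            [range(reps), range(cols)], names=["rep", "round"]
        )
        return pd.DataFrame(
            {
                "pps_all": self.pps_all.ravel(),
                "pps_grs": self.pps_grs.ravel(),
                "pps_srs": self.pps_srs.ravel(),
                "mean_gain": self.mean_gain.ravel(),
            },
            index=idx,
        ).reset_index()

    def mean_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "round": np.arange(self.pps_all.shape[1]),
                "pps_all": self.mean_series("pps_all"),
                "pps_grs": self.mean_series("pps_grs"),
                "pps_srs": self.mean_series("pps_srs"),
                "mean_gain": self.mean_series("mean_gain"),
            }
        )


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def initialize_strategies(
    net: TypedNetwork, m0: float, r0: float, rng: np.random.Generator
) -> StrategyMap:
    """Assign exactly round(n_srs*m0) positive SRSs and round(n_grs*r0) positive GRSs.

    Positive nodes are drawn uniformly at random within each role; the
    exact-count assignment (rather than independent Bernoulli draws)
    reduces replicate variance while matching the stated proportions.
    """
    if not (0.0 <= m0 <= 1.0 and 0.0 <= r0 <= 1.0):
        raise ValueError("m0 and r0 must lie in [0, 1]")
    strategies: StrategyMap = {}
    for role, frac in ((Role.SRS, m0), (Role.GRS, r0)):
        ids = net.nodes_with_role(role)
        k = _round_half_up(len(ids) * frac)
        positive = set(rng.choice(len(ids), size=k, replace=False)) if k else set()
        for idx, node in enumerate(ids):
            strategies[node] = (
                Strategy.POSITIVE if idx in positive else Strategy.NEGATIVE
            )
    return strategies


def play_round(
    net: TypedNetwork, strategies: StrategyMap, params: GameParameters
) -> RoundPayoffs:
    """Accumulate each node's round gain over its cross-role neighbor games.

    Same-role edges contribute zero payoff (the stage game is defined only
    between an SRS and a GRS); gains are recomputed fresh each round.
    """
    u = {n: 0.0 for n in net.node_ids}
    for a, b in net.edges:
        ra, rb = net.role(a), net.role(b)
        if ra is rb:
            continue
        srs, grs = (a, b) if ra is Role.SRS else (b, a)
        pay = pair_payoff(strategies[srs], strategies[grs], params)
        u[srs] += pay.srs_gain
        u[grs] += pay.grs_gain
    return RoundPayoffs(u=u)


def selection_probabilities(
    i: str,
    net: TypedNetwork,
    payoffs: RoundPayoffs,
    learning: LearningParameters,
    neighbors: Optional[List[str]] = None,
) -> Dict[str, float]:
    """Boltzmann learning-object probabilities over i's neighbor set.

    Each neighbor j gets probability proportional to
    exp((u_j + alpha_j)/lambda), normalized over the neighbor set (self
    excluded).  The exponent is max-shifted for numerical safety, which
    leaves the probabilities unchanged.  Empty for isolated nodes.
    """
    J = net.neighbors(i) if neighbors is None else neighbors
    if not J:
        return {}
    scores = [(payoffs.u[j] + learning.alpha) / learning.lam for j in J]
    shift = max(scores)
    weights = [math.exp(s - shift) for s in scores]
    total = sum(weights)
    return {j: w / total for j, w in zip(J, weights)}


def select_learning_target(
    i: str,
    net: TypedNetwork,
    payoffs: RoundPayoffs,
    learning: LearningParameters,
    rng: np.random.Generator,
    neighbors: Optional[List[str]] = None,
) -> Optional[str]:
    """Sample one neighbor of ``i`` as the learning object (None if isolated).

    Samples from :func:`selection_probabilities`.
    """
    probs = selection_probabilities(i, net, payoffs, learning, neighbors)
    if not probs:
        return None
    x = rng.random()
    acc = 0.0
    items = list(probs.items())
    for j, p in items:
        acc += p
        if x < acc:
            return j
    return items[-1][0]


def adoption_probability(u_i: float, u_j: float, xi: float) -> float:
    """Fermi probability that i adopts j's strategy: 1/(1+exp((u_i-u_j)/xi))."""
    if not xi > 0:
        raise ValueError(f"xi must be positive, got {xi}")
    z = (u_i - u_j) / xi
    if z > 700.0:  # avoid overflow; probability underflows to 0 anyway
        return 0.0
    return 1.0 / (1.0 + math.exp(z))


def step(
    net: TypedNetwork,
    strategies: StrategyMap,
    params: GameParameters,
    learning: LearningParameters,
    rng: np.random.Generator,
    payoffs: Optional[RoundPayoffs] = None,
    cross_role_learning: bool = True,
    _neighbor_cache: Optional[Dict[str, List[str]]] = None,
) -> StrategyMap:
    """One synchronous update: every node picks a target and maybe imitates.

    ``payoffs`` defaults to a fresh :func:`play_round` on the current
    strategies.  With ``cross_role_learning`` off, only same-role
    neighbors are eligible learning objects.
    """
    if payoffs is None:
        payoffs = play_round(net, strategies, params)
    if _neighbor_cache is None:
        _neighbor_cache = {n: net.neighbors(n) for n in net.node_ids}
    new: StrategyMap = {}
    for i in net.node_ids:
        J = _neighbor_cache[i]
        if not cross_role_learning:
            J = [j for j in J if net.role(j) is net.role(i)]
        j = select_learning_target(i, net, payoffs, learning, rng, neighbors=J)
        s = strategies[i]
        if j is not None:
            omega = adoption_probability(payoffs.u[i], payoffs.u[j], learning.xi)
            if rng.random() < omega:
                s = strategies[j]
        new[i] = s
    return new


def run_simulation(config: SimulationConfig) -> Trajectory:
    """Run the full replicated simulation and collect trajectories.

    Each replicate k uses an independent RNG seeded ``config.seed + k`` so
    replicates are individually reproducible.  A replicate stops early
    once no node has changed strategy for ``quiescence_window`` consecutive
    rounds (homogeneous states are absorbing and always trigger this);
    its series are padded with the final values so replicate arrays align.
    """
    net = config.resolve_network()
    node_ids = net.node_ids
    roles = {n: net.role(n) for n in node_ids}
    grs_nodes = [n for n in node_ids if roles[n] is Role.GRS]
    srs_nodes = [n for n in node_ids if roles[n] is Role.SRS]
    n_grs, n_srs, n_all = len(grs_nodes), len(srs_nodes), len(node_ids)
    neighbor_cache = {n: net.neighbors(n) for n in node_ids}

    shape = (config.reps, config.rounds + 1)
    pps_all = np.empty(shape)
    pps_grs = np.empty(shape)
    pps_srs = np.empty(shape)
    mean_gain = np.empty(shape)
    absorption = np.full(config.reps, -1, dtype=int)

    for k in range(config.reps):
        rng = np.random.default_rng(config.seed + k)
        strategies = initialize_strategies(net, config.m0, config.r0, rng)
        quiet_streak = 0
        last = config.rounds
        for t in range(config.rounds + 1):
            payoffs = play_round(net, strategies, config.params)
            pos_g = sum(strategies[n] is Strategy.POSITIVE for n in grs_nodes)
            pos_s = sum(strategies[n] is Strategy.POSITIVE for n in srs_nodes)
            pps_grs[k, t] = pos_g / n_grs if n_grs else 0.0
            pps_srs[k, t] = pos_s / n_srs if n_srs else 0.0
            pps_all[k, t] = (pos_g + pos_s) / n_all
            g = math.fsum(payoffs.u.values()) / n_all
            if not math.isfinite(g):
                raise FloatingPointError(f"non-finite mean gain at round {t}")
            mean_gain[k, t] = g
            if t == config.rounds:
                break
            new = step(
                net,
                strategies,
                config.params,
                config.learning,
                rng,
                payoffs=payoffs,
                cross_role_learning=config.cross_role_learning,
                _neighbor_cache=neighbor_cache,
            )
            changed = sum(new[n] is not strategies[n] for n in node_ids)
            strategies = new
            quiet_streak = 0 if changed else quiet_streak + 1
            if quiet_streak >= config.quiescence_window:
                last = t
                break
        if last < config.rounds:
            absorption[k] = max(last - config.quiescence_window + 1, 0)
            for arr in (pps_all, pps_grs, pps_srs, mean_gain):
                arr[k, last + 1 :] = arr[k, last]
    return Trajectory(
        pps_all=pps_all,
        pps_grs=pps_grs,
        pps_srs=pps_srs,
        mean_gain=mean_gain,
        absorption_round=absorption,
        n_grs=n_grs,
        n_srs=n_srs,
    )
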