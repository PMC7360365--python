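"""Stochastic assembly through compartment series as a continuous-time
Markov chain over oligomer states.

Within a compartment, each matching (enzyme, site) pair fires with a
constant propensity equal to the enzyme's concentration, so the growing
oligomer performs a CTMC on the compartment's reaction network.  The
oligomer exits after an exponentially distributed time with mean ``T``
(transport model) or after exactly ``T`` (maturation model); ``T = ∞``
sends all probability mass to terminal oligomers.  The Shannon entropy of
the exit distribution, in bits, quantifies the microheterogeneity of the
resulting glycan profile.

Exact computation uses the resolvent of the generator (transport), the
matrix exponential (maturation), or absorption probabilities of the
embedded jump chain (``T = ∞``).  The Monte Carlo path samples Gillespie
trajectories and serves as an independent cross-check of the exact path.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .diagnostics import (
    Compartment,
    DEFAULT_SIZE_CAP,
    build_reaction_network,
    detect_runaway,
)
from .enzymes import match_sites
from .oligomer import Oligomer, add_monomer

__all__ = [
    "OutputDistribution",
    "EntropyCurve",
    "RunawayError",
    "exact_output_distribution",
    "simulate_compartment",
    "run_series",
    "shannon_entropy",
    "entropy_curve",
    "EXACT_STATE_CAP",
]

EXACT_STATE_CAP = 500


class RunawayError(RuntimeError):
    """Exact computation requested where a runaway reaction makes the
    terminal distribution ill-defined (infinite residence time with a
    reachable linkage loop)."""


@dataclass
class OutputDistribution:
    """A probability distribution over exit oligomers."""

    probabilities: dict[Oligomer, float]
    method: str = "exact"
    n_samples: int | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        total = sum(self.probabilities.values())
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ValueError(f"probabilities sum to {total}, not 1")
        if any(p < -1e-12 or p > 1 + 1e-12 for p in self.probabilities.values()):
            raise ValueError("probabilities outside [0, 1]")

    @classmethod
    def point(cls, o: Oligomer) -> "OutputDistribution":
        return cls({o: 1.0})

    def support(self, atol: float = 1e-12) -> list[Oligomer]:
        return sorted(
            (o for o, p in self.probabilities.items() if p > atol),
            key=lambda o: o.canonical,
        )

    def prob(self, o: Oligomer) -> float:
        return self.probabilities.get(o, 0.0)

    def by_string(self) -> dict[str, float]:
        return {o.canonical: p for o, p in sorted(
            self.probabilities.items(), key=lambda kv: kv[0].canonical)}

    def pruned(self, atol: float = 1e-15) -> "OutputDistribution":
        kept = {o: p for o, p in self.probabilities.items() if p > atol}
        total = sum(kept.values())
        return OutputDistribution(
            {o: p / total for o, p in kept.items()},
            method=self.method, n_samples=self.n_samples, seed=self.seed,
        )


@dataclass
class EntropyCurve:
    T_grid: list[float]
    entropies: list[float]
    scenario: str = ""

    def __post_init__(self) -> None:
        if len(self.T_grid) != len(self.entropies):
            raise ValueError("grid and entropy lists differ in length")
        if any(h < -1e-12 for h in self.entropies):
            raise ValueError("negative entropy")


def shannon_entropy(d: OutputDistribution) -> float:
    """−Σ p·log₂p in bits, with 0·log0 = 0."""
    h = -sum(p * math.log2(p) for p in d.probabilities.values() if p > 0)
    return float(max(0.0, h))


# -- exact computation -------------------------------------------------------


def _multi_source_network(
    c: Compartment, inputs: list[Oligomer], size_cap: int
) -> tuple[list[Oligomer], dict[str, int], np.ndarray, list[bool], bool]:
    """Union reaction network over the input support; returns states, the
    index map, the dense generator Q, per-state clipped flags and a
    global truncation flag."""
    states: list[Oligomer] = []
    index: dict[str, int] = {}
    clipped: list[bool] = []
    edges: dict[tuple[int, int], float] = {}
    truncated = False
    for o in inputs:
        net = build_reaction_network(c, o, size_cap)
        truncated = truncated or net.truncated
        for key in net.graph.nodes:
            if key not in index:
                index[key] = len(states)
                states.append(net.oligomer(key))
                clipped.append(bool(net.graph.nodes[key]["clipped"]))
            elif net.graph.nodes[key]["clipped"]:
                clipped[index[key]] = True
        for u, v, d in net.graph.edges(data=True):
            edges[(index[u], index[v])] = d["rate"]
    n = len(states)
    if n > EXACT_STATE_CAP:
        raise RunawayError(
            f"exact state space ({n}) exceeds the cap ({EXACT_STATE_CAP}); "
            "use Monte Carlo simulation or lower the size cap"
        )
    Q = np.zeros((n, n))
    for (i, j), rate in edges.items():
        Q[i, j] += rate
        Q[i, i] -= rate
    return states, index, Q, clipped, truncated


def exact_output_distribution(
    c: Compartment,
    input_dist: OutputDistribution,
    size_cap: int = DEFAULT_SIZE_CAP,
    *,
    allow_clipped: bool = False,
) -> OutputDistribution:
    """Exit distribution of the compartment CTMC, computed exactly.

    Raises :class:`RunawayError` for an infinite residence time with a
    reachable runaway reaction (no terminal distribution exists).  With
    ``allow_clipped`` the size-capped network is used as-is, treating
    clipped states as absorbing — an explicit approximation for runaway
    scenarios probed at finite times.
    """
    T = c.residence_time
    inputs = input_dist.support()
    if not c.enzymes or T == 0:
        return OutputDistribution(dict(input_dist.probabilities))
    if math.isinf(T) and not allow_clipped:
        for o in inputs:
            if detect_runaway(c, o):
                raise RunawayError(
                    "runaway reaction reachable at infinite residence time"
                )
    states, index, Q, clipped, truncated = _multi_source_network(c, inputs, size_cap)
    if truncated and not allow_clipped and math.isinf(T):
        raise RunawayError("size cap hit while expanding at infinite residence time")
    n = len(states)
    pi0 = np.zeros(n)
    for o in inputs:
        pi0[index[o.canonical]] = input_dist.prob(o)

    if math.isinf(T):
        out = _absorb(Q, pi0)
    elif c.exit_model == "transport":
        lam = 1.0 / T
        out = np.linalg.solve((lam * np.eye(n) - Q).T, lam * pi0)
    else:  # maturation: fixed exit time
        out = pi0 @ scipy.linalg.expm(Q * T)
    out = np.clip(out, 0.0, None)
    out = out / out.sum()
    probs = {states[i]: float(out[i]) for i in range(n) if out[i] > 0}
    return OutputDistribution(probs, method="exact")


def _absorb(Q: np.ndarray, pi0: np.ndarray) -> np.ndarray:
    """Distribution over absorbing (terminal) states at t → ∞."""
    n = Q.shape[0]
    rates = -np.diag(Q)
    transient = rates > 0
    out = np.zeros(n)
    out[~transient] = pi0[~transient]
    if transient.any():
        idx_t = np.where(transient)[0]
        idx_a = np.where(~transient)[0]
        # embedded jump chain restricted to transient states
        P_tt = Q[np.ix_(idx_t, idx_t)] / rates[idx_t, None]
        np.fill_diagonal(P_tt, 0.0)
        P_ta = Q[np.ix_(idx_t, idx_a)] / rates[idx_t, None]
        # expected visits: solve (I - P_tt)^T x = pi0_t
        visits = np.linalg.solve((np.eye(len(idx_t)) - P_tt).T, pi0[idx_t])
        out[idx_a] += visits @ P_ta
    return out


# -- Monte Carlo -------------------------------------------------------------


def simulate_compartment(
    c: Compartment,
    input_dist: OutputDistribution,
    n_samples: int,
    seed: int | None = None,
    size_cap: int = 10_000,
) -> OutputDistribution:
    """Gillespie trajectories with exit per the compartment's exit model;
    reproducible given a seed."""
    if n_samples < 1:
        raise ValueError("need at least one sample")
    rng = np.random.default_rng(seed)
    inputs = input_dist.support(atol=0.0)
    weights = np.array([input_dist.prob(o) for o in inputs])
    weights = weights / weights.sum()
    move_cache: dict[Oligomer, list[tuple[float, Oligomer]]] = {}

    def moves(o: Oligomer) -> list[tuple[float, Oligomer]]:
        cached = move_cache.get(o)
        if cached is None:
            cached = []
            for e in c.sorted_enzymes:
                if e.concentration == 0:
                    continue
                for s in match_sites(e, o):
                    cached.append(
                        (e.concentration, add_monomer(o, s, e.donor_type, e.donor_carbon))
                    )
            move_cache[o] = cached
        return cached

    T = c.residence_time
    counts: dict[Oligomer, int] = {}
    for _ in range(n_samples):
        o = inputs[rng.choice(len(inputs), p=weights)]
        if math.isinf(T):
            exit_t = math.inf
        elif c.exit_model == "transport":
            exit_t = rng.exponential(T)
        else:
            exit_t = T
        t = 0.0
        while True:
            mv = moves(o)
            if not mv:
                break
            total = sum(r for r, _ in mv)
            t += rng.exponential(1.0 / total)
            if t > exit_t:
                break
            r = rng.random() * total
            acc = 0.0
            for rate, product in mv:
                acc += rate
                if r <= acc:
                    o = product
                    break
            if o.size > size_cap:
                raise RunawayError("trajectory exceeded the size cap")
        counts[o] = counts.get(o, 0) + 1
    probs = {o: k / n_samples for o, k in counts.items()}
    return OutputDistribution(probs, method="monte_carlo", n_samples=n_samples, seed=seed)


# -- series composition ------------------------------------------------------


def run_series(
    series: list[Compartment],
    input: Oligomer | OutputDistribution,
    method: str | int = "exact",
    seed: int | None = None,
    size_cap: int = DEFAULT_SIZE_CAP,
    *,
    allow_clipped: bool = False,
) -> OutputDistribution:
    """Compose compartment maps in order; the output of stage k is the
    input distribution of stage k+1.  ``method`` is ``"exact"`` or a
    Monte Carlo sample count."""
    dist = input if isinstance(input, OutputDistribution) else OutputDistribution.point(input)
    for k, comp in enumerate(series):
        if method == "exact":
            dist = exact_output_distribution(
                comp, dist, size_cap=size_cap, allow_clipped=allow_clipped
            )
        else:
            stage_seed = None if seed is None else seed + 7919 * k
            dist = simulate_compartment(comp, dist, int(method), seed=stage_seed)
    return dist


def entropy_curve(
    series: list[Compartment],
    input: Oligomer,
    T_grid: list[float],
    which_stage: int = -1,
    size_cap: int = DEFAULT_SIZE_CAP,
    scenario: str = "",
) -> EntropyCurve:
    """Entropy of the final output distribution as the probed stage's
    residence time sweeps ``T_grid``; all other stages keep their own
    (typically infinite) residence times."""
    stage = which_stage % len(series) if series else 0
    upstream = series[:stage]
    probed = series[stage]
    downstream = series[stage + 1:]
    base = run_series(upstream, input, "exact", size_cap=size_cap)
    entropies = []
    for T in T_grid:
        comp = Compartment(probed.enzymes, T, probed.exit_model)
        dist = exact_output_distribution(
            comp, base, size_cap=size_cap, allow_clipped=True
        )
        dist = run_series(downstream, dist, "exact", size_cap=size_cap, allow_clipped=True)
        entropies.append(shannon_entropy(dist))
    return EntropyCurve(list(T_grid), entropies, scenario=scenario)
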