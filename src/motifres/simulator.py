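"""Randomized-parameter ODE ensemble simulation of a network topology.

Each node T follows

    dT/dt = G_T * prod_i Hs(P_i) * prod_j Hs(N_j) - k_T * T

where Hs is the shifted Hill function (1 at zero regulator, fold change
``lambda`` at saturation) over the node's activating inputs P_i and
inhibiting inputs N_j.  An ensemble draws thousands of kinetic parameter
sets from fixed biologically plausible ranges, integrates each from many
random initial conditions, and pools the distinct stable steady states —
characterizing the *generic* dynamics a topology supports rather than a
single parameterization.

Parameter ranges
----------------
production G in [1, 100] (molecules/time), degradation k in [0.1, 1] (1/time),
integer Hill coefficient n in 1..6, activation fold change in [1, 100],
inhibition fold change sampled as the reciprocal of a uniform [1, 100]
variate (so fold-repression is distributed symmetrically to
fold-activation), and each edge threshold drawn by the half-functional rule:
uniform within +/-98% of the regulator's median attainable level, estimated
by Monte Carlo from the regulator's own in-degree.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from ._ode import integrate_ensemble
from .topology import ACTIVATION, NetworkTopology

# Sampling ranges for the randomized kinetic parameters.
G_RANGE = (1.0, 100.0)
K_RANGE = (0.1, 1.0)
LAMBDA_ACT_RANGE = (1.0, 100.0)      # activation fold change, uniform
LAMBDA_INH_RANGE = (0.01, 1.0)       # inhibition: 1/u, u uniform in [1,100]
HILL_RANGE = (1, 6)                  # integer Hill coefficient
THRESHOLD_SPREAD = 0.98              # threshold uniform in [0.02 M, 1.98 M]

DEFAULT_DT = 0.1
DEFAULT_T_MAX = 1000.0
DEFAULT_CONV_TOL = 1e-6
DEFAULT_DEDUP_TOL = 1e-2
MAX_REPORTED_STATES = 10
_CHECK_EVERY = 10
# Limit-cycle cut-off: a trajectory whose 10-step relative change still
# exceeds OSC_TOL at t = OSC_T is oscillating, not contracting (decay rates
# are bounded below by the degradation terms), and is discarded as
# non-convergent early instead of burning the remaining step budget.
DEFAULT_OSC_T = 100.0
DEFAULT_OSC_TOL = 3e-2


def shifted_hill(b, b0, n, lam):
    """Shifted Hill regulation multiplier.

    Hs(B) = B0^n / (B0^n + B^n) + lam * B^n / (B0^n + B^n)

    Continuous and monotone in B, equal to 1 at B = 0 and tending to the
    fold change ``lam`` as B -> infinity; at B = B0 it is (1 + lam) / 2.
    """
    b = np.asarray(b, dtype=float)
    b0 = np.asarray(b0, dtype=float)
    if np.any(b0 <= 0):
        raise ValueError("threshold B0 must be positive")
    b0n = b0**n
    bn = b**n
    return (b0n + lam * bn) / (b0n + bn)


@dataclass
class ParameterSet:
    """One randomized kinetic parameterization of a topology.

    ``g`` and ``k`` are per-node (topology node order); ``n_hill``, ``lam``
    and ``threshold`` are per-edge (topology edge order).
    """

    topology: NetworkTopology
    g: np.ndarray
    k: np.ndarray
    n_hill: np.ndarray
    lam: np.ndarray
    threshold: np.ndarray


@dataclass
class ParameterEnsemble:
    """Stacked parameter sets: row ``m`` of each array is model ``m``."""

    topology: NetworkTopology
    g: np.ndarray          # (n_models, n_nodes)
    k: np.ndarray          # (n_models, n_nodes)
    n_hill: np.ndarray     # (n_models, n_edges), topology edge order
    lam: np.ndarray        # (n_models, n_edges)
    threshold: np.ndarray  # (n_models, n_edges)
    medians: np.ndarray    # (n_nodes,) half-functional rule medians
    seed: Optional[int] = None

    @property
    def n_models(self) -> int:
        return self.g.shape[0]

    def parameter_set(self, m: int) -> ParameterSet:
        return ParameterSet(
            topology=self.topology, g=self.g[m], k=self.k[m],
            n_hill=self.n_hill[m], lam=self.lam[m], threshold=self.threshold[m],
        )

    def to_frame(self) -> pd.DataFrame:
        """Parameter table: one row per model, columns in topology order."""
        cols: dict[str, np.ndarray] = {"model_id": np.arange(self.n_models)}
        for i, node in enumerate(self.topology.nodes):
            cols[f"G_{node}"] = self.g[:, i]
            cols[f"k_{node}"] = self.k[:, i]
        for e, (s, t, sign) in enumerate(self.topology.edges):
            tag = f"{s}_{t}"
            cols[f"n_{tag}"] = self.n_hill[:, e]
            cols[f"lambda_{tag}"] = self.lam[:, e]
            cols[f"threshold_{tag}"] = self.threshold[:, e]
        return pd.DataFrame(cols)


def node_threshold_medians(
    topology: NetworkTopology,
    rng: np.random.Generator,
    n_draws: int = 10_000,
) -> np.ndarray:
    """Half-functional-rule medians: for each node R, the Monte Carlo median
    of its stand-alone level G/k multiplied by one independently drawn
    shifted-Hill factor per incoming edge of R, each regulator equally likely
    fully occupied (factor = lambda) or absent (factor = 1).  The median grows
    or shrinks with R's in-degree, which is what ties thresholds to network
    context."""
    src, tgt, sgn = topology.edge_arrays()
    medians = np.empty(topology.n_nodes)
    for r in range(topology.n_nodes):
        level = rng.uniform(*G_RANGE, n_draws) / rng.uniform(*K_RANGE, n_draws)
        for e in np.nonzero(tgt == r)[0]:
            u = rng.uniform(*LAMBDA_ACT_RANGE, n_draws)
            lam_e = u if sgn[e] == ACTIVATION else 1.0 / u
            occupied = rng.integers(0, 2, n_draws).astype(bool)
            level *= np.where(occupied, lam_e, 1.0)
        medians[r] = np.median(level)
    return medians


def sample_parameter_ensemble(
    topology: NetworkTopology,
    n_models: int,
    rng: np.random.Generator,
    seed: Optional[int] = None,
) -> ParameterEnsemble:
    nn, ne = topology.n_nodes, topology.n_edges
    src, tgt, sgn = topology.edge_arrays()
    medians = node_threshold_medians(topology, rng)
    g = rng.uniform(*G_RANGE, (n_models, nn))
    k = rng.uniform(*K_RANGE, (n_models, nn))
    n_hill = rng.integers(HILL_RANGE[0], HILL_RANGE[1] + 1, (n_models, ne))
    u = rng.uniform(*LAMBDA_ACT_RANGE, (n_models, ne))
    lam = np.where(sgn[None, :] == ACTIVATION, u, 1.0 / u)
    m_src = medians[src]
    threshold = rng.uniform(0, 1, (n_models, ne)) * (2 * THRESHOLD_SPREAD * m_src) \
        + (1 - THRESHOLD_SPREAD) * m_src
    return ParameterEnsemble(
        topology=topology, g=g, k=k, n_hill=n_hill, lam=lam,
        threshold=threshold, medians=medians, seed=seed,
    )


def sample_parameter_set(
    topology: NetworkTopology, rng: np.random.Generator
) -> ParameterSet:
    """Draw a single randomized parameter set (see module docstring)."""
    return sample_parameter_ensemble(topology, 1, rng).parameter_set(0)


def derivative(
    state: np.ndarray, params: ParameterSet, topology: NetworkTopology
) -> np.ndarray:
    """dT/dt for every node at ``state``.  Nodes with no regulators reduce to
    G - k*T (fixed point G/k); inhibitory inputs at zero contribute factor 1."""
    state = np.asarray(state, dtype=float)
    if state.shape != (topology.n_nodes,):
        raise ValueError(
            f"state has shape {state.shape}, expected ({topology.n_nodes},)"
        )
    src, tgt, sgn = topology.edge_arrays()
    prod = np.ones(topology.n_nodes)
    for e in range(topology.n_edges):
        prod[tgt[e]] *= shifted_hill(
            state[src[e]], params.threshold[e], int(params.n_hill[e]),
            params.lam[e],
        )
    return params.g * prod - params.k * state


@dataclass
class SteadyStateTable:
    """Pooled stable steady states of one ensemble.

    ``states`` has one row per (model, stable state): ``model_id``,
    ``state_id``, ``multiplicity`` (number of distinct stable states of that
    model), ``n_inits`` (initial conditions that reached the state), then one
    concentration column per node.  ``params`` retains the full parameter
    ensemble so steady states can be normalized by each model's G/k.
    """

    states: pd.DataFrame
    params: ParameterEnsemble
    n_init: int
    n_unconverged: int = 0
    n_truncated_models: int = 0
    seed: Optional[int] = None

    @property
    def topology(self) -> NetworkTopology:
        return self.params.topology

    def normalized(self) -> pd.DataFrame:
        """Eq.-style normalization: each node's value divided by its model's
        G/k, appended to the identifying columns."""
        out = self.states[["model_id", "state_id", "multiplicity"]].copy()
        mids = self.states["model_id"].to_numpy()
        for i, node in enumerate(self.topology.nodes):
            scale = self.params.k[mids, i] / self.params.g[mids, i]
            out[node] = self.states[node].to_numpy() * scale
        return out


def _csr_layout(topology: NetworkTopology):
    """Group edges by target node; returns CSR pointers, sources, and the
    permutation from topology edge order to CSR order."""
    src, tgt, _ = topology.edge_arrays()
    perm = np.argsort(tgt, kind="stable")
    eptr = np.zeros(topology.n_nodes + 1, dtype=np.int64)
    np.add.at(eptr[1:], tgt, 1)
    eptr = np.cumsum(eptr)
    return eptr, src[perm].astype(np.int64), perm


def _initial_conditions(
    ens: ParameterEnsemble, n_init: int, rng: np.random.Generator
) -> np.ndarray:
    """Log-uniform initial conditions per node on [1e-2, G/k * prod(lambda+)],
    spanning the reachable expression range of each node."""
    topo = ens.topology
    src, tgt, sgn = topo.edge_arrays()
    act_prod = np.ones_like(ens.g)
    for e in range(topo.n_edges):
        if sgn[e] == ACTIVATION:
            act_prod[:, tgt[e]] *= ens.lam[:, e]
    hi = ens.g / ens.k * act_prod
    lo = 1e-2
    u = rng.uniform(size=(ens.n_models, n_init, topo.n_nodes))
    return lo * (hi[:, None, :] / lo) ** u


def _run_kernel(ens, inits, dt, t_max, conv_tol, dedup_tol, max_slots):
    eptr, esrc, perm = _csr_layout(ens.topology)
    nh = np.ascontiguousarray(ens.n_hill[:, perm])
    lam = np.ascontiguousarray(ens.lam[:, perm])
    b0n = np.ascontiguousarray(ens.threshold[:, perm] ** nh)
    n_steps = int(round(t_max / dt))
    osc_steps = min(n_steps, int(round(DEFAULT_OSC_T / dt)))
    return integrate_ensemble(
        eptr, esrc, ens.g, ens.k, nh, lam, b0n,
        np.ascontiguousarray(inits), dt, n_steps, _CHECK_EVERY,
        conv_tol, dedup_tol, max_slots, osc_steps, DEFAULT_OSC_TOL,
    )


def find_steady_states(
    topology: NetworkTopology,
    params: ParameterSet,
    n_init: int,
    rng: np.random.Generator,
    dt: float = DEFAULT_DT,
    t_max: float = DEFAULT_T_MAX,
    conv_tol: float = DEFAULT_CONV_TOL,
    dedup_tol: float = DEFAULT_DEDUP_TOL,
) -> tuple[list[tuple[np.ndarray, int]], int]:
    """Stable fixed points of one parameter set from ``n_init`` random starts.

    Returns ``(states, n_unconverged)`` where ``states`` is a list of
    ``(state_vector, n_inits_reaching_it)`` pairs; trajectories that fail to
    converge within the step budget are discarded and counted.
    """
    if n_init < 1:
        raise ValueError("n_init must be >= 1")
    ens = ParameterEnsemble(
        topology=topology,
        g=params.g[None, :], k=params.k[None, :],
        n_hill=params.n_hill[None, :], lam=params.lam[None, :],
        threshold=params.threshold[None, :],
        medians=np.zeros(topology.n_nodes),
    )
    inits = _initial_conditions(ens, n_init, rng)
    max_slots = min(n_init, 100)
    states, counts, n_states, n_failed = _run_kernel(
        ens, inits, dt, t_max, conv_tol, dedup_tol, max_slots
    )
    out = [
        (states[s].copy(), int(counts[s]))
        for s in range(int(n_states[0]))
    ]
    out.sort(key=lambda sc: -sc[1])
    return out, int(n_failed[0])


def simulate_ensemble(
    topology: NetworkTopology,
    n_models: int,
    n_init: int,
    seed: Optional[int] = None,
    dt: float = DEFAULT_DT,
    t_max: float = DEFAULT_T_MAX,
    conv_tol: float = DEFAULT_CONV_TOL,
    dedup_tol: float = DEFAULT_DEDUP_TOL,
    max_states: int = MAX_REPORTED_STATES,
    rng: Optional[np.random.Generator] = None,
) -> SteadyStateTable:
    """Simulate ``n_models`` randomized parameter sets of ``topology`` from
    ``n_init`` initial conditions each and pool the stable steady states.

    Fully reproducible from ``seed``.  Models yielding more than
    ``max_states`` distinct states are truncated to the most-visited ones
    (the count of affected models is reported on the returned table).
    """
    if n_models < 1:
        raise ValueError("n_models must be >= 1")
    if n_init < 1:
        raise ValueError("n_init must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    ens = sample_parameter_ensemble(topology, n_models, rng, seed=seed)
    inits = _initial_conditions(ens, n_init, rng)
    max_slots = min(n_init, 100)
    states, counts, n_states, n_failed = _run_kernel(
        ens, inits, dt, t_max, conv_tol, dedup_tol, max_slots
    )

    model_ids: list[int] = []
    state_ids: list[int] = []
    mults: list[int] = []
    n_inits_col: list[int] = []
    vecs: list[np.ndarray] = []
    n_truncated = 0
    for m in range(n_models):
        base = m * max_slots
        k_states = int(n_states[m])
        order = np.argsort(-counts[base:base + k_states], kind="stable")
        if k_states > max_states:
            n_truncated += 1
            order = order[:max_states]
        mult = len(order)
        for sid, s in enumerate(order):
            model_ids.append(m)
            state_ids.append(sid)
            mults.append(mult)
            n_inits_col.append(int(counts[base + s]))
            vecs.append(states[base + s])
    df = pd.DataFrame({
        "model_id": np.array(model_ids, dtype=np.int64),
        "state_id": np.array(state_ids, dtype=np.int64),
        "multiplicity": np.array(mults, dtype=np.int64),
        "n_inits": np.array(n_inits_col, dtype=np.int64),
    })
    mat = np.vstack(vecs) if vecs else np.zeros((0, topology.n_nodes))
    for i, node in enumerate(topology.nodes):
        df[node] = mat[:, i]
    return SteadyStateTable(
        states=df, params=ens, n_init=n_init,
        n_unconverged=int(n_failed.sum()),
        n_truncated_models=n_truncated, seed=seed,
    )


def write_solutions(table: SteadyStateTable, prefix: str | Path) -> list[Path]:
    """Write per-multiplicity solution tables ``<prefix>_solution_<k>.dat``:
    model_id, multiplicity, then one steady-state column per node."""
    paths = []
    df = table.states
    for mult, group in df.groupby("multiplicity"):
        path = Path(f"{prefix}_solution_{mult}.dat")
        cols = ["model_id", "multiplicity", *table.topology.nodes]
        group[cols].to_csv(path, sep="\t", index=False)
        paths.append(path)
    return paths


def write_parameters(table: SteadyStateTable, path: str | Path) -> Path:
    """Write the sampled parameter table (one row per model)."""
    path = Path(path)
    table.params.to_frame().to_csv(path, sep="\t", index=False)
    return path
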