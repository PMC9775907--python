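import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import motifres as mr
from motifres.simulator import (
    G_RANGE,
    K_RANGE,
    derivative,
    find_steady_states,
    node_threshold_medians,
    sample_parameter_ensemble,
    sample_parameter_set,
    shifted_hill,
    simulate_ensemble,
)
from motifres.topology import (
    ACTIVATION,
    INHIBITION,
    NetworkTopology,
    build_motif,
    motif_topology,
)


# ---------------------------------------------------------------- shifted Hill

def test_shifted_hill_limits():
    assert shifted_hill(0.0, 10.0, 4, 37.0) == pytest.approx(1.0)
    assert shifted_hill(1e12, 10.0, 4, 37.0) == pytest.approx(37.0, rel=1e-6)
    assert shifted_hill(10.0, 10.0, 3, 0.25) == pytest.approx((1 + 0.25) / 2)


def test_shifted_hill_rejects_bad_threshold():
    with pytest.raises(ValueError, match="positive"):
        shifted_hill(1.0, 0.0, 2, 0.5)


@settings(derandomize=True, max_examples=100, deadline=None)
@given(
    b=st.floats(0, 1e4), b0=st.floats(1e-2, 1e3), n=st.integers(1, 6),
    lam=st.floats(0.01, 100),
)
def test_shifted_hill_bounded_and_monotone(b, b0, n, lam):
    h = shifted_hill(b, b0, n, lam)
    assert min(1.0, lam) - 1e-9 <= h <= max(1.0, lam) + 1e-9
    h2 = shifted_hill(b * 1.5 + 1e-6, b0, n, lam)
    if lam >= 1:
        assert h2 >= h - 1e-12
    else:
        assert h2 <= h + 1e-12


# ------------------------------------------------------------------- sampling

def test_parameter_ranges_conserved(rng):
    topo = motif_topology("TT")
    ens = sample_parameter_ensemble(topo, 10_000, rng)
    assert ens.g.min() >= 1.0 and ens.g.max() <= 100.0
    assert ens.k.min() >= 0.1 and ens.k.max() <= 1.0
    assert ens.n_hill.min() >= 1 and ens.n_hill.max() <= 6
    assert np.issubdtype(ens.n_hill.dtype, np.integer)
    assert set(np.unique(ens.n_hill)) <= set(range(1, 7))
    # all TT edges are inhibitory: fold change is the reciprocal of a
    # uniform [1, 100] variate
    assert ens.lam.min() >= 0.01 and ens.lam.max() <= 1.0
    assert ens.threshold.min() > 0


def test_inputless_threshold_median_matches_monte_carlo(rng):
    # a regulator with no inputs has median level = median of G/k
    lone = NetworkTopology(nodes=("A",), edges=(), motif=None)
    m = node_threshold_medians(lone, rng)[0]
    oracle = np.median(
        rng.uniform(*G_RANGE, 100_000) / rng.uniform(*K_RANGE, 100_000)
    )
    assert m == pytest.approx(oracle, rel=0.05)


def test_regulated_threshold_median_is_discounted(rng):
    # an inhibited regulator's median attainable level sits well below G/k
    ts = motif_topology("TS")
    m_ts = node_threshold_medians(ts, rng)
    lone = NetworkTopology(nodes=("A",), edges=(), motif=None)
    m_free = node_threshold_medians(lone, rng)[0]
    assert np.all(m_ts < m_free)


def test_sample_parameter_set_shapes():
    topo = motif_topology("TS")
    ps = sample_parameter_set(topo, np.random.default_rng(0))
    assert ps.g.shape == (2,) and ps.n_hill.shape == (2,)


# ----------------------------------------------------------------- derivative

def test_unregulated_node_fixed_point():
    lone = NetworkTopology(nodes=("A",), edges=(), motif=None)
    ps = sample_parameter_set(lone, np.random.default_rng(3))
    fp = ps.g / ps.k
    assert derivative(fp, ps, lone) == pytest.approx(0.0, abs=1e-9)


def test_ts_derivative_with_inhibitor_absent():
    topo = motif_topology("TS")
    ps = sample_parameter_set(topo, np.random.default_rng(4))
    d = derivative(np.array([5.0, 0.0]), ps, topo)
    # with B = 0 the inhibitory Hill factor is 1: dA/dt = G_A - k_A * A
    assert d[0] == pytest.approx(ps.g[0] - ps.k[0] * 5.0)


def test_derivative_rejects_dimension_mismatch():
    topo = motif_topology("TS")
    ps = sample_parameter_set(topo, np.random.default_rng(5))
    with pytest.raises(ValueError, match="shape"):
        derivative(np.zeros(3), ps, topo)


# -------------------------------------------------------- steady-state search

def test_single_node_reaches_g_over_k(rng):
    lone = NetworkTopology(nodes=("A",), edges=(), motif=None)
    ps = sample_parameter_set(lone, rng)
    states, failed = find_steady_states(lone, ps, 20, rng)
    assert failed == 0
    assert len(states) == 1
    vec, count = states[0]
    assert count == 20
    assert vec[0] == pytest.approx(ps.g[0] / ps.k[0], rel=1e-3)


def _symmetric_ts_params(lam_inh, g=50.0, k=0.5, n=4, b0=None):
    topo = motif_topology("TS")
    if b0 is None:
        b0 = g / (2 * k)
    from motifres.simulator import ParameterSet
    return topo, ParameterSet(
        topology=topo,
        g=np.array([g, g]), k=np.array([k, k]),
        n_hill=np.array([n, n]), lam=np.array([lam_inh, lam_inh]),
        threshold=np.array([b0, b0]),
    )


def _nullcline_stable_count(g, k, n, b0, lam, grid=4000):
    """Independent oracle: stable fixed points of the symmetric toggle
    switch counted by bisection on f(A) = phi(phi(A)) - A with
    phi(y) = (G/k) * Hs(y); a root is stable iff the composition slope
    phi'(phi(A)) * phi'(A) < 1."""
    gk = g / k

    def hs(y):
        yn = y**n
        return (b0**n + lam * yn) / (b0**n + yn)

    def dhs(y):
        yn = y**n
        return (lam - 1) * n * b0**n * y ** (n - 1) / (b0**n + yn) ** 2

    def f(a):
        return gk * hs(gk * hs(a)) - a

    xs = np.geomspace(1e-6, gk * 1.5, grid)
    fs = f(xs)
    roots = []
    for i in range(len(xs) - 1):
        if fs[i] == 0.0:
            roots.append(xs[i])
        elif fs[i] * fs[i + 1] < 0:
            lo, hi = xs[i], xs[i + 1]
            for _ in range(80):
                mid = 0.5 * (lo + hi)
                if f(lo) * f(mid) <= 0:
                    hi = mid
                else:
                    lo = mid
            roots.append(0.5 * (lo + hi))
    stable = 0
    for a in roots:
        slope = gk * dhs(gk * hs(a)) * gk * dhs(a)
        if slope < 1:
            stable += 1
    return stable


def test_symmetric_ts_is_bistable_with_mirror_states(rng):
    topo, ps = _symmetric_ts_params(lam_inh=0.01)
    states, _ = find_steady_states(topo, ps, 60, rng)
    assert len(states) == 2
    (s1, _), (s2, _) = states
    assert s1[0] == pytest.approx(s2[1], rel=1e-2)
    assert s1[1] == pytest.approx(s2[0], rel=1e-2)


def test_symmetric_ts_state_count_matches_nullcline_oracle(rng):
    g, k, n = 50.0, 0.5, 4
    b0 = g / (2 * k)
    for lam in np.geomspace(0.01, 1.0, 20):
        expected = _nullcline_stable_count(g, k, n, b0, lam)
        topo, ps = _symmetric_ts_params(lam_inh=float(lam))
        states, _ = find_steady_states(topo, ps, 60, rng)
        assert len(states) == expected, f"lambda={lam}"


def test_close_endpoints_merge(rng):
    # a monostable configuration: all initial conditions collapse to one
    # state within the deduplication tolerance
    topo, ps = _symmetric_ts_params(lam_inh=0.9)
    states, _ = find_steady_states(topo, ps, 50, rng)
    assert len(states) == 1
    assert states[0][1] == 50


# ------------------------------------------------------------------- ensemble

def test_ensemble_reproducible_and_bookkept(ts_small):
    again = simulate_ensemble(motif_topology("TS"), 400, 25, seed=11)
    assert again.states.equals(ts_small.states)
    df = ts_small.states
    # multiplicity column counts the distinct states of its model
    sizes = df.groupby("model_id").size()
    mults = df.groupby("model_id")["multiplicity"].first()
    assert (sizes == mults).all()
    # basin bookkeeping: initial-condition counts never exceed n_init
    assert (df.groupby("model_id")["n_inits"].sum() <= 25).all()
    assert df["model_id"].nunique() >= 395  # virtually no all-failed models


def test_ensemble_rejects_bad_sizes():
    with pytest.raises(ValueError):
        simulate_ensemble(motif_topology("TS"), 0, 10)
    with pytest.raises(ValueError):
        simulate_ensemble(motif_topology("TS"), 10, 0)


def test_derivative_vanishes_at_reported_states(ts_small):
    ens = ts_small.params
    df = ts_small.states
    for _, row in df.head(20).iterrows():
        ps = ens.parameter_set(int(row["model_id"]))
        vec = np.array([row["A"], row["B"]])
        d = derivative(vec, ps, ts_small.topology)
        assert np.max(np.abs(d)) < 1e-2 * max(1.0, vec.max())


def test_solution_and_parameter_tables_round_trip(tmp_path, ts_small):
    import pandas as pd

    paths = mr.write_solutions(ts_small, tmp_path / "ts")
    total = 0
    for p in paths:
        df = pd.read_csv(p, sep="\t")
        assert list(df.columns) == ["model_id", "multiplicity", "A", "B"]
        total += len(df)
    assert total == len(ts_small.states)
    ppath = mr.write_parameters(ts_small, tmp_path / "ts_parameters.dat")
    pdf = pd.read_csv(ppath, sep="\t")
    assert len(pdf) == 400
    assert "lambda_A_B" in pdf.columns and "threshold_B_A" in pdf.columns
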