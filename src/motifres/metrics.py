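"""Per-network resilience metrics for embedded mutually repressing motifs.

For a toggle switch the canonical signature is bimodal node distributions,
a strongly negative Spearman correlation between the two nodes, dominance of
the single-positive (01/10) states, and co-existence of both in bistable
parameter sets (B:M ratio above one).  For a toggle triad the diagnostic
quantities are the fractions of single-positive (F1), double-positive (F2)
and all-ON/all-OFF (F3) states, their ratio F1/F2, the maximum of the three
pairwise correlations (MaxCC), and a multiple linear regression of node C on
nodes A and B.  This module computes each metric on pooled steady-state rows
(multistable models contribute one row per state, unweighted).
"""

from __future__ import annotations

from itertools import combinations
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .states import BinarizedStateTable, zscore_binarize
from .topology import NetworkTopology, in_degree_profile

BIMODALITY_THRESHOLD = 5.0 / 9.0  # samples above this are called bimodal


def bimodality_coefficient(samples) -> float:
    """Sarle's bimodality coefficient with finite-sample correction.

    BiC = (m3^2 + 1) / (m4 + 3 (n-1)^2 / ((n-2)(n-3)))

    with m3 the sample skewness and m4 the sample excess kurtosis (both
    population-style moment estimators, Gaussian -> 0).  Lies in (0, 1];
    a uniform sample gives 5/9, the conventional bimodality threshold.
    """
    x = np.asarray(samples, dtype=float)
    n = x.size
    if n < 4:
        raise ValueError("need at least 4 samples for the finite-size term")
    if np.ptp(x) == 0:
        raise ValueError("zero-variance sample has undefined moments")
    m3 = stats.skew(x, bias=True)
    m4 = stats.kurtosis(x, fisher=True, bias=True)
    return float((m3**2 + 1) / (m4 + 3 * (n - 1) ** 2 / ((n - 2) * (n - 3))))


def spearman_cc(x, y) -> float:
    """Spearman rank correlation (average ranks on ties); NaN when either
    input is constant."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    rho = stats.spearmanr(x, y).statistic
    return float(rho)


def state_fractions(states: Sequence[str] | BinarizedStateTable,
                    n_nodes: Optional[int] = None) -> dict[str, float]:
    """Fractions of binarized state classes among all pooled rows.

    Two-node motif: F1 counts the single-positive strings {01, 10}; the
    complementary fractions f00 and f11 are also reported.  Three-node motif:
    F1 single-positive {001, 010, 100}, F2 double-positive {011, 101, 110},
    F3 all-ON/all-OFF {000, 111}; the three fractions partition the table so
    F1 + F2 + F3 = 1 exactly.
    """
    if isinstance(states, BinarizedStateTable):
        states = states.state_strings.tolist()
    states = list(states)
    if not states:
        raise ValueError("empty state table")
    if n_nodes is None:
        n_nodes = len(states[0])
    total = len(states)
    ones = np.array([s.count("1") for s in states])
    if n_nodes == 2:
        return {
            "F1": float(np.mean(ones == 1)),
            "f00": float(np.mean(ones == 0)),
            "f11": float(np.mean(ones == 2)),
        }
    if n_nodes == 3:
        f1 = float(np.mean(ones == 1))
        f2 = float(np.mean(ones == 2))
        f3 = float(np.mean((ones == 0) | (ones == 3)))
        return {"F1": f1, "F2": f2, "F3": f3}
    raise ValueError(f"unsupported motif size {n_nodes}")


def bistable_monostable_ratio(
    binarized: BinarizedStateTable, relative_to: str = "qualifying"
) -> float:
    """B:M ratio of a two-node motif.

    Numerator: the fraction of bistable parameter sets whose binarized
    motif states are exactly {01, 10}.  Denominator: the fraction of
    monostable parameter sets whose state is 01 or 10.  Stability classes
    are counted at the motif level: a parameter set is bistable when its
    rows carry exactly two *distinct* motif state strings and monostable
    when they carry one, so multistability among background nodes (which
    duplicates motif states across network states) does not misclassify an
    embedded motif.  With the default ``relative_to='qualifying'`` each
    fraction is taken within its own stability class, so an isolated toggle
    switch — where essentially all bistable sets are canonical — sits above
    one, and embedding pushes the ratio below one as bistable sets acquire
    non-canonical states.  ``relative_to='all'`` normalizes both fractions by
    the total model count instead.  NaN when no model qualifies for the
    denominator.
    """
    if relative_to not in ("qualifying", "all"):
        raise ValueError("relative_to must be 'qualifying' or 'all'")
    df = binarized.table
    if "model_id" not in df.columns or "multiplicity" not in df.columns:
        raise ValueError("binarized table lacks model bookkeeping columns")
    n_models = df["model_id"].nunique()
    if n_models == 0:
        raise ValueError("empty state table")
    per_model = df.groupby("model_id").agg(
        states=("state", lambda s: frozenset(s)),
    )
    per_model["mult"] = per_model["states"].apply(len)
    canonical = frozenset({"01", "10"})
    is_bi = per_model["mult"] == 2
    is_mono = per_model["mult"] == 1
    bi_canon = (is_bi & (per_model["states"] == canonical)).sum()
    mono_canon = (
        is_mono & per_model["states"].apply(lambda s: s <= canonical)
    ).sum()
    if relative_to == "qualifying":
        if is_mono.sum() == 0 or mono_canon == 0:
            return float("nan")
        if is_bi.sum() == 0:
            return 0.0  # no bistable sets at all: the numerator vanishes
        return float((bi_canon / is_bi.sum()) / (mono_canon / is_mono.sum()))
    if mono_canon == 0:
        return float("nan")
    return float((bi_canon / n_models) / (mono_canon / n_models))


def max_min_cc(cc_ab: float, cc_bc: float, cc_ac: float) -> tuple[float, float]:
    """(MaxCC, MinCC) over the three pairwise correlations; missing inputs
    propagate to missing outputs."""
    ccs = np.array([cc_ab, cc_bc, cc_ac], dtype=float)
    if np.any(np.isnan(ccs)):
        return float("nan"), float("nan")
    return float(ccs.max()), float(ccs.min())


def mlr_fit(a, b, c) -> dict[str, float]:
    """Ordinary least squares plane c ~ ACoeff*a + BCoeff*b + intercept.

    Returns the two slopes, the intercept and the coefficient of
    determination R^2.  Raises on rank-deficient designs (e.g. a and b
    collinear)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    c = np.asarray(c, dtype=float)
    if not (a.shape == b.shape == c.shape):
        raise ValueError("a, b, c must have equal length")
    n = a.size
    if n < 4:
        raise ValueError("need at least 4 observations")
    design = np.column_stack([a, b, np.ones(n)])
    if np.linalg.matrix_rank(design) < 3:
        raise ValueError("rank-deficient design matrix")
    coef, *_ = np.linalg.lstsq(design, c, rcond=None)
    resid = c - design @ coef
    ss_res = float(resid @ resid)
    ss_tot = float(((c - c.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    return {
        "ACoeff": float(coef[0]),
        "BCoeff": float(coef[1]),
        "intercept": float(coef[2]),
        "R2": r2,
    }


def compute_metrics(
    steady_table,
    nodes: Optional[Sequence[str]] = None,
    log2_values: bool = True,
    log2_binarize: bool = False,
    include_indegree: bool = True,
) -> dict[str, float]:
    """All per-network resilience metrics from one ensemble's pooled states.

    ``nodes`` defaults to the motif nodes; passing background nodes instead
    yields the random-node control on identical pooling.  Keys follow the
    motif-node labelling A, B[, C] regardless of which concrete nodes were
    selected, with the actual node names recorded under ``nodes``.

    Distribution-shape statistics (BiC) are computed on log2-scale normalized
    values by default, matching the log2 convention of ensemble-simulation
    output tables; rank statistics (Spearman CC) are unaffected by that
    monotone transform.  ON/OFF binarization defaults to the linear
    normalized scale, where the z > 0 rule separates the high-expression
    branch cleanly; on the log scale, deeply repressed tails (fold-repression
    products far below 1) drag the node mean down and reclassify mildly low
    states as ON.
    """
    topo: NetworkTopology = steady_table.topology
    if nodes is None:
        if topo.motif is None:
            raise ValueError("topology has no motif; pass nodes explicitly")
        nodes = list(topo.motif.nodes)
    nodes = list(nodes)
    if len(nodes) not in (2, 3):
        raise ValueError("metrics are defined for 2- or 3-node selections")

    norm = steady_table.normalized()
    binar = zscore_binarize(norm, nodes=nodes, log2=log2_binarize)
    values = norm[nodes].to_numpy(dtype=float)
    if log2_values:
        values = np.log2(np.maximum(values, 1e-12))

    labels = ["A", "B", "C"][: len(nodes)]
    rec: dict[str, float] = {"nodes": ",".join(nodes)}
    for lab, col in zip(labels, values.T):
        rec[f"BiC_{lab}"] = bimodality_coefficient(col)
    pair_ccs = {}
    for (i, li), (j, lj) in combinations(enumerate(labels), 2):
        pair_ccs[f"CC_{li}{lj}"] = spearman_cc(values[:, i], values[:, j])
    rec.update(pair_ccs)
    rec.update(state_fractions(binar, n_nodes=len(nodes)))

    if len(nodes) == 2:
        rec["B_to_M"] = bistable_monostable_ratio(binar)
    else:
        rec["MaxCC"], rec["MinCC"] = max_min_cc(
            rec["CC_AB"], rec["CC_BC"], rec["CC_AC"]
        )
        rec["F1_over_F2"] = (
            rec["F1"] / rec["F2"] if rec["F2"] > 0 else float("nan")
        )
        fit = mlr_fit(values[:, 0], values[:, 1], values[:, 2])
        rec["ACoeff"] = fit["ACoeff"]
        rec["BCoeff"] = fit["BCoeff"]
        rec["R2"] = fit["R2"]

    rec["n_rows"] = len(norm)
    if include_indegree and topo.motif is not None and nodes == list(topo.motif.nodes):
        rec.update(in_degree_profile(topo))
    return rec
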