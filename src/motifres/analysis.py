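"""Experiment orchestration and meta-analysis across network ensembles.

An experiment sweeps a motif over classes of random networks (network order
N x mean connectivity E:xN), simulates every network in replicate, and
collects one metric record per network x replicate.  The meta-analyses
mirror the study design: pairwise Mann-Whitney group comparisons across
orders or connectivities, Spearman correlations of every metric against raw
and normalized in-degree descriptors, per-(in_A, in_B) bin summaries with
in-degree/bimodality asymmetry log-ratios, and a random-node control that
recomputes the metrics on background nodes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from itertools import combinations
from pathlib import Path
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .metrics import compute_metrics
from .simulator import SteadyStateTable, simulate_ensemble
from .topology import (
    NetworkTopology,
    add_self_regulation,
    generate_network_batch,
)

#: The full study grid: four network orders x three mean connectivities.
FULL_CLASSES: tuple[tuple[int, int], ...] = tuple(
    (n, x) for n in (5, 10, 15, 20) for x in (2, 4, 6)
)
#: Grid used for the self-activation / self-inhibition variants.
SASI_CLASSES: tuple[tuple[int, int], ...] = ((5, 2), (5, 6), (20, 2), (20, 6))


@dataclass(frozen=True)
class ExperimentPlan:
    """One motif's simulation campaign.

    ``classes`` lists (order_N, connectivity_x) pairs; each class contributes
    ``networks_per_class`` random networks, each simulated ``replicates``
    times with a fresh parameter seed, ``n_models`` parameter sets and
    ``n_init`` initial conditions per set.  ``seed`` roots the whole
    seed hierarchy (master -> per-class topology seed -> per-replicate
    parameter seed)."""

    motif: str
    classes: tuple[tuple[int, int], ...] = FULL_CLASSES
    networks_per_class: int = 100
    replicates: int = 3
    n_models: int = 10_000
    n_init: int = 100
    seed: int = 0
    log2_values: bool = True
    log2_binarize: bool = False
    t_max: float = 1000.0


#: Named problem sizes.  ``full`` is the complete study design;
#: ``scaled_down`` trades sampling depth for desk-scale runtime;
#: ``acceptance`` is the smallest preset whose rank statistics remain stable,
#: used by the bundled acceptance checks.
PRESETS: dict[str, dict] = {
    "full": dict(networks_per_class=100, replicates=3,
                 n_models=10_000, n_init=100, t_max=1000.0),
    "scaled_down": dict(networks_per_class=40, replicates=1,
                        n_models=1_000, n_init=20, t_max=300.0),
    "acceptance": dict(networks_per_class=20, replicates=1,
                       n_models=400, n_init=10, t_max=300.0),
}


def plan_classes(kind: str = "full") -> tuple[tuple[int, int], ...]:
    """Class grid by name: ``full`` (12 classes) or ``sasi`` (4 classes)."""
    if kind == "full":
        return FULL_CLASSES
    if kind == "sasi":
        return SASI_CLASSES
    raise ValueError(f"unknown class grid {kind!r}")


def make_plan(motif: str, preset: str = "full", seed: int = 0,
              classes: Optional[Sequence[tuple[int, int]]] = None,
              **overrides) -> ExperimentPlan:
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}")
    kw = dict(PRESETS[preset])
    kw.update(overrides)
    if classes is None:
        classes = SASI_CLASSES if motif.endswith(("-SA", "-SI")) else FULL_CLASSES
    return ExperimentPlan(motif=motif, classes=tuple(classes), seed=seed, **kw)


def run_experiment(
    plan: ExperimentPlan,
    cache_dir: Optional[str | Path] = None,
    progress: Optional[Callable[[str], None]] = None,
) -> pd.DataFrame:
    """Execute a plan and return one MetricRecord row per network x replicate.

    Per-network failures are logged (``df.attrs['failures']``) and excluded
    rather than aborting the batch.  With ``cache_dir`` set, finished records
    are stored as JSON keyed by their seeds, making reruns resumable."""
    master = np.random.default_rng(plan.seed)
    cache = Path(cache_dir) if cache_dir else None
    if cache:
        cache.mkdir(parents=True, exist_ok=True)
    rows: list[dict] = []
    failures: list[str] = []
    for order_n, conn_x in plan.classes:
        batch_seed = int(master.integers(2**31))
        batch = generate_network_batch(
            plan.motif, order_n, conn_x, plan.networks_per_class,
            seed=batch_seed,
        )
        for i, topo in enumerate(batch):
            net_id = f"{plan.motif}_{order_n}N_E{conn_x}N_{i:03d}"
            for rep in range(plan.replicates):
                sim_seed = int(master.integers(2**31))
                key = f"{net_id}_rep{rep}_s{sim_seed}"
                if cache and (cache / f"{key}.json").exists():
                    rows.append(json.loads((cache / f"{key}.json").read_text()))
                    continue
                try:
                    table = simulate_ensemble(
                        topo, plan.n_models, plan.n_init, seed=sim_seed,
                        t_max=plan.t_max,
                    )
                    rec = compute_metrics(
                        table, log2_values=plan.log2_values,
                        log2_binarize=plan.log2_binarize,
                    )
                except Exception as exc:  # pragma: no cover - defensive
                    failures.append(f"{key}: {exc}")
                    continue
                rec.update(
                    network_id=net_id, replicate=rep, motif=plan.motif,
                    order_N=order_n, connectivity_x=conn_x,
                    topo_seed=topo.seed, sim_seed=sim_seed,
                )
                rows.append(rec)
                if cache:
                    (cache / f"{key}.json").write_text(json.dumps(rec))
                if progress:
                    progress(key)
    df = pd.DataFrame(rows)
    df.attrs["failures"] = failures
    df.attrs["plan"] = plan
    return df


def run_self_regulation_comparison(
    base_motif: str,
    classes: Sequence[tuple[int, int]] = SASI_CLASSES,
    networks_per_class: int = 10,
    n_models: int = 300,
    n_init: int = 10,
    seed: int = 0,
    t_max: float = 300.0,
    log2_values: bool = True,
    log2_binarize: bool = False,
) -> pd.DataFrame:
    """Metrics for a plain motif and its SA/SI variants on matched backgrounds.

    For each random background network, the plain motif and the variants
    with one self-activation or self-inhibition loop per motif node are
    simulated on the *same* background (same random edges, same parameter
    seed), so the comparison across variants is paired and free of
    background-to-background variability."""
    master = np.random.default_rng(seed)
    rows: list[dict] = []
    for order_n, conn_x in classes:
        batch = generate_network_batch(
            base_motif, order_n, conn_x, networks_per_class,
            seed=int(master.integers(2**31)),
        )
        for i, plain in enumerate(batch):
            sim_seed = int(master.integers(2**31))
            variants = {
                base_motif: plain,
                f"{base_motif}-SA": add_self_regulation(plain, "SA"),
                f"{base_motif}-SI": add_self_regulation(plain, "SI"),
            }
            for name, topo in variants.items():
                table = simulate_ensemble(
                    topo, n_models, n_init, seed=sim_seed, t_max=t_max
                )
                rec = compute_metrics(
                    table, log2_values=log2_values,
                    log2_binarize=log2_binarize,
                )
                rec.update(
                    network_id=f"{base_motif}_{order_n}N_E{conn_x}N_{i:03d}",
                    motif=name, order_N=order_n, connectivity_x=conn_x,
                    sim_seed=sim_seed,
                )
                rows.append(rec)
    return pd.DataFrame(rows)


def significance_stars(p: float) -> str:
    """Categorize a p-value: **** <=1e-4, *** <=1e-3, ** <=0.01, * <=0.05."""
    if p <= 0.0001:
        return "****"
    if p <= 0.001:
        return "***"
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return "ns"


def compare_groups(
    records: pd.DataFrame, metric: str, by: str
) -> pd.DataFrame:
    """Two-sided pairwise Mann-Whitney U tests of ``metric`` between the
    groups defined by column ``by`` (e.g. ``order_N`` or ``connectivity_x``).
    """
    groups = {
        key: grp[metric].dropna().to_numpy()
        for key, grp in records.groupby(by)
    }
    if len(groups) < 2:
        raise ValueError("need at least 2 groups to compare")
    for key, vals in groups.items():
        if vals.size < 2:
            raise ValueError(f"group {key!r} has fewer than 2 records")
    rows = []
    for (ka, xa), (kb, xb) in combinations(groups.items(), 2):
        res = stats.mannwhitneyu(xa, xb, alternative="two-sided")
        rows.append({
            "group_a": ka, "group_b": kb,
            "n_a": xa.size, "n_b": xb.size,
            "U": float(res.statistic), "p": float(res.pvalue),
            "stars": significance_stars(float(res.pvalue)),
        })
    return pd.DataFrame(rows)


def add_normalized_indegrees(records: pd.DataFrame) -> pd.DataFrame:
    """Append in_X/in_motif and pairwise in_XY/in_motif descriptor columns."""
    df = records.copy()
    labels = [c[3:] for c in df.columns if c.startswith("in_") and len(c) == 4]
    for lab in labels:
        df[f"in_{lab}_frac"] = df[f"in_{lab}"] / df["in_motif"]
    for la, lb in combinations(labels, 2):
        df[f"in_{la}{lb}_frac"] = (
            (df[f"in_{la}"] + df[f"in_{lb}"]) / df["in_motif"]
        )
    return df


def indegree_metric_correlations(
    records: pd.DataFrame,
    metrics: Sequence[str],
    descriptors: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Spearman rho (and p) of every metric against every in-degree
    descriptor, pooled across all records of an experiment."""
    if len(records) < 10:
        raise ValueError("need at least 10 records for a meta-correlation")
    df = add_normalized_indegrees(records)
    if descriptors is None:
        descriptors = [
            c for c in df.columns
            if c == "in_motif" or (c.startswith("in_") and c != "in_motif")
        ]
    rows = []
    for desc in descriptors:
        for met in metrics:
            sub = df[[desc, met]].dropna()
            if sub[desc].nunique() < 2 or sub[met].nunique() < 2:
                rho, p = float("nan"), float("nan")
            else:
                res = stats.spearmanr(sub[desc], sub[met])
                rho, p = float(res.statistic), float(res.pvalue)
            rows.append({"descriptor": desc, "metric": met,
                         "rho": rho, "p": p, "n": len(sub)})
    return pd.DataFrame(rows)


def indegree_bin_summary(
    records: pd.DataFrame,
    metrics: Sequence[str],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Mean of each metric per (in_A, in_B) cell, plus the asymmetry table
    carrying log2(in_A/in_B), log2(BiC_A/BiC_B) and CC_AB per record."""
    bins = (
        records.groupby(["in_A", "in_B"])[list(metrics)]
        .mean()
        .reset_index()
    )
    counts = records.groupby(["in_A", "in_B"]).size().rename("n_networks")
    bins = bins.merge(counts.reset_index(), on=["in_A", "in_B"])
    asym = records[["in_A", "in_B"]].copy()
    asym["log2_in_ratio"] = np.log2(records["in_A"] / records["in_B"])
    if "BiC_A" in records and "BiC_B" in records:
        asym["log2_bic_ratio"] = np.log2(records["BiC_A"] / records["BiC_B"])
    if "CC_AB" in records:
        asym["CC_AB"] = records["CC_AB"]
    return bins, asym


def random_node_control(
    steady_table: SteadyStateTable,
    rng: np.random.Generator,
    n_nodes: Optional[int] = None,
    log2_values: bool = True,
    log2_binarize: bool = False,
) -> dict[str, float]:
    """Metrics recomputed on uniformly chosen background (non-motif) nodes.

    The control asks whether the motif-node metric distributions are motif
    specific or generic to any node set of the same size in the network.
    """
    topo = steady_table.topology
    if topo.motif is None:
        raise ValueError("topology has no identified motif")
    if n_nodes is None:
        n_nodes = topo.motif.n_nodes
    background = [n for n in topo.nodes if n not in topo.motif.nodes]
    if len(background) < n_nodes:
        raise ValueError(
            f"need at least {n_nodes} background nodes, have {len(background)}"
        )
    chosen_idx = sorted(rng.choice(len(background), size=n_nodes, replace=False))
    chosen = [background[i] for i in chosen_idx]
    rec = compute_metrics(
        steady_table, nodes=chosen, log2_values=log2_values,
        log2_binarize=log2_binarize, include_indegree=False,
    )
    rec["control"] = True
    return rec
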