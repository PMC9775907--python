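"""Normalization, z-scoring, and ON/OFF binarization of steady states.

Raw steady-state concentrations are first made dimensionless per model by
dividing each node's value by that model's G/k (the node's unregulated
level), then z-scored per node across *all* pooled steady-state rows of one
network's ensemble.  A node with z-score above zero is ON (1), otherwise OFF
(0); the motif-node bits concatenated in node order (A, B[, C]) form the
binarized state string.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats


def normalize_steady_state(s, g, k):
    """Dimensionless steady-state level S / (G/k) = S*k/G."""
    s = np.asarray(s, dtype=float)
    g = np.asarray(g, dtype=float)
    k = np.asarray(k, dtype=float)
    if np.any(g <= 0):
        raise ValueError("production rate G must be positive")
    if np.any(k <= 0):
        raise ValueError("degradation rate k must be positive")
    return s * k / g


@dataclass
class BinarizedStateTable:
    """Binarized pooled steady states of one network's ensemble.

    ``table`` carries the identifying columns, per-node z-scores
    (``z_<node>``), and the motif-restricted ``state`` string; ``nodes`` are
    the nodes the string spans; ``means``/``stds`` are the per-node pooling
    statistics used, retained so the transform is auditable.
    """

    table: pd.DataFrame
    nodes: tuple[str, ...]
    all_nodes: tuple[str, ...]
    means: np.ndarray
    stds: np.ndarray
    log2: bool = False

    @property
    def state_strings(self) -> pd.Series:
        return self.table["state"]

    def write(self, path: str | Path) -> Path:
        path = Path(path)
        self.table.to_csv(path, sep="\t", index=False)
        return path

    @staticmethod
    def read(path: str | Path, nodes: Sequence[str]) -> "BinarizedStateTable":
        df = pd.read_csv(path, sep="\t", dtype={"state": str})
        all_nodes = tuple(
            c[2:] for c in df.columns if c.startswith("z_")
        )
        zs = df[[f"z_{n}" for n in all_nodes]].to_numpy()
        return BinarizedStateTable(
            table=df, nodes=tuple(nodes), all_nodes=all_nodes,
            means=np.full(len(all_nodes), np.nan),
            stds=np.full(len(all_nodes), np.nan),
        )


def zscore_binarize(
    normalized: pd.DataFrame,
    nodes: Sequence[str],
    all_nodes: Optional[Sequence[str]] = None,
    log2: bool = False,
) -> BinarizedStateTable:
    """Z-score per node over all pooled rows and binarize at z > 0.

    ``normalized`` is the output of :meth:`SteadyStateTable.normalized` (or
    any table with identifying columns plus one column per node).  ``nodes``
    selects the columns entering the state string (motif nodes, in order);
    z-scores are nonetheless computed and retained for every node so that
    controls on background nodes use identical pooling.  With ``log2=True``
    values are log2-transformed before z-scoring (binarization is invariant
    to per-node affine maps but not to log-compression, so the switch can
    matter for threshold-crossing rows).
    """
    if all_nodes is None:
        id_cols = {"model_id", "state_id", "multiplicity", "n_inits"}
        all_nodes = [c for c in normalized.columns if c not in id_cols]
    missing = [n for n in nodes if n not in all_nodes]
    if missing:
        raise ValueError(f"nodes {missing} not present in the table")
    if len(normalized) < 2:
        raise ValueError("need at least 2 pooled rows to z-score")

    values = normalized[list(all_nodes)].to_numpy(dtype=float)
    if log2:
        values = np.log2(np.maximum(values, 1e-12))
    means = values.mean(axis=0)
    stds = values.std(axis=0)
    for j, n in enumerate(all_nodes):
        if stds[j] == 0:
            raise ValueError(f"node {n!r} has zero variance; cannot z-score")
    z = stats.zscore(values, axis=0, ddof=0)

    id_cols_present = [
        c for c in ("model_id", "state_id", "multiplicity", "n_inits")
        if c in normalized.columns
    ]
    out = normalized[id_cols_present].copy()
    for j, n in enumerate(all_nodes):
        out[f"z_{n}"] = z[:, j]
    sel = [list(all_nodes).index(n) for n in nodes]
    bits = (z[:, sel] > 0).astype(int)
    out["state"] = ["".join(map(str, row)) for row in bits]
    return BinarizedStateTable(
        table=out, nodes=tuple(nodes), all_nodes=tuple(all_nodes),
        means=means, stds=stds, log2=log2,
    )
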