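"""Graph metrics on weighted functional-connectivity matrices.

Node-level participation coefficient (PC) and within-module degree z-score
(WMD) in their canonical weighted forms,

    PC_i  = 1 − Σ_s (k_is / k_i)²
    WMD_i = (k_i^within − μ_m(i)) / σ_m(i)

where k_i is node i's (preprocessed) weighted degree, k_is its summed weight
to module s, and μ_m/σ_m the mean and population standard deviation of
within-module degree over the nodes of i's module. High PC marks connector
hubs (edges spread across modules), high WMD marks provincial hubs (strong
within their own module). The two scalars entering the mediation model are
unweighted means of PC and WMD over a declared frontoparietal node set.

The module partition is always consumed as input (no community detection);
negative edge weights are zeroed by default before degree computation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SYMMETRY_TOL = 1e-10


def validate_connectivity(weights: np.ndarray) -> np.ndarray:
    """Check an FC matrix is square, symmetric and zero-diagonal."""
    W = np.asarray(weights, float)
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise ValueError(f"connectivity matrix must be square, got {W.shape}")
    if W.shape[0] < 2:
        raise ValueError("connectivity matrix needs at least 2 nodes")
    if np.abs(W - W.T).max() > SYMMETRY_TOL:
        raise ValueError("connectivity matrix is not symmetric")
    if np.abs(np.diag(W)).max() > SYMMETRY_TOL:
        raise ValueError("connectivity matrix must have a zero diagonal")
    return W


def preprocess_weights(
    weights: np.ndarray,
    policy: str = "zero_negative",
    proportional_threshold: float | None = None,
) -> np.ndarray:
    """Apply the declared edge-preprocessing policy.

    ``zero_negative`` (default) sets negative weights to zero; ``none``
    leaves the matrix untouched. ``proportional_threshold`` (0 < q ≤ 1)
    additionally keeps only the strongest fraction q of positive edges
    (weights retained, not binarized); off by default.
    """
    W = validate_connectivity(weights).copy()
    if policy == "zero_negative":
        W[W < 0] = 0.0
    elif policy != "none":
        raise ValueError(f"unknown preprocessing policy {policy!r}")
    if proportional_threshold is not None:
        if not 0 < proportional_threshold <= 1:
            raise ValueError("proportional_threshold must be in (0, 1]")
        iu = np.triu_indices_from(W, k=1)
        vals = W[iu]
        pos = vals[vals > 0]
        if pos.size:
            cut = np.quantile(pos, 1 - proportional_threshold)
            W[W < cut] = 0.0
            np.fill_diagonal(W, 0.0)
    return W


def node_degree(weights: np.ndarray, preprocessed: bool = False) -> np.ndarray:
    """Weighted degree k_i = Σ_j w'_ij after preprocessing."""
    W = weights if preprocessed else preprocess_weights(weights)
    return W.sum(axis=1)


def _module_indices(modules: np.ndarray) -> dict:
    labels = np.asarray(modules)
    return {lab: np.flatnonzero(labels == lab) for lab in np.unique(labels)}


def module_degree_matrix(W: np.ndarray, modules: np.ndarray) -> np.ndarray:
    """k_is: summed weight from each node to each module (columns ordered by
    sorted unique module label)."""
    idx = _module_indices(modules)
    return np.column_stack([W[:, ix].sum(axis=1) for ix in idx.values()])


def participation_coefficient(
    weights: np.ndarray, modules: np.ndarray, preprocessed: bool = False
) -> np.ndarray:
    """PC_i = 1 − Σ_s (k_is/k_i)² for every node; 0 for isolated nodes."""
    W = weights if preprocessed else preprocess_weights(weights)
    k_is = module_degree_matrix(W, modules)
    k = k_is.sum(axis=1)
    pc = np.zeros(len(k))
    nz = k > 0
    pc[nz] = 1.0 - ((k_is[nz] / k[nz, None]) ** 2).sum(axis=1)
    return pc


def within_module_degree_z(
    weights: np.ndarray, modules: np.ndarray, preprocessed: bool = False
) -> np.ndarray:
    """WMD_i: z-score of within-module degree relative to i's own module.

    Uses the population (n-denominator) standard deviation; degenerate
    modules (size 1 or zero spread) get WMD = 0.
    """
    W = weights if preprocessed else preprocess_weights(weights)
    labels = np.asarray(modules)
    wmd = np.zeros(W.shape[0])
    for ix in _module_indices(labels).values():
        within = W[np.ix_(ix, ix)].sum(axis=1)
        sd = within.std()  # population sd
        if len(ix) > 1 and sd > 0:
            wmd[ix] = (within - within.mean()) / sd
    return wmd


@dataclass
class NodeMetrics:
    """Per-node PC/WMD plus their frontoparietal averages."""

    node_ids: list[str]
    degree: np.ndarray
    pc: np.ndarray
    wmd: np.ndarray
    pc_fp: float
    wmd_fp: float
    fp_nodes: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "node_id": self.node_ids,
                "degree": self.degree,
                "pc": self.pc,
                "wmd": self.wmd,
                "is_fp": [n in set(self.fp_nodes) for n in self.node_ids],
            }
        )


def average_fp_metrics(
    pc: np.ndarray, wmd: np.ndarray, node_ids: list[str], fp_nodes: list[str]
) -> tuple[float, float]:
    """Unweighted means of PC and WMD over the frontoparietal node set."""
    if not fp_nodes:
        raise ValueError("frontoparietal node set is empty")
    pos = {n: i for i, n in enumerate(node_ids)}
    missing = [n for n in fp_nodes if n not in pos]
    if missing:
        raise ValueError(f"frontoparietal nodes not in graph: {missing}")
    ix = [pos[n] for n in fp_nodes]
    return float(np.mean(pc[ix])), float(np.mean(wmd[ix]))


def compute_node_metrics(
    weights: np.ndarray,
    node_ids: list[str],
    modules: np.ndarray,
    fp_nodes: list[str],
    scope: str = "full",
    policy: str = "zero_negative",
    proportional_threshold: float | None = None,
) -> NodeMetrics:
    """PC/WMD for every node and their frontoparietal averages.

    ``scope='full'`` (default) computes metrics on the whole graph and then
    averages over the frontoparietal nodes; ``scope='subgraph'`` restricts
    the matrix and partition to the frontoparietal nodes before computing.
    """
    node_ids = [str(n) for n in node_ids]
    modules = np.asarray(modules)
    if len(node_ids) != len(modules):
        raise ValueError("one module label per node required")
    if scope == "subgraph":
        pos = {n: i for i, n in enumerate(node_ids)}
        missing = [n for n in fp_nodes if n not in pos]
        if missing:
            raise ValueError(f"frontoparietal nodes not in graph: {missing}")
        ix = [pos[n] for n in fp_nodes]
        weights = np.asarray(weights, float)[np.ix_(ix, ix)]
        node_ids = [node_ids[i] for i in ix]
        modules = modules[ix]
    elif scope != "full":
        raise ValueError(f"unknown scope {scope!r}")
    W = preprocess_weights(weights, policy=policy,
                           proportional_threshold=proportional_threshold)
    pc = participation_coefficient(W, modules, preprocessed=True)
    wmd = within_module_degree_z(W, modules, preprocessed=True)
    pc_fp, wmd_fp = average_fp_metrics(pc, wmd, node_ids, list(fp_nodes))
    return NodeMetrics(
        node_ids=node_ids,
        degree=node_degree(W, preprocessed=True),
        pc=pc,
        wmd=wmd,
        pc_fp=pc_fp,
        wmd_fp=wmd_fp,
        fp_nodes=[str(n) for n in fp_nodes],
    )
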