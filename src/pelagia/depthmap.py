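"""Ancestral depth reconstruction on a chronogram by re-rooting contrasts.

Species depths are the means of their minimum and maximum reported depths.
Ancestral states follow the Brownian-motion maximum-likelihood procedure
that re-roots the tree at each internal node and takes the contrast
(pruning) state at that root; these estimates coincide with the joint GLS
reconstruction for a Gaussian model.  States along a branch are
interpolated linearly in time between the endpoint estimates.

Implementation note: re-rooting is realized by message passing on the
unrooted view of the tree.  Each subtree hanging off a node contributes a
Gaussian message (mean m, variance factor v, in units of the BM rate); the
re-rooted pruning estimate at a node is the precision-weighted combination
of the messages arriving from all its neighbours, which is manifestly
independent of the original root position.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from .trees import ensure_node_labels, node_ages, tree_to_graph

logger = logging.getLogger(__name__)

__all__ = [
    "DepthRecord",
    "AncestralStateMap",
    "mean_depth",
    "load_depths",
    "pic_root_estimate",
    "rerooting_ancestral_states",
    "interpolate_branch_states",
    "reconstruct_depths",
    "depth_zone",
]

#: epipelagic/mesopelagic boundary (m): the euphotic zone is the upper 200 m
EPIPELAGIC_MAX_M = 200.0


@dataclass(frozen=True)
class DepthRecord:
    species: str
    depth_min: float  # m
    depth_max: float  # m

    def __post_init__(self):
        if not 0 <= self.depth_min <= self.depth_max:
            raise ValueError(
                f"{self.species}: need 0 <= depth_min <= depth_max, "
                f"got ({self.depth_min}, {self.depth_max})"
            )

    @property
    def mean_depth(self) -> float:
        return (self.depth_min + self.depth_max) / 2


@dataclass
class AncestralStateMap:
    """Per-node (estimate, variance) plus optional per-branch profiles."""

    states: dict[str, tuple[float, float]]  # node label -> (estimate m, variance m^2)
    sigma2: float  # contrasts-estimated BM rate (m^2/My)
    branch_states: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)

    def estimate(self, label: str) -> float:
        return self.states[label][0]

    def variance(self, label: str) -> float:
        return self.states[label][1]


def mean_depth(record: DepthRecord) -> float:
    """Arithmetic mean of the reported minimum and maximum depths (m)."""
    return record.mean_depth


def load_depths(path) -> pd.DataFrame:
    """Species depth TSV (species, depth_min, depth_max, both in m).

    Rows with a missing bound are excluded -- not imputed -- with a logged
    reason; the returned frame carries a ``mean_depth`` column.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"species", "depth_min", "depth_max"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    bad = df["depth_min"].isna() | df["depth_max"].isna()
    for species in df.loc[bad, "species"]:
        logger.info("excluding %s: missing depth bound", species)
    df = df[~bad].copy()
    df["mean_depth"] = (df["depth_min"] + df["depth_max"]) / 2
    return df


# ---------------------------------------------------------------------------
# message passing


def _upward(adj, tip_values, src: str, dst: str, cache) -> tuple[float, float]:
    """Gaussian message from the subtree on ``src``'s side of edge (src, dst).

    Returned (m, v): the subtree data constrain x_dst as N(m, sigma2 * v).
    """
    key = (src, dst)
    if key in cache:
        return cache[key]
    length = next(l for nbr, l in adj[src] if nbr == dst)
    incoming = [
        _upward(adj, tip_values, nbr, src, cache)
        for nbr, _ in adj[src]
        if nbr != dst
    ]
    if not incoming:  # src is a tip
        out = (tip_values[src], length)
    else:
        m, v = _combine(incoming)
        out = (m, v + length)
    cache[key] = out
    return out


def _combine(messages: list[tuple[float, float]]) -> tuple[float, float]:
    """Precision-weighted combination of Gaussian messages.

    Zero-variance messages are exact constraints; several exact constraints
    with differing means (a zero-length polytomy/cherry) fall back to their
    simple average, the limit rule, with a logged note.
    """
    exact = [m for m, v in messages if v == 0.0]
    if exact:
        if len(exact) > 1 and max(exact) - min(exact) > 0:
            logger.info("zero-length clash: averaging %d exact constraints", len(exact))
        return float(np.mean(exact)), 0.0
    w = np.array([1.0 / v for _, v in messages])
    m = np.array([m for m, _ in messages])
    return float(np.sum(w * m) / np.sum(w)), float(1.0 / np.sum(w))


def _check_tips(leaves, tip_values):
    missing = set(leaves) - set(tip_values)
    if missing:
        raise KeyError(f"tips without values: {sorted(missing)}")


def _contrasts_sigma2(adj, leaves, tip_values, root: str) -> float:
    """BM rate from standardized independent contrasts (pruning pass).

    Each internal combination of two (or, sequentially, more) descendant
    messages yields one contrast u = (m1 - m2)/sqrt(v1 + v2); sigma2_hat is
    the mean squared standardized contrast.
    """
    contrasts: list[float] = []

    def prune(src: str, parent: str | None) -> tuple[float, float]:
        children = [(nbr, l) for nbr, l in adj[src] if nbr != parent]
        if not children:
            return tip_values[src], 0.0
        msgs = []
        for child, length in children:
            m, v = prune(child, src)
            msgs.append((m, v + length))
        m1, v1 = msgs[0]
        for m2, v2 in msgs[1:]:
            if v1 + v2 > 0:
                contrasts.append((m1 - m2) / np.sqrt(v1 + v2))
            w1, w2 = (1 / v1 if v1 else np.inf), (1 / v2 if v2 else np.inf)
            if np.isinf(w1) and np.isinf(w2):
                m1, v1 = (m1 + m2) / 2, 0.0
            elif np.isinf(w1) or np.isinf(w2):
                m1, v1 = (m1, 0.0) if np.isinf(w1) else (m2, 0.0)
            else:
                v_new = 1 / (w1 + w2)
                m1, v1 = v_new * (w1 * m1 + w2 * m2), v_new
        return m1, v1

    prune(root, None)
    if not contrasts:
        return 0.0
    return float(np.mean(np.square(contrasts)))


def pic_root_estimate(
    tree: dendropy.Tree,
    tip_values: dict[str, float],
) -> tuple[float, float]:
    """Contrasts (pruning) estimate of the root state and its variance.

    The estimate is the branch-length-weighted pruning average of the tip
    values; the variance is the combined message variance scaled by the
    contrasts-estimated BM rate.
    """
    ensure_node_labels(tree)
    adj, leaves, internals = tree_to_graph(tree)
    _check_tips(leaves, tip_values)
    root = tree.seed_node.label
    cache: dict = {}
    msgs = [_upward(adj, tip_values, nbr, root, cache) for nbr, _ in adj[root]]
    m, v = _combine(msgs)
    sigma2 = _contrasts_sigma2(adj, leaves, tip_values, root)
    return m, sigma2 * v


def rerooting_ancestral_states(
    tree: dendropy.Tree,
    tip_values: dict[str, float],
) -> AncestralStateMap:
    """ML ancestral states at every node via re-rooted contrasts.

    For each internal node the estimate equals the pruning root state of
    the tree re-rooted at that node; tips carry their observed value with
    zero variance.  Estimates are invariant to the original root position.
    """
    ensure_node_labels(tree)
    adj, leaves, internals = tree_to_graph(tree)
    _check_tips(leaves, tip_values)
    sigma2 = _contrasts_sigma2(adj, leaves, tip_values, tree.seed_node.label)
    cache: dict = {}
    states: dict[str, tuple[float, float]] = {}
    for node in internals:
        msgs = [_upward(adj, tip_values, nbr, node, cache) for nbr, _ in adj[node]]
        m, v = _combine(msgs)
        states[node] = (m, sigma2 * v)
    for leaf in leaves:
        states[leaf] = (float(tip_values[leaf]), 0.0)
    return AncestralStateMap(states=states, sigma2=sigma2)


def interpolate_branch_states(
    asr: AncestralStateMap,
    tree: dendropy.Tree,
    n_points: int,
) -> dict[tuple[str, str], np.ndarray]:
    """States along each branch, linear in elapsed time between endpoints.

    ``n_points >= 2`` samples per branch including both endpoints, which
    match the node estimates exactly.  Profiles are stored on the map and
    returned keyed by (parent label, child label).
    """
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    ensure_node_labels(tree)
    profiles: dict[tuple[str, str], np.ndarray] = {}
    for node in tree.preorder_node_iter():
        for child in node.child_nodes():
            a = asr.estimate(node.label)
            b = asr.estimate(child.label)
            profiles[(node.label, child.label)] = np.linspace(a, b, n_points)
    asr.branch_states = profiles
    return profiles


def depth_zone(depth_m: float) -> str:
    return "epipelagic" if depth_m <= EPIPELAGIC_MAX_M else "mesopelagic"


def reconstruct_depths(
    tree: dendropy.Tree,
    depth_table: pd.DataFrame,
    n_points: int = 10,
) -> tuple[AncestralStateMap, pd.DataFrame]:
    """Full pipeline: mean depths -> pruning -> reconstruction -> report.

    Tips without a depth record are pruned (and listed in the report's
    attrs); needs at least two matched tips.  The report has one row per
    node with its age, depth estimate, variance, and depth-zone label.
    """
    if "mean_depth" not in depth_table.columns:
        depth_table = depth_table.copy()
        depth_table["mean_depth"] = (
            depth_table["depth_min"] + depth_table["depth_max"]
        ) / 2
    values = dict(zip(depth_table["species"], depth_table["mean_depth"]))
    tree = tree.clone(depth=1)
    ensure_node_labels(tree)
    tip_labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    matched = [t for t in tip_labels if t in values]
    pruned = sorted(set(tip_labels) - set(matched))
    if len(matched) < 2:
        raise ValueError(f"fewer than 2 tips with depth data (matched: {matched})")
    if pruned:
        logger.info("pruning %d tips without depth data: %s", len(pruned), pruned)
        tree.retain_taxa_with_labels(matched)
        ensure_node_labels(tree)
    asr = rerooting_ancestral_states(tree, {t: values[t] for t in matched})
    interpolate_branch_states(asr, tree, n_points)
    ages = node_ages(tree)
    rows = []
    for node in tree.preorder_node_iter():
        est, var = asr.states[node.label]
        rows.append(
            {
                "node": node.label,
                "is_tip": node.is_leaf(),
                "age_ma": ages[node.label],
                "depth_m": est,
                "variance_m2": var,
                "zone": depth_zone(est),
            }
        )
    report = pd.DataFrame(rows)
    report.attrs["pruned_tips"] = pruned
    return asr, report


def plot_depth_profile(report: pd.DataFrame, path) -> None:
    """Node age vs reconstructed depth, colored by depth zone."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for zone, color in (("epipelagic", "tab:cyan"), ("mesopelagic", "tab:blue")):
        sub = report[report["zone"] == zone]
        ax.scatter(sub["age_ma"], sub["depth_m"], label=zone, color=color)
    ax.axhline(EPIPELAGIC_MAX_M, color="grey", lw=0.8, ls=":")
    ax.invert_yaxis()
    ax.invert_xaxis()
    ax.set_xlabel("age (Ma)")
    ax.set_ylabel("depth (m)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
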