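"""Concordance between paleontological and molecular timescales.

Pairs the fossil-based maximum-likelihood origin estimate of each
total-group family with the molecular age of the same lineage -- by default
the *stem* age (age of the parent of the family's MRCA), since the stem
node is the total-group origin in a sampled phylogeny -- and quantifies
disagreement as the residual sum of squares from the 1:1 line.  Also
summarizes differences between two calibration schemes over a node-age
table, and simple divergence-window statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd

from .trees import node_ages

__all__ = [
    "TimescalePair",
    "stem_age_lookup",
    "crown_age_lookup",
    "pair_timescales",
    "rss_one_to_one",
    "residuals_one_to_one",
    "scheme_difference_summary",
    "divergence_window",
    "read_node_ages",
    "plot_concordance",
]


@dataclass(frozen=True)
class TimescalePair:
    family: str
    paleo_age: float  # Ma, ML point estimate from fossils
    molecular_age: float  # Ma, posterior mean stem age
    paleo_ci: tuple[float, float] | None = None
    molecular_ci: tuple[float, float] | None = None

    def __post_init__(self):
        if self.paleo_age <= 0 or self.molecular_age <= 0:
            raise ValueError("ages must be > 0")


def _family_mrca(tree: dendropy.Tree, family_tips: set[str]) -> dendropy.Node:
    if not family_tips:
        raise ValueError("family_tips is empty")
    tip_labels = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    missing = family_tips - tip_labels
    if missing:
        raise KeyError(f"tips absent from tree: {sorted(missing)}")
    if len(family_tips) == 1:
        (label,) = family_tips
        return next(
            leaf for leaf in tree.leaf_node_iter() if leaf.taxon.label == label
        )
    taxa = [tree.taxon_namespace.get_taxon(lbl) for lbl in sorted(family_tips)]
    mrca = tree.mrca(taxa=taxa)
    under = {leaf.taxon.label for leaf in mrca.leaf_iter()}
    intruders = under - family_tips
    if intruders:
        raise ValueError(
            f"tip set not monophyletic: MRCA also contains {sorted(intruders)}"
        )
    return mrca


def stem_age_lookup(tree: dendropy.Tree, family_tips: set[str]) -> float:
    """Stem (total-group) age: the age of the parent of the family's MRCA.

    For a single-tip family this is the age of the tip's parent.  Raises if
    any tip is absent, the set is not monophyletic, or it spans the root
    (no stem lineage exists).
    """
    mrca = _family_mrca(tree, set(family_tips))
    if mrca.parent_node is None:
        raise ValueError("tip set spans the root: no stem lineage exists")
    ages = node_ages(tree)
    return ages[mrca.parent_node.label]


def crown_age_lookup(tree: dendropy.Tree, family_tips: set[str]) -> float:
    """Crown age: the age of the family's MRCA itself (0 for a single tip)."""
    mrca = _family_mrca(tree, set(family_tips))
    return node_ages(tree)[mrca.label]


def pair_timescales(
    records,
    tree: dendropy.Tree,
    family_tips: dict[str, set[str]],
    age_kind: str = "stem",
) -> list[TimescalePair]:
    """Pair estimable families' ML origin estimates with tree ages.

    Families that are not estimable (no fossil point estimate) are skipped,
    mirroring a concordance plot that shows only families with dense
    records.  ``age_kind`` selects stem (default, total-group) or crown
    molecular ages.
    """
    from .fossilrec import ml_origin_estimate

    lookup = {"stem": stem_age_lookup, "crown": crown_age_lookup}[age_kind]
    pairs = []
    for rec in records:
        if not rec.estimable or rec.family not in family_tips:
            continue
        pairs.append(
            TimescalePair(
                family=rec.family,
                paleo_age=ml_origin_estimate(rec),
                molecular_age=lookup(tree, family_tips[rec.family]),
            )
        )
    return pairs


def _coords(pairs) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(pairs, pd.DataFrame):
        return pairs["paleo_age"].to_numpy(float), pairs["molecular_age"].to_numpy(float)
    return (
        np.array([p.paleo_age for p in pairs], dtype=float),
        np.array([p.molecular_age for p in pairs], dtype=float),
    )


def residuals_one_to_one(pairs) -> np.ndarray:
    """Signed residuals molecular - paleo (positive: molecular older)."""
    paleo, mol = _coords(pairs)
    if paleo.size == 0:
        raise ValueError("no pairs given")
    return mol - paleo


def rss_one_to_one(pairs) -> float:
    """Residual sum of squares about the 1:1 line (My^2).

    Symmetric in the two coordinates and invariant to pair order.
    """
    return float(np.sum(residuals_one_to_one(pairs) ** 2))


def scheme_difference_summary(
    nodes: pd.DataFrame,
    subset: str = "all",
    ddof: int = 1,
) -> tuple[float, float]:
    """Mean and SD of per-node |scheme b - scheme a| posterior-mean ages.

    ``subset`` is ``"all"`` or ``"pelagia"`` (rows with a truthy
    ``in_pelagia``).  SD is the sample SD by default (``ddof=1``); pass
    ``ddof=0`` for the population SD.
    """
    if subset not in ("all", "pelagia"):
        raise ValueError(f"subset must be 'all' or 'pelagia', got {subset!r}")
    df = nodes if subset == "all" else nodes[nodes["in_pelagia"].astype(bool)]
    if len(df) == 0:
        raise ValueError(f"empty subset {subset!r}")
    delta = (df["posterior_mean_b"] - df["posterior_mean_a"]).abs().to_numpy(float)
    sd = float(np.std(delta, ddof=ddof)) if len(delta) > ddof else 0.0
    return float(np.mean(delta)), sd


def divergence_window(ages) -> tuple[float, float, float]:
    """(min, max, span) of a set of node ages (Ma)."""
    arr = np.asarray(list(ages), dtype=float)
    if arr.size == 0:
        raise ValueError("no ages given")
    return float(arr.min()), float(arr.max()), float(arr.max() - arr.min())


def read_node_ages(path) -> pd.DataFrame:
    """Node-age table TSV: node_id, posterior_mean_a, ci_low_a, ci_high_a,
    posterior_mean_b, ci_low_b, ci_high_b, in_pelagia."""
    df = pd.read_csv(path, sep="\t")
    required = {"node_id", "posterior_mean_a", "posterior_mean_b", "in_pelagia"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    for scheme in "ab":
        lo, mid, hi = f"ci_low_{scheme}", f"posterior_mean_{scheme}", f"ci_high_{scheme}"
        if lo in df.columns and hi in df.columns:
            bad = ~((df[lo] <= df[mid]) & (df[mid] <= df[hi]))
            if bad.any():
                raise ValueError(f"{path}: CI does not bracket mean for scheme {scheme}")
    return df


def plot_concordance(pairs_by_scheme: dict[str, list[TimescalePair]], path) -> None:
    """Scatter of molecular vs paleontological ages with the 1:1 line."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(
        1, len(pairs_by_scheme), figsize=(5 * len(pairs_by_scheme), 5), squeeze=False
    )
    for ax, (name, pairs) in zip(axes[0], pairs_by_scheme.items()):
        paleo, mol = _coords(pairs)
        lim = max(paleo.max(), mol.max()) * 1.1
        ax.plot([0, lim], [0, lim], "k--", lw=1)
        ax.scatter(paleo, mol, zorder=3)
        ax.set_xlabel("paleontological ML origin (Ma)")
        ax.set_ylabel("molecular stem age (Ma)")
        ax.set_title(f"{name}: RSS = {rss_one_to_one(pairs):.2f}")
        ax.set_xlim(0, lim)
        ax.set_ylim(0, lim)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
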