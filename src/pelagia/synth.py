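"""Synthetic-data generators with known ground truth.

Every downstream stage of the pipeline can be exercised without external
downloads: fossil horizon ages from a (piecewise) Poisson preservation
process, chronograms with Brownian trait evolution, paired timescale
estimates, and annotated codon alignments.  All generators take an integer
seed and are bit-reproducible for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd

from .supermatrix import GeneAlignment, _VERTMITO
from .trees import ensure_node_labels

__all__ = [
    "PreservationScenario",
    "SimulatedTraitSet",
    "simulate_fossil_horizons",
    "simulate_chronogram",
    "simulate_bm_traits",
    "simulate_paired_timescales",
    "simulate_codon_alignment",
    "simulate_rna_alignment",
]


@dataclass(frozen=True)
class PreservationScenario:
    """Preservation model for one lineage.

    Horizons are produced by a Poisson process on the age interval
    ``[end_age, origin_age]`` with intensity ``rate`` horizons/My.  If
    ``boundary_age`` is set, the intensity before (older than) the boundary
    is ``rate * early_factor`` -- ``early_factor = 0.1`` models preservation
    an order of magnitude higher during the observed fossil range than in
    the lineage's earlier history.
    """

    origin_age: float  # Ma, true origin (> end_age)
    end_age: float = 0.0  # Ma, extinction (0 for extant)
    rate: float = 0.2  # expected horizons per My
    early_factor: float = 1.0
    boundary_age: float | None = None  # Ma; rate*early_factor applies above it
    seed: int = 0

    def __post_init__(self):
        if not self.origin_age > self.end_age >= 0:
            raise ValueError(
                f"need origin_age > end_age >= 0, got {self.origin_age}, {self.end_age}"
            )
        if self.rate < 0:
            raise ValueError(f"rate must be >= 0, got {self.rate}")
        if not 0 < self.early_factor <= 1:
            raise ValueError(f"early_factor must be in (0, 1], got {self.early_factor}")
        if self.boundary_age is not None and not (
            self.end_age <= self.boundary_age <= self.origin_age
        ):
            raise ValueError("boundary_age must lie within [end_age, origin_age]")


@dataclass
class SimulatedTraitSet:
    """Ground truth for a Brownian-motion trait simulated on a chronogram."""

    tree: dendropy.Tree
    root_state: float
    sigma2: float  # trait-units^2 per My
    tip_values: dict[str, float]
    true_node_values: dict[str, float]
    seed: int


def simulate_fossil_horizons(scenario: PreservationScenario) -> np.ndarray:
    """Horizon ages (Ma) drawn from the scenario's Poisson process.

    Returned sorted oldest-first.  A zero-intensity segment yields no
    horizons; ``rate = 0`` yields an empty array.
    """
    rng = np.random.default_rng(scenario.seed)
    segments = []  # (young_age, old_age, intensity)
    if scenario.boundary_age is None or scenario.early_factor == 1.0:
        segments.append((scenario.end_age, scenario.origin_age, scenario.rate))
    else:
        segments.append((scenario.end_age, scenario.boundary_age, scenario.rate))
        segments.append(
            (scenario.boundary_age, scenario.origin_age, scenario.rate * scenario.early_factor)
        )
    ages = []
    for young, old, intensity in segments:
        n = rng.poisson(intensity * (old - young))
        ages.append(rng.uniform(young, old, size=n))
    out = np.concatenate(ages) if ages else np.empty(0)
    return np.sort(out)[::-1]


def simulate_chronogram(
    n_tips: int,
    crown_age: float = 69.0,
    seed: int = 0,
    prefix: str = "T",
) -> dendropy.Tree:
    """Random ultrametric chronogram (pure-birth shape, rescaled crown age).

    A coalescent-style construction: at each step two random lineages merge
    at a strictly increasing age; ages are then rescaled so the root sits at
    ``crown_age`` Ma.  All branch lengths are strictly positive.
    """
    if n_tips < 2:
        raise ValueError("need at least 2 tips")
    rng = np.random.default_rng(seed)
    taxa = dendropy.TaxonNamespace([f"{prefix}{i + 1}" for i in range(n_tips)])
    nodes = []
    for taxon in taxa:
        leaf = dendropy.Node(taxon=taxon)
        leaf.age = 0.0
        nodes.append(leaf)
    # merge times: cumulative sums of positive exponentials
    merge_ages = np.cumsum(rng.exponential(1.0, size=n_tips - 1))
    merge_ages *= crown_age / merge_ages[-1]
    for age in merge_ages:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = dendropy.Node()
        parent.age = float(age)
        for child in (nodes[i], nodes[j]):
            parent.add_child(child)
            child.edge.length = parent.age - child.age
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [parent]
    tree = dendropy.Tree(taxon_namespace=taxa, seed_node=nodes[0])
    tree.is_rooted = True
    ensure_node_labels(tree)
    return tree


def simulate_bm_traits(
    tree: dendropy.Tree,
    root_state: float,
    sigma2: float,
    seed: int = 0,
) -> SimulatedTraitSet:
    """Evolve a Brownian-motion trait along a chronogram.

    Each branch adds an independent Gaussian increment with variance
    ``sigma2 * branch_length``.  ``sigma2 = 0`` degenerates to a constant
    trait equal to the root state.
    """
    if sigma2 < 0:
        raise ValueError(f"sigma2 must be >= 0, got {sigma2}")
    ensure_node_labels(tree)
    rng = np.random.default_rng(seed)
    values: dict[str, float] = {}
    tips: dict[str, float] = {}
    internals: dict[str, float] = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            values[node.label] = root_state
        else:
            length = node.edge.length or 0.0
            values[node.label] = values[node.parent_node.label] + rng.normal(
                0.0, np.sqrt(sigma2 * length)
            )
        (tips if node.is_leaf() else internals)[node.label] = values[node.label]
    return SimulatedTraitSet(
        tree=tree,
        root_state=root_state,
        sigma2=sigma2,
        tip_values=tips,
        true_node_values=internals,
        seed=seed,
    )


def simulate_paired_timescales(
    n: int,
    noise_sd: float = 5.0,
    bias: float = 16.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Paired age estimates of the same true divergences.

    ``estimate_a = true + N(0, noise_sd^2)`` (e.g. a fossil-only molecular
    scheme) and ``estimate_b = true + bias + N(0, noise_sd^2)`` (e.g. a
    scheme with extra biogeographic calibrations that pushes ages older by
    ``bias`` My on average).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    true = rng.uniform(20.0, 70.0, size=n)
    return pd.DataFrame(
        {
            "true_age": true,
            "estimate_a": true + rng.normal(0, noise_sd, size=n),
            "estimate_b": true + bias + rng.normal(0, noise_sd, size=n),
        }
    )


def _draw_codons(rng, n, composition):
    """i.i.d. codons from per-base composition, rejecting stop codons."""
    composition = np.asarray(composition, dtype=float)
    if composition.shape != (4,) or not np.isclose(composition.sum(), 1.0):
        raise ValueError("composition must be 4 frequencies (A,C,G,T) summing to 1")
    bases = np.array(list("ACGT"))
    stops = set(_VERTMITO.stop_codons)
    out = []
    while len(out) < n:
        draw = bases[rng.choice(4, size=3, p=composition)]
        codon = "".join(draw)
        if codon in stops:
            continue
        out.append(codon)
    return out


def simulate_codon_alignment(
    n_taxa: int,
    n_codons: int,
    composition=(0.25, 0.25, 0.25, 0.25),
    seed: int = 0,
    n_genes: int = 2,
    gene_prefix: str = "G",
) -> list[GeneAlignment]:
    """Annotated protein-coding alignment(s) of i.i.d. codons.

    Codons are drawn independently per taxon and site from the per-base
    composition (A, C, G, T); vertebrate-mitochondrial stop codons are
    rejected everywhere, so no internal stops occur.  The ``n_codons``
    columns are split across ``n_genes`` gene alignments with frame 0.
    """
    if n_taxa < 1 or n_codons < 1:
        raise ValueError("need at least one taxon and one codon")
    rng = np.random.default_rng(seed)
    taxa = [f"taxon{i + 1}" for i in range(n_taxa)]
    per_gene = [n_codons // n_genes] * n_genes
    per_gene[-1] += n_codons - sum(per_gene)
    genes = []
    for gi, ncod in enumerate(per_gene):
        seqs = {
            taxon: "".join(_draw_codons(rng, ncod, composition)) for taxon in taxa
        }
        genes.append(
            GeneAlignment(gene=f"{gene_prefix}{gi + 1}", cls="protein", sequences=seqs)
        )
    return genes


def simulate_rna_alignment(
    n_taxa: int,
    n_sites: int,
    cls: str = "rRNA",
    gene: str | None = None,
    composition=(0.25, 0.25, 0.25, 0.25),
    seed: int = 0,
) -> GeneAlignment:
    """i.i.d. RNA-gene alignment (rRNA or tRNA) for supermatrix fixtures."""
    rng = np.random.default_rng(seed)
    composition = np.asarray(composition, dtype=float)
    bases = np.array(list("ACGT"))
    taxa = [f"taxon{i + 1}" for i in range(n_taxa)]
    seqs = {
        taxon: "".join(bases[rng.choice(4, size=n_sites, p=composition)])
        for taxon in taxa
    }
    return GeneAlignment(gene=gene or ("rrnS" if cls == "rRNA" else "trnV"), cls=cls, sequences=seqs)


# ---------------------------------------------------------------------------
# fixture writers (same formats the pipeline reads)


def write_occurrences_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def write_depths_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def write_chronogram(tree: dendropy.Tree, path) -> None:
    tree.write(path=str(path), schema="newick", suppress_rooting=True)
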