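"""Mitogenomic supermatrix construction and coding.

Builds the four standard data-set variants from per-gene alignments of a
vertebrate mitogenome (12 protein-coding genes after excluding ND6 for its
heterogeneous base composition, plus rRNA and tRNA genes):

- ``12n3rRTn``: codon positions 1+2 as nucleotides, third positions
  RY-coded (purines A/G -> A, pyrimidines C/T -> C), rRNA, tRNA; 5 partitions.
- ``123nRTn``: all codon positions untransformed; 5 partitions
  (pos1/pos2/pos3/rRNA/tRNA).
- ``12nRTn``: third positions excluded entirely; 4 partitions.
- ``123aRTn``: protein genes translated to amino acids under the vertebrate
  mitochondrial code; 3 partitions (aa/rRNA/tRNA).

Output columns are grouped into contiguous partition blocks (all first
positions, then second, then third, then rRNA, then tRNA); a per-column
provenance map records the source gene and codon phase of every emitted
column.  Internal column coordinates are 0-based half-open; emitted
partition files are 1-based inclusive, the convention of partitioned-ML
input files.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from Bio import SeqIO
from Bio.Data import CodonTable

logger = logging.getLogger(__name__)

__all__ = [
    "GeneAlignment",
    "SupermatrixVariant",
    "VARIANTS",
    "dedup_longest",
    "concatenate",
    "ry_code_third_positions",
    "translate_vertmito",
    "build_variant",
    "read_gene_alignments",
    "write_gene_alignments",
    "write_fasta",
    "write_phylip",
    "write_partitions",
    "read_partitions",
]

VARIANTS = ("12n3rRTn", "123nRTn", "12nRTn", "123aRTn")

_PURINES = {"A", "G", "R"}
_PYRIMIDINES = {"C", "T", "Y"}
_GAPS = {"-", "?"}
_VERTMITO = CodonTable.unambiguous_dna_by_id[2]


@dataclass
class GeneAlignment:
    """One gene's aligned sequences (taxon -> aligned, upper-case bases)."""

    gene: str
    cls: str  # "protein" | "rRNA" | "tRNA"
    sequences: dict[str, str]
    frame: int = 0  # reading-frame offset for protein genes

    def __post_init__(self):
        if self.cls not in ("protein", "rRNA", "tRNA"):
            raise ValueError(f"{self.gene}: unknown gene class {self.cls!r}")
        lengths = {len(s) for s in self.sequences.values()}
        if len(lengths) > 1:
            raise ValueError(f"{self.gene}: unequal aligned lengths {sorted(lengths)}")
        if self.cls == "protein" and self.sequences:
            if (self.width - self.frame) % 3 != 0:
                raise ValueError(
                    f"{self.gene}: length {self.width} minus frame {self.frame} "
                    "not divisible by 3"
                )
        self.sequences = {t: s.upper() for t, s in self.sequences.items()}

    @property
    def width(self) -> int:
        return len(next(iter(self.sequences.values()))) if self.sequences else 0


@dataclass
class Scaffold:
    """Concatenated matrix plus per-column provenance, pre-coding.

    ``col_gene``/``col_phase`` give, for each column, the source gene and
    codon phase (1/2/3 for protein columns, 0 for RNA columns).
    """

    matrix: dict[str, str]
    col_gene: list[str]
    col_cls: list[str]
    col_phase: list[int]
    log: list[str] = field(default_factory=list)

    @property
    def width(self) -> int:
        return len(self.col_gene)


@dataclass
class SupermatrixVariant:
    variant: str
    matrix: dict[str, str]
    partitions: list[tuple[str, int, int]]  # (name, start, end), 1-based inclusive
    col_map: list[tuple[str, int]]  # per emitted column: (source gene, phase; 0=RNA, -1=aa)
    provenance: list[str] = field(default_factory=list)

    @property
    def width(self) -> int:
        return len(self.col_map)


def dedup_longest(
    sequences: list[tuple[str, str, str]],
) -> list[tuple[str, str, str]]:
    """Keep, per (species, gene), only the longest sequence.

    Length is counted over non-gap characters; ties keep the first
    occurrence and log a warning.  Distinct species never collapse.
    """
    best: dict[tuple[str, str], tuple[str, str, str]] = {}
    order: list[tuple[str, str]] = []
    for species, gene, seq in sequences:
        key = (species, gene)
        length = sum(1 for ch in seq if ch not in "-?")
        if key not in best:
            best[key] = (species, gene, seq)
            order.append(key)
        else:
            kept_len = sum(1 for ch in best[key][2] if ch not in "-?")
            if length > kept_len:
                best[key] = (species, gene, seq)
            elif length == kept_len:
                logger.warning("tie for longest %s/%s: keeping first occurrence", species, gene)
    return [best[key] for key in order]


def concatenate(
    genes: list[GeneAlignment],
    exclude: set[str] = frozenset({"ND6"}),
) -> Scaffold:
    """Concatenate gene alignments: protein genes first, then rRNA, then tRNA.

    Genes named in ``exclude`` (default: ND6, whose base composition is
    heterogeneous) are dropped.  Taxa missing from a gene get a gap block of
    that gene's width, with a log entry.
    """
    kept = [g for g in genes if g.gene not in exclude]
    dropped = [g.gene for g in genes if g.gene in exclude]
    if not kept:
        raise ValueError("no genes left after exclusion")
    ordered = (
        [g for g in kept if g.cls == "protein"]
        + [g for g in kept if g.cls == "rRNA"]
        + [g for g in kept if g.cls == "tRNA"]
    )
    taxa = sorted({t for g in ordered for t in g.sequences})
    log = [f"excluded gene {name}" for name in dropped]
    parts: dict[str, list[str]] = {t: [] for t in taxa}
    col_gene: list[str] = []
    col_cls: list[str] = []
    col_phase: list[int] = []
    for g in ordered:
        for t in taxa:
            if t in g.sequences:
                parts[t].append(g.sequences[t])
            else:
                parts[t].append("-" * g.width)
                log.append(f"taxon {t} missing from {g.gene}: gap-filled")
        col_gene += [g.gene] * g.width
        col_cls += [g.cls] * g.width
        if g.cls == "protein":
            col_phase += [((i - g.frame) % 3) + 1 for i in range(g.width)]
        else:
            col_phase += [0] * g.width
    for entry in log:
        logger.info(entry)
    return Scaffold(
        matrix={t: "".join(parts[t]) for t in taxa},
        col_gene=col_gene,
        col_cls=col_cls,
        col_phase=col_phase,
        log=log,
    )


def ry_code_symbol(ch: str) -> str:
    """RY-code one third-position symbol.

    Purine symbols (A, G, R) -> A; pyrimidine symbols (C, T, Y) -> C; gaps
    and '?' preserved; IUPAC symbols mixing the two classes (and N) -> N.
    Idempotent by construction (A and C map to themselves, N to N).
    """
    up = ch.upper()
    if up in _PURINES:
        return "A"
    if up in _PYRIMIDINES:
        return "C"
    if ch in _GAPS:
        return ch
    return "N"


def ry_code_third_positions(scaffold: Scaffold) -> Scaffold:
    """RY-code every third codon position; other columns untouched."""
    if not scaffold.col_phase:
        raise ValueError("scaffold has no codon-phase map")
    third = [i for i, ph in enumerate(scaffold.col_phase) if ph == 3]
    third_set = set(third)
    matrix = {
        t: "".join(
            ry_code_symbol(ch) if i in third_set else ch for i, ch in enumerate(seq)
        )
        for t, seq in scaffold.matrix.items()
    }
    return Scaffold(
        matrix=matrix,
        col_gene=list(scaffold.col_gene),
        col_cls=list(scaffold.col_cls),
        col_phase=list(scaffold.col_phase),
        log=scaffold.log + [f"RY-coded {len(third)} third positions"],
    )


def translate_codon(codon: str) -> str:
    """Vertebrate-mitochondrial translation of one codon.

    All-gap codons become '-' (missing state); codons containing gaps or
    unresolvable ambiguity become 'X'; stop codons become '*' (callers warn
    on internal stops).
    """
    codon = codon.upper()
    if codon == "---":
        return "-"
    if any(ch in _GAPS for ch in codon) or any(ch not in "ACGT" for ch in codon):
        return "X"
    if codon in _VERTMITO.stop_codons:
        return "*"
    return _VERTMITO.forward_table[codon]


def translate_vertmito(scaffold: Scaffold) -> Scaffold:
    """Translate the protein partitions to amino acids; RNA columns appended
    unchanged.  Warns with position on internal stop codons."""
    prot_cols = [i for i, cls in enumerate(scaffold.col_cls) if cls == "protein"]
    rna_cols = [i for i, cls in enumerate(scaffold.col_cls) if cls != "protein"]
    if len(prot_cols) % 3 != 0:
        raise ValueError("protein partitions not in frame")
    aa_gene = [scaffold.col_gene[i] for i in prot_cols[::3]]
    matrix = {}
    for taxon, seq in scaffold.matrix.items():
        aas = []
        for k in range(0, len(prot_cols), 3):
            codon = "".join(seq[prot_cols[k + j]] for j in range(3))
            aa = translate_codon(codon)
            if aa == "*" and k < len(prot_cols) - 3:
                logger.warning(
                    "internal stop codon %s at aa position %d (%s) in %s",
                    codon, k // 3 + 1, aa_gene[k // 3], taxon,
                )
            aas.append(aa)
        matrix[taxon] = "".join(aas) + "".join(seq[i] for i in rna_cols)
    return Scaffold(
        matrix=matrix,
        col_gene=aa_gene + [scaffold.col_gene[i] for i in rna_cols],
        col_cls=["protein_aa"] * len(aa_gene) + [scaffold.col_cls[i] for i in rna_cols],
        col_phase=[-1] * len(aa_gene) + [scaffold.col_phase[i] for i in rna_cols],
        log=scaffold.log + ["translated protein partitions (vertebrate mito code)"],
    )


def _select(scaffold: Scaffold, cols: list[int]) -> dict[str, str]:
    return {t: "".join(seq[i] for i in cols) for t, seq in scaffold.matrix.items()}


def build_variant(
    genes: list[GeneAlignment],
    variant: str,
    exclude: set[str] = frozenset({"ND6"}),
) -> SupermatrixVariant:
    """Build one of the four coded data-set variants.

    Columns are regrouped into contiguous partition blocks; the per-column
    ``col_map`` retains each column's source gene and phase.
    """
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; expected one of {VARIANTS}")
    scaffold = concatenate(genes, exclude=exclude)

    def cols_of(phase=None, cls=None):
        return [
            i
            for i in range(scaffold.width)
            if (phase is None or scaffold.col_phase[i] == phase)
            and (cls is None or scaffold.col_cls[i] == cls)
        ]

    rrna = cols_of(cls="rRNA")
    trna = cols_of(cls="tRNA")
    if variant == "123aRTn":
        coded = translate_vertmito(scaffold)
        aa = [i for i, c in enumerate(coded.col_cls) if c == "protein_aa"]
        rrna2 = [i for i, c in enumerate(coded.col_cls) if c == "rRNA"]
        trna2 = [i for i, c in enumerate(coded.col_cls) if c == "tRNA"]
        blocks = [("aa", aa, coded), ("rRNA", rrna2, coded), ("tRNA", trna2, coded)]
    else:
        source = ry_code_third_positions(scaffold) if variant == "12n3rRTn" else scaffold
        pos = {ph: cols_of(phase=ph) for ph in (1, 2, 3)}
        if variant == "12nRTn":
            blocks = [
                ("pos1", pos[1], source),
                ("pos2", pos[2], source),
                ("rRNA", rrna, source),
                ("tRNA", trna, source),
            ]
        else:  # 12n3rRTn / 123nRTn
            name3 = "pos3_RY" if variant == "12n3rRTn" else "pos3"
            blocks = [
                ("pos1", pos[1], source),
                ("pos2", pos[2], source),
                (name3, pos[3], source),
                ("rRNA", rrna, source),
                ("tRNA", trna, source),
            ]
    blocks = [(name, cols, src) for name, cols, src in blocks if cols]
    taxa = sorted(scaffold.matrix)
    out = {t: [] for t in taxa}
    partitions = []
    col_map: list[tuple[str, int]] = []
    start = 1
    for name, cols, src in blocks:
        sub = _select(src, cols)
        for t in taxa:
            out[t].append(sub[t])
        partitions.append((name, start, start + len(cols) - 1))
        col_map += [(src.col_gene[i], src.col_phase[i]) for i in cols]
        start += len(cols)
    return SupermatrixVariant(
        variant=variant,
        matrix={t: "".join(out[t]) for t in taxa},
        partitions=partitions,
        col_map=col_map,
        provenance=scaffold.log + [f"variant {variant}: partitions "
                                   + ", ".join(p[0] for p in partitions)],
    )


# ---------------------------------------------------------------------------
# I/O


def read_gene_alignments(fasta_paths: dict[str, str], annotations_path) -> list[GeneAlignment]:
    """Read per-gene FASTA files with a sidecar annotation TSV.

    ``fasta_paths`` maps gene name to FASTA path; the sidecar has columns
    gene, class, frame.
    """
    import pandas as pd

    ann = pd.read_csv(annotations_path, sep="\t").set_index("gene")
    genes = []
    for gene, path in fasta_paths.items():
        if gene not in ann.index:
            raise ValueError(f"gene {gene!r} missing from annotation sidecar")
        seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}
        genes.append(
            GeneAlignment(
                gene=gene,
                cls=str(ann.loc[gene, "class"]),
                sequences=seqs,
                frame=int(ann.loc[gene, "frame"]),
            )
        )
    return genes


def write_gene_alignments(genes: list[GeneAlignment], outdir) -> dict[str, str]:
    """Write one FASTA per gene plus annotations.tsv; returns gene->path."""
    import os

    import pandas as pd

    os.makedirs(outdir, exist_ok=True)
    paths = {}
    for g in genes:
        path = os.path.join(outdir, f"{g.gene}.fasta")
        with open(path, "w") as fh:
            for taxon in sorted(g.sequences):
                fh.write(f">{taxon}\n{g.sequences[taxon]}\n")
        paths[g.gene] = path
    pd.DataFrame(
        [{"gene": g.gene, "class": g.cls, "frame": g.frame} for g in genes]
    ).to_csv(os.path.join(outdir, "annotations.tsv"), sep="\t", index=False)
    return paths


def write_fasta(variant: SupermatrixVariant, path) -> None:
    with open(path, "w") as fh:
        for taxon in sorted(variant.matrix):
            fh.write(f">{taxon}\n{variant.matrix[taxon]}\n")


def write_phylip(variant: SupermatrixVariant, path) -> None:
    """Relaxed PHYLIP: full names, two-space separator."""
    taxa = sorted(variant.matrix)
    with open(path, "w") as fh:
        fh.write(f"{len(taxa)} {variant.width}\n")
        for taxon in taxa:
            fh.write(f"{taxon}  {variant.matrix[taxon]}\n")


def write_partitions(variant: SupermatrixVariant, path) -> None:
    """Partition scheme in the ``DNA, name = start-end`` dialect (1-based
    inclusive); the amino-acid block uses the MTREV model tag."""
    with open(path, "w") as fh:
        for name, start, end in variant.partitions:
            dtype = "MTREV" if name == "aa" else "DNA"
            fh.write(f"{dtype}, {name} = {start}-{end}\n")


def read_partitions(path) -> list[tuple[str, int, int]]:
    parts = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            _, rest = line.split(",", 1)
            name, span = rest.split("=")
            start, end = span.strip().split("-")
            parts.append((name.strip(), int(start), int(end)))
    return parts
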