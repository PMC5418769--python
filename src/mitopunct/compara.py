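"""Cross-taxon comparison: alignments, supermatrix, identity, indels.

Orthologous genes are pulled from annotated mitogenomes in coding
orientation, aligned codon-aware (protein-guided, nucleotides back-mapped
so every gap is a whole codon), concatenated into a partitioned
supermatrix, and summarised as a pairwise nucleotide identity (PNI)
matrix, per-gene amino-acid conservation and shared indel events.

The default alignment engine is deterministic: pairwise global
Needleman-Wunsch (BLOSUM62, gap open -10, extend -1) merged progressively
around the first input sequence (center-star, "once a gap always a gap").
Tree inference is exported (relaxed PHYLIP + partition file), never
computed here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from mitopunct import genetic_code
from mitopunct.crscan import GapEvent, gap_events
from mitopunct.synthetic import Feature

logger = logging.getLogger(__name__)


class InternalStopError(ValueError):
    def __init__(self, taxon: str, gene: str, codon_index: int):
        self.taxon = taxon
        super().__init__(f"{gene}: internal stop codon in frame for {taxon} "
                         f"at codon {codon_index}")


@dataclass
class AnnotatedGenome:
    taxon: str
    sequence: str
    features: Sequence


# ---------------------------------------------------------------------------
# ortholog extraction
# ---------------------------------------------------------------------------

def extract_orthologs(
    genomes: Sequence[AnnotatedGenome],
    gene_name: str,
) -> list[tuple[str, str, str]]:
    """(taxon, sequence, completeness) per genome carrying the gene.

    Light-strand genes are reverse-complemented into coding orientation.
    Genomes lacking the gene are omitted with a warning; a gene absent
    from every genome is an error.
    """
    out: list[tuple[str, str, str]] = []
    for g in genomes:
        feat = next((f for f in g.features if f.name == gene_name), None)
        if feat is None:
            logger.warning("%s: no %s annotation, taxon omitted",
                           g.taxon, gene_name)
            continue
        seq = g.sequence[feat.start:feat.end].upper()
        if feat.strand == "-":
            seq = genetic_code.reverse_complement(seq)
        completeness = getattr(feat, "completeness", None)
        if completeness is None:
            completeness = ("not_sequenced" if set(seq) <= {"N"}
                            else "partial" if "N" in seq else "complete")
        out.append((g.taxon, seq, completeness))
    if not out:
        raise ValueError(f"{gene_name} is not annotated in any genome")
    return out


# ---------------------------------------------------------------------------
# pairwise + progressive alignment
# ---------------------------------------------------------------------------

def _protein_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -1.0
    aligner.mode = "global"
    return aligner


def _nucleotide_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.match_score = 5.0
    aligner.mismatch_score = -4.0
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -1.0
    aligner.mode = "global"
    return aligner


def _pairwise(aligner: Align.PairwiseAligner, a: str, b: str) -> tuple[str, str]:
    aln = aligner.align(a, b)[0]  # first optimal alignment: deterministic
    return str(aln[0]), str(aln[1])


def center_star_msa(
    sequences: Sequence[str],
    aligner: Align.PairwiseAligner,
) -> list[str]:
    """Progressive multiple alignment around the first sequence.

    Every sequence is aligned pairwise to the first; gaps opened in the
    center are merged across pairs (insertions at the same center slot are
    left-aligned).  Guide order is the input order, making the result
    deterministic.
    """
    if not sequences:
        return []
    center = sequences[0]
    if len(sequences) == 1:
        return [center]
    n0 = len(center)
    # per sequence: insertions before each center position (slot n0 = tail)
    slot_ins: list[list[str]] = []
    aligned_to_center: list[list[str]] = []  # char aligned to center residue k
    for s in sequences[1:]:
        ac, aq = _pairwise(aligner, center, s)
        ins: list[str] = ["" for _ in range(n0 + 1)]
        at: list[str] = []
        k = 0
        for cc, qc in zip(ac, aq):
            if cc == "-":
                ins[k] += qc
            else:
                at.append(qc)
                k += 1
        slot_ins.append(ins)
        aligned_to_center.append(at)
    slot_width = [max(len(ins[k]) for ins in slot_ins)
                  for k in range(n0 + 1)]

    rows: list[str] = []
    center_row = "".join("-" * slot_width[k] + center[k] for k in range(n0))
    center_row += "-" * slot_width[n0]
    rows.append(center_row)
    for ins, at in zip(slot_ins, aligned_to_center):
        parts = []
        for k in range(n0):
            parts.append(ins[k].ljust(slot_width[k], "-"))
            parts.append(at[k])
        parts.append(ins[n0].ljust(slot_width[n0], "-"))
        rows.append("".join(parts))
    return rows


# ---------------------------------------------------------------------------
# gene alignment
# ---------------------------------------------------------------------------

@dataclass
class GeneAlignment:
    gene: str
    mode: str  # "codon-aware" | "nucleotide"
    rows: list[tuple[str, str]]  # (taxon, aligned nucleotides)
    protein_rows: list[tuple[str, str]] = field(default_factory=list)

    @property
    def width(self) -> int:
        return len(self.rows[0][1]) if self.rows else 0


def align_gene(
    sequences: Sequence[tuple[str, str]],
    mode: str = "codon-aware",
    gene: str = "gene",
) -> GeneAlignment:
    """Align ortholog nucleotide sequences.

    ``codon-aware``: translate under the vertebrate mitochondrial code
    (incomplete-stop remainders set aside), align the proteins, back-map
    gaps onto whole codons, and re-append the remainders (padded with
    gaps to a common width).  ``nucleotide``: direct nucleotide alignment,
    for rRNAs.  An internal in-frame stop is an error naming the taxon.
    """
    taxa = [t for t, _ in sequences]
    if len(set(taxa)) != len(taxa):
        raise ValueError(f"{gene}: duplicate taxon in input")
    if mode == "nucleotide":
        msa = center_star_msa([s for _, s in sequences], _nucleotide_aligner())
        return GeneAlignment(gene, mode, list(zip(taxa, msa)))
    if mode != "codon-aware":
        raise ValueError(f"unknown alignment mode {mode!r}")

    codon_parts: list[str] = []
    tails: list[str] = []
    proteins: list[str] = []
    for taxon, nt in sequences:
        nt = nt.upper()
        rem = len(nt) % 3
        codon_nt = nt[:len(nt) - rem] if rem else nt
        tails.append(nt[len(nt) - rem:] if rem else "")
        prot = genetic_code.translate(codon_nt)
        internal = prot[:-1].find("*")
        if internal != -1:
            raise InternalStopError(taxon, gene, internal)
        codon_parts.append(codon_nt)
        proteins.append(prot)

    prot_msa = center_star_msa(proteins, _protein_aligner())
    max_tail = max(len(t) for t in tails)
    rows: list[tuple[str, str]] = []
    for taxon, codon_nt, tail, prot_row in zip(taxa, codon_parts, tails,
                                               prot_msa):
        codons = iter(codon_nt[i:i + 3] for i in range(0, len(codon_nt), 3))
        nt_row = "".join("---" if c == "-" else next(codons)
                         for c in prot_row)
        nt_row += tail.ljust(max_tail, "-")
        rows.append((taxon, nt_row))
    return GeneAlignment(gene, mode, rows,
                         protein_rows=list(zip(taxa, prot_msa)))


# ---------------------------------------------------------------------------
# supermatrix
# ---------------------------------------------------------------------------

@dataclass
class Supermatrix:
    taxa: list[str]
    rows: list[str]  # same order as taxa; '-' gaps, 'N' missing blocks
    partitions: dict[str, tuple[int, int]]  # gene -> column interval

    def __post_init__(self) -> None:
        widths = {len(r) for r in self.rows}
        if len(widths) > 1:
            raise ValueError("supermatrix rows differ in length")
        total = sum(e - s for s, e in self.partitions.values())
        if self.rows and total != len(self.rows[0]):
            raise ValueError("partitions do not tile the supermatrix columns")

    @property
    def width(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def slice_gene(self, gene: str) -> list[tuple[str, str]]:
        s, e = self.partitions[gene]
        return [(t, r[s:e]) for t, r in zip(self.taxa, self.rows)]


def concatenate(
    per_gene_alignments: Sequence[GeneAlignment],
    taxon_order: Sequence[str] | None = None,
) -> Supermatrix:
    """Concatenate per-gene alignments into a partitioned supermatrix.

    Taxa missing from a gene get an all-N block of that gene's width.
    """
    if not per_gene_alignments:
        raise ValueError("no alignments to concatenate")
    if taxon_order is None:
        seen: list[str] = []
        for aln in per_gene_alignments:
            for t, _ in aln.rows:
                if t not in seen:
                    seen.append(t)
        taxon_order = seen
    parts: dict[str, list[str]] = {t: [] for t in taxon_order}
    partitions: dict[str, tuple[int, int]] = {}
    col = 0
    for aln in per_gene_alignments:
        taxa_here = [t for t, _ in aln.rows]
        if len(set(taxa_here)) != len(taxa_here):
            raise ValueError(f"{aln.gene}: duplicate taxon")
        width = aln.width
        by_taxon = dict(aln.rows)
        for t in taxon_order:
            parts[t].append(by_taxon.get(t, "N" * width))
        partitions[aln.gene] = (col, col + width)
        col += width
    return Supermatrix(
        taxa=list(taxon_order),
        rows=["".join(parts[t]) for t in taxon_order],
        partitions=partitions)


# ---------------------------------------------------------------------------
# pairwise nucleotide identity
# ---------------------------------------------------------------------------

@dataclass
class PNIMatrix:
    taxa: list[str]
    values: np.ndarray  # percent, rounded to 0.1; nan where undefined
    counts: np.ndarray  # compared positions per cell
    undefined: list[tuple[str, str]] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.taxa, columns=self.taxa)

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i, j = self.taxa.index(pair[0]), self.taxa.index(pair[1])
        return float(self.values[i, j])


def pairwise_nucleotide_identity(
    supermatrix: Supermatrix | Sequence[tuple[str, str]],
) -> PNIMatrix:
    """Percent identity per taxon pair with pairwise deletion.

    Only columns where both rows carry an unambiguous base (A/C/G/T) are
    compared; gaps and N are excluded pairwise.  Values are rounded to
    0.1; the diagonal is 100 and pairs with no comparable column are
    flagged undefined (nan).
    """
    if isinstance(supermatrix, Supermatrix):
        taxa, rows = supermatrix.taxa, supermatrix.rows
    else:
        taxa = [t for t, _ in supermatrix]
        rows = [r for _, r in supermatrix]
    if len(taxa) < 2:
        raise ValueError("need at least 2 taxa")
    arr = np.array([list(r.upper()) for r in rows])
    mask = np.isin(arr, list("ACGT"))
    n = len(taxa)
    values = np.full((n, n), np.nan)
    counts = np.zeros((n, n), dtype=np.int64)
    undefined: list[tuple[str, str]] = []
    np.fill_diagonal(values, 100.0)
    for i in range(n):
        counts[i, i] = int(mask[i].sum())
        for j in range(i + 1, n):
            comp = mask[i] & mask[j]
            m = int(comp.sum())
            counts[i, j] = counts[j, i] = m
            if m == 0:
                undefined.append((taxa[i], taxa[j]))
                continue
            matches = int((arr[i][comp] == arr[j][comp]).sum())
            values[i, j] = values[j, i] = round(100.0 * matches / m, 1)
    return PNIMatrix(list(taxa), values, counts, undefined)


# ---------------------------------------------------------------------------
# conservation and indels
# ---------------------------------------------------------------------------

def invariable_amino_acid_percent(
    protein_alignment: Sequence[tuple[str, str]],
) -> int:
    """Percent columns whose non-gap residues are all identical.

    Columns with fewer than half the taxa present do not count as
    invariable.  Rounded to integer percent.
    """
    rows = [r for _, r in protein_alignment]
    if not rows or not rows[0]:
        raise ValueError("empty alignment")
    ncol = len(rows[0])
    ntaxa = len(rows)
    invariable = 0
    for j in range(ncol):
        residues = [r[j] for r in rows if r[j] != "-"]
        if 2 * len(residues) >= ntaxa and residues \
                and all(x == residues[0] for x in residues):
            invariable += 1
    return round(100.0 * invariable / ncol)


@dataclass(frozen=True)
class IndelEvent:
    gene: str
    columns: tuple[int, int]
    length: int
    taxa: tuple[str, ...]
    kind: str  # insertion | deletion


def detect_alignment_indels(
    alignment: GeneAlignment | Sequence[tuple[str, str]],
    gene: str | None = None,
) -> list[IndelEvent]:
    """Maximal gap-column runs private to a taxon subset, as indel events."""
    if isinstance(alignment, GeneAlignment):
        rows = alignment.rows
        gene = gene or alignment.gene
    else:
        rows = list(alignment)
        gene = gene or "alignment"
    return [IndelEvent(gene, ev.columns, ev.length, ev.taxa, ev.kind)
            for ev in gap_events(rows)]


def junction_insertion_events(
    deviations,
    gene: str = "intergenic",
) -> list[IndelEvent]:
    """Re-express gene-order junction deviations as insertion events."""
    events = []
    for d in deviations:
        if d.kind != "junction":
            continue
        k = int(d.detail.split(", ")[-1].split("-nt")[0])
        events.append(IndelEvent(gene, (0, 0), k, tuple(d.names), "insertion"))
    return events


# ---------------------------------------------------------------------------
# exports
# ---------------------------------------------------------------------------

def write_supermatrix_fasta(sm: Supermatrix, path: str | Path) -> None:
    lines = []
    for t, r in zip(sm.taxa, sm.rows):
        lines.append(f">{t}")
        lines.append(r)
    Path(path).write_text("\n".join(lines) + "\n")


def write_supermatrix_phylip(sm: Supermatrix, path: str | Path) -> None:
    """Relaxed PHYLIP: full taxon names, two-space separator."""
    lines = [f"{len(sm.taxa)} {sm.width}"]
    pad = max(len(t) for t in sm.taxa) + 2
    for t, r in zip(sm.taxa, sm.rows):
        lines.append(t.ljust(pad) + r)
    Path(path).write_text("\n".join(lines) + "\n")


def write_partition_file(sm: Supermatrix, path: str | Path) -> None:
    """RAxML-style partition file, 1-based inclusive column ranges."""
    lines = [f"DNA, {gene} = {s + 1}-{e}"
             for gene, (s, e) in sm.partitions.items()]
    Path(path).write_text("\n".join(lines) + "\n")


def write_pni_tsv(pni: PNIMatrix, path: str | Path) -> None:
    pni.to_frame().to_csv(path, sep="\t", float_format="%.1f")
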