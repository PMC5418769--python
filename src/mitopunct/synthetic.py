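"""Synthetic mitogenome cohorts with known ground truth.

Everything downstream (scaffolding, annotation transfer, depth profiling,
heteroplasmy calling, control-region scanning, supermatrix construction)
is exercised against data built here, so each simulator returns an explicit
truth object: feature coordinates, transcript-unit boundaries, planted
heteroplasmic sites and control-region deletions.

The toy genome is a linear sequence in the canonical vertebrate gene order
(linearized at the tRNA-Phe start, control region last, matching how
mitogenomes are deposited): 13 protein-coding genes, 2 rRNAs, 22 tRNAs,
the light-strand replication origin and the control region.  Protein-coding
genes are built from in-frame sense codons of the vertebrate mitochondrial
code, so they translate without internal stops; genes whose length is not
a codon multiple end in the incomplete stops T-- or TA- that are completed
by polyadenylation in vivo.  Transcript contigs follow the punctuation
model: the polycistronic transcript is cleaved at tRNAs, leaving one
contig per mRNA/rRNA unit, with nad4l/nad4 and atp8/atp6 as bicistronic
units.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from mitopunct import genetic_code
from mitopunct.depthmap import BaseCountProfile
from mitopunct.motifs import IUPAC, MotifDef, default_motif_library


class SyntheticSpecError(ValueError):
    """Invalid toy-genome specification; message names the offending field."""


# ---------------------------------------------------------------------------
# canonical vertebrate mitogenome layout
# ---------------------------------------------------------------------------

#: (feature name, strand) in canonical vertebrate order, heavy strand = '+'.
#: nad6 and eight tRNAs (Q, A, N, C, Y, S2, E, P) lie on the light strand.
CANONICAL_GENE_ORDER: tuple[tuple[str, str], ...] = (
    ("trnF", "+"), ("rrnS", "+"), ("trnV", "+"), ("rrnL", "+"),
    ("trnL2", "+"), ("nad1", "+"), ("trnI", "+"), ("trnQ", "-"),
    ("trnM", "+"), ("nad2", "+"), ("trnW", "+"), ("trnA", "-"),
    ("trnN", "-"), ("OL", "+"), ("trnC", "-"), ("trnY", "-"),
    ("cox1", "+"), ("trnS2", "-"), ("trnD", "+"), ("cox2", "+"),
    ("trnK", "+"), ("atp8", "+"), ("atp6", "+"), ("cox3", "+"),
    ("trnG", "+"), ("nad3", "+"), ("trnR", "+"), ("nad4l", "+"),
    ("nad4", "+"), ("trnH", "+"), ("trnS1", "+"), ("trnL1", "+"),
    ("nad5", "+"), ("nad6", "-"), ("trnE", "-"), ("cob", "+"),
    ("trnT", "+"), ("trnP", "-"), ("CR", "+"),
)

PCGS = frozenset({"nad1", "nad2", "nad3", "nad4", "nad4l", "nad5", "nad6",
                  "cox1", "cox2", "cox3", "atp6", "atp8", "cob"})
RRNAS = frozenset({"rrnS", "rrnL"})
TRNAS = frozenset({
    "trnF", "trnV", "trnL2", "trnI", "trnQ", "trnM", "trnW", "trnA", "trnN",
    "trnC", "trnY", "trnS2", "trnD", "trnK", "trnG", "trnR", "trnH", "trnS1",
    "trnL1", "trnE", "trnT", "trnP",
})

#: bicistronic mRNAs of the punctuation model
BICISTRONIC_PAIRS = (("nad4l", "nad4"), ("atp8", "atp6"))


def feature_kind(name: str) -> str:
    if name in PCGS:
        return "PCG"
    if name in RRNAS:
        return "rRNA"
    if name in TRNAS:
        return "tRNA"
    if name == "CR":
        return "CR"
    if name == "OL":
        return "origin"
    raise SyntheticSpecError(f"gene_order: unknown feature name {name!r}")


# gene lengths (nt).  PCG lengths reproduce values typical of loricariid
# catfish deposits: cox1 1551, cob 1138, nad6 522, atp8 168.  A remainder of
# 1 or 2 over full codons yields the incomplete stops T-- / TA-.
DEFAULT_GENE_LENGTHS: dict[str, int] = {
    "rrnS": 951, "rrnL": 1677, "OL": 32,
    "nad1": 975, "nad2": 1045, "nad3": 349, "nad4": 1381, "nad4l": 297,
    "nad5": 1839, "nad6": 522, "cox1": 1551, "cox2": 691, "cox3": 784,
    "atp6": 683, "atp8": 168, "cob": 1138,
    "trnF": 69, "trnV": 72, "trnL2": 74, "trnI": 71, "trnQ": 71, "trnM": 69,
    "trnW": 71, "trnA": 69, "trnN": 73, "trnC": 67, "trnY": 70, "trnS2": 72,
    "trnD": 71, "trnK": 74, "trnG": 69, "trnR": 68, "trnH": 69, "trnS1": 68,
    "trnL1": 73, "trnE": 69, "trnT": 72, "trnP": 70,
}

_START_OVERRIDES = {"cox1": "GTG"}


@dataclass(frozen=True)
class CRSpec:
    """Layout of the synthetic control region.

    Motifs are placed in canonical order with random spacers; the
    T-homopolymer sits between CSB-D and the AT-rich opening of Domain III.
    """

    motif_order: tuple[str, ...] = ("TAS", "CSB-F", "CSB-E", "CSB-D",
                                    "CSB-1", "CSB-2", "CSB-3")
    spacer_length: int = 25
    t_homopolymer_length: int = 12
    at_rich_length: int = 60
    leading_length: int = 30
    trailing_length: int = 40


@dataclass(frozen=True)
class ToyGenomeSpec:
    gene_order: tuple[tuple[str, str], ...] = CANONICAL_GENE_ORDER
    gene_lengths: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_GENE_LENGTHS))
    cr_spec: CRSpec = field(default_factory=CRSpec)
    seed: int = 0

    def validate(self) -> None:
        names = [n for n, _ in self.gene_order]
        if len(names) != len(set(names)):
            dup = sorted({n for n in names if names.count(n) > 1})
            raise SyntheticSpecError(f"gene_order: duplicated features {dup}")
        present = set(names)
        for group, expect in ((PCGS, 13), (RRNAS, 2), (TRNAS, 22)):
            missing = group - present
            if missing:
                raise SyntheticSpecError(
                    f"gene_order: missing features {sorted(missing)}")
        if "CR" not in present:
            raise SyntheticSpecError("gene_order: missing CR")
        for name in names:
            feature_kind(name)  # raises on unknown
            if name == "CR":
                continue
            length = self.gene_lengths.get(name)
            if length is None:
                raise SyntheticSpecError(f"gene_lengths: no length for {name}")
            if length <= 0:
                raise SyntheticSpecError(
                    f"gene_lengths: non-positive length for {name}")
        for fld in ("spacer_length", "t_homopolymer_length", "at_rich_length",
                    "leading_length", "trailing_length"):
            if getattr(self.cr_spec, fld) < 0:
                raise SyntheticSpecError(f"cr_spec.{fld}: negative")


class Feature(NamedTuple):
    name: str
    start: int  # 0-based half-open
    end: int
    strand: str


class Heteroplasmy(NamedTuple):
    position: int
    major: str
    minor: str
    minor_freq: float
    depth: int


class CRDeletion(NamedTuple):
    start: int
    end: int
    csb_d_overlap: int


@dataclass
class TruthSet:
    """Ground truth accompanying a synthetic genome."""

    features: list[Feature]
    transcript_units: list[tuple[int, int]]
    heteroplasmies: list[Heteroplasmy] = field(default_factory=list)
    cr_deletion: CRDeletion | None = None
    cr_motifs: list[tuple[str, int, int]] = field(default_factory=list)
    t_homopolymer: tuple[int, int] | None = None

    def feature(self, name: str) -> Feature:
        for f in self.features:
            if f.name == name:
                return f
        raise KeyError(name)


# ---------------------------------------------------------------------------
# sequence builders
# ---------------------------------------------------------------------------

def _random_seq(rng: np.random.Generator, n: int, alphabet: str = "ACGT",
                max_t_run: int = 6) -> str:
    """Random sequence with T-runs capped so planted homopolymers stay unique."""
    chars = list(rng.choice(list(alphabet), size=n))
    run = 0
    for i, c in enumerate(chars):
        if c == "T":
            run += 1
            if run > max_t_run:
                chars[i] = "C"
                run = 0
        else:
            run = 0
    return "".join(chars)


def _coding_sequence(rng: np.random.Generator, name: str, length: int) -> str:
    """In-frame PCG sequence: start codon, sense codons, stop by length class."""
    rem = length % 3
    ncod = length // 3
    start = _START_OVERRIDES.get(name, "ATG")
    if rem == 0:
        if ncod < 3:
            raise SyntheticSpecError(f"gene_lengths: {name} too short for a PCG")
        body = rng.choice(genetic_code.SENSE_CODONS, size=ncod - 2)
        return start + "".join(body) + "TAA"
    if ncod < 2:
        raise SyntheticSpecError(f"gene_lengths: {name} too short for a PCG")
    body = rng.choice(genetic_code.SENSE_CODONS, size=ncod - 1)
    return start + "".join(body) + ("T" if rem == 1 else "TA")


def _resolve_consensus(motif: MotifDef) -> str:
    # deterministic concrete instance of an IUPAC consensus
    return "".join(sorted(IUPAC[c])[0] for c in motif.consensus.upper())


def _build_control_region(
    rng: np.random.Generator,
    cr_spec: CRSpec,
    library: dict[str, MotifDef],
) -> tuple[str, list[tuple[str, int, int]], tuple[int, int]]:
    """Assemble a CR; returns (sequence, motif coords, T-homopolymer interval)."""
    parts: list[str] = []
    coords: list[tuple[str, int, int]] = []
    pos = 0

    def emit(seq: str) -> None:
        nonlocal pos
        parts.append(seq)
        pos += len(seq)

    def emit_spacer(n: int, alphabet: str = "ACGT") -> None:
        emit(_random_seq(rng, n, alphabet))

    emit_spacer(cr_spec.leading_length, "ACGT")
    homopolymer: tuple[int, int] | None = None
    for name in cr_spec.motif_order:
        if name not in library:
            raise SyntheticSpecError(f"cr_spec.motif_order: unknown motif {name}")
        if name == "CSB-1":
            # Domain III opens with the T-homopolymer then an AT-rich segment
            t_run = "T" * cr_spec.t_homopolymer_length
            emit("A")  # block extension of the run to the left
            homopolymer = (pos, pos + len(t_run))
            emit(t_run)
            emit("C")  # block extension to the right
            emit_spacer(cr_spec.at_rich_length, "AT")
        seq = _resolve_consensus(library[name])
        coords.append((name, pos, pos + len(seq)))
        emit(seq)
        emit_spacer(cr_spec.spacer_length)
    emit_spacer(cr_spec.trailing_length)
    if homopolymer is None:
        raise SyntheticSpecError("cr_spec.motif_order: must include CSB-1")
    return "".join(parts), coords, homopolymer


#: processing boundaries without an intervening tRNA: the non-canonical
#: atp6|cox3 cleavage site and the strand switch at nad5|nad6
_EXTRA_CLEAVAGES = {("atp6", "cox3"), ("nad5", "nad6")}


def _transcript_units(features: Sequence[Feature]) -> list[tuple[int, int]]:
    """Maximal inter-tRNA intervals holding at least one PCG or rRNA.

    Units also break at known tRNA-less processing sites, leaving exactly
    the nad4l/nad4 and atp8/atp6 bicistronic messages intact.
    """
    units: list[tuple[int, int]] = []
    block: list[Feature] = []

    def flush() -> None:
        nonlocal block
        if block:
            units.append((block[0].start, block[-1].end))
        block = []

    for f in features:
        if f.name in TRNAS:
            flush()
        elif f.name in PCGS or f.name in RRNAS:
            if block and (block[-1].name, f.name) in _EXTRA_CLEAVAGES:
                flush()
            block.append(f)
        # OL / CR do not belong to any mRNA unit; they break nothing
    flush()
    return units


def build_toy_mitogenome(
    spec: ToyGenomeSpec | None = None,
    motif_library: dict[str, MotifDef] | None = None,
) -> tuple[str, TruthSet]:
    """Generate a toy mitogenome and its truth set.

    Deterministic under ``spec.seed``.  Every PCG translates without
    internal stops under the vertebrate mitochondrial code; control-region
    motifs are embedded verbatim from the motif library.
    """
    spec = spec or ToyGenomeSpec()
    spec.validate()
    library = motif_library or default_motif_library()
    rng = np.random.default_rng(spec.seed)

    parts: list[str] = []
    features: list[Feature] = []
    cr_motifs: list[tuple[str, int, int]] = []
    t_homopolymer: tuple[int, int] | None = None
    pos = 0
    for name, strand in spec.gene_order:
        kind = feature_kind(name)
        if kind == "PCG":
            seq = _coding_sequence(rng, name, spec.gene_lengths[name])
            if strand == "-":
                seq = genetic_code.reverse_complement(seq)
        elif kind == "CR":
            seq, local_motifs, local_t = _build_control_region(
                rng, spec.cr_spec, library)
            cr_motifs = [(n, pos + s, pos + e) for n, s, e in local_motifs]
            t_homopolymer = (pos + local_t[0], pos + local_t[1])
        else:
            seq = _random_seq(rng, spec.gene_lengths[name])
        features.append(Feature(name, pos, pos + len(seq), strand))
        parts.append(seq)
        pos += len(seq)

    sequence = "".join(parts)
    truth = TruthSet(
        features=features,
        transcript_units=_transcript_units(features),
        cr_motifs=cr_motifs,
        t_homopolymer=t_homopolymer,
    )
    return sequence, truth


# ---------------------------------------------------------------------------
# transcript contigs (punctuation model)
# ---------------------------------------------------------------------------

def simulate_transcript_contigs(
    sequence: str,
    truth: TruthSet,
    dropout: float = 0.0,
    seed: int = 0,
) -> list[SeqRecord]:
    """One contig per transcript unit, cleaved at tRNA boundaries.

    ``dropout`` is the per-unit probability that no contig is emitted
    (an unexpressed or unassembled transcript).
    """
    if not 0.0 <= dropout <= 1.0:
        raise ValueError("dropout must be a probability")
    rng = np.random.default_rng(seed)
    feature_by_span = sorted(
        (f for f in truth.features if f.name in PCGS or f.name in RRNAS),
        key=lambda f: f.start)
    records: list[SeqRecord] = []
    for i, (start, end) in enumerate(truth.transcript_units):
        if rng.random() < dropout:
            continue
        unit_features = [f for f in feature_by_span
                         if start <= f.start and f.end <= end]
        label = "-".join(f.name for f in unit_features) or f"{start}-{end}"
        seq = sequence[start:end]
        if unit_features and all(f.strand == "-" for f in unit_features):
            seq = genetic_code.reverse_complement(seq)  # light-strand mRNA
        records.append(SeqRecord(
            Seq(seq),
            id=f"tu{i:02d}_{label}",
            description=f"transcript unit {start}:{end}"))
    return records


# ---------------------------------------------------------------------------
# read pileups
# ---------------------------------------------------------------------------

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


def punctuated_depth_tiers(
    truth: TruthSet,
    cox_depth: int = 1000,
    mrna_depth: int = 300,
    trna_depth: int = 40,
) -> dict[str, int]:
    """Depth tiers emulating the punctuation expression pattern.

    Cytochrome c oxidase transcripts deepest, other mRNA/rRNA units
    intermediate, tRNAs and non-transcribed elements shallow.
    """
    tiers: dict[str, int] = {}
    for f in truth.features:
        if f.name.startswith("cox"):
            tiers[f.name] = cox_depth
        elif f.name in PCGS or f.name in RRNAS:
            tiers[f.name] = mrna_depth
        else:
            tiers[f.name] = trna_depth
    return tiers


def plant_random_heteroplasmies(
    sequence: str,
    truth: TruthSet,
    count: int,
    depth: int = 500,
    minor_freq: float = 0.2,
    seed: int = 0,
    region: tuple[int, int] | None = None,
) -> TruthSet:
    """Return a copy of ``truth`` with ``count`` random heteroplasmic sites."""
    if not 0.0 < minor_freq <= 0.5:
        raise ValueError("minor_freq must be in (0, 0.5]")
    rng = np.random.default_rng(seed)
    lo, hi = region if region else (0, len(sequence))
    positions = rng.choice(np.arange(lo, hi), size=count, replace=False)
    sites = []
    for p in sorted(int(x) for x in positions):
        major = sequence[p]
        minor = str(rng.choice([b for b in "ACGT" if b != major]))
        sites.append(Heteroplasmy(p, major, minor, minor_freq, depth))
    return dataclasses.replace(truth,
                               heteroplasmies=truth.heteroplasmies + sites)


def simulate_read_pileup(
    sequence: str,
    truth: TruthSet,
    depth_per_feature: dict[str, int] | None = None,
    error_rate: float = 0.001,
    seed: int = 0,
    default_depth: int = 200,
) -> BaseCountProfile:
    """Per-position A/C/G/T counts with feature depth tiers and planted sites.

    Depth at each position is binomially sampled around its feature's tier
    (heteroplasmic positions use their configured total depth exactly);
    sequencing error substitutes a base uniformly at ``error_rate``.
    """
    if not 0.0 <= error_rate <= 0.05:
        raise ValueError("error_rate must be in [0, 0.05]")
    depth_per_feature = depth_per_feature or {}
    for name, d in depth_per_feature.items():
        if d < 0:
            raise ValueError(f"negative depth for {name}")
    L = len(sequence)
    rng = np.random.default_rng(seed)

    expected = np.full(L, default_depth, dtype=np.int64)
    for f in truth.features:
        if f.name in depth_per_feature:
            expected[f.start:f.end] = depth_per_feature[f.name]
    depth = rng.binomial(2 * expected, 0.5)
    for site in truth.heteroplasmies:
        if not 0 <= site.position < L:
            raise ValueError(f"heteroplasmy position {site.position} "
                             f"outside sequence of length {L}")
        if site.major == site.minor:
            raise ValueError(f"heteroplasmy at {site.position}: major and "
                             f"minor base are both {site.major}")
        depth[site.position] = site.depth

    ref_idx = np.fromiter((_BASE_INDEX[b] for b in sequence), dtype=np.int64,
                          count=L)
    counts = np.zeros((L, 4), dtype=np.int64)
    # error channel, vectorized: errors split uniformly over the 3 other bases
    errors = rng.binomial(depth, error_rate)
    e1 = rng.binomial(errors, 1.0 / 3.0)
    e2 = rng.binomial(errors - e1, 0.5)
    e3 = errors - e1 - e2
    rows = np.arange(L)
    counts[rows, ref_idx] = depth - errors
    others = np.array([[i for i in range(4) if i != r] for r in range(4)])
    alt = others[ref_idx]  # (L, 3)
    np.add.at(counts, (rows, alt[:, 0]), e1)
    np.add.at(counts, (rows, alt[:, 1]), e2)
    np.add.at(counts, (rows, alt[:, 2]), e3)

    # planted heteroplasmies: re-draw the site from the two-allele mixture
    for site in truth.heteroplasmies:
        maj, mnr = _BASE_INDEX[site.major], _BASE_INDEX[site.minor]
        pvec = ((1 - site.minor_freq) * _channel(maj, error_rate)
                + site.minor_freq * _channel(mnr, error_rate))
        counts[site.position] = rng.multinomial(site.depth, pvec)
    return BaseCountProfile(counts)


def _channel(base_idx: int, error_rate: float) -> np.ndarray:
    p = np.full(4, error_rate / 3.0)
    p[base_idx] = 1.0 - error_rate
    return p


def mutate_genome(
    sequence: str,
    truth: TruthSet,
    n_substitutions: int,
    seed: int = 0,
) -> str:
    """Plant ``n_substitutions`` random substitutions for cohort divergence.

    Substitutions never create an in-frame stop codon in a PCG (checked on
    the coding strand) and never touch a PCG's first or last codon, so
    mutated cohorts stay translatable and alignable.
    """
    rng = np.random.default_rng(seed)
    chars = list(sequence)
    pcg_of: dict[int, Feature] = {}
    for f in truth.features:
        if f.name in PCGS:
            for p in range(f.start, f.end):
                pcg_of[p] = f
    placed = 0
    attempts = 0
    while placed < n_substitutions and attempts < 50 * n_substitutions:
        attempts += 1
        p = int(rng.integers(len(chars)))
        new = str(rng.choice([b for b in "ACGT" if b != chars[p]]))
        f = pcg_of.get(p)
        if f is not None:
            # coding-strand codon containing p, skipping boundary codons
            if f.strand == "+":
                offset = p - f.start
            else:
                offset = f.end - 1 - p
            codon_idx = offset // 3
            ncodons = (f.end - f.start) // 3
            if codon_idx == 0 or codon_idx >= ncodons - 1:
                continue
            cs = (f.start + 3 * codon_idx if f.strand == "+"
                  else f.end - 3 * codon_idx - 3)
            codon = chars[cs:cs + 3]
            codon[p - cs] = new
            codon_str = "".join(codon)
            if f.strand == "-":
                codon_str = genetic_code.reverse_complement(codon_str)
            if codon_str in genetic_code.STOP_CODONS:
                continue
        chars[p] = new
        placed += 1
    return "".join(chars)


# ---------------------------------------------------------------------------
# control-region deletion
# ---------------------------------------------------------------------------

def apply_cr_deletion(
    sequence: str,
    truth: TruthSet,
    deletion_length: int,
    csb_d_overlap: int = 7,
) -> tuple[str, TruthSet]:
    """Delete ``deletion_length`` nt anchored at the CSB-D 3' end.

    The deletion removes the last ``csb_d_overlap`` nucleotides of CSB-D and
    extends downstream, emulating the clade-specific truncation observed in
    hypostomine control regions.
    """
    if deletion_length < 0:
        raise ValueError("deletion_length must be >= 0")
    if deletion_length == 0:
        return sequence, truth
    cr = truth.feature("CR")
    cr_len = cr.end - cr.start
    if deletion_length >= cr_len:
        raise ValueError(f"deletion of {deletion_length} nt exceeds the "
                         f"{cr_len} nt control region")
    csbd = next(((n, s, e) for n, s, e in truth.cr_motifs if n == "CSB-D"), None)
    if csbd is None:
        raise ValueError("truth has no CSB-D motif to anchor the deletion")
    _, _, csbd_end = csbd
    if csb_d_overlap < 0 or csb_d_overlap > deletion_length:
        raise ValueError("csb_d_overlap must be in [0, deletion_length]")
    del_start = csbd_end - csb_d_overlap
    del_end = del_start + deletion_length
    if del_start < cr.start or del_end > cr.end:
        raise ValueError("deletion extends outside the control region")

    new_seq = sequence[:del_start] + sequence[del_end:]
    L = deletion_length

    def shift(x: int) -> int:
        if x <= del_start:
            return x
        if x >= del_end:
            return x - L
        return del_start  # truncated inside the deletion

    new_features = [Feature(f.name, shift(f.start), shift(f.end), f.strand)
                    for f in truth.features]
    new_motifs = [(n, shift(s), shift(e)) for n, s, e in truth.cr_motifs]
    new_t = (tuple(map(shift, truth.t_homopolymer))
             if truth.t_homopolymer else None)
    overlap = max(0, min(csbd_end, del_end) - max(csbd[1], del_start))
    return new_seq, dataclasses.replace(
        truth,
        features=new_features,
        cr_motifs=new_motifs,
        t_homopolymer=new_t,
        cr_deletion=CRDeletion(del_start, del_end, overlap),
    )


# ---------------------------------------------------------------------------
# synthetic CR alignments (for truncation detection)
# ---------------------------------------------------------------------------

def simulate_cr_alignment(
    n_taxa: int = 6,
    n_carriers: int = 3,
    deletion_length: int = 60,
    csb_d_overlap: int = 7,
    substitution_rate: float = 0.01,
    seed: int = 0,
    motif_library: dict[str, MotifDef] | None = None,
) -> tuple[list[tuple[str, str]], dict]:
    """Aligned CR cohort where ``n_carriers`` taxa share a CSB-D truncation.

    Returns (alignment rows as (taxon, aligned sequence) pairs, truth dict
    with the deletion column interval, CSB-D columns and carrier taxa).
    Substitutions are planted outside motif columns so motif scans stay
    exact by construction.
    """
    if n_carriers > n_taxa:
        raise ValueError("n_carriers cannot exceed n_taxa")
    rng = np.random.default_rng(seed)
    library = motif_library or default_motif_library()
    cr_seq, motif_coords, _ = _build_control_region(rng, CRSpec(), library)
    csbd = next((s, e) for n, s, e in motif_coords if n == "CSB-D")
    del_start = csbd[1] - csb_d_overlap
    del_end = del_start + deletion_length
    if del_end > len(cr_seq):
        raise ValueError("deletion extends beyond the control region")

    motif_cols = np.zeros(len(cr_seq), dtype=bool)
    for _, s, e in motif_coords:
        motif_cols[s:e] = True
    carriers = [f"taxon{i:02d}" for i in range(n_carriers)]
    rows: list[tuple[str, str]] = []
    for i in range(n_taxa):
        taxon = f"taxon{i:02d}"
        chars = list(cr_seq)
        nsub = rng.binomial(len(cr_seq), substitution_rate)
        free = np.flatnonzero(~motif_cols)
        for p in rng.choice(free, size=min(nsub, free.size), replace=False):
            chars[p] = str(rng.choice([b for b in "ACGT" if b != chars[p]]))
        if taxon in carriers:
            for p in range(del_start, del_end):
                chars[p] = "-"
        rows.append((taxon, "".join(chars)))
    truth = {
        "deletion_columns": (del_start, del_end),
        "deletion_length": deletion_length,
        "csb_d_columns": csbd,
        "csb_d_overlap": csb_d_overlap,
        "carriers": carriers,
    }
    return rows, truth


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_fasta(records: Sequence[SeqRecord] | Sequence[tuple[str, str]],
                path: str | Path) -> None:
    from Bio import SeqIO
    recs = [r if isinstance(r, SeqRecord)
            else SeqRecord(Seq(r[1]), id=r[0], description="")
            for r in records]
    SeqIO.write(recs, str(path), "fasta")


def write_truth_bed(truth: TruthSet, path: str | Path) -> None:
    """BED-like TSV of truth features (0-based half-open)."""
    lines = [f"{f.name}\t{f.start}\t{f.end}\t{f.strand}"
             for f in truth.features]
    Path(path).write_text("\n".join(lines) + "\n")


def write_truth_json(truth: TruthSet, path: str | Path) -> None:
    payload = {
        "features": [f._asdict() for f in truth.features],
        "transcript_units": truth.transcript_units,
        "heteroplasmies": [h._asdict() for h in truth.heteroplasmies],
        "cr_deletion": (truth.cr_deletion._asdict()
                        if truth.cr_deletion else None),
        "cr_motifs": truth.cr_motifs,
        "t_homopolymer": truth.t_homopolymer,
    }
    Path(path).write_text(json.dumps(payload, indent=1))
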