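"""Reference-guided scaffolding of mitochondrial contigs.

Transcriptome contigs are captured by similarity to a reference mitogenome,
placed in reference coordinates (both orientations tried), and merged into
a scaffold of exactly the reference length with uncovered positions filled
with N — the reconstruction strategy used when a mitogenome is assembled
from RNA-seq contigs that stop at tRNA punctuation boundaries.

Placement uses exact infix edit-distance alignment (edlib) of each contig
against the reference; alignments are rescored with match +1, mismatch -2,
gap open -5, gap extend -2, and that score ranks contigs when overlapping
placements disagree.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import edlib
import numpy as np

from mitopunct.genetic_code import reverse_complement

logger = logging.getLogger(__name__)

MATCH_SCORE = 1
MISMATCH_SCORE = -2
GAP_OPEN = -5
GAP_EXTEND = -2

#: overlapping placements disagreeing on more than this fraction of shared
#: positions are treated as irreconcilable
CONFLICT_FRACTION = 0.20


class EmptyReferenceError(ValueError):
    pass


class ScaffoldConflictError(ValueError):
    """Two placements disagree on too many shared positions."""

    def __init__(self, contig_a: str, contig_b: str, disagreement: float):
        self.contigs = (contig_a, contig_b)
        super().__init__(
            f"placements of {contig_a} and {contig_b} disagree on "
            f"{disagreement:.0%} of shared positions")


@dataclass(frozen=True)
class CaptureHit:
    """A contig placed on the reference."""

    contig_id: str
    score: int
    ref_start: int  # 0-based half-open on the reference
    ref_end: int
    contig_start: int
    contig_end: int
    orientation: str  # '+' or '-'
    identity: float  # percent over alignment columns
    cigar: str = ""


@dataclass
class MitoScaffold:
    sequence: str
    reference_id: str
    placements: list[CaptureHit]
    conflicts: list[tuple[str, str, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        bad = set(self.sequence) - set("ACGTN")
        if bad:
            raise ValueError(f"scaffold contains non-ACGTN symbols {sorted(bad)}")


def _as_pairs(contigs) -> list[tuple[str, str]]:
    out = []
    for c in contigs:
        if isinstance(c, tuple):
            out.append((c[0], str(c[1]).upper()))
        else:  # SeqRecord
            out.append((c.id, str(c.seq).upper()))
    return out


def _parse_cigar(cigar: str):
    n = 0
    for ch in cigar:
        if ch.isdigit():
            n = n * 10 + ord(ch) - 48
        else:
            yield n, ch
            n = 0


def _score_and_identity(cigar: str) -> tuple[int, float, int]:
    """(affine score, percent identity over columns, alignment columns)."""
    score = matches = columns = 0
    for n, op in _parse_cigar(cigar):
        columns += n
        if op == "=":
            matches += n
            score += MATCH_SCORE * n
        elif op == "X":
            score += MISMATCH_SCORE * n
        elif op in "ID":
            score += GAP_OPEN + GAP_EXTEND * (n - 1)
    identity = 100.0 * matches / columns if columns else 0.0
    return score, identity, columns


def _align_one(contig_seq: str, reference: str) -> dict | None:
    res = edlib.align(contig_seq, reference, mode="HW", task="path")
    if res["editDistance"] < 0 or not res["locations"]:
        return None
    start, end_inclusive = res["locations"][0]
    return {"cigar": res["cigar"], "ref_start": start,
            "ref_end": end_inclusive + 1}


def capture_mitochondrial_contigs(
    contigs,
    reference: str,
    min_identity: float = 80.0,
    min_length: int = 100,
) -> list[CaptureHit]:
    """Capture contigs similar to the reference mitogenome.

    Each contig is aligned in both orientations; the better-scoring
    orientation is kept, and hits below ``min_identity`` percent or
    spanning fewer than ``min_length`` reference nucleotides are dropped
    (non-mitochondrial transcripts).
    """
    reference = str(reference).upper()
    if not reference:
        raise EmptyReferenceError("empty reference sequence")
    pairs = _as_pairs(contigs)
    if not pairs:
        raise ValueError("empty contig set")
    hits: list[CaptureHit] = []
    for cid, seq in pairs:
        best: CaptureHit | None = None
        for orientation, oriented in (("+", seq),
                                      ("-", reverse_complement(seq))):
            aln = _align_one(oriented, reference)
            if aln is None:
                continue
            score, identity, _ = _score_and_identity(aln["cigar"])
            hit = CaptureHit(
                contig_id=cid, score=score,
                ref_start=aln["ref_start"], ref_end=aln["ref_end"],
                contig_start=0, contig_end=len(seq),
                orientation=orientation, identity=identity,
                cigar=aln["cigar"])
            if best is None or hit.score > best.score:
                best = hit
        if best is None:
            continue
        if best.identity >= min_identity \
                and best.ref_end - best.ref_start >= min_length:
            hits.append(best)
    return hits


def _placed_bases(hit: CaptureHit, contig_seq: str) -> dict[int, str]:
    """Map reference position -> contig base for one placement."""
    oriented = (contig_seq if hit.orientation == "+"
                else reverse_complement(contig_seq))
    out: dict[int, str] = {}
    rpos, qpos = hit.ref_start, 0
    for n, op in _parse_cigar(hit.cigar):
        if op in "=X":
            for k in range(n):
                out[rpos + k] = oriented[qpos + k]
            rpos += n
            qpos += n
        elif op == "I":  # extra contig bases, no reference position
            qpos += n
        elif op == "D":  # reference bases absent from the contig
            rpos += n
    return out


def merge_to_scaffold(
    hits: Sequence[CaptureHit],
    contigs,
    reference: str,
    reference_id: str = "reference",
) -> MitoScaffold:
    """Merge placed contigs into an N-gap-filled scaffold.

    The scaffold has exactly the reference length; positions covered by at
    least one contig carry the contig base.  Where overlapping contigs
    disagree on fewer than 20% of their shared positions, the base from
    the higher-scoring contig wins (ties: longer contig, then smaller id);
    above that fraction a :class:`ScaffoldConflictError` is raised.
    """
    reference = str(reference).upper()
    if not reference:
        raise EmptyReferenceError("empty reference sequence")
    seq_by_id = dict(_as_pairs(contigs))
    length = len(reference)
    for h in hits:
        if not (0 <= h.ref_start <= h.ref_end <= length):
            raise ValueError(f"hit {h.contig_id} outside reference bounds")

    placed = []
    for h in hits:
        contig_len = len(seq_by_id[h.contig_id])
        placed.append((h, contig_len, _placed_bases(h, seq_by_id[h.contig_id])))
    # priority: score desc, contig length desc, id asc
    placed.sort(key=lambda t: (-t[0].score, -t[1], t[0].contig_id))

    scaffold = np.full(length, "N", dtype="U1")
    owner = np.full(length, -1, dtype=np.int64)
    conflicts: list[tuple[str, str, int, int]] = []
    for idx, (hit, _, bases) in enumerate(placed):
        shared = disagree = 0
        by_owner: dict[int, list[int]] = {}
        for pos, base in bases.items():
            if owner[pos] >= 0:
                shared += 1
                if scaffold[pos] != base:
                    disagree += 1
                    by_owner.setdefault(int(owner[pos]), []).append(pos)
            else:
                scaffold[pos] = base
                owner[pos] = idx
        if shared:
            frac = disagree / shared
            for oidx, positions in by_owner.items():
                conflicts.append((placed[oidx][0].contig_id, hit.contig_id,
                                  len(positions), shared))
                logger.info("conflict: %s vs %s at %d/%d shared positions",
                            placed[oidx][0].contig_id, hit.contig_id,
                            len(positions), shared)
            if frac > CONFLICT_FRACTION:
                worst = max(by_owner, key=lambda o: len(by_owner[o]))
                raise ScaffoldConflictError(
                    placed[worst][0].contig_id, hit.contig_id, frac)
    return MitoScaffold(
        sequence="".join(scaffold),
        reference_id=reference_id,
        placements=[p[0] for p in placed],
        conflicts=conflicts)


def coverage_percent(scaffold: MitoScaffold | str) -> float:
    """Percent non-N positions, rounded to 0.1."""
    seq = scaffold.sequence if isinstance(scaffold, MitoScaffold) else scaffold
    if not seq:
        raise ValueError("empty scaffold")
    non_n = sum(1 for c in seq if c != "N")
    return round(100.0 * non_n / len(seq), 1)


def trim_scaffold_ends(
    scaffold: MitoScaffold,
    reference: str,
    window: int = 20,
    min_window_identity: float = 70.0,
) -> MitoScaffold:
    """Mask poorly aligned terminal windows to N.

    Walking inward from each end, each ``window``-nt block whose identity
    to the reference (over its non-N positions) falls below the threshold
    is replaced by N.  All-N blocks are passed over; the first
    well-matching block stops the walk.  Interior sequence is untouched.
    """
    reference = str(reference).upper()
    seq = list(scaffold.sequence)
    length = len(seq)
    if len(reference) != length:
        raise ValueError("reference length does not match scaffold")
    window = max(1, min(window, length))

    def window_identity(start: int, stop: int) -> float | None:
        compared = matched = 0
        for i in range(start, stop):
            if seq[i] != "N":
                compared += 1
                if seq[i] == reference[i]:
                    matched += 1
        return None if compared == 0 else 100.0 * matched / compared

    def sweep(blocks) -> None:
        for start, stop in blocks:
            ident = window_identity(start, stop)
            if ident is None:
                continue  # all-N gap; keep walking inward
            if ident < min_window_identity:
                for i in range(start, stop):
                    seq[i] = "N"
            else:
                break

    half = (length + 1) // 2
    left_blocks = [(s, min(s + window, length)) for s in range(0, half, window)]
    right_blocks = []
    stop = length
    while stop > half:
        start = max(stop - window, half)
        right_blocks.append((start, stop))
        stop = start
    sweep(left_blocks)
    sweep(right_blocks)
    return MitoScaffold(sequence="".join(seq),
                        reference_id=scaffold.reference_id,
                        placements=scaffold.placements,
                        conflicts=scaffold.conflicts)


def write_scaffold_report(scaffold: MitoScaffold, path: str | Path) -> None:
    payload = {
        "reference_id": scaffold.reference_id,
        "length": len(scaffold.sequence),
        "coverage_percent": coverage_percent(scaffold),
        "n_placements": len(scaffold.placements),
        "conflicts": scaffold.conflicts,
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def write_placements_tsv(scaffold: MitoScaffold, path: str | Path) -> None:
    lines = ["contig_id\tref_start\tref_end\torientation\tidentity\tscore"]
    for h in scaffold.placements:
        lines.append(f"{h.contig_id}\t{h.ref_start}\t{h.ref_end}\t"
                     f"{h.orientation}\t{h.identity:.1f}\t{h.score}")
    Path(path).write_text("\n".join(lines) + "\n")
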