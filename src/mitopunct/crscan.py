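"""Control-region annotation: conserved sequence blocks and truncations.

The control region (CR) lies between tRNA-Pro and tRNA-Phe and divides
into Domain I (TAS), Domain II (CSB-F, CSB-E, CSB-D) and Domain III
(T-homopolymer, AT-rich segment, CSB-1/2/3).  Motifs are located by
minimal-mismatch IUPAC-aware scanning; taxon-shared deletions that
truncate the 3' end of CSB-D are measured on a supplied multiple
alignment of CRs.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from mitopunct.motifs import (
    DEFAULT_LIBRARY_VERSION,
    IUPAC,
    MotifDef,
    default_motif_library,
)
from mitopunct.synthetic import Feature


class MissingFlankError(ValueError):
    pass


@dataclass(frozen=True)
class MotifHit:
    name: str
    start: int  # within the scanned sequence, 0-based half-open
    end: int
    mismatches: int


@dataclass
class ControlRegionAnnotation:
    interval: tuple[int, int]
    hits: list[MotifHit]
    t_homopolymer: tuple[int, int] | None
    domains: dict[str, tuple[int, int]]
    not_sequenced: bool = False
    order_violations: list[str] = field(default_factory=list)
    library_version: str = DEFAULT_LIBRARY_VERSION


# ---------------------------------------------------------------------------
# locating the CR
# ---------------------------------------------------------------------------

def locate_control_region(
    features: Sequence[Feature],
    sequence: str,
    circular: bool = False,
) -> tuple[int, int, bool]:
    """Interval strictly between trnP end and trnF start.

    Returns (start, end, not_sequenced).  On a linear genome deposited
    with trnF first the CR runs from trnP end to the sequence end; with
    ``circular`` the interval may wrap (end > len(sequence) encodes the
    wrap).  ``not_sequenced`` is set when the span carries no called base
    (an all-N scaffold CR).
    """
    by_name = {f.name: f for f in features}
    missing = [n for n in ("trnP", "trnF") if n not in by_name]
    if missing:
        raise MissingFlankError(f"CR flanking tRNA(s) missing: {missing}")
    trnp, trnf = by_name["trnP"], by_name["trnF"]
    L = len(sequence)
    if trnf.start >= trnp.end:
        start, end = trnp.end, trnf.start
        segment = sequence[start:end]
    else:
        start = trnp.end
        end = L + trnf.start if circular else L
        segment = sequence[trnp.end:] + (sequence[:trnf.start] if circular
                                         else "")
    not_sequenced = len(segment) > 0 and all(c == "N" for c in segment)
    return start, end, not_sequenced


# ---------------------------------------------------------------------------
# motif scanning
# ---------------------------------------------------------------------------

def _mismatch_counts(seq: str, motif: MotifDef) -> np.ndarray:
    """Hamming mismatches of the IUPAC consensus at every offset."""
    m = len(motif.consensus)
    L = len(seq)
    if L < m:
        return np.empty(0, dtype=np.int64)
    arr = np.frombuffer(seq.encode(), dtype="S1")
    windows = np.lib.stride_tricks.sliding_window_view(arr, m)
    mism = np.zeros(L - m + 1, dtype=np.int64)
    for j, sym in enumerate(motif.consensus.upper()):
        allowed = np.array([b.encode() for b in IUPAC[sym]], dtype="S1")
        mism += ~np.isin(windows[:, j], allowed)
    return mism


def best_placement(seq: str, motif: MotifDef) -> MotifHit | None:
    """Minimal-mismatch placement (leftmost on ties); None if over budget."""
    mism = _mismatch_counts(seq.upper(), motif)
    if mism.size == 0:
        return None
    pos = int(np.argmin(mism))  # argmin returns the leftmost minimum
    if mism[pos] > motif.max_mismatches:
        return None
    return MotifHit(motif.name, pos, pos + len(motif.consensus),
                    int(mism[pos]))


def scan_conserved_blocks(
    cr_sequence: str,
    motif_library: dict[str, MotifDef] | None = None,
) -> list[MotifHit]:
    """Best placement of every library motif within the CR.

    Each motif is placed independently at its minimal-mismatch position
    (leftmost on ties); motifs whose best placement exceeds their mismatch
    budget are absent from the result.
    """
    library = motif_library or default_motif_library()
    hits = []
    for motif in library.values():
        hit = best_placement(cr_sequence, motif)
        if hit is not None:
            hits.append(hit)
    return sorted(hits, key=lambda h: h.start)


def annotate_control_region(
    cr_sequence: str,
    motif_library: dict[str, MotifDef] | None = None,
    min_t_homopolymer: int = 8,
    interval: tuple[int, int] | None = None,
    library_version: str = DEFAULT_LIBRARY_VERSION,
) -> ControlRegionAnnotation:
    """Full CR annotation: motif hits, T-homopolymer, domain boundaries.

    Domains are defined operationally: Domain I runs from the CR start to
    the TAS end, Domain II from there to the CSB-D end, Domain III to the
    CR end.  Hits out of canonical order (TAS < CSB-F < CSB-E < CSB-D <
    CSB-1 < CSB-2 < CSB-3) are recorded as violations, not dropped.
    """
    hits = scan_conserved_blocks(cr_sequence, motif_library)
    by_name = {h.name: h for h in hits}
    order = [n for n in ("TAS", "CSB-F", "CSB-E", "CSB-D",
                         "CSB-1", "CSB-2", "CSB-3") if n in by_name]
    violations = [
        f"{a} at {by_name[a].start} not left of {b} at {by_name[b].start}"
        for a, b in zip(order, order[1:])
        if by_name[a].start >= by_name[b].start
    ]
    L = len(cr_sequence)
    domains: dict[str, tuple[int, int]] = {}
    tas_end = by_name["TAS"].end if "TAS" in by_name else 0
    csbd_end = by_name["CSB-D"].end if "CSB-D" in by_name else tas_end
    domains["I"] = (0, tas_end)
    domains["II"] = (tas_end, csbd_end)
    domains["III"] = (csbd_end, L)
    not_sequenced = L > 0 and set(cr_sequence.upper()) <= {"N"}
    return ControlRegionAnnotation(
        interval=interval or (0, L),
        hits=hits,
        t_homopolymer=detect_t_homopolymer(cr_sequence, min_t_homopolymer),
        domains=domains,
        not_sequenced=not_sequenced,
        order_violations=violations,
        library_version=library_version,
    )


def detect_t_homopolymer(cr_sequence: str,
                         min_length: int = 8) -> tuple[int, int] | None:
    """Longest run of T of at least ``min_length`` nt; leftmost on ties."""
    best: tuple[int, int] | None = None
    for m in re.finditer("T+", cr_sequence.upper()):
        if m.end() - m.start() >= min_length:
            if best is None or (m.end() - m.start()) > (best[1] - best[0]):
                best = (m.start(), m.end())
    return best


# ---------------------------------------------------------------------------
# shared indels on CR alignments
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GapEvent:
    kind: str  # deletion | insertion
    columns: tuple[int, int]
    length: int
    taxa: tuple[str, ...]  # taxa carrying the event


@dataclass
class TruncationReport:
    csb_d_columns: tuple[int, int]
    deletions: list[GapEvent]
    insertions: list[GapEvent]

    @property
    def truncations(self) -> list[GapEvent]:
        """Deletions overlapping CSB-D."""
        s, e = self.csb_d_columns
        return [d for d in self.deletions
                if min(e, d.columns[1]) > max(s, d.columns[0])]

    def csb_d_overlap(self, event: GapEvent) -> int:
        s, e = self.csb_d_columns
        return max(0, min(e, event.columns[1]) - max(s, event.columns[0]))


def gap_events(alignment: Sequence[tuple[str, str]]) -> list[GapEvent]:
    """Maximal column runs with an identical, non-trivial gap pattern.

    Taxa sharing gaps over a run form one event.  When the gapped taxa are
    the majority, the bases are the rarity: the event is reported as an
    insertion carried by the base-bearing minority; otherwise a deletion
    carried by the gapped taxa (ties count as deletions).
    """
    taxa = [t for t, _ in alignment]
    rows = [s for _, s in alignment]
    if not rows:
        return []
    ncol = len(rows[0])
    if any(len(r) != ncol for r in rows):
        raise ValueError("alignment rows differ in length")
    gap = np.array([[c == "-" for c in r] for r in rows])  # (ntaxa, ncol)
    events: list[GapEvent] = []
    col = 0
    while col < ncol:
        pattern = gap[:, col]
        if not pattern.any():
            col += 1
            continue
        end = col + 1
        while end < ncol and (gap[:, end] == pattern).all():
            end += 1
        gapped = tuple(t for t, g in zip(taxa, pattern) if g)
        based = tuple(t for t, g in zip(taxa, pattern) if not g)
        if len(gapped) > len(based) and based:
            events.append(GapEvent("insertion", (col, end), end - col, based))
        else:
            events.append(GapEvent("deletion", (col, end), end - col, gapped))
        col = end
    return events


def detect_csb_d_truncation(
    cr_alignment: Sequence[tuple[str, str]],
    csb_d_hits: dict[str, tuple[int, int]] | None = None,
    motif_library: dict[str, MotifDef] | None = None,
) -> TruncationReport:
    """Measure taxon-shared deletions against complete-CSB-D coordinates.

    ``csb_d_hits`` maps taxa to CSB-D intervals in alignment columns; when
    omitted, each taxon's ungapped sequence is scanned for CSB-D and hits
    are mapped to columns.  The CSB-D column interval is anchored on taxa
    whose hit is gap-free (complete); at least one such taxon is required.
    """
    library = motif_library or default_motif_library()
    if csb_d_hits is None:
        csb_d_hits = {}
        motif = library["CSB-D"]
        for taxon, row in cr_alignment:
            ungapped = row.replace("-", "")
            hit = best_placement(ungapped, motif)
            if hit is None:
                continue
            col_of = [i for i, c in enumerate(row) if c != "-"]
            csb_d_hits[taxon] = (col_of[hit.start], col_of[hit.end - 1] + 1)

    rows = dict(cr_alignment)
    complete = {
        taxon: (s, e) for taxon, (s, e) in csb_d_hits.items()
        if "-" not in rows[taxon][s:e]
    }
    if not complete:
        raise ValueError("no taxon carries a complete CSB-D hit")
    # all complete hits should agree; anchor on the most common interval
    intervals = sorted(complete.values())
    anchor = max(set(intervals), key=intervals.count)

    events = gap_events(cr_alignment)
    deletions = [e for e in events if e.kind == "deletion"]
    insertions = [e for e in events if e.kind == "insertion"]
    return TruncationReport(csb_d_columns=anchor, deletions=deletions,
                            insertions=insertions)


# ---------------------------------------------------------------------------
# reports
# ---------------------------------------------------------------------------

def write_cr_report_json(annotation: ControlRegionAnnotation,
                         path: str | Path) -> None:
    payload = {
        "interval": annotation.interval,
        "not_sequenced": annotation.not_sequenced,
        "library_version": annotation.library_version,
        "hits": [{"name": h.name, "start": h.start, "end": h.end,
                  "mismatches": h.mismatches} for h in annotation.hits],
        "t_homopolymer": annotation.t_homopolymer,
        "domains": annotation.domains,
        "order_violations": annotation.order_violations,
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def write_truncation_tsv(report: TruncationReport, path: str | Path) -> None:
    lines = ["kind\tcol_start\tcol_end\tlength\tcsb_d_overlap\ttaxa"]
    for ev in report.deletions + report.insertions:
        lines.append(f"{ev.kind}\t{ev.columns[0]}\t{ev.columns[1]}\t"
                     f"{ev.length}\t{report.csb_d_overlap(ev)}\t"
                     f"{','.join(ev.taxa)}")
    Path(path).write_text("\n".join(lines) + "\n")
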