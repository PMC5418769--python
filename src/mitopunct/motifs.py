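"""Control-region motif library.

Consensus sequences for the conserved elements of the vertebrate
mitochondrial control region: the termination associated sequence (TAS)
in Domain I, CSB-F/E/D in Domain II and CSB-1/2/3 in Domain III.

Published consensus blocks differ between lineages, so the library is a
plain editable configuration rather than a fixed constant: load your own
with :func:`load_motif_library` (one tab-separated line per motif:
``name  IUPAC-consensus  max_mismatches  domain``).  The defaults below
are teleost-style consensus approximations with the hallmark features of
each block (AT-rich TACAT/ATGTA cores in TAS, the G-box of CSB-E, the
C-runs of CSB-2/3); every report records which library produced it.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

IUPAC = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_IUPAC_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


@dataclass(frozen=True)
class MotifDef:
    """A named IUPAC consensus with a mismatch budget and CR domain."""

    name: str
    consensus: str
    max_mismatches: int
    domain: str  # "I", "II" or "III"

    def __post_init__(self) -> None:
        if not self.consensus:
            raise ValueError(f"motif {self.name}: empty consensus")
        bad = set(self.consensus.upper()) - set(IUPAC)
        if bad:
            raise ValueError(f"motif {self.name}: non-IUPAC symbols {sorted(bad)}")
        if not 0 <= self.max_mismatches < len(self.consensus):
            raise ValueError(
                f"motif {self.name}: max_mismatches must be in [0, len(consensus))"
            )
        if self.domain not in ("I", "II", "III"):
            raise ValueError(f"motif {self.name}: domain must be I, II or III")

    def reverse_complement(self) -> "MotifDef":
        rc = self.consensus.upper().translate(_IUPAC_COMPLEMENT)[::-1]
        return MotifDef(self.name, rc, self.max_mismatches, self.domain)


#: canonical 5'->3' order of CR elements on the heavy strand
MOTIF_ORDER = ("TAS", "CSB-F", "CSB-E", "CSB-D", "CSB-1", "CSB-2", "CSB-3")

DEFAULT_MOTIFS = (
    MotifDef("TAS", "TACATATTATGTATTATCATACAT", 3, "I"),
    MotifDef("CSB-F", "ATGGACTAATGACTAATCAGCCCAT", 3, "II"),
    MotifDef("CSB-E", "AGGGACAATAATTGTGGGGGTTTCAC", 3, "II"),
    MotifDef("CSB-D", "CCTATTACTGGCATCTGGTTCCTACTT", 3, "II"),
    MotifDef("CSB-1", "TTAATGTAGTAAGAGACCACCAACC", 3, "III"),
    MotifDef("CSB-2", "CAAACCCCCCTTACCCCCCG", 2, "III"),
    MotifDef("CSB-3", "TCTTGCCAAACCCCAAAAACAAAG", 3, "III"),
)

DEFAULT_LIBRARY_VERSION = "builtin-teleost-approx-1"


def default_motif_library() -> dict[str, MotifDef]:
    return {m.name: m for m in DEFAULT_MOTIFS}


def load_motif_library(path: str | Path) -> dict[str, MotifDef]:
    """Read a motif config: ``name\\tconsensus\\tmax_mismatches\\tdomain``."""
    lib: dict[str, MotifDef] = {}
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 4:
            raise ValueError(f"motif config line needs 4 tab-separated fields: {raw!r}")
        name, consensus, max_mm, domain = parts
        lib[name] = MotifDef(name, consensus.upper(), int(max_mm), domain)
    return lib


def write_motif_library(lib: Iterable[MotifDef] | dict[str, MotifDef],
                        path: str | Path) -> None:
    motifs = lib.values() if isinstance(lib, dict) else lib
    lines = ["# name\tconsensus\tmax_mismatches\tdomain"]
    lines += [f"{m.name}\t{m.consensus}\t{m.max_mismatches}\t{m.domain}"
              for m in motifs]
    Path(path).write_text("\n".join(lines) + "\n")
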