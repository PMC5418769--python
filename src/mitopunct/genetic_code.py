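"""Vertebrate mitochondrial genetic code (NCBI translation table 2).

Constants and small helpers shared across annotation and comparative
modules.  Under this code AGA and AGG are stop codons (not arginine) and
both ATG and GTG serve as initiation codons, which is what produces the
GTG starts and AGG stops seen in fish mitogenomes.
"""

from __future__ import annotations

from Bio.Seq import Seq

#: translation table id for the vertebrate mitochondrial code
TABLE_ID = 2

START_CODONS = frozenset({"ATG", "GTG"})
STOP_CODONS = frozenset({"TAA", "TAG", "AGA", "AGG"})

_BASES = "TCAG"
ALL_CODONS = tuple(a + b + c for a in _BASES for b in _BASES for c in _BASES)
#: codons that encode an amino acid under table 2
SENSE_CODONS = tuple(c for c in ALL_CODONS if c not in STOP_CODONS)

_COMPLEMENT = str.maketrans("ACGTNacgtn-", "TGCANtgcan-")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def translate(nt: str) -> str:
    """Translate ``nt`` (full codons only) under table 2; stops become '*'."""
    usable = len(nt) - len(nt) % 3
    return str(Seq(nt[:usable]).translate(table=TABLE_ID))


def is_stop(codon: str) -> bool:
    return codon.upper() in STOP_CODONS
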