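"""Annotation transfer and codon auditing for reconstructed mitogenomes.

Because the scaffold is built in reference coordinates, reference features
project directly onto it; completeness is decided by the N content of the
projected span (complete / partial / not_sequenced).  Start and stop
codons of protein-coding genes are classified under the vertebrate
mitochondrial code, including the incomplete stops T-- and TA- completed
by polyadenylation at tRNA punctuation boundaries, AGA/AGG stops, and
premature in-frame stops such as the penultimate-codon cob stop of some
lineages.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from mitopunct import genetic_code
from mitopunct.synthetic import (
    CANONICAL_GENE_ORDER,
    PCGS,
    RRNAS,
    TRNAS,
    Feature,
    feature_kind,
)


class MissingFeatureError(ValueError):
    def __init__(self, names: Sequence[str]):
        self.names = list(names)
        super().__init__(f"reference lacks canonical features: {self.names}")


class FrameshiftError(ValueError):
    """In-frame stop too early in the gene to be a stop-codon variant."""


@dataclass(frozen=True)
class GeneFeature:
    name: str
    kind: str  # PCG | rRNA | tRNA | CR | origin
    strand: str
    start: int  # 0-based half-open on the scaffold
    end: int
    completeness: str  # complete | partial | not_sequenced


@dataclass(frozen=True)
class CodonReport:
    feature: str
    start_codon: str
    stop_class: str  # e.g. "complete:TAA", "incomplete:T--"
    premature_stop: tuple[int, str] | None = None
    start_ambiguous: bool = False


def _completeness(segment: str) -> str:
    if not segment or all(c == "N" for c in segment):
        return "not_sequenced"
    if "N" in segment:
        return "partial"
    return "complete"


def transfer_annotations(
    scaffold_seq: str,
    reference_features: Sequence[Feature],
    reference_seq: str | None = None,
    refine_window: int = 6,
) -> list[GeneFeature]:
    """Project reference features onto the scaffold.

    A span that is entirely N becomes ``not_sequenced``; a mixture of N and
    bases ``partial``; no N ``complete``.  When the reference sequence is
    supplied, each boundary pair is refined within ``±refine_window`` nt to
    the offset maximising identity with the reference ortholog (offset 0
    preferred on ties), guarding against off-by-codon transfers.
    """
    names = {f.name for f in reference_features}
    missing = sorted((PCGS | RRNAS | TRNAS | {"CR"}) - names)
    if missing:
        raise MissingFeatureError(missing)

    out: list[GeneFeature] = []
    for f in reference_features:
        start, end = f.start, f.end
        if reference_seq is not None and refine_window > 0:
            start, end = _refine_span(scaffold_seq, reference_seq, f,
                                      refine_window)
        segment = scaffold_seq[start:end]
        out.append(GeneFeature(
            name=f.name, kind=feature_kind(f.name), strand=f.strand,
            start=start, end=end, completeness=_completeness(segment)))
    return out


def _refine_span(scaffold_seq: str, reference_seq: str, f: Feature,
                 window: int) -> tuple[int, int]:
    ref_gene = reference_seq[f.start:f.end]
    best = (f.start, f.end)
    best_key = None
    for off in sorted(range(-window, window + 1), key=lambda o: (abs(o), o)):
        s, e = f.start + off, f.end + off
        if s < 0 or e > len(scaffold_seq):
            continue
        seg = scaffold_seq[s:e]
        matched = sum(1 for a, b in zip(seg, ref_gene) if a == b and a != "N")
        if best_key is None or matched > best_key:
            best_key = matched
            best = (s, e)
    return best


# ---------------------------------------------------------------------------
# codon classification
# ---------------------------------------------------------------------------

def classify_codons(
    feature: GeneFeature | Feature,
    scaffold_seq: str,
    reference_start_codon: str | None = None,
) -> CodonReport:
    """Classify start and stop codons of a complete protein-coding gene.

    Stop classes: a table-2 stop as the final full codon is ``complete:<codon>``;
    a 1-nt remainder ending in T is ``incomplete:T--``; a 2-nt remainder
    ending in TA is ``incomplete:TA-`` (both completed to UAA by
    polyadenylation).  An in-frame stop before the final codon is reported
    as a premature stop, unless it occurs in the first half of the gene, in
    which case a :class:`FrameshiftError` is raised.  When an ATG
    immediately precedes an aligned GTG start, the upstream ATG is
    preferred and the ambiguity recorded.
    """
    if getattr(feature, "kind", "PCG") != "PCG":
        raise ValueError(f"{feature.name} is not a protein-coding gene")
    seq = scaffold_seq[feature.start:feature.end].upper()
    if feature.strand == "-":
        seq = genetic_code.reverse_complement(seq)
    if "N" in seq:
        raise ValueError(f"{feature.name} is not completely sequenced")

    start_codon = seq[:3]
    start_ambiguous = False
    if start_codon == "GTG" and reference_start_codon == "ATG" \
            and feature.start >= 3:
        upstream = scaffold_seq[feature.start - 3:feature.start].upper()
        if feature.strand == "+" and upstream == "ATG":
            start_ambiguous = True

    rem = len(seq) % 3
    codons = [seq[i:i + 3] for i in range(0, len(seq) - rem - 2, 3)]
    final = codons[-1]
    if rem == 0 and genetic_code.is_stop(final):
        stop_class = f"complete:{final}"
        coding_codons = codons[:-1]
    elif rem == 1 and seq.endswith("T"):
        stop_class = "incomplete:T--"
        coding_codons = codons
    elif rem == 2 and seq.endswith("TA"):
        stop_class = "incomplete:TA-"
        coding_codons = codons
    else:
        stop_class = "unclassified"
        coding_codons = codons

    premature = None
    for i, codon in enumerate(coding_codons[1:], start=1):
        if genetic_code.is_stop(codon):
            if i < len(coding_codons) / 2:
                raise FrameshiftError(
                    f"{feature.name}: in-frame stop {codon} at codon {i} "
                    f"({i / len(coding_codons):.0%} of gene) suggests a "
                    f"frameshift")
            premature = (i, codon)
            break
    return CodonReport(feature=feature.name, start_codon=start_codon,
                       stop_class=stop_class, premature_stop=premature,
                       start_ambiguous=start_ambiguous)


# ---------------------------------------------------------------------------
# gene order verification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OrderDeviation:
    kind: str  # swap | misplaced | strand | missing | junction
    names: tuple[str, ...]
    detail: str


#: canonical head-to-tail junctions with no intervening nucleotides
TIGHT_JUNCTIONS = (("atp8", "atp6"), ("atp6", "cox3"), ("nad4l", "nad4"))


def verify_gene_order(
    features: Sequence[GeneFeature | Feature],
    canonical: Sequence[tuple[str, str]] = CANONICAL_GENE_ORDER,
) -> list[OrderDeviation]:
    """Deviations from the canonical vertebrate gene arrangement.

    Reports missing features, strand flips, pairwise swaps and other
    misplacements, plus disruptions of the canonical head-to-tail
    junctions (atp8-atp6, atp6-cox3, nad4l-nad4) by inserted sequence.
    An empty list means order and strands are canonical.
    """
    deviations: list[OrderDeviation] = []
    ordered = sorted(features, key=lambda f: f.start)
    observed_names = [f.name for f in ordered]
    canonical_names = [n for n, _ in canonical]
    canonical_strand = dict(canonical)

    for name in canonical_names:
        if name not in observed_names:
            deviations.append(OrderDeviation(
                "missing", (name,), f"{name} absent from annotation"))
    present_canonical = [n for n in canonical_names if n in observed_names]
    observed_known = [n for n in observed_names if n in canonical_strand]

    exp_idx = {n: i for i, n in enumerate(present_canonical)}
    obs_idx = {n: i for i, n in enumerate(observed_known)}
    displaced = [n for n in present_canonical if exp_idx[n] != obs_idx[n]]
    reported: set[str] = set()
    for n in displaced:
        if n in reported:
            continue
        partner = next(
            (m for m in displaced
             if m != n and exp_idx[m] == obs_idx[n] and exp_idx[n] == obs_idx[m]),
            None)
        if partner is not None:
            deviations.append(OrderDeviation(
                "swap", (n, partner),
                f"{n} and {partner} exchange positions"))
            reported.update({n, partner})
        else:
            deviations.append(OrderDeviation(
                "misplaced", (n,),
                f"{n} at rank {obs_idx[n]}, expected {exp_idx[n]}"))
            reported.add(n)

    for f in ordered:
        expect = canonical_strand.get(f.name)
        if expect is not None and f.strand != expect:
            deviations.append(OrderDeviation(
                "strand", (f.name,),
                f"{f.name} on {f.strand} strand, expected {expect}"))

    by_name = {f.name: f for f in ordered}
    for a, b in TIGHT_JUNCTIONS:
        fa, fb = by_name.get(a), by_name.get(b)
        if fa is None or fb is None:
            continue
        gap = fb.start - fa.end
        if gap > 0:
            deviations.append(OrderDeviation(
                "junction", (a, b),
                f"{a}–{b} disrupted, {gap}-nt insert"))
    return deviations


# ---------------------------------------------------------------------------
# tables
# ---------------------------------------------------------------------------

def nucleotide_frequencies(seq: str) -> dict[str, float]:
    """A/C/G/T fractions over non-N positions; empty dict if no bases."""
    seq = seq.upper()
    total = sum(seq.count(b) for b in "ACGT")
    if total == 0:
        return {}
    return {b: seq.count(b) / total for b in "ACGT"}


def gene_tables(
    features: Sequence[GeneFeature],
    scaffold_seq: str,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Per-feature summary table and genome-wide nucleotide frequencies.

    The table has one row per feature (length, completeness, and the codon
    report for complete PCGs).  The frequency dict is empty — an explicit
    degenerate-input flag — when the scaffold has no called bases.
    """
    rows = []
    for f in sorted(features, key=lambda x: x.start):
        row = {"name": f.name, "kind": f.kind, "strand": f.strand,
               "start": f.start, "end": f.end, "length": f.end - f.start,
               "completeness": f.completeness,
               "start_codon": None, "stop_class": None}
        if f.kind == "PCG" and f.completeness == "complete":
            report = classify_codons(f, scaffold_seq)
            row["start_codon"] = report.start_codon
            row["stop_class"] = report.stop_class
        rows.append(row)
    return pd.DataFrame(rows), nucleotide_frequencies(scaffold_seq)


def mterf_segment_completeness(
    scaffold_seq: str,
    features: Sequence[GeneFeature],
    segment_offset: int,
    segment_length: int,
) -> str:
    """Completeness of the mTERF-binding segment inside tRNA-Leu2.

    The segment is supplied as an offset/length within trnL2 (its sequence
    is lineage-configurable and not hard-coded here).  Returns complete /
    partial / not_sequenced.
    """
    trnl2 = next((f for f in features if f.name == "trnL2"), None)
    if trnl2 is None:
        raise MissingFeatureError(["trnL2"])
    s = trnl2.start + segment_offset
    e = min(s + segment_length, trnl2.end)
    return _completeness(scaffold_seq[s:e])


# ---------------------------------------------------------------------------
# GenBank-facing I/O (1-based inclusive coordinates)
# ---------------------------------------------------------------------------

def write_feature_tsv(features: Sequence[GeneFeature], path: str | Path) -> None:
    lines = ["name\tkind\tstrand\tstart\tend\tcompleteness"]
    for f in sorted(features, key=lambda x: x.start):
        lines.append(f"{f.name}\t{f.kind}\t{f.strand}\t{f.start}\t{f.end}\t"
                     f"{f.completeness}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_codon_report_json(reports: Sequence[CodonReport],
                            path: str | Path) -> None:
    payload = [{"feature": r.feature, "start_codon": r.start_codon,
                "stop_class": r.stop_class,
                "premature_stop": r.premature_stop,
                "start_ambiguous": r.start_ambiguous}
               for r in reports]
    Path(path).write_text(json.dumps(payload, indent=1))


def read_genbank_features(path: str | Path) -> tuple[str, list[Feature]]:
    """Read a GenBank flat file into (sequence, features).

    Feature names are normalised to the package's canonical vocabulary
    where recognisable (gene/product qualifiers); coordinates convert from
    1-based inclusive to 0-based half-open.
    """
    from Bio import SeqIO

    record = SeqIO.read(str(path), "genbank")
    features: list[Feature] = []
    for feat in record.features:
        if feat.type not in ("gene", "CDS", "rRNA", "tRNA", "D-loop",
                             "rep_origin"):
            continue
        if feat.type == "gene":
            continue  # CDS/rRNA/tRNA carry the usable qualifiers
        name = _normalise_name(feat)
        if name is None:
            continue
        strand = "-" if feat.location.strand == -1 else "+"
        features.append(Feature(name, int(feat.location.start),
                                int(feat.location.end), strand))
    # keep first occurrence per name
    seen: set[str] = set()
    unique = []
    for f in sorted(features, key=lambda x: x.start):
        if f.name not in seen:
            unique.append(f)
            seen.add(f.name)
    return str(record.seq).upper(), unique


_PRODUCT_ALIASES = {
    "12s ribosomal rna": "rrnS", "16s ribosomal rna": "rrnL",
    "s-rrna": "rrnS", "l-rrna": "rrnL",
}
_TRNA_BY_AA = {
    "phe": "trnF", "val": "trnV", "ile": "trnI", "gln": "trnQ", "met": "trnM",
    "trp": "trnW", "ala": "trnA", "asn": "trnN", "cys": "trnC", "tyr": "trnY",
    "asp": "trnD", "lys": "trnK", "gly": "trnG", "arg": "trnR", "his": "trnH",
    "glu": "trnE", "thr": "trnT", "pro": "trnP",
}
_GENE_ALIASES = {
    "coi": "cox1", "coii": "cox2", "coiii": "cox3", "co1": "cox1",
    "co2": "cox2", "co3": "cox3", "cytb": "cob", "cob": "cob",
    "nd1": "nad1", "nd2": "nad2", "nd3": "nad3", "nd4": "nad4",
    "nd4l": "nad4l", "nd5": "nad5", "nd6": "nad6",
    "atp6": "atp6", "atp8": "atp8", "atpase6": "atp6", "atpase8": "atp8",
}


def _normalise_name(feat) -> str | None:
    if feat.type == "D-loop":
        return "CR"
    if feat.type == "rep_origin":
        return "OL"
    gene = (feat.qualifiers.get("gene", [None])[0] or "").lower()
    product = (feat.qualifiers.get("product", [None])[0] or "").lower()
    if feat.type == "rRNA":
        return _PRODUCT_ALIASES.get(product) or _PRODUCT_ALIASES.get(gene)
    if feat.type == "tRNA":
        for aa, name in _TRNA_BY_AA.items():
            if aa in product:
                return name
        if "leu" in product:
            return "trnL2" if "uur" in product or "taa" in product else "trnL1"
        if "ser" in product:
            return "trnS2" if "ucn" in product or "tga" in product else "trnS1"
        return None
    name = gene.replace(" ", "")
    if name in PCGS:
        return name
    return _GENE_ALIASES.get(name)
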