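#!/usr/bin/env python
"""Regression checks against published mitogenome deposits.

Runs the annotation and comparative pipeline on a directory of GenBank
flat files (fetched separately, e.g. with NCBI efetch) and prints the
quantities that published loricariid mitogenomes are known for: per-gene
lengths (cox1, cob, nad6, atp8), the atp6-cox3 junction insertion in
Corydoras, CSB-D truncation status, pairwise nucleotide identity extremes
and cox1 amino-acid conservation.

Usage:
    python scripts/regression_accessions.py --genomes genbank_dir/ \
        [--pni-pair KX087182 KX087183]
"""

from __future__ import annotations

import argparse
from pathlib import Path

from mitopunct import annotate, compara, crscan
from mitopunct.synthetic import PCGS, RRNAS


def load_genomes(directory: Path) -> list[compara.AnnotatedGenome]:
    genomes = []
    for path in sorted(directory.glob("*.gb")) + sorted(directory.glob("*.gbk")):
        seq, features = annotate.read_genbank_features(path)
        genomes.append(compara.AnnotatedGenome(path.stem, seq, features))
    if not genomes:
        raise SystemExit(f"no GenBank files (*.gb, *.gbk) in {directory}")
    return genomes


def gene_length_table(genomes) -> None:
    print("\n== gene lengths (nt) ==")
    for gene in ("cox1", "cob", "nad6", "atp8"):
        lengths = {}
        for g in genomes:
            feat = next((f for f in g.features if f.name == gene), None)
            if feat:
                lengths.setdefault(feat.end - feat.start, []).append(g.taxon)
        for length, taxa in sorted(lengths.items()):
            print(f"{gene}\t{length}\t{len(taxa)} taxa\t{','.join(taxa[:4])}"
                  + ("..." if len(taxa) > 4 else ""))


def junction_insertions(genomes) -> None:
    print("\n== atp6-cox3 junction ==")
    for g in genomes:
        devs = annotate.verify_gene_order(g.features)
        for d in devs:
            if d.kind == "junction" and d.names == ("atp6", "cox3"):
                print(f"{g.taxon}\t{d.detail}")


def csb_d_status(genomes) -> None:
    print("\n== CSB-D status per control region ==")
    for g in genomes:
        try:
            s, e, flag = crscan.locate_control_region(g.features, g.sequence)
        except crscan.MissingFlankError:
            print(f"{g.taxon}\tCR flanks not annotated")
            continue
        if flag:
            print(f"{g.taxon}\tCR not sequenced")
            continue
        ann = crscan.annotate_control_region(g.sequence[s:e])
        hit = next((h for h in ann.hits if h.name == "CSB-D"), None)
        print(f"{g.taxon}\tCSB-D "
              + (f"found ({hit.mismatches} mm)" if hit else "absent/truncated"))


def supermatrix_and_pni(genomes, pni_pairs) -> None:
    alignments = []
    cox1_protein = None
    for gene in sorted(PCGS) + sorted(RRNAS):
        try:
            orth = compara.extract_orthologs(genomes, gene)
        except ValueError:
            continue
        mode = "codon-aware" if gene in PCGS else "nucleotide"
        try:
            aln = compara.align_gene([(t, s) for t, s, _ in orth], mode, gene)
        except compara.InternalStopError as exc:
            print(f"skipping {gene}: {exc}")
            continue
        alignments.append(aln)
        if gene == "cox1":
            cox1_protein = aln.protein_rows
    sm = compara.concatenate(alignments)
    print(f"\n== supermatrix: {len(sm.taxa)} taxa x {sm.width} columns ==")
    pni = compara.pairwise_nucleotide_identity(sm)
    import numpy as np
    off = pni.values[~np.eye(len(sm.taxa), dtype=bool)]
    finite = off[np.isfinite(off)]
    print(f"PNI range: {finite.min():.1f} .. {finite.max():.1f}")
    for a, b in pni_pairs:
        if a in pni.taxa and b in pni.taxa:
            print(f"PNI {a} vs {b}: {pni[(a, b)]:.1f}")
    if cox1_protein:
        pct = compara.invariable_amino_acid_percent(cox1_protein)
        print(f"cox1 invariable amino acids: {pct}%")


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--genomes", type=Path, required=True,
                        help="directory of annotated GenBank flat files")
    parser.add_argument("--pni-pair", nargs=2, action="append", default=[],
                        metavar=("TAXON_A", "TAXON_B"),
                        help="report PNI for this taxon pair (repeatable)")
    args = parser.parse_args()
    genomes = load_genomes(args.genomes)
    print(f"loaded {len(genomes)} genomes")
    gene_length_table(genomes)
    junction_insertions(genomes)
    csb_d_status(genomes)
    supermatrix_and_pni(genomes, args.pni_pair)


if __name__ == "__main__":
    main()
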