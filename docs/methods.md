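# Methods

## The reconstruction model

The package targets the situation where a vertebrate mitochondrial genome
is reconstructed not from genomic reads but from transcriptome assembly
contigs. Because the mitochondrial genome is transcribed as a polycistron
that is processed by excision of the interspersed tRNAs (the punctuation
model), transcript contigs correspond to mRNA/rRNA units: the two rRNAs,
eleven monocistronic mRNAs, and the two bicistronic messages nad4l/nad4
and atp8/atp6. Two processing boundaries have no tRNA — the atp6|cox3
junction and the heavy/light strand switch at nad5|nad6 — and are treated
as cleavage sites, which is why exactly those two bicistronic units
remain. Consequences the pipeline is built around:

- contigs tile the coding portion of the genome and stop at tRNA
  boundaries, so a merged scaffold has N-gaps at tRNAs, the light-strand
  replication origin, and (partially) the control region;
- the scaffold lives in the reference coordinate system, making
  annotation transfer a projection rather than a search;
- per-position read depth is an expression readout: cytochrome c oxidase
  transcripts deepest, tRNAs and non-transcribed elements shallowest,
  with near-zero depth change inside a bicistronic unit.

## Scaffolding

Contigs are placed with exact infix edit-distance alignment (edlib) of
each contig against the reference, in both orientations. Each alignment
path is rescored with match +1, mismatch −2, gap open −5, gap extension
−2; identity is matches over alignment columns. Defaults `min_identity`
80% and `min_length` 100 nt separate mitochondrial from nuclear contigs —
random-sequence alignments sit far below 80% identity at these lengths
(verified empirically in the tests). Where overlapping placements
disagree on at most 20% of shared positions the higher-scoring contig
wins (ties: longer contig, then lexicographic id) and every conflicting
position is logged; above 20% the merge aborts, since that indicates a
mis-captured contig rather than allelic noise. End trimming walks windows
(default 20 nt) inward from each end and masks windows whose identity to
the reference falls below 70%, passing over all-N gaps; this mirrors the
manual removal of poorly aligned terminal bases in reference-guided
assemblies. Coverage is 100 × non-N/length, rounded to 0.1.

Coordinates are 0-based half-open internally; GenBank-facing I/O is
1-based inclusive.

## Annotation and codon classes

Completeness is decided purely by N-content of the projected span
(complete / partial / not_sequenced) — tRNA structure is not validated.
Boundaries can be refined by ±6 nt against the reference ortholog to
avoid off-by-codon transfers (offset 0 preferred on ties). The genetic
code is fixed to the vertebrate mitochondrial table: starts {ATG, GTG},
stops {TAA, TAG, AGA, AGG}. Stop classes follow the length remainder of
the gene: a final full stop codon is `complete:<codon>`; a 1-nt remainder
ending in T is `incomplete:T--`; a 2-nt remainder ending in TA is
`incomplete:TA-`. An in-frame stop before the final codon is reported as
a premature stop when it falls in the second half of the gene (the
biologically observed case is a stop at the penultimate codon of cob in
some lineages); earlier in-frame stops raise a frameshift error, since a
real stop that early would abolish the protein. When a GTG start has an
ATG immediately upstream, the report flags the ambiguity rather than
choosing silently. Gene-order verification reports missing features,
strand flips, pairwise swaps and disruptions of the tight head-to-tail
junctions (atp8–atp6, atp6–cox3, nad4l–nad4) with the insert length.

## Depth and heteroplasmy

Base counts tally aligned read bases per reference position; deletions,
reference skips and N calls contribute nothing, and indel alleles are
never counted. Medians are taken over positions with non-zero coverage;
the even-count median is the midpoint of the two central values. The
heteroplasmy caller applies three conditions with strict inequalities:
(1) more than one nucleotide observed; (2) depth > `min_depth`
(default 100); (3) second-most-frequent base frequency > `min_minor_freq`
(default 0.10), with the denominator being the sum of A/C/G/T counts at
the position. Frequency comparisons use exact rational arithmetic
(`Fraction`), so a site at exactly the threshold is never called and the
result cannot depend on floating-point representation. The ≥10-read
minor-allele support at any called site is a consequence of the two
thresholds, not a fourth condition; `scripts/acceptance.py` recomputes it
by exhaustive enumeration (the true minimum is 11 reads, at depth 101).
Tri-allelic sites are called on the second most frequent base and
flagged when a third base also clears the frequency bar. No duplicate-read
or mapping-quality filtering is applied before counting (configurable
upstream; the SAM parser is the ingestion boundary).

## Control region

The CR is located between tRNA-Pro and tRNA-Phe (wrapping supported for
circular input). Motif scanning is IUPAC-aware minimal-mismatch Hamming
placement, leftmost on ties, with per-motif mismatch budgets; a motif
whose best placement exceeds its budget is reported absent. Domains are
operational: Domain I = CR start to TAS end, Domain II = TAS end to CSB-D
end, Domain III = remainder. The motif library is an editable plain-text
configuration (name, IUPAC consensus, max mismatches, domain) because
published CSB consensus sequences are lineage-dependent; the shipped
defaults are teleost-style approximations carrying the hallmark features
of each block (AT-rich TACAT/ATGTA cores in TAS, the G-box of CSB-E, the
C-runs of CSB-2/3), and every report records the library version so
results are auditable against the library that produced them.

Truncation detection operates on a supplied multi-taxon CR alignment.
Maximal column runs with an identical gap pattern become events; when the
gapped taxa are the majority, the event is an insertion carried by the
base-bearing minority, otherwise a deletion carried by the gapped taxa
(ties are deletions). Deletions are measured against the CSB-D column
interval anchored on taxa with a gap-free CSB-D hit, yielding per-event
length and CSB-D overlap — the geometry of the clade-specific ~60-nt
deletion that removes the last 7 nt of CSB-D in some hypostomine
control regions.

## Comparative analysis

Protein-coding genes are aligned codon-aware: translate (vertebrate
mitochondrial code; incomplete-stop remainders set aside), align the
proteins, back-map every protein gap to a 3-nt gap, then re-append the
remainders padded to a common width. Ungapping any aligned row always
reproduces its input exactly. The default engine is deterministic:
pairwise global Needleman–Wunsch (BLOSUM62, gap open −10, extend −1, via
biopython's PairwiseAligner) merged progressively around the first input
sequence (center-star; insertions at the same center slot are
left-aligned). A different engine (e.g. MUSCLE/MAFFT) can be substituted
where matching an external study's exact column counts matters — aligned
column counts such as a concatenated supermatrix length are
engine-sensitive and are deliberately not treated as contracts.

The supermatrix records a partition map (gene → column interval);
missing taxon/gene blocks are N, and partitions must tile the columns
exactly (asserted per construction). PNI uses pairwise deletion: only
columns where both rows carry A/C/G/T are compared, reported to 0.1
percentage point with the per-cell comparison count retained so that the
denominator convention is auditable. Amino-acid conservation is the
percentage of columns whose non-gap residues are identical with at least
half the taxa present, rounded to integer percent. Tree inference is
exported (relaxed PHYLIP + RAxML-style partition file), never computed.

## Synthetic data: what it emulates, and what it does not

The generator builds a linear toy genome in the canonical vertebrate
order (linearized at tRNA-Phe, control region last, matching deposition
convention): 13 PCGs, 2 rRNAs, 22 tRNAs, OL and CR, with no intergenic
spacers. PCGs are sampled from in-frame sense codons, so they translate
cleanly; stop classes follow gene length (cox1 1551 nt with a GTG start,
cob 1138 nt ending T--, atp8 168 nt, nad6 522 nt on the light strand —
length classes typical of loricariid deposits). CR motifs are embedded
verbatim from the motif library with random spacers whose T-runs are
capped, so motif scans and T-homopolymer detection are exact by
construction. Pileups draw per-position depth binomially around
per-feature tiers (defaults cox 1000 / other mRNA-rRNA 300 / tRNA and
non-transcribed 40, default 200 — magnitudes are free parameters, only
the ranks are meaningful) with a uniform substitution-error channel
(default rate 0.001) and exact configured depth at planted heteroplasmic
sites. Cohorts diverge by stop-avoiding random substitutions.

Passing tests on this generator demonstrate algorithmic correctness —
coordinate bookkeeping, threshold logic, alignment algebra — under known
truth. They do not demonstrate robustness to real-data phenomena the
generator deliberately omits: quality-dependent and indel sequencing
errors, chimeric or misassembled contigs, NUMT contamination, uneven
within-gene coverage, RNA editing, or genuinely divergent motif variants.
The accession-based regression script (`scripts/regression_accessions.py`)
exists to run the same pipeline on real GenBank deposits when they are
available on disk.

## Numerical conventions and degenerate inputs

- Strict inequalities throughout the heteroplasmy caller; exact rational
  frequency comparison.
- Rounding: coverage and PNI to 0.1; conservation to integer percent.
- Ties: leftmost motif placement; alphabetical base order for equal
  counts; higher score, then longer contig, then smaller id for scaffold
  conflicts; offset 0 for boundary refinement.
- Degenerate inputs: all-N scaffolds annotate as not_sequenced with an
  empty nucleotide-frequency table; a zero-length CR is a valid interval;
  an empty contig set, empty reference, or gene absent from every genome
  raise informative errors; trimming windows larger than the scaffold
  evaluate the whole sequence.
- All randomness flows through explicit integer seeds
  (`numpy.random.default_rng`); same seed, same bytes.

## Problem sizes

The test suite runs the full pipeline on 20 seeded ~16-kb cohorts, the
heteroplasmy caller against a literal three-condition oracle on 100
seeded profiles, truncation measurement on 100 seeded CR alignments, and
supermatrix/PNI algebra up to 50 taxa × 2 kb; the whole suite completes
in a few seconds on one CPU.
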