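# Methods

## The inference

A stop-codon reassignment leaves a quantitative fingerprint in translated
similarity searches. Let a transcript be translated under the standard code
(NCBI table 1) and under a candidate alternative table, and let each
translation be aligned locally against a conserved reference protein. Where
the transcript uses a reassigned codon, the standard translation shows `*`
(scored −4 against every residue in the extended BLOSUM62 convention,
+1 against `*`), while the alternative translation shows the reassigned
amino acid, which scores positively — often as an identity — against the
homologous position. The package operationalises this in three tiers:

1. **Stop counting** — in-frame standard-code stops inside the best
   alignment's span (stops outside the span are tallied separately, since
   local alignment says nothing about them).
2. **Score-delta classification** — a transcript is *improved* under a
   table iff identities **or** positives are strictly greater than under
   table 1. With the UGA=Trp table (4) and the UAR=Gln table (6) this gives
   five labels: `equal`, `improved_UGA_only`, `improved_UAR_only`,
   `improved_both`, `no_hit`. Each table is realigned independently — the
   alternative translation may extend further or gap differently — rather
   than rescoring a frozen alignment.
3. **Residue tabulation** — for every stop codon inside the best
   alignment's span, the subject residue across from it. A true
   reassignment produces a strongly modal profile (Gln for UAA/UAG, Trp for
   UGA); chance in-frame stops produce a flat one. Gap-aligned occurrences
   are counted separately and excluded from the frequencies.

No single NCBI table encodes UAR=Gln *and* UGA=Trp simultaneously (such a
table would have no stop codon), so a genome using both reassignments shows
`improved_both` transcripts and the all-table ranking (best table by
positives, ties to the lower table id) concentrates on table 6, whose
recoded codons are the more frequent.

## Alignment engine

Exact Smith–Waterman with affine gaps (cost `open + k·extend` for a gap of
length k; defaults 11/1, matching translated-search conventions), BLOSUM62
with the extended `B/Z/X/*` columns taken from Biopython's matrix data.
`*` is a first-class symbol so standard-code translations containing stops
remain alignable — this is what makes per-code score deltas well defined.
The DP is numba-compiled; traceback tie-breaks are fixed
(diagonal > up > left; the traceback starts at the first maximal cell in
row-major order), so alignments are deterministic. E-values are
Karlin–Altschul `K·m·n·exp(−λS)` with fixed gapped-BLOSUM62 constants
(λ = 0.267 nats, K = 0.041) and no length correction; they are used only as
filters (default hit cutoff 1e-10), never reported as statistics.

Scanning every reference for every frame and table is exact but quadratic,
so `compare_codes` prescreens candidates by shared protein 4-mers (top 5
references with ≥ 2 shared k-mers per frame by default). Small databases,
or `prescreen_top=None`, fall back to the exhaustive scan. The prescreen is
a candidate filter above the aligner; the aligner itself performs no
seeding or X-dropoff heuristics and always extends through `*` columns.

## Terminal stops and context

A transcript is called a **complete ORF** when (a) its alignment ends
within `tol_subject_aa` (default 10) residues of the subject's end and
(b) the first in-frame standard-code stop at or after the alignment end
lies within `tol_downstream_codons` (default 10) codons. "Similar position"
is not quantified in the underlying methodology, so these two explicit
tolerances make it testable; completeness is monotone in both. The scan
uses, among the per-table best hits, the alignment reaching furthest along
the subject: a reassigned codon at the very end of the CDS is read as `*`
by the tables that do not recode it and trimmed from their alignments, and
scanning from the most 3'-extending alignment prevents that codon from
masquerading as the terminal stop. Terminal-stop surveys are intended for
highly conserved hits (the very-low-e-value stratum); at high divergence a
trimmed tail can still expose a coding UAR codon, which is a property of
the data, not a calling bug.

Coding-UGA position is summarised as (subject coordinate aligned to the
most 3' UGA) / (subject length), in (0, 1]; genuine coding UGA shows a 5'
bias while terminal UGA sits at 1.

**Context windows** are 5 nt upstream + codon + 12 nt downstream (20 nt,
never padded — windows overrunning an end are skipped and counted). The
two-sample logo statistic is a per-position, per-base two-sample t-test on
0/1 base-presence indicators (pooled variance by default, Welch optional);
group means are base frequencies, the reported difference is
freq_A − freq_B, and no multiple-testing correction is applied (α = 0.05 on
raw p-values, matching the two-sample-logo methodology; with 68 cells,
~3–4 significant cells are expected under the null). Minimum group size
is 20. Masking of low-abundance cells is left to the user (off by
default).

## Codon usage

RSCU follows the standard definition `X_ij · n_i / Σ_j X_ij` with families
defined by the chosen table (default: ciliate table 6, under which
glutamine is the four-codon family CAA/CAG/UAA/UAG summing to 4).
Zero-count families are reported as undefined, never 0. Third-position
statistics (A3s/T3s/C3s/G3s, GC3s = G3s + C3s) are base frequencies at
third positions of codons in multi-codon families, stop codons and
single-codon families (ATG; TGG under table 6) excluded; all four
fractions share one denominator. Bulk usage extracts the longest
stop-to-stop ORF per transcript in any frame under table 6 (minimum 100
codons by default, start codons ignored), and transcripts with detected
coding UGA can be excluded — UGA's contingent nature otherwise deflates the
apparent UAR usage.

## tRNA inventory

"Decoding" means exact Watson–Crick reverse complement of the anticodon;
wobble is deliberately not modelled, so missing exact decoders are
*reported* as gaps and interpreted by the user (wobble reading of U-ending
codons by G-starting anticodons is the usual explanation). Filtering keeps
records passing a coverage threshold (default 10, applied only where
coverage is annotated), an optional contaminant-contig exclusion list, and
a pseudogene drop. The selenocysteine tRNA (anticodon TCA) is retained and
flagged. Minus-strand genes keep the begin > end coordinate convention of
tRNAscan-SE with a derived strand field.

## Editing detection

Organellar dinoflagellate-style editing is substitutional, so the model is
ungapped: exact 31-mer seeding on both strands of each contig, ungapped
extension over the transcript's full span, best placement by identity,
rejection below 90% identity (an indel shifts the register and collapses
identity, aborting the window with a warning rather than force-aligning).
All reporting is in mRNA sense — genome bases are complemented for
minus-strand placements, so an A→G edit reads as A→G on either strand.
Planted-edit recovery is exact for substitution-only data at any density
within the identity threshold.

## Partitioning and reference-set selection

AT content is (A+T)/(A+T+G+C), ambiguous bases excluded from both numerator
and denominator (a documented choice; the underlying method is silent on
ambiguity). The host/parasite partition threshold is 58% AT, boundary
inclusive on the high side. Spliced-leader detection requires the motif
(default CTCAAG, the 3' end of the dinoflagellate spliced leader) to start
within the first 30 bases. The UGA-as-stop reference set intersects five
criteria: best-hit e-value below a cutoff (default 1e-100), AT ≥ 58%, no
improvement under alternative tables, one longest representative per
assembly graph component, and absence from a caller-supplied exclusion list
(the generalisation of a host-chloroplast BLASTn screen, since no host data
ships with the package). Selection is monotone: tightening any criterion
never adds members.

## Synthetic data

The generator emulates the statistical structure the inference assumes,
not sequence evolution:

* **Reference proteome** — iid residues at average proteome frequencies
  (Trp ≈ 1.1%, Gln ≈ 3.9%), lengths normal (mean 150, sd 40, min 50).
* **Parasite-like transcripts** (defaults) — each transcript takes a
  reference protein, substitutes residues independently at the divergence
  rate (0.2; a uniform substitution model without rate heterogeneity —
  enough to stress the aligner, not a model of evolution), and
  back-translates the mutated copy under the *contingent* code: ciliate
  families with P(TAA|Q) = 0.25, P(TAG|Q) = 0.10, the remaining glutamine
  mass on CAA/CAG, and P(TGA|W) = 0.30 against TGG. Within every other
  family the A/T-ending codons share probability `at3_bias` (default 0.75)
  so the synonymous third-position A+T fraction is exact by construction.
  UTRs (5': 30 ± 10 nt; 3': 60 ± 20 nt) are AT-rich (65%); the terminal
  stop is always UGA. An option restricts coding UGA to the 5' half of the
  protein for positional-bias studies.
* **Host-like transcripts** — the same machinery under the standard code
  with no reassignment, GC-richer synonymous positions (at3 0.45) and UTRs
  (45% AT), realising ≈ 53% overall AT versus ≈ 63% for the parasite
  condition, so the 58% partition threshold separates them as it does the
  real mixed assembly. Host CDS contain no standard-code stops by
  construction.
* **Editing pairs** — a 68%-AT gene embedded in a contig with 200-nt
  flanks; the requested number of sites per substitution type planted at
  distinct eligible positions, optionally on the minus strand.
* **tRNA inventories** — tRNAscan-SE-format records whose anticodons
  reverse-complement to a specified decoder spectrum, plus pseudogene and
  low-coverage decoys that the filters must remove.

Every generator draws from an independent, named sub-stream
(`numpy.random.SeedSequence(seed, spawn_key=...)`) of one top-level seed:
outputs are byte-reproducible and adding one generator call never perturbs
another. A self-audit (`audit_truth`) recomputes reassigned-codon positions,
terminal stops and the protein round trip from the emitted FASTA and fails
loudly on any inconsistency.

What the simulations do **not** contain: assembly artifacts and chimeras,
sequencing error, rate heterogeneity across sites, real codon-usage
correlations, wobble decoding, SECIS-driven selenocysteine, and genuine
homology structure between references. Passing tests therefore demonstrate
that the algorithms recover planted signals of the assumed shape at
realistic magnitudes — not that the biological conclusions would survive
confounders absent from the generator.

## Problem sizes and numerical choices

Test and acceptance runs use 200 transcripts against a 100-protein
reference set (the terminal-stop survey uses 100 transcripts at divergence
0.05, reflecting that that analysis targets the most conserved,
zero-e-value stratum of a real dataset). Logo calibration uses 300 windows
per group and 200 replicates; calibration is judged on the pooled per-cell
false-positive rate against the binomial 99% interval (per-cell intervals
at 200 replicates would flag ~1 of 68 cells by chance even for a perfectly
calibrated test). The aligner is verified against an independent
implementation (Biopython's `PairwiseAligner`) on 500 random pairs and
against a from-scratch exhaustive alignment enumerator on tiny instances.
Degenerate inputs are explicit errors, not silent defaults: empty
sequences, frames outside 0–5, CDS lengths not divisible by 3, context
windows overrunning transcript ends (skipped and counted), zero-count RSCU
families (undefined, not 0).

## Known limitations

* E-values are uncorrected Karlin–Altschul approximations — adequate for
  thresholding within one analysis, not comparable to BLAST's reported
  values.
* The k-mer prescreen can in principle miss a remote homolog that shares
  fewer than two 4-mers with every frame; use `prescreen_top=None` for
  exhaustive scans when the database is small.
* Whether translated-search tools truncate extensions at in-frame stops is
  tool-dependent; this engine always extends through `*`, so score deltas
  on real data may differ in magnitude (not in sign) from a given tool's.
* The two-sample logo inherits the raw-p-value convention of its source
  methodology; with 68 simultaneous cells, isolated significant cells are
  expected under the null and should be read accordingly.
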