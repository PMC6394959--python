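# recodon

Inference of nuclear stop-codon reassignment from transcriptome and proteome
comparisons.

Some lineages — ciliates, certain green algae, and syndinian dinoflagellates
such as *Amoebophrya* — do not use the standard genetic code in their nuclear
genes. `recodon` implements the comparative-alignment workflow that detects
such reassignments from assembled transcripts alone: if UAA/UAG really encode
glutamine (Q) and UGA is contingently read as tryptophan (W) inside ORFs but
as a terminator at their ends, then translating a transcript under the right
NCBI table must raise its alignment identities and positives against
conserved reference proteins, the residues aligned across from those "stop"
codons must be strongly modal (Q, W), complete ORFs must end in UGA at the
position where the reference protein ends, and the reassigned codons must
behave like ordinary members of their synonymous families in codon-usage
statistics.

## What it computes

* **Per-code translated alignment** — each transcript is translated in all
  six frames under the standard code (NCBI table 1), the UGA=Trp code
  (table 4) and the ciliate UAR=Gln code (table 6) — or all 19 tables used by
  translated-search tools — and locally aligned (Smith–Waterman, BLOSUM62
  with `*` columns, affine gaps 11/1) against a reference protein set. A
  transcript is *improved* under a table when identities **or** positives
  strictly exceed the standard-code values.
* **Stop-aligned residue profiles** — the subject residue across from every
  in-frame UGA/UAA/UAG in the best alignment, tabulated per codon (gaps
  excluded), with an e-value stringency sweep.
* **Terminal-stop calls** — a transcript is a complete ORF when its
  alignment reaches the subject's end (tolerance 10 aa) and the first
  in-frame standard stop after the alignment end is within 10 codons; the
  identity of that codon is the call. The subject-relative position of the
  most 3' coding UGA is also reported.
* **Context statistics** — 5 nt upstream / 12 nt downstream windows around
  UGA codons, compared between terminal and coding sets with per-position,
  per-base two-sample t-tests (a two-sample logo).
* **Codon usage** — codon counts, RSCU
  (`RSCU_ij = X_ij · n_i / Σ_j X_ij`, family values sum to the family size),
  and third-position composition (GC3s/A3s/T3s) under a chosen table.
* **tRNA decoder inventory** — tRNAscan-SE output parsed, anticodons mapped
  to codons by exact reverse complement, filtered (coverage, pseudogenes,
  exclusion lists), and contrasted with mRNA codon usage to expose
  third-position decoder gaps.
* **RNA-editing detection** — transcripts anchored to genome contigs by
  exact k-mer seeding with ungapped extension; every mismatch is classified
  into one of the 12 substitution types (organellar dinoflagellate editing is
  A→G / T→C).
* **Synthetic data** — a generator producing reference proteomes,
  parasite-like transcripts under the contingent code, host-like
  standard-code transcripts, editing pairs and tRNA inventories, all with a
  complete machine-checkable truth table, so every stage is testable with
  known ground truth.

## Worked example

```python
import recodon as rc
from collections import Counter

cfg = rc.SimulationConfig(seed=42, n_transcripts=50, n_proteins=30)
proteome = rc.simulate_reference_proteome(cfg)
transcripts, truth = rc.simulate_transcriptome(cfg, proteome)

db = rc.ReferenceDB(proteome)
records = [rc.compare_codes(tid, seq, db) for tid, seq in transcripts.items()]
print(Counter(r.classification for r in records))

improved = [r for r in records if r.classification.startswith("improved")]
items = [(r.transcript_id, r.best_hit, transcripts[r.transcript_id])
         for r in improved]
profile = rc.tabulate_aligned_residues(items)
for codon in ("TGA", "TAA", "TAG"):
    freqs = profile.frequencies(codon)
    top = sorted(freqs.items(), key=lambda kv: -kv[1])[:3]
    print(codon, [(aa, round(f, 2)) for aa, f in top])

code1 = rc.load_tables((1,))[1]
calls = [rc.call_terminal_stop(r.transcript_id, transcripts[r.transcript_id],
                               r.stop_call_hit, code1)
         for r in records if r.stop_call_hit is not None]
complete = [c for c in calls if c.complete]
print(f"{len(complete)} complete ORFs,",
      Counter(c.stop_codon for c in complete))
```

prints

```
Counter({'improved_UAR_only': 30, 'improved_both': 9, 'equal': 8, 'improved_UGA_only': 3})
TGA [('W', 0.64), ('V', 0.09), ('D', 0.05)]
TAA [('Q', 0.82), ('A', 0.05), ('V', 0.03)]
TAG [('Q', 0.77), ('V', 0.04), ('M', 0.04)]
50 complete ORFs, Counter({'TGA': 49, 'TAA': 1})
```

Most transcripts improve under the alternative tables (these simulated
sequences carry UAR=Gln and contingent UGA=Trp), the modal residue across
from UAA/UAG is glutamine and across from UGA is tryptophan, and the
terminal stop is essentially always UGA — the one TAA call comes from a
glutamine-TAA codon exposed when a diverged tail is trimmed from the
alignment, which is why terminal-stop surveys are best run on highly
conserved hits (see `docs/methods.md`).

The same stages are available from a CLI
(`recodon simulate|compare-codes|tabulate-residues|stop-call|context-logo|rscu|trna-report|editing|run-all`).

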