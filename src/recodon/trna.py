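"""tRNA inventory: tRNAscan-SE parsing and decoder-gap analysis.

A reassigned codon needs a tRNA to read it.  This module parses tRNAscan-SE
tabular output, maps each anticodon to the mRNA codon it reads by exact
Watson-Crick reverse complement (wobble is deliberately not modelled — gaps
in the exact-decoder inventory are reported and left to interpretation),
filters to genuine genes (coverage, pseudogene flag, contaminant exclusion
list) and contrasts decoder counts with mRNA codon usage.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

from .codon_usage import RSCUTable
from .genetic_codes import ALL_CODONS, reverse_complement


@dataclass
class TRNAGene:
    contig: str
    trna_number: int
    begin: int
    end: int
    isotype: str
    anticodon: str
    score: float
    pseudogene: bool = False
    coverage: float | None = None
    note: str = ""

    @property
    def strand(self) -> str:
        """Derived strand: tRNAscan-SE reports minus-strand genes with begin > end."""
        return "-" if self.begin > self.end else "+"

    @property
    def is_selenocysteine(self) -> bool:
        return self.isotype.lower() in {"sec", "sec(e)", "sece", "selcys"} \
            or (self.isotype.lower() == "sup" and self.anticodon == "TCA")


def anticodon_to_codon(anticodon: str) -> str:
    """mRNA codon read by an anticodon: exact reverse complement, DNA alphabet."""
    ac = anticodon.upper().replace("U", "T")
    if len(ac) != 3 or any(b not in "ACGT" for b in ac):
        raise ValueError(f"invalid anticodon {anticodon!r}")
    return reverse_complement(ac)


def parse_trnascan_output(stream) -> list[TRNAGene]:
    """Parse tRNAscan-SE tabular output (header lines tolerated).

    Expected columns: name, tRNA#, begin, end, isotype, anticodon, intron
    begin, intron end, score, optional note.  A note containing ``pseudo``
    sets the pseudogene flag; a ``cov=<float>`` token supplies coverage.
    """
    if isinstance(stream, str):
        lines = stream.splitlines()
    else:
        lines = [ln.rstrip("\n") for ln in stream]
    genes: list[TRNAGene] = []
    for lineno, line in enumerate(lines, 1):
        if not line.strip():
            continue
        low = line.lower()
        if low.startswith(("sequence", "name", "-----")) or "trna #" in low:
            continue
        fields = line.split("\t")
        if len(fields) < 9:
            fields = line.split()
        if len(fields) < 9:
            raise ValueError(f"line {lineno}: expected >= 9 columns, got {len(fields)}")
        try:
            note = "\t".join(fields[9:]).strip() if len(fields) > 9 else ""
            coverage = None
            for token in note.replace(",", " ").split():
                if token.lower().startswith("cov="):
                    coverage = float(token[4:])
            genes.append(TRNAGene(
                contig=fields[0].strip(),
                trna_number=int(fields[1]),
                begin=int(fields[2]),
                end=int(fields[3]),
                isotype=fields[4].strip(),
                anticodon=fields[5].strip().upper().replace("U", "T"),
                score=float(fields[8]),
                pseudogene="pseudo" in note.lower(),
                coverage=coverage,
                note=note,
            ))
        except (ValueError, IndexError) as exc:
            raise ValueError(f"line {lineno}: malformed tRNAscan-SE record: {exc}") from exc
    return genes


def filter_genuine(trnas: list[TRNAGene], min_coverage: float = 10,
                   exclusion_ids: set[str] | None = None,
                   drop_pseudogenes: bool = True) -> list[TRNAGene]:
    """Retain records passing every supplied predicate.

    Records with no coverage annotation pass the coverage test (the threshold
    applies only where coverage is known).
    """
    exclusion_ids = exclusion_ids or set()
    out = []
    for t in trnas:
        if t.contig in exclusion_ids:
            continue
        if drop_pseudogenes and t.pseudogene:
            continue
        if t.coverage is not None and t.coverage < min_coverage:
            continue
        out.append(t)
    return out


def decoder_counts(trnas: list[TRNAGene]) -> Counter:
    """codon -> number of tRNA genes whose anticodon exactly decodes it."""
    counts: Counter = Counter()
    for t in trnas:
        counts[anticodon_to_codon(t.anticodon)] += 1
    return counts


def decoder_gap_report(decoders: Counter, usage: RSCUTable,
                       codons: tuple[str, ...] = ALL_CODONS) -> dict:
    """Join decoder counts with codon usage and summarise third-base gaps.

    Returns ``rows`` (codon, amino acid, usage count, RSCU, decoder count)
    and ``gaps``: for each third-position base, the used codons (count > 0)
    with zero exact decoders.
    """
    rows = []
    for codon in codons:
        entry = usage.entries.get(codon)
        rows.append({
            "codon": codon,
            "amino_acid": entry.amino_acid if entry else "*",
            "usage_count": entry.count if entry else 0,
            "rscu": entry.rscu if entry else None,
            "decoder_count": decoders.get(codon, 0),
        })
    gaps: dict[str, list[str]] = {b: [] for b in "ACGT"}
    for row in rows:
        if row["usage_count"] > 0 and row["decoder_count"] == 0:
            gaps[row["codon"][2]].append(row["codon"])
    return {"rows": rows,
            "gaps": gaps,
            "gap_counts": {b: len(v) for b, v in gaps.items()}}
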