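"""Codon counting, RSCU and third-position composition.

Relative synonymous codon usage (RSCU) for codon j of amino acid i with a
family of n_i synonymous codons is

    RSCU_ij = X_ij * n_i / sum_j X_ij

so uniform usage gives 1.0 everywhere and family values sum to the family
size.  Under the ciliate nuclear code (table 6) glutamine is a four-codon
family (CAA, CAG, UAA, UAG) whose RSCU values sum to four — the quantity
that exposes reassigned stop codons as working glutamine codons.

Third-position statistics (GC3s, A3s, ...) are computed over third positions
of codons belonging to multi-codon families only; single-codon families
(ATG; TGG where Trp has one codon) and stop codons are excluded, and all
four base fractions share that one denominator.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from .alignment import AlignmentResult
from .comparison import CodeHit
from .genetic_codes import ALL_CODONS, GeneticCode, load_tables, reverse_complement


@dataclass
class CodonCountTable:
    counts: Counter = field(default_factory=Counter)
    n_sequences: int = 0

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def __add__(self, other: "CodonCountTable") -> "CodonCountTable":
        return CodonCountTable(self.counts + other.counts,
                               self.n_sequences + other.n_sequences)


@dataclass
class RSCUEntry:
    codon: str
    amino_acid: str
    family_size: int
    count: int
    rscu: float | None  # None when the whole family has zero counts


@dataclass
class RSCUTable:
    table_id: int
    entries: dict[str, RSCUEntry]

    def value(self, codon: str) -> float | None:
        """RSCU of a sense codon; None for stop codons of the table."""
        entry = self.entries.get(codon)
        return entry.rscu if entry else None

    def count(self, codon: str) -> int:
        entry = self.entries.get(codon)
        return entry.count if entry else 0

    def family_sum(self, amino_acid: str) -> float | None:
        vals = [e.rscu for e in self.entries.values() if e.amino_acid == amino_acid]
        if any(v is None for v in vals):
            return None
        return sum(vals)


@dataclass
class ThirdPositionStats:
    A3s: float
    C3s: float
    G3s: float
    T3s: float
    n_synonymous_third_positions: int

    @property
    def GC3s(self) -> float:
        return self.G3s + self.C3s


def count_codons(cds_set: dict[str, str] | list[str]) -> CodonCountTable:
    """Exact codon counts over in-frame CDS; raises per-sequence on bad length."""
    if isinstance(cds_set, dict):
        items = list(cds_set.items())
    else:
        items = [(str(i), s) for i, s in enumerate(cds_set)]
    table = CodonCountTable()
    for sid, seq in items:
        s = seq.upper()
        if len(s) % 3 != 0:
            raise ValueError(f"sequence {sid!r}: length {len(s)} not divisible by 3")
        for i in range(0, len(s), 3):
            table.counts[s[i:i + 3]] += 1
        table.n_sequences += 1
    return table


def _families(code: GeneticCode) -> dict[str, list[str]]:
    """Synonymous families (amino acid -> codons); stops excluded."""
    fams: dict[str, list[str]] = {}
    for codon in ALL_CODONS:
        aa = code.codon_to_aa[codon]
        if aa == "*":
            continue
        fams.setdefault(aa, []).append(codon)
    return fams


def rscu(counts: CodonCountTable, code: GeneticCode | None = None) -> RSCUTable:
    """RSCU per sense codon under ``code`` (default: ciliate nuclear, table 6).

    Families with zero total counts get ``rscu=None`` (undefined), never 0.
    """
    if code is None:
        code = load_tables((6,))[6]
    entries: dict[str, RSCUEntry] = {}
    for aa, codons in _families(code).items():
        n_i = len(codons)
        fam_total = sum(counts.counts.get(c, 0) for c in codons)
        for c in codons:
            x = counts.counts.get(c, 0)
            val = None if fam_total == 0 else x * n_i / fam_total
            entries[c] = RSCUEntry(c, aa, n_i, x, val)
    return RSCUTable(table_id=code.table_id, entries=entries)


def third_position_stats(cds_set: dict[str, str] | list[str],
                         code: GeneticCode | None = None) -> ThirdPositionStats:
    """Base composition at third positions of synonymous (multi-codon-family)
    codons; stop codons and single-codon families are excluded, codonw-style."""
    if code is None:
        code = load_tables((6,))[6]
    fams = _families(code)
    synonymous = {c for codons in fams.values() if len(codons) > 1 for c in codons}
    counts = count_codons(cds_set)
    base_counts = Counter()
    total = 0
    for codon, n in counts.counts.items():
        if codon in synonymous:
            base_counts[codon[2]] += n
            total += n
    if total == 0:
        return ThirdPositionStats(0.0, 0.0, 0.0, 0.0, 0)
    return ThirdPositionStats(
        A3s=base_counts["A"] / total, C3s=base_counts["C"] / total,
        G3s=base_counts["G"] / total, T3s=base_counts["T"] / total,
        n_synonymous_third_positions=total)


def extract_aligned_codons(transcript: str, hit: CodeHit) -> list[str]:
    """One codon per alignment column where the query has a residue.

    Columns where the query is gapped contribute nothing; columns where the
    subject is gapped still emit the query codon.  Codons are read from the
    transcript strand in the hit's frame, in subject (alignment) order.
    """
    seq = transcript.upper()
    frame = hit.frame
    if frame >= 3:
        seq = reverse_complement(seq)
        frame -= 3
    aln: AlignmentResult = hit.alignment
    out = []
    qpos = aln.query_start - 1  # 1-based protein position of last consumed residue
    for qc, _sc in aln.pairs:
        if qc == "-":
            continue
        qpos += 1
        start = frame + (qpos - 1) * 3
        codon = seq[start:start + 3]
        if len(codon) != 3:
            raise RuntimeError("alignment frame inconsistent with transcript length")
        out.append(codon)
    return out


DEFAULT_FAMILIES: dict[str, tuple[str, ...]] = {
    "W": ("TGG", "TGA"),
    "Q": ("CAA", "CAG", "TAA", "TAG"),
}


def family_codon_report(aligned_codons: list[str],
                        families: dict[str, tuple[str, ...]] | None = None) -> dict:
    """Counts and RSCU for the likely-Trp and likely-Gln codon families.

    Mirrors the per-gene analysis of conserved gene families: among codons
    extracted from the alignment, count TGG/TGA (tryptophan family, RSCU sums
    to 2) and CAA/CAG/TAA/TAG (glutamine family, sums to 4).
    """
    families = families or DEFAULT_FAMILIES
    counts = Counter(aligned_codons)
    report: dict = {}
    for aa, codons in families.items():
        fam_total = sum(counts.get(c, 0) for c in codons)
        n_i = len(codons)
        fam = {}
        for c in codons:
            x = counts.get(c, 0)
            fam[c] = {"count": x,
                      "rscu": None if fam_total == 0 else x * n_i / fam_total}
        report[aa] = {"total": fam_total, "codons": fam}
    return report


def find_longest_orf(transcript: str, code: GeneticCode | None = None,
                     min_codons: int = 100) -> tuple[str, int, int] | None:
    """Longest stop-to-stop ORF across all six frames under ``code``.

    Returns (cds, frame, nt_start) with nt_start 1-based on the reading
    strand, or None when no ORF reaches ``min_codons``.  Start codons are
    ignored (longorfs-style stop-to-stop segments).
    """
    if code is None:
        code = load_tables((6,))[6]
    best: tuple[int, int, int] | None = None  # (-len, frame, start_codon_idx)
    seqs = {}
    for frame in range(6):
        seq = transcript.upper()
        off = frame
        if frame >= 3:
            seq = reverse_complement(seq)
            off = frame - 3
        seqs[frame] = (seq, off)
        n_codons = (len(seq) - off) // 3
        run_start = 0
        for ci in range(n_codons + 1):
            at_end = ci == n_codons
            codon = seq[off + ci * 3: off + ci * 3 + 3] if not at_end else None
            if at_end or code.codon_to_aa.get(codon, "X") == "*":
                run_len = ci - run_start
                if run_len >= min_codons:
                    key = (-run_len, frame, run_start)
                    if best is None or key < best:
                        best = key
                run_start = ci + 1
    if best is None:
        return None
    neg_len, frame, start_ci = best
    seq, off = seqs[frame]
    start = off + start_ci * 3
    cds = seq[start:start + (-neg_len) * 3]
    return cds, frame, start + 1


def contains_coding_uga(transcript: str, hit: CodeHit) -> bool:
    """True when the best alignment's span contains an in-frame TGA codon."""
    from .comparison import stops_in_span
    inside, _ = stops_in_span(transcript, hit)
    return inside.get("TGA", 0) > 0
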