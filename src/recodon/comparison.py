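"""Per-genetic-code translated alignment and score-delta classification.

The three-tier inference: (1) count in-frame standard-code stops in the
translated query, (2) ask whether translating under an alternative table
(UGA=Trp, table 4; UAA/UAG=Gln, table 6) strictly increases identities or
positives against the best reference hit, (3) tabulate which subject residue
sits across from each stop codon.  A transcriptome whose stops are really
sense codons shows a large improved fraction and a strongly modal aligned
residue (Trp for UGA, Gln for UAA/UAG); a standard-code transcriptome shows
almost none.

Each code is realigned independently (each table gets its own best hit),
mirroring how a translated search is re-run per code rather than rescoring a
fixed alignment.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field

from .alignment import (AlignmentResult, EvalueParams, GapPenalties,
                        ScoringMatrix, approximate_evalue, default_matrix,
                        local_align, local_align_score)
from .genetic_codes import (BUNDLED_TABLE_IDS, CodeTableSet, GeneticCode,
                            load_tables, translate)

logger = logging.getLogger(__name__)

STANDARD_STOPS = ("TGA", "TAA", "TAG")

#: classification labels
EQUAL = "equal"
IMPROVED_UGA = "improved_UGA_only"
IMPROVED_UAR = "improved_UAR_only"
IMPROVED_BOTH = "improved_both"
NO_HIT = "no_hit"

DEFAULT_EVALUE_CUTOFF = 1e-10


@dataclass
class CodeHit:
    """Best hit for one transcript under one translation table."""

    table_id: int
    frame: int
    subject_id: str
    subject_len: int
    alignment: AlignmentResult
    evalue: float

    @property
    def identities(self) -> int:
        return self.alignment.identities

    @property
    def positives(self) -> int:
        return self.alignment.positives


@dataclass
class CodeComparisonRecord:
    """Per-transcript outcome of the multi-code comparison."""

    transcript_id: str
    per_code: dict[int, CodeHit]
    n_stops_in_query: Counter  # standard-code stops inside the best span
    stops_outside_span: Counter
    classification: str
    best_table_id: int | None = None
    at_content: float | None = None
    component_id: str | None = None

    @property
    def best_hit(self) -> CodeHit | None:
        if self.best_table_id is None:
            return None
        return self.per_code[self.best_table_id]

    @property
    def stop_call_hit(self) -> CodeHit | None:
        """Hit preferred for terminal-stop calling: the alignment reaching
        furthest along the subject (ties: raw score, then lower table id).

        A reassigned codon at the very end of the CDS is read as '*' by the
        tables that do not recode it and gets trimmed from their alignments;
        scanning for the terminal stop from the most 3'-extending alignment
        prevents that codon from masquerading as the stop.
        """
        if not self.per_code:
            return None
        return min(self.per_code.values(),
                   key=lambda h: (-h.alignment.subject_end,
                                  -h.alignment.raw_score, h.table_id))


@dataclass
class ResidueProfile:
    """Subject residues aligned to query stop codons, per codon."""

    counts: dict[str, Counter] = field(default_factory=dict)
    gap_counts: Counter = field(default_factory=Counter)

    def frequencies(self, codon: str) -> dict[str, float]:
        c = self.counts.get(codon, Counter())
        total = sum(c.values())
        if total == 0:
            return {}
        return {aa: n / total for aa, n in c.items()}

    def modal_residue(self, codon: str) -> str | None:
        c = self.counts.get(codon, Counter())
        if not c:
            return None
        # deterministic: highest count, then alphabetical
        return min(c, key=lambda aa: (-c[aa], aa))


class ReferenceDB:
    """Reference proteins plus a k-mer index for candidate prescreening.

    Aligning every frame against every reference is exact but quadratic in
    database size; the prescreen keeps only references sharing at least
    ``min_seed_hits`` k-mers with the translated frame (top ``prescreen_top``
    by shared-k-mer count).  With ``prescreen_top=None`` every reference is
    aligned.  Small databases (<= prescreen_top) are always exhaustive.
    """

    def __init__(self, references: dict[str, str], k: int = 4):
        self.references = dict(references)
        self.k = k
        self.total_len = sum(len(s) for s in references.values())
        self._index: dict[str, list[str]] = defaultdict(list)
        for sid, seq in self.references.items():
            seen = set()
            for i in range(len(seq) - k + 1):
                kmer = seq[i:i + k]
                if kmer not in seen:
                    seen.add(kmer)
                    self._index[kmer].append(sid)

    def __len__(self) -> int:
        return len(self.references)

    def candidates(self, protein: str, top: int | None,
                   min_seed_hits: int = 2) -> list[str]:
        if top is None or len(self.references) <= (top or 0):
            return sorted(self.references)
        hits: Counter = Counter()
        seen = set()
        for i in range(len(protein) - self.k + 1):
            kmer = protein[i:i + self.k]
            if kmer in seen or "*" in kmer or "X" in kmer:
                continue
            seen.add(kmer)
            for sid in self._index.get(kmer, ()):
                hits[sid] += 1
        ranked = [sid for sid, n in hits.items() if n >= min_seed_hits]
        ranked.sort(key=lambda sid: (-hits[sid], sid))
        return ranked[:top]


def _best_hit_for_table(transcript: str, db: ReferenceDB, code: GeneticCode,
                        matrix: ScoringMatrix, gaps: GapPenalties,
                        evalue_params: EvalueParams,
                        prescreen_top: int | None) -> CodeHit | None:
    """Highest-raw-score hit over all six frames and candidate references.

    Ties break by lexicographic subject id, then lowest frame.
    """
    best: tuple[int, str, int] | None = None  # (-score, sid, frame)
    best_seqs: tuple[str, str] | None = None
    for frame in range(6):
        prot = translate(transcript, frame, code)
        if len(prot) < db.k:
            continue
        for sid in db.candidates(prot, prescreen_top):
            subject = db.references[sid]
            if not subject:
                continue
            score = local_align_score(prot, subject, matrix, gaps)
            if score <= 0:
                continue
            key = (-score, sid, frame)
            if best is None or key < best:
                best = key
                best_seqs = (prot, subject)
    if best is None:
        return None
    neg_score, sid, frame = best
    prot, subject = best_seqs
    aln = local_align(prot, subject, matrix, gaps)
    ev = approximate_evalue(aln.raw_score, len(prot), db.total_len, evalue_params)
    return CodeHit(table_id=code.table_id, frame=frame, subject_id=sid,
                   subject_len=len(subject), alignment=aln, evalue=ev)


def stops_in_span(transcript: str, hit: CodeHit) -> tuple[Counter, Counter]:
    """Standard-code stop codons inside vs outside the best alignment's query span.

    Codons are read in the hit's frame; 'inside' means the codon's protein
    position falls within [query_start, query_end] of the alignment.
    """
    from .genetic_codes import reverse_complement
    seq = transcript.upper()
    frame = hit.frame
    if frame >= 3:
        seq = reverse_complement(seq)
        frame -= 3
    inside: Counter = Counter()
    outside: Counter = Counter()
    aa_pos = 0
    for i in range(frame, len(seq) - 2, 3):
        aa_pos += 1
        codon = seq[i:i + 3]
        if codon in STANDARD_STOPS:
            if hit.alignment.query_start <= aa_pos <= hit.alignment.query_end:
                inside[codon] += 1
            else:
                outside[codon] += 1
    return inside, outside


def classify(per_code: dict[int, CodeHit | None],
             baseline: int = 1, uga_table: int = 4, uar_table: int = 6) -> str:
    """Label score deltas relative to the standard code.

    'Improved' under a table means identities OR positives strictly greater
    than under the baseline (standard) table.
    """
    base = per_code.get(baseline)
    if base is None:
        raise ValueError("baseline (standard code) hit missing from per_code")
    base_id, base_pos = base.identities, base.positives

    def improved(table: int) -> bool:
        hit = per_code.get(table)
        if hit is None:
            return False
        return hit.identities > base_id or hit.positives > base_pos

    up_uga, up_uar = improved(uga_table), improved(uar_table)
    if up_uga and up_uar:
        return IMPROVED_BOTH
    if up_uga:
        return IMPROVED_UGA
    if up_uar:
        return IMPROVED_UAR
    return EQUAL


def compare_codes(transcript_id: str, transcript: str, db: ReferenceDB,
                  tables: CodeTableSet | None = None,
                  table_ids: tuple[int, ...] = (1, 4, 6),
                  matrix: ScoringMatrix | None = None,
                  gaps: GapPenalties = GapPenalties(),
                  evalue_params: EvalueParams = EvalueParams(),
                  evalue_cutoff: float = DEFAULT_EVALUE_CUTOFF,
                  prescreen_top: int | None = 5) -> CodeComparisonRecord:
    """Run the per-code comparison for one transcript.

    For each table the transcript is translated in all six frames and the
    best-scoring local alignment against the reference database retained.
    Hits failing the e-value cutoff are discarded; a transcript with no hit
    under the baseline table is classified ``no_hit``.
    """
    tables = tables or load_tables()
    matrix = matrix or default_matrix()
    per_code: dict[int, CodeHit] = {}
    for tid in table_ids:
        hit = _best_hit_for_table(transcript, db, tables[tid], matrix, gaps,
                                  evalue_params, prescreen_top)
        if hit is not None and hit.evalue <= evalue_cutoff:
            per_code[tid] = hit
    if 1 not in per_code:
        return CodeComparisonRecord(transcript_id, per_code, Counter(), Counter(),
                                    NO_HIT, None)
    label = classify(per_code)
    best_tid = min(per_code,
                   key=lambda t: (-per_code[t].alignment.raw_score, t))
    inside, outside = stops_in_span(transcript, per_code[best_tid])
    return CodeComparisonRecord(transcript_id, per_code, inside, outside,
                                label, best_tid)


def stop_aligned_residues(transcript: str, hit: CodeHit,
                          codons: tuple[str, ...] = STANDARD_STOPS) -> list[tuple[str, int, str]]:
    """(codon, transcript_nt_pos, subject_residue_or_'-') for every standard-code
    stop codon inside the hit's aligned span.

    Positions are 1-based first bases of the codon on the reading strand.
    """
    from .genetic_codes import reverse_complement
    seq = transcript.upper()
    frame = hit.frame
    if frame >= 3:
        seq = reverse_complement(seq)
        frame -= 3
    # map query protein position -> subject residue (or '-') from the pairs
    aln = hit.alignment
    sub_for_q: dict[int, str] = {}
    qpos = aln.query_start - 1
    spos = aln.subject_start - 1
    for qc, sc in aln.pairs:
        if qc != "-" and sc != "-":
            qpos += 1
            spos += 1
            sub_for_q[qpos] = sc
        elif qc != "-":
            qpos += 1
            sub_for_q[qpos] = "-"
        else:
            spos += 1
    out = []
    aa_pos = 0
    for i in range(frame, len(seq) - 2, 3):
        aa_pos += 1
        codon = seq[i:i + 3]
        if codon in codons and aa_pos in sub_for_q:
            out.append((codon, i + 1, sub_for_q[aa_pos]))
    return out


def tabulate_aligned_residues(items: list[tuple[str, CodeHit, str]],
                              codons: tuple[str, ...] = STANDARD_STOPS) -> ResidueProfile:
    """Aggregate subject residues aligned to stop codons across transcripts.

    ``items`` holds (transcript_id, best CodeHit, transcript_sequence); the
    caller restricts the set (e.g. to improved transcripts).  Gap-aligned
    occurrences are tallied separately and excluded from the frequencies.
    """
    profile = ResidueProfile(counts={c: Counter() for c in codons})
    for _tid, hit, seq in items:
        for codon, _pos, residue in stop_aligned_residues(seq, hit, codons):
            if residue == "-":
                profile.gap_counts[codon] += 1
            else:
                profile.counts[codon][residue] += 1
    return profile


def rank_all_codes(transcripts: dict[str, str], db: ReferenceDB,
                   tables: CodeTableSet | None = None,
                   table_ids: tuple[int, ...] = BUNDLED_TABLE_IDS,
                   matrix: ScoringMatrix | None = None,
                   gaps: GapPenalties = GapPenalties(),
                   evalue_params: EvalueParams = EvalueParams(),
                   evalue_cutoff: float = DEFAULT_EVALUE_CUTOFF,
                   prescreen_top: int | None = 5) -> tuple[dict[str, int | None], Counter]:
    """Best table per transcript by positives (ties -> lower table id).

    Returns (per-transcript best table or None, histogram Counter including a
    ``no_hit`` bucket).
    """
    tables = tables or load_tables()
    matrix = matrix or default_matrix()
    best_per_transcript: dict[str, int | None] = {}
    histogram: Counter = Counter()
    for tid_seq, seq in transcripts.items():
        best: tuple[int, int] | None = None  # (-positives, table_id)
        for tid in table_ids:
            hit = _best_hit_for_table(seq, db, tables[tid], matrix, gaps,
                                      evalue_params, prescreen_top)
            if hit is None or hit.evalue > evalue_cutoff:
                continue
            key = (-hit.positives, tid)
            if best is None or key < best:
                best = key
        if best is None:
            best_per_transcript[tid_seq] = None
            histogram["no_hit"] += 1
        else:
            best_per_transcript[tid_seq] = best[1]
            histogram[best[1]] += 1
    return best_per_transcript, histogram


def stringency_sweep(items: list[tuple[str, CodeHit, str]],
                     thresholds: list[float],
                     codons: tuple[str, ...] = STANDARD_STOPS) -> list[dict]:
    """Residue profiles recomputed at descending e-value cutoffs.

    Each row reports, per codon, the proportion of the modal target residue
    among non-gap aligned residues; rows with no passing record are flagged
    empty.
    """
    if len(thresholds) < 1:
        raise ValueError("at least one threshold required")
    rows = []
    for cutoff in thresholds:
        passing = [(tid, hit, seq) for tid, hit, seq in items
                   if hit.evalue <= cutoff]
        profile = tabulate_aligned_residues(passing, codons)
        row: dict = {"cutoff": cutoff, "n_records": len(passing),
                     "empty": len(passing) == 0}
        for codon in codons:
            freqs = profile.frequencies(codon)
            modal = profile.modal_residue(codon)
            row[codon] = {"modal_residue": modal,
                          "modal_fraction": freqs.get(modal, float("nan")) if modal else float("nan"),
                          "n": sum(profile.counts[codon].values())}
        rows.append(row)
    return rows


def collapse_components(records: list[CodeComparisonRecord],
                        component_of: dict[str, str],
                        lengths: dict[str, int]) -> list[CodeComparisonRecord]:
    """One representative per assembly graph component: the longest transcript."""
    by_comp: dict[str, CodeComparisonRecord] = {}
    for rec in records:
        comp = component_of.get(rec.transcript_id, rec.transcript_id)
        cur = by_comp.get(comp)
        if cur is None or lengths[rec.transcript_id] > lengths[cur.transcript_id]:
            by_comp[comp] = rec
    return list(by_comp.values())
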