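"""Genome-vs-transcript substitution editing detection.

Dinoflagellate-style organellar RNA editing is substitutional, so the model
here is deliberately ungapped: the transcript is anchored to the best genome
contig window by exact k-mer seeding on both strands, extended without gaps,
and every mismatch column becomes a candidate editing site.  All reporting
is in mRNA sense — for minus-strand matches the genome base is complemented
so an A→G edit reads as A→G regardless of which strand the gene sits on.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

from .genetic_codes import reverse_complement

logger = logging.getLogger(__name__)

SUBSTITUTION_TYPES = tuple(f"{a}->{b}" for a in "ACGT" for b in "ACGT" if a != b)


@dataclass
class NucleotideAlignment:
    """Ungapped transcript-to-genome alignment, mRNA sense."""

    gene_id: str
    contig: str
    strand: str  # transcript strand relative to the contig
    transcript_seq: str
    genome_seq: str  # same length, already complemented for minus strand
    contig_start: int  # 1-based, on the contig's forward strand
    identity: float
    truncated_left: int = 0
    truncated_right: int = 0


@dataclass
class EditingSite:
    gene_id: str
    transcript_nt_pos: int  # 1-based
    genome_base: str
    transcript_base: str
    strand: str

    @property
    def substitution(self) -> str:
        return f"{self.genome_base}->{self.transcript_base}"


@dataclass
class EditingSummary:
    per_gene: dict[str, dict] = field(default_factory=dict)
    restricted_to: tuple[str, ...] | None = None
    all_within_restriction: bool | None = None

    def total(self, gene_id: str) -> int:
        return self.per_gene[gene_id]["total"]

    def type_count(self, gene_id: str, substitution: str) -> int:
        return self.per_gene[gene_id]["types"].get(substitution, 0)


def anchor_and_align(gene_id: str, transcript: str,
                     genome_contigs: dict[str, str],
                     seed_k: int = 31,
                     min_identity: float = 0.90) -> NucleotideAlignment | None:
    """Locate the transcript on the best contig window (both strands).

    Exact k-mer seeding followed by ungapped extension over the full
    transcript span; the best (contig, strand, offset) placement by identity
    is kept and returned in mRNA sense, or None when no seed matches or the
    best identity falls below ``min_identity`` (e.g. an indel shifted the
    frame — such windows are not force-aligned).
    """
    t = transcript.upper()
    if len(t) < seed_k:
        raise ValueError(f"transcript shorter than seed_k={seed_k}")
    seeds = {t[i:i + seed_k]: i for i in range(len(t) - seed_k + 1)}
    best: NucleotideAlignment | None = None
    for contig_id in sorted(genome_contigs):
        contig = genome_contigs[contig_id].upper()
        for strand in "+-":
            g = contig if strand == "+" else reverse_complement(contig)
            offsets = set()
            for i in range(len(g) - seed_k + 1):
                kmer = g[i:i + seed_k]
                if kmer in seeds:
                    offsets.add(i - seeds[kmer])
            for off in sorted(offsets):
                g_start = max(0, off)
                t_start = g_start - off
                span = min(len(t) - t_start, len(g) - g_start)
                if span <= 0:
                    continue
                t_win = t[t_start:t_start + span]
                g_win = g[g_start:g_start + span]
                matches = sum(a == b for a, b in zip(t_win, g_win))
                identity = matches / len(t)  # over the whole transcript
                if best is None or identity > best.identity:
                    if strand == "+":
                        contig_start = g_start + 1
                    else:
                        contig_start = len(contig) - (g_start + span) + 1
                    best = NucleotideAlignment(
                        gene_id=gene_id, contig=contig_id, strand=strand,
                        transcript_seq=t_win, genome_seq=g_win,
                        contig_start=contig_start, identity=identity,
                        truncated_left=t_start,
                        truncated_right=len(t) - t_start - span)
    if best is None:
        return None
    if best.identity < min_identity:
        logger.warning("%s: best placement identity %.3f below %.2f "
                       "(possible indel); no match reported",
                       gene_id, best.identity, min_identity)
        return None
    return best


def call_edits(alignment: NucleotideAlignment) -> list[EditingSite]:
    """One EditingSite per mismatch column of an anchored alignment."""
    sites = []
    for i, (gb, tb) in enumerate(zip(alignment.genome_seq,
                                     alignment.transcript_seq)):
        if gb != tb and gb in "ACGT" and tb in "ACGT":
            sites.append(EditingSite(
                gene_id=alignment.gene_id,
                transcript_nt_pos=alignment.truncated_left + i + 1,
                genome_base=gb, transcript_base=tb,
                strand=alignment.strand))
    return sites


def summarize_edits(sites: list[EditingSite],
                    restrict_types: tuple[str, ...] | None = None) -> EditingSummary:
    """Per-gene totals and per-substitution-type counts.

    With ``restrict_types`` supplied (e.g. ``("A->G", "T->C")``) the summary
    flags whether every site falls within that set.
    """
    summary = EditingSummary(restricted_to=restrict_types)
    for site in sites:
        gene = summary.per_gene.setdefault(
            site.gene_id, {"total": 0, "types": Counter()})
        gene["total"] += 1
        gene["types"][site.substitution] += 1
    if restrict_types is not None:
        allowed = set(restrict_types)
        summary.all_within_restriction = all(
            s.substitution in allowed for s in sites)
    return summary
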