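"""FASTA/TSV I/O, pipeline configuration and the end-to-end pipeline."""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import codon_usage as cu
from . import comparison as cmp
from . import editing as ed
from . import partition as pt
from . import stop_context as sc
from . import trna as tr
from .genetic_codes import load_tables

logger = logging.getLogger(__name__)


def read_fasta(path: str | Path) -> dict[str, str]:
    """Ordered {id: sequence}; duplicate ids are an error; CRLF tolerated."""
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
        records[rec.id] = str(rec.seq)
    return records


def write_fasta(records: dict[str, str], path: str | Path, wrap: int = 60) -> None:
    seq_records = [SeqRecord(Seq(s), id=sid, description="")
                   for sid, s in records.items()]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=wrap)
        writer.write_file(seq_records)


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


@dataclass
class PipelineConfig:
    """Every tunable of the end-to-end run, serialisable to YAML."""

    transcripts_path: str = ""
    references_path: str = ""
    genome_path: str = ""
    trna_path: str = ""
    out_dir: str = "recodon_out"
    table_ids: list[int] = field(default_factory=lambda: [1, 4, 6])
    evalue_cutoff: float = 1e-10
    gap_open: int = 11
    gap_extend: int = 1
    prescreen_top: int = 5
    at_threshold: float = 0.58
    sl_motif: str = "CTCAAG"
    sl_window: int = 30
    tol_subject_aa: int = 10
    tol_downstream_codons: int = 10
    context_up: int = 5
    context_down: int = 12
    logo_alpha: float = 0.05
    logo_min_group: int = 20
    min_orf_codons: int = 100
    trna_min_coverage: float = 10.0
    seed: int = 0

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


def comparison_table(records: list[cmp.CodeComparisonRecord]) -> pd.DataFrame:
    rows = []
    for rec in records:
        row: dict = {"transcript_id": rec.transcript_id,
                     "classification": rec.classification,
                     "at_content": rec.at_content,
                     "best_table": rec.best_table_id}
        for tid, hit in sorted(rec.per_code.items()):
            row[f"score_t{tid}"] = hit.alignment.raw_score
            row[f"identities_t{tid}"] = hit.identities
            row[f"positives_t{tid}"] = hit.positives
            row[f"evalue_t{tid}"] = hit.evalue
        for codon in cmp.STANDARD_STOPS:
            row[f"stops_{codon}"] = rec.n_stops_in_query.get(codon, 0)
        rows.append(row)
    return pd.DataFrame(rows)


def residue_profile_table(profile: cmp.ResidueProfile) -> pd.DataFrame:
    rows = []
    for codon, counts in sorted(profile.counts.items()):
        freqs = profile.frequencies(codon)
        for aa in sorted(counts):
            rows.append({"codon": codon, "residue": aa,
                         "count": counts[aa], "frequency": freqs[aa]})
        rows.append({"codon": codon, "residue": "-",
                     "count": profile.gap_counts.get(codon, 0),
                     "frequency": float("nan")})
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig) -> dict:
    """Chain the analysis stages and write per-stage TSV reports.

    Stages: read inputs, per-code comparison and classification, residue
    profiles over improved transcripts, terminal-stop calls and relative
    UGA positions, bulk codon usage (RSCU, third-position stats) over
    longest ORFs, and — when inputs are provided — the tRNA decoder report
    and editing detection.  Returns the summary dict it also writes.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logger.info("reading inputs")
    transcripts = read_fasta(config.transcripts_path)
    references = read_fasta(config.references_path)
    db = cmp.ReferenceDB(references)
    tables = load_tables()
    from .alignment import GapPenalties
    gaps = GapPenalties(config.gap_open, config.gap_extend)

    logger.info("comparing genetic codes over %d transcripts", len(transcripts))
    records = []
    for tid, seq in transcripts.items():
        rec = cmp.compare_codes(tid, seq, db, tables,
                                table_ids=tuple(config.table_ids), gaps=gaps,
                                evalue_cutoff=config.evalue_cutoff,
                                prescreen_top=config.prescreen_top)
        rec.at_content = pt.at_content(seq)
        records.append(rec)
    write_tsv(comparison_table(records), out / "code_comparison.tsv")
    class_counts = Counter(r.classification for r in records)
    n_hits = sum(v for k, v in class_counts.items() if k != cmp.NO_HIT)

    improved = [r for r in records if r.classification.startswith("improved")]
    items = [(r.transcript_id, r.best_hit, transcripts[r.transcript_id])
             for r in improved if r.best_hit is not None]
    profile = cmp.tabulate_aligned_residues(items)
    write_tsv(residue_profile_table(profile), out / "residue_profile.tsv")

    logger.info("terminal-stop calls")
    stop_rows = []
    rel_positions = []
    code1 = tables[1]
    for rec in records:
        hit = rec.stop_call_hit
        if hit is None:
            continue
        call = sc.call_terminal_stop(rec.transcript_id,
                                     transcripts[rec.transcript_id], hit, code1,
                                     config.tol_subject_aa,
                                     config.tol_downstream_codons)
        rel = sc.relative_last_recoded_position(hit, transcripts[rec.transcript_id])
        if rel is not None:
            rel_positions.append(rel)
        stop_rows.append({"transcript_id": call.transcript_id,
                          "stop_codon": call.stop_codon,
                          "stop_nt_pos": call.stop_nt_pos,
                          "complete": call.complete,
                          "relative_last_TGA": rel})
    write_tsv(pd.DataFrame(stop_rows), out / "terminal_stops.tsv")

    logger.info("bulk codon usage")
    orfs = {}
    for tid, seq in transcripts.items():
        found = cu.find_longest_orf(seq, tables[6], config.min_orf_codons)
        if found is not None:
            orfs[tid] = found[0]
    usage_summary: dict = {"n_orfs": len(orfs)}
    if orfs:
        counts = cu.count_codons(orfs)
        table = cu.rscu(counts, tables[6])
        stats3 = cu.third_position_stats(orfs, tables[6])
        write_tsv(pd.DataFrame(
            [{"codon": e.codon, "amino_acid": e.amino_acid, "count": e.count,
              "rscu": e.rscu} for e in table.entries.values()]),
            out / "codon_usage.tsv")
        usage_summary.update({"total_codons": counts.total,
                              "GC3s": stats3.GC3s, "A3s": stats3.A3s,
                              "T3s": stats3.T3s})

    summary: dict = {
        "n_transcripts": len(transcripts),
        "n_hits": n_hits,
        "classification_counts": dict(class_counts),
        "classification_proportions": {
            k: v / n_hits for k, v in class_counts.items() if k != cmp.NO_HIT
        } if n_hits else {},
        "modal_residues": {c: profile.modal_residue(c)
                           for c in cmp.STANDARD_STOPS},
        "n_complete_stops": sum(1 for r in stop_rows if r["complete"]),
        "terminal_stop_counts": dict(Counter(
            r["stop_codon"] for r in stop_rows if r["complete"])),
        "mean_relative_last_TGA": (sum(rel_positions) / len(rel_positions)
                                   if rel_positions else None),
        "codon_usage": usage_summary,
    }

    if config.trna_path:
        logger.info("tRNA inventory")
        with open(config.trna_path) as fh:
            genes = tr.parse_trnascan_output(fh)
        kept = tr.filter_genuine(genes, min_coverage=config.trna_min_coverage)
        decoders = tr.decoder_counts(kept)
        if orfs:
            report = tr.decoder_gap_report(decoders, table)
            write_tsv(pd.DataFrame(report["rows"]), out / "trna_decoders.tsv")
            summary["trna"] = {"n_genes": len(kept),
                               "gap_counts": report["gap_counts"]}

    if config.genome_path:
        logger.info("editing detection")
        contigs = read_fasta(config.genome_path)
        all_sites = []
        for tid, seq in transcripts.items():
            aln = ed.anchor_and_align(tid, seq, contigs)
            if aln is not None:
                all_sites.extend(ed.call_edits(aln))
        edits = ed.summarize_edits(all_sites, restrict_types=("A->G", "T->C"))
        write_tsv(pd.DataFrame([
            {"gene_id": s.gene_id, "transcript_nt_pos": s.transcript_nt_pos,
             "genome_base": s.genome_base, "transcript_base": s.transcript_base,
             "strand": s.strand} for s in all_sites]), out / "editing_sites.tsv")
        summary["editing"] = {g: {"total": d["total"], **dict(d["types"])}
                              for g, d in edits.per_gene.items()}

    with open(out / "summary.yaml", "w") as fh:
        yaml.safe_dump(_plain(summary), fh, sort_keys=True)
    return summary


def _plain(obj):
    """YAML-safe plain-python copy (Counters, numpy scalars, None keys)."""
    if isinstance(obj, dict):
        return {str(k): _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if hasattr(obj, "item"):
        return obj.item()
    return obj
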