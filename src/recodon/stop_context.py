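"""Terminal-stop calling and nucleotide context around UGA codons.

A contingently translated codon (UGA read as Trp inside the ORF but as stop
at its end) leaves two signatures: complete ORFs terminate in UGA at a
position matching the reference protein's end, and the nucleotide context
of coding UGA differs from terminal UGA.  This module calls terminal stops
from best alignments, measures where coding UGA falls along the subject,
extracts fixed context windows (5 nt upstream, codon, 12 nt downstream) and
compares two window sets with the two-sample-logo t statistic.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .comparison import CodeHit
from .genetic_codes import GeneticCode, load_tables, reverse_complement

_BASES = "ACGT"


@dataclass
class TerminalStopCall:
    transcript_id: str
    stop_codon: str | None
    stop_nt_pos: int | None  # 1-based first base, reading-strand coordinates
    complete: bool
    upstream_inframe_stop_counts: Counter


@dataclass
class ContextWindow:
    """20-nt window: 5 nt upstream, the codon, 12 nt downstream."""

    upstream: str
    codon: str
    downstream: str
    sense_label: str  # "stop" or "coding"

    @property
    def flanks(self) -> str:
        """The 17 variable positions (codon excluded)."""
        return self.upstream + self.downstream


@dataclass
class LogoResult:
    """Per (flank position, base): group frequencies, difference and p-value.

    Arrays are shaped (17, 4) over positions 1-17 (5 upstream then 12
    downstream) and bases ACGT.
    """

    freq_a: np.ndarray
    freq_b: np.ndarray
    diff: np.ndarray
    p_value: np.ndarray
    significant: np.ndarray
    alpha: float
    n_a: int
    n_b: int


def _oriented(transcript: str, frame: int) -> tuple[str, int]:
    seq = transcript.upper()
    if frame >= 3:
        return reverse_complement(seq), frame - 3
    return seq, frame


def call_terminal_stop(transcript_id: str, transcript: str, hit: CodeHit,
                       code: GeneticCode | None = None,
                       tol_subject_aa: int = 10,
                       tol_downstream_codons: int = 10) -> TerminalStopCall:
    """Call the transcript's terminal stop from its best alignment.

    The ORF is complete when (a) the alignment reaches within
    ``tol_subject_aa`` residues of the subject's end and (b) the first
    in-frame standard-code stop at or after the alignment end lies within
    ``tol_downstream_codons`` codons.  The identity of that codon is the
    call.  ``code`` supplies the stop set scanned for (default: standard).
    """
    if code is None:
        code = load_tables((1,))[1]
    stops = code.stop_codons
    seq, offset = _oriented(transcript, hit.frame)
    aln = hit.alignment
    near_end = aln.subject_end >= hit.subject_len - tol_subject_aa

    # in-frame codons, 1-based protein positions
    upstream: Counter = Counter()
    stop_codon = None
    stop_pos = None
    stop_aa_pos = None
    aa_pos = 0
    for i in range(offset, len(seq) - 2, 3):
        aa_pos += 1
        codon = seq[i:i + 3]
        if codon in stops:
            if aa_pos <= aln.query_end:
                if aa_pos >= aln.query_start:
                    upstream[codon] += 1
            elif stop_codon is None:
                stop_codon = codon
                stop_pos = i + 1
                stop_aa_pos = aa_pos
    if stop_codon is None:
        return TerminalStopCall(transcript_id, None, None, False, upstream)
    within = (stop_aa_pos - aln.query_end) <= tol_downstream_codons
    complete = bool(near_end and within)
    return TerminalStopCall(transcript_id, stop_codon, stop_pos, complete, upstream)


def relative_last_recoded_position(hit: CodeHit, transcript: str,
                                   codon: str = "TGA") -> float | None:
    """Subject-relative position of the most 3' occurrence of ``codon``.

    Returns (subject coordinate of the residue aligned to the last in-span
    occurrence) / subject length, in (0, 1]; None when the codon is absent
    from the aligned span (or aligned only to gaps).
    """
    from .comparison import stop_aligned_residues
    aln = hit.alignment
    # map query protein position -> subject coordinate
    sub_coord: dict[int, int] = {}
    qpos = aln.query_start - 1
    spos = aln.subject_start - 1
    for qc, sc in aln.pairs:
        if qc != "-":
            qpos += 1
        if sc != "-":
            spos += 1
        if qc != "-" and sc != "-":
            sub_coord[qpos] = spos
    seq, offset = _oriented(transcript, hit.frame)
    last = None
    aa_pos = 0
    for i in range(offset, len(seq) - 2, 3):
        aa_pos += 1
        if seq[i:i + 3] == codon and aa_pos in sub_coord:
            last = sub_coord[aa_pos]
    if last is None:
        return None
    return last / hit.subject_len


def extract_context(transcript: str, codon_nt_pos: int,
                    up: int = 5, down: int = 12,
                    sense_label: str = "stop") -> ContextWindow | None:
    """Window around the codon at 1-based ``codon_nt_pos``; None when the
    window would overrun either end of the transcript (skipped, not padded)."""
    seq = transcript.upper()
    start = codon_nt_pos - up
    end = codon_nt_pos + 2 + down  # 1-based inclusive end
    if start < 1 or end > len(seq):
        return None
    return ContextWindow(upstream=seq[start - 1:codon_nt_pos - 1],
                         codon=seq[codon_nt_pos - 1:codon_nt_pos + 2],
                         downstream=seq[codon_nt_pos + 2:end],
                         sense_label=sense_label)


def extract_context_set(transcript: str, positions: list[int],
                        up: int = 5, down: int = 12,
                        sense_label: str = "stop") -> tuple[list[ContextWindow], int]:
    """Windows for many codon positions; returns (windows, n_skipped)."""
    windows, skipped = [], 0
    for pos in positions:
        w = extract_context(transcript, pos, up, down, sense_label)
        if w is None:
            skipped += 1
        else:
            windows.append(w)
    return windows, skipped


def _indicator_array(windows: list[ContextWindow]) -> np.ndarray:
    """(n_windows, 17, 4) one-hot base indicators over the flank positions."""
    n = len(windows)
    width = len(windows[0].flanks)
    arr = np.zeros((n, width, 4), dtype=np.float64)
    idx = {b: i for i, b in enumerate(_BASES)}
    for w_i, w in enumerate(windows):
        for p, base in enumerate(w.flanks):
            j = idx.get(base)
            if j is not None:
                arr[w_i, p, j] = 1.0
    return arr


def two_sample_logo(group_a: list[ContextWindow], group_b: list[ContextWindow],
                    alpha: float = 0.05, min_group_size: int = 20,
                    welch: bool = False) -> LogoResult:
    """Two-sample t-test on base-presence indicators at every flank position.

    For each position and base, the indicator (1 if the window carries that
    base) is compared between groups with a pooled-variance two-sample t-test
    (Welch optional).  Group means are the base frequencies, so the reported
    difference is freq_A - freq_B.  No multiple-testing correction is applied.
    """
    if len(group_a) < min_group_size or len(group_b) < min_group_size:
        raise ValueError(f"both groups must have >= {min_group_size} windows")
    a = _indicator_array(group_a)
    b = _indicator_array(group_b)
    n_a, n_b = a.shape[0], b.shape[0]
    pa, pb = a.mean(axis=0), b.mean(axis=0)
    if welch:
        _t, p = stats.ttest_ind(a, b, axis=0, equal_var=False)
    else:
        _t, p = stats.ttest_ind(a, b, axis=0, equal_var=True)
    p = np.asarray(p)
    # identical all-zero or all-one columns: no variance, no difference
    p = np.where(np.isnan(p), 1.0, p)
    diff = pa - pb
    return LogoResult(freq_a=pa, freq_b=pb, diff=diff, p_value=p,
                      significant=p < alpha, alpha=alpha, n_a=n_a, n_b=n_b)


def codon_position_base_frequencies(coding_regions: list[str]) -> np.ndarray:
    """(3, 4) base frequencies at codon positions 1-3 over in-frame CDS."""
    counts = np.zeros((3, 4), dtype=np.int64)
    idx = {b: i for i, b in enumerate(_BASES)}
    for cds in coding_regions:
        s = cds.upper()
        if len(s) % 3 != 0:
            raise ValueError("coding region length must be divisible by 3")
        for i, base in enumerate(s):
            j = idx.get(base)
            if j is not None:
                counts[i % 3, j] += 1
    totals = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        freqs = counts / totals
    return freqs


def logo_table(result: LogoResult) -> list[dict]:
    """Flat rows (position, base, freqA, freqB, diff, p, significant)."""
    rows = []
    for p in range(result.freq_a.shape[0]):
        for b_i, base in enumerate(_BASES):
            rows.append({
                "position": p + 1, "base": base,
                "freq_a": result.freq_a[p, b_i],
                "freq_b": result.freq_b[p, b_i],
                "diff": result.diff[p, b_i],
                "p_value": result.p_value[p, b_i],
                "significant": bool(result.significant[p, b_i]),
            })
    return rows
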