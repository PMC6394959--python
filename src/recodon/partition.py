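"""AT-content partitioning, spliced-leader detection and reference-set selection.

In a mixed host/parasite transcriptome the parasite fraction is strongly
AT-biased; a simple AT-content threshold (default >= 58%, boundary
inclusive) separates the two.  The dinoflagellate spliced leader's 3' end
(CTCAAG) near the 5' terminus marks trans-spliced mRNAs.  The stop-codon
reference set — sequences trusted to use UGA only as a terminator — is the
intersection of five criteria: very low e-value, parasite-level AT content,
no score improvement under alternative codes, one (longest) representative
per assembly graph component, and absence from a caller-supplied
contaminant exclusion list.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .comparison import EQUAL, CodeComparisonRecord


@dataclass(frozen=True)
class PartitionConfig:
    at_threshold: float = 0.58
    sl_motif: str = "CTCAAG"
    sl_window: int = 30

    def __post_init__(self) -> None:
        if not 0 < self.at_threshold < 1:
            raise ValueError("at_threshold must be in (0, 1)")
        if self.sl_window < len(self.sl_motif):
            raise ValueError("sl_window must be >= motif length")


@dataclass(frozen=True)
class SelectionCriteria:
    max_evalue: float = 1e-100
    min_at: float = 0.58
    require_no_improvement: bool = True
    one_per_component: bool = True
    exclusion_ids: frozenset[str] = field(default_factory=frozenset)


def at_content(seq: str) -> float:
    """(A+T) / unambiguous length; ambiguous bases excluded from both sides."""
    if not seq:
        raise ValueError("empty sequence")
    s = seq.upper()
    at = s.count("A") + s.count("T")
    gc = s.count("G") + s.count("C")
    if at + gc == 0:
        raise ValueError("sequence has no unambiguous bases")
    return at / (at + gc)


def partition_by_at(seqs: dict[str, str],
                    config: PartitionConfig = PartitionConfig()) -> tuple[dict[str, str], dict[str, str]]:
    """Split into (high_at, low_at); the threshold boundary is inclusive high."""
    high, low = {}, {}
    for sid, seq in seqs.items():
        if at_content(seq) >= config.at_threshold:
            high[sid] = seq
        else:
            low[sid] = seq
    return high, low


def detect_spliced_leader(seq: str,
                          config: PartitionConfig = PartitionConfig()) -> bool:
    """True iff the motif starts within the first ``sl_window`` bases."""
    prefix = seq.upper()[:config.sl_window]
    return config.sl_motif.upper() in prefix


def select_stop_reference_set(records: list[CodeComparisonRecord],
                              lengths: dict[str, int],
                              criteria: SelectionCriteria = SelectionCriteria()) -> set[str]:
    """Transcripts usable as the UGA-as-stop reference set.

    A record passes when its best-hit e-value is below ``max_evalue``, its AT
    content is at least ``min_at``, its classification shows no improvement
    under alternative codes, it is the longest member of its graph component
    (when ``one_per_component``), and its id is not excluded.  Records
    lacking a best hit or AT annotation never pass.
    """
    candidates: list[CodeComparisonRecord] = []
    for rec in records:
        if rec.transcript_id in criteria.exclusion_ids:
            continue
        hit = rec.best_hit
        if hit is None or hit.evalue >= criteria.max_evalue:
            continue
        if rec.at_content is None or rec.at_content < criteria.min_at:
            continue
        if criteria.require_no_improvement and rec.classification != EQUAL:
            continue
        candidates.append(rec)
    if not criteria.one_per_component:
        return {rec.transcript_id for rec in candidates}
    best_per_component: dict[str, str] = {}
    for rec in candidates:
        comp = rec.component_id or rec.transcript_id
        cur = best_per_component.get(comp)
        if cur is None or (lengths[rec.transcript_id], rec.transcript_id) > \
                (lengths[cur], cur):
            best_per_component[comp] = rec.transcript_id
    return set(best_per_component.values())
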