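"""Synthetic data with known truth for every pipeline stage.

The generator emulates the statistical structure the inference assumes:

* a reference proteome (subject database) with realistic amino-acid
  composition;
* parasite-like transcripts produced by back-translating a diverged copy of
  a reference protein under a *contingent* code — ciliate-nuclear (table 6)
  synonymous families, UAA/UAG carrying part of the glutamine mass, UGA
  carrying part of the tryptophan mass, and UGA as the terminal stop — with
  AT-biased synonymous third positions and AT-rich UTRs;
* host-like transcripts under the standard code with no internal
  standard-code stop codons by construction;
* genome/transcript pairs with exact planted A→G / T→C editing sites,
  optionally on the minus strand;
* tRNA inventories with planted exact-decoder counts plus pseudogene and
  low-coverage decoys.

Every generator draws from an independent, named sub-stream of one
top-level seed, so outputs are byte-reproducible and adding one generator
call does not perturb the others.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

from .genetic_codes import ALL_CODONS, GeneticCode, load_tables, reverse_complement

# Average amino-acid frequencies of well-annotated proteomes (percent scale;
# normalised at use).  Trp ~1%, Gln ~4% — the two residues whose codon
# families carry the reassignment signal.
DEFAULT_AA_FREQS: dict[str, float] = {
    "A": 8.25, "R": 5.53, "N": 4.06, "D": 5.45, "C": 1.37, "Q": 3.93,
    "E": 6.75, "G": 7.07, "H": 2.27, "I": 5.96, "L": 9.66, "K": 5.84,
    "M": 2.42, "F": 3.86, "P": 4.70, "S": 6.56, "T": 5.34, "W": 1.08,
    "Y": 2.92, "V": 6.87,
}

CONTINGENT = "contingent"

_STREAM = {"proteome": 0, "transcriptome": 1, "editing": 2, "trna": 3}


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic transcriptome.

    The defaults are the parasite-like condition: contingent code (table-6
    families with P(TAA|Q)=0.25, P(TAG|Q)=0.10, P(TGA|W)=0.30), protein-level
    divergence 0.2 between transcript and subject, synonymous third-position
    A+T target 0.75 and AT-rich UTRs.  ``host_like()`` switches to the
    standard-code, GC-richer host condition.
    """

    seed: int
    n_proteins: int = 100
    protein_length_mean: float = 150.0
    protein_length_sd: float = 40.0
    protein_length_min: int = 50
    aa_freqs: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_AA_FREQS))
    n_transcripts: int = 200
    divergence: float = 0.2
    code_truth: int | str = CONTINGENT
    p_taa_q: float = 0.25
    p_tag_q: float = 0.10
    p_tga_w: float = 0.30
    at3_bias: float = 0.75
    uga_5prime_half_only: bool = False
    utr5_mean: float = 30.0
    utr5_sd: float = 10.0
    utr3_mean: float = 60.0
    utr3_sd: float = 20.0
    utr_at: float = 0.65

    def __post_init__(self) -> None:
        for name in ("divergence", "p_taa_q", "p_tag_q", "p_tga_w",
                     "at3_bias", "utr_at"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.p_taa_q + self.p_tag_q > 1.0:
            raise ValueError("P(TAA|Q) + P(TAG|Q) must not exceed 1")

    def host_like(self) -> "SimulationConfig":
        """Standard-code, GC-richer condition emulating the host fraction."""
        return replace(self, code_truth=1, p_taa_q=0.0, p_tag_q=0.0,
                       p_tga_w=0.0, at3_bias=0.45, utr_at=0.45)


@dataclass
class TranscriptTruth:
    transcript_id: str
    ref_id: str
    encoded_protein: str
    code: int | str
    cds_start: int  # 1-based first base of the CDS
    cds_len_nt: int  # excluding the terminal stop
    utr5_len: int
    utr3_len: int
    stop_codon: str
    stop_nt_pos: int
    tga_positions: list[int] = field(default_factory=list)  # coding TGA (=Trp)
    taa_positions: list[int] = field(default_factory=list)  # coding TAA (=Gln)
    tag_positions: list[int] = field(default_factory=list)  # coding TAG (=Gln)

    @property
    def n_reassigned(self) -> int:
        return len(self.tga_positions) + len(self.taa_positions) + len(self.tag_positions)


@dataclass
class TruthTable:
    transcripts: dict[str, TranscriptTruth] = field(default_factory=dict)

    def __getitem__(self, tid: str) -> TranscriptTruth:
        return self.transcripts[tid]

    def __len__(self) -> int:
        return len(self.transcripts)


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(_STREAM[stream],)))


def truth_decoder_code(config: SimulationConfig) -> GeneticCode:
    """The code that decodes a simulated CDS back to its protein.

    For the contingent truth this is the ciliate table with UGA additionally
    read as Trp (no codon is a stop inside the CDS; termination is
    positional, by the appended terminal UGA).
    """
    if config.code_truth == CONTINGENT:
        base = load_tables((6,))[6]
        mapping = dict(base.codon_to_aa)
        mapping["TGA"] = "W"
        return GeneticCode(table_id=0, name="contingent (ciliate + UGA=Trp)",
                           codon_to_aa=mapping)
    return load_tables((config.code_truth,))[config.code_truth]


def _codon_weights(code: GeneticCode, at3_bias: float) -> dict[str, tuple[list[str], np.ndarray]]:
    """Per-amino-acid codon lists and third-position-biased weights.

    Within each family the A/T-ending codons share probability ``at3_bias``
    and the G/C-ending codons share the rest, so every family that offers
    both classes realises exactly the target synonymous-third-position A+T
    fraction.  Families with a single third-base class (none among the
    standard multi-codon families) fall back to uniform.
    """
    fams: dict[str, list[str]] = {}
    for codon in ALL_CODONS:
        aa = code.codon_to_aa[codon]
        if aa != "*":
            fams.setdefault(aa, []).append(codon)
    out = {}
    for aa, codons in fams.items():
        at_codons = [c for c in codons if c[2] in "AT"]
        gc_codons = [c for c in codons if c[2] in "GC"]
        if at_codons and gc_codons:
            w = np.array([at3_bias / len(at_codons) if c[2] in "AT"
                          else (1 - at3_bias) / len(gc_codons)
                          for c in codons])
        else:
            w = np.full(len(codons), 1.0 / len(codons))
        out[aa] = (codons, w / w.sum())
    return out


def simulate_reference_proteome(config: SimulationConfig) -> dict[str, str]:
    """Reference (subject) proteins: iid residues, normal lengths (clipped)."""
    rng = _rng(config.seed, "proteome")
    aas = sorted(config.aa_freqs)
    p = np.array([config.aa_freqs[a] for a in aas], dtype=float)
    p = p / p.sum()
    proteome: dict[str, str] = {}
    for i in range(config.n_proteins):
        length = max(config.protein_length_min,
                     int(round(rng.normal(config.protein_length_mean,
                                          config.protein_length_sd))))
        seq = "".join(rng.choice(aas, size=length, p=p))
        proteome[f"ref_{i:04d}"] = seq
    return proteome


def _mutate_protein(protein: str, divergence: float, rng: np.random.Generator,
                    aas: list[str], p: np.ndarray) -> str:
    if divergence == 0:
        return protein
    out = list(protein)
    hits = np.nonzero(rng.random(len(out)) < divergence)[0]
    for i in hits:
        new = out[i]
        while new == out[i]:
            new = rng.choice(aas, p=p)
        out[i] = str(new)
    return "".join(out)


def _random_utr(length: int, at: float, rng: np.random.Generator) -> str:
    if length <= 0:
        return ""
    p = np.array([at / 2, (1 - at) / 2, (1 - at) / 2, at / 2])
    return "".join(rng.choice(["A", "C", "G", "T"], size=length, p=p))


def simulate_transcriptome(config: SimulationConfig,
                           proteome: dict[str, str]) -> tuple[dict[str, str], TruthTable]:
    """Back-translate diverged copies of reference proteins under the truth code.

    Each transcript: pick a reference protein, substitute residues at the
    divergence rate (the encoded protein), back-translate it codon by codon
    with the family weights, flank with UTRs, and terminate with the truth
    code's stop (UGA for the contingent code).  Every reassigned-codon
    position is recorded in the truth table.
    """
    if not proteome:
        raise ValueError("proteome must be non-empty")
    rng = _rng(config.seed, "transcriptome")
    contingent = config.code_truth == CONTINGENT
    base_code = load_tables((6,))[6] if contingent \
        else load_tables((config.code_truth,))[config.code_truth]
    weights = _codon_weights(base_code, config.at3_bias)
    aas = sorted(config.aa_freqs)
    p_aa = np.array([config.aa_freqs[a] for a in aas], dtype=float)
    p_aa = p_aa / p_aa.sum()
    ref_ids = sorted(proteome)

    # glutamine / tryptophan reassignment weights under the contingent code
    if contingent:
        q_codons = ["TAA", "TAG", "CAA", "CAG"]
        rem = 1.0 - config.p_taa_q - config.p_tag_q
        caa_share = config.at3_bias / 2 / (config.at3_bias / 2 + (1 - config.at3_bias) / 2)
        q_w = np.array([config.p_taa_q, config.p_tag_q,
                        rem * caa_share, rem * (1 - caa_share)])
        w_codons = ["TGA", "TGG"]
        w_w = np.array([config.p_tga_w, 1.0 - config.p_tga_w])
        w_w_tail = np.array([0.0, 1.0])  # used when UGA is restricted to the 5' half

    transcripts: dict[str, str] = {}
    truth = TruthTable()
    for t in range(config.n_transcripts):
        tid = f"tx_{t:05d}"
        ref_id = ref_ids[int(rng.integers(len(ref_ids)))]
        encoded = _mutate_protein(proteome[ref_id], config.divergence, rng, aas, p_aa)
        utr5_len = max(0, int(round(rng.normal(config.utr5_mean, config.utr5_sd))))
        utr3_len = max(0, int(round(rng.normal(config.utr3_mean, config.utr3_sd))))
        utr5 = _random_utr(utr5_len, config.utr_at, rng)
        utr3 = _random_utr(utr3_len, config.utr_at, rng)

        codons: list[str] = []
        tga_pos: list[int] = []
        taa_pos: list[int] = []
        tag_pos: list[int] = []
        half = len(encoded) / 2
        for i, aa in enumerate(encoded):
            if contingent and aa == "Q":
                codon = str(rng.choice(q_codons, p=q_w))
            elif contingent and aa == "W":
                w_sel = w_w_tail if (config.uga_5prime_half_only and i >= half) else w_w
                codon = str(rng.choice(w_codons, p=w_sel))
            else:
                fam_codons, fam_w = weights[aa]
                codon = str(rng.choice(fam_codons, p=fam_w))
            nt_pos = utr5_len + 3 * i + 1  # 1-based in the final transcript
            if codon == "TGA":
                tga_pos.append(nt_pos)
            elif codon == "TAA":
                taa_pos.append(nt_pos)
            elif codon == "TAG":
                tag_pos.append(nt_pos)
            codons.append(codon)
        cds = "".join(codons)
        if contingent:
            stop = "TGA"
        else:
            stops = sorted(base_code.stop_codons)
            stop = stops[int(rng.integers(len(stops)))]
        stop_nt_pos = utr5_len + len(cds) + 1
        transcripts[tid] = utr5 + cds + stop + utr3
        truth.transcripts[tid] = TranscriptTruth(
            transcript_id=tid, ref_id=ref_id, encoded_protein=encoded,
            code=config.code_truth, cds_start=utr5_len + 1,
            cds_len_nt=len(cds), utr5_len=utr5_len, utr3_len=len(utr3),
            stop_codon=stop, stop_nt_pos=stop_nt_pos,
            tga_positions=tga_pos, taa_positions=taa_pos, tag_positions=tag_pos)
    return transcripts, truth


def audit_truth(transcripts: dict[str, str], truth: TruthTable,
                config: SimulationConfig) -> None:
    """Raise if the truth table is inconsistent with the emitted sequences."""
    decoder = truth_decoder_code(config)
    for tid, row in truth.transcripts.items():
        seq = transcripts[tid]
        cds = seq[row.cds_start - 1: row.cds_start - 1 + row.cds_len_nt]
        prot = "".join(decoder.codon_to_aa[cds[i:i + 3]]
                       for i in range(0, len(cds), 3))
        if prot != row.encoded_protein:
            raise AssertionError(f"{tid}: decoded CDS does not match encoded protein")
        if seq[row.stop_nt_pos - 1: row.stop_nt_pos + 2] != row.stop_codon:
            raise AssertionError(f"{tid}: terminal stop mismatch")
        for positions, codon in ((row.tga_positions, "TGA"),
                                 (row.taa_positions, "TAA"),
                                 (row.tag_positions, "TAG")):
            for pos in positions:
                if seq[pos - 1: pos + 2] != codon:
                    raise AssertionError(f"{tid}: truth position {pos} is not {codon}")


@dataclass
class EditingTruth:
    gene_id: str
    strand: str
    sites: list[tuple[int, str, str]]  # (transcript_nt_pos, genome_base, transcript_base)


def simulate_editing_pair(seed: int, gene_id: str = "coxI",
                          gene_length: int = 1500,
                          n_edits: Mapping[str, int] | None = None,
                          strand: str = "+", flank: int = 200,
                          gene_at: float = 0.68) -> tuple[dict[str, str], dict[str, str], EditingTruth]:
    """Genome contig + transcript with exactly the requested planted edits.

    ``n_edits`` maps substitution labels (mRNA sense, e.g. ``"A->G"``) to the
    exact number of sites to plant at distinct eligible positions.  With
    ``strand="-"`` the contig carries the reverse complement of the gene
    region, exercising mRNA-sense reporting.
    """
    n_edits = dict({"A->G": 16, "T->C": 5} if n_edits is None else n_edits)
    rng = _rng(seed, "editing")
    p = np.array([gene_at / 2, (1 - gene_at) / 2, (1 - gene_at) / 2, gene_at / 2])
    gene = "".join(rng.choice(["A", "C", "G", "T"], size=gene_length, p=p))
    transcript = list(gene)
    sites: list[tuple[int, str, str]] = []
    taken: set[int] = set()
    for sub in sorted(n_edits):
        n = n_edits[sub]
        frm, to = sub.split("->")
        eligible = [i for i, b in enumerate(gene) if b == frm and i not in taken]
        if n > len(eligible):
            raise ValueError(f"{sub}: requested {n} sites, only {len(eligible)} "
                             f"eligible positions")
        chosen = rng.choice(len(eligible), size=n, replace=False)
        for k in sorted(int(c) for c in chosen):
            i = eligible[k]
            taken.add(i)
            transcript[i] = to
            sites.append((i + 1, frm, to))
    sites.sort()
    flank_l = _random_utr(flank, 0.5, rng)
    flank_r = _random_utr(flank, 0.5, rng)
    contig = flank_l + gene + flank_r
    if strand == "-":
        contig = reverse_complement(contig)
    genome = {f"contig_{gene_id}": contig}
    transcripts = {gene_id: "".join(transcript)}
    return genome, transcripts, EditingTruth(gene_id, strand, sites)


_AA3 = {
    "A": "Ala", "R": "Arg", "N": "Asn", "D": "Asp", "C": "Cys", "Q": "Gln",
    "E": "Glu", "G": "Gly", "H": "His", "I": "Ile", "L": "Leu", "K": "Lys",
    "M": "Met", "F": "Phe", "P": "Pro", "S": "Ser", "T": "Thr", "W": "Trp",
    "Y": "Tyr", "V": "Val", "*": "Sup",
}


def simulate_trna_inventory(seed: int, decoder_spec: Mapping[str, int],
                            n_pseudogenes: int = 0,
                            n_low_coverage: int = 0) -> tuple[str, dict[str, int]]:
    """tRNAscan-SE-like tabular text with planted exact-decoder counts.

    Genuine records get coverage >= 10; decoys are emitted as pseudogenes or
    low-coverage records (both removable by ``filter_genuine``) and are not
    part of the returned truth counts.  The TGA decoder is labelled SeC,
    matching how a scanner reports the selenocysteine tRNA.
    """
    rng = _rng(seed, "trna")
    code6 = load_tables((6,))[6]
    lines = ["Sequence\ttRNA #\tBegin\tEnd\tType\tCodon\tIntron Begin\t"
             "Intron End\tScore\tNote",
             "--------\t------\t-----\t---\t----\t-----\t------------\t"
             "----------\t-----\t----"]
    truth: dict[str, int] = {}
    counter = 0

    def emit(codon: str, cov: float, note_extra: str = "") -> None:
        nonlocal counter
        counter += 1
        anticodon = reverse_complement(codon)
        aa = code6.codon_to_aa[codon]
        isotype = "SeC" if codon == "TGA" else _AA3.get(aa, "Sup")
        begin = int(rng.integers(1, 50_000))
        end = begin + 71
        if rng.random() < 0.5:
            begin, end = end, begin  # minus strand, tRNAscan convention
        score = float(np.round(rng.uniform(40, 90), 1))
        note = f"cov={cov:.1f}" + (f" {note_extra}" if note_extra else "")
        lines.append(f"gscaf_{counter:04d}\t1\t{begin}\t{end}\t{isotype}\t"
                     f"{anticodon}\t0\t0\t{score}\t{note}")

    for codon in sorted(decoder_spec):
        n = decoder_spec[codon]
        for _ in range(n):
            emit(codon, cov=float(np.round(rng.uniform(10, 100), 1)))
        if n:
            truth[codon] = n
    decoy_codons = sorted(ALL_CODONS)
    for _ in range(n_pseudogenes):
        codon = decoy_codons[int(rng.integers(len(decoy_codons)))]
        emit(codon, cov=float(np.round(rng.uniform(10, 100), 1)),
             note_extra="pseudo")
    for _ in range(n_low_coverage):
        codon = decoy_codons[int(rng.integers(len(decoy_codons)))]
        emit(codon, cov=float(np.round(rng.uniform(1, 9.9), 1)))
    return "\n".join(lines) + "\n", truth
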