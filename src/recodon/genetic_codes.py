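"""NCBI translation tables and six-frame translation.

The inference at the heart of this package asks which genetic code best
explains a transcriptome: the standard code (NCBI table 1), the mold/
protozoan mitochondrial code (table 4, UGA = Trp), the ciliate nuclear code
(table 6, UAA/UAG = Gln), or any of the other tables a translated search
tool implements.  This module represents those tables and translates DNA
under them.

Codons are kept in the DNA alphabet internally (T, not U); reports may
print U for readability but every lookup key here is DNA.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

from Bio.Data import CodonTable as _BioCodonTable

#: The 19 NCBI tables implemented by translated-search tools and bundled here.
BUNDLED_TABLE_IDS: tuple[int, ...] = (1, 2, 3, 4, 5, 6, 9, 10, 11, 12, 13, 14, 15, 16,
                                      21, 22, 23, 24, 25)

_BASES = "ACGT"
ALL_CODONS: tuple[str, ...] = tuple(a + b + c for a in _BASES for b in _BASES for c in _BASES)

_COMPLEMENT = str.maketrans("ACGTNRYSWKMBDHVacgtnryswkmbdhv",
                            "TGCANYRSWMKVHDBtgcanyrswmkvhdb")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string (IUPAC codes tolerated)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GeneticCode:
    """One NCBI-style translation table.

    Attributes
    ----------
    table_id : int
        NCBI table number.
    name : str
        NCBI table name (e.g. ``"Ciliate Nuclear"``).
    codon_to_aa : dict
        All 64 DNA codons mapped to a one-letter amino acid or ``'*'``.
    stop_codons : frozenset
        Codons mapped to ``'*'``.
    """

    table_id: int
    name: str
    codon_to_aa: dict[str, str]
    stop_codons: frozenset[str] = field(init=False)

    def __post_init__(self) -> None:
        if set(self.codon_to_aa) != set(ALL_CODONS):
            raise ValueError(f"table {self.table_id}: must map exactly the 64 codons")
        object.__setattr__(
            self, "stop_codons",
            frozenset(c for c, aa in self.codon_to_aa.items() if aa == "*"))

    def translate_codon(self, codon: str) -> str:
        """Amino acid for one codon; 'X' if the codon has non-ACGT characters."""
        aa = self.codon_to_aa.get(codon.upper())
        return aa if aa is not None else "X"


@dataclass(frozen=True)
class CodeTableSet:
    """The collection of loaded genetic codes, keyed by NCBI table id."""

    tables: dict[int, GeneticCode]

    def __getitem__(self, table_id: int) -> GeneticCode:
        return self.tables[table_id]

    def __iter__(self):
        return iter(self.tables.values())

    def __len__(self) -> int:
        return len(self.tables)

    @property
    def ids(self) -> tuple[int, ...]:
        return tuple(sorted(self.tables))


def _from_biopython(table_id: int) -> GeneticCode:
    bt = _BioCodonTable.unambiguous_dna_by_id[table_id]
    mapping = {c: bt.forward_table.get(c, "*") for c in ALL_CODONS}
    for stop in bt.stop_codons:
        mapping[stop] = "*"
    return GeneticCode(table_id=table_id, name=bt.names[0], codon_to_aa=mapping)


def load_tables(ids: Iterable[int] = BUNDLED_TABLE_IDS) -> CodeTableSet:
    """Load NCBI translation tables (default: the 19 used in translated searches)."""
    return CodeTableSet(tables={i: _from_biopython(i) for i in ids})


def load_custom_table(path: str) -> GeneticCode:
    """Read a custom code from text: first line ``table_id<TAB>name``, then 64
    lines ``codon<TAB>aa``."""
    with open(path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip() and not ln.startswith("#")]
    head = lines[0].split("\t")
    table_id, name = int(head[0]), (head[1] if len(head) > 1 else f"custom_{head[0]}")
    mapping: dict[str, str] = {}
    for ln in lines[1:]:
        codon, aa = ln.split("\t")
        mapping[codon.upper()] = aa.upper()
    return GeneticCode(table_id=table_id, name=name, codon_to_aa=mapping)


def translate(seq: str, frame: int, code: GeneticCode) -> str:
    """Translate ``seq`` in one of six frames under ``code``.

    Frames 0-2 read the forward strand with offsets 0-2; frames 3-5 read the
    reverse complement with offsets 0-2.  One character is emitted per
    complete codon; stops are ``'*'`` and codons containing non-ACGT
    characters become ``'X'``.
    """
    if not 0 <= frame <= 5:
        raise ValueError(f"frame must be 0-5, got {frame}")
    s = seq.upper()
    if frame >= 3:
        s = reverse_complement(s)
        frame -= 3
    s = s[frame:]
    n = len(s) - len(s) % 3
    lookup = code.codon_to_aa
    return "".join(lookup.get(s[i:i + 3], "X") for i in range(0, n, 3))


def translate_six_frames(seq: str, code: GeneticCode) -> list[str]:
    """Translations of all six frames, indexed by frame 0-5."""
    return [translate(seq, f, code) for f in range(6)]


def tables_recoding(codon: str, aa: str,
                    tables: CodeTableSet | None = None) -> list[int]:
    """Ids of loaded tables translating ``codon`` as ``aa``, ascending.

    With the bundled 19 tables, ``tables_recoding("TGA", "W")`` returns the
    nine tables that read UGA as tryptophan.
    """
    codon = codon.upper()
    if codon not in ALL_CODONS:
        raise ValueError(f"invalid codon {codon!r}")
    if tables is None:
        tables = load_tables()
    return sorted(t.table_id for t in tables if t.codon_to_aa[codon] == aa.upper())
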