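"""Genetic code tables for translation under NCBI codes 1 and 4.

Code 4 (mold/protozoan/coelenterate mitochondrial) is the reading frame
convention for fungal mitochondria and mitoviruses: it is identical to the
standard code except that UGA encodes tryptophan instead of stop.  Tables
are taken from Biopython's NCBI codon-table data rather than typed by hand.
"""

from __future__ import annotations

import dataclasses
import itertools
from functools import lru_cache

from Bio.Data import CodonTable as _BioCodonTable

STOP = "*"
CANONICAL_START = "AUG"
#: Alternative initiation codons considered when refining start calls.
DEFAULT_ALTERNATIVE_STARTS = frozenset({"GUG", "AUU"})

ALL_CODONS = tuple(
    "".join(c) for c in itertools.product("UCAG", repeat=3)
)


@dataclasses.dataclass(frozen=True)
class GeneticCode:
    """A total map from the 64 RNA codons to amino acids or ``'*'`` (stop).

    Attributes
    ----------
    code_id : int
        NCBI translation table number (1 = standard, 4 = mold/protozoan
        mitochondrial).
    table : dict
        Codon -> single-letter amino acid, with stops as ``'*'``.
    canonical_start : str
        The conventional initiation codon (AUG).
    alternative_starts : frozenset of str
        Codons considered as possible alternative initiators.
    """

    code_id: int
    table: dict
    canonical_start: str = CANONICAL_START
    alternative_starts: frozenset = DEFAULT_ALTERNATIVE_STARTS

    def __post_init__(self) -> None:
        missing = set(ALL_CODONS) - set(self.table)
        if missing:
            raise ValueError(f"genetic code table missing codons: {sorted(missing)}")

    @property
    def stop_codons(self) -> frozenset:
        return frozenset(c for c, aa in self.table.items() if aa == STOP)

    @property
    def start_codons(self) -> frozenset:
        """All codons accepted as initiators (canonical + alternatives)."""
        return frozenset({self.canonical_start}) | self.alternative_starts

    def is_stop(self, codon: str) -> bool:
        return self.table.get(codon) == STOP


@lru_cache(maxsize=None)
def get_code(code_id: int = 4) -> GeneticCode:
    """Return the :class:`GeneticCode` for an NCBI translation table id."""
    try:
        bio = _BioCodonTable.unambiguous_rna_by_id[code_id]
    except KeyError as exc:
        raise ValueError(f"unknown NCBI translation table id: {code_id}") from exc
    table = dict(bio.forward_table)
    for codon in bio.stop_codons:
        table[codon] = STOP
    return GeneticCode(code_id=code_id, table=table)
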