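"""FASTA input/output and sequence normalization.

All sequences are held internally in the RNA alphabet: ``T`` is raised to
``U`` on ingestion so that downstream codon logic (AUG starts, UGA stops or
Trp) only ever sees RNA codons.  IUPAC ambiguity letters are retained and
handled downstream as untranslatable.
"""

from __future__ import annotations

import dataclasses
import io
from pathlib import Path
from typing import Iterable, Sequence

#: RNA alphabet plus IUPAC ambiguity letters (post T->U normalization).
IUPAC_RNA = frozenset("ACGUNRYSWKMBDHV")


class FastaError(ValueError):
    """Malformed FASTA input (duplicate ids, empty records, bad characters)."""


@dataclasses.dataclass(frozen=True)
class NucSeq:
    """A named plus-strand nucleotide sequence in the RNA alphabet.

    Parameters
    ----------
    id : str
        Record identifier, unique within a dataset.
    residues : str
        Uppercase RNA residues (``ACGU`` plus IUPAC ambiguity letters).
    source : str
        Free-text provenance tag.
    """

    id: str
    residues: str
    source: str = ""

    def __post_init__(self) -> None:
        norm = normalize_residues(self.residues)
        if norm != self.residues:
            object.__setattr__(self, "residues", norm)
        if not self.residues:
            raise FastaError(f"record {self.id!r}: empty sequence")
        bad = set(self.residues) - IUPAC_RNA
        if bad:
            raise FastaError(
                f"record {self.id!r}: characters outside IUPAC alphabet: "
                f"{sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)


def normalize_residues(raw: str) -> str:
    """Uppercase and convert DNA ``T`` to RNA ``U``.  Idempotent."""
    return raw.upper().replace("T", "U").replace(" ", "").replace("\t", "")


_COMPLEMENT = str.maketrans("ACGUNRYSWKMBDHV", "UGCANYRSWMKVHDB")


def reverse_complement(residues: str) -> str:
    """Reverse complement in the RNA alphabet (ambiguity-aware)."""
    return residues.translate(_COMPLEMENT)[::-1]


def read_fasta(path: str | Path) -> list[NucSeq]:
    """Read a FASTA file into an ordered list of :class:`NucSeq`.

    Lowercase is raised to uppercase and T is converted to U.  Errors
    (missing file, duplicate ids, empty records, non-IUPAC characters) are
    reported with the offending record id and line number.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such FASTA file: {path}")
    with open(path, "rt", encoding="utf-8") as fh:
        return _parse_fasta(fh, str(path))


def parse_fasta_str(text: str, source: str = "<string>") -> list[NucSeq]:
    """Parse FASTA-formatted text (same contract as :func:`read_fasta`)."""
    return _parse_fasta(io.StringIO(text), source)


def _parse_fasta(fh: Iterable[str], source: str) -> list[NucSeq]:
    records: list[NucSeq] = []
    seen: set[str] = set()
    cur_id: str | None = None
    cur_line = 0
    chunks: list[str] = []

    def flush() -> None:
        if cur_id is None:
            return
        residues = normalize_residues("".join(chunks))
        if not residues:
            raise FastaError(f"{source}:{cur_line}: record {cur_id!r} is empty")
        bad = set(residues) - IUPAC_RNA
        if bad:
            raise FastaError(
                f"{source}:{cur_line}: record {cur_id!r} contains characters "
                f"outside the IUPAC alphabet: {sorted(bad)}"
            )
        records.append(NucSeq(id=cur_id, residues=residues, source=source))

    for lineno, line in enumerate(fh, start=1):
        line = line.rstrip("\n\r")
        if not line.strip():
            continue
        if line.startswith(">"):
            flush()
            cur_id = line[1:].split()[0] if line[1:].strip() else ""
            if not cur_id:
                raise FastaError(f"{source}:{lineno}: header with no id")
            if cur_id in seen:
                raise FastaError(f"{source}:{lineno}: duplicate record id {cur_id!r}")
            seen.add(cur_id)
            cur_line = lineno
            chunks = []
        else:
            if cur_id is None:
                raise FastaError(f"{source}:{lineno}: sequence data before any header")
            chunks.append(line.strip())
    flush()
    return records


def write_fasta(
    seqs: Sequence[NucSeq], path: str | Path, line_width: int = 60
) -> None:
    """Write sequences as wrapped multi-record FASTA.

    Round-trips with :func:`read_fasta` up to T->U normalization.
    """
    if line_width < 1:
        raise ValueError("line_width must be a positive integer")
    ids = [s.id for s in seqs]
    if len(set(ids)) != len(ids):
        raise FastaError("duplicate ids in output set")
    path = Path(path)
    with open(path, "wt", encoding="utf-8") as fh:
        for seq in seqs:
            fh.write(f">{seq.id}\n")
            for i in range(0, len(seq.residues), line_width):
                fh.write(seq.residues[i : i + line_width] + "\n")


def write_tsv(rows: Sequence[dict], path: str | Path, columns: Sequence[str] | None = None) -> None:
    """Write a list of dict rows as a UTF-8 TSV with a header row."""
    if columns is None:
        columns = list(rows[0].keys()) if rows else []
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("\t".join(columns) + "\n")
        for row in rows:
            fh.write("\t".join(str(row.get(c, "")) for c in columns) + "\n")
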