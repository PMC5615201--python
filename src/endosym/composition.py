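"""Nucleotide sequence records, FASTA I/O, and base-composition statistics.

AT content is the standard genome-reduction signature for insect
endosymbionts: obligate intracellular lineages accumulate A/T through
mutational bias and relaxed selection, so the percentage of A+T among
unambiguous bases in a 16S rRNA gene is a quick proxy for how far down the
reductive road a symbiont has travelled.
"""

from __future__ import annotations

import io
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.SeqIO.FastaIO import FastaWriter
from Bio.SeqRecord import SeqRecord
from Bio.Seq import Seq

__all__ = [
    "SequenceRecord",
    "CompositionSummary",
    "FastaParseError",
    "read_fasta",
    "write_fasta",
    "at_content",
    "gc_content",
    "ungapped_length",
]

# Unambiguous bases, RNA uracil, IUPAC ambiguity codes, and gap characters.
_UNAMBIGUOUS = set("ACGT")
_AMBIGUOUS = set("URYSWKMBDHVN")
_GAPS = set("-.")
_ALPHABET = _UNAMBIGUOUS | _AMBIGUOUS | _GAPS


class FastaParseError(ValueError):
    """Raised for malformed FASTA input; message names the offending line."""


@dataclass(frozen=True)
class SequenceRecord:
    """A named nucleotide sequence (uppercase, validated alphabet)."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be nonempty")
        object.__setattr__(self, "residues", self.residues.upper())
        bad = set(self.residues) - _ALPHABET
        if bad:
            raise ValueError(
                f"record {self.id!r}: illegal residue characters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class CompositionSummary:
    """Per-sequence base counts and AT content (percent of unambiguous bases)."""

    length_ungapped: int
    a: int
    c: int
    g: int
    t: int
    ambiguous_count: int
    at_content: float

    def __post_init__(self) -> None:
        total = self.a + self.c + self.g + self.t + self.ambiguous_count
        if total != self.length_ungapped:
            raise ValueError("base counts do not sum to ungapped length")


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a FASTA file into validated records.

    Residues are upper-cased; U is preserved as written (counted as T only
    by the composition statistics). Raises :class:`FastaParseError` naming
    the first offending line for empty files, data before the first header,
    or illegal characters.
    """
    path = Path(path)
    text = path.read_text()
    # Pre-validate line by line so errors can name the line; Biopython's
    # parser is permissive and would silently accept arbitrary characters.
    seen_header = False
    nonblank = 0
    for lineno, line in enumerate(text.splitlines(), start=1):
        stripped = line.strip()
        if not stripped:
            continue
        nonblank += 1
        if stripped.startswith(">"):
            if len(stripped) == 1 or not stripped[1:].strip():
                raise FastaParseError(f"{path}:{lineno}: empty FASTA header")
            seen_header = True
        else:
            if not seen_header:
                raise FastaParseError(
                    f"{path}:{lineno}: sequence data before any '>' header"
                )
            bad = set(stripped.upper()) - _ALPHABET
            if bad:
                raise FastaParseError(
                    f"{path}:{lineno}: illegal characters {sorted(bad)}"
                )
    if nonblank == 0:
        raise FastaParseError(f"{path}:1: empty FASTA file")
    records = [
        SequenceRecord(id=rec.id, residues=str(rec.seq))
        for rec in SeqIO.parse(io.StringIO(text), "fasta")
    ]
    if not records:
        raise FastaParseError(f"{path}:1: no records parsed")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    """Write records as FASTA, wrapped at 70 columns (bit-stable output)."""
    seqs = [
        SeqRecord(Seq(rec.residues), id=rec.id, description="") for rec in records
    ]
    with open(path, "w") as handle:
        FastaWriter(handle, wrap=70).write_file(seqs)


def _count(record: SequenceRecord) -> Counter:
    counts = Counter(record.residues)
    # rRNA-style input: uracil behaves as thymine throughout.
    counts["T"] += counts.pop("U", 0)
    return counts


def at_content(record: SequenceRecord) -> CompositionSummary:
    """Base counts and AT content of one record.

    AT content is ``100*(A+T)/(A+C+G+T)``; gaps and ambiguity codes are
    excluded from both numerator and denominator. Raises ``ValueError`` if
    the record contains no unambiguous base.
    """
    counts = _count(record)
    a, c, g, t = (counts.get(b, 0) for b in "ACGT")
    ambiguous = sum(counts.get(b, 0) for b in _AMBIGUOUS)
    unambiguous = a + c + g + t
    if unambiguous == 0:
        raise ValueError(
            f"record {record.id!r} has no unambiguous bases; AT content undefined"
        )
    return CompositionSummary(
        length_ungapped=unambiguous + ambiguous,
        a=a,
        c=c,
        g=g,
        t=t,
        ambiguous_count=ambiguous,
        at_content=100.0 * (a + t) / unambiguous,
    )


def gc_content(record: SequenceRecord) -> float:
    """GC percentage computed identically to :func:`at_content` (their sum is 100)."""
    summary = at_content(record)
    return 100.0 * (summary.g + summary.c) / (summary.a + summary.c + summary.g + summary.t)


def ungapped_length(record: SequenceRecord) -> int:
    """Number of non-gap characters (ambiguity codes included)."""
    return sum(1 for ch in record.residues if ch not in _GAPS)
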