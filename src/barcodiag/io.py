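"""Labeled sequence collections and FASTA round-tripping.

Species labels travel in FASTA headers as a ``species=...`` key-value pair,
e.g. ``>seq_007 species=Ursus arctos``.  Records without the key are treated
as unlabeled queries and carry the reserved label ``QUERY``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: Reserved label for sequences under identification (not part of any species).
QUERY_LABEL = "QUERY"

#: Canonical nucleotide alphabet used throughout.
NUCLEOTIDES = ("A", "C", "G", "T")

_SPECIES_RE = re.compile(r"species=(.+?)\s*$")


def normalize_sequence(seq: str) -> str:
    """Uppercase a nucleotide string and map RNA ``U`` to ``T``."""
    return seq.upper().replace("U", "T")


@dataclass(frozen=True)
class LabeledSequence:
    """A single nucleotide sequence with an identifier and a species label."""

    id: str
    species: str
    sequence: str

    @property
    def is_query(self) -> bool:
        return self.species == QUERY_LABEL

    def __len__(self) -> int:
        return len(self.sequence)


class LabeledAlignment:
    """An ordered collection of equal-purpose labeled sequences.

    Sequences are not required to be equal length at construction time;
    operations that need a true alignment (column tabulation, p-distances)
    enforce equal lengths themselves.
    """

    def __init__(self, records: Iterable[LabeledSequence]):
        self.records: list[LabeledSequence] = list(records)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[LabeledSequence]:
        return iter(self.records)

    def __getitem__(self, i: int) -> LabeledSequence:
        return self.records[i]

    @property
    def species_labels(self) -> list[str]:
        """Distinct non-query species labels, in order of first appearance."""
        seen: dict[str, None] = {}
        for rec in self.records:
            if not rec.is_query and rec.species not in seen:
                seen[rec.species] = None
        return list(seen)

    def by_species(self, species: str) -> list[LabeledSequence]:
        return [r for r in self.records if r.species == species]

    @property
    def queries(self) -> list[LabeledSequence]:
        return [r for r in self.records if r.is_query]

    def sequence_length(self) -> int:
        """Common sequence length; raises if lengths differ or empty."""
        if not self.records:
            raise ValueError("empty alignment")
        lengths = {len(r) for r in self.records}
        if len(lengths) != 1:
            raise ValueError(f"unequal sequence lengths: {sorted(lengths)}")
        return lengths.pop()


def parse_species_label(description: str) -> str:
    """Extract the ``species=`` value from a FASTA description line."""
    m = _SPECIES_RE.search(description)
    return m.group(1).strip() if m else QUERY_LABEL


def read_fasta(path: str | Path) -> LabeledAlignment:
    """Read a FASTA file into a :class:`LabeledAlignment`."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(
            LabeledSequence(
                id=rec.id,
                species=parse_species_label(rec.description),
                sequence=normalize_sequence(str(rec.seq)),
            )
        )
    return LabeledAlignment(records)


def write_fasta(alignment: LabeledAlignment, path: str | Path) -> None:
    """Write a :class:`LabeledAlignment` to FASTA with species-tagged headers."""
    seqrecords = [
        SeqRecord(Seq(rec.sequence), id=rec.id, description=f"species={rec.species}")
        for rec in alignment
    ]
    SeqIO.write(seqrecords, str(path), "fasta")
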