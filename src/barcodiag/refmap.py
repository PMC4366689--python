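"""Place a short fragment on a reference gene and convert coordinates.

Mapping is ungapped: the query (or its reverse complement) is slid along
the reference and the placement maximising exact matches wins.  All
coordinates are 1-based inclusive, the convention in which gene positions
such as "positions 451-554" are quoted.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from .io import NUCLEOTIDES

_COMPLEMENT = str.maketrans("ACGTRYKMBVDHacgtrykmbvdh", "TGCAYRMKVBHDtgcayrmkvbhd")

FORWARD = "forward"
REVERSE = "reverse"


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class FragmentMapping:
    """Ungapped placement of a fragment on a reference sequence.

    ``ref_start``/``ref_end`` are 1-based inclusive reference coordinates;
    ``identity`` is the fraction of fragment positions matching the
    reference exactly (ambiguity codes never count as matches).
    """

    reference_id: str
    ref_start: int
    ref_end: int
    strand: str
    identity: float
    fragment_length: int
    mapped: bool = True

    def __post_init__(self) -> None:
        if self.mapped:
            if self.ref_start > self.ref_end:
                raise ValueError("ref_start must not exceed ref_end")
            if self.fragment_length != self.ref_end - self.ref_start + 1:
                raise ValueError("fragment_length inconsistent with window")
            if not 0.0 <= self.identity <= 1.0:
                raise ValueError("identity must be in [0, 1]")
            if self.strand not in (FORWARD, REVERSE):
                raise ValueError(f"unknown strand {self.strand!r}")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    def to_tsv_row(self) -> str:
        return "\t".join(
            str(x)
            for x in (
                self.reference_id,
                self.ref_start,
                self.ref_end,
                self.strand,
                f"{self.identity:.6g}",
            )
        )


def _match_counts_all_offsets(query: str, reference: str) -> np.ndarray:
    """Exact-match count of *query* at every ungapped offset of *reference*.

    Only unambiguous A/C/G/T positions of both sequences can match.
    """
    q = np.frombuffer(query.encode(), dtype="S1")
    r = np.frombuffer(reference.encode(), dtype="S1")
    m, n = q.size, r.size
    n_offsets = n - m + 1
    counts = np.zeros(n_offsets, dtype=np.int64)
    valid = {c.encode() for c in NUCLEOTIDES}
    q_ok = np.isin(q, list(valid))
    for off in range(n_offsets):
        window = r[off : off + m]
        counts[off] = np.count_nonzero((q == window) & q_ok)
    return counts


def map_fragment(
    query: str,
    reference: str,
    min_identity: float = 0.8,
    reference_id: str = "reference",
) -> FragmentMapping:
    """Find the best ungapped placement of *query* on *reference*.

    Both orientations are tried; at equal match counts the forward strand
    wins, and within a strand the leftmost placement wins.  If the best
    identity falls below ``min_identity`` an unmapped result (``mapped
    False``) is returned rather than raising.
    """
    query = query.upper().replace("U", "T")
    reference = reference.upper().replace("U", "T")
    if len(query) == 0 or len(query) > len(reference):
        raise ValueError("query must be nonempty and no longer than the reference")

    best_matches = -1
    best_offset = 0
    best_strand = FORWARD
    for strand, oriented in ((FORWARD, query), (REVERSE, reverse_complement(query))):
        counts = _match_counts_all_offsets(oriented, reference)
        off = int(np.argmax(counts))  # argmax is leftmost on ties
        if counts[off] > best_matches:
            best_matches, best_offset, best_strand = int(counts[off]), off, strand

    m = len(query)
    identity = best_matches / m
    if identity < min_identity:
        return FragmentMapping(
            reference_id=reference_id,
            ref_start=0,
            ref_end=0,
            strand=FORWARD,
            identity=identity,
            fragment_length=m,
            mapped=False,
        )
    return FragmentMapping(
        reference_id=reference_id,
        ref_start=best_offset + 1,
        ref_end=best_offset + m,
        strand=best_strand,
        identity=identity,
        fragment_length=m,
    )


def ref_to_fragment(mapping: FragmentMapping, ref_pos: int) -> int:
    """Convert a reference coordinate to a 1-based fragment coordinate."""
    if not mapping.mapped:
        raise ValueError("cannot convert coordinates on an unmapped fragment")
    if not (mapping.ref_start <= ref_pos <= mapping.ref_end):
        raise ValueError(
            f"reference position {ref_pos} outside mapped window "
            f"[{mapping.ref_start}, {mapping.ref_end}]"
        )
    if mapping.strand == FORWARD:
        return ref_pos - mapping.ref_start + 1
    return mapping.ref_end - ref_pos + 1


def fragment_to_ref(mapping: FragmentMapping, fragment_pos: int) -> int:
    """Convert a 1-based fragment coordinate back to a reference coordinate."""
    if not mapping.mapped:
        raise ValueError("cannot convert coordinates on an unmapped fragment")
    if not (1 <= fragment_pos <= mapping.fragment_length):
        raise ValueError(
            f"fragment position {fragment_pos} outside [1, {mapping.fragment_length}]"
        )
    if mapping.strand == FORWARD:
        return mapping.ref_start + fragment_pos - 1
    return mapping.ref_end - fragment_pos + 1
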