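"""Ungapped local similarity scoring with Karlin-Altschul statistics.

Raw scores follow the classic nucleotide scheme (match reward, mismatch
penalty); the best ungapped local alignment of a query/subject pair is the
maximal-scoring segment over all diagonals and both strands.  Raw scores S
are normalised to bit scores S' = (lambda*S - ln K) / ln 2 and to E-values
E = K*m*n*exp(-lambda*S).  Defaults are the standard megablast
parameterisation: reward +1, penalty -2, lambda = 1.28, K = 0.46, under
which a perfect 104-nt match displays as 193 bits.

No seeding heuristics, masking or effective-length corrections are applied:
every subject is scored exhaustively, which is exact and fast at barcode
scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .io import LabeledAlignment
from .refmap import reverse_complement


@dataclass(frozen=True)
class ScoringParams:
    """Match/mismatch rewards and Karlin-Altschul constants."""

    reward: int = 1
    penalty: int = -2
    lam: float = 1.28
    K: float = 0.46

    def __post_init__(self) -> None:
        if not (self.reward > 0 > self.penalty):
            raise ValueError("require reward > 0 > penalty")
        if self.lam <= 0 or self.K <= 0:
            raise ValueError("lambda and K must be positive")


DEFAULT_PARAMS = ScoringParams()


@dataclass(frozen=True)
class Hit:
    """One subject of a ranked database search."""

    subject_id: str
    species: str
    raw_score: int
    bit_score: float
    displayed_bits: int
    evalue: float
    rank: int = 0
    tie_group: int = 0


def _diagonal_best(query: str, subject: str, params: ScoringParams) -> int:
    """Best ungapped segment score over all diagonals of one orientation."""
    q = np.frombuffer(query.encode(), dtype="S1")
    s = np.frombuffer(subject.encode(), dtype="S1")
    m, n = q.size, s.size
    reward, penalty = params.reward, params.penalty
    best = 0
    # Diagonal d aligns q[i] with s[i + d], d in [-(m-1), n-1].
    for d in range(-(m - 1), n):
        i0 = max(0, -d)
        i1 = min(m, n - d)
        if i1 <= i0:
            continue
        matches = q[i0:i1] == s[i0 + d : i1 + d]
        scores = np.where(matches, reward, penalty)
        # Maximal-scoring segment (Kadane) along the diagonal: for each end
        # position, segment score = cumsum - min prefix sum before the start.
        cs = np.cumsum(scores)
        prefix_min = np.minimum.accumulate(np.concatenate(([0], cs[:-1])))
        best = max(best, int((cs - prefix_min).max()))
    return best


def best_ungapped_score(query: str, subject: str, params: ScoringParams = DEFAULT_PARAMS) -> int:
    """Maximum ungapped segment score over both strands; never below 0."""
    if not query or not subject:
        raise ValueError("query and subject must be nonempty")
    query = query.upper().replace("U", "T")
    subject = subject.upper().replace("U", "T")
    return max(
        _diagonal_best(query, subject, params),
        _diagonal_best(reverse_complement(query), subject, params),
    )


def bit_score(raw_score: int, params: ScoringParams = DEFAULT_PARAMS) -> float:
    """Normalised score in bits: (lambda*S - ln K) / ln 2."""
    if raw_score < 0:
        raise ValueError("raw score must be >= 0")
    return (params.lam * raw_score - math.log(params.K)) / math.log(2)


def displayed_bit_score(raw_score: int, params: ScoringParams = DEFAULT_PARAMS) -> int:
    """Bit score rounded half-away-from-zero to an integer for display."""
    b = bit_score(raw_score, params)
    return int(math.floor(b + 0.5)) if b >= 0 else -int(math.floor(-b + 0.5))


def evalue(
    raw_score: int,
    query_len: int,
    db_len: int,
    params: ScoringParams = DEFAULT_PARAMS,
) -> float:
    """Expected chance hits: K * m * n * exp(-lambda * S).

    *db_len* is the summed length of all database sequences.  No
    effective-length correction is applied.
    """
    if query_len <= 0 or db_len <= 0:
        raise ValueError("lengths must be positive")
    return params.K * query_len * db_len * math.exp(-params.lam * raw_score)


def rank_database(
    query: str,
    database: LabeledAlignment,
    params: ScoringParams = DEFAULT_PARAMS,
) -> list[Hit]:
    """Score every database subject against *query* and rank with tie groups.

    Hits are sorted by bit score descending (subject id breaks ties for a
    stable, input-order-independent listing); subjects with equal displayed
    bit scores share a tie group.
    """
    if len(database) == 0:
        raise ValueError("empty database")
    db_len = sum(len(rec) for rec in database)
    hits = []
    for rec in database:
        raw = best_ungapped_score(query, rec.sequence, params)
        hits.append(
            Hit(
                subject_id=rec.id,
                species=rec.species,
                raw_score=raw,
                bit_score=bit_score(raw, params),
                displayed_bits=displayed_bit_score(raw, params),
                evalue=evalue(raw, len(query), db_len, params),
            )
        )
    hits.sort(key=lambda h: (-h.bit_score, h.subject_id))

    ranked: list[Hit] = []
    tie_group = 0
    prev_bits: int | None = None
    for i, h in enumerate(hits, start=1):
        if h.displayed_bits != prev_bits:
            tie_group += 1
            prev_bits = h.displayed_bits
        ranked.append(
            Hit(
                subject_id=h.subject_id,
                species=h.species,
                raw_score=h.raw_score,
                bit_score=h.bit_score,
                displayed_bits=h.displayed_bits,
                evalue=h.evalue,
                rank=i,
                tie_group=tie_group,
            )
        )
    return ranked


def tie_group_summary(hits: list[Hit]) -> list[dict]:
    """Per-tie-group size, displayed bits and species composition."""
    groups: dict[int, list[Hit]] = {}
    for h in hits:
        groups.setdefault(h.tie_group, []).append(h)
    out = []
    for g in sorted(groups):
        members = groups[g]
        species: dict[str, int] = {}
        for h in members:
            species[h.species] = species.get(h.species, 0) + 1
        out.append(
            {
                "tie_group": g,
                "size": len(members),
                "displayed_bits": members[0].displayed_bits,
                "species": species,
            }
        )
    return out


def hits_to_tsv(hits: list[Hit]) -> str:
    header = "subject_id\tspecies\traw\tbits\tdisplayed_bits\tevalue\ttie_group"
    lines = [header]
    for h in hits:
        lines.append(
            f"{h.subject_id}\t{h.species}\t{h.raw_score}\t{h.bit_score:.4f}"
            f"\t{h.displayed_bits}\t{h.evalue:.3g}\t{h.tie_group}"
        )
    return "\n".join(lines) + "\n"
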