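"""Synthetic alignments with prescribed per-site character-state counts.

This module makes every downstream stage testable without any sequence
download.  Its centrepiece is the compiled-in Brown Bear / Polar Bear 12S
rRNA fragment dataset: 49 *Ursus arctos* and 32 *Ursus maritimus*
individuals over a 104-bp fragment spanning positions 451-554 of the
complete gene, with exactly four variable sites (gene positions 474, 478,
492 and 550) whose per-species state counts match the published variability
summary, plus two identical focal query sequences.

The published data are per-site marginal counts; the joint arrangement of
states across individuals is not published.  The fixture therefore fixes one
canonical haplotype completion that (a) reproduces every marginal count and
(b) contains a full haplotype shared between the two species, which is the
configuration consistent with the finding that no nucleotide combination
separates them.  Combination-level results on the fixture are properties of
this completion, not a reproduction of unpublished individual-level data.

For property testing the module also generates alignments from arbitrary
marginal specifications, random references with embedded fragments, and
per-site mutagenised sequence sets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import NUCLEOTIDES, QUERY_LABEL, LabeledAlignment, LabeledSequence

BROWN_BEAR = "Ursus arctos"
POLAR_BEAR = "Ursus maritimus"

#: 1-based coordinates of the fragment on the complete 12S gene.
FRAGMENT_START = 451
FRAGMENT_END = 554
FRAGMENT_LENGTH = FRAGMENT_END - FRAGMENT_START + 1  # 104 bp

#: Gene coordinates of the four variable sites of the fragment.
VARIABLE_POSITIONS = (474, 478, 492, 550)

#: Approximate length of the complete mitochondrial 12S rRNA gene.
DEFAULT_GENE_LENGTH = 957

#: Canonical joint haplotypes over the four variable sites.  Each entry is
#: (haplotype, copy count).  The marginals these induce equal the published
#: per-site counts; the shared (T,A,G,T) haplotype encodes the species
#: overlap.  See the module docstring for the status of this completion.
URSUS_HAPLOTYPES: dict[str, list[tuple[tuple[str, ...], int]]] = {
    BROWN_BEAR: [
        (("T", "A", "G", "C"), 34),
        (("C", "A", "G", "C"), 5),
        (("C", "A", "G", "T"), 4),
        (("T", "G", "G", "T"), 3),
        (("T", "G", "G", "C"), 1),
        (("T", "G", "A", "T"), 1),
        (("T", "A", "G", "T"), 1),
    ],
    POLAR_BEAR: [
        (("C", "A", "G", "T"), 31),
        (("T", "A", "G", "T"), 1),
    ],
}

#: Haplotype of the two focal query sequences over the variable sites.
FOCAL_HAPLOTYPE = ("T", "A", "G", "T")

#: Invariant background state for synthetic fragments (arbitrary; invisible
#: to every per-site statistic, which only ever sees the variable columns).
BACKGROUND_STATE = "A"


@dataclass(frozen=True)
class MarginalSpec:
    """Per-species, per-site state counts from which to generate an alignment.

    Parameters
    ----------
    species
        Map from species label to ``(n_individuals, sites)`` where *sites*
        maps a 1-based reference position to a ``state -> count`` dict.
        Counts at each site must sum to ``n_individuals``.
    fragment_start, fragment_end
        1-based inclusive reference coordinates of the fragment.  Every
        variable position must lie inside this window.
    background_state
        Nucleotide filling all non-variable fragment columns.
    """

    species: dict[str, tuple[int, dict[int, dict[str, int]]]]
    fragment_start: int = FRAGMENT_START
    fragment_end: int = FRAGMENT_END
    background_state: str = BACKGROUND_STATE

    def __post_init__(self) -> None:
        if self.fragment_start < 1 or self.fragment_end < self.fragment_start:
            raise ValueError("invalid fragment window")
        if self.background_state not in NUCLEOTIDES:
            raise ValueError(f"background state {self.background_state!r} not a nucleotide")
        for label, (n, sites) in self.species.items():
            if n < 1:
                raise ValueError(f"{label}: need at least one individual")
            for pos, counts in sites.items():
                if not (self.fragment_start <= pos <= self.fragment_end):
                    raise ValueError(
                        f"{label}: position {pos} outside fragment "
                        f"[{self.fragment_start}, {self.fragment_end}]"
                    )
                if any(s not in NUCLEOTIDES for s in counts):
                    raise ValueError(f"{label} @ {pos}: states must be A/C/G/T")
                if any(c < 0 for c in counts.values()):
                    raise ValueError(f"{label} @ {pos}: negative count")
                if sum(counts.values()) != n:
                    raise ValueError(
                        f"{label} @ {pos}: counts sum to {sum(counts.values())}, "
                        f"expected {n}"
                    )

    @property
    def fragment_length(self) -> int:
        return self.fragment_end - self.fragment_start + 1

    @property
    def positions(self) -> list[int]:
        """Sorted union of variable reference positions across species."""
        pos: set[int] = set()
        for _, sites in self.species.values():
            pos.update(sites)
        return sorted(pos)


def ursus_marginal_spec() -> MarginalSpec:
    """The published per-site counts of the bear fragment as a MarginalSpec."""
    species: dict[str, tuple[int, dict[int, dict[str, int]]]] = {}
    for label, haps in URSUS_HAPLOTYPES.items():
        n = sum(c for _, c in haps)
        sites: dict[int, dict[str, int]] = {}
        for i, pos in enumerate(VARIABLE_POSITIONS):
            counts: dict[str, int] = {}
            for hap, c in haps:
                counts[hap[i]] = counts.get(hap[i], 0) + c
            sites[pos] = counts
        species[label] = (n, sites)
    return MarginalSpec(species=species)


def _fragment_from_haplotype(haplotype: tuple[str, ...],
                             positions: tuple[int, ...] = VARIABLE_POSITIONS,
                             start: int = FRAGMENT_START,
                             length: int = FRAGMENT_LENGTH,
                             background: str = BACKGROUND_STATE) -> str:
    chars = [background] * length
    for state, pos in zip(haplotype, positions):
        chars[pos - start] = state
    return "".join(chars)


def build_ursus_fixture() -> LabeledAlignment:
    """Build the canonical two-species bear alignment plus focal queries.

    Returns 83 sequences of length 104: 49 Brown Bear, 32 Polar Bear and two
    identical focal queries, with the four variable sites at fragment
    positions 24, 28, 42 and 100 (gene positions 474, 478, 492, 550).
    """
    records: list[LabeledSequence] = []
    prefixes = {BROWN_BEAR: "Uarc", POLAR_BEAR: "Umar"}
    for label, haps in URSUS_HAPLOTYPES.items():
        i = 0
        for hap, copies in haps:
            frag = _fragment_from_haplotype(hap)
            for _ in range(copies):
                i += 1
                records.append(LabeledSequence(f"{prefixes[label]}_{i:02d}", label, frag))
    focal = _fragment_from_haplotype(FOCAL_HAPLOTYPE)
    records.append(LabeledSequence("focal_1", QUERY_LABEL, focal))
    records.append(LabeledSequence("focal_2", QUERY_LABEL, focal))
    return LabeledAlignment(records)


def focal_fragment() -> str:
    """The 104-bp sequence of the (identical) focal queries."""
    return _fragment_from_haplotype(FOCAL_HAPLOTYPE)


def generate_from_marginals(spec: MarginalSpec, seed: int) -> LabeledAlignment:
    """Generate an alignment whose column tabulation equals *spec* exactly.

    Randomness affects only the joint arrangement of states across
    individuals: each variable column is an independent random permutation
    of the prescribed multiset of states.  Deterministic given *seed*.
    """
    rng = np.random.default_rng(seed)
    records: list[LabeledSequence] = []
    length = spec.fragment_length
    for label, (n, sites) in spec.species.items():
        rows = np.full((n, length), spec.background_state, dtype="U1")
        for pos in sorted(sites):
            column = np.repeat(
                [s for s in sorted(sites[pos])],
                [sites[pos][s] for s in sorted(sites[pos])],
            )
            rng.shuffle(column)
            rows[:, pos - spec.fragment_start] = column
        safe = label.replace(" ", "_")
        for i in range(n):
            records.append(
                LabeledSequence(f"{safe}_{i + 1:03d}", label, "".join(rows[i]))
            )
    return LabeledAlignment(records)


def generate_reference_and_fragment(
    ref_length: int, start: int, end: int, seed: int
) -> tuple[str, str]:
    """Random reference sequence and its substring at 1-based [start, end]."""
    if not (1 <= start <= end <= ref_length):
        raise ValueError(
            f"require 1 <= start <= end <= ref_length, got ({start}, {end}, {ref_length})"
        )
    rng = np.random.default_rng(seed)
    reference = "".join(rng.choice(list(NUCLEOTIDES), size=ref_length))
    return reference, reference[start - 1 : end]


def build_ursus_reference(gene_length: int = DEFAULT_GENE_LENGTH, seed: int = 0) -> str:
    """A synthetic complete-gene reference carrying the focal fragment.

    Positions 451-554 hold the focal fragment; the flanks are random,
    which makes the embedded placement the unique best ungapped match.
    """
    if gene_length < FRAGMENT_END:
        raise ValueError(f"gene_length must be >= {FRAGMENT_END}")
    rng = np.random.default_rng(seed)
    ref = list("".join(rng.choice(list(NUCLEOTIDES), size=gene_length)))
    ref[FRAGMENT_START - 1 : FRAGMENT_END] = focal_fragment()
    return "".join(ref)


def mutate_sequences(
    base_sequence: str, n_copies: int, per_site_substitution_prob: float, seed: int
) -> list[str]:
    """Independent per-site mutagenesis of *base_sequence*.

    Each site of each copy is substituted, with the given probability, to a
    state chosen uniformly among the three alternatives.  Deterministic
    given *seed*.
    """
    if not 0.0 <= per_site_substitution_prob <= 1.0:
        raise ValueError("substitution probability must be in [0, 1]")
    rng = np.random.default_rng(seed)
    base = np.array(list(base_sequence), dtype="U1")
    L = base.size
    out: list[str] = []
    for _ in range(n_copies):
        copy = base.copy()
        hit = rng.random(L) < per_site_substitution_prob
        for i in np.flatnonzero(hit):
            alternatives = [s for s in NUCLEOTIDES if s != copy[i]]
            copy[i] = alternatives[rng.integers(3)]
        out.append("".join(copy))
    return out
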