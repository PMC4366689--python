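"""Population aggregation analysis (PAA): character-based species diagnosis.

Two populations are diagnosable at a character when their observed state
sets are disjoint — presence/absence only, never frequencies: one shared
individual destroys the diagnosis.  The notion extends to combinations: a
k-tuple of positions is diagnostic when the two species' *joint* haplotypes
projected onto those positions share no state vector.  Joint projection,
not a product of marginal sets, is what makes the combination search
meaningful: two species can overlap at every single site while their
two-site haplotypes are disjoint.

Query sequences are assigned by compatibility: a species is compatible
either site-wise (the query's state at every variable position occurs in
the species) or by exact haplotype membership.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from itertools import combinations
from math import comb

from .io import NUCLEOTIDES, LabeledAlignment, LabeledSequence
from .refmap import FragmentMapping, ref_to_fragment
from .variability import tabulate, variable_positions

#: Refuse combination searches that would enumerate more tuples than this.
COMBINATION_GUARD = 10**6

SITE_WISE = "site_wise"
EXACT_HAPLOTYPE = "exact_haplotype"

UNAMBIGUOUS = "unambiguous"
AMBIGUOUS = "ambiguous"
UNASSIGNABLE = "unassignable"


@dataclass(frozen=True)
class SpeciesProfile:
    """Observed character states of one species over the variable positions.

    ``state_sets[pos]`` is the set of unambiguous states seen at reference
    position *pos*; ``haplotypes`` is the set of joint state vectors over
    ``positions`` from individuals with no missing data at any of them.
    """

    species: str
    positions: tuple[int, ...]
    state_sets: dict[int, frozenset[str]]
    haplotypes: frozenset[tuple[str, ...]]

    def project(self, subset: tuple[int, ...]) -> frozenset[tuple[str, ...]]:
        """Joint haplotype set restricted to a subset of positions."""
        idx = [self.positions.index(p) for p in subset]
        return frozenset(tuple(h[i] for i in idx) for h in self.haplotypes)


@dataclass(frozen=True)
class DiagnosticReport:
    """Diagnostic sites and combinations between two species."""

    species_pair: tuple[str, str]
    positions: tuple[int, ...]
    single_site_diagnostics: list[int]
    combination_diagnostics: dict[int, list[tuple[int, ...]]]
    kmax: int

    @property
    def any_diagnostic(self) -> bool:
        return bool(self.single_site_diagnostics) or any(
            self.combination_diagnostics.values()
        )

    def to_json(self) -> str:
        return json.dumps(
            {
                "species_pair": list(self.species_pair),
                "variable_positions": list(self.positions),
                "single_site_diagnostics": self.single_site_diagnostics,
                "combination_diagnostics": {
                    str(k): [list(t) for t in tuples]
                    for k, tuples in self.combination_diagnostics.items()
                },
                "kmax": self.kmax,
                "any_diagnostic": self.any_diagnostic,
            },
            indent=2,
        )


@dataclass(frozen=True)
class AssignmentVerdict:
    """Compatibility verdict for one query sequence."""

    query_id: str
    compatible_species: frozenset[str]
    status: str
    mode: str
    reason: str = ""

    def __post_init__(self) -> None:
        expected = (
            UNAMBIGUOUS
            if len(self.compatible_species) == 1
            else (UNASSIGNABLE if not self.compatible_species else AMBIGUOUS)
        )
        if self.status != expected:
            raise ValueError(
                f"status {self.status!r} inconsistent with "
                f"{len(self.compatible_species)} compatible species"
            )


def species_profiles(
    alignment: LabeledAlignment,
    mapping: FragmentMapping,
    positions: list[int] | None = None,
) -> dict[str, SpeciesProfile]:
    """Build per-species state sets and joint haplotypes.

    *positions* defaults to the variable positions of the alignment
    (queries excluded).  Individuals missing data at a position are skipped
    for that position's state set and excluded from the haplotype set
    entirely if any position is missing.
    """
    table = tabulate(alignment, mapping)
    if positions is None:
        positions = variable_positions(table)
    pos_tuple = tuple(sorted(positions))
    frag_idx = [ref_to_fragment(mapping, p) - 1 for p in pos_tuple]

    profiles: dict[str, SpeciesProfile] = {}
    for sp in table.species:
        seqs = [r.sequence for r in alignment.by_species(sp)]
        state_sets: dict[int, set[str]] = {p: set() for p in pos_tuple}
        haplotypes: set[tuple[str, ...]] = set()
        usable = 0
        for seq in seqs:
            states = [seq[i] for i in frag_idx]
            complete = True
            for p, s in zip(pos_tuple, states):
                if s in NUCLEOTIDES:
                    state_sets[p].add(s)
                else:
                    complete = False
            if complete:
                haplotypes.add(tuple(states))
            if any(s in NUCLEOTIDES for s in states) or not pos_tuple:
                usable += 1
        if pos_tuple and usable == 0:
            raise ValueError(f"species {sp!r} has no usable sequence")
        profiles[sp] = SpeciesProfile(
            species=sp,
            positions=pos_tuple,
            state_sets={p: frozenset(s) for p, s in state_sets.items()},
            haplotypes=frozenset(haplotypes),
        )
    return profiles


def diagnostic_sites(
    profiles: dict[str, SpeciesProfile], species_a: str, species_b: str
) -> list[int]:
    """Positions where the two species' observed state sets are disjoint."""
    pa, pb = profiles[species_a], profiles[species_b]
    return [
        p
        for p in pa.positions
        if pa.state_sets[p]
        and pb.state_sets[p]
        and not (pa.state_sets[p] & pb.state_sets[p])
    ]


def diagnostic_combinations(
    profiles: dict[str, SpeciesProfile],
    species_a: str,
    species_b: str,
    kmax: int = 4,
) -> DiagnosticReport:
    """Exhaustively search k-tuples of positions with disjoint joint states.

    For every k up to *kmax*, a tuple is reported when the two species'
    haplotype sets projected onto it share no joint state vector.  The
    search refuses instances with more than 10^6 candidate tuples.
    """
    if kmax < 1:
        raise ValueError("kmax must be >= 1")
    pa, pb = profiles[species_a], profiles[species_b]
    positions = pa.positions
    n = len(positions)
    kmax_eff = min(kmax, n)
    total = sum(comb(n, k) for k in range(1, kmax_eff + 1))
    if total > COMBINATION_GUARD:
        raise ValueError(
            f"combination search too large: {total} tuples exceeds guard "
            f"{COMBINATION_GUARD}"
        )

    combos: dict[int, list[tuple[int, ...]]] = {k: [] for k in range(1, kmax_eff + 1)}
    for k in range(1, kmax_eff + 1):
        for subset in combinations(positions, k):
            if not (pa.project(subset) & pb.project(subset)):
                combos[k].append(subset)
    return DiagnosticReport(
        species_pair=(species_a, species_b),
        positions=positions,
        single_site_diagnostics=diagnostic_sites(profiles, species_a, species_b),
        combination_diagnostics=combos,
        kmax=kmax_eff,
    )


def assign_query(
    query: LabeledSequence,
    profiles: dict[str, SpeciesProfile],
    mapping: FragmentMapping,
    mode: str = SITE_WISE,
) -> AssignmentVerdict:
    """Assign one query fragment to the species it is compatible with.

    ``site_wise``: a species is compatible when the query's state at every
    variable position (where the query has data) occurs in that species.
    ``exact_haplotype``: compatible when the query's complete joint
    haplotype is among the species' observed haplotypes.
    """
    if mode not in (SITE_WISE, EXACT_HAPLOTYPE):
        raise ValueError(f"unknown assignment mode {mode!r}")
    some_profile = next(iter(profiles.values()))
    positions = some_profile.positions
    frag_idx = [ref_to_fragment(mapping, p) - 1 for p in positions]
    states = tuple(query.sequence[i] for i in frag_idx)
    known = [s in NUCLEOTIDES for s in states]

    if positions and not any(known):
        return AssignmentVerdict(
            query_id=query.id,
            compatible_species=frozenset(),
            status=UNASSIGNABLE,
            mode=mode,
            reason="query has no data at any variable position",
        )

    compatible: set[str] = set()
    for sp, prof in profiles.items():
        if mode == SITE_WISE:
            ok = all(
                s in prof.state_sets[p]
                for p, s, k in zip(positions, states, known)
                if k
            )
        else:
            ok = all(known) and states in prof.haplotypes
        if ok:
            compatible.add(sp)

    status = (
        UNAMBIGUOUS
        if len(compatible) == 1
        else (UNASSIGNABLE if not compatible else AMBIGUOUS)
    )
    reason = "" if compatible else "no species contains the query's character states"
    return AssignmentVerdict(
        query_id=query.id,
        compatible_species=frozenset(compatible),
        status=status,
        mode=mode,
        reason=reason,
    )
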