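"""Per-site, per-species character-state count tables.

The central object is the :class:`VariabilityTable`: for every reference
position covered by a mapped fragment and every species in the alignment,
the number of individuals carrying each nucleotide state.  Gaps and
ambiguity codes count as missing.  Query sequences (label ``QUERY``) are
excluded from species statistics but tabulated in their own row, mirroring
the "focal sequences" row of a published variability table.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field

import pandas as pd

from .io import NUCLEOTIDES, QUERY_LABEL, LabeledAlignment
from .refmap import FragmentMapping, fragment_to_ref

# How two species' columns are compared by between_species_differences:
#   set_or_modal  -- observed state sets differ OR modal states differ
#   frequency     -- relative state-frequency distributions differ
SET_OR_MODAL = "set_or_modal"
FREQUENCY = "frequency"


@dataclass
class VariabilityTable:
    """Per-position, per-species state counts over a mapped fragment.

    ``counts[species][ref_pos]`` maps nucleotide states to individual
    counts; ``missing[species][ref_pos]`` counts gap/ambiguous individuals.
    For every species and position, state counts plus missing equal the
    species sample size.  The reserved ``QUERY`` group is tabulated like a
    species but ignored by all species-level derivations.
    """

    positions: list[int]
    counts: dict[str, dict[int, dict[str, int]]]
    missing: dict[str, dict[int, int]]
    sample_sizes: dict[str, int]
    modal_ties: set[tuple[str, int]] = field(default_factory=set)

    @property
    def species(self) -> list[str]:
        return [s for s in self.counts if s != QUERY_LABEL]

    def states_at(self, species: str, position: int) -> set[str]:
        """Observed (non-missing) states of *species* at *position*."""
        self._check(species, position)
        return {s for s, c in self.counts[species][position].items() if c > 0}

    def modal_state(self, species: str, position: int) -> str | None:
        """Most frequent state; alphabetical on ties (tie recorded)."""
        self._check(species, position)
        col = {s: c for s, c in self.counts[species][position].items() if c > 0}
        if not col:
            return None
        top = max(col.values())
        winners = sorted(s for s, c in col.items() if c == top)
        if len(winners) > 1:
            self.modal_ties.add((species, position))
        return winners[0]

    def _check(self, species: str, position: int) -> None:
        if species not in self.counts:
            raise KeyError(f"unknown species {species!r}")
        if position not in self.counts[species]:
            raise KeyError(f"position {position} not tabulated")

    def to_frame(self, positions: list[int] | None = None) -> pd.DataFrame:
        """Render as a species x position table of ``STATE (count)`` cells."""
        positions = self.positions if positions is None else positions
        rows = {}
        for sp in list(self.counts):
            cells = []
            for pos in positions:
                col = self.counts[sp][pos]
                ordered = sorted(
                    ((s, c) for s, c in col.items() if c > 0),
                    key=lambda sc: (-sc[1], sc[0]),
                )
                cells.append("; ".join(f"{s} ({c})" for s, c in ordered))
            rows[sp] = cells
        return pd.DataFrame.from_dict(rows, orient="index", columns=positions)

    def to_json(self, positions: list[int] | None = None) -> str:
        positions = self.positions if positions is None else positions
        payload = {
            "positions": positions,
            "sample_sizes": self.sample_sizes,
            "counts": {
                sp: {str(p): self.counts[sp][p] for p in positions}
                for sp in self.counts
            },
            "missing": {
                sp: {str(p): self.missing[sp][p] for p in positions}
                for sp in self.counts
            },
        }
        return json.dumps(payload, indent=2)


def tabulate(alignment: LabeledAlignment, mapping: FragmentMapping) -> VariabilityTable:
    """Count character states per species per reference position.

    All sequences must have length ``mapping.fragment_length``; column *j*
    (1-based) is assigned the reference coordinate ``fragment_to_ref(j)``.
    """
    if len(alignment) == 0:
        raise ValueError("empty alignment")
    length = alignment.sequence_length()
    if length != mapping.fragment_length:
        raise ValueError(
            f"alignment length {length} != mapped fragment length "
            f"{mapping.fragment_length}"
        )

    groups: dict[str, list[str]] = {}
    for rec in alignment:
        groups.setdefault(rec.species, []).append(rec.sequence)

    positions = sorted(fragment_to_ref(mapping, j) for j in range(1, length + 1))
    counts: dict[str, dict[int, dict[str, int]]] = {}
    missing: dict[str, dict[int, int]] = {}
    for sp, seqs in groups.items():
        counts[sp] = {}
        missing[sp] = {}
        for j in range(1, length + 1):
            ref_pos = fragment_to_ref(mapping, j)
            col = Counter(seq[j - 1] for seq in seqs)
            states = {s: c for s, c in col.items() if s in NUCLEOTIDES}
            counts[sp][ref_pos] = states
            missing[sp][ref_pos] = len(seqs) - sum(states.values())
    return VariabilityTable(
        positions=positions,
        counts=counts,
        missing=missing,
        sample_sizes={sp: len(seqs) for sp, seqs in groups.items()},
    )


def variable_positions(table: VariabilityTable) -> list[int]:
    """Positions with more than one state across all species pooled.

    Query sequences are excluded from the pool.
    """
    out = []
    for pos in table.positions:
        pooled: set[str] = set()
        for sp in table.species:
            pooled |= table.states_at(sp, pos)
        if len(pooled) > 1:
            out.append(pos)
    return out


def within_species_polymorphic(table: VariabilityTable, species: str) -> list[int]:
    """Positions at which *species* shows two or more states."""
    if species not in table.counts or species == QUERY_LABEL:
        raise KeyError(f"unknown species {species!r}")
    return [p for p in table.positions if len(table.states_at(species, p)) >= 2]


def exclusively_polymorphic(table: VariabilityTable, species: str) -> list[int]:
    """Positions polymorphic in *species* while every other species is fixed.

    Separates polymorphism private to one population from shared
    polymorphism; the counts quoted in variability summaries of the form
    "polymorphic in three positions, the other only in one" refer to this
    split on the bear fragment.
    """
    own = set(within_species_polymorphic(table, species))
    for other in table.species:
        if other != species:
            own -= {
                p for p in table.positions if len(table.states_at(other, p)) >= 2
            }
    return sorted(own)


def between_species_differences(
    table: VariabilityTable,
    species_a: str,
    species_b: str,
    rule: str = SET_OR_MODAL,
) -> list[int]:
    """Positions at which two species' columns differ.

    Under the default ``set_or_modal`` rule a position differs when the two
    observed state sets are unequal or the modal states are unequal; this
    counts a site where the species are fixed-vs-mostly for different
    states even though a rare shared state makes the sets equal.  The
    ``frequency`` rule compares relative state-frequency distributions
    (computed over non-missing individuals) instead.
    """
    for sp in (species_a, species_b):
        if sp not in table.counts or sp == QUERY_LABEL:
            raise KeyError(f"unknown species {sp!r}")
    out = []
    for pos in table.positions:
        if rule == SET_OR_MODAL:
            differs = table.states_at(species_a, pos) != table.states_at(
                species_b, pos
            ) or table.modal_state(species_a, pos) != table.modal_state(species_b, pos)
        elif rule == FREQUENCY:
            differs = _frequencies(table, species_a, pos) != _frequencies(
                table, species_b, pos
            )
        else:
            raise ValueError(f"unknown comparison rule {rule!r}")
        if differs:
            out.append(pos)
    return out


def _frequencies(table: VariabilityTable, species: str, pos: int) -> dict[str, float]:
    col = table.counts[species][pos]
    total = sum(col.values())
    if total == 0:
        return {}
    return {s: c / total for s, c in col.items() if c > 0}
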