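import numpy as np
import pytest

from barcodiag import (
    LabeledAlignment,
    LabeledSequence,
    build_ursus_fixture,
    build_ursus_reference,
    focal_fragment,
    map_fragment,
    species_profiles,
    tabulate,
)

BROWN = "Ursus arctos"
POLAR = "Ursus maritimus"


@pytest.fixture(scope="session")
def ursus_alignment():
    return build_ursus_fixture()


@pytest.fixture(scope="session")
def ursus_reference():
    return build_ursus_reference(seed=0)


@pytest.fixture(scope="session")
def ursus_mapping(ursus_alignment, ursus_reference):
    return map_fragment(
        ursus_alignment.queries[0].sequence, ursus_reference, reference_id="ref12S"
    )


@pytest.fixture(scope="session")
def ursus_table(ursus_alignment, ursus_mapping):
    return tabulate(ursus_alignment, ursus_mapping)


@pytest.fixture(scope="session")
def ursus_profiles(ursus_alignment, ursus_mapping):
    return species_profiles(ursus_alignment, ursus_mapping)


def one_mismatch_database(n_perfect=2, n_mismatch=98, seed=1):
    """Query plus a database of perfect and single-interior-mismatch subjects.

    Mismatches are placed so that both flanks are at most 100 sites long:
    then the full 101-scoring alignment beats either trimmed flank and all
    mismatch subjects land in one tie group.
    """
    q = focal_fragment()
    rng = np.random.default_rng(seed)
    records = [
        LabeledSequence(f"perfect_{i}", POLAR, q) for i in range(n_perfect)
    ]
    for i in range(n_mismatch):
        pos = int(rng.integers(3, 101))
        alt = [c for c in "ACGT" if c != q[pos]][int(rng.integers(3))]
        mutated = q[:pos] + alt + q[pos + 1 :]
        species = BROWN if i < 94 else POLAR
        records.append(LabeledSequence(f"mismatch_{i}", species, mutated))
    return q, LabeledAlignment(records)


def random_two_species_alignment(rng, n_a=None, n_b=None, length=None):
    """Small random alignment with two species and optional queries."""
    n_a = n_a or int(rng.integers(2, 8))
    n_b = n_b or int(rng.integers(2, 8))
    length = length or int(rng.integers(5, 15))
    alphabet = list("ACGT")
    records = []
    for label, n, prefix in ((BROWN, n_a, "a"), (POLAR, n_b, "b")):
        for i in range(n):
            seq = "".join(rng.choice(alphabet, size=length))
            records.append(LabeledSequence(f"{prefix}{i}", label, seq))
    return LabeledAlignment(records)
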