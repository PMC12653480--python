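import numpy as np
import pytest

from orsite import (
    AlignedFamily,
    BundleSimSpec,
    FamilySimSpec,
    SequenceRecord,
    TopologySpec,
    jtt,
    simulate_bundle,
    simulate_family,
)

# the seven TM helix ranges of the 356-residue insect odorant receptor used
# as the worked example throughout the suite
OR_TM_SEGMENTS = (
    (11, 31),
    (42, 62),
    (103, 123),
    (157, 177),
    (234, 254),
    (265, 285),
    (336, 356),
)


@pytest.fixture(scope="session")
def model():
    return jtt()


@pytest.fixture(scope="session")
def or_topology():
    return TopologySpec(
        protein_length=356,
        tm_segments=OR_TM_SEGMENTS,
        n_term_side="cytoplasmic",
    )


@pytest.fixture()
def tiny_family():
    return AlignedFamily(
        members=(
            SequenceRecord("a", "MKVLA"),
            SequenceRecord("b", "MKVLG"),
            SequenceRecord("c", "MKV-A"),
            SequenceRecord("d", "MKVXA"),
        ),
        reference_id="a",
    )


@pytest.fixture(scope="session")
def sim_family():
    family, _ = simulate_family(
        FamilySimSpec(n_taxa=6, length=200, max_terminal_trim=5, seed=11)
    )
    return family


@pytest.fixture(scope="session")
def bundle():
    return simulate_bundle(BundleSimSpec(seed=1))


def random_aligned_family(rng: np.random.Generator, n: int, length: int):
    """A uniformly random gapped family for brute-force comparisons."""
    alphabet = "ACDEFGHIKLMNPQRSTVWYXBZ-"
    rows = [
        "".join(rng.choice(list(alphabet), size=length)) for _ in range(n)
    ]
    # reference must be a valid member; leave it ungapped for simplicity
    rows[0] = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=length))
    members = tuple(
        SequenceRecord(f"s{i}", row) for i, row in enumerate(rows)
    )
    return AlignedFamily(members=members, reference_id="s0")
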