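import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from domrearr import (
    DomainArrangement,
    ProteinArchitecture,
    SequenceProvider,
    SpeciesTree,
)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
LINKER = "GGGGG"


def arr(key: str) -> DomainArrangement:
    """Shorthand: arr('A B') -> arrangement (A, B)."""
    return DomainArrangement.from_key(key)


def random_seq(rng: np.random.Generator, length: int = 60) -> str:
    return "".join(AMINO_ACIDS[i] for i in rng.integers(0, 20, size=length))


def diverge(rng: np.random.Generator, seq: str, fraction: float) -> str:
    """Substitute a fixed fraction of positions with different residues."""
    k = max(1, int(round(fraction * len(seq))))
    positions = rng.choice(len(seq), size=k, replace=False)
    chars = list(seq)
    for i in positions:
        options = AMINO_ACIDS.replace(chars[i], "")
        chars[i] = options[rng.integers(0, len(options))]
    return "".join(chars)


def make_provider(tree: SpeciesTree, spec: dict) -> SequenceProvider:
    """Build a SequenceProvider from {leaf: {pid: (arrangement key, [domain seqs])}}."""
    architectures: dict[str, dict[str, ProteinArchitecture]] = {}
    sequences: dict[str, dict[str, str]] = {}
    for leaf, proteins in spec.items():
        architectures[leaf] = {}
        sequences[leaf] = {}
        for pid, (key, seqs) in proteins.items():
            arrangement = arr(key)
            assert len(arrangement) == len(seqs)
            spans = []
            offset = 1
            instances = []
            for acc, s in zip(arrangement.domains, seqs):
                spans.append((offset, offset + len(s) - 1))
                instances.append((acc, offset, offset + len(s) - 1))
                offset += len(s) + len(LINKER)
            architectures[leaf][pid] = ProteinArchitecture(
                pid, leaf, arrangement, instances, spans
            )
            sequences[leaf][pid] = LINKER.join(seqs)
    return SequenceProvider(tree, architectures, sequences)


@pytest.fixture
def quartet() -> SpeciesTree:
    """((A,B),(C,D)); — internal ids N1=(A,B), N2=(C,D), N3=root."""
    return SpeciesTree.from_newick("((A,B),(C,D));")


@pytest.fixture
def balanced16() -> SpeciesTree:
    def build(labels):
        if len(labels) == 1:
            return labels[0]
        half = len(labels) // 2
        return f"({build(labels[:half])},{build(labels[half:])})"

    labels = [f"L{i:02d}" for i in range(16)]
    return SpeciesTree.from_newick(build(labels) + ";")
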