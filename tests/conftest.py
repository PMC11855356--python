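"""Shared fixtures: random tree/alignment generators built at test time."""

import numpy as np
import pytest

from phylodiscord.treekit import Alignment, parse_newick


def random_newick(labels, rng, with_lengths=True, max_len=3.0):
    """A random rooted binary topology over the labels, as newick."""

    def length():
        return f":{rng.uniform(0.01, max_len):.6g}" if with_lengths else ""

    parts = [lab + length() for lab in labels]
    rng.shuffle(parts)
    while len(parts) > 1:
        a = parts.pop(int(rng.integers(len(parts))))
        b = parts.pop(int(rng.integers(len(parts))))
        parts.append(f"({a},{b})" + length())
    s = parts[0]
    if with_lengths:  # the root itself carries no branch
        s = s[: s.rindex(":")]
    return s + ";"


def random_tree(labels, rng, with_lengths=True):
    return parse_newick(random_newick(labels, rng, with_lengths=with_lengths))


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


@pytest.fixture
def small_alignment():
    return Alignment.from_rows(
        [
            ("t1", "ACGTAC"),
            ("t2", "ACG-AC"),
            ("t3", "ACGTAN"),
            ("t4", "TCGTAC"),
        ]
    )
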