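import numpy as np
import pytest

from exonevo import load_scoring_scheme
from exonevo.seq_io import AMINO_ACIDS

RESIDUES = AMINO_ACIDS  # 20 standard letters


@pytest.fixture(scope="session")
def scheme():
    """Default scoring scheme: BLOSUM62, 10/0.5 affine gaps, free ends."""
    return load_scoring_scheme()


@pytest.fixture()
def rng():
    return np.random.default_rng(20260921)


def random_protein(rng, length):
    return "".join(rng.choice(list(RESIDUES), size=length))


# --- independent alignment oracle -----------------------------------------

def enumerate_alignments(a: str, b: str):
    """Yield every global alignment of a and b (no two-gap columns)."""
    if not a and not b:
        yield "", ""
        return
    if a:
        for ga, gb in enumerate_alignments(a[1:], b):
            yield a[0] + ga, "-" + gb
    if b:
        for ga, gb in enumerate_alignments(a, b[1:]):
            yield "-" + ga, b[0] + gb
    if a and b:
        for ga, gb in enumerate_alignments(a[1:], b[1:]):
            yield a[0] + ga, b[0] + gb


def score_alignment(ga: str, gb: str, scheme) -> float:
    """Affine-gap score of an explicit alignment, independent of any DP.

    A gap of length L costs open + (L-1)*extend; terminal gaps are free
    unless the scheme penalizes end gaps.
    """
    score = 0.0
    for ca, cb in zip(ga, gb):
        if ca != "-" and cb != "-":
            score += scheme.pair_score(ca, cb)
    for row in (ga, gb):
        runs = []
        start = None
        for i, c in enumerate(row + "X"):  # sentinel closes a trailing run
            if c == "-" and start is None:
                start = i
            elif c != "-" and start is not None:
                runs.append((start, i))
                start = None
        for lo, hi in runs:
            if not scheme.penalize_end_gaps and (lo == 0 or hi == len(row)):
                continue
            score -= scheme.gap_open + (hi - lo - 1) * scheme.gap_extend
    return score


def brute_force_best_score(a: str, b: str, scheme) -> float:
    return max(
        score_alignment(ga, gb, scheme) for ga, gb in enumerate_alignments(a, b)
    )


# --- independent random-tree oracle ----------------------------------------

def random_additive_tree(rng, n_taxa):
    """A random binary tree with positive branch lengths, as a Newick string."""
    nodes = [f"t{i}:{rng.uniform(0.1, 1.0):.6f}" for i in range(n_taxa)]
    while len(nodes) > 2:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        right = nodes.pop(j)
        left = nodes.pop(i)
        nodes.append(f"({left},{right}):{rng.uniform(0.1, 1.0):.6f}")
    return f"({nodes[0]},{nodes[1]});"
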