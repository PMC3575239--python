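import numpy as np
import pytest

from nimtools import SimParams, simulate_alignment


@pytest.fixture(scope="session")
def neutral_1mb():
    """One neutral-only 1 Mb simulation shared across tests."""
    params = SimParams(genome_length=1_200_000, indel_rate_per_branch=0.005,
                       constrained_fraction=0.0, seed=11)
    blocks, truth = simulate_alignment(params)
    return params, blocks, truth


@pytest.fixture(scope="session")
def constrained_1mb():
    """A 1 Mb simulation with 10% constrained sequence in 500 bp elements."""
    params = SimParams(genome_length=1_000_000, indel_rate_per_branch=0.005,
                       constrained_fraction=0.10, element_length=500, seed=12)
    blocks, truth = simulate_alignment(params)
    return params, blocks, truth


def naive_igs_lengths(ref: str, qry: str):
    """Brute-force column walk: lengths of maximal runs where neither row
    is gapped, with edge-truncation flags."""
    out = []
    run = 0
    start = None
    for i, (r, q) in enumerate(zip(ref, qry)):
        if r != "-" and q != "-":
            if run == 0:
                start = i
            run += 1
        else:
            if run:
                out.append((run, start == 0, False))
            run = 0
    if run:
        out.append((run, start == 0, True))
    # re-derive right-edge truncation exactly
    fixed = []
    for length, left_edge, right_edge in out:
        fixed.append((length, left_edge or right_edge))
    return fixed


def random_block_strings(rng, n_cols=80, gap_prob=0.15):
    """Random two-row gapped strings with no gap-in-both column."""
    bases = "ACGT"
    ref, qry = [], []
    for _ in range(n_cols):
        u = rng.random()
        if u < gap_prob / 2:
            ref.append("-")
            qry.append(bases[rng.integers(4)])
        elif u < gap_prob:
            ref.append(bases[rng.integers(4)])
            qry.append("-")
        else:
            ref.append(bases[rng.integers(4)])
            qry.append(bases[rng.integers(4)])
    return "".join(ref), "".join(qry)
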