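"""Properties of the two-branch indel simulator and the smaller generators."""

import numpy as np
import pytest
from scipy import stats

from nimtools import (PlacementError, SimParams, extract_igs,
                      make_codon_fixture, make_go_fixture,
                      make_read_coverage_fixture, make_spliced_gene_fixture,
                      simulate_alignment, species_sequences)


def test_no_mutation_gives_identical_ungapped_rows():
    params = SimParams(genome_length=10_000, indel_rate_per_branch=0.0,
                       substitution_rate=0.0, seed=1)
    blocks, truth = simulate_alignment(params)
    assert len(blocks) == 1
    b = blocks[0]
    assert b.ref_text == b.qry_text
    assert "-" not in b.ref_text
    assert truth.realized_indel_events == {"A": 0, "B": 0}


def test_mean_igs_length_matches_realized_delimiter_density(neutral_1mb):
    """Mean segment length ~ 1/p_eff where p_eff is counted directly from
    the emitted alignment (gap runs over aligned bases)."""
    _, blocks, _ = neutral_1mb
    segs = extract_igs(blocks[0])
    interior = [s.length for s in segs if not s.boundary_truncated]
    n_delims = len(segs) - 1  # gap runs between consecutive segments
    aligned = sum(s.length for s in segs)
    p_eff = n_delims / aligned
    assert np.mean(interior) == pytest.approx(1.0 / p_eff, rel=0.05)


def test_constrained_bases_and_gap_exclusion(constrained_1mb):
    params, blocks, truth = constrained_1mb
    assert truth.total_constrained_bases == pytest.approx(
        0.10 * params.genome_length, abs=params.element_length)
    assert truth.total_constrained_bases == sum(
        b - a for a, b in truth.element_intervals)
    # intervals sorted, non-overlapping
    for (a1, b1), (a2, b2) in zip(truth.element_intervals,
                                  truth.element_intervals[1:]):
        assert b1 <= a2
    # no gap column intersects any element: in reference coordinates every
    # element interval must lie inside a single ungapped run of the block
    segs = extract_igs(blocks[0])
    seg_iv = sorted(s.ref_interval for s in segs)
    starts = [iv[0] for iv in seg_iv]
    for a, b in truth.element_intervals_ref:
        i = np.searchsorted(starts, a, side="right") - 1
        assert i >= 0
        s0, s1 = seg_iv[i]
        assert s0 <= a and b <= s1, f"element {(a, b)} crosses a gap"


def test_determinism_bit_identical():
    params = SimParams(genome_length=50_000, indel_rate_per_branch=0.005,
                       constrained_fraction=0.05, element_length=250, seed=7)
    b1, t1 = simulate_alignment(params)
    b2, t2 = simulate_alignment(params)
    assert b1[0].ref_text == b2[0].ref_text
    assert b1[0].qry_text == b2[0].qry_text
    assert t1.element_intervals == t2.element_intervals
    assert t1.realized_indel_events == t2.realized_indel_events


def test_gap_removal_recovers_species_sequences(neutral_1mb):
    """Degapping either row reproduces that species' emitted sequence."""
    _, blocks, _ = neutral_1mb
    seqs = species_sequences(blocks)
    b = blocks[0]
    assert seqs[b.ref_name] == b.ref_text.replace("-", "")
    assert len(seqs[b.ref_name]) == b.ref_size
    assert len(seqs[b.qry_name]) == b.qry_size


def test_null_igs_lengths_are_geometric(neutral_1mb):
    """Chi-squared goodness of fit of interior segment lengths against a
    geometric law at the ML-estimated rate (alpha = 0.001)."""
    _, blocks, _ = neutral_1mb
    lengths = np.array([s.length for s in extract_igs(blocks[0])
                        if not s.boundary_truncated])
    assert len(lengths) >= 10_000
    p = len(lengths) / lengths.sum()
    edges = np.unique(np.quantile(lengths, np.linspace(0, 1, 21)).astype(int))
    obs, _ = np.histogram(lengths, bins=np.append(edges, lengths.max() + 1))
    cdf = lambda l: 1.0 - (1.0 - p) ** l  # P(L <= l), support {1, 2, ...}
    bounds = np.append(edges, lengths.max() + 1)
    exp = len(lengths) * np.diff([cdf(b - 1) for b in bounds])
    keep = exp >= 5
    chi2 = ((obs[keep] - exp[keep]) ** 2 / exp[keep]).sum()
    dof = keep.sum() - 1 - 1  # one estimated parameter
    assert stats.chi2.sf(chi2, dof) > 0.001


def test_infeasible_element_placement_raises():
    with pytest.raises(PlacementError):
        simulate_alignment(SimParams(genome_length=1000,
                                     constrained_fraction=0.9,
                                     element_length=500, seed=0))
    with pytest.raises(PlacementError):
        simulate_alignment(SimParams(genome_length=1000,
                                     constrained_fraction=0.5,
                                     element_length=2000, seed=0))


def test_param_validation():
    with pytest.raises(ValueError):
        SimParams(genome_length=0)
    with pytest.raises(ValueError):
        SimParams(genome_length=100, constrained_fraction=1.0)
    with pytest.raises(ValueError):
        SimParams(genome_length=100, indel_rate_per_branch=-1)


def test_gc_profile_shapes_base_composition():
    params = SimParams(genome_length=200_000, indel_rate_per_branch=0.0,
                       substitution_rate=0.0, window_size=100_000,
                       gc_profile=[0.30, 0.70], seed=3)
    blocks, _ = simulate_alignment(params)
    seq = blocks[0].ref_text
    gc1 = sum(c in "GC" for c in seq[:100_000]) / 100_000
    gc2 = sum(c in "GC" for c in seq[100_000:]) / 100_000
    assert gc1 == pytest.approx(0.30, abs=0.01)
    assert gc2 == pytest.approx(0.70, abs=0.01)


# -- codon fixture -----------------------------------------------------------

def test_codon_fixture_clean_by_default():
    aln, ledger = make_codon_fixture(n_species=4, n_codons=50, seed=5)
    assert (aln.quals == 40).all()
    assert not (aln.nts == "-").any()
    assert (aln.nts == aln.nts[0]).all()  # no substitutions planted
    assert all(not v for v in ledger.values())


def test_codon_fixture_burst_recorded_and_placed():
    aln, ledger = make_codon_fixture(n_codons=50,
                                     substitution_bursts=[(30, 6)], seed=5)
    assert ledger["bursts"] == [(30, 6)]
    a, b = aln.row("gmagnirostris"), aln.row("tguttata")
    mism = np.flatnonzero(a != b)
    assert len(mism) == 6
    assert mism.min() >= 30 and mism.max() < 45


def test_codon_fixture_deterministic():
    a1, l1 = make_codon_fixture(n_codons=100, n_random_low_quality=5,
                                n_random_gaps=3, seed=9)
    a2, l2 = make_codon_fixture(n_codons=100, n_random_low_quality=5,
                                n_random_gaps=3, seed=9)
    assert (a1.nts == a2.nts).all() and (a1.quals == a2.quals).all()
    assert l1 == l2


def test_codon_fixture_out_of_range_plants_rejected():
    with pytest.raises(ValueError):
        make_codon_fixture(n_codons=10, low_quality=[(0, 999, 20)])
    with pytest.raises(ValueError):
        make_codon_fixture(n_codons=10, gap_codons=[(0, 10)])


# -- spliced gene fixture ----------------------------------------------------

def test_spliced_fixture_counts_and_truth():
    fx = make_spliced_gene_fixture(n_genes=10, introns_per_gene=5, seed=2)
    assert fx["truth"]["splice_nt_total"] == 10 * 5 * 4  # 200 nt
    assert fx["truth"]["planted_splice_errors"] == []
    fx3 = make_spliced_gene_fixture(n_genes=10, introns_per_gene=5,
                                    planted_splice_errors=3, seed=2)
    assert len(fx3["truth"]["planted_splice_errors"]) == 3


def test_spliced_fixture_deterministic():
    a = make_spliced_gene_fixture(planted_splice_errors=2,
                                  planted_indel_errors=4, seed=8)
    b = make_spliced_gene_fixture(planted_splice_errors=2,
                                  planted_indel_errors=4, seed=8)
    assert a["target_row"] == b["target_row"]
    assert a["truth"] == b["truth"]


def test_spliced_fixture_error_overflow():
    with pytest.raises(ValueError):
        make_spliced_gene_fixture(n_genes=1, introns_per_gene=1,
                                  planted_splice_errors=5, seed=0)


# -- coverage and GO fixtures ------------------------------------------------

def test_coverage_fixture_mode_at_requested_fold():
    cov, total = make_read_coverage_fixture(1_000_000, fold=8, seed=4)
    counts = np.bincount(cov[1000:-1000])  # interior, away from ramp-up
    assert counts.argmax() == 8


def test_go_fixture_deterministic_and_consistent():
    o1, ann1, sites1, t1 = make_go_fixture(n_genes=20, ps_genes=["gene3"],
                                           seed=6)
    o2, ann2, sites2, t2 = make_go_fixture(n_genes=20, ps_genes=["gene3"],
                                           seed=6)
    assert o1 == o2 and ann1 == ann2 and sites1 == sites2
    assert all(len(v) == 1 for v in ann1.values())
    assert sites1["gene3"] == (100, 3)
    assert sites1["gene0"] == (100, 0)
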