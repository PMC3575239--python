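"""Filter cascade rules against brute-force oracles and boundary semantics."""

import numpy as np
import pytest

from nimtools import (CodonAlignment, discard_gene, flank_removal,
                      make_codon_fixture, mask_low_quality_codons,
                      remove_gap_columns, run_filter_cascade,
                      window_substitution_filter)
from nimtools.msa_filter import (FilterMask, flank_columns, gap_codons,
                                 low_quality_codons,
                                 window_substitution_columns)

# -- brute-force oracles -------------------------------------------------------


def oracle_low_quality(aln, threshold):
    out = set()
    for c in range(aln.n_codons):
        for sp in range(len(aln.species)):
            for o in range(3):
                p = 3 * c + o
                if aln.nts[sp, p] != "-" and 0 <= aln.quals[sp, p] <= threshold:
                    out.add(c)
    return out


def oracle_gaps(aln):
    return {c for c in range(aln.n_codons)
            if any(aln.nts[sp, 3 * c + o] == "-"
                   for sp in range(len(aln.species)) for o in range(3))}


def oracle_window(aln, pair, window=15, max_subs=5):
    a, b = aln.row(pair[0]), aln.row(pair[1])
    n = len(a)
    bad_nt = set()
    for s in range(0, n - window + 1):
        subs = sum(1 for i in range(s, s + window)
                   if a[i] not in "-N" and b[i] not in "-N" and a[i] != b[i])
        if subs > max_subs:
            bad_nt.update(range(s, s + window))
    return {p // 3 for p in bad_nt}


def oracle_flank(removed, n_codons, flank=7):
    out = set()
    for c in removed:
        out.update(range(max(0, c - flank), min(n_codons, c + flank + 1)))
    return out - set(removed)


# -- boundary semantics --------------------------------------------------------


def test_quality_threshold_is_inclusive_at_30():
    aln, _ = make_codon_fixture(n_codons=20, low_quality=[(0, 10, 30)],
                                seed=1)
    assert low_quality_codons(aln, 30) == {3}  # nt 10 -> codon 3
    aln31, _ = make_codon_fixture(n_codons=20, low_quality=[(0, 10, 31)],
                                  seed=1)
    assert low_quality_codons(aln31, 30) == set()


def test_all_high_quality_nothing_removed():
    aln, _ = make_codon_fixture(n_codons=30, seed=2)
    assert mask_low_quality_codons(aln).removed() == set()
    assert remove_gap_columns(aln).removed() == set()


def test_single_gap_codon_removed():
    aln, _ = make_codon_fixture(n_codons=30, gap_codons=[(2, 17)], seed=3)
    assert gap_codons(aln) == {17}


def test_window_five_substitutions_kept_six_removed():
    """Strictly 'greater than 5': 5 mismatches in an isolated 15-nt span are
    kept, 6 are removed."""
    aln5, _ = make_codon_fixture(n_codons=40, substitution_bursts=[(45, 5)],
                                 seed=4)
    mask5 = window_substitution_filter(aln5, ("gmagnirostris", "tguttata"))
    assert mask5.removed() == set()

    aln6, _ = make_codon_fixture(n_codons=40, substitution_bursts=[(45, 6)],
                                 seed=4)
    mask6 = window_substitution_filter(aln6, ("gmagnirostris", "tguttata"))
    assert mask6.removed() == oracle_window(aln6,
                                            ("gmagnirostris", "tguttata"))
    assert mask6.removed()


def test_flank_dilation_single_seed():
    mask = FilterMask(50).apply_rule("window", [25])
    flank_removal(mask, 7)
    assert mask.removed() == set(range(18, 33))  # 15 codons
    # clipped at the ends
    mask2 = FilterMask(10).apply_rule("window", [1])
    flank_removal(mask2, 7)
    assert mask2.removed() == set(range(0, 9))


def test_flank_removal_is_single_pass():
    """Flank removals do not seed further flanks."""
    mask = FilterMask(100).apply_rule("window", [50])
    flank_removal(mask, 7)
    assert max(mask.removed()) == 57 and min(mask.removed()) == 43


def test_discard_boundaries():
    aln = CodonAlignment(["a"], np.full((1, 300), "A", dtype="U1"),
                         predicted_codon_count=200)
    mask = FilterMask(100)
    mask.apply_rule("window", [0])  # 99 remaining of 100 aligned codons
    keep, reason = discard_gene(aln, mask)
    assert not keep and "length" in reason

    aln2 = CodonAlignment(["a"], np.full((1, 450), "A", dtype="U1"),
                          predicted_codon_count=2000)
    keep2, reason2 = discard_gene(aln2, FilterMask(150))  # 150 of 2000 = 7.5%
    assert not keep2 and "fraction" in reason2

    aln3 = CodonAlignment(["a"], np.full((1, 300), "A", dtype="U1"),
                          predicted_codon_count=500)
    keep3, _ = discard_gene(aln3, FilterMask(100))  # 100 codons, 20%
    assert keep3


# -- oracle equivalence on random fixtures -------------------------------------


@pytest.mark.parametrize("batch", range(5))
def test_rules_equal_bruteforce_on_random_fixtures(batch):
    rng = np.random.default_rng(100 + batch)
    for i in range(100):
        n_codons = int(rng.integers(10, 60))
        n_bursts = int(rng.integers(0, 3))
        bursts = []
        for _ in range(n_bursts):
            if 3 * n_codons >= 15:
                bursts.append((int(rng.integers(0, 3 * n_codons - 14)),
                               int(rng.integers(1, 9))))
        aln, _ = make_codon_fixture(
            n_species=int(rng.integers(2, 6)), n_codons=n_codons,
            n_random_low_quality=int(rng.integers(0, 5)),
            n_random_gaps=int(rng.integers(0, 4)),
            substitution_bursts=bursts,
            seed=int(rng.integers(0, 2**31)))
        pair = (aln.species[0], aln.species[1])
        assert low_quality_codons(aln, 30) == oracle_low_quality(aln, 30)
        assert gap_codons(aln) == oracle_gaps(aln)
        assert (window_substitution_columns(aln, pair)
                == oracle_window(aln, pair))
        removed = low_quality_codons(aln, 30) | gap_codons(aln)
        assert (flank_columns(removed, n_codons)
                == oracle_flank(removed, n_codons))


# -- cascade-level properties --------------------------------------------------


def test_cascade_clean_fixture_passes_through():
    aln, _ = make_codon_fixture(n_codons=150, seed=10)
    filtered, mask, report = run_filter_cascade(aln)
    assert report["decision"] == "keep"
    assert mask.n_kept == 150
    assert (filtered.nts == aln.nts).all()


def test_cascade_composition_equals_individual_oracles():
    aln, ledger = make_codon_fixture(
        n_codons=200, low_quality=[(0, 33, 12), (2, 301, 30)],
        gap_codons=[(1, 70)], substitution_bursts=[(450, 7)], seed=11)
    pair = (aln.species[0], aln.species[1])
    _, mask, report = run_filter_cascade(aln)
    gaps = oracle_gaps(aln)
    quals = oracle_low_quality(aln, 30) - gaps
    active = np.ones(600, dtype=bool)
    for c in gaps | quals:
        active[3 * c:3 * c + 3] = False
    window = window_substitution_columns(aln, pair, active_nt=active)
    window -= gaps | quals
    pre = gaps | quals | window
    flank = oracle_flank(pre, aln.n_codons)
    assert mask.removed() == pre | flank
    assert report["per_rule"]["gap"] == len(gaps)
    assert report["per_rule"]["quality"] == len(quals)
    assert report["per_rule"]["window"] == len(window)
    assert report["per_rule"]["flank"] == len(flank)


def test_quality_and_gap_rules_commute():
    aln, _ = make_codon_fixture(n_codons=80, n_random_low_quality=6,
                                n_random_gaps=4, seed=12)
    m1 = FilterMask(80)
    m1.apply_rule("quality", low_quality_codons(aln, 30))
    m1.apply_rule("gap", gap_codons(aln))
    m2 = FilterMask(80)
    m2.apply_rule("gap", gap_codons(aln))
    m2.apply_rule("quality", low_quality_codons(aln, 30))
    assert m1.removed() == m2.removed()


def test_kept_set_only_shrinks_and_ledger_replays():
    aln, _ = make_codon_fixture(n_codons=120, n_random_low_quality=4,
                                n_random_gaps=3,
                                substitution_bursts=[(100, 8)], seed=13)
    _, mask, _ = run_filter_cascade(aln)
    # monotonicity: replay the ledger step by step
    running = FilterMask(mask.n_codons)
    kept_sizes = [running.n_kept]
    for rule, cols in mask.ledger:
        running.apply_rule(rule, cols)
        kept_sizes.append(running.n_kept)
    assert all(a >= b for a, b in zip(kept_sizes, kept_sizes[1:]))
    # replay reproduces the final mask and the filtered alignment exactly
    replayed = mask.replay()
    assert replayed.status == mask.status
    assert (aln.subset(replayed.kept()).nts
            == aln.subset(mask.kept()).nts).all()


def test_external_masks_applied_first():
    aln, _ = make_codon_fixture(n_codons=150, seed=14)
    _, mask, report = run_filter_cascade(
        aln, external_masks={"gblocks": {0, 1, 2}})
    assert mask.ledger[0][0] == "external:gblocks"
    assert {0, 1, 2}.issubset(mask.removed())
    # flanks extend from the external removals too
    assert 9 in mask.removed() and 10 not in mask.removed()
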