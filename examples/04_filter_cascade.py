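"""Run the codon-alignment filter cascade on a fixture with planted defects.

A 300-codon alignment of five species gets a low-quality base, a gapped
codon and a burst of 7 substitutions between the focal pair.  The cascade
removes the affected codons plus 7 flanking codons around each removal and
then decides whether enough alignment survives to test the gene at all.
"""

from nimtools import make_codon_fixture, run_filter_cascade

aln, ledger = make_codon_fixture(
    n_species=5, n_codons=300,
    low_quality=[(0, 150, 25)],          # species 0, nucleotide 150, phred 25
    gap_codons=[(2, 200)],               # species 2, codon 200
    substitution_bursts=[(750, 7)],      # 7 mismatches within 15 nt at nt 750
    seed=3)

filtered, mask, report = run_filter_cascade(aln)

print("planted:", {k: v for k, v in ledger.items() if v})
print("removed per rule:", report["per_rule"])
print(f"kept {report['kept_codons']} of {aln.n_codons} codons "
      f"-> {report['decision']} ({report['reason']})")
# Each removal seeds a +/-7 codon flank, so one bad codon costs up to 15;
# genes keeping fewer than 100 codons or under 10% of their predicted
# length are discarded before any selection test.
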