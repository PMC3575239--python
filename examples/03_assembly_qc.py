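"""Assembly completeness and error estimators on published-style inputs.

The first block reproduces the kind of arithmetic reported in a genome
survey; the second audits a synthetic three-genome fixture with planted
errors to show the estimators recover planted truth.
"""

from nimtools import (aligned_fraction, euchromatic_completeness,
                      geneset_completeness, genome_size_from_coverage,
                      indel_error_upper_bound, make_spliced_gene_fixture,
                      splice_site_substitution_rate)

# survey arithmetic: 7.529 Gb of reads at 6.0-fold modal coverage, a 991 Mb
# assembly with 122 Mb of outgroup-shared sequence missing, 569/823 Mb
# aligning to two relatives, 7,416 vs 10,222 one-to-one orthologues
print(f"genome size:      {genome_size_from_coverage(7.529e9, 6.0) / 1e9:.2f} Gb")
print(f"euchromatic completeness: "
      f"{100 * euchromatic_completeness(991, 122):.0f}%")
print(f"aligned to outgroup:      {aligned_fraction(569, 991)}%")
print(f"aligned to sister clade:  {aligned_fraction(823, 991)}%")
print(f"gene set completeness:    {geneset_completeness(7416, 10222)}%")
print()

# fixture audit: 3 planted splice-site substitutions and 12 target-only
# indels in a toy three-genome alignment
fx = make_spliced_gene_fixture(n_genes=10, introns_per_gene=5,
                               planted_splice_errors=3,
                               planted_indel_errors=12, seed=1)
audit = splice_site_substitution_rate(
    fx["gff3"], {"ref.chr1": fx["fasta"]["ref.chr1"]}, fx["target_map"])
print(f"splice audit:     {audit.n_changed} changed of {audit.n_sites_nt} nt "
      f"-> {100 * audit.rate:.2f}% apparent substitution error")
rate = indel_error_upper_bound([(fx["ref_row"], fx["target_row"],
                                 fx["sister_row"])])
print(f"indel audit:      {rate:.2f} target-only indels per kb "
      "(upper bound on assembly indel error)")
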