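"""Assembly completeness and error-rate estimators.

Simple audits computable from genome-scale summary numbers and alignments:
coverage-based genome size, euchromatic completeness by outgroup
triangulation, a splice-dinucleotide substitution audit (GT-AG sites are
essentially invariant, so apparent changes in the target assembly measure
base-call error plus mis-alignment), a three-way indel error upper bound,
and aligned-fraction / gene-set completeness arithmetic.

Percentages are reported to the integer and rates to two significant
figures.
"""

from __future__ import annotations

import io
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO


@dataclass
class AssemblyStats:
    total_sequenced_bases: float = 0.0
    modal_coverage: float = 0.0
    assembly_span: float = 0.0
    contig_span: float = 0.0
    scaffold_n50: float = 0.0

    def __post_init__(self):
        if min(self.total_sequenced_bases, self.modal_coverage,
               self.assembly_span, self.contig_span, self.scaffold_n50) < 0:
            raise ValueError("assembly statistics must be non-negative")
        if self.contig_span > self.assembly_span > 0:
            raise ValueError("contig span cannot exceed assembly span")


@dataclass
class SpliceSiteAudit:
    """Outcome of the splice-dinucleotide substitution audit."""

    n_sites_nt: int
    n_changed: int
    n_unaligned: int = 0
    n_skipped_introns: int = 0
    skipped: list = field(default_factory=list)

    @property
    def rate(self) -> float:
        return self.n_changed / self.n_sites_nt if self.n_sites_nt else 0.0

    @property
    def rate_2sf(self) -> float:
        return round_sig(self.rate, 2)


def round_sig(x: float, sig: int = 2) -> float:
    """Round to ``sig`` significant figures (0 stays 0)."""
    if x == 0:
        return 0.0
    return round(x, -int(math.floor(math.log10(abs(x)))) + (sig - 1))


def genome_size_from_coverage(total_sequenced_bases: float,
                              modal_coverage: float) -> float:
    """True genome size under equal library representation: total / coverage."""
    if modal_coverage <= 0:
        raise ValueError("modal coverage must be positive")
    return total_sequenced_bases / modal_coverage


def modal_coverage(coverage_track) -> int:
    """Mode of the integer per-base coverage histogram over contigs."""
    cov = np.asarray(coverage_track, dtype=np.int64)
    if cov.size == 0:
        raise ValueError("empty coverage track")
    return int(np.bincount(cov).argmax())


def euchromatic_completeness(assembly_euchromatic_span: float,
                             outgroup_pair_aligned_absent: float) -> float:
    """Fraction of the euchromatic genome present in the assembly.

    Sequence aligned between two relatives of the target but absent from
    the target assembly estimates what the assembly is missing, so
    completeness = span / (span + absent).
    """
    denom = assembly_euchromatic_span + outgroup_pair_aligned_absent
    if denom <= 0:
        raise ValueError("spans must be positive")
    return assembly_euchromatic_span / denom


def aligned_fraction(aligned_bases: float, assembly_span: float) -> int:
    """Percentage of the assembly covered by an alignment, to the integer."""
    if assembly_span <= 0:
        raise ValueError("assembly span must be positive")
    return int(round(100.0 * aligned_bases / assembly_span))


def geneset_completeness(n_orthologs_target_pair: int,
                         n_orthologs_reference_pair: int) -> int:
    """1:1-ortholog count of the target pair relative to a reference pair, %."""
    if n_orthologs_reference_pair <= 0:
        raise ValueError("reference ortholog count must be positive")
    return int(round(100.0 * n_orthologs_target_pair
                     / n_orthologs_reference_pair))


def scaffold_n50(lengths) -> int:
    """Length such that scaffolds at least this long hold half the span."""
    arr = np.sort(np.asarray(list(lengths), dtype=np.int64))[::-1]
    if arr.size == 0:
        return 0
    half = arr.sum() / 2.0
    return int(arr[np.searchsorted(np.cumsum(arr), half)])


# ---------------------------------------------------------------------------
# splice-site substitution audit
# ---------------------------------------------------------------------------

def _parse_gff3_introns(gff3) -> list[tuple[str, int, int, str]]:
    """(seqid, start0, end0, strand) for every intron feature (0-based)."""
    if hasattr(gff3, "read"):
        text = gff3.read()
    else:
        try:
            with open(gff3) as fh:
                text = fh.read()
        except (OSError, ValueError):
            text = str(gff3)
    introns = []
    for ln, line in enumerate(text.splitlines(), start=1):
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 8:
            raise ValueError(f"malformed GFF3 line {ln}")
        if parts[2] == "intron":
            introns.append((parts[0], int(parts[3]) - 1, int(parts[4]),
                            parts[6]))
    return introns


_COMPL = str.maketrans("ACGTN-", "TGCAN-")


def splice_site_substitution_rate(gff3, ref_fasta,
                                  target_alignment_map) -> SpliceSiteAudit:
    """Audit GT-AG splice dinucleotides of reference introns in the target.

    ``target_alignment_map`` maps reference sequence name to the target
    sequence projected onto reference coordinates ('-' where unaligned).
    Unaligned splice nucleotides leave the denominator; introns whose
    reference dinucleotides are not canonical GT..AG are skipped with a
    warning and recorded.
    """
    if isinstance(ref_fasta, dict):
        ref = {k: str(v).upper() for k, v in ref_fasta.items()}
    else:
        ref = {rec.id: str(rec.seq).upper()
               for rec in SeqIO.parse(str(ref_fasta), "fasta")}
    audited = changed = unaligned = 0
    skipped = []
    for seqid, s, e, strand in _parse_gff3_introns(gff3):
        rseq = ref[seqid]
        donor, acceptor = rseq[s:s + 2], rseq[e - 2:e]
        if strand == "-":
            donor, acceptor = (acceptor.translate(_COMPL)[::-1],
                               donor.translate(_COMPL)[::-1])
        if donor != "GT" or acceptor != "AG":
            warnings.warn(f"non-canonical intron {seqid}:{s}-{e} "
                          f"({donor}..{acceptor}); skipped")
            skipped.append((seqid, s, e))
            continue
        tseq = target_alignment_map.get(seqid)
        if tseq is None:
            unaligned += 4
            continue
        for pos in (s, s + 1, e - 2, e - 1):
            t = tseq[pos].upper()
            if t in "-.":
                unaligned += 1
                continue
            audited += 1
            if t != rseq[pos]:
                changed += 1
    return SpliceSiteAudit(n_sites_nt=audited, n_changed=changed,
                           n_unaligned=unaligned,
                           n_skipped_introns=len(skipped), skipped=skipped)


# ---------------------------------------------------------------------------
# three-way indel error bound
# ---------------------------------------------------------------------------

def indel_error_upper_bound(threeway_blocks) -> float:
    """Upper bound on assembly indel errors, per kb of aligned sequence.

    Each block is (outgroup_row, target_row, sister_row), equal-length
    gapped strings.  Assuming no true target-lineage indels, every indel
    event private to the target row (a maximal gap run where the target's
    gap state differs from both other rows, with a consistent column
    pattern) is an assembly error.  The denominator is columns where the
    outgroup row is ungapped.  Blocks without exactly 3 rows are skipped
    with a warning.
    """
    events = 0
    aligned_cols = 0
    for block in threeway_blocks:
        if len(block) != 3:
            warnings.warn(f"skipping block with {len(block)} rows")
            continue
        o, t, s = block
        if not (len(o) == len(t) == len(s)):
            raise ValueError("rows of a three-way block differ in length")
        oa = np.frombuffer(o.encode("ascii"), dtype=np.uint8) == ord("-")
        ta = np.frombuffer(t.encode("ascii"), dtype=np.uint8) == ord("-")
        sa = np.frombuffer(s.encode("ascii"), dtype=np.uint8) == ord("-")
        aligned_cols += int((~oa).sum())
        target_private = (ta != oa) & (ta != sa)
        # pattern code per column; an event = maximal run of the same
        # target-private pattern
        code = np.where(target_private, 1 + ta.astype(np.int8), 0)
        if code.size:
            run_start = np.concatenate(([True], code[1:] != code[:-1]))
            events += int(((code != 0) & run_start).sum())
    if aligned_cols == 0:
        return 0.0
    return events / (aligned_cols / 1000.0)
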