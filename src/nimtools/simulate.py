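"""Synthetic data generators for every analysis stage in the package.

The central generator, :func:`simulate_alignment`, realises the null model
that the neutral indel analysis assumes — indels accumulate uniformly at a
per-base rate in neutral sequence — plus embedded indel-free constrained
elements whose purging the analysis is meant to detect.  Two descendant
sequences evolve independently from a common ancestor; because every indel
event is recorded, the emitted pairwise alignment is the true alignment,
not a re-inferred one, and a truth ledger reports exactly how much
constrained sequence was planted and where.

Smaller generators produce codon alignments with planted filterable
features, spliced toy gene trios with planted assembly errors, GO DAG
fixtures, and read-coverage tracks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .alignio import PairAlignmentBlock

BASE_LUT = np.frombuffer(b"ACGT", dtype=np.uint8)
GAP = ord("-")


class PlacementError(ValueError):
    """Constrained elements cannot be placed at the requested density."""


@dataclass(frozen=True)
class SimParams:
    """Parameters of the two-branch indel/substitution simulation.

    ``indel_rate_per_branch`` is events per NEUTRAL base per branch; indel
    lengths default to geometric with mean 3 (the length law is exposed as a
    parameter, not asserted).  ``gc_profile`` may be a scalar GC fraction, a
    per-window sequence, or None (uniform 0.41, a typical avian genome-wide
    value).  ``element_gc_weight`` biases constrained-element placement
    toward GC-rich windows (weight proportional to exp(w * GC)); 0 = uniform.
    """

    genome_length: int
    indel_rate_per_branch: float = 0.005
    indel_length_dist: str = "geometric"
    indel_length_mean: float = 3.0
    substitution_rate: float = 0.02
    constrained_fraction: float = 0.0
    element_length: int = 500
    gc_profile: object = None
    window_size: int = 10_000
    element_gc_weight: float = 0.0
    ref_name: str = "finchA.chr1"
    qry_name: str = "finchB.chr1"
    seed: int = 0

    def __post_init__(self):
        if self.genome_length <= 0:
            raise ValueError("genome_length must be positive")
        if not (0.0 <= self.constrained_fraction < 1.0):
            raise ValueError("constrained_fraction must be in [0, 1)")
        for r in (self.indel_rate_per_branch, self.substitution_rate):
            if r < 0:
                raise ValueError("rates must be non-negative")
        if self.indel_length_dist not in ("geometric", "fixed"):
            raise ValueError("indel_length_dist must be 'geometric' or 'fixed'")
        if self.element_length < 1:
            raise ValueError("element_length must be >= 1")

    @property
    def n_windows(self) -> int:
        return -(-self.genome_length // self.window_size)


@dataclass
class SimTruth:
    """Ground truth of one simulation run."""

    total_constrained_bases: int
    element_intervals: list  # ancestral half-open intervals, sorted
    element_intervals_ref: list  # same elements in reference coordinates
    realized_indel_events: dict
    window_gc: np.ndarray = field(default_factory=lambda: np.zeros(0))
    constrained_bases_per_window: np.ndarray = field(
        default_factory=lambda: np.zeros(0, dtype=np.int64))


def _window_gc_targets(params: SimParams) -> np.ndarray:
    nw = params.n_windows
    gp = params.gc_profile
    if gp is None:
        return np.full(nw, 0.41)
    if np.isscalar(gp):
        return np.full(nw, float(gp))
    arr = np.asarray(gp, dtype=float)
    if len(arr) != nw:
        raise ValueError(f"gc_profile length {len(arr)} != n_windows {nw}")
    return arr


def _draw_ancestor(rng, params: SimParams, gc_w: np.ndarray) -> np.ndarray:
    L = params.genome_length
    reps = np.full(params.n_windows, params.window_size)
    reps[-1] = L - params.window_size * (params.n_windows - 1)
    gc = np.repeat(gc_w, reps)
    u = rng.random(L)
    # cumulative thresholds A | C | G | T at (1-g)/2, 1/2, (1+g)/2
    code = ((u >= (1.0 - gc) / 2).astype(np.int8)
            + (u >= 0.5) + (u >= (1.0 + gc) / 2))
    return code.astype(np.uint8)


def _place_elements(rng, params: SimParams, gc_w: np.ndarray
                    ) -> tuple[np.ndarray, list]:
    L = params.genome_length
    elen = params.element_length
    n_elem = int(round(params.constrained_fraction * L / elen))
    constrained = np.zeros(L, dtype=bool)
    if params.constrained_fraction > 0 and elen > L:
        raise PlacementError(
            f"element length {elen} exceeds genome length {L}")
    if n_elem == 0:
        return constrained, []
    if n_elem * elen > 0.8 * L:
        raise PlacementError(
            f"cannot place {n_elem} elements of {elen} bp in {L} bp")
    w = np.exp(params.element_gc_weight * gc_w)
    w /= w.sum()
    starts = []
    max_attempts = 200 * n_elem
    attempts = 0
    while len(starts) < n_elem:
        attempts += 1
        if attempts > max_attempts:
            raise PlacementError(
                "element placement failed: density too high for rejection "
                "sampling")
        win = rng.choice(params.n_windows, p=w)
        lo = win * params.window_size
        hi = min(L, (win + 1) * params.window_size)
        s = int(rng.integers(lo, hi))
        if s + elen > L:
            continue
        if constrained[s:s + elen].any():
            continue
        constrained[s:s + elen] = True
        starts.append(s)
    starts.sort()
    return constrained, [(s, s + elen) for s in starts]


def _draw_indels(rng, params: SimParams, constrained: np.ndarray):
    """One branch's indel events, rejected out of constrained elements.

    Returns (deletion mask over ancestral bases, insertion lengths per
    anchor 0..L, event count).
    """
    L = params.genome_length
    n_neutral = L - int(constrained.sum())
    n_events = int(rng.poisson(params.indel_rate_per_branch * n_neutral))
    del_mask = np.zeros(L, dtype=bool)
    ins_len = np.zeros(L + 1, dtype=np.int64)
    if n_events == 0:
        return del_mask, ins_len, 0
    is_del = rng.random(n_events) < 0.5
    if params.indel_length_dist == "geometric":
        lengths = rng.geometric(1.0 / params.indel_length_mean, n_events)
    else:
        lengths = np.full(n_events, int(params.indel_length_mean))
    cs = np.concatenate(([0], np.cumsum(constrained)))
    pos = np.where(is_del, rng.integers(0, L, n_events),
                   rng.integers(0, L + 1, n_events))
    for _ in range(10_000):
        ends = np.minimum(pos + np.where(is_del, lengths, 0), L)
        del_bad = is_del & (cs[ends] - cs[np.minimum(pos, L)] > 0)
        p = pos.copy()
        ins_bad = (~is_del & (p > 0) & (p < L)
                   & constrained[np.maximum(p - 1, 0)]
                   & constrained[np.minimum(p, L - 1)])
        bad = del_bad | ins_bad
        if not bad.any():
            break
        nb = int(bad.sum())
        pos[bad] = np.where(is_del[bad], rng.integers(0, L, nb),
                            rng.integers(0, L + 1, nb))
    else:  # pragma: no cover - only at extreme densities
        raise PlacementError("indel rejection sampling did not converge")
    dpos, dlen = pos[is_del], lengths[is_del]
    for s, ln in zip(dpos, dlen):
        del_mask[s:min(s + ln, L)] = True
    np.add.at(ins_len, pos[~is_del], lengths[~is_del])
    return del_mask, ins_len, n_events


def _substitute(rng, seq: np.ndarray, rate: float) -> np.ndarray:
    out = seq.copy()
    if rate > 0:
        m = rng.random(len(seq)) < rate
        n = int(m.sum())
        out[m] = (out[m] + rng.integers(1, 4, n).astype(np.uint8)) % 4
    return out


def simulate_alignment(params: SimParams
                       ) -> tuple[list[PairAlignmentBlock], SimTruth]:
    """Simulate two-branch neutral indel evolution with constrained elements.

    Indel events whose footprint touches a constrained element are rejected
    and redrawn, so element bases are exactly indel-free; substitutions are
    applied everywhere.  The emitted block is the true alignment known from
    event bookkeeping.  Identical params (including seed) give bit-identical
    output.
    """
    rng = np.random.default_rng(params.seed)
    L = params.genome_length
    gc_w = _window_gc_targets(params)
    ancestor = _draw_ancestor(rng, params, gc_w)
    constrained, elements = _place_elements(rng, params, gc_w)

    del_a, ins_a, n_ev_a = _draw_indels(rng, params, constrained)
    del_b, ins_b, n_ev_b = _draw_indels(rng, params, constrained)
    seq_a = _substitute(rng, ancestor, params.substitution_rate)
    seq_b = _substitute(rng, ancestor, params.substitution_rate)
    ins_bases_a = rng.integers(0, 4, int(ins_a.sum())).astype(np.uint8)
    ins_bases_b = rng.integers(0, 4, int(ins_b.sum())).astype(np.uint8)

    # column layout: insertions anchored at i precede ancestral base i;
    # A-branch insertions come before B-branch insertions at the same anchor
    ins_counts = ins_a + ins_b
    cum_incl = np.cumsum(ins_counts)          # sum over anchors <= i
    cum_excl = cum_incl - ins_counts          # sum over anchors < i
    total_cols = L + int(cum_incl[-1])
    ref = np.full(total_cols, GAP, dtype=np.uint8)
    qry = np.full(total_cols, GAP, dtype=np.uint8)

    base_col = np.arange(L, dtype=np.int64) + cum_incl[:L]
    keep_a = ~del_a
    keep_b = ~del_b
    ref[base_col[keep_a]] = BASE_LUT[seq_a[keep_a]]
    qry[base_col[keep_b]] = BASE_LUT[seq_b[keep_b]]

    def _insertion_cols(ins_len, lead):
        anchors = np.repeat(np.arange(L + 1, dtype=np.int64), ins_len)
        offs = (np.arange(len(anchors), dtype=np.int64)
                - np.repeat(np.cumsum(ins_len) - ins_len, ins_len))
        return anchors + cum_excl[anchors] + lead[anchors] + offs

    zeros = np.zeros(L + 1, dtype=np.int64)
    if ins_bases_a.size:
        ref[_insertion_cols(ins_a, zeros)] = BASE_LUT[ins_bases_a]
    if ins_bases_b.size:
        qry[_insertion_cols(ins_b, ins_a)] = BASE_LUT[ins_bases_b]

    keep_cols = ~((ref == GAP) & (qry == GAP))
    ref = ref[keep_cols]
    qry = qry[keep_cols]

    # map ancestral element intervals into reference (branch A) coordinates:
    # A-coordinates advance on surviving ancestral bases and A-insertions only
    del_a_excl = np.concatenate(([0], np.cumsum(del_a)))
    ins_a_incl = np.cumsum(ins_a)
    elements_ref = []
    for a, b in elements:
        rs = a - int(del_a_excl[a]) + int(ins_a_incl[a])
        elements_ref.append((rs, rs + (b - a)))

    ref_text = ref.tobytes().decode("ascii")
    qry_text = qry.tobytes().decode("ascii")
    ref_size = len(ref_text) - ref_text.count("-")
    qry_size = len(qry_text) - qry_text.count("-")
    block = PairAlignmentBlock(
        params.ref_name, 0, ref_size, "+",
        params.qry_name, 0, qry_size, "+",
        ref_text, qry_text, ref_size, qry_size)

    per_window = np.zeros(params.n_windows, dtype=np.int64)
    for a, b in elements:
        for w in range(a // params.window_size, (b - 1) // params.window_size + 1):
            lo = max(a, w * params.window_size)
            hi = min(b, (w + 1) * params.window_size)
            per_window[w] += hi - lo
    truth = SimTruth(
        total_constrained_bases=int(constrained.sum()),
        element_intervals=elements,
        element_intervals_ref=elements_ref,
        realized_indel_events={"A": n_ev_a, "B": n_ev_b},
        window_gc=gc_w,
        constrained_bases_per_window=per_window)
    return [block], truth


def species_sequences(blocks: list[PairAlignmentBlock]) -> dict[str, str]:
    """Ungapped per-species sequences recovered from alignment rows."""
    out: dict[str, list[str]] = {}
    for b in blocks:
        out.setdefault(b.ref_name, []).append(b.ref_text.replace("-", ""))
        out.setdefault(b.qry_name, []).append(b.qry_text.replace("-", ""))
    return {k: "".join(v) for k, v in out.items()}


def write_fasta(seqs: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i:i + 80] + "\n")


# ---------------------------------------------------------------------------
# codon-alignment fixtures for the filter cascade
# ---------------------------------------------------------------------------

def make_codon_fixture(n_species: int = 5, n_codons: int = 200,
                       low_quality=None, gap_codons=None,
                       substitution_bursts=None,
                       n_random_low_quality: int = 0,
                       n_random_gaps: int = 0,
                       predicted_codon_count: int | None = None,
                       seed: int = 0):
    """Codon alignment with a machine-readable ledger of planted features.

    ``low_quality``: (species_idx, nt_pos, phred) triples.
    ``gap_codons``: (species_idx, codon_idx) pairs.
    ``substitution_bursts``: (nt_start, n_subs) pairs — n_subs mismatches
    between the first two species planted inside [nt_start, nt_start+15).
    With no planted features all qualities are 40 and there are no gaps.
    Returns (CodonAlignment, ledger dict).
    """
    from .msa_filter import CodonAlignment

    if n_codons < 1:
        raise ValueError("n_codons must be >= 1")
    rng = np.random.default_rng(seed)
    n_nt = 3 * n_codons
    base = BASE_LUT[rng.integers(0, 4, n_nt)]
    nts = np.tile(base, (n_species, 1)).copy()
    quals = np.full((n_species, n_nt), 40, dtype=np.int16)

    ledger = {"low_quality": [], "gap_codons": [], "bursts": []}

    low_quality = list(low_quality or [])
    for _ in range(n_random_low_quality):
        low_quality.append((int(rng.integers(0, n_species)),
                            int(rng.integers(0, n_nt)),
                            int(rng.integers(0, 31))))
    for sp, pos, ph in low_quality:
        if not (0 <= pos < n_nt):
            raise ValueError(f"low-quality position {pos} out of range")
        quals[sp, pos] = ph
        ledger["low_quality"].append((sp, pos, ph))

    gap_codons = list(gap_codons or [])
    for _ in range(n_random_gaps):
        gap_codons.append((int(rng.integers(0, n_species)),
                           int(rng.integers(0, n_codons))))
    for sp, c in gap_codons:
        if not (0 <= c < n_codons):
            raise ValueError(f"gap codon {c} out of range")
        nts[sp, 3 * c:3 * c + 3] = GAP
        ledger["gap_codons"].append((sp, c))

    for start, n_subs in (substitution_bursts or []):
        if not (0 <= start and start + 15 <= n_nt):
            raise ValueError(f"burst at {start} out of range")
        if n_subs > 15:
            raise ValueError("burst cannot exceed window size")
        offs = rng.choice(15, size=n_subs, replace=False)
        for o in offs:
            p = start + int(o)
            cur = nts[1, p]
            choices = BASE_LUT[BASE_LUT != cur]
            nts[1, p] = rng.choice(choices)
        ledger["bursts"].append((start, int(n_subs)))

    species = [f"sp{i}" for i in range(n_species)]
    species[0], species[1] = "gmagnirostris", "tguttata"
    aln = CodonAlignment(
        species=species,
        nts=nts.view("S1").astype("U1"),
        quals=quals,
        predicted_codon_count=predicted_codon_count or n_codons)
    return aln, ledger


# ---------------------------------------------------------------------------
# spliced gene / three-genome fixtures for assembly QC
# ---------------------------------------------------------------------------

def make_spliced_gene_fixture(n_genes: int = 10, introns_per_gene: int = 5,
                              planted_splice_errors: int = 0,
                              planted_indel_errors: int = 0,
                              exon_length: int = 90, intron_length: int = 200,
                              spacer: int = 100,
                              substitution_rate: float = 0.0,
                              seed: int = 0):
    """Three aligned toy genomes (reference, target, sister) with GT-AG introns.

    The reference carries ``n_genes`` genes of ``introns_per_gene`` introns
    each; every intron starts GT and ends AG.  The target carries exactly the
    planted substitutions at splice dinucleotides and the planted target-only
    indel events (deletions of 1-5 bp placed outside splice dinucleotides);
    the sister genome is indel-free relative to the reference.

    Returns a dict with aligned rows ("ref_row", "target_row",
    "sister_row"), ungapped FASTA sequences ("fasta"), a GFF3 string for the
    reference ("gff3"), a reference-coordinate target map for the splice
    audit ("target_map"), and a truth ledger ("truth").
    """
    rng = np.random.default_rng(seed)
    parts = []
    gff = ["##gff-version 3"]
    splice_nt = []  # reference coordinates of all GT/AG nucleotides
    pos = 0
    seqname = "ref.chr1"

    def rand_seq(n):
        return "".join("ACGT"[i] for i in rng.integers(0, 4, n))

    for g in range(n_genes):
        pos += spacer
        parts.append(rand_seq(spacer))
        gene_start = pos
        for i in range(introns_per_gene + 1):
            parts.append(rand_seq(exon_length))
            exon_start = pos
            pos += exon_length
            gff.append("\t".join([seqname, "toy", "exon", str(exon_start + 1),
                                  str(pos), ".", "+", ".",
                                  f"Parent=gene{g}"]))
            if i < introns_per_gene:
                inner = rand_seq(intron_length - 4)
                parts.append("GT" + inner + "AG")
                splice_nt.extend([pos, pos + 1,
                                  pos + intron_length - 2,
                                  pos + intron_length - 1])
                gff.append("\t".join([seqname, "toy", "intron", str(pos + 1),
                                      str(pos + intron_length), ".", "+", ".",
                                      f"Parent=gene{g}"]))
                pos += intron_length
        gff.append("\t".join([seqname, "toy", "gene", str(gene_start + 1),
                              str(pos), ".", "+", ".", f"ID=gene{g}"]))
    parts.append(rand_seq(spacer))
    pos += spacer
    ref_seq = "".join(parts)
    L = len(ref_seq)

    if planted_splice_errors > len(splice_nt):
        raise ValueError("planted splice errors exceed available splice sites")

    target = np.frombuffer(ref_seq.encode(), dtype=np.uint8).copy()
    sister = np.frombuffer(ref_seq.encode(), dtype=np.uint8).copy()
    if substitution_rate > 0:
        # background divergence, kept away from splice sites so truth is exact
        for arr in (target, sister):
            idx = np.flatnonzero(rng.random(L) < substitution_rate)
            idx = idx[~np.isin(idx, splice_nt)]
            shift = rng.integers(1, 4, idx.size)
            codes = np.searchsorted(BASE_LUT, arr[idx])
            arr[idx] = BASE_LUT[(codes + shift) % 4]

    err_sites = sorted(rng.choice(len(splice_nt), size=planted_splice_errors,
                                  replace=False).tolist())
    planted_splice_positions = []
    for j in err_sites:
        p = splice_nt[j]
        code = int(np.searchsorted(BASE_LUT, target[p]))
        target[p] = BASE_LUT[(code + int(rng.integers(1, 4))) % 4]
        planted_splice_positions.append(p)

    # target-only deletions, never touching splice dinucleotides
    splice_set = set(splice_nt)
    del_events = []
    deleted = np.zeros(L, dtype=bool)
    attempts = 0
    while len(del_events) < planted_indel_errors:
        attempts += 1
        if attempts > 10_000:
            raise PlacementError("could not place planted indels")
        ln = int(rng.integers(1, 6))
        s = int(rng.integers(0, L - ln))
        footprint = range(s - 1, s + ln + 1)  # keep events non-adjacent
        if any(0 <= i < L and deleted[i] for i in footprint):
            continue
        if any(i in splice_set for i in range(s, s + ln)):
            continue
        deleted[s:s + ln] = True
        del_events.append((s, s + ln))
    del_events.sort()

    ref_row = ref_seq
    sister_row = sister.tobytes().decode()
    t = target.copy()
    t_chars = np.array(list(t.tobytes().decode()))
    t_chars[deleted] = "-"
    target_row = "".join(t_chars)

    target_map = {seqname: target_row}  # reference is ungapped: columns == coords
    fasta = {"ref.chr1": ref_seq,
             "target.chr1": target_row.replace("-", ""),
             "sister.chr1": sister_row}
    truth = {
        "splice_nt_total": len(splice_nt),
        "splice_nt_positions": splice_nt,
        "planted_splice_errors": planted_splice_positions,
        "planted_indel_events": del_events,
        "aligned_bases": L,
    }
    return {"ref_row": ref_row, "target_row": target_row,
            "sister_row": sister_row, "fasta": fasta,
            "gff3": "\n".join(gff) + "\n", "target_map": target_map,
            "truth": truth}


def make_read_coverage_fixture(genome_length: int, fold: int = 8,
                               read_length: int = 100, jitter: int = 5,
                               seed: int = 0):
    """Near-uniform read tiling at a known fold coverage.

    Reads of ``read_length`` are tiled at spacing read_length/fold with a
    small seeded jitter, emulating an evenly represented library.  Returns
    (coverage array, total sequenced bases).
    """
    rng = np.random.default_rng(seed)
    step = read_length / fold
    starts = (np.arange(0, genome_length - read_length, step)
              + rng.integers(-jitter, jitter + 1,
                             size=len(np.arange(0, genome_length - read_length,
                                                step))))
    starts = np.clip(starts.astype(int), 0, genome_length - read_length)
    cov = np.zeros(genome_length + 1, dtype=np.int64)
    np.add.at(cov, starts, 1)
    np.add.at(cov, starts + read_length, -1)
    coverage = np.cumsum(cov[:-1])
    total = len(starts) * read_length
    return coverage, total


# ---------------------------------------------------------------------------
# GO DAG fixtures for site enrichment
# ---------------------------------------------------------------------------

def make_go_fixture(n_genes: int = 50, dag_spec: dict | None = None,
                    sites_per_gene: int = 100, ps_genes=None,
                    ps_sites_per_gene: int = 3, seed: int = 0):
    """Small GO DAG with annotated genes and positively selected sites.

    ``dag_spec`` maps term id -> list of is_a parents (default: a root with
    two branches of two leaves each).  Each gene is annotated to one leaf
    term; genes named in ``ps_genes`` carry ``ps_sites_per_gene`` positively
    selected sites, all others none.  Returns (obo_text, annotations,
    site_table, truth) where annotations maps gene -> set of direct terms
    and site_table maps gene -> (total sites, ps sites).
    """
    rng = np.random.default_rng(seed)
    if dag_spec is None:
        dag_spec = {
            "GO:0000001": [],
            "GO:0000002": ["GO:0000001"],
            "GO:0000003": ["GO:0000001"],
            "GO:0000004": ["GO:0000002"],
            "GO:0000005": ["GO:0000002"],
            "GO:0000006": ["GO:0000003"],
            "GO:0000007": ["GO:0000003"],
        }
    leaves = [t for t in dag_spec
              if not any(t in ps for ps in dag_spec.values())]
    genes = [f"gene{i}" for i in range(n_genes)]
    annotations = {g: {leaves[int(rng.integers(0, len(leaves)))]}
                   for g in genes}
    ps_genes = set(ps_genes or [])
    site_table = {g: (sites_per_gene,
                      ps_sites_per_gene if g in ps_genes else 0)
                  for g in genes}
    truth = {"leaves": leaves, "ps_genes": sorted(ps_genes)}
    return write_obo(dag_spec), annotations, site_table, truth


def write_obo(dag_spec: dict) -> str:
    """Render a term -> parents mapping as minimal OBO text."""
    lines = ["format-version: 1.2", "ontology: synthetic", ""]
    for term in sorted(dag_spec):
        lines.append("[Term]")
        lines.append(f"id: {term}")
        lines.append(f"name: {term.lower().replace(':', '_')}")
        for parent in dag_spec[term]:
            lines.append(f"is_a: {parent} ! parent")
        lines.append("")
    return "\n".join(lines)
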