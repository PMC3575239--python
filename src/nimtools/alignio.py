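"""Pairwise alignment blocks, inter-gap segments and GC-binned histograms.

The neutral indel model works on the lengths of inter-gap segments (IGSs):
maximal runs of alignment columns in which neither species is gapped.  This
module reads/writes two-row MAF blocks, reduces them to IGSs, assigns each
segment a local G+C bin (quantiles of window GC weighted by aligned bases,
so every bin holds roughly the same amount of aligned sequence) and builds
per-bin length histograms.

Coordinates are 0-based half-open throughout; 1-based conventions appear
only at GFF3 boundaries elsewhere in the package.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
from Bio import AlignIO, SeqIO
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

GAP = ord("-")

#: sequences whose names match this pattern are dropped from NIM input;
#: the neutral expectation is calibrated on autosomes only.
DEFAULT_EXCLUDE_PATTERN = r"chrZ|chrW|chrUn|random"


class MafParseError(ValueError):
    """Raised when a MAF block cannot be interpreted."""


@dataclass
class PairAlignmentBlock:
    """One gapped two-row alignment block with source coordinates.

    ``ref_text`` and ``qry_text`` are equal-length gapped strings.  A column
    gapped in both rows carries no information and is disallowed.
    """

    ref_name: str
    ref_start: int
    ref_size: int
    ref_strand: str
    qry_name: str
    qry_start: int
    qry_size: int
    qry_strand: str
    ref_text: str
    qry_text: str
    ref_src_size: int = 0
    qry_src_size: int = 0

    def __post_init__(self) -> None:
        if len(self.ref_text) != len(self.qry_text):
            raise ValueError("alignment rows differ in length")
        r = np.frombuffer(self.ref_text.encode("ascii"), dtype=np.uint8)
        q = np.frombuffer(self.qry_text.encode("ascii"), dtype=np.uint8)
        if int((r == GAP).sum()) != len(r) - self.ref_size:
            raise ValueError("ref_size inconsistent with gapped text")
        if int((q == GAP).sum()) != len(q) - self.qry_size:
            raise ValueError("qry_size inconsistent with gapped text")
        if bool(((r == GAP) & (q == GAP)).any()):
            raise ValueError("column gapped in both rows")
        if self.ref_src_size == 0:
            self.ref_src_size = self.ref_start + self.ref_size
        if self.qry_src_size == 0:
            self.qry_src_size = self.qry_start + self.qry_size

    def __len__(self) -> int:
        return len(self.ref_text)

    def _arrays(self) -> tuple[np.ndarray, np.ndarray]:
        return (
            np.frombuffer(self.ref_text.encode("ascii"), dtype=np.uint8),
            np.frombuffer(self.qry_text.encode("ascii"), dtype=np.uint8),
        )


@dataclass
class InterGapSegment:
    """A maximal ungapped run of aligned columns."""

    length: int
    gc_bin: int = 0
    boundary_truncated: bool = False
    ref_name: str = ""
    ref_interval: tuple[int, int] = (0, 0)


@dataclass
class IGSHistogram:
    """Counts of inter-gap segment lengths, stratified by GC bin.

    ``counts[b]`` is an integer array indexed by exact segment length
    (index 0 unused).  Segments in the sentinel bin (-1) are never stored.
    """

    counts: dict[int, np.ndarray] = field(default_factory=dict)
    n_bins: int = 1
    total_aligned: dict[int, int] = field(default_factory=dict)

    @property
    def max_length(self) -> int:
        return max((len(c) - 1 for c in self.counts.values()), default=0)

    def bin_counts(self, b: int) -> np.ndarray:
        return self.counts.get(b, np.zeros(1, dtype=np.int64))

    def total_segments(self, b: int) -> int:
        return int(self.bin_counts(b).sum())

    @classmethod
    def from_lengths(cls, lengths, b: int = 0) -> "IGSHistogram":
        """Histogram of raw integer lengths in a single bin (for fitting)."""
        arr = np.asarray(list(lengths), dtype=np.int64)
        if arr.size and arr.min() < 1:
            raise ValueError("segment lengths must be >= 1")
        counts = np.bincount(arr) if arr.size else np.zeros(1, dtype=np.int64)
        return cls(counts={b: counts.astype(np.int64)}, n_bins=b + 1,
                   total_aligned={b: int(arr.sum())})


def read_maf(path, n_rows: int = 2) -> list[PairAlignmentBlock]:
    """Read two-row MAF blocks; blocks with a different row count are skipped.

    Raises :class:`MafParseError` on malformed input.
    """
    blocks = []
    try:
        for msa in AlignIO.parse(str(path), "maf"):
            if len(msa) != n_rows:
                logger.warning("skipping MAF block with %d rows", len(msa))
                continue
            rows = []
            for rec in msa:
                ann = rec.annotations
                strand = "+" if ann.get("strand", 1) == 1 else "-"
                rows.append((rec.id, int(ann["start"]), int(ann["size"]),
                             strand, int(ann.get("srcSize", 0)), str(rec.seq)))
            (rn, rs, rz, rst, rss, rt), (qn, qs, qz, qst, qss, qt) = rows
            blocks.append(PairAlignmentBlock(rn, rs, rz, rst, qn, qs, qz, qst,
                                             rt, qt, rss, qss))
    except ValueError as exc:
        raise MafParseError(f"malformed MAF file {path}: {exc}") from exc
    return blocks


def read_maf_rows(path) -> list[list[tuple[str, str]]]:
    """Read MAF blocks of any row count as [(name, gapped_text), ...] lists."""
    out = []
    for msa in AlignIO.parse(str(path), "maf"):
        out.append([(rec.id, str(rec.seq)) for rec in msa])
    return out


def write_maf(blocks: list[PairAlignmentBlock], path) -> None:
    """Write blocks as MAF (two ``s`` lines per block)."""
    msas = []
    for b in blocks:
        recs = []
        for name, start, size, strand, src, text in (
            (b.ref_name, b.ref_start, b.ref_size, b.ref_strand,
             b.ref_src_size, b.ref_text),
            (b.qry_name, b.qry_start, b.qry_size, b.qry_strand,
             b.qry_src_size, b.qry_text),
        ):
            rec = SeqRecord(Seq(text), id=name, description="")
            rec.annotations.update(
                start=start, size=size, strand=1 if strand == "+" else -1,
                srcSize=src)
            recs.append(rec)
        msas.append(MultipleSeqAlignment(recs))
    with open(path, "w") as fh:
        AlignIO.write(msas, fh, "maf")


def extract_igs(block: PairAlignmentBlock,
                gc_assigner: "GcBinner | None" = None) -> list[InterGapSegment]:
    """Reduce a block to its inter-gap segments.

    A run of one or more consecutive gap columns — whichever row carries the
    gap — is a single delimiter.  Runs abutting a block edge are flagged
    ``boundary_truncated`` (their true length is censored by the block
    boundary rather than delimited by an indel).
    """
    n = len(block)
    if n == 0:
        return []
    r, q = block._arrays()
    aligned = (r != GAP) & (q != GAP)
    # run boundaries of the aligned mask
    padded = np.concatenate(([False], aligned, [False]))
    d = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    # reference offset (count of non-gap ref chars before each column)
    ref_off = np.concatenate(([0], np.cumsum(r != GAP)))
    segs = []
    for c0, c1 in zip(starts, ends):
        rs = block.ref_start + int(ref_off[c0])
        length = int(c1 - c0)
        mid = rs + length // 2
        gc_bin = gc_assigner.assign(block.ref_name, mid) if gc_assigner else 0
        segs.append(InterGapSegment(
            length=length,
            gc_bin=gc_bin,
            boundary_truncated=bool(c0 == 0 or c1 == n),
            ref_name=block.ref_name,
            ref_interval=(rs, rs + length),
        ))
    return segs


class GcBinner:
    """Assigns reference positions to GC-quantile bins.

    GC is measured in fixed non-overlapping windows of the reference genome
    (N bases excluded from both numerator and denominator; an all-N window
    gets the sentinel bin -1).  Bin edges are quantiles of window GC weighted
    by aligned bases per window, so bins are equally populated with aligned
    sequence.  A segment takes the bin of the window containing its
    reference midpoint.
    """

    UNBINNED = -1

    def __init__(self, window_gc: dict[str, np.ndarray],
                 window_size: int = 10_000, n_bins: int = 20):
        if n_bins < 1:
            raise ValueError("n_bins must be >= 1")
        self.window_gc = window_gc
        self.window_size = int(window_size)
        self.n_bins = int(n_bins)
        self.edges: np.ndarray | None = None

    # -- construction -----------------------------------------------------
    @classmethod
    def from_fasta(cls, fasta, window_size: int = 10_000,
                   n_bins: int = 20) -> "GcBinner":
        """Build from a FASTA path or a {name: sequence} mapping."""
        if isinstance(fasta, dict):
            seqs = {k: str(v) for k, v in fasta.items()}
        else:
            seqs = {rec.id: str(rec.seq)
                    for rec in SeqIO.parse(str(fasta), "fasta")}
        window_gc = {}
        for name, seq in seqs.items():
            b = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
            nw = max(1, -(-len(b) // window_size))
            gc = np.full(nw, np.nan)
            for w in range(nw):
                chunk = b[w * window_size:(w + 1) * window_size]
                valid = chunk != ord("N")
                nv = int(valid.sum())
                if nv:
                    g = int(((chunk == ord("G")) | (chunk == ord("C"))).sum())
                    gc[w] = g / nv
            window_gc[name] = gc
        return cls(window_gc, window_size, n_bins)

    # -- fitting -----------------------------------------------------------
    def fit(self, segments: list[InterGapSegment]) -> "GcBinner":
        """Split aligned bases equally across bins, assigning whole windows.

        Windows are ranked by GC (ties broken by sequence name and window
        index, deterministically) and cut where the cumulative aligned bases
        cross each quantile; each window's bin is decided by the midpoint of
        its own aligned mass.  Window GC is quantized (1/window_size steps),
        so value-level edges would lump tied windows together; window-level
        assignment keeps the imbalance to one window per boundary.
        """
        keys = sorted(self.window_gc)
        entries = []  # (gc, name, window index)
        for name in keys:
            for w, gc in enumerate(self.window_gc[name]):
                if not np.isnan(gc):
                    entries.append((float(gc), name, w))
        weights = {(name, w): 0.0 for _, name, w in entries}
        for seg in segments:
            mid = (seg.ref_interval[0] + seg.ref_interval[1]) // 2
            key = (seg.ref_name, mid // self.window_size)
            if key in weights:
                weights[key] += seg.length
        if not entries:
            self.edges = np.array([])
            self._window_bin = {}
            return self
        entries.sort()
        w_arr = np.array([weights[(n, w)] for _, n, w in entries])
        cw = np.cumsum(w_arr)
        total = cw[-1]
        if total <= 0:
            bins = np.zeros(len(entries), dtype=int)
        else:
            mid_mass = cw - w_arr / 2.0
            bins = np.minimum((mid_mass / (total / self.n_bins)).astype(int),
                              self.n_bins - 1)
        self._window_bin = {(n, w): int(b)
                            for (_, n, w), b in zip(entries, bins)}
        # representative edges (max GC in each bin) for reporting
        edges = []
        for b in range(self.n_bins - 1):
            in_bin = [gc for (gc, n, w), bb in zip(entries, bins) if bb == b]
            edges.append(max(in_bin) if in_bin
                         else (edges[-1] if edges else 0.0))
        self.edges = np.array(edges)
        return self

    def _window_gc_at(self, name: str, pos: int) -> float:
        gc = self.window_gc.get(name)
        if gc is None:
            return float("nan")
        w = pos // self.window_size
        if w < 0 or w >= len(gc):
            return float("nan")
        return float(gc[w])

    def assign(self, ref_name: str, pos: int) -> int:
        gc = self._window_gc_at(ref_name, pos)
        if np.isnan(gc):
            return self.UNBINNED
        if self.n_bins == 1:
            return 0
        wb = getattr(self, "_window_bin", None)
        if wb is not None:
            b = wb.get((ref_name, pos // self.window_size))
            if b is not None:
                return b
        if self.edges is None or len(self.edges) == 0:
            return 0
        return int(np.searchsorted(self.edges, gc, side="left"))

    def label(self, segments: list[InterGapSegment]) -> None:
        for seg in segments:
            mid = (seg.ref_interval[0] + seg.ref_interval[1]) // 2
            seg.gc_bin = self.assign(seg.ref_name, mid)


def assign_gc_bins(fasta, window_size: int = 10_000,
                   n_bins: int = 20) -> GcBinner:
    """Convenience wrapper: window-GC table from a genome, ready to fit."""
    return GcBinner.from_fasta(fasta, window_size=window_size, n_bins=n_bins)


def build_histogram(segments: list[InterGapSegment],
                    exclude_truncated: bool = True,
                    n_bins: int | None = None) -> IGSHistogram:
    """Per-bin histogram of IGS lengths.

    Block-edge (censored) segments are excluded by default: their observed
    lengths are lower bounds, which would distort the geometric fit.
    Sentinel-bin (-1) segments are always excluded.
    """
    by_bin: dict[int, list[int]] = {}
    aligned: dict[int, int] = {}
    for seg in segments:
        if seg.gc_bin < 0:
            continue
        if exclude_truncated and seg.boundary_truncated:
            continue
        by_bin.setdefault(seg.gc_bin, []).append(seg.length)
        aligned[seg.gc_bin] = aligned.get(seg.gc_bin, 0) + seg.length
    nb = n_bins if n_bins is not None else (max(by_bin) + 1 if by_bin else 1)
    counts = {b: np.bincount(np.asarray(ls, dtype=np.int64)).astype(np.int64)
              for b, ls in by_bin.items()}
    return IGSHistogram(counts=counts, n_bins=nb, total_aligned=aligned)


def filter_blocks(blocks: list[PairAlignmentBlock],
                  exclude_pattern: str = DEFAULT_EXCLUDE_PATTERN
                  ) -> list[PairAlignmentBlock]:
    """Drop blocks whose reference sequence name matches the pattern.

    Sex chromosomes and unplaced scaffolds violate the autosomal-rate
    assumption of the neutral indel model and are excluded by default.
    """
    pat = re.compile(exclude_pattern)
    return [b for b in blocks if not pat.search(b.ref_name)]


def histogram_to_table(hist: IGSHistogram):
    """Histogram as a DataFrame (columns: bin, length, count; zero rows
    omitted)."""
    import pandas as pd

    rows = []
    for b in sorted(hist.counts):
        counts = hist.counts[b]
        for length in np.flatnonzero(counts):
            rows.append((b, int(length), int(counts[length])))
    return pd.DataFrame(rows, columns=["bin", "length", "count"])


def segments_to_table(segments: list[InterGapSegment]):
    """Segments as a DataFrame (columns: bin, length, truncated, ref coords)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "gc_bin": [s.gc_bin for s in segments],
            "length": [s.length for s in segments],
            "boundary_truncated": [s.boundary_truncated for s in segments],
            "ref_name": [s.ref_name for s in segments],
            "ref_start": [s.ref_interval[0] for s in segments],
            "ref_end": [s.ref_interval[1] for s in segments],
        }
    )
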