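"""Stringent codon-alignment filtering ahead of positive-selection testing.

Branch-site tests are notoriously sensitive to alignment and base-call
error, so candidate codon alignments are filtered hard before any test is
run.  The cascade, in order: externally supplied column masks (from tools
such as SEG/GBLOCKS/GUIDANCE, consumed from file and never recomputed
here), removal of any codon column containing a gap, removal of codons
containing a base with phred quality <= 30 (inclusive), removal of
nucleotide columns inside any 15-bp window with more than 5 substitutions
between a designated species pair (a codon goes if any of its three
nucleotides goes), removal of codons within 7 codons of previously filtered
sequence (single pass: flank removals do not seed new flanks), and finally
a per-gene discard rule: drop the gene when fewer than 10% of its predicted
codons, or fewer than 100 codons, survive.

Every removal is recorded in an ordered ledger that can be replayed to
reproduce the final mask exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

KEPT = "kept"


@dataclass
class CodonAlignment:
    """Species-by-codon alignment with optional per-base phred qualities.

    ``nts`` is an (n_species, 3*n_codons) array of single characters; a
    gapped codon is three '-' characters.  ``quals`` aligns to ``nts``
    (negative value = quality unknown for that base).
    """

    species: list[str]
    nts: np.ndarray
    quals: np.ndarray | None = None
    predicted_codon_count: int = 0

    def __post_init__(self):
        self.nts = np.asarray(self.nts, dtype="U1")
        if self.nts.ndim != 2 or self.nts.shape[1] % 3 != 0:
            raise ValueError("nts must be (n_species, 3*n_codons)")
        if len(self.species) != self.nts.shape[0]:
            raise ValueError("species list does not match row count")
        if self.quals is not None:
            self.quals = np.asarray(self.quals)
            if self.quals.shape != self.nts.shape:
                raise ValueError("qualities not aligned to bases")
        if self.predicted_codon_count == 0:
            self.predicted_codon_count = self.n_codons

    @property
    def n_codons(self) -> int:
        return self.nts.shape[1] // 3

    def row(self, species: str) -> np.ndarray:
        return self.nts[self.species.index(species)]

    def subset(self, kept_codons: np.ndarray) -> "CodonAlignment":
        nt_idx = np.repeat(kept_codons * 3, 3) + np.tile([0, 1, 2],
                                                         len(kept_codons))
        return CodonAlignment(
            species=list(self.species),
            nts=self.nts[:, nt_idx],
            quals=None if self.quals is None else self.quals[:, nt_idx],
            predicted_codon_count=self.predicted_codon_count)


@dataclass
class FilterMask:
    """Per-codon-column removal state with an ordered rule ledger."""

    n_codons: int
    status: list[str] = field(default_factory=list)
    ledger: list[tuple[str, tuple[int, ...]]] = field(default_factory=list)

    def __post_init__(self):
        if not self.status:
            self.status = [KEPT] * self.n_codons

    def removed(self) -> set[int]:
        return {i for i, s in enumerate(self.status) if s != KEPT}

    def kept(self) -> np.ndarray:
        return np.array([i for i, s in enumerate(self.status) if s == KEPT],
                        dtype=np.int64)

    @property
    def n_kept(self) -> int:
        return sum(s == KEPT for s in self.status)

    def apply_rule(self, rule: str, columns) -> "FilterMask":
        """Remove columns under a rule name; removed columns never return."""
        new = tuple(sorted(c for c in set(columns)
                           if self.status[c] == KEPT))
        for c in new:
            self.status[c] = rule
        self.ledger.append((rule, new))
        return self

    def replay(self, n_codons: int | None = None) -> "FilterMask":
        """Rebuild a mask from the ledger alone."""
        out = FilterMask(n_codons or self.n_codons)
        for rule, cols in self.ledger:
            out.apply_rule(rule, cols)
        return out


# ---------------------------------------------------------------------------
# individual rules (each returns the set of codon columns it would remove,
# judged on the raw alignment unless an active mask is supplied)
# ---------------------------------------------------------------------------

def low_quality_codons(aln: CodonAlignment, threshold: int = 30) -> set[int]:
    """Codons containing a base with phred <= threshold (inclusive)."""
    if aln.quals is None:
        return set()
    bad = (aln.quals >= 0) & (aln.quals <= threshold) & (aln.nts != "-")
    bad_nt = bad.any(axis=0)
    return set(np.flatnonzero(bad_nt.reshape(-1, 3).any(axis=1)).tolist())


def gap_codons(aln: CodonAlignment) -> set[int]:
    """Codon columns where any species carries a gap (no gaps are allowed)."""
    g = (aln.nts == "-").any(axis=0)
    return set(np.flatnonzero(g.reshape(-1, 3).any(axis=1)).tolist())


def window_substitution_columns(aln: CodonAlignment, species_pair,
                                window_nt: int = 15, max_subs: int = 5,
                                mode: str = "sliding",
                                active_nt: np.ndarray | None = None
                                ) -> set[int]:
    """Codons hit by any 15-nt window with > max_subs pair substitutions.

    Runs of substitutions of that density between the two focal species are
    more likely sequencing or alignment error than signal.  Positions where
    either base is a gap or N never count as substitutions, nor do positions
    outside ``active_nt`` (a boolean per-nt mask of still-kept sequence).
    In 'sliding' mode windows start at every nucleotide (the stricter
    reading); 'tiled' mode uses non-overlapping windows.
    """
    a = aln.row(species_pair[0])
    b = aln.row(species_pair[1])
    valid = ~np.isin(a, ("-", "N")) & ~np.isin(b, ("-", "N"))
    mismatch = (a != b) & valid
    if active_nt is not None:
        mismatch = mismatch & active_nt
    n = len(mismatch)
    removed_nt = np.zeros(n, dtype=bool)
    starts = (range(0, max(n - window_nt + 1, 0))
              if mode == "sliding" else range(0, n, window_nt))
    cs = np.concatenate(([0], np.cumsum(mismatch)))
    for s in starts:
        e = min(s + window_nt, n)
        if cs[e] - cs[s] > max_subs:
            removed_nt[s:e] = True
    return set(np.flatnonzero(
        removed_nt.reshape(-1, 3).any(axis=1)).tolist())


def flank_columns(removed: set[int], n_codons: int,
                  flank_codons: int = 7) -> set[int]:
    """Codons within ``flank_codons`` of already-removed codons (single pass)."""
    out: set[int] = set()
    for c in removed:
        lo = max(0, c - flank_codons)
        hi = min(n_codons, c + flank_codons + 1)
        out.update(range(lo, hi))
    return out - removed


# -- spec-level wrappers returning FilterMask objects -----------------------

def mask_low_quality_codons(aln: CodonAlignment,
                            threshold: int = 30) -> FilterMask:
    return FilterMask(aln.n_codons).apply_rule(
        "quality", low_quality_codons(aln, threshold))


def remove_gap_columns(aln: CodonAlignment) -> FilterMask:
    return FilterMask(aln.n_codons).apply_rule("gap", gap_codons(aln))


def window_substitution_filter(aln: CodonAlignment, species_pair,
                               window_nt: int = 15, max_subs: int = 5,
                               mode: str = "sliding") -> FilterMask:
    return FilterMask(aln.n_codons).apply_rule(
        "window", window_substitution_columns(aln, species_pair, window_nt,
                                              max_subs, mode))


def flank_removal(mask: FilterMask, flank_codons: int = 7) -> FilterMask:
    return mask.apply_rule(
        "flank", flank_columns(mask.removed(), mask.n_codons, flank_codons))


def discard_gene(aln: CodonAlignment, mask: FilterMask,
                 min_codons: int = 100,
                 min_fraction: float = 0.10) -> tuple[bool, str]:
    """(keep, reason): drop the gene if too little alignment survives."""
    remaining = mask.n_kept
    if remaining < min_codons:
        return False, (f"remaining {remaining} codons < {min_codons} "
                       "(length rule)")
    if remaining < min_fraction * aln.predicted_codon_count:
        return False, (f"remaining {remaining} codons < "
                       f"{min_fraction:.0%} of predicted "
                       f"{aln.predicted_codon_count} (fraction rule)")
    return True, "kept"


def run_filter_cascade(aln: CodonAlignment, species_pair=None,
                       phred_min: int = 30, window_nt: int = 15,
                       max_subs: int = 5, flank: int = 7,
                       min_codons: int = 100, min_fraction: float = 0.10,
                       window_mode: str = "sliding",
                       external_masks: dict[str, set] | None = None):
    """Apply the full cascade; returns (filtered aln, mask, report).

    Order: external masks, gap removal, quality masking, window filter
    (counting substitutions only at still-kept positions, i.e. after the
    gap/quality stages), flank removal, discard decision.
    """
    if species_pair is None:
        species_pair = tuple(aln.species[:2])
    mask = FilterMask(aln.n_codons)
    for name, cols in (external_masks or {}).items():
        mask.apply_rule(f"external:{name}", cols)
    mask.apply_rule("gap", gap_codons(aln))
    mask.apply_rule("quality", low_quality_codons(aln, phred_min))
    active_nt = np.ones(3 * aln.n_codons, dtype=bool)
    for c in mask.removed():
        active_nt[3 * c:3 * c + 3] = False
    mask.apply_rule("window", window_substitution_columns(
        aln, species_pair, window_nt, max_subs, window_mode, active_nt))
    flank_removal(mask, flank)
    keep, reason = discard_gene(aln, mask, min_codons, min_fraction)
    report = {
        "per_rule": {rule: len(cols) for rule, cols in mask.ledger},
        "kept_codons": mask.n_kept,
        "predicted_codons": aln.predicted_codon_count,
        "decision": "keep" if keep else "discard",
        "reason": reason,
    }
    filtered = aln.subset(mask.kept())
    return filtered, mask, report


def read_external_mask(path_or_text) -> set[int]:
    """BED-like removal intervals (0-based half-open, codon units) -> columns."""
    try:
        with open(path_or_text) as fh:
            text = fh.read()
    except (OSError, ValueError):
        text = str(path_or_text)
    cols: set[int] = set()
    for line in text.splitlines():
        if not line.strip() or line.startswith(("#", "track")):
            continue
        parts = line.split("\t")
        start, end = int(parts[1]), int(parts[2])
        cols.update(range(start, end))
    return cols
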