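"""Neutral indel model: geometric fit per GC bin and constrained-sequence bounds.

Under neutral evolution, indels fall uniformly on the alignment, so
inter-gap segment (IGS) lengths are geometrically distributed.  The fit is a
weighted log-linear regression of observed counts O(l) against length l
over a short-length window assumed free of constraint; the slope gives the
per-base indel rate p and the mean neutral spacing K = 1/p.  Segments far
longer than the neutral expectation E(l) are indel-purified: their excess
count S and excess bases B beyond a threshold length l* yield bounds on the
amount of constrained sequence.  Each excess segment is assumed to contain
between K and 2K neutral bases (flanks on both sides of the functional
element), so

    lower = B - 2K*S        upper = B - K*S

clipped at zero.  Everything is stratified by GC bin, because indel rates
covary with local base composition, and aggregated over usable bins.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .alignio import (DEFAULT_EXCLUDE_PATTERN, GcBinner, IGSHistogram,
                      build_histogram, extract_igs, filter_blocks)


class FitError(ValueError):
    """The histogram cannot support a geometric fit (e.g. counts not decaying)."""


@dataclass
class NeutralFit:
    """Fitted geometric neutral model for one GC bin."""

    bin: int
    p_hat: float
    scale: float          # expected count at length 0 on the fitted line
    fit_window: tuple[int, int]
    r_squared: float
    n_segments: int

    @property
    def K(self) -> float:
        """Mean number of bases between indels in neutral sequence (1/p)."""
        return 1.0 / self.p_hat

    def expected(self, lengths) -> np.ndarray:
        """Neutral expectation E(l) = scale * (1-p)^l."""
        l = np.asarray(lengths, dtype=float)
        return self.scale * (1.0 - self.p_hat) ** l


@dataclass
class ConstraintEstimate:
    """Excess-segment statistics and constrained-sequence bounds."""

    bin: int
    l_star: int
    S_excess: float       # excess count of indel-purified segments
    B_excess: float       # bases contained in the excess segments
    lower_bound: float
    upper_bound: float

    def __post_init__(self):
        if not (0 <= self.lower_bound <= self.upper_bound <= max(self.B_excess, 0) + 1e-9):
            raise ValueError("bound ordering violated")


def fit_neutral_geometric(histogram: IGSHistogram, bin: int = 0,
                          fit_window: tuple[int, int] = (2, 120)
                          ) -> NeutralFit:
    """Weighted least-squares fit of ln O(l) ~ l over the fit window.

    Weights are the counts themselves (Poisson log-counts have variance
    ~1/count).  Zero-count lengths inside the window are dropped from the
    regression (log undefined) but the fitted line is still evaluated there.
    The slope b maps to p = 1 - e^b; a non-negative slope means the counts
    do not decay and the bin is unusable.
    """
    lo, hi = fit_window
    if lo >= hi:
        raise ValueError("fit window must satisfy lo < hi")
    counts = histogram.bin_counts(bin)
    hi_eff = min(hi, len(counts) - 1)
    lengths = np.arange(lo, hi_eff + 1)
    if hi_eff < lo:
        raise FitError(f"bin {bin}: no counts inside fit window")
    obs = counts[lo:hi_eff + 1].astype(float)
    nz = obs > 0
    if np.count_nonzero(nz) < 2 or len(np.unique(lengths[nz])) < 2:
        raise FitError(f"bin {bin}: fewer than 2 distinct lengths in window")
    x = lengths[nz].astype(float)
    y = np.log(obs[nz])
    w = np.sqrt(obs[nz])  # np.polyfit weights multiply residuals
    b, a = np.polyfit(x, y, 1, w=w)
    if b >= -1e-12:
        raise FitError(f"bin {bin}: counts do not decay with length "
                       f"(slope {b:.4g} >= 0)")
    yhat = a + b * x
    ybar = np.average(y, weights=obs[nz])
    ss_res = float(np.sum(obs[nz] * (y - yhat) ** 2))
    ss_tot = float(np.sum(obs[nz] * (y - ybar) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return NeutralFit(bin=bin, p_hat=1.0 - math.exp(b), scale=math.exp(a),
                      fit_window=(lo, hi), r_squared=r2,
                      n_segments=int(obs.sum()))


def ml_geometric_p(lengths) -> float:
    """Closed-form maximum-likelihood p for geometric lengths on {1, 2, ...}.

    Independent of the regression path; used as a cross-check.
    """
    arr = np.asarray(list(lengths), dtype=float)
    return float(len(arr) / arr.sum())


def default_l_star(histogram: IGSHistogram, fit: NeutralFit,
                   tail_prob: float = 0.01) -> int | None:
    """Smallest length with O(l) > E(l) whose geometric tail probability
    under the fit is below ``tail_prob``; always beyond the fit window."""
    q = 1.0 - fit.p_hat
    l_tail = math.ceil(math.log(tail_prob) / math.log(q))
    lo = max(l_tail, fit.fit_window[1] + 1)
    counts = histogram.bin_counts(fit.bin)
    if lo >= len(counts):
        return None
    lengths = np.arange(lo, len(counts))
    obs = counts[lo:].astype(float)
    exp = fit.expected(lengths)
    over = np.flatnonzero(obs > exp)
    if over.size == 0:
        return None
    return int(lengths[over[0]])


def _geometric_tail_sums(scale: float, p: float, m: int) -> tuple[float, float]:
    """Closed-form sums of E(l) and l*E(l) for l >= m, E(l) = scale*q^l."""
    q = 1.0 - p
    count = scale * q ** m / (1.0 - q)
    bases = scale * q ** m * (m - m * q + q) / (1.0 - q) ** 2
    return count, bases


def estimate_constrained(histogram: IGSHistogram, fit: NeutralFit,
                         l_star: int | None = None) -> ConstraintEstimate:
    """Excess of long segments over the neutral expectation, with K/2K bounds.

    For l >= l*, the departure D(l) = O(l) - E(l) is accumulated (signed, so
    sampling noise in the neutral tail cancels rather than piling up):
    S = sum D(l), B = sum l*D(l), with the expectation tail taken in closed
    form.  Bounds: lower = B - 2K*S, upper = B - K*S, clipped at zero.
    """
    if l_star is None:
        l_star = default_l_star(histogram, fit)
        if l_star is None:
            return ConstraintEstimate(fit.bin, 0, 0.0, 0.0, 0.0, 0.0)
    if l_star <= fit.fit_window[1]:
        raise ValueError("l_star must lie beyond the fit window")
    counts = histogram.bin_counts(fit.bin)
    if l_star < len(counts):
        lengths = np.arange(l_star, len(counts))
        obs = counts[l_star:].astype(float)
        o_count = float(obs.sum())
        o_bases = float((lengths * obs).sum())
    else:
        o_count = o_bases = 0.0
    e_count, e_bases = _geometric_tail_sums(fit.scale, fit.p_hat, l_star)
    S = max(0.0, o_count - e_count)
    B = max(0.0, o_bases - e_bases)
    K = fit.K
    lower = max(0.0, B - 2.0 * K * S)
    upper = max(0.0, B - K * S)
    if lower > upper:  # only possible through clipping pathologies
        lower = upper
    return ConstraintEstimate(fit.bin, int(l_star), S, B,
                              min(lower, B), min(upper, B))


@dataclass
class NimResult:
    """Full per-bin and aggregate output of a neutral indel model run."""

    per_bin: pd.DataFrame
    lower_bound: float
    upper_bound: float
    aligned_bases: int
    fits: dict[int, NeutralFit] = field(default_factory=dict)
    estimates: dict[int, ConstraintEstimate] = field(default_factory=dict)
    histogram: IGSHistogram | None = None

    def to_json(self) -> str:
        payload = {
            "lower_bound": self.lower_bound,
            "upper_bound": self.upper_bound,
            "aligned_bases": self.aligned_bases,
            "per_bin": self.per_bin.to_dict(orient="records"),
        }
        return json.dumps(payload, indent=2, sort_keys=True)


def run_nim(blocks, genome, n_bins: int = 20, window_size: int = 10_000,
            fit_window: tuple[int, int] = (2, 120), l_star: int | None = None,
            min_segments: int = 1000,
            exclude_pattern: str = DEFAULT_EXCLUDE_PATTERN) -> NimResult:
    """Run the full neutral indel model on pairwise alignment blocks.

    ``genome`` is the reference FASTA (path or {name: seq} mapping) used for
    GC binning.  Bins whose fit window holds fewer than ``min_segments``
    segments, or whose counts do not decay, are flagged unusable and
    excluded from the aggregate.  Returns per-bin table plus aggregate
    lower/upper constrained-sequence bounds (sums over usable bins).
    """
    blocks = filter_blocks(list(blocks), exclude_pattern)
    segments = []
    for b in blocks:
        segments.extend(extract_igs(b))
    cols = ["gc_bin", "gc_lo", "gc_hi", "aligned_bases", "n_segments",
            "p_hat", "K", "l_star", "S_excess", "B_excess",
            "lower_bound", "upper_bound", "usable", "note"]
    if not segments:
        return NimResult(pd.DataFrame(columns=cols), 0.0, 0.0, 0)

    binner = GcBinner.from_fasta(genome, window_size=window_size,
                                 n_bins=n_bins)
    binner.fit(segments)
    binner.label(segments)
    hist = build_histogram(segments, exclude_truncated=True, n_bins=n_bins)

    edges = np.concatenate(([0.0], binner.edges
                            if binner.edges is not None and len(binner.edges)
                            else np.array([]), [1.0]))
    rows, fits, ests = [], {}, {}
    lower = upper = 0.0
    for b in range(n_bins):
        aligned = hist.total_aligned.get(b, 0)
        n_seg = hist.total_segments(b)
        row = {"gc_bin": b,
               "gc_lo": float(edges[min(b, len(edges) - 2)]),
               "gc_hi": float(edges[min(b + 1, len(edges) - 1)]),
               "aligned_bases": aligned, "n_segments": n_seg,
               "p_hat": np.nan, "K": np.nan, "l_star": 0,
               "S_excess": 0.0, "B_excess": 0.0,
               "lower_bound": 0.0, "upper_bound": 0.0,
               "usable": False, "note": ""}
        try:
            fit = fit_neutral_geometric(hist, b, fit_window)
        except FitError as exc:
            row["note"] = str(exc)
            rows.append(row)
            continue
        fits[b] = fit
        row.update(p_hat=fit.p_hat, K=fit.K)
        if fit.n_segments < min_segments:
            row["note"] = "low confidence: too few segments in fit window"
            rows.append(row)
            continue
        est = estimate_constrained(hist, fit, l_star)
        ests[b] = est
        row.update(l_star=est.l_star, S_excess=est.S_excess,
                   B_excess=est.B_excess, lower_bound=est.lower_bound,
                   upper_bound=est.upper_bound, usable=True)
        lower += est.lower_bound
        upper += est.upper_bound
        rows.append(row)
    per_bin = pd.DataFrame(rows, columns=cols)
    aligned_total = int(per_bin["aligned_bases"].sum())
    return NimResult(per_bin, lower, upper, aligned_total, fits, ests, hist)


def plot_bin(result: NimResult, b: int, ax=None, max_length: int | None = None):
    """Observed IGS histogram against the neutral expectation for one bin.

    The area between the observed tail and the fitted line beyond l* is the
    indel-purified sequence the model reports.
    """
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    counts = result.histogram.bin_counts(b) if result.histogram else np.zeros(1)
    lengths = np.arange(1, len(counts))
    ax.semilogy(lengths, np.maximum(counts[1:], 0.1), ".", ms=2,
                label="observed")
    fit = result.fits.get(b)
    if fit is not None:
        ax.semilogy(lengths, np.maximum(fit.expected(lengths), 1e-2),
                    "-", label=f"neutral fit (K={fit.K:.0f})")
    est = result.estimates.get(b)
    if est is not None:
        ax.axvline(est.l_star, ls=":", color="grey", label="l*")
    if max_length:
        ax.set_xlim(0, max_length)
    ax.set_xlabel("inter-gap segment length (bp)")
    ax.set_ylabel("count")
    ax.legend(frameon=False)
    return ax
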