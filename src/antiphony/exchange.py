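"""Cross-correlation analysis of paired calling point processes.

The focal bird's call onsets define time zero; partner onsets are binned at
their lag relative to each focal call (±2 s in 100 bins by default).  Partner
calls within half a second after a focal call are *answers*, those within half
a second before are *answered* calls, and the directionality index

    (n_answers − n_answered) / (n_answers + n_answered)

summarises the asymmetry of the exchange: 0 for a symmetric exchange, positive
when the partner answers more than the focal bird.  Significance of correlogram
structure is assessed against Poisson limits computed from the baseline flanks
(lags in [−4, −2) and (2, 4] s), where calling is assumed uncorrelated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

__all__ = [
    "Correlogram",
    "ExchangeSummary",
    "cross_correlogram",
    "count_answers",
    "directionality_index",
    "poisson_limits",
    "detect_antiphony",
    "overlap_rate",
    "summarize_exchange",
]

ANSWER_WINDOW_S = 0.5


@dataclass
class Correlogram:
    """Lag histogram of partner onsets around each focal call.

    ``counts[i]`` is the number of (focal, partner) onset pairs whose lag
    ``partner − focal`` falls in ``[bin_edges[i], bin_edges[i+1])``.
    ``baseline_counts`` holds the same-width bins over the flanking lags
    [−2·half_window, −half_window) and (half_window, 2·half_window], used as
    the null calling rate.
    """

    bin_edges: np.ndarray
    counts: np.ndarray
    n_focal: int
    baseline_counts: np.ndarray

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])

    @property
    def density(self) -> np.ndarray:
        """Counts per focal call (NaN when there are no focal calls)."""
        if self.n_focal == 0:
            return np.full_like(self.counts, np.nan, dtype=float)
        return self.counts / self.n_focal

    @property
    def baseline_lambda(self) -> float:
        """Mean baseline count per bin (the Poisson null rate)."""
        return float(np.mean(self.baseline_counts))


@dataclass
class ExchangeSummary:
    """Answer/answered bookkeeping for one pair-day (focal = female)."""

    n_focal: int
    n_partner: int
    n_answers: int
    n_answered: int
    directionality: float  # in [-1, 1]; NaN when undefined
    overlap_rate: float = float("nan")
    undefined: bool = False

    @property
    def directionality_display(self) -> float:
        """Index on the ×100 reporting scale."""
        return self.directionality * 100.0

    @property
    def answer_proportion_partner(self) -> float:
        """Partner's answers as a share of the partner's own calls."""
        return self.n_answers / self.n_partner if self.n_partner else float("nan")

    @property
    def answer_proportion_focal(self) -> float:
        """Focal bird's answers (= partner calls answered) over focal calls."""
        return self.n_answered / self.n_focal if self.n_focal else float("nan")


def _as_sorted(x) -> np.ndarray:
    a = np.asarray(x, dtype=float)
    if a.ndim != 1:
        raise ValueError("onset arrays must be one-dimensional")
    if np.any(np.diff(a) < 0):
        raise ValueError("onsets must be sorted ascending")
    return a


def cross_correlogram(
    focal_onsets,
    partner_onsets,
    half_window_s: float = 2.0,
    n_bins: int = 100,
) -> Correlogram:
    """Bin partner onsets by lag relative to every focal onset.

    Bins are half-open ``[left, right)``; a lag of exactly ``+half_window_s``
    is excluded and ``−half_window_s`` included.  The baseline flanks cover
    ``[−2w, −w)`` and ``(w, 2w]`` at the same bin width.
    """
    focal = _as_sorted(focal_onsets)
    partner = _as_sorted(partner_onsets)
    # edges rounded like the lags, so an exact-width lag hits its edge
    edges = np.round(np.linspace(-half_window_s, half_window_s, n_bins + 1), 9)
    width = 2.0 * half_window_s / n_bins
    n_flank = int(round(half_window_s / width))

    if focal.size == 0 or partner.size == 0:
        return Correlogram(edges, np.zeros(n_bins, dtype=int), int(focal.size),
                           np.zeros(2 * n_flank, dtype=int))

    # Collect all lags within ±2w via sorted search, then histogram once.
    lo = np.searchsorted(partner, focal - 2.0 * half_window_s, side="left")
    hi = np.searchsorted(partner, focal + 2.0 * half_window_s, side="right")
    lags = np.concatenate(
        [partner[a:b] - t for t, a, b in zip(focal, lo, hi)]
    ) if focal.size else np.empty(0)
    # snap float-cancellation noise so lags like 10.2 − 10.0 hit their bin edge
    lags = np.round(lags, 9)

    main = lags[(lags >= -half_window_s) & (lags < half_window_s)]
    counts, _ = np.histogram(main, bins=edges)

    left = lags[(lags >= -2.0 * half_window_s) & (lags < -half_window_s)]
    right = lags[(lags > half_window_s) & (lags <= 2.0 * half_window_s)]
    lc, _ = np.histogram(left, bins=np.round(
        np.linspace(-2 * half_window_s, -half_window_s, n_flank + 1), 9))
    rc, _ = np.histogram(right, bins=np.round(
        np.linspace(half_window_s, 2 * half_window_s, n_flank + 1), 9))
    return Correlogram(edges, counts, int(focal.size), np.concatenate([lc, rc]))


def count_answers(
    focal_onsets,
    partner_onsets,
    window_s: float = ANSWER_WINDOW_S,
    dedupe: bool = True,
) -> tuple[int, int]:
    """Count partner answers and answered partner calls.

    Returns ``(n_answers, n_answered)`` where an *answer* is a partner onset
    within ``(0, window_s]`` after a focal onset and an *answered* call is a
    partner onset within ``[−window_s, 0]`` before one (a zero lag counts as
    answered).  With ``dedupe=True`` (default) each partner call is assigned
    to its nearest focal call only, so every partner call contributes at most
    once; ``dedupe=False`` counts all (focal, partner) pairs within the
    window, the literal reading of the definition.
    """
    focal = _as_sorted(focal_onsets)
    partner = _as_sorted(partner_onsets)
    if focal.size == 0 or partner.size == 0:
        return 0, 0

    if not dedupe:
        n_ans = n_ansd = 0
        for t in focal:
            n_ans += int(np.searchsorted(partner, t + window_s, side="right")
                         - np.searchsorted(partner, t, side="right"))
            n_ansd += int(np.searchsorted(partner, t, side="right")
                          - np.searchsorted(partner, t - window_s, side="left"))
        return n_ans, n_ansd

    idx = np.searchsorted(focal, partner)
    d_prev = np.where(idx > 0, partner - focal[np.clip(idx - 1, 0, None)], np.inf)
    d_next = np.where(idx < focal.size, focal[np.clip(idx, None, focal.size - 1)] - partner, np.inf)
    # nearest focal call; a tie (equidistant) goes to the preceding one, which
    # classifies the partner call as an answer
    use_prev = d_prev <= d_next
    lag = np.where(use_prev, d_prev, -d_next)  # partner − focal
    n_answers = int(np.sum((lag > 0) & (lag <= window_s)))
    n_answered = int(np.sum((lag <= 0) & (lag >= -window_s)))
    return n_answers, n_answered


def directionality_index(n_answers: int, n_answered: int) -> float:
    """(answers − answered) / (answers + answered); NaN when both are zero.

    Zero for a symmetric exchange; +1 when the partner only answers, −1 when
    the partner is only answered.  The undefined 0/0 case is returned as NaN
    (missing), never as 0, so that silent pair-days are not read as symmetric.
    """
    total = n_answers + n_answered
    if total == 0:
        return float("nan")
    if n_answers < 0 or n_answered < 0:
        raise ValueError("counts must be non-negative")
    return (n_answers - n_answered) / total


def poisson_limits(
    baseline_counts,
    alpha: float = 0.05,
) -> tuple[int, int, float]:
    """Per-bin Poisson confidence limits from the baseline flanks.

    λ is the mean baseline count per bin; the upper limit is the smallest
    integer U with P(X ≤ U) ≥ 1 − α/2 and the lower limit the α/2 quantile,
    so a bin count outside [lower, upper] is significant at level α under the
    homogeneous-baseline null.  Returns ``(lower, upper, lam)``.
    """
    baseline = np.asarray(baseline_counts, dtype=float)
    if baseline.size == 0:
        raise ValueError("baseline flanks are empty; cannot form Poisson limits")
    lam = float(baseline.mean())
    if lam <= 0:
        warnings.warn("baseline rate is zero; any nonzero bin is significant",
                      stacklevel=2)
        return 0, 0, 0.0
    lower = int(sps.poisson.ppf(alpha / 2.0, lam))
    upper = int(sps.poisson.ppf(1.0 - alpha / 2.0, lam))
    return lower, upper, lam


@dataclass
class AntiphonyResult:
    is_antiphonal: bool
    peak_latency_s: float  # NaN when not antiphonal
    significant_mask: np.ndarray = field(repr=False)
    lower: int = 0
    upper: int = 0
    baseline_lambda: float = 0.0


def detect_antiphony(
    correlogram: Correlogram,
    alpha: float = 0.05,
    answer_window_s: float = ANSWER_WINDOW_S,
) -> AntiphonyResult:
    """Flag a coordinated answer peak in the (0, answer_window] lag range.

    The pair-day is antiphonal when at least one bin whose center lies in
    (0, answer_window] exceeds the upper Poisson limit; the peak latency is
    the center of the maximal such bin.
    """
    lower, upper, lam = poisson_limits(correlogram.baseline_counts, alpha=alpha)
    mask = (correlogram.counts > upper) | (correlogram.counts < lower)
    centers = correlogram.bin_centers
    window = (centers > 0) & (centers <= answer_window_s)
    sig_in_window = mask & window & (correlogram.counts > upper)
    if not sig_in_window.any():
        return AntiphonyResult(False, float("nan"), mask, lower, upper, lam)
    wc = np.where(window)[0]
    peak = wc[np.argmax(correlogram.counts[wc])]
    return AntiphonyResult(True, float(centers[peak]), mask, lower, upper, lam)


def overlap_rate(focal_onsets, focal_durations, partner_onsets, partner_durations) -> float:
    """Proportion of focal calls whose interval intersects any partner call.

    Intervals are half-open [onset, onset+duration).  Missing durations are an
    error: overlap is undefined on onsets alone.
    """
    f_on = np.asarray(focal_onsets, dtype=float)
    p_on = np.asarray(partner_onsets, dtype=float)
    f_dur = np.asarray(focal_durations, dtype=float)
    p_dur = np.asarray(partner_durations, dtype=float)
    if f_on.size != f_dur.size or p_on.size != p_dur.size:
        raise ValueError("onsets and durations must have equal length")
    if f_on.size and (not np.all(np.isfinite(f_dur)) or np.any(f_dur < 0)):
        raise ValueError("focal durations missing or negative; overlap is "
                         "undefined in onset-only mode")
    if p_on.size and (not np.all(np.isfinite(p_dur)) or np.any(p_dur < 0)):
        raise ValueError("partner durations missing or negative; overlap is "
                         "undefined in onset-only mode")
    if f_on.size == 0:
        return float("nan")
    if p_on.size == 0:
        return 0.0
    order = np.argsort(p_on)
    s = p_on[order]
    e = (p_on + p_dur)[order]
    # prefix max of interval ends ordered by start: focal [a, b) overlaps some
    # partner interval iff among partners starting before b, some end exceeds a
    emax = np.maximum.accumulate(e)
    idx = np.searchsorted(s, f_on + f_dur, side="left")  # starts strictly < b
    hit = (idx > 0) & (emax[np.clip(idx - 1, 0, None)] > f_on)
    return float(np.mean(hit))


def summarize_exchange(
    focal_onsets,
    partner_onsets,
    focal_durations=None,
    partner_durations=None,
    window_s: float = ANSWER_WINDOW_S,
    dedupe: bool = True,
) -> ExchangeSummary:
    """Answer counts, directionality and (if durations given) overlap rate."""
    focal = _as_sorted(focal_onsets)
    partner = _as_sorted(partner_onsets)
    n_ans, n_ansd = count_answers(focal, partner, window_s=window_s, dedupe=dedupe)
    d = directionality_index(n_ans, n_ansd)
    ov = float("nan")
    if focal_durations is not None and partner_durations is not None:
        ov = overlap_rate(focal, focal_durations, partner, partner_durations)
    return ExchangeSummary(
        n_focal=int(focal.size), n_partner=int(partner.size),
        n_answers=n_ans, n_answered=n_ansd, directionality=d,
        overlap_rate=ov, undefined=bool(np.isnan(d)),
    )
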