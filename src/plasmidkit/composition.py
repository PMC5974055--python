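"""GC statistics and compositional segmentation.

PL6-family plasmids have a characteristic base-composition architecture:
a high-GC (~55%) forward gene block, an AT-rich (~41–43% GC) central
region and a reverse gene block near the plasmid average.  This module
computes exact GC percentages, circular sliding-window GC series, and a
cumulative GC-excess ("GC profile") segmentation that recovers the block
boundaries without any gene annotation.

The segmentation walks the mean-detrended cumulative GC-excess curve

    c(i) = sum_{j<=i} (+1 if base j is G/C else -1) - i * (2*f_GC - 1)

and recursively splits at the position of maximum deviation from the
chord joining the current segment's endpoints, until the deviation drops
below a permutation-calibrated threshold or ``max_segments`` is reached.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .seqio import CircularSequence, SequenceError, interval_length, subsequence


@dataclass
class GCProfile:
    """Windowed GC series, cumulative GC-excess curve and segmentation."""

    window_gc: list[tuple[int, float]]
    cumulative: np.ndarray
    breakpoints: list[int]
    segments: list[tuple[int, int, float]]


def region_gc(seq: CircularSequence, start: int = 1, end: int | None = None) -> float:
    """Exact GC percent of the inclusive interval ``start..end`` (wraps)."""
    if end is None:
        end = seq.length
    s = subsequence(seq, start, end, "+")
    gc = s.count("G") + s.count("C")
    return 100.0 * gc / len(s)


def window_gc(
    seq: CircularSequence, window: int = 200, step: int = 50
) -> list[tuple[int, float]]:
    """GC fraction in circular sliding windows.

    Windows are centered every ``step`` nt starting at position 1 and wrap
    through the origin, so the series has ``ceil(length/step)`` points.
    """
    if window < 10:
        raise SequenceError("window must be >= 10 nt")
    if window > seq.length:
        raise SequenceError(
            f"window {window} exceeds sequence length {seq.length}"
        )
    if step < 1:
        raise SequenceError("step must be >= 1")
    is_gc = np.frombuffer(seq.residues.encode(), dtype=np.uint8)
    is_gc = (is_gc == ord("G")) | (is_gc == ord("C"))
    # circular: prefix sums over a doubled indicator
    doubled = np.concatenate([is_gc, is_gc])
    csum = np.concatenate([[0], np.cumsum(doubled)])
    half = window // 2
    out = []
    for center in range(1, seq.length + 1, step):
        lo = center - half  # may be <= 0; doubled array absorbs the wrap
        start0 = (lo - 1) % seq.length  # 0-based into doubled
        out.append(
            (center, float(csum[start0 + window] - csum[start0]) / window)
        )
    return out


def cumulative_gc_excess(seq: CircularSequence) -> np.ndarray:
    """Mean-detrended cumulative GC excess, one value per nt (1-based c[i-1])."""
    arr = np.frombuffer(seq.residues.encode(), dtype=np.uint8)
    excess = np.where((arr == ord("G")) | (arr == ord("C")), 1.0, -1.0)
    c = np.cumsum(excess)
    trend = c[-1] / seq.length * np.arange(1, seq.length + 1)
    return c - trend


def _max_chord_deviation(c: np.ndarray, lo: int, hi: int) -> tuple[int, float]:
    """Index and value of max |c - chord| strictly inside [lo, hi] (0-based)."""
    if hi - lo < 2:
        return lo, 0.0
    x = np.arange(lo, hi + 1)
    chord = c[lo] + (c[hi] - c[lo]) * (x - lo) / (hi - lo)
    dev = np.abs(c[lo : hi + 1] - chord)
    dev[0] = dev[-1] = 0.0
    k = int(np.argmax(dev))
    return lo + k, float(dev[k])


def _changepoint_lr(
    c: np.ndarray, lo: int, hi: int, margin: int = 10
) -> tuple[int, float]:
    """ML slope changepoint and its likelihood-ratio gain.

    The per-base GC-excess increments are i.i.d. around a segment drift,
    so the cumulative curve is a random walk with piecewise drift; the
    profile likelihood of a drift change at k reduces to maximizing

        G(k) = (c[k]-c[lo])^2/(k-lo) + (c[hi]-c[k])^2/(hi-k)
               - (c[hi]-c[lo])^2/(hi-lo).

    G is invariant under Brownian rescaling, so one permutation-
    calibrated threshold applies to intervals of any length.  Returns
    (argmax k, max G).
    """
    if hi - lo < 2 * margin + 2:
        return lo, 0.0
    ks = np.arange(lo + margin, hi - margin + 1)
    left = (c[ks] - c[lo]) ** 2 / (ks - lo)
    right = (c[hi] - c[ks]) ** 2 / (hi - ks)
    base = (c[hi] - c[lo]) ** 2 / (hi - lo)
    g = left + right - base
    j = int(np.argmax(g))
    return int(ks[j]), float(g[j])


def _lsq_changepoint(c: np.ndarray, lo: int, hi: int, margin: int = 20) -> int:
    """Two-line least-squares changepoint of c over [lo, hi] (0-based).

    The argmax of the chord deviation wanders with random-walk noise;
    fitting two independent regression lines and minimizing total RSS
    uses every point and localizes slope changes much more precisely.
    """
    n = hi - lo + 1
    if n < 2 * margin + 3:
        return _max_chord_deviation(c, lo, hi)[0]
    y = c[lo : hi + 1].astype(float)
    x = np.arange(n, dtype=float)

    def prefix(v):
        return np.concatenate([[0.0], np.cumsum(v)])

    Sy, Sx = prefix(y), prefix(x)
    Syy, Sxx, Sxy = prefix(y * y), prefix(x * x), prefix(x * y)

    def rss(a, b):  # vectorized over arrays of equal shape, [a, b) windows
        m = b - a
        sy = Sy[b] - Sy[a]
        sx = Sx[b] - Sx[a]
        syy = Syy[b] - Syy[a]
        sxx = Sxx[b] - Sxx[a]
        sxy = Sxy[b] - Sxy[a]
        sxx_c = sxx - sx * sx / m
        sxy_c = sxy - sx * sy / m
        syy_c = syy - sy * sy / m
        beta = np.where(sxx_c > 0, sxy_c / np.maximum(sxx_c, 1e-12), 0.0)
        return syy_c - beta * sxy_c

    ks = np.arange(margin, n - margin)
    total = rss(np.zeros_like(ks), ks) + rss(ks, np.full_like(ks, n))
    return lo + int(ks[np.argmin(total)])


def calibrate_deviation_threshold(
    seq: CircularSequence,
    n_permutations: int = 100,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Permutation threshold for the max chord deviation.

    Shuffles the residues ``n_permutations`` times and returns a
    conservative upper quantile of the null maximum deviation: the
    k-th order statistic with k the smallest integer such that
    ``(m + 1 - k) / (m + 1) <= alpha``, plus two more ranks as a
    finite-sample margin.  A fresh draw from the null then exceeds the
    threshold with probability safely below ``alpha``, so segmentation
    of a compositionally homogeneous sequence reports a breakpoint in
    fewer than ``alpha`` of runs.
    """
    rng = np.random.default_rng(seed)
    arr = np.frombuffer(seq.residues.encode(), dtype=np.uint8).copy()
    m = n_permutations
    maxima = np.empty(m)
    n = len(arr)
    for i in range(m):
        rng.shuffle(arr)
        excess = np.where((arr == ord("G")) | (arr == ord("C")), 1.0, -1.0)
        c = np.cumsum(excess)
        c -= c[-1] / n * np.arange(1, n + 1)
        _, d = _max_chord_deviation(c, 0, n - 1)
        maxima[i] = d
    maxima.sort()
    k = int(np.ceil((1 - alpha) * (m + 1))) + 2
    return float(maxima[min(k, m) - 1])


def gc_profile_segment(
    seq: CircularSequence,
    max_segments: int = 6,
    threshold: float | None = None,
    window: int = 200,
    step: int = 50,
    n_permutations: int = 100,
    seed: int = 0,
) -> GCProfile:
    """Segment a plasmid by recursive chord-deviation splitting.

    ``threshold`` defaults to the permutation-calibrated 95th percentile
    of the null maximum deviation (see
    :func:`calibrate_deviation_threshold`).  Breakpoints are 1-based
    positions; segments tile 1..length without overlap and carry their
    mean GC%.
    """
    if seq.length < 1000:
        raise SequenceError("segmentation requires length >= 1000 nt")
    c = cumulative_gc_excess(seq)
    if threshold is None:
        threshold = calibrate_deviation_threshold(
            seq, n_permutations=n_permutations, seed=seed
        )

    breakpoints: list[int] = []
    intervals = [(0, seq.length - 1)]
    while intervals and len(breakpoints) < max_segments - 1:
        # split the interval with the globally largest deviation first
        best = None
        for lo, hi in intervals:
            _k, d = _max_chord_deviation(c, lo, hi)
            # the null maximum deviation scales like a Brownian bridge,
            # ~sqrt(n): length-adjust the full-sequence threshold
            scale = math.sqrt((hi - lo + 1) / seq.length)
            excess = d - threshold * scale
            if best is None or excess > best[2]:
                best = (lo, hi, excess)
        lo, hi, excess = best
        if excess <= 0:
            break
        # detection by excursion (powerful for mid-sequence changes),
        # localization by the increment-likelihood argmax (precise)
        k, _g = _changepoint_lr(c, lo, hi)
        intervals.remove((lo, hi))
        breakpoints.append(k + 1)
        intervals.extend([(lo, k), (k, hi)])

    breakpoints.sort()
    # coordinate-descent refinement: re-estimate each breakpoint over
    # the span between its neighbors, where the one-changepoint model
    # holds and the estimator uses both adjacent segments in full
    for _sweep in range(3):
        moved = False
        for i, b in enumerate(breakpoints):
            lo = breakpoints[i - 1] if i > 0 else 0
            hi = breakpoints[i + 1] if i + 1 < len(breakpoints) else seq.length - 1
            k, _g = _changepoint_lr(c, lo, hi)
            if k + 1 != b and lo < k < hi:
                breakpoints[i] = k + 1
                moved = True
        breakpoints.sort()
        if not moved:
            break

    bounds = [1] + [b + 1 for b in breakpoints] + [seq.length + 1]
    segments = []
    for s, e in zip(bounds[:-1], bounds[1:]):
        if e - 1 >= s:
            segments.append((s, e - 1, region_gc(seq, s, e - 1)))
    return GCProfile(
        window_gc=window_gc(seq, window=window, step=step),
        cumulative=c,
        breakpoints=breakpoints,
        segments=segments,
    )
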