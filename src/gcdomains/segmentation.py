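"""Recursive compositional segmentation by Jensen-Shannon divergence.

A window-GC track is recursively bisected at the split that maximizes the
Jensen-Shannon divergence

    D_JS = H(p) - (n1/n) H(p1) - (n2/n) H(p2)        [bits]

where p, p1, p2 are the mean GC of the whole segment and of its two parts
and H is the binary entropy. A split is accepted only if its D_JS exceeds a
*dynamic threshold*: the null quantile (default 95th percentile) of the
maximal D_JS observed on simulated compositionally homogeneous segments of
the same length and window-GC standard deviation. Segments that cannot be
split significantly are emitted as compositional domains and classified as
homogeneous or nonhomogeneous by comparing their window-GC variance with
that of the chromosome they reside on.

Null-threshold simulations are expensive, so thresholds are evaluated lazily
on a (log2 n_windows x sd_gc) grid and interpolated bilinearly; node values
are seeded deterministically from the run seed and the node coordinates, so
a grid-node query equals a direct (uncached) simulation with the same seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import stats
from scipy.special import xlogy

from .sequence_io import WindowGCTrack

__all__ = [
    "SegmentationParams",
    "Segment",
    "Domain",
    "UnsplittableSegment",
    "js_divergence",
    "best_split",
    "dynamic_threshold",
    "ThresholdCache",
    "segment_track",
    "classify_homogeneity",
    "segment_chromosome",
]

HOMOGENEOUS = "homogeneous"
NONHOMOGENEOUS = "nonhomogeneous"


class UnsplittableSegment(ValueError):
    """Raised when a segment is too short to admit any valid split."""


@dataclass
class SegmentationParams:
    """Controls of the segmentation recursion and its halting criterion.

    window_bp
        Window width of the GC track, bp.
    min_domain_bp
        Smallest emitted domain, bp; must be a multiple of ``window_bp``.
    null_quantile
        Quantile of the simulated null maximal D_JS used as the halting
        threshold (0.95 keeps the per-segment false-split rate near 5%).
    n_null_sims
        Homogeneous tracks simulated per threshold evaluation.
    seed
        Base seed for all null simulations (thresholds are deterministic
        given this seed).
    alpha_homogeneity
        Level of the one-sided variance-ratio homogeneity test.
    """

    window_bp: int = 32
    min_domain_bp: int = 1024
    null_quantile: float = 0.95
    n_null_sims: int = 1000
    seed: int = 0
    alpha_homogeneity: float = 0.05

    def __post_init__(self) -> None:
        if self.min_domain_bp % self.window_bp != 0:
            raise ValueError("min_domain_bp must be a multiple of window_bp")
        if not 0.0 < self.null_quantile < 1.0:
            raise ValueError("null_quantile must lie in (0, 1)")

    @property
    def min_windows(self) -> int:
        return self.min_domain_bp // self.window_bp


@dataclass
class Segment:
    """A segment of a window track, in window indices (half-open)."""

    start_w: int
    end_w: int
    mean_gc: float
    sd_gc: float
    d_js_at_split: float = float("nan")
    sub_minimum: bool = False

    @property
    def n_windows(self) -> int:
        return self.end_w - self.start_w


@dataclass
class Domain:
    """A compositional domain in bp coordinates (0-based, half-open)."""

    chrom: str
    start_bp: int
    end_bp: int
    gc: float
    gc_sigma: float
    homogeneity: str
    gc_class: Optional[str] = None
    length_class: Optional[str] = None
    isochoric: bool = False

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp


def binary_entropy(q) -> np.ndarray:
    """H(q) in bits, with H(0) = H(1) = 0."""
    q = np.asarray(q, dtype=np.float64)
    return -(xlogy(q, q) + xlogy(1.0 - q, 1.0 - q)) / np.log(2.0)


def js_divergence(track_gc: np.ndarray, split_w: int) -> float:
    """D_JS (bits) of splitting a window-GC slice at ``split_w``."""
    gc = np.asarray(track_gc, dtype=np.float64)
    n = gc.size
    if not 1 <= split_w <= n - 1:
        raise ValueError(f"split {split_w} outside 1..{n - 1}")
    p = gc.mean()
    p1 = gc[:split_w].mean()
    p2 = gc[split_w:].mean()
    h = binary_entropy([p, p1, p2])
    return float(h[0] - (split_w / n) * h[1] - ((n - split_w) / n) * h[2])


def _split_scores(gc: np.ndarray, min_windows: int) -> tuple[np.ndarray, np.ndarray]:
    """D_JS at every admissible split of a slice (both children >= min)."""
    n = gc.size
    s = np.arange(min_windows, n - min_windows + 1)
    cs = np.cumsum(gc)
    tot = cs[-1]
    left = cs[s - 1] / s
    right = (tot - cs[s - 1]) / (n - s)
    d = (
        binary_entropy(tot / n)
        - (s / n) * binary_entropy(left)
        - ((n - s) / n) * binary_entropy(right)
    )
    return s, np.maximum(d, 0.0)


def best_split(track_gc: np.ndarray, min_windows: int = 1) -> tuple[int, float]:
    """Admissible split maximizing D_JS; ties broken by smallest index."""
    gc = np.asarray(track_gc, dtype=np.float64)
    if gc.size < 2 * min_windows:
        raise UnsplittableSegment(
            f"slice of {gc.size} windows admits no split with both children >= {min_windows}"
        )
    s, d = _split_scores(gc, min_windows)
    i = int(np.argmax(d))  # argmax returns the first maximum: leftmost tie-break
    return int(s[i]), float(d[i])


def _null_seed(seed: int, n_windows: int, sd_gc: float) -> np.random.SeedSequence:
    # Seed derived from the query point so cached grid nodes and direct
    # evaluations of the same (n, sd) agree exactly.
    return np.random.SeedSequence(seed, spawn_key=(int(n_windows), int(round(sd_gc * 1e6))))


def _simulate_null_max(
    n_windows: int, sd_gc: float, params: SegmentationParams
) -> np.ndarray:
    """Max admissible D_JS of ``n_null_sims`` homogeneous Gaussian tracks."""
    m = params.min_windows
    rng = np.random.default_rng(_null_seed(params.seed, n_windows, sd_gc))
    maxima = np.empty(params.n_null_sims)
    # chunked so the (chunk, n) matrices stay modest
    chunk = max(1, int(8e6) // max(n_windows, 1))
    done = 0
    s = np.arange(m, n_windows - m + 1)
    w1 = (s / n_windows).astype(np.float32)
    w2 = ((n_windows - s) / n_windows).astype(np.float32)
    while done < params.n_null_sims:
        c = min(chunk, params.n_null_sims - done)
        x = rng.normal(0.5, sd_gc, size=(c, n_windows))
        np.clip(x, 0.0, 1.0, out=x)
        cs = np.cumsum(x, axis=1)  # float64 partial sums, then float32 means
        tot = cs[:, -1:]
        left = (cs[:, s - 1] / s).astype(np.float32)
        right = ((tot - cs[:, s - 1]) / (n_windows - s)).astype(np.float32)
        d = (
            binary_entropy((tot / n_windows).astype(np.float32))
            - w1 * binary_entropy(left)
            - w2 * binary_entropy(right)
        )
        maxima[done : done + c] = d.max(axis=1)
        done += c
    return np.maximum(maxima, 0.0)


def dynamic_threshold(
    n_windows: int,
    sd_gc: float,
    params: SegmentationParams,
    cache: "ThresholdCache | None" = None,
) -> float:
    """Halting threshold (bits) for a segment of given length and dispersion.

    The threshold is the ``null_quantile`` of the maximal admissible D_JS
    over ``n_null_sims`` simulated homogeneous tracks whose window GC is
    i.i.d. normal with standard deviation ``sd_gc`` (clamped to [0, 1]).
    With a :class:`ThresholdCache` the value is bilinearly interpolated from
    lazily simulated grid nodes; a query on a grid node is exact.
    """
    if sd_gc < 0:
        raise ValueError("sd_gc must be >= 0")
    if n_windows < 2 * params.min_windows:
        raise UnsplittableSegment("segment too short for a threshold to be meaningful")
    if sd_gc == 0.0:
        return 0.0
    if cache is not None:
        return cache.value(n_windows, sd_gc)
    sims = _simulate_null_max(n_windows, sd_gc, params)
    return float(np.quantile(sims, params.null_quantile))


class ThresholdCache:
    """Lazy (log2 n_windows x sd_gc) grid of dynamic thresholds.

    Nodes sit at integer powers of two in ``n_windows`` and multiples of
    ``sd_step`` in ``sd_gc``; values are simulated on demand with node-derived
    seeds and interpolated bilinearly in (log2 n, sd). One cache is intended
    to be shared by all chromosomes of a run.
    """

    def __init__(self, params: SegmentationParams, sd_step: float = 0.005):
        self.params = params
        self.sd_step = float(sd_step)
        self._nodes: dict[tuple[int, int], float] = {}
        self.hits = 0
        self.misses = 0

    def _node(self, k: int, j: int) -> float:
        key = (k, j)
        if key in self._nodes:
            self.hits += 1
            return self._nodes[key]
        self.misses += 1
        sd = j * self.sd_step
        if j == 0:
            val = 0.0
        else:
            sims = _simulate_null_max(2**k, sd, self.params)
            val = float(np.quantile(sims, self.params.null_quantile))
        self._nodes[key] = val
        return val

    #: node size above which the quick-accept bound is used: the null
    #: threshold decreases with segment length at fixed sd (the maximal
    #: null D_JS scales like sd^2 log log n / n), so the threshold at
    #: 2**BOUND_K windows bounds it from above for all longer segments.
    BOUND_K = 12

    def upper_bound(self, n_windows: int, sd_gc: float) -> float:
        """Cheap upper bound on value(n_windows, sd_gc) for long segments."""
        if n_windows <= 2**self.BOUND_K:
            return self.value(n_windows, sd_gc)
        return self.value(2**self.BOUND_K, sd_gc)

    def lower_bound(self, n_windows: int, sd_gc: float) -> float:
        """Lower bound: the (sd-interpolated) node at the upper k bracket."""
        k1 = int(np.ceil(np.log2(n_windows)))
        j0 = int(np.floor(sd_gc / self.sd_step))
        j1 = j0 if j0 * self.sd_step == sd_gc else j0 + 1
        ts = 0.0 if j1 == j0 else (sd_gc - j0 * self.sd_step) / self.sd_step
        v0 = self._node(k1, j0)
        v1 = self._node(k1, j1) if j1 != j0 else v0
        return (1 - ts) * v0 + ts * v1

    def decide_split(self, n_windows: int, sd_gc: float, d_js: float) -> bool:
        """Accept/reject a split using monotone bracketing shortcuts.

        The full bilinear threshold is only simulated when ``d_js`` falls
        between the cheap bounds; outside that sliver the decision equals
        comparing against the bilinear value.
        """
        if d_js > self.upper_bound(n_windows, sd_gc):
            return True
        if n_windows > 2**self.BOUND_K and d_js <= self.lower_bound(n_windows, sd_gc):
            return False
        return d_js > self.value(n_windows, sd_gc)

    def value(self, n_windows: int, sd_gc: float) -> float:
        ln = np.log2(n_windows)
        k0 = int(np.floor(ln))
        k1 = k0 if 2**k0 == n_windows else k0 + 1
        # keep the lower node admissible (needs >= 2 * min_windows)
        kmin = int(np.ceil(np.log2(2 * self.params.min_windows)))
        k0 = max(k0, kmin)
        k1 = max(k1, k0)
        j0 = int(np.floor(sd_gc / self.sd_step))
        j1 = j0 if j0 * self.sd_step == sd_gc else j0 + 1
        tn = 0.0 if k1 == k0 else (ln - k0) / (k1 - k0)
        ts = 0.0 if j1 == j0 else (sd_gc - j0 * self.sd_step) / self.sd_step
        v00 = self._node(k0, j0)
        v01 = self._node(k0, j1) if j1 != j0 else v00
        v10 = self._node(k1, j0) if k1 != k0 else v00
        v11 = self._node(k1, j1) if (k1 != k0 or j1 != j0) else v00
        return float(
            (1 - tn) * ((1 - ts) * v00 + ts * v01) + tn * ((1 - ts) * v10 + ts * v11)
        )


def segment_track(
    track: WindowGCTrack | np.ndarray,
    params: SegmentationParams,
    cache: ThresholdCache | None = None,
) -> list[Segment]:
    """Recursively segment a window-GC track.

    Depth-first, left child first; a split is accepted iff its D_JS exceeds
    the dynamic threshold for the segment's length and window-GC standard
    deviation. The result tiles the track contiguously in order. A track
    shorter than ``min_domain_bp`` is returned as a single segment flagged
    ``sub_minimum``.
    """
    gc = track.gc if isinstance(track, WindowGCTrack) else np.asarray(track, dtype=np.float64)
    n = gc.size
    if n == 0:
        raise ValueError("empty track")
    m = params.min_windows
    if n < m:
        return [
            Segment(0, n, float(gc.mean()), float(gc.std(ddof=1)) if n > 1 else 0.0,
                    sub_minimum=True)
        ]
    out: list[Segment] = []
    stack: list[tuple[int, int]] = [(0, n)]
    while stack:
        i, j = stack.pop()
        seg = gc[i:j]
        nw = j - i
        mean = float(seg.mean())
        sd = float(seg.std(ddof=1)) if nw > 1 else 0.0
        d_audit = float("nan")
        if nw >= 2 * m:
            s, d = best_split(seg, m)
            if cache is not None and sd > 0:
                accept = cache.decide_split(nw, sd, d)
            else:
                accept = d > dynamic_threshold(nw, sd, params, cache)
            if accept:
                # push right first so the left child is processed first
                stack.append((i + s, j))
                stack.append((i, i + s))
                continue
            d_audit = d  # best (rejected) split, kept for audit
        out.append(Segment(i, j, mean, sd, d_js_at_split=d_audit))
    out.sort(key=lambda s: s.start_w)
    return out


def classify_homogeneity(
    domain_gc: np.ndarray, chrom_var: float, alpha: float = 0.05
) -> str:
    """Classify a domain by its window-GC variance against the chromosome.

    Homogeneous iff the domain variance is significantly *smaller* than the
    chromosome variance by a one-sided variance-ratio test: with n windows,
    (n-1) * var / chrom_var is referred to a chi-square(n-1) lower tail
    (the large-sample limit of the F reference).
    """
    gc = np.asarray(domain_gc, dtype=np.float64)
    n = gc.size
    if n < 2:
        raise ValueError("homogeneity needs >= 2 windows")
    if chrom_var <= 0:
        raise ValueError("chromosome window-GC variance must be positive")
    var = gc.var(ddof=1)
    p = stats.chi2.cdf((n - 1) * var / chrom_var, df=n - 1)
    return HOMOGENEOUS if p < alpha else NONHOMOGENEOUS


def segment_chromosome(
    track: WindowGCTrack,
    params: SegmentationParams,
    cache: ThresholdCache | None = None,
    chrom_name: str | None = None,
) -> list[Domain]:
    """Segment one chromosome track and classify each domain's homogeneity."""
    name = chrom_name if chrom_name is not None else track.chrom_ref
    gc = track.gc
    chrom_var = float(gc.var(ddof=1)) if gc.size > 1 else 0.0
    segs = segment_track(track, params, cache)
    w = track.window_bp
    domains = []
    for s in segs:
        if chrom_var > 0 and s.n_windows >= 2:
            homog = classify_homogeneity(
                gc[s.start_w : s.end_w], chrom_var, params.alpha_homogeneity
            )
        else:
            homog = NONHOMOGENEOUS
        domains.append(
            Domain(
                chrom=name,
                start_bp=s.start_w * w,
                end_bp=s.end_w * w,
                gc=s.mean_gc,
                gc_sigma=s.sd_gc,
                homogeneity=homog,
            )
        )
    return domains
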