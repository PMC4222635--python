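"""Per-genome attributes of compositional domains.

Implements the summary layer: the GC-rich/GC-poor critical value, length
classes (short 1e3-1e4 bp, medium-short 1e4-1e5, medium-long 1e5-1e6, long
>= 1e6), the "isochoric" flag for homogeneous domains >= 300 kb, domain
density (domains per Mb), genomic coverage of the four homogeneity x length
categories, GC-sigma, length percentiles, joint (GC x length) histograms,
whole-genome summaries, and the Euclidean distance between coverage
vectors used to compare genome architectures.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .segmentation import Domain, HOMOGENEOUS, NONHOMOGENEOUS

__all__ = [
    "GenomeSummary",
    "JointHistogram",
    "critical_gc",
    "annotate_domains",
    "domain_density",
    "coverage_by_category",
    "gc_sigma",
    "length_percentile",
    "joint_histogram",
    "summarize_genome",
    "coverage_distance",
    "load_published_stats",
    "ISOCHORE_CUTOFF_BP",
    "LENGTH_CLASSES",
]

ISOCHORE_CUTOFF_BP = 300_000

#: (name, lower bound inclusive, upper bound exclusive); "long" is open-ended
#: above 1e6 so the rare >10 Mb domain still belongs to a class.
LENGTH_CLASSES = [
    ("sub-short", 0, 1_000),
    ("short", 1_000, 10_000),
    ("medium-short", 10_000, 100_000),
    ("medium-long", 100_000, 1_000_000),
    ("long", 1_000_000, float("inf")),
]

GC_RICH = "GC-rich"
GC_POOR = "GC-poor"


@dataclass
class JointHistogram:
    """2-D counts of (x, y) pairs on fixed bin edges."""

    x_edges: np.ndarray
    y_edges: np.ndarray
    counts: np.ndarray
    n_dropped: int
    x_label: str = "x"
    y_label: str = "y"

    def to_frame(self) -> pd.DataFrame:
        idx = pd.Index(self.x_edges[:-1], name=f"{self.x_label}_left_edge")
        cols = pd.Index(self.y_edges[:-1], name=f"{self.y_label}_left_edge")
        return pd.DataFrame(self.counts, index=idx, columns=cols)


@dataclass
class GenomeSummary:
    """One genome's domain statistics (one column of the published tables)."""

    genome_label: str
    sequenced_gb: float
    mean_gc_pct: float
    n_domains: int
    domain_density_per_mb: float
    n_homogeneous: int
    frac_homogeneous_pct: float
    n_nonhomogeneous: int
    frac_nonhomogeneous_pct: float
    n_isochoric: int
    frac_isochoric_of_all_pct: float
    frac_isochoric_of_homogeneous_pct: float
    coverage_pct: dict[str, float]
    length_stats: dict[str, dict[str, float]] = field(default_factory=dict)
    gc_stats: dict[str, dict[str, float]] = field(default_factory=dict)
    largest_domain_mb: dict[str, float] = field(default_factory=dict)

    def to_row(self) -> dict:
        row = {
            "genome": self.genome_label,
            "sequenced_gb": self.sequenced_gb,
            "mean_gc_pct": round(self.mean_gc_pct, 1),
            "n_domains": self.n_domains,
            "density_per_mb": self.domain_density_per_mb,
            "n_homogeneous": self.n_homogeneous,
            "hom_frac_pct": self.frac_homogeneous_pct,
            "n_nonhomogeneous": self.n_nonhomogeneous,
            "nonhom_frac_pct": self.frac_nonhomogeneous_pct,
            "n_isochoric": self.n_isochoric,
            "iso_frac_all_pct": self.frac_isochoric_of_all_pct,
            "iso_frac_hom_pct": self.frac_isochoric_of_homogeneous_pct,
        }
        for cat, v in self.coverage_pct.items():
            row[f"cov_{cat}_pct"] = v
        for typ, st in self.length_stats.items():
            row[f"{typ}_mean_len_bp"] = st["mean"]
            row[f"{typ}_median_len_bp"] = st["median"]
        for typ, st in self.gc_stats.items():
            row[f"{typ}_mean_gc_pct"] = round(st["mean"], 1)
            row[f"{typ}_median_gc_pct"] = round(st["median"], 1)
        for typ, v in self.largest_domain_mb.items():
            row[f"{typ}_largest_mb"] = v
        return row


def load_published_stats() -> pd.DataFrame:
    """Published compositional-domain statistics for 11 amniote genomes.

    Whole-genome and per-domain-type counts, fractions, and coverages from
    an IsoPlotter-based segmentation of ten mammalian genomes and chicken;
    used for cross-checking the summary arithmetic of this package.
    """
    with (resources.files("gcdomains") / "data" / "published_genome_stats.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


def critical_gc(genome_mean_gcs: Sequence[float]) -> float:
    """Unweighted mean GC over a cohort of genomes: the GC-rich/poor cutoff."""
    vals = np.asarray(genome_mean_gcs, dtype=np.float64)
    if vals.size == 0:
        raise ValueError("critical_gc needs at least one genome mean")
    return float(vals.mean())


def _length_class(length_bp: float) -> str:
    for name, lo, hi in LENGTH_CLASSES:
        if lo <= length_bp < hi:
            return name
    raise ValueError(f"length {length_bp} outside all classes")


def annotate_domains(
    domains: Iterable[Domain],
    critical: float,
    isochore_cutoff_bp: int = ISOCHORE_CUTOFF_BP,
) -> list[Domain]:
    """Set gc_class, length_class, and the isochoric flag in place.

    GC-rich means gc strictly above the critical value (equality is
    GC-poor); isochoric means homogeneous and length >= the cutoff.
    """
    domains = list(domains)
    for d in domains:
        d.gc_class = GC_RICH if d.gc > critical else GC_POOR
        d.length_class = _length_class(d.length_bp)
        d.isochoric = d.homogeneity == HOMOGENEOUS and d.length_bp >= isochore_cutoff_bp
    return domains


def domain_density(n_domains: int, span_bp: float) -> float:
    """Domains per Mb of sequence."""
    if span_bp <= 0:
        raise ValueError("span_bp must be positive")
    return n_domains / (span_bp / 1e6)


def coverage_by_category(
    domains: Iterable[Domain],
    genome_bp: float,
    isochore_cutoff_bp: int = ISOCHORE_CUTOFF_BP,
) -> dict[str, float]:
    """Percent of the genome covered by the four homogeneity x length types.

    Categories: homogeneous >= cutoff ("isochoric"), homogeneous < cutoff,
    nonhomogeneous >= cutoff, nonhomogeneous < cutoff. Domains must be
    non-overlapping and fit within ``genome_bp``.
    """
    doms = sorted(domains, key=lambda d: (d.chrom, d.start_bp))
    total = 0
    cov = {"hom_long": 0, "hom_short": 0, "nonhom_long": 0, "nonhom_short": 0}
    prev_chrom, prev_end = None, 0
    for d in doms:
        if d.chrom == prev_chrom and d.start_bp < prev_end:
            raise ValueError(f"overlapping domains on {d.chrom}")
        prev_chrom, prev_end = d.chrom, d.end_bp
        long = d.length_bp >= isochore_cutoff_bp
        hom = d.homogeneity == HOMOGENEOUS
        key = ("hom_" if hom else "nonhom_") + ("long" if long else "short")
        cov[key] += d.length_bp
        total += d.length_bp
    if total > genome_bp:
        raise ValueError("domains span more than the genome")
    return {k: 100.0 * v / genome_bp for k, v in cov.items()}


def gc_sigma(domain_gc: np.ndarray) -> float:
    """Sample standard deviation (n-1) of window GC within a domain."""
    gc = np.asarray(domain_gc, dtype=np.float64)
    if gc.size < 2:
        raise ValueError("GC-sigma needs >= 2 windows")
    return float(gc.std(ddof=1))


def length_percentile(lengths: Sequence[float], q: float) -> float:
    """Empirical percentile with linear interpolation between order stats."""
    arr = np.asarray(lengths, dtype=np.float64)
    if arr.size == 0:
        raise ValueError("empty length sample")
    if not 0 < q < 100:
        raise ValueError("q must lie in (0, 100)")
    return float(np.percentile(arr, q, method="linear"))


def joint_histogram(
    x: Sequence[float],
    y: Sequence[float],
    x_edges: Sequence[float],
    y_edges: Sequence[float],
    x_label: str = "x",
    y_label: str = "y",
) -> JointHistogram:
    """2-D histogram; out-of-range points are dropped and counted."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.size != y.size:
        raise ValueError("x and y must have equal lengths")
    counts, xe, ye = np.histogram2d(x, y, bins=[np.asarray(x_edges), np.asarray(y_edges)])
    counts = counts.astype(np.int64)
    return JointHistogram(
        x_edges=xe,
        y_edges=ye,
        counts=counts,
        n_dropped=int(x.size - counts.sum()),
        x_label=x_label,
        y_label=y_label,
    )


def _type_subsets(domains: list[Domain]) -> dict[str, list[Domain]]:
    return {
        "all": domains,
        "homogeneous": [d for d in domains if d.homogeneity == HOMOGENEOUS],
        "nonhomogeneous": [d for d in domains if d.homogeneity == NONHOMOGENEOUS],
        "isochoric": [d for d in domains if d.isochoric],
    }


def summarize_genome(
    domains: Iterable[Domain],
    genome_label: str,
    genome_bp: float,
    density_span_bp: float | None = None,
    isochore_cutoff_bp: int = ISOCHORE_CUTOFF_BP,
) -> GenomeSummary:
    """Compute the per-genome summary from an annotated domain table.

    ``genome_bp`` is the sequenced (coverage) denominator; ``density_span_bp``
    defaults to it and lets callers choose the null-free span instead.
    """
    domains = list(domains)
    if not domains:
        raise ValueError("cannot summarize an empty domain list")
    span = density_span_bp if density_span_bp is not None else genome_bp
    subsets = _type_subsets(domains)
    n_all = len(domains)
    n_hom = len(subsets["homogeneous"])
    n_non = len(subsets["nonhomogeneous"])
    n_iso = len(subsets["isochoric"])
    lengths = np.array([d.length_bp for d in domains], dtype=np.float64)
    gcs = np.array([d.gc for d in domains], dtype=np.float64)
    mean_gc_pct = float(100.0 * np.average(gcs, weights=lengths))

    length_stats, gc_stats, largest = {}, {}, {}
    for typ, sub in subsets.items():
        if not sub:
            continue
        ls = np.array([d.length_bp for d in sub], dtype=np.float64)
        gs = np.array([d.gc for d in sub], dtype=np.float64)
        length_stats[typ] = {"mean": float(ls.mean()), "median": float(np.median(ls))}
        gc_stats[typ] = {
            "mean": float(100.0 * gs.mean()),
            "median": float(100.0 * np.median(gs)),
        }
        largest[typ] = float(ls.max() / 1e6)

    return GenomeSummary(
        genome_label=genome_label,
        sequenced_gb=genome_bp / 1e9,
        mean_gc_pct=mean_gc_pct,
        n_domains=n_all,
        domain_density_per_mb=domain_density(n_all, span),
        n_homogeneous=n_hom,
        frac_homogeneous_pct=100.0 * n_hom / n_all,
        n_nonhomogeneous=n_non,
        frac_nonhomogeneous_pct=100.0 * n_non / n_all,
        n_isochoric=n_iso,
        frac_isochoric_of_all_pct=100.0 * n_iso / n_all,
        frac_isochoric_of_homogeneous_pct=(100.0 * n_iso / n_hom) if n_hom else float("nan"),
        coverage_pct=coverage_by_category(domains, genome_bp, isochore_cutoff_bp),
        length_stats=length_stats,
        gc_stats=gc_stats,
        largest_domain_mb=largest,
    )


def coverage_distance(cov_a: Sequence[float], cov_b: Sequence[float]) -> float:
    """Euclidean (L2) distance between two coverage-percentage vectors."""
    a = np.asarray(cov_a, dtype=np.float64)
    b = np.asarray(cov_b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("coverage vectors must have equal length")
    return float(np.linalg.norm(a - b))
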