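"""Per-genome runs and cross-genome cohort comparisons.

``run_genome`` segments every chromosome of one genome, classifies and
annotates the domains, and produces the genome summary. ``run_cohort``
takes two or more completed runs and produces the pairwise comparison
matrices (lengths and GC, per domain type, FDR-adjusted within each
family), the power-law fit table, and the coverage-distance matrix.
All outputs are deterministic given inputs and seed.
"""

from __future__ import annotations

import itertools
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import attributes as attr
from . import compare as cmp
from . import powerlaw as pl
from .segmentation import (
    Domain,
    SegmentationParams,
    ThresholdCache,
    segment_chromosome,
)
from .sequence_io import ChromosomeSequence, gc_track, write_domains, write_removed_runs

log = logging.getLogger("gcdomains")

__all__ = ["RunConfig", "GenomeRun", "run_genome", "run_cohort"]

DOMAIN_TYPES = ("all", "homogeneous", "nonhomogeneous")


@dataclass
class RunConfig:
    """Configuration of one genome run (loadable from a YAML file)."""

    fasta: str | None = None
    genome_label: str | None = None
    params: SegmentationParams = field(default_factory=SegmentationParams)
    critical_gc: float | str = "auto"
    density_denominator: str = "sequenced"  # or "nullfree"
    isochore_cutoff_bp: int = attr.ISOCHORE_CUTOFF_BP
    outdir: str | None = None

    def __post_init__(self) -> None:
        if self.density_denominator not in ("sequenced", "nullfree"):
            raise ValueError("density_denominator must be 'sequenced' or 'nullfree'")

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update(overrides)
        param_keys = raw.pop("params", {})
        return cls(params=SegmentationParams(**param_keys), **raw)


@dataclass
class GenomeRun:
    """Results of one segmented genome."""

    label: str
    domains: list[Domain]
    summary: attr.GenomeSummary
    sequenced_bp: int
    nullfree_bp: int
    mean_gc: float  # genome GC fraction over null-free residues


def run_genome(
    seqs: Sequence[ChromosomeSequence],
    params: SegmentationParams | None = None,
    critical: float | None = None,
    isochore_cutoff_bp: int = attr.ISOCHORE_CUTOFF_BP,
    density_denominator: str = "sequenced",
    label: str | None = None,
    cache: ThresholdCache | None = None,
) -> GenomeRun:
    """Segment, classify, annotate, and summarize one genome.

    ``critical`` defaults to the genome's own mean GC; cohort-level critical
    values are applied by :func:`run_cohort`. The per-chromosome work shares
    one threshold cache, and results are independent of chromosome order.
    """
    if not seqs:
        raise ValueError("run_genome needs at least one chromosome")
    params = params if params is not None else SegmentationParams()
    label = label if label is not None else seqs[0].genome_label
    cache = cache if cache is not None else ThresholdCache(params)

    t0 = time.perf_counter()
    domains: list[Domain] = []
    gc_sum = 0.0
    gc_n = 0
    for seq in seqs:
        track = gc_track(seq, params.window_bp)
        gc_sum += float(track.gc.sum()) * params.window_bp
        gc_n += track.n_windows * params.window_bp
        domains.extend(segment_chromosome(track, params, cache))
        log.info("%s/%s: %d windows", label, seq.chrom_name, track.n_windows)
    mean_gc = gc_sum / gc_n
    crit = critical if critical is not None else mean_gc
    attr.annotate_domains(domains, crit, isochore_cutoff_bp)

    sequenced_bp = sum(s.original_length for s in seqs)
    nullfree_bp = sum(s.nullfree_length for s in seqs)
    span = nullfree_bp if density_denominator == "nullfree" else sequenced_bp
    summary = attr.summarize_genome(
        domains, label, genome_bp=sequenced_bp, density_span_bp=span,
        isochore_cutoff_bp=isochore_cutoff_bp,
    )
    log.info(
        "%s: %d domains, cache %d nodes (%d hits), %.1fs",
        label, len(domains), cache.misses, cache.hits, time.perf_counter() - t0,
    )
    return GenomeRun(
        label=label, domains=domains, summary=summary,
        sequenced_bp=sequenced_bp, nullfree_bp=nullfree_bp, mean_gc=mean_gc,
    )


def _domain_values(run: GenomeRun, domain_type: str, attribute: str) -> np.ndarray:
    doms = run.domains
    if domain_type != "all":
        doms = [d for d in doms if d.homogeneity == domain_type]
    if attribute == "length":
        return np.array([d.length_bp for d in doms], dtype=np.float64)
    if attribute == "gc":
        return np.array([d.gc for d in doms], dtype=np.float64)
    raise ValueError(f"unknown attribute {attribute!r}")


def run_cohort(
    runs: Sequence[GenomeRun],
    attributes: Sequence[str] = ("length", "gc"),
    domain_types: Sequence[str] = DOMAIN_TYPES,
    critical: float | str = "auto",
    n_boot: int = 1000,
    seed: int = 0,
    powerlaw_domain_type: str = "homogeneous",
) -> dict:
    """Cross-genome statistics over >= 2 completed genome runs.

    Re-annotates every run with the cohort critical GC (mean of per-genome
    means when "auto"), then produces one pairwise comparison table per
    (attribute x domain type) family with FDR applied within the family,
    the power-law fit table, and the coverage-distance matrix.
    """
    if len(runs) < 2:
        raise ValueError("a cohort needs at least two genomes")
    crit = (
        attr.critical_gc([r.mean_gc for r in runs]) if critical == "auto" else float(critical)
    )
    for r in runs:
        attr.annotate_domains(r.domains, crit)

    comparisons: dict[tuple[str, str], pd.DataFrame] = {}
    for attribute in attributes:
        for dtype in domain_types:
            rows = []
            for a, b in itertools.combinations(runs, 2):
                x = _domain_values(a, dtype, attribute)
                y = _domain_values(b, dtype, attribute)
                res = cmp.compare_distributions(x, y, kind=attribute)
                rows.append(
                    {
                        "genome_a": a.label, "genome_b": b.label,
                        "ks_D": res.ks_D, "p_raw": res.p_raw,
                        "nonoverlap_pct": res.nonoverlap_pct,
                        "hedges_g": res.hedges_g, "meaningful": res.meaningful,
                    }
                )
            df = pd.DataFrame(rows)
            if not df.empty:
                df["p_fdr"] = cmp.fdr_adjust(df["p_raw"].to_numpy())
            comparisons[(attribute, dtype)] = df

    pl_rows = []
    for r in runs:
        lengths = _domain_values(r, powerlaw_domain_type, "length")
        fit = pl.fit_power_law(lengths, n_boot=n_boot, seed=seed)
        pl_rows.append(
            {
                "genome": r.label, "domain_type": powerlaw_domain_type,
                "xmin": fit.xmin, "alpha": fit.alpha, "n_tail": fit.n_tail,
                "ks_D": fit.ks_D, "p_gof": fit.p_gof, "n_boot": fit.n_boot,
                "seed": seed,
                "power_law_ruled_out": fit.p_gof < pl.RULE_OUT_P,
            }
        )
    powerlaw_table = pd.DataFrame(pl_rows)

    labels = [r.label for r in runs]
    covs = {
        r.label: [r.summary.coverage_pct[k] for k in
                  ("hom_long", "hom_short", "nonhom_long", "nonhom_short")]
        for r in runs
    }
    dist = pd.DataFrame(
        [[attr.coverage_distance(covs[a], covs[b]) for b in labels] for a in labels],
        index=labels, columns=labels,
    )
    return {
        "critical_gc": crit,
        "comparisons": comparisons,
        "powerlaw": powerlaw_table,
        "coverage_distance": dist,
    }


def write_genome_outputs(run: GenomeRun, seqs, params: SegmentationParams, outdir: str | Path) -> None:
    """Write the BED-like domain table, summary row, sidecars, and manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_domains(run.domains, outdir / f"{run.label}.domains.tsv")
    write_removed_runs(list(seqs), outdir / f"{run.label}.removed_runs.json")
    pd.DataFrame([run.summary.to_row()]).to_csv(
        outdir / f"{run.label}.summary.tsv", sep="\t", index=False
    )
    manifest = {
        "genome": run.label,
        "sequenced_bp": run.sequenced_bp,
        "nullfree_bp": run.nullfree_bp,
        "mean_gc": run.mean_gc,
        "params": {
            "window_bp": params.window_bp,
            "min_domain_bp": params.min_domain_bp,
            "null_quantile": params.null_quantile,
            "n_null_sims": params.n_null_sims,
            "seed": params.seed,
            "alpha_homogeneity": params.alpha_homogeneity,
        },
    }
    (outdir / f"{run.label}.manifest.json").write_text(json.dumps(manifest, indent=1) + "\n")
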