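"""Synthetic genomes with known compositional architecture.

Each chromosome is a mosaic of contiguous domains whose lengths follow a
heavy-tailed lognormal law (median ~8 kb, right tail reaching Mb scale) and
whose mean GC is drawn from a truncated normal law centered near 41%. A
configurable fraction of domains is compositionally *nonhomogeneous*,
realized either as within-domain GC gradients or as fine-grained sub-domain
mosaics whose blocks are shorter than the segmenter's minimum domain (so
they inflate within-domain variance without creating a single significant
breakpoint). Optional runs of N emulate assembly gaps. The generator
records the ground-truth architecture so segmentation, classification, and
the attribute layer can each be tested against known truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

from .sequence_io import ChromosomeSequence

__all__ = [
    "ArchitectureConfig",
    "DomainSpec",
    "SyntheticGenome",
    "sample_architecture",
    "realize_sequence",
    "simulate_genome",
    "boundary_recovery",
]

_BASES = np.frombuffer(b"ATGC", dtype=np.uint8)  # index: 2*is_gc + strand coin


@dataclass
class ArchitectureConfig:
    """Study conditions of the generator.

    Lengths: lognormal with ``length_median_bp`` and ``length_sigma_log``
    (natural-log sd), clipped below at ``min_domain_bp``. GC: normal
    (mean 0.41, sd 0.06) truncated to ``gc_bounds``. ``nonhomogeneous_fraction``
    of domains are realized per ``nonhomogeneous_kind`` ("mosaic",
    "gradient", or "mixed" = half each). N-runs are inserted at
    ``n_run_rate_per_mb`` runs/Mb of fixed length ``n_run_len_bp`` (0 = off).
    """

    n_chromosomes: int = 4
    chromosome_bp: int = 5_000_000
    length_median_bp: float = 8_000.0
    length_sigma_log: float = 1.5
    min_domain_bp: int = 1_024
    gc_mean: float = 0.41
    gc_sd: float = 0.06
    gc_bounds: tuple[float, float] = (0.25, 0.65)
    nonhomogeneous_fraction: float = 0.3
    nonhomogeneous_kind: str = "mosaic"
    gradient_delta: float = 0.25
    mosaic_block_bp: int = 32
    mosaic_jitter_sd: float = 0.10
    n_run_rate_per_mb: float = 0.0
    n_run_len_bp: int = 500


@dataclass
class DomainSpec:
    """Ground truth for one domain before sequence realization."""

    length_bp: int
    mean_gc: float
    kind: str  # iid | gradient | mosaic
    kind_params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.length_bp < 1:
            raise ValueError("domain length must be >= 1 bp")
        if not 0.0 <= self.mean_gc <= 1.0:
            raise ValueError("mean_gc must lie in [0, 1]")


@dataclass
class SyntheticGenome:
    """Realized chromosomes plus the per-chromosome architecture truth."""

    chromosomes: list[ChromosomeSequence]
    truth: list[list[DomainSpec]]
    seed: int
    config: ArchitectureConfig

    def truth_breakpoints(self, chrom_index: int) -> np.ndarray:
        """Internal domain boundaries (bp, null-free system) of one chromosome."""
        lengths = np.array([s.length_bp for s in self.truth[chrom_index]])
        return np.cumsum(lengths)[:-1]

    def truth_homogeneous_fraction(self) -> float:
        specs = [s for chrom in self.truth for s in chrom]
        return sum(s.kind == "iid" for s in specs) / len(specs)


def _truncated_normal(rng, mean, sd, lo, hi, size):
    out = rng.normal(mean, sd, size)
    bad = (out < lo) | (out > hi)
    while np.any(bad):
        out[bad] = rng.normal(mean, sd, bad.sum())
        bad = (out < lo) | (out > hi)
    return out


def sample_architecture(
    config: ArchitectureConfig, seed: int
) -> list[list[DomainSpec]]:
    """Draw the domain architecture of each chromosome; reproducible by seed."""
    if config.min_domain_bp > config.chromosome_bp:
        raise ValueError("min_domain_bp exceeds chromosome length")
    if not 0.0 <= config.nonhomogeneous_fraction <= 1.0:
        raise ValueError("nonhomogeneous_fraction must lie in [0, 1]")
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(0,)))
    mu = np.log(config.length_median_bp)
    chroms: list[list[DomainSpec]] = []
    for _ in range(config.n_chromosomes):
        specs: list[DomainSpec] = []
        remaining = config.chromosome_bp
        while remaining > 0:
            L = int(np.clip(rng.lognormal(mu, config.length_sigma_log),
                            config.min_domain_bp, None))
            L = min(L, remaining)
            gc = float(_truncated_normal(rng, config.gc_mean, config.gc_sd,
                                         *config.gc_bounds, size=1)[0])
            if rng.random() < config.nonhomogeneous_fraction:
                kind = config.nonhomogeneous_kind
                if kind == "mixed":
                    kind = "mosaic" if rng.random() < 0.5 else "gradient"
                if kind == "gradient":
                    half = config.gradient_delta / 2.0
                    sign = 1.0 if rng.random() < 0.5 else -1.0
                    start = float(np.clip(gc - sign * half, 0.05, 0.95))
                    end = float(np.clip(gc + sign * half, 0.05, 0.95))
                    params = {"start_gc": start, "end_gc": end}
                else:
                    params = {
                        "block_bp": config.mosaic_block_bp,
                        "jitter_sd": config.mosaic_jitter_sd,
                    }
                specs.append(DomainSpec(L, gc, kind, params))
            else:
                specs.append(DomainSpec(L, gc, "iid"))
            remaining -= L
        chroms.append(specs)
    return chroms


def _gc_probability_profile(spec: DomainSpec, rng) -> np.ndarray:
    L = spec.length_bp
    if spec.kind == "iid":
        return np.full(L, spec.mean_gc)
    if spec.kind == "gradient":
        return np.linspace(spec.kind_params["start_gc"], spec.kind_params["end_gc"], L)
    if spec.kind == "mosaic":
        block = int(spec.kind_params["block_bp"])
        jit = float(spec.kind_params["jitter_sd"])
        nblocks = -(-L // block)
        levels = np.clip(rng.normal(spec.mean_gc, jit, nblocks), 0.02, 0.98)
        return np.repeat(levels, block)[:L]
    raise ValueError(f"unknown domain kind {spec.kind!r}")


def realize_sequence(
    specs_per_chromosome: Sequence[Sequence[DomainSpec]],
    seed: int,
    config: ArchitectureConfig | None = None,
    genome_label: str = "synthetic",
) -> SyntheticGenome:
    """Realize base sequences from an architecture.

    Each base is G/C with the local GC probability (G and C equiprobable),
    else A/T equiprobable. If the config enables N-runs, runs *replace*
    stretches of sequence, so with-N coordinates equal original coordinates
    and the null-free truth breakpoints are recoverable by subtracting the
    removed run lengths.
    """
    config = config if config is not None else ArchitectureConfig()
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(1,)))
    chromosomes: list[ChromosomeSequence] = []
    for ci, specs in enumerate(specs_per_chromosome):
        profile = np.concatenate([_gc_probability_profile(s, rng) for s in specs])
        L = profile.size
        is_gc = rng.random(L) < profile
        coin = rng.random(L) < 0.5
        codes = (is_gc.astype(np.uint8) << 1) | coin.astype(np.uint8)
        seq = _BASES[codes]
        removed_runs: list[tuple[int, int]] = []
        if config.n_run_rate_per_mb > 0 and config.n_run_len_bp > 0:
            n_runs = rng.poisson(config.n_run_rate_per_mb * L / 1e6)
            starts = np.sort(rng.integers(0, max(L - config.n_run_len_bp, 1), n_runs))
            last_end = -1
            for st in starts:
                if st <= last_end:  # keep runs disjoint
                    continue
                en = min(st + config.n_run_len_bp, L)
                seq[st:en] = ord("N")
                removed_runs.append((int(st), int(en - st)))
                last_end = en
        residues = seq.tobytes().decode("ascii")
        nullfree = residues.replace("N", "")
        chromosomes.append(
            ChromosomeSequence(
                genome_label=genome_label,
                chrom_name=f"chr{ci + 1}",
                residues=nullfree,
                original_length=L,
                removed_runs=removed_runs,
            )
        )
    return SyntheticGenome(
        chromosomes=chromosomes,
        truth=[list(s) for s in specs_per_chromosome],
        seed=seed,
        config=config,
    )


def simulate_genome(
    config: ArchitectureConfig, seed: int, genome_label: str = "synthetic"
) -> SyntheticGenome:
    """Convenience wrapper: sample an architecture and realize it."""
    specs = sample_architecture(config, seed)
    return realize_sequence(specs, seed, config=config, genome_label=genome_label)


def truth_breakpoints_nullfree(genome: SyntheticGenome, chrom_index: int) -> np.ndarray:
    """Truth breakpoints shifted into the null-free coordinate system."""
    bps = genome.truth_breakpoints(chrom_index)
    runs = genome.chromosomes[chrom_index].removed_runs
    if not runs:
        return bps
    starts = np.array([s for s, _ in runs])
    lens = np.array([n for _, n in runs])
    shift = np.array([lens[starts < b].sum() for b in bps])
    return bps - shift


def boundary_recovery(
    truth_breaks: Sequence[float],
    inferred_breaks: Sequence[float],
    tol_bp: float,
) -> tuple[float, float]:
    """Greedy one-to-one matching of breakpoints within +/- tol_bp.

    Returns (precision, recall) = (matched / inferred, matched / truth);
    an empty inferred list yields (0, 0) by convention.
    """
    if tol_bp < 0:
        raise ValueError("tolerance must be non-negative")
    t = np.sort(np.asarray(truth_breaks, dtype=np.float64))
    f = np.sort(np.asarray(inferred_breaks, dtype=np.float64))
    if t.size == 0 or f.size == 0:
        return (0.0, 0.0) if f.size == 0 else (0.0, 0.0)
    i = j = matched = 0
    while i < t.size and j < f.size:
        d = f[j] - t[i]
        if abs(d) <= tol_bp:
            matched += 1
            i += 1
            j += 1
        elif d < 0:
            j += 1
        else:
            i += 1
    return matched / f.size, matched / t.size
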