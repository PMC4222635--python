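"""Sequence input/output and window GC tracks.

Chromosome sequences are read from FASTA, ambiguous characters ("nulls":
anything outside A/C/G/T after upper-casing) are discarded and their runs
recorded, and the null-free sequence is summarised as a track of GC
fractions over fixed-width non-overlapping windows. The window track is the
substrate of all downstream segmentation arithmetic.

Coordinates are 0-based, half-open, and by default live in the null-free
coordinate system; ``removed_runs`` allows lifting back to the original
coordinates.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = [
    "ChromosomeSequence",
    "WindowGCTrack",
    "read_fasta",
    "gc_track",
    "write_domains",
    "read_domains",
    "write_removed_runs",
    "DOMAIN_COLUMNS",
]

_NON_ACGT = re.compile(r"[^ACGT]+")

DOMAIN_COLUMNS = [
    "chrom",
    "start",
    "end",
    "gc",
    "gc_sigma",
    "homogeneity",
    "gc_class",
    "length_class",
]


@dataclass
class ChromosomeSequence:
    """A null-stripped chromosome sequence.

    ``residues`` contains only A/C/G/T; ``removed_runs`` lists the
    (start, length) of every discarded run in the *original* coordinate
    system, so that ``sum(lengths) + len(residues) == original_length``.
    """

    genome_label: str
    chrom_name: str
    residues: str
    original_length: int
    removed_runs: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        removed = sum(n for _, n in self.removed_runs)
        if removed + len(self.residues) != self.original_length:
            raise ValueError(
                f"{self.chrom_name}: removed runs ({removed}) + residues "
                f"({len(self.residues)}) != original length ({self.original_length})"
            )

    @property
    def nullfree_length(self) -> int:
        return len(self.residues)


@dataclass
class WindowGCTrack:
    """GC fraction per fixed-width non-overlapping window.

    The trailing partial window is discarded, so
    ``n_windows == nullfree_length // window_bp``.
    """

    chrom_ref: str
    window_bp: int
    gc: np.ndarray

    @property
    def n_windows(self) -> int:
        return len(self.gc)


def strip_nulls(sequence: str) -> tuple[str, list[tuple[int, int]]]:
    """Upper-case a sequence, discard non-ACGT runs, and record them.

    Returns the null-free residues and the (start, length) list of removed
    runs in the coordinates of the input sequence.
    """
    seq = sequence.upper()
    runs = [(m.start(), m.end() - m.start()) for m in _NON_ACGT.finditer(seq)]
    residues = _NON_ACGT.sub("", seq)
    return residues, runs


def read_fasta(path: str | Path, genome_label: str | None = None) -> list[ChromosomeSequence]:
    """Read a (possibly multi-record, multi-line, mixed-case) FASTA file.

    Ambiguous characters are discarded per record; records appear in file
    order. A record with no sequence raises a ``ValueError`` naming it.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    label = genome_label if genome_label is not None else path.stem
    out: list[ChromosomeSequence] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        raw = str(rec.seq)
        if not raw:
            raise ValueError(f"FASTA record {rec.id!r} in {path} has no sequence")
        residues, runs = strip_nulls(raw)
        out.append(
            ChromosomeSequence(
                genome_label=label,
                chrom_name=rec.id,
                residues=residues,
                original_length=len(raw),
                removed_runs=runs,
            )
        )
    if not out:
        raise ValueError(f"FASTA file {path} contains no records")
    return out


def split_at_long_n(
    genome_label: str, chrom_name: str, sequence: str, min_run_bp: int
) -> list[ChromosomeSequence]:
    """Break a raw sequence into pieces at N-runs of at least ``min_run_bp``.

    Alternative to concatenating across gaps: each piece becomes its own
    null-stripped record named ``<chrom>.partK``, with run coordinates local
    to the piece. Short ambiguity runs are still discarded within pieces.
    """
    if min_run_bp < 1:
        raise ValueError("min_run_bp must be >= 1")
    seq = sequence.upper()
    breaker = re.compile("[^ACGT]{%d,}" % min_run_bp)
    pieces, pos, out = [], 0, []
    for m in breaker.finditer(seq):
        if m.start() > pos:
            pieces.append((pos, seq[pos : m.start()]))
        pos = m.end()
    if pos < len(seq):
        pieces.append((pos, seq[pos:]))
    for k, (_, chunk) in enumerate(pieces, start=1):
        residues, runs = strip_nulls(chunk)
        name = chrom_name if len(pieces) == 1 else f"{chrom_name}.part{k}"
        out.append(
            ChromosomeSequence(
                genome_label=genome_label, chrom_name=name, residues=residues,
                original_length=len(chunk), removed_runs=runs,
            )
        )
    return out


def sequence_to_gc01(residues: str) -> np.ndarray:
    """Encode residues as a uint8 0/1 array marking G or C."""
    a = np.frombuffer(residues.encode("ascii"), dtype=np.uint8)
    return ((a == ord("G")) | (a == ord("C"))).astype(np.uint8)


def gc_track(seq: ChromosomeSequence | str, window_bp: int = 32) -> WindowGCTrack:
    """Compute the fixed-width window GC track of a null-free sequence.

    The trailing partial window is dropped. Raises if the sequence is
    shorter than one window.
    """
    if window_bp < 1:
        raise ValueError("window_bp must be >= 1")
    if isinstance(seq, ChromosomeSequence):
        residues, name = seq.residues, seq.chrom_name
    else:
        residues, name = seq, "<anonymous>"
    n = len(residues)
    if n < window_bp:
        raise ValueError(f"{name}: sequence ({n} bp) shorter than one window ({window_bp} bp)")
    nw = n // window_bp
    is_gc = sequence_to_gc01(residues)[: nw * window_bp]
    gc = is_gc.reshape(nw, window_bp).mean(axis=1)
    return WindowGCTrack(chrom_ref=name, window_bp=window_bp, gc=gc)


def _domains_frame(domains) -> pd.DataFrame:
    rows = []
    for d in domains:
        rows.append(
            {
                "chrom": d.chrom,
                "start": d.start_bp,
                "end": d.end_bp,
                "gc": round(float(d.gc), 6),
                "gc_sigma": round(float(d.gc_sigma), 6),
                "homogeneity": d.homogeneity,
                "gc_class": d.gc_class if d.gc_class is not None else ".",
                "length_class": d.length_class if d.length_class is not None else ".",
            }
        )
    return pd.DataFrame(rows, columns=DOMAIN_COLUMNS)


def write_domains(domains, path: str | Path) -> None:
    """Write domains as a BED-like TSV (0-based half-open coordinates).

    Domains must be sorted and non-overlapping within each chromosome.
    Output is bit-stable given the same input.
    """
    df = _domains_frame(domains)
    for chrom, sub in df.groupby("chrom", sort=False):
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        if np.any(ends <= starts):
            raise ValueError(f"{chrom}: empty or inverted domain interval")
        if np.any(starts[1:] < ends[:-1]):
            raise ValueError(f"{chrom}: domains overlap or are unsorted")
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_domains(path: str | Path) -> pd.DataFrame:
    """Read a domain TSV written by :func:`write_domains`."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = set(DOMAIN_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"domain table {path} lacks columns: {sorted(missing)}")
    return df


def write_removed_runs(seqs: list[ChromosomeSequence], path: str | Path) -> None:
    """JSON sidecar mapping chromosome name -> removed (start, length) runs."""
    payload = {
        s.chrom_name: {
            "original_length": s.original_length,
            "removed_runs": [list(r) for r in s.removed_runs],
        }
        for s in seqs
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")
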