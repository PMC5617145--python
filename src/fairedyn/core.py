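"""Core genomic domain types.

Every coordinate in this package is 0-based half-open (BED convention).
VCF positions are converted on ingest; nothing downstream ever sees a
1-based coordinate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

VALID_STRANDS = ("+", "-", ".")


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval [start, end) on a named chromosome.

    The universal currency of the pipeline: peaks, fragments, TADs,
    gene bodies and regulatory domains are all intervals.
    """

    chrom: str
    start: int
    end: int
    name: str | None = None
    score: float | None = None
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"negative start {self.start} on {self.chrom}")
        if self.start >= self.end:
            raise ValueError(
                f"empty or inverted interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"strand must be one of {VALID_STRANDS}, got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def center(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_length(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


def merge_intervals(intervals: list[GenomicInterval]) -> list[GenomicInterval]:
    """Merge overlapping (or abutting) intervals into a disjoint sorted union."""
    by_pos = sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
    merged: list[GenomicInterval] = []
    for iv in by_pos:
        if merged and merged[-1].chrom == iv.chrom and iv.start <= merged[-1].end:
            last = merged[-1]
            if iv.end > last.end:
                merged[-1] = GenomicInterval(last.chrom, last.start, iv.end)
        else:
            merged.append(GenomicInterval(iv.chrom, iv.start, iv.end))
    return merged


@dataclass
class GenomeAssembly:
    """Chromosome sizes plus (optionally) the sequence itself."""

    chrom_sizes: dict[str, int]
    sequence: dict[str, str] | None = None

    def __post_init__(self) -> None:
        if self.sequence is not None:
            for chrom, seq in self.sequence.items():
                if chrom not in self.chrom_sizes:
                    raise ValueError(f"sequence for unknown chromosome {chrom}")
                if len(seq) != self.chrom_sizes[chrom]:
                    raise ValueError(
                        f"sequence length {len(seq)} != chrom_sizes[{chrom}] "
                        f"= {self.chrom_sizes[chrom]}"
                    )

    @property
    def total_length(self) -> int:
        return sum(self.chrom_sizes.values())

    def effective_length(self) -> int:
        """Total length minus N runs; the mappable-genome stand-in."""
        if self.sequence is None:
            return self.total_length
        n_count = sum(seq.count("N") for seq in self.sequence.values())
        return self.total_length - n_count

    def fetch(self, chrom: str, start: int, end: int) -> str:
        if self.sequence is None:
            raise ValueError("assembly has no sequence")
        if chrom not in self.sequence:
            raise KeyError(f"unknown chromosome {chrom}")
        if start < 0 or end > self.chrom_sizes[chrom]:
            raise ValueError(
                f"query {chrom}:{start}-{end} outside chromosome bounds "
                f"[0, {self.chrom_sizes[chrom]})"
            )
        return self.sequence[chrom][start:end]

    def check_interval(self, iv: GenomicInterval) -> None:
        if iv.chrom not in self.chrom_sizes:
            raise ValueError(f"interval on unknown chromosome {iv.chrom}")
        if iv.end > self.chrom_sizes[iv.chrom]:
            raise ValueError(
                f"interval {iv.chrom}:{iv.start}-{iv.end} exceeds chromosome "
                f"length {self.chrom_sizes[iv.chrom]}"
            )


@dataclass
class GeneModel:
    """A gene with a strand-aware transcription start site."""

    gene_id: str
    chrom: str
    tss: int
    strand: str
    body: GenomicInterval

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene strand must be + or -, got {self.strand!r}")
        if not (self.body.start <= self.tss < self.body.end):
            raise ValueError(
                f"TSS {self.tss} outside gene body "
                f"{self.body.chrom}:{self.body.start}-{self.body.end}"
            )
        if self.chrom != self.body.chrom:
            raise ValueError("gene chrom differs from body chrom")


class SignalTrack:
    """Dense per-chromosome non-negative signal, piecewise constant in spirit.

    Stored as one float array per chromosome for O(1) slicing; written out
    as run-length-compressed bedGraph.
    """

    def __init__(
        self,
        data: dict[str, np.ndarray],
        sample: str = "",
        total_fragments: int | None = None,
        normalized: bool = False,
    ):
        self.data = {c: np.asarray(v, dtype=float) for c, v in data.items()}
        for chrom, arr in self.data.items():
            if (arr < 0).any():
                raise ValueError(f"negative signal on {chrom}")
        self.sample = sample
        self.total_fragments = total_fragments
        self.normalized = normalized

    @classmethod
    def zeros(cls, chrom_sizes: dict[str, int], **kwargs) -> "SignalTrack":
        return cls({c: np.zeros(n) for c, n in chrom_sizes.items()}, **kwargs)

    def chrom_sizes(self) -> dict[str, int]:
        return {c: len(v) for c, v in self.data.items()}

    def values(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Signal over [start, end); positions outside the chromosome read 0."""
        arr = self.data[chrom]
        lo, hi = max(start, 0), min(end, len(arr))
        out = np.zeros(end - start)
        if hi > lo:
            out[lo - start : hi - start] = arr[lo:hi]
        return out
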