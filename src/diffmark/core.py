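"""Core genomic data containers.

All coordinates throughout the package are 0-based, half-open (BED
convention). GFF3 input is converted on read; nothing else ever sees
1-based coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

import numpy as np

__all__ = [
    "GenomicInterval",
    "ChromSizes",
    "CoverageTrack",
    "ValidationError",
]


class ValidationError(ValueError):
    """Raised when genomic data violates a structural invariant."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic interval [start, end) on ``chrom``."""

    chrom: str
    start: int
    end: int
    name: str | None = field(default=None, compare=False)
    strand: str = field(default=".", compare=False)

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValidationError("interval chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in ("+", "-", "."):
            raise ValidationError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlap_length(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def overlaps(self, other: "GenomicInterval") -> bool:
        return self.overlap_length(other) > 0


class ChromSizes(Mapping[str, int]):
    """Mapping chromosome name -> length in bp, with interval validation."""

    def __init__(self, sizes: Mapping[str, int]):
        for chrom, length in sizes.items():
            if not chrom:
                raise ValidationError("chrom name must be non-empty")
            if int(length) <= 0:
                raise ValidationError(f"chrom {chrom}: length must be > 0")
        self._sizes = {str(c): int(n) for c, n in sizes.items()}

    def __getitem__(self, chrom: str) -> int:
        return self._sizes[chrom]

    def __iter__(self) -> Iterator[str]:
        return iter(self._sizes)

    def __len__(self) -> int:
        return len(self._sizes)

    def __repr__(self) -> str:
        return f"ChromSizes({self._sizes!r})"

    def validate_interval(self, interval: GenomicInterval) -> None:
        if interval.chrom not in self._sizes:
            raise ValidationError(f"unknown chrom {interval.chrom!r}")
        if interval.end > self._sizes[interval.chrom]:
            raise ValidationError(
                f"interval {interval.chrom}:{interval.start}-{interval.end} "
                f"exceeds chrom length {self._sizes[interval.chrom]}"
            )


class CoverageTrack:
    """One sample's genome coverage as sorted, non-overlapping valued intervals.

    Per chromosome the track stores parallel numpy arrays (starts, ends,
    values). Gaps between records are implicit zero coverage, following
    bedGraph semantics. Values are real (not integer) so that normalized
    tracks reuse the container.
    """

    def __init__(
        self,
        data: Mapping[str, tuple[np.ndarray, np.ndarray, np.ndarray]],
        chrom_sizes: ChromSizes | None = None,
    ):
        self._data: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom, (starts, ends, values) in data.items():
            starts = np.asarray(starts, dtype=np.int64)
            ends = np.asarray(ends, dtype=np.int64)
            values = np.asarray(values, dtype=np.float64)
            if not (len(starts) == len(ends) == len(values)):
                raise ValidationError(f"{chrom}: ragged track arrays")
            if len(starts):
                if np.any(starts < 0) or np.any(ends <= starts):
                    raise ValidationError(f"{chrom}: require 0 <= start < end")
                if np.any(starts[1:] < ends[:-1]):
                    raise ValidationError(f"{chrom}: overlapping or unsorted records")
                if np.any(~np.isfinite(values)) or np.any(values < 0):
                    raise ValidationError(f"{chrom}: values must be finite and >= 0")
                if chrom_sizes is not None:
                    if chrom not in chrom_sizes:
                        raise ValidationError(f"unknown chrom {chrom!r}")
                    if ends[-1] > chrom_sizes[chrom]:
                        raise ValidationError(
                            f"{chrom}: record end {ends[-1]} exceeds chrom "
                            f"length {chrom_sizes[chrom]}"
                        )
            self._data[chrom] = (starts, ends, values)
        self.chrom_sizes = chrom_sizes

    @classmethod
    def from_records(
        cls,
        records: Iterable[tuple[str, int, int, float]],
        chrom_sizes: ChromSizes | None = None,
        sort: bool = False,
    ) -> "CoverageTrack":
        by_chrom: dict[str, list[tuple[int, int, float]]] = {}
        for chrom, start, end, value in records:
            by_chrom.setdefault(chrom, []).append((int(start), int(end), float(value)))
        data = {}
        for chrom, recs in by_chrom.items():
            if sort:
                recs = sorted(recs)
            starts, ends, values = (np.array(x) for x in zip(*recs))
            data[chrom] = (starts, ends, values)
        return cls(data, chrom_sizes)

    def chroms(self) -> list[str]:
        return list(self._data)

    def arrays(self, chrom: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return self._data[chrom]

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._data

    def records(self) -> Iterator[tuple[str, int, int, float]]:
        for chrom, (starts, ends, values) in self._data.items():
            for s, e, v in zip(starts, ends, values):
                yield chrom, int(s), int(e), float(v)

    def n_records(self) -> int:
        return sum(len(s) for s, _, _ in self._data.values())

    def total_value(self) -> float:
        """Sum of record values (library total in read-count units when
        records are per-segment read counts)."""
        return float(sum(values.sum() for _, _, values in self._data.values()))

    def mass(self) -> float:
        """Total coverage mass: sum of value x interval length."""
        return float(
            sum(((ends - starts) * values).sum() for starts, ends, values in self._data.values())
        )
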