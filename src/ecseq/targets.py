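"""Target space: the genomic intervals interrogated by the amplicon panel.

Coordinates are 0-based half-open internally (standard BED convention);
1-based coordinates appear only in VCF/pileup text output.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from intervaltree import IntervalTree

from .errors import ConfigurationError


@dataclass
class TargetSpace:
    """A merged set of (chrom, start, end) intervals with fast membership tests."""

    intervals: list[tuple[str, int, int]]
    name: str = "target"
    _trees: dict[str, IntervalTree] = field(init=False, repr=False, default_factory=dict)

    def __post_init__(self) -> None:
        for chrom, start, end in self.intervals:
            if end <= start:
                raise ConfigurationError(f"empty interval {chrom}:{start}-{end}")
        merged: list[tuple[str, int, int]] = []
        for chrom, start, end in sorted(self.intervals):
            if merged and merged[-1][0] == chrom and start <= merged[-1][2]:
                prev = merged[-1]
                merged[-1] = (chrom, prev[1], max(prev[2], end))
            else:
                merged.append((chrom, start, end))
        self.intervals = merged
        for chrom, start, end in merged:
            self._trees.setdefault(chrom, IntervalTree()).addi(start, end)

    @classmethod
    def from_bed(cls, path: str | Path, name: str | None = None) -> "TargetSpace":
        intervals = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                fields = line.split("\t")
                if len(fields) < 3:
                    raise ConfigurationError(f"malformed BED line: {line!r}")
                intervals.append((fields[0], int(fields[1]), int(fields[2])))
        return cls(intervals, name=name or Path(path).stem)

    def to_bed(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for chrom, start, end in self.intervals:
                fh.write(f"{chrom}\t{start}\t{end}\t{self.name}\n")

    def contains(self, chrom: str, pos: int) -> bool:
        """Whether 0-based position ``pos`` lies inside the target."""
        tree = self._trees.get(chrom)
        return bool(tree is not None and tree.overlaps_point(pos))

    @property
    def chroms(self) -> set[str]:
        return set(self._trees)

    @property
    def n_positions(self) -> int:
        return sum(end - start for _, start, end in self.intervals)

    def positions(self) -> Iterator[tuple[str, int]]:
        """Iterate every (chrom, 0-based position) in the target, sorted."""
        for chrom, start, end in self.intervals:
            for pos in range(start, end):
                yield chrom, pos

    def __iter__(self) -> Iterator[tuple[str, int, int]]:
        return iter(self.intervals)


def make_target(intervals: Iterable[tuple[str, int, int]], name: str = "target") -> TargetSpace:
    return TargetSpace(list(intervals), name=name)
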