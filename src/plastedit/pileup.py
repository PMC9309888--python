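"""Per-position RNA read pileups aligned against a genome.

Counts are reported on the plus strand of the genome; qualities are mean
Phred scores per base.  Insertions are anchored immediately *after* their
column's position.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .genome import DNA_BASES


@dataclass
class PileupColumn:
    position: int
    ref_base: str
    counts: dict[str, int]
    mean_phred: dict[str, float]
    insertions: list[tuple[str, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for b in DNA_BASES:
            self.counts.setdefault(b, 0)
            if self.counts[b] < 0:
                raise ValueError(f"negative count for {b} at {self.position}")
            if self.counts[b] > 0 and b not in self.mean_phred:
                raise ValueError(
                    f"missing quality for base {b} with count > 0 at {self.position}"
                )

    @property
    def coverage(self) -> int:
        return sum(self.counts[b] for b in DNA_BASES)


@dataclass
class Pileup:
    sequence_id: str
    columns: dict[int, PileupColumn] = field(default_factory=dict)

    def add(self, column: PileupColumn) -> None:
        if column.position in self.columns:
            raise ValueError(f"duplicate pileup position {column.position}")
        self.columns[column.position] = column

    def __iter__(self):
        return (self.columns[p] for p in sorted(self.columns))

    def __len__(self) -> int:
        return len(self.columns)

    def validate_against(self, genome_length: int) -> None:
        for p in self.columns:
            if not (1 <= p <= genome_length):
                raise ValueError(f"pileup position {p} outside 1..{genome_length}")
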