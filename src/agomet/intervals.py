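"""Genomic data model: intervals, tiling-array probes, promoters.

Coordinates are 0-based half-open (BED-compatible) everywhere. Distances
between features are measured center-to-center; a pair of features on
different chromosomes has infinite distance (a sentinel, never a number).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

STRANDS = ("+", "-", ".")

#: Sentinel returned for the distance between features on different chromosomes.
INFINITE_DISTANCE = math.inf

PROBE_LENGTH = 50
PROBES_PER_PROMOTER = 15


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic range ``[start, end)`` on one chromosome.

    ``strand`` is ``+``, ``-`` or ``.`` (unstranded); ``assembly`` is a
    free-text genome-build tag such as ``hg17``, ``hg18`` or ``synth1``.
    """

    chrom: str
    start: int
    end: int
    strand: str = "."
    assembly: str = ""

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}): require 0 <= start < end"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}, got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def center(self) -> int:
        return interval_center(self)

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


def interval_center(interval: GenomicInterval) -> int:
    """Center of an interval in bp: ``floor((start + end) / 2)``.

    For an odd-length range the center is the floor of the midpoint, which
    keeps all arithmetic in integer base pairs.
    """
    return (interval.start + interval.end) // 2


def center_distance(a: GenomicInterval, b: GenomicInterval) -> float:
    """Distance between the centers of two ranges, in bp.

    Returns :data:`INFINITE_DISTANCE` when the intervals lie on different
    chromosomes — cross-chromosome pairs are never "in proximity".
    """
    if a.chrom != b.chrom:
        return INFINITE_DISTANCE
    return abs(interval_center(a) - interval_center(b))


@dataclass(frozen=True)
class Probe:
    """One 50-bp methylation probe of a promoter tiling array."""

    interval: GenomicInterval
    probe_index: int  # 1-based position within the promoter tile, 1..15
    methylation: float
    promoter_id: str

    def __post_init__(self) -> None:
        if self.interval.length != PROBE_LENGTH:
            raise ValueError(
                f"probe {self.promoter_id}/{self.probe_index}: length "
                f"{self.interval.length} != {PROBE_LENGTH}"
            )
        if not (1 <= self.probe_index <= PROBES_PER_PROMOTER):
            raise ValueError(f"probe_index must be in 1..{PROBES_PER_PROMOTER}")
        if not math.isfinite(self.methylation) or self.methylation < 0:
            raise ValueError("methylation must be finite and >= 0")


@dataclass(frozen=True)
class Promoter:
    """A promoter tile: exactly 15 ordered, non-overlapping 50-bp probes.

    The promoter boundary is the region from the start of probe 1 to the end
    of probe 15; promoter-level methylation is summarized over all 15 probes.
    """

    promoter_id: str
    gene: str
    tss: int
    strand: str
    probes: tuple[Probe, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError("promoter strand must be '+' or '-'")
        if len(self.probes) != PROBES_PER_PROMOTER:
            raise ValueError(
                f"promoter {self.promoter_id}: expected {PROBES_PER_PROMOTER} "
                f"probes, got {len(self.probes)}"
            )
        chroms = {p.interval.chrom for p in self.probes}
        if len(chroms) != 1:
            raise ValueError(f"promoter {self.promoter_id}: probes span chromosomes")
        idx = [p.probe_index for p in self.probes]
        if idx != list(range(1, PROBES_PER_PROMOTER + 1)):
            raise ValueError(
                f"promoter {self.promoter_id}: probe indices must be 1..15 in order"
            )
        for prev, cur in zip(self.probes, self.probes[1:]):
            if cur.interval.start < prev.interval.end:
                raise ValueError(
                    f"promoter {self.promoter_id}: probes overlap or are unordered"
                )

    @property
    def chrom(self) -> str:
        return self.probes[0].interval.chrom

    @property
    def boundary(self) -> GenomicInterval:
        """Region between the first and the 15th (last) probe."""
        return GenomicInterval(
            chrom=self.chrom,
            start=self.probes[0].interval.start,
            end=self.probes[-1].interval.end,
            strand=self.strand,
            assembly=self.probes[0].interval.assembly,
        )

    @property
    def methylation_sum(self) -> float:
        return float(sum(p.methylation for p in self.probes))

    @property
    def methylation_mean(self) -> float:
        return self.methylation_sum / len(self.probes)


def promoters_from_table(
    probe_table,
    tss_table=None,
    assembly: str = "",
) -> list[Promoter]:
    """Build validated :class:`Promoter` objects from a probe table.

    ``probe_table`` is a DataFrame with columns promoter_id, gene,
    probe_index, chrom, start, end, strand, methylation. ``tss_table``
    (optional) carries promoter_id, tss; without it the TSS falls back to the
    boundary edge on the 5' side of the gene.
    """
    tss_map = {}
    if tss_table is not None:
        tss_map = dict(zip(tss_table["promoter_id"], tss_table["tss"]))
    promoters = []
    for pid, grp in probe_table.groupby("promoter_id", sort=True):
        grp = grp.sort_values("probe_index")
        probes = tuple(
            Probe(
                interval=GenomicInterval(
                    chrom=row.chrom,
                    start=int(row.start),
                    end=int(row.end),
                    strand=row.strand,
                    assembly=assembly,
                ),
                probe_index=int(row.probe_index),
                methylation=float(row.methylation),
                promoter_id=str(pid),
            )
            for row in grp.itertuples()
        )
        strand = grp["strand"].iloc[0]
        if pid in tss_map:
            tss = int(tss_map[pid])
        else:
            tss = int(grp["start"].min()) if strand == "+" else int(grp["end"].max())
        promoters.append(
            Promoter(
                promoter_id=str(pid),
                gene=str(grp["gene"].iloc[0]),
                tss=tss,
                strand=strand,
                probes=probes,
            )
        )
    return promoters
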