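"""CLIP mapped-read ingest: multimapper filtering and binding-site calling.

A binding site is simply a mapped read location — no peak calling or cluster
merging. Reads mapping to more than ``max_locations`` (default 30) genomic
locations are discarded as likely repeat-derived. Each location is classified
``perfect`` (zero mismatches/insertions/deletions) or ``approximate``
(anything else); the ``include_approximate`` site mode is a superset that
keeps perfect locations too, while ``perfect_only`` keeps only perfect ones.
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import pandas as pd

from .intervals import GenomicInterval
from . import io

MAX_LOCATIONS_DEFAULT = 30
MIN_LENGTH_DEFAULT = 15
#: Binding-length sweep, bp (default threshold 15 highlighted in analyses).
MIN_LENGTH_SWEEP = (1, 5, 10, 15, 20, 25)

MatchClass = Literal["perfect", "approximate"]
MatchMode = Literal["perfect_only", "include_approximate"]

_LABEL_RE = re.compile(r"^\S+$")


def validate_protein_label(label: str) -> str:
    """Protein labels are open-ended (AGO1-4, PUMILIO2, ...) but must be a
    single non-empty token."""
    if not isinstance(label, str) or not _LABEL_RE.match(label):
        raise ValueError(f"invalid protein label: {label!r}")
    return label


@dataclass(frozen=True)
class EditCounts:
    mismatches: int
    insertions: int
    deletions: int

    def __post_init__(self) -> None:
        if min(self.mismatches, self.insertions, self.deletions) < 0:
            raise ValueError("edit counts must be >= 0")

    @property
    def is_perfect(self) -> bool:
        return self.mismatches == self.insertions == self.deletions == 0


@dataclass(frozen=True)
class MappedRead:
    """One sequenced RNA with its genomic mapping locations.

    ``copies`` is the sequenced copy count; ``edits[i]`` gives the
    mismatch/insertion/deletion counts of ``locations[i]``.
    """

    read_id: str
    sequence: str
    copies: int
    locations: tuple[GenomicInterval, ...]
    edits: tuple[EditCounts, ...]

    def __post_init__(self) -> None:
        if self.copies < 1:
            raise ValueError("copies must be >= 1")
        if not self.locations:
            raise ValueError("locations must be non-empty")
        if len(self.locations) != len(self.edits):
            raise ValueError("edits must align one-to-one with locations")


@dataclass(frozen=True)
class BindingSite:
    interval: GenomicInterval
    ago: str
    match_class: MatchClass
    support: int

    @property
    def length(self) -> int:
        return self.interval.length


def reads_from_tables(mapped: pd.DataFrame, mappings: pd.DataFrame,
                      assembly: str = "") -> list[MappedRead]:
    """Join the two-file CLIP dialect into :class:`MappedRead` records."""
    seq_info = mapped.set_index("read_id")
    reads: list[MappedRead] = []
    for read_id, grp in mappings.groupby("read_id", sort=True):
        if read_id not in seq_info.index:
            raise ValueError(f"mapping for unknown read {read_id!r}")
        row = seq_info.loc[read_id]
        locs = tuple(
            GenomicInterval(chrom=m.chrom, start=int(m.start), end=int(m.end),
                            strand=m.strand, assembly=assembly)
            for m in grp.itertuples()
        )
        edits = tuple(
            EditCounts(int(m.mismatches), int(m.insertions), int(m.deletions))
            for m in grp.itertuples()
        )
        reads.append(
            MappedRead(read_id=str(read_id), sequence=str(row["sequence"]),
                       copies=int(row["copies"]), locations=locs, edits=edits)
        )
    return reads


def read_clip_pair(mapped_path, mappings_path, assembly: str = "") -> list[MappedRead]:
    return reads_from_tables(
        io.read_clipz_mapped(mapped_path), io.read_clipz_mappings(mappings_path),
        assembly=assembly,
    )


def filter_multimappers(
    reads: Sequence[MappedRead], max_locations: int = MAX_LOCATIONS_DEFAULT
) -> tuple[list[MappedRead], int]:
    """Drop reads mapping to more than ``max_locations`` genomic locations.

    Returns ``(retained_reads, n_removed)``. A read with exactly
    ``max_locations`` locations is retained (the cutoff is ``> max``).
    """
    if max_locations < 1:
        raise ValueError("max_locations must be >= 1")
    kept = [r for r in reads if len(r.locations) <= max_locations]
    return kept, len(reads) - len(kept)


def classify_match(read: MappedRead, location_index: int) -> MatchClass:
    """'perfect' iff the location has zero mismatches, insertions and
    deletions; 'approximate' otherwise."""
    return "perfect" if read.edits[location_index].is_perfect else "approximate"


def reads_to_sites(
    reads: Sequence[MappedRead],
    ago: str,
    min_length: int = MIN_LENGTH_DEFAULT,
    match_mode: MatchMode = "include_approximate",
) -> list[BindingSite]:
    """Turn read locations into binding sites.

    One candidate site per retained read location; locations shorter than
    ``min_length`` are dropped. ``perfect_only`` keeps only perfectly matched
    locations; ``include_approximate`` keeps all locations (a superset that
    includes the perfect ones). Identical intervals are aggregated, with
    support = sum of the copy counts of the supporting reads; an aggregated
    site is 'perfect' only if every supporting location is.
    """
    validate_protein_label(ago)
    if min_length < 1:
        raise ValueError("min_length must be >= 1")
    if match_mode not in ("perfect_only", "include_approximate"):
        raise ValueError(f"unknown match_mode {match_mode!r}")
    agg: dict[GenomicInterval, list[int]] = {}  # interval -> [support, n_approx]
    for read in reads:
        for i, loc in enumerate(read.locations):
            perfect = read.edits[i].is_perfect
            if match_mode == "perfect_only" and not perfect:
                continue
            if loc.length < min_length:
                continue
            entry = agg.setdefault(loc, [0, 0])
            entry[0] += read.copies
            entry[1] += 0 if perfect else 1
    sites = [
        BindingSite(
            interval=iv, ago=ago,
            match_class="perfect" if n_approx == 0 else "approximate",
            support=support,
        )
        for iv, (support, n_approx) in agg.items()
    ]
    sites.sort(key=lambda s: (s.interval.chrom, s.interval.start, s.interval.end,
                              s.interval.strand))
    return sites


def sites_to_frame(sites: Iterable[BindingSite]) -> pd.DataFrame:
    """Tabular form used by the association layer and the BED6 writer."""
    rows = [
        {
            "chrom": s.interval.chrom, "start": s.interval.start,
            "end": s.interval.end, "name": s.ago, "score": s.support,
            "strand": s.interval.strand, "match_class": s.match_class,
        }
        for s in sites
    ]
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "name", "score", "strand",
                       "match_class"],
    )
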