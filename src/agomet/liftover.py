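"""UCSC chain-file parsing and interval liftover between genome assemblies.

A chain records a gapped alignment between a *source* assembly (the ``t``
side of the chain header, the build the input coordinates are in — e.g. hg17
in an hg17→hg18 over.chain) and a *target* assembly (the ``q`` side). An
interval lifts over only when it lies wholly inside one aligned block of one
chain; an interval that straddles an alignment gap, or that no block covers,
is reported as unmapped rather than truncated — matching the reject behavior
of the UCSC liftOver tool.

Chain format (public UCSC spec):

    chain score tName tSize tStrand tStart tEnd qName qSize qStrand qStart qEnd id
    size dt dq
    ...
    size

Block coordinates on a ``-`` strand count from the far end of the sequence;
mapped intervals are always re-expressed on the forward strand of the target,
with the feature's strand field flipped for reverse-strand chains.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

from .intervals import GenomicInterval


@dataclass(frozen=True)
class AlignedBlock:
    """One ungapped block in absolute strand-local coordinates."""

    t_start: int
    q_start: int
    size: int

    @property
    def t_end(self) -> int:
        return self.t_start + self.size

    @property
    def q_end(self) -> int:
        return self.q_start + self.size


@dataclass
class Chain:
    score: int
    t_name: str
    t_size: int
    t_strand: str
    t_start: int
    t_end: int
    q_name: str
    q_size: int
    q_strand: str
    q_start: int
    q_end: int
    chain_id: str
    blocks: list[AlignedBlock] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.t_strand != "+":
            raise ValueError("chain tStrand must be '+' (UCSC convention)")
        if self.q_strand not in ("+", "-"):
            raise ValueError("chain qStrand must be '+' or '-'")
        prev_t = prev_q = -1
        t_span = q_span = 0
        for b in self.blocks:
            if b.t_start < prev_t or b.q_start < prev_q:
                raise ValueError("chain blocks overlap or are unordered")
            prev_t, prev_q = b.t_end, b.q_end
            t_span, q_span = b.t_end, b.q_end
        if self.blocks:
            if self.blocks[0].t_start != self.t_start or t_span != self.t_end:
                raise ValueError("chain blocks do not tile the stated source span")
            if self.blocks[0].q_start != self.q_start or q_span != self.q_end:
                raise ValueError("chain blocks do not tile the stated target span")


@dataclass
class ChainFile:
    """An ordered collection of chains (highest score first, as UCSC emits)."""

    chains: list[Chain]
    source_assembly: str = ""
    target_assembly: str = ""


@dataclass(frozen=True)
class LiftoverResult:
    mapped: Optional[GenomicInterval]
    reason: str = ""  # empty on success; 'gap', 'unmapped_chrom', 'outside_blocks'

    @property
    def ok(self) -> bool:
        return self.mapped is not None


def parse_chain_text(text: str, source_assembly: str = "", target_assembly: str = "") -> ChainFile:
    chains: list[Chain] = []
    lines = iter(text.splitlines())
    for line in lines:
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split()
        if fields[0] != "chain":
            raise ValueError(f"expected 'chain' header, got: {line!r}")
        if len(fields) < 12:
            raise ValueError(f"malformed chain header: {line!r}")
        (score, t_name, t_size, t_strand, t_start, t_end,
         q_name, q_size, q_strand, q_start, q_end) = fields[1:12]
        chain_id = fields[12] if len(fields) > 12 else ""
        blocks: list[AlignedBlock] = []
        t_pos, q_pos = int(t_start), int(q_start)
        for body in lines:
            body = body.strip()
            if not body:
                break
            parts = [int(x) for x in body.split()]
            size = parts[0]
            blocks.append(AlignedBlock(t_start=t_pos, q_start=q_pos, size=size))
            if len(parts) == 1:  # terminal line: just the last block size
                break
            dt, dq = parts[1], parts[2]
            t_pos += size + dt
            q_pos += size + dq
        chains.append(
            Chain(
                score=int(score), t_name=t_name, t_size=int(t_size),
                t_strand=t_strand, t_start=int(t_start), t_end=int(t_end),
                q_name=q_name, q_size=int(q_size), q_strand=q_strand,
                q_start=int(q_start), q_end=int(q_end), chain_id=chain_id,
                blocks=blocks,
            )
        )
    chains.sort(key=lambda c: -c.score)
    return ChainFile(chains=chains, source_assembly=source_assembly,
                     target_assembly=target_assembly)


def read_chain_file(path, source_assembly: str = "", target_assembly: str = "") -> ChainFile:
    return parse_chain_text(Path(path).read_text(), source_assembly, target_assembly)


def chain_to_text(chain: Chain) -> str:
    header = (
        f"chain {chain.score} {chain.t_name} {chain.t_size} {chain.t_strand} "
        f"{chain.t_start} {chain.t_end} {chain.q_name} {chain.q_size} "
        f"{chain.q_strand} {chain.q_start} {chain.q_end} {chain.chain_id}".rstrip()
    )
    lines = [header]
    for i, b in enumerate(chain.blocks):
        if i == len(chain.blocks) - 1:
            lines.append(f"{b.size}")
        else:
            nxt = chain.blocks[i + 1]
            dt = nxt.t_start - b.t_end
            dq = nxt.q_start - b.q_end
            lines.append(f"{b.size} {dt} {dq}")
    return "\n".join(lines) + "\n\n"


def write_chain_file(chain_file: ChainFile, path) -> None:
    Path(path).write_text("".join(chain_to_text(c) for c in chain_file.chains))


_FLIP = {"+": "-", "-": "+", ".": "."}


def liftover_interval(interval: GenomicInterval, chain_file: ChainFile) -> LiftoverResult:
    """Map an interval to the target assembly through a chain file.

    Both endpoints must fall inside the same aligned block of the same chain
    (which preserves interval length); otherwise the interval is unmapped
    with a reason code. Chains are tried in descending score order.
    """
    if chain_file.source_assembly and interval.assembly and \
            interval.assembly != chain_file.source_assembly:
        raise ValueError(
            f"interval assembly {interval.assembly!r} does not match chain "
            f"source {chain_file.source_assembly!r}"
        )
    saw_chrom = False
    saw_gap = False
    for chain in chain_file.chains:
        if chain.t_name != interval.chrom:
            continue
        saw_chrom = True
        if interval.end <= chain.t_start or interval.start >= chain.t_end:
            continue
        for b in chain.blocks:
            if b.t_start <= interval.start and interval.end <= b.t_end:
                q_lo = b.q_start + (interval.start - b.t_start)
                q_hi = q_lo + interval.length
                if chain.q_strand == "-":
                    # re-express on the forward strand of the target
                    start = chain.q_size - q_hi
                    end = chain.q_size - q_lo
                    strand = _FLIP[interval.strand]
                else:
                    start, end = q_lo, q_hi
                    strand = interval.strand
                return LiftoverResult(
                    mapped=GenomicInterval(
                        chrom=chain.q_name, start=start, end=end, strand=strand,
                        assembly=chain_file.target_assembly or chain.q_name.split(".")[0],
                    )
                )
        # overlapped the chain span but no single block contains it
        saw_gap = True
    if saw_gap:
        return LiftoverResult(mapped=None, reason="gap")
    if saw_chrom:
        return LiftoverResult(mapped=None, reason="outside_blocks")
    return LiftoverResult(mapped=None, reason="unmapped_chrom")


def liftover_intervals(
    intervals: Iterable[GenomicInterval], chain_file: ChainFile
) -> tuple[list[GenomicInterval], list[tuple[GenomicInterval, str]]]:
    """Lift a collection; returns (mapped, [(unmapped_interval, reason), ...]).

    Unmapped intervals are reported, never dropped silently.
    """
    mapped: list[GenomicInterval] = []
    unmapped: list[tuple[GenomicInterval, str]] = []
    for iv in intervals:
        res = liftover_interval(iv, chain_file)
        if res.ok:
            mapped.append(res.mapped)
        else:
            unmapped.append((iv, res.reason))
    return mapped, unmapped
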