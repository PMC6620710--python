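"""COBRA band-intensity quantification of global LINE-1 and Alu methylation.

Combined bisulfite restriction analysis (COBRA) digests bisulfite-PCR
products of interspersed repeats with methylation-discriminating enzymes and
reads methylation off the gel band pattern. Each amplicon molecule carries
two informative CpG sites, so the assay resolves fully methylated, singly
(hemi-) methylated and unmethylated molecules into distinct fragment sizes.

For a lane, each counted band intensity is first divided by an
assay-specific effective fragment length, giving molar-equivalent
components A-F, and the methylation percentage follows from a fixed linear
combination of those components:

LINE-1 (bands 92/60/50/42/32 bp):
    A = I(92)/92, B = I(60)/56, C = I(50)/48, D = I(42)/40, E = I(32)/28,
    F = [(D + E) - (B + C)] / 2
    percent = (A + 2C + F) * 100 / (2A + 2B + 2C + 2F)

Alu (bands 133/90/75/58/43 bp; note the letter order):
    A = I(133)/133, B = I(58)/58, C = I(75)/75, D = I(90)/90, E = I(43)/43,
    F = [(E + B) - (C + D)] / 2
    percent = (2F + D + C) * 100 / (2A + 2C + 2D + 2F)

Both estimators are scale-invariant in the lane intensities and, under the
molar forward model implemented in :mod:`agomet.synth`, return exactly the
true methylated-CpG fraction of the molecule population.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Literal

import numpy as np
import pandas as pd

Assay = Literal["LINE1", "ALU"]

LINE1_SIZES = (92, 60, 50, 42, 32)
ALU_SIZES = (133, 90, 75, 58, 43)

#: band size -> divisor (effective length) used in the normalization
LINE1_DIVISORS = {92: 92, 60: 56, 50: 48, 42: 40, 32: 28}
ALU_DIVISORS = {133: 133, 90: 90, 75: 75, 58: 58, 43: 43}

#: band size feeding each lettered component, per assay
LINE1_LETTERS = {"A": 92, "B": 60, "C": 50, "D": 42, "E": 32}
ALU_LETTERS = {"A": 133, "B": 58, "C": 75, "D": 90, "E": 43}


@dataclass(frozen=True)
class GelLane:
    """Band-size -> intensity map for one COBRA lane."""

    assay: Assay
    bands: dict[int, float]
    replicate_id: str = ""

    def __post_init__(self) -> None:
        allowed = set(LINE1_SIZES if self.assay == "LINE1" else ALU_SIZES)
        if self.assay not in ("LINE1", "ALU"):
            raise ValueError(f"unknown assay {self.assay!r}")
        unknown = set(self.bands) - allowed
        if unknown:
            raise ValueError(
                f"{self.assay} lane has unknown band sizes {sorted(unknown)}; "
                f"allowed: {sorted(allowed)}"
            )
        for size, intensity in self.bands.items():
            if not math.isfinite(intensity) or intensity < 0:
                raise ValueError(f"band {size}: intensity must be finite and >= 0")

    @property
    def missing_bands(self) -> tuple[int, ...]:
        sizes = LINE1_SIZES if self.assay == "LINE1" else ALU_SIZES
        return tuple(s for s in sizes if s not in self.bands)

    def intensity(self, size: int) -> float:
        return float(self.bands.get(size, 0.0))


@dataclass(frozen=True)
class MethylationEstimate:
    percent: float  # NaN when the denominator is zero
    components: dict[str, float]  # A..F in molar-equivalent units
    assay: Assay
    replicate_id: str = ""
    out_of_range: bool = False  # percent outside [0, 100] (reported, not clamped)
    undefined: bool = False
    missing_bands: tuple[int, ...] = ()


def normalize_lane(lane: GelLane) -> dict[str, float]:
    """Molar-equivalent components A..F of a lane.

    Each counted band intensity is divided by its assay divisor; a missing
    band contributes intensity 0 (reported via ``GelLane.missing_bands``).
    F combines the components to isolate the doubly-cut molecules.
    """
    if lane.assay == "LINE1":
        letters, divisors = LINE1_LETTERS, LINE1_DIVISORS
    else:
        letters, divisors = ALU_LETTERS, ALU_DIVISORS
    comp = {L: lane.intensity(size) / divisors[size] for L, size in letters.items()}
    if lane.assay == "LINE1":
        comp["F"] = ((comp["D"] + comp["E"]) - (comp["B"] + comp["C"])) / 2
    else:
        comp["F"] = ((comp["E"] + comp["B"]) - (comp["C"] + comp["D"])) / 2
    return comp


def _estimate(lane: GelLane, numerator: float, denominator: float,
              comp: dict[str, float]) -> MethylationEstimate:
    if denominator == 0:
        return MethylationEstimate(
            percent=float("nan"), components=comp, assay=lane.assay,
            replicate_id=lane.replicate_id, undefined=True,
            missing_bands=lane.missing_bands,
        )
    percent = numerator * 100.0 / denominator
    return MethylationEstimate(
        percent=percent, components=comp, assay=lane.assay,
        replicate_id=lane.replicate_id,
        out_of_range=not (0.0 <= percent <= 100.0),
        missing_bands=lane.missing_bands,
    )


def line1_methylation(lane: GelLane) -> MethylationEstimate:
    """LINE-1 methylation %: (A + 2C + F) * 100 / (2A + 2B + 2C + 2F)."""
    if lane.assay != "LINE1":
        raise ValueError("lane is not a LINE1 assay")
    comp = normalize_lane(lane)
    num = comp["A"] + 2 * comp["C"] + comp["F"]
    den = 2 * comp["A"] + 2 * comp["B"] + 2 * comp["C"] + 2 * comp["F"]
    return _estimate(lane, num, den, comp)


def alu_methylation(lane: GelLane) -> MethylationEstimate:
    """Alu methylation %: (2F + D + C) * 100 / (2A + 2C + 2D + 2F)."""
    if lane.assay != "ALU":
        raise ValueError("lane is not an ALU assay")
    comp = normalize_lane(lane)
    num = 2 * comp["F"] + comp["D"] + comp["C"]
    den = 2 * comp["A"] + 2 * comp["C"] + 2 * comp["D"] + 2 * comp["F"]
    return _estimate(lane, num, den, comp)


def estimate_lane(lane: GelLane) -> MethylationEstimate:
    return line1_methylation(lane) if lane.assay == "LINE1" else alu_methylation(lane)


def lanes_from_table(table: pd.DataFrame, clamp_negative: bool = True
                     ) -> list[GelLane]:
    """Build lanes from the long-format lane TSV (replicate_id, assay,
    band_size, intensity). Negative intensities (over-subtracted background)
    are clamped to 0 with a warning when ``clamp_negative``."""
    lanes = []
    for (rep, assay), grp in table.groupby(["replicate_id", "assay"], sort=True):
        bands = {}
        for row in grp.itertuples():
            val = float(row.intensity)
            if val < 0:
                if not clamp_negative:
                    raise ValueError(
                        f"lane {rep}/{assay}: negative intensity at "
                        f"{row.band_size} bp"
                    )
                import warnings

                warnings.warn(
                    f"lane {rep}/{assay}: negative intensity at "
                    f"{row.band_size} bp clamped to 0"
                )
                val = 0.0
            bands[int(row.band_size)] = val
        lanes.append(GelLane(assay=str(assay), bands=bands, replicate_id=str(rep)))
    return lanes


def estimates_to_frame(estimates: Iterable[MethylationEstimate]) -> pd.DataFrame:
    rows = []
    for e in estimates:
        row = {"replicate_id": e.replicate_id, "assay": e.assay,
               "percent": e.percent}
        row.update(e.components)
        row["out_of_range"] = e.out_of_range
        row["undefined"] = e.undefined
        row["missing_bands"] = ",".join(map(str, e.missing_bands))
        rows.append(row)
    return pd.DataFrame(rows)


def ddct_fold_change(
    ct_target_case: float,
    ct_reference_case: float,
    ct_target_control: float,
    ct_reference_control: float,
) -> float:
    """Relative qPCR quantity by the delta-delta-CT method:
    2 ** -((ct_t,case - ct_ref,case) - (ct_t,control - ct_ref,control))."""
    for v in (ct_target_case, ct_reference_case, ct_target_control,
              ct_reference_control):
        if not math.isfinite(v):
            raise ValueError("CT values must be finite")
    ddct = (ct_target_case - ct_reference_case) - (
        ct_target_control - ct_reference_control
    )
    return float(2.0 ** (-ddct))


def ddct_table(ct: pd.DataFrame) -> pd.DataFrame:
    out = ct.copy()
    out["fold_change"] = [
        ddct_fold_change(r.ct_target_case, r.ct_reference_case,
                         r.ct_target_control, r.ct_reference_control)
        for r in ct.itertuples()
    ]
    return out
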