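"""Colocalization statistics linking probe methylation to protein binding.

The central object is a 2x2 contingency table over methylation probes::

                 MET+            MET-
    AGO+          a               b
    AGO-          c               d

MET+/- dichotomizes the continuous probe methylation value (median split by
default, or an absolute threshold); AGO+ marks probes whose center lies
within ``d_max`` bp of the center of at least one binding site. The table
yields an odds ratio ad/(bc), a 95% Wald confidence interval on ln OR, and a
Pearson chi-square (1 df) p-value. When any cell is zero the
Haldane–Anscombe correction (add 0.5 to every cell) is applied to the OR and
CI — never to the chi-square — and flagged.

Promoter-level association is the Pearson correlation between the number of
binding sites overlapping a promoter boundary and the promoter's methylation
summary (sum of its 15 probe values by default).
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import INFINITE_DISTANCE

D_MAX_DEFAULT = 500
#: Proximity-distance sweep (bp) for the contingency analysis and Fig-style profiles.
D_MAX_SWEEP = (50, 100, 200, 500, 1000)


# ---------------------------------------------------------------------------
# contingency machinery

@dataclass(frozen=True)
class ContingencyTable:
    """Probe counts: a = MET+ & AGO+, b = MET- & AGO+, c = MET+ & AGO-,
    d = MET- & AGO-."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be >= 0")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def has_zero_cell(self) -> bool:
        return min(self.a, self.b, self.c, self.d) == 0

    @property
    def has_degenerate_margin(self) -> bool:
        return (
            self.a + self.b == 0 or self.c + self.d == 0
            or self.a + self.c == 0 or self.b + self.d == 0
        )


@dataclass(frozen=True)
class AssociationResult:
    odds_ratio: float
    ci_low: float
    ci_high: float
    chi_square: float  # NaN when a margin is degenerate
    p_value: float     # NaN when chi-square undefined
    continuity_note: bool  # True when the 0.5 zero-cell correction was applied
    table: ContingencyTable


def build_contingency(met: np.ndarray, ago: np.ndarray) -> ContingencyTable:
    """Cross-tabulate boolean MET+ and AGO+ labels into the 2x2 table.

    Every classified probe lands in exactly one cell.
    """
    met = np.asarray(met, dtype=bool)
    ago = np.asarray(ago, dtype=bool)
    if met.shape != ago.shape:
        raise ValueError("met and ago label arrays must align")
    return ContingencyTable(
        a=int(np.sum(met & ago)),
        b=int(np.sum(~met & ago)),
        c=int(np.sum(met & ~ago)),
        d=int(np.sum(~met & ~ago)),
    )


def association_stats(table: ContingencyTable, z: float = 1.959963984540054
                      ) -> AssociationResult:
    """OR, 95% CI and chi-square p for one table.

    chi-square is the uncorrected (no Yates continuity) Pearson statistic
    n(ad-bc)^2 / ((a+b)(c+d)(a+c)(b+d)) on the raw cells; its p-value is the
    upper tail of chi-square with 1 df. The OR and Wald CI use the raw cells,
    or all four cells + 0.5 when any cell is zero (flagged).
    """
    if table.n < 1:
        raise ValueError("empty table")
    corrected = table.has_zero_cell
    a, b, c, d = (float(x) + (0.5 if corrected else 0.0)
                  for x in (table.a, table.b, table.c, table.d))
    odds_ratio = (a * d) / (b * c)
    log_or = math.log(odds_ratio)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    ci_low = math.exp(log_or - z * se)
    ci_high = math.exp(log_or + z * se)
    if table.has_degenerate_margin:
        chi2 = float("nan")
        p = float("nan")
    else:
        ra, rb, rc, rd = (float(x) for x in (table.a, table.b, table.c, table.d))
        n = ra + rb + rc + rd
        chi2 = (n * (ra * rd - rb * rc) ** 2
                / ((ra + rb) * (rc + rd) * (ra + rc) * (rb + rd)))
        p = float(stats.chi2.sf(chi2, df=1))
    return AssociationResult(
        odds_ratio=odds_ratio, ci_low=ci_low, ci_high=ci_high,
        chi_square=chi2, p_value=p, continuity_note=corrected, table=table,
    )


# ---------------------------------------------------------------------------
# probe labeling

@dataclass(frozen=True)
class DichotomyInfo:
    rule: str
    cutoff: float
    n_met_pos: int
    n_met_neg: int
    all_identical: bool = False


def dichotomize_methylation(
    values: np.ndarray,
    rule: Literal["median", "threshold"] = "median",
    threshold: Optional[float] = None,
) -> tuple[np.ndarray, DichotomyInfo]:
    """Label probes MET+ / MET-.

    median rule: MET+ iff value > median of all classified probes (ties at
    the median go to MET-). threshold rule: MET+ iff value > ``threshold``.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("no probes to dichotomize")
    if not np.all(np.isfinite(values)):
        raise ValueError("methylation values must be finite")
    if rule == "median":
        cutoff = float(np.median(values))
    elif rule == "threshold":
        if threshold is None:
            raise ValueError("threshold rule requires a threshold value")
        cutoff = float(threshold)
    else:
        raise ValueError(f"unknown dichotomization rule {rule!r}")
    labels = values > cutoff
    all_identical = bool(np.all(values == values[0]))
    info = DichotomyInfo(
        rule=rule, cutoff=cutoff,
        n_met_pos=int(labels.sum()), n_met_neg=int((~labels).sum()),
        all_identical=all_identical,
    )
    return labels, info


def _centers(df: pd.DataFrame) -> np.ndarray:
    return (df["start"].to_numpy(np.int64) + df["end"].to_numpy(np.int64)) // 2


def nearest_site_distance(probes: pd.DataFrame, sites: pd.DataFrame) -> np.ndarray:
    """Per-probe distance (bp) from the probe center to the nearest site
    center on the same chromosome; inf when no site shares the chromosome."""
    out = np.full(len(probes), INFINITE_DISTANCE, dtype=float)
    if len(sites) == 0 or len(probes) == 0:
        return out
    probe_centers = _centers(probes)
    for chrom, site_grp in sites.groupby("chrom", sort=False):
        mask = (probes["chrom"] == chrom).to_numpy()
        if not mask.any():
            continue
        sc = np.sort(_centers(site_grp))
        pc = probe_centers[mask]
        idx = np.searchsorted(sc, pc)
        left = np.where(idx > 0, np.abs(pc - sc[np.maximum(idx - 1, 0)]),
                        np.inf)
        right = np.where(idx < len(sc), np.abs(sc[np.minimum(idx, len(sc) - 1)] - pc),
                         np.inf)
        out[mask] = np.minimum(left, right)
    return out


def label_probes_by_proximity(
    probes: pd.DataFrame, sites: pd.DataFrame, d_max: float = D_MAX_DEFAULT
) -> np.ndarray:
    """AGO+ iff the nearest site center is within ``d_max`` bp of the probe
    center. Each probe is labeled exactly once regardless of how many sites
    are near; with no sites every probe is AGO-."""
    if d_max < 0:
        raise ValueError("d_max must be >= 0")
    return nearest_site_distance(probes, sites) <= d_max


# ---------------------------------------------------------------------------
# promoter-level operations

def _overlap_counts(boundaries: pd.DataFrame, sites: pd.DataFrame) -> np.ndarray:
    """Number of sites overlapping each boundary interval (half-open)."""
    out = np.zeros(len(boundaries), dtype=np.int64)
    if len(sites) == 0:
        return out
    for chrom, site_grp in sites.groupby("chrom", sort=False):
        mask = (boundaries["chrom"] == chrom).to_numpy()
        if not mask.any():
            continue
        starts = np.sort(site_grp["start"].to_numpy(np.int64))
        ends = np.sort(site_grp["end"].to_numpy(np.int64))
        b_start = boundaries.loc[mask, "start"].to_numpy(np.int64)
        b_end = boundaries.loc[mask, "end"].to_numpy(np.int64)
        # overlap iff site.start < b.end and site.end > b.start
        n_start_before_end = np.searchsorted(starts, b_end, side="left")
        n_end_before_start = np.searchsorted(ends, b_start, side="right")
        out[mask] = n_start_before_end - n_end_before_start
    return out


def promoter_boundaries(probes: pd.DataFrame) -> pd.DataFrame:
    """Boundary (probe-1 start to probe-15 end) and methylation summaries per
    promoter."""
    g = probes.groupby("promoter_id", sort=True)
    out = pd.DataFrame(
        {
            "promoter_id": list(g.groups.keys()),
            "chrom": g["chrom"].first().to_numpy(),
            "start": g["start"].min().to_numpy(),
            "end": g["end"].max().to_numpy(),
            "strand": g["strand"].first().to_numpy(),
            "methylation_sum": g["methylation"].sum().to_numpy(),
            "methylation_mean": g["methylation"].mean().to_numpy(),
        }
    )
    return out


def select_exclusive_promoters(
    probes: pd.DataFrame, sites: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Keep promoters bound by at most one protein type.

    A promoter whose boundary overlaps sites of two or more distinct protein
    labels is excluded (possible protein-protein interaction); promoters
    overlapping exactly one protein are kept, and promoters with no binding
    at all are kept as background. Returns (kept_probes, exclusion_report).
    """
    bounds = promoter_boundaries(probes)
    proteins = sorted(sites["name"].unique()) if len(sites) else []
    bound_by = np.zeros(len(bounds), dtype=int)
    per_protein = {}
    for protein in proteins:
        counts = _overlap_counts(bounds, sites[sites["name"] == protein])
        per_protein[protein] = counts > 0
        bound_by += (counts > 0).astype(int)
    keep_mask = bound_by <= 1
    report = pd.DataFrame(
        {
            "promoter_id": bounds["promoter_id"],
            "n_proteins_bound": bound_by,
            "kept": keep_mask,
        }
    )
    for protein, flag in per_protein.items():
        report[f"bound_{protein}"] = flag
    kept_ids = set(bounds.loc[keep_mask, "promoter_id"])
    return probes[probes["promoter_id"].isin(kept_ids)].copy(), report


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p_value: float
    n: int
    degenerate: bool = False  # zero variance in x or y


def promoter_correlation(
    probes: pd.DataFrame,
    sites: pd.DataFrame,
    summary: Literal["sum", "mean"] = "sum",
) -> CorrelationResult:
    """Pearson correlation of promoter methylation vs. binding-site count.

    x = number of sites overlapping the promoter boundary, y = promoter
    methylation summary over its 15 probes (sum by default; sum and mean are
    scale-equivalent for the correlation). Two-sided p from the exact t
    transform on n-2 df.
    """
    bounds = promoter_boundaries(probes)
    n = len(bounds)
    if n < 3:
        raise ValueError("need >= 3 promoters for a defined p-value")
    x = _overlap_counts(bounds, sites).astype(float)
    y = bounds["methylation_sum" if summary == "sum" else "methylation_mean"]
    y = y.to_numpy(float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return CorrelationResult(r=float("nan"), p_value=float("nan"), n=n,
                                 degenerate=True)
    res = stats.pearsonr(x, y)
    return CorrelationResult(r=float(res.statistic), p_value=float(res.pvalue), n=n)


# ---------------------------------------------------------------------------
# positional profiles

def proximity_profile(
    probes: pd.DataFrame, sites: pd.DataFrame, thresholds: Sequence[float]
) -> pd.DataFrame:
    """Mean probe methylation among probes within each proximity threshold.

    Probe membership is cumulative in the threshold (the probe set at a
    smaller threshold is a subset of the set at a larger one). Bins with no
    probe report NaN, with the count making the emptiness explicit.
    """
    thresholds = list(thresholds)
    if any(b <= a for a, b in zip(thresholds, thresholds[1:])):
        raise ValueError("thresholds must be strictly increasing")
    dist = nearest_site_distance(probes, sites)
    meth = probes["methylation"].to_numpy(float)
    rows = []
    for t in thresholds:
        mask = dist <= t
        rows.append(
            {
                "threshold_bp": t,
                "n_probes": int(mask.sum()),
                "mean_methylation": float(meth[mask].mean()) if mask.any()
                else float("nan"),
            }
        )
    return pd.DataFrame(rows)


def tss_binding_profile(
    sites: pd.DataFrame, promoters: pd.DataFrame, bin_width: int = 50
) -> pd.DataFrame:
    """Strand-aware histogram of site centers relative to the TSS.

    For every (site, promoter) pair where the site overlaps the promoter
    boundary, the signed offset is (site center - TSS) measured along the
    gene's transcriptional orientation (positive = downstream). Sites are
    split into sense (site strand equals gene strand) and antisense.
    ``promoters`` needs columns chrom, start, end, tss, strand.
    """
    if bin_width < 1:
        raise ValueError("bin_width must be >= 1")
    records = []
    for chrom, site_grp in sites.groupby("chrom", sort=False):
        proms = promoters[promoters["chrom"] == chrom]
        if len(proms) == 0:
            continue
        s_start = site_grp["start"].to_numpy(np.int64)
        s_end = site_grp["end"].to_numpy(np.int64)
        s_center = (s_start + s_end) // 2
        s_strand = site_grp["strand"].to_numpy()
        for prom in proms.itertuples():
            hit = (s_start < prom.end) & (s_end > prom.start)
            if not hit.any():
                continue
            offs = s_center[hit] - int(prom.tss)
            if prom.strand == "-":
                offs = -offs
            sense = s_strand[hit] == prom.strand
            for off, is_sense in zip(offs, sense):
                records.append((int(np.floor(off / bin_width)) * bin_width,
                                bool(is_sense)))
    if not records:
        return pd.DataFrame(columns=["bin_start", "sense", "antisense"])
    df = pd.DataFrame(records, columns=["bin_start", "is_sense"])
    out = (
        df.groupby(["bin_start", "is_sense"]).size().unstack(fill_value=0)
        .reindex(columns=[True, False], fill_value=0)
    )
    out.columns = ["sense", "antisense"]
    return out.reset_index().sort_values("bin_start").reset_index(drop=True)


# ---------------------------------------------------------------------------
# group comparison

@dataclass(frozen=True)
class GroupComparison:
    statistic: float
    p_value: float  # NaN when the test is undefined (e.g. zero-variance diffs)
    paired: bool
    n_a: int
    n_b: int


def compare_groups(values_a, values_b, paired: bool = True) -> GroupComparison:
    """Two-sided paired or unpaired t-test between replicate methylation
    values (figure-style comparisons). Zero-variance paired differences make
    the statistic undefined; that is reported as NaN, never masked."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if paired:
        if len(a) != len(b):
            raise ValueError("paired test requires equal-length groups")
        if len(a) < 2:
            raise ValueError("need n >= 2 per group")
        diffs = a - b
        if np.ptp(diffs) == 0:
            return GroupComparison(float("nan"), float("nan"), True, len(a), len(b))
        res = stats.ttest_rel(a, b)
    else:
        if min(len(a), len(b)) < 2:
            raise ValueError("need n >= 2 per group")
        res = stats.ttest_ind(a, b)
    return GroupComparison(float(res.statistic), float(res.pvalue), paired,
                           len(a), len(b))
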