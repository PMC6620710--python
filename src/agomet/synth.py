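"""Synthetic data with planted ground truth for every pipeline input.

The generators emulate the statistical structure of the real inputs — a
promoter tiling array (15 probes x 50 bp per promoter, spread over ~1.5 kb),
CLIP mapped-read tables with multimapping and imperfect alignments, and
COBRA gel lanes derived from per-molecule two-CpG methylation patterns —
without any sequence-level realism. Every generator is deterministic under
its seed (byte-identical outputs) and records its planted parameters in a
manifest whose quantities are recomputable from the emitted files.

Planted structure:

* probe-level association — a chosen fraction of probes is designated AGO+
  by placing one binding site within ``assoc_d_max`` bp of the probe center;
  latent MET status is drawn per arm with the planted conditional
  probabilities, and continuous methylation values are emitted as two
  well-separated Gaussian components (means 80 / 20, sd 5) so a threshold at
  50 recovers the latent labels exactly.
* promoter-level correlation — site count k ~ Poisson, promoter methylation
  y = baseline + slope*k + N(0, noise_sd); the implied Pearson r
  slope*sqrt(var k) / sqrt(slope^2 var k + noise_sd^2) is recorded.
* gel lanes — molecules drawn multinomially over methylation patterns and
  mapped to restriction fragments; band intensity = molar count x the band's
  effective length, so the lane estimators recover the true methylated-CpG
  fraction exactly in the noiseless case.
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import clip as clip_mod
from . import io
from .cobra import (ALU_DIVISORS, GelLane, LINE1_DIVISORS, estimate_lane)
from .intervals import PROBES_PER_PROMOTER, PROBE_LENGTH
from .liftover import AlignedBlock, Chain, ChainFile, write_chain_file

ASSEMBLY = "synth1"


@dataclass
class SyntheticTruth:
    """Generator manifest: every planted parameter in one place."""

    seed: int = 0
    # promoter array geometry
    promoter_count: int = 1000
    probes_per_promoter: int = PROBES_PER_PROMOTER
    probe_length: int = PROBE_LENGTH
    promoter_span: int = 1500
    n_chromosomes: int = 1
    intergenic_gap: tuple[int, int] = (1000, 5000)
    tss_offset_frac: float = 0.8  # TSS position along the span, 5'->3'
    # probe-level association plant
    ago_positive_fraction: float = 0.5
    p_met_given_ago: float = 0.6367
    p_met_given_noago: float = 0.3000
    assoc_d_max: int = 30
    site_offset_max: int = 15
    site_length: int = 20
    met_high_mean: float = 80.0
    met_low_mean: float = 20.0
    met_sd: float = 5.0
    met_threshold: float = 50.0
    # promoter-level correlation plant
    corr_slope: float = 5.0
    corr_noise_sd: float = 41.0
    corr_site_count_mean: float = 2.0
    corr_baseline: float = 300.0
    # CLIP reads
    clip_n_reads: int = 300
    multimap_fraction: float = 0.2
    multiplicity_range: tuple[int, int] = (2, 40)
    edit_fraction: float = 0.3
    read_length_range: tuple[int, int] = (10, 40)
    # gel lanes
    line1_pattern_probs: tuple[float, float, float] = (0.6, 0.2, 0.2)  # mm, hemi, uu
    alu_pattern_probs: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    molecule_count: int = 1000
    gel_noise_cv: float = 0.0

    def __post_init__(self) -> None:
        for p in (self.ago_positive_fraction, self.p_met_given_ago,
                  self.p_met_given_noago, self.multimap_fraction,
                  self.edit_fraction):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")
        for probs in (self.line1_pattern_probs, self.alu_pattern_probs):
            if abs(sum(probs) - 1.0) > 1e-9:
                raise ValueError("pattern probabilities must sum to 1")
        if self.promoter_span < self.probes_per_promoter * self.probe_length:
            raise ValueError(
                f"promoter span {self.promoter_span} too small for "
                f"{self.probes_per_promoter} x {self.probe_length} bp probes"
            )
        if not (1 <= self.multiplicity_range[0] <= self.multiplicity_range[1] <= 60):
            raise ValueError("multiplicity range must lie within [1, 60]")
        spacing = (self.promoter_span - self.probe_length) // (
            self.probes_per_promoter - 1
        )
        if spacing <= self.assoc_d_max + self.site_offset_max:
            raise ValueError(
                "probe spacing must exceed assoc_d_max + site_offset_max so "
                "planted AGO labels are exact"
            )

    @property
    def planted_or(self) -> float:
        """Odds ratio implied by the two conditional MET probabilities."""
        p1, p0 = self.p_met_given_ago, self.p_met_given_noago
        return (p1 / (1 - p1)) / (p0 / (1 - p0))

    @property
    def implied_r(self) -> float:
        """Closed-form Pearson r of the Poisson/linear correlation plant."""
        var_k = self.corr_site_count_mean  # Poisson variance
        s2 = self.corr_slope ** 2 * var_k
        return self.corr_slope * math.sqrt(var_k) / math.sqrt(
            s2 + self.corr_noise_sd ** 2
        )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["planted_or"] = self.planted_or
        d["implied_r"] = self.implied_r
        return d


# ---------------------------------------------------------------------------
# promoter array

def gen_promoter_array(truth: SyntheticTruth, rng: np.random.Generator
                       ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Non-overlapping promoters tiled with evenly spaced 50-bp probes.

    Returns (probe_table, promoter_table); probe methylation is initialized
    to 0 and filled by the association / correlation planters. With
    span == 15*50 the probes tile contiguously (probe i starts where probe
    i-1 ends); larger spans spread them evenly across the region.
    """
    n, k, plen = truth.promoter_count, truth.probes_per_promoter, truth.probe_length
    span = truth.promoter_span
    offsets = np.round(np.arange(k) * (span - plen) / (k - 1)).astype(np.int64)
    chrom_idx = np.arange(n) % truth.n_chromosomes
    gaps = rng.integers(truth.intergenic_gap[0], truth.intergenic_gap[1] + 1, size=n)
    strands = np.where(rng.random(n) < 0.5, "+", "-")
    prom_start = np.zeros(n, dtype=np.int64)
    cursor = np.zeros(truth.n_chromosomes, dtype=np.int64)
    for i in range(n):
        c = chrom_idx[i]
        prom_start[i] = cursor[c] + gaps[i]
        cursor[c] = prom_start[i] + span
    chroms = np.array([f"chrS{c + 1}" for c in chrom_idx])
    tss_off = int(round(truth.tss_offset_frac * span))
    tss = np.where(strands == "+", prom_start + tss_off,
                   prom_start + span - tss_off)
    pids = np.array([f"P{i:06d}" for i in range(n)])
    promoter_df = pd.DataFrame(
        {"promoter_id": pids, "gene": np.char.add("GENE_", pids),
         "chrom": chroms, "start": prom_start, "end": prom_start + span,
         "tss": tss, "strand": strands}
    )
    starts = (prom_start[:, None] + offsets[None, :]).ravel()
    probe_df = pd.DataFrame(
        {
            "promoter_id": np.repeat(pids, k),
            "gene": np.repeat(promoter_df["gene"].to_numpy(), k),
            "probe_index": np.tile(np.arange(1, k + 1), n),
            "chrom": np.repeat(chroms, k),
            "start": starts,
            "end": starts + plen,
            "strand": np.repeat(strands, k),
            "methylation": np.zeros(n * k),
        }
    )
    return probe_df, promoter_df


# ---------------------------------------------------------------------------
# probe-level association plant

def gen_probe_association(
    truth: SyntheticTruth, probe_df: pd.DataFrame, rng: np.random.Generator
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Plant AGO+/- labels and conditional MET status on an existing array.

    Returns (probe_table with methylation filled, sites_table, manifest).
    The geometry guarantees a planted site is within ``assoc_d_max`` of its
    own probe center and farther than ``assoc_d_max`` from every other probe
    center, so proximity labeling at the same d_max recovers the plant
    exactly.
    """
    probe_df = probe_df.copy()
    n = len(probe_df)
    n_pos = int(round(truth.ago_positive_fraction * n))
    perm = rng.permutation(n)
    ago = np.zeros(n, dtype=bool)
    ago[perm[:n_pos]] = True

    centers = (probe_df["start"].to_numpy(np.int64)
               + probe_df["end"].to_numpy(np.int64)) // 2
    off = rng.integers(-truth.site_offset_max, truth.site_offset_max + 1,
                       size=n_pos)
    site_centers = centers[ago] + off
    half = truth.site_length // 2
    site_start = site_centers - half
    site_df = pd.DataFrame(
        {
            "chrom": probe_df.loc[ago, "chrom"].to_numpy(),
            "start": site_start,
            "end": site_start + truth.site_length,
            "name": "AGO4",
            "score": rng.integers(1, 10, size=n_pos),
            "strand": np.where(rng.random(n_pos) < 0.5, "+", "-"),
        }
    ).sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)

    p = np.where(ago, truth.p_met_given_ago, truth.p_met_given_noago)
    met = rng.random(n) < p
    high = rng.normal(truth.met_high_mean, truth.met_sd, size=n)
    low = rng.normal(truth.met_low_mean, truth.met_sd, size=n)
    values = np.clip(np.where(met, high, low), 0.0, None)
    probe_df["methylation"] = values

    a = int(np.sum(met & ago)); b = int(np.sum(~met & ago))
    c = int(np.sum(met & ~ago)); d = int(np.sum(~met & ~ago))
    manifest = {
        "kind": "association",
        "seed": truth.seed,
        "n_probes": n,
        "n_ago_pos": n_pos,
        "n_ago_neg": n - n_pos,
        "n_met_pos": int(met.sum()),
        "latent_table": {"a": a, "b": b, "c": c, "d": d},
        "latent_or": (a * d) / (b * c) if b * c else None,
        "planted_or": truth.planted_or,
        "p_met_given_ago": truth.p_met_given_ago,
        "p_met_given_noago": truth.p_met_given_noago,
        "d_max": truth.assoc_d_max,
        "met_threshold": truth.met_threshold,
        "site_length": truth.site_length,
        "site_offset_max": truth.site_offset_max,
    }
    return probe_df, site_df, manifest


# ---------------------------------------------------------------------------
# promoter-level correlation plant

def gen_promoter_correlation_data(
    truth: SyntheticTruth,
    probe_df: pd.DataFrame,
    promoter_df: pd.DataFrame,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Plant a linear methylation ~ site-count relation across promoters.

    k ~ Poisson(site_count_mean) sites are placed uniformly inside each
    promoter boundary; promoter methylation y = baseline + slope*k + noise
    is spread evenly over the 15 probes (so the sum recovers y).
    """
    probe_df = probe_df.copy()
    n = len(promoter_df)
    k = rng.poisson(truth.corr_site_count_mean, size=n)
    noise = rng.normal(0.0, truth.corr_noise_sd, size=n)
    y = truth.corr_baseline + truth.corr_slope * k + noise
    n_clipped = int(np.sum(y < 0))
    y = np.clip(y, 0.0, None)

    total = int(k.sum())
    rep = np.repeat(np.arange(n), k)
    lo = promoter_df["start"].to_numpy(np.int64)[rep]
    hi = promoter_df["end"].to_numpy(np.int64)[rep] - truth.site_length
    starts = rng.integers(lo, hi + 1)
    site_df = pd.DataFrame(
        {
            "chrom": promoter_df["chrom"].to_numpy()[rep],
            "start": starts,
            "end": starts + truth.site_length,
            "name": "AGO4",
            "score": np.ones(total, dtype=int),
            "strand": np.where(rng.random(total) < 0.5, "+", "-"),
        }
    ).sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)

    per_probe = np.repeat(y / truth.probes_per_promoter,
                          truth.probes_per_promoter)
    order = probe_df.sort_values(["promoter_id", "probe_index"]).index
    probe_df.loc[order, "methylation"] = per_probe

    sample_r = float(np.corrcoef(k, y)[0, 1]) if np.ptp(k) > 0 else float("nan")
    manifest = {
        "kind": "correlation",
        "seed": truth.seed,
        "n_promoters": n,
        "slope": truth.corr_slope,
        "noise_sd": truth.corr_noise_sd,
        "site_count_mean": truth.corr_site_count_mean,
        "baseline": truth.corr_baseline,
        "implied_r": truth.implied_r,
        "sample_r": sample_r,
        "total_sites": total,
        "n_clipped_promoters": n_clipped,
    }
    return probe_df, site_df, manifest


# ---------------------------------------------------------------------------
# CLIP reads

_BASES = np.array(list("ACGT"))


def gen_clip_reads(truth: SyntheticTruth, rng: np.random.Generator
                   ) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Two-file mapped-read tables with planted multimapping and edits.

    Read lengths straddle the binding-length filter; a ``multimap_fraction``
    of reads carries 2..multiplicity_max locations, and each location
    independently carries mismatch/insertion/deletion edits with probability
    ``edit_fraction``.
    """
    n = truth.clip_n_reads
    lo_len, hi_len = truth.read_length_range
    lengths = rng.integers(lo_len, hi_len + 1, size=n)
    copies = rng.integers(1, 6, size=n)
    is_multi = rng.random(n) < truth.multimap_fraction
    lo_m, hi_m = truth.multiplicity_range
    n_loc = np.where(is_multi, rng.integers(lo_m, hi_m + 1, size=n), 1)
    seqs = ["".join(_BASES[rng.integers(0, 4, size=int(L))]) for L in lengths]
    read_ids = [f"R{i:05d}" for i in range(n)]
    mapped_df = pd.DataFrame(
        {"read_id": read_ids, "sequence": seqs, "copies": copies}
    )
    chrom_size = 5_000_000
    rep = np.repeat(np.arange(n), n_loc)
    total = int(n_loc.sum())
    starts = rng.integers(0, chrom_size - hi_len, size=total)
    has_edit = rng.random(total) < truth.edit_fraction
    mm = np.where(has_edit, rng.integers(0, 3, size=total), 0)
    ins = np.where(has_edit, rng.integers(0, 2, size=total), 0)
    dele = np.where(has_edit, rng.integers(0, 2, size=total), 0)
    # an 'edited' location must have at least one edit
    allzero = has_edit & (mm + ins + dele == 0)
    mm = np.where(allzero, 1, mm)
    mappings_df = pd.DataFrame(
        {
            "read_id": np.array(read_ids)[rep],
            "chrom": "chrS1",
            "start": starts,
            "end": starts + lengths[rep],
            "strand": np.where(rng.random(total) < 0.5, "+", "-"),
            "mismatches": mm,
            "insertions": ins,
            "deletions": dele,
        }
    )
    n_over = int(np.sum(n_loc > clip_mod.MAX_LOCATIONS_DEFAULT))
    # survival table: run the real ingest path per sweep point
    reads = clip_mod.reads_from_tables(mapped_df, mappings_df, assembly=ASSEMBLY)
    kept, _ = clip_mod.filter_multimappers(reads)
    survival = {}
    for min_len in clip_mod.MIN_LENGTH_SWEEP:
        for mode in ("perfect_only", "include_approximate"):
            sites = clip_mod.reads_to_sites(kept, "AGO4", min_length=min_len,
                                            match_mode=mode)
            survival[f"min_len_{min_len}_{mode}"] = len(sites)
    manifest = {
        "kind": "clip",
        "seed": truth.seed,
        "n_reads": n,
        "n_locations_total": total,
        "n_reads_over_30_locations": n_over,
        "multimap_fraction": truth.multimap_fraction,
        "multiplicity_range": list(truth.multiplicity_range),
        "edit_fraction": truth.edit_fraction,
        "read_length_range": list(truth.read_length_range),
        "surviving_sites": survival,
    }
    return mapped_df, mappings_df, manifest


# ---------------------------------------------------------------------------
# gel lanes

def lane_from_pattern_counts(
    assay: str,
    pattern_counts: Sequence[int],
    rng: Optional[np.random.Generator] = None,
    noise_cv: float = 0.0,
    replicate_id: str = "",
) -> tuple[GelLane, float]:
    """Deterministic forward model: molecule pattern counts -> gel lane.

    LINE-1 patterns (mm, hemi, uu): fully methylated molecules cut into the
    50+42 bp fragments, fully unmethylated into 60+32 bp, singly methylated
    stay uncut at 92 bp. Alu patterns (mm, mu, um, uu): both sites cut ->
    58 + 43 bp counted bands (the middle fragment is not a counted band),
    site 1 only -> 58+75, site 2 only -> 90+43, uncut -> 133. Band intensity
    = molar fragment count x the band's effective length, optionally scaled
    by multiplicative log-normal noise (unit mean, coefficient of variation
    ``noise_cv``). Returns (lane, true methylated-CpG percent).
    """
    counts = [int(x) for x in pattern_counts]
    if any(c < 0 for c in counts):
        raise ValueError("pattern counts must be >= 0")
    total = sum(counts)
    if total < 1:
        raise ValueError("need at least one molecule")
    if assay == "LINE1":
        if len(counts) != 3:
            raise ValueError("LINE1 expects (n_mm, n_hemi, n_uu)")
        mm, hemi, uu = counts
        molar = {92: hemi, 60: uu, 50: mm, 42: mm, 32: uu}
        divisors = LINE1_DIVISORS
        true_fraction = (2 * mm + hemi) / (2 * total)
    elif assay == "ALU":
        if len(counts) != 4:
            raise ValueError("ALU expects (n_mm, n_mu, n_um, n_uu)")
        mm, mu, um, uu = counts
        molar = {133: uu, 90: um, 75: mu, 58: mm + mu, 43: mm + um}
        divisors = ALU_DIVISORS
        true_fraction = (2 * mm + mu + um) / (2 * total)
    else:
        raise ValueError(f"unknown assay {assay!r}")
    bands = {}
    for size, count in molar.items():
        intensity = float(count * divisors[size])
        if noise_cv > 0:
            if rng is None:
                raise ValueError("noise_cv > 0 requires an rng")
            sigma = math.sqrt(math.log(1.0 + noise_cv ** 2))
            intensity *= float(rng.lognormal(-sigma ** 2 / 2, sigma))
        bands[size] = intensity
    lane = GelLane(assay=assay, bands=bands, replicate_id=replicate_id)
    return lane, true_fraction * 100.0


def gen_gel_lane(
    assay: str,
    molecule_count: int,
    pattern_probs: Sequence[float],
    rng: np.random.Generator,
    noise_cv: float = 0.0,
    replicate_id: str = "",
) -> tuple[GelLane, float, dict]:
    """One COBRA lane: molecules drawn multinomially over methylation
    patterns, then pushed through :func:`lane_from_pattern_counts`.

    Returns (lane, true methylated-CpG percent, manifest).
    """
    if molecule_count < 1:
        raise ValueError("molecule_count must be >= 1")
    probs = np.asarray(pattern_probs, dtype=float)
    if abs(probs.sum() - 1.0) > 1e-9:
        raise ValueError("pattern probabilities must sum to 1")
    counts = rng.multinomial(molecule_count, probs)
    lane, true_percent = lane_from_pattern_counts(
        assay, counts, rng=rng, noise_cv=noise_cv, replicate_id=replicate_id
    )
    names = ("mm", "hemi", "uu") if assay == "LINE1" else ("mm", "mu", "um", "uu")
    manifest = {
        "assay": assay,
        "replicate_id": replicate_id,
        "molecule_count": molecule_count,
        "pattern_probs": list(map(float, probs)),
        "pattern_counts": dict(zip(names, (int(x) for x in counts))),
        "true_percent": true_percent,
        "noise_cv": noise_cv,
        "forward_model_note": (
            "band assignment chosen so the lane formula is exact on molar "
            "counts; it is a modeling construct, not a digestion-chemistry claim"
        ),
    }
    return lane, true_percent, manifest


# ---------------------------------------------------------------------------
# chain fixture

def gen_chain(
    t_name: str,
    t_size: int,
    q_name: str,
    q_size: int,
    blocks: Sequence[tuple[int, int, int]],
    score: int = 1000,
    chain_id: str = "1",
) -> ChainFile:
    """A syntactically valid chain from (t_start, t_end, q_offset) blocks.

    An identity chain is one block ``(0, t_size, 0)``; a pure shift is one
    block with a nonzero offset. Blocks must be non-overlapping and ordered
    on both source and target sides.
    """
    aligned = []
    prev_t = prev_q = -1
    for t_start, t_end, q_off in blocks:
        if not (0 <= t_start < t_end <= t_size):
            raise ValueError(f"block [{t_start},{t_end}) outside source sequence")
        q_start = t_start + q_off
        if q_start < 0 or q_start + (t_end - t_start) > q_size:
            raise ValueError("block maps outside target sequence")
        if t_start < prev_t or q_start < prev_q:
            raise ValueError("blocks overlap or are unordered")
        aligned.append(AlignedBlock(t_start=t_start, q_start=q_start,
                                    size=t_end - t_start))
        prev_t, prev_q = t_end, q_start + (t_end - t_start)
    if not aligned:
        raise ValueError("need at least one block")
    chain = Chain(
        score=score, t_name=t_name, t_size=t_size, t_strand="+",
        t_start=aligned[0].t_start, t_end=aligned[-1].t_end,
        q_name=q_name, q_size=q_size, q_strand="+",
        q_start=aligned[0].q_start, q_end=aligned[-1].q_end,
        chain_id=chain_id, blocks=aligned,
    )
    return ChainFile(chains=[chain])


# ---------------------------------------------------------------------------
# file-emitting wrappers + manifest verification

def _write_manifest(outdir: Path, manifest: dict) -> None:
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )


def _seed_comments(truth: SyntheticTruth, extra: str = "") -> list[str]:
    base = [f"seed={truth.seed}", f"assembly={ASSEMBLY}"]
    if extra:
        base.append(extra)
    return base


def emit_association_dataset(truth: SyntheticTruth, outdir) -> dict:
    """probes.tsv + promoters.tsv + sites.bed + manifest.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(truth.seed)
    probe_df, promoter_df = gen_promoter_array(truth, rng)
    probe_df, site_df, manifest = gen_probe_association(truth, probe_df, rng)
    io.write_tsv(probe_df, outdir / "probes.tsv", _seed_comments(truth))
    io.write_tsv(promoter_df, outdir / "promoters.tsv", _seed_comments(truth))
    io.write_bed(site_df, outdir / "sites.bed", _seed_comments(truth))
    _write_manifest(outdir, manifest)
    return manifest


def emit_correlation_dataset(truth: SyntheticTruth, outdir) -> dict:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(truth.seed)
    probe_df, promoter_df = gen_promoter_array(truth, rng)
    probe_df, site_df, manifest = gen_promoter_correlation_data(
        truth, probe_df, promoter_df, rng
    )
    io.write_tsv(probe_df, outdir / "probes.tsv", _seed_comments(truth))
    io.write_tsv(promoter_df, outdir / "promoters.tsv", _seed_comments(truth))
    io.write_bed(site_df, outdir / "sites.bed", _seed_comments(truth))
    _write_manifest(outdir, manifest)
    return manifest


def emit_clip_dataset(truth: SyntheticTruth, outdir) -> dict:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(truth.seed)
    mapped_df, mappings_df, manifest = gen_clip_reads(truth, rng)
    io.write_tsv(mapped_df, outdir / "mapped_sequences.tsv", _seed_comments(truth))
    io.write_tsv(mappings_df, outdir / "genome_mappings.tsv", _seed_comments(truth))
    _write_manifest(outdir, manifest)
    return manifest


def emit_gel_dataset(truth: SyntheticTruth, outdir, n_replicates: int = 3) -> dict:
    """lanes.tsv (long format, both assays x replicates) + manifest.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(truth.seed)
    rows = []
    lane_manifests = []
    for rep in range(1, n_replicates + 1):
        for assay, probs in (("LINE1", truth.line1_pattern_probs),
                             ("ALU", truth.alu_pattern_probs)):
            lane, true_pct, m = gen_gel_lane(
                assay, truth.molecule_count, probs, rng,
                noise_cv=truth.gel_noise_cv, replicate_id=f"rep{rep}",
            )
            lane_manifests.append(m)
            for size in sorted(lane.bands, reverse=True):
                rows.append({"replicate_id": lane.replicate_id, "assay": assay,
                             "band_size": size, "intensity": lane.bands[size]})
    lanes_df = pd.DataFrame(rows)
    io.write_tsv(lanes_df, outdir / "lanes.tsv", _seed_comments(truth))
    manifest = {"kind": "gel", "seed": truth.seed,
                "noise_cv": truth.gel_noise_cv, "lanes": lane_manifests}
    _write_manifest(outdir, manifest)
    return manifest


def emit_chain_fixture(truth: SyntheticTruth, outdir,
                       blocks: Optional[Sequence[tuple[int, int, int]]] = None,
                       t_size: int = 1_000_000) -> dict:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if blocks is None:
        blocks = [(0, t_size, 0)]  # identity
    q_size = t_size + max(0, max(b[2] for b in blocks)) + 1000
    cf = gen_chain("chrS1", t_size, "chrS1", q_size, list(blocks))
    write_chain_file(cf, outdir / "fixture.chain")
    manifest = {"kind": "chain", "seed": truth.seed, "t_size": t_size,
                "blocks": [list(b) for b in blocks]}
    _write_manifest(outdir, manifest)
    return manifest


def verify_manifest(outdir) -> None:
    """Assert every manifest quantity is recomputable from the emitted files.

    Raises AssertionError on any mismatch (no hidden generator state).
    """
    outdir = Path(outdir)
    manifest = json.loads((outdir / "manifest.json").read_text())
    kind = manifest["kind"]
    if kind == "association":
        from . import association as assoc

        probes = io.read_probe_table(outdir / "probes.tsv")
        sites = io.read_bed(outdir / "sites.bed")
        assert len(probes) == manifest["n_probes"]
        ago = assoc.label_probes_by_proximity(probes, sites,
                                              d_max=manifest["d_max"])
        assert int(ago.sum()) == manifest["n_ago_pos"]
        met, _ = assoc.dichotomize_methylation(
            probes["methylation"].to_numpy(), rule="threshold",
            threshold=manifest["met_threshold"],
        )
        assert int(met.sum()) == manifest["n_met_pos"]
        table = assoc.build_contingency(met, ago)
        lt = manifest["latent_table"]
        assert (table.a, table.b, table.c, table.d) == (
            lt["a"], lt["b"], lt["c"], lt["d"]
        )
    elif kind == "correlation":
        from . import association as assoc

        probes = io.read_probe_table(outdir / "probes.tsv")
        sites = io.read_bed(outdir / "sites.bed")
        assert len(sites) == manifest["total_sites"]
        res = assoc.promoter_correlation(probes, sites)
        assert res.n == manifest["n_promoters"]
        assert abs(res.r - manifest["sample_r"]) < 1e-9
    elif kind == "clip":
        reads = clip_mod.read_clip_pair(outdir / "mapped_sequences.tsv",
                                        outdir / "genome_mappings.tsv")
        assert len(reads) == manifest["n_reads"]
        n_over = sum(1 for r in reads if len(r.locations) > 30)
        assert n_over == manifest["n_reads_over_30_locations"]
        kept, removed = clip_mod.filter_multimappers(reads)
        assert removed == n_over
        for key, expected in manifest["surviving_sites"].items():
            parts = key.split("_")  # min_len_<L>_<mode...>
            min_len = int(parts[2])
            mode = "_".join(parts[3:])
            sites = clip_mod.reads_to_sites(kept, "AGO4", min_length=min_len,
                                            match_mode=mode)
            assert len(sites) == expected, key
    elif kind == "gel":
        lanes = cobra_lanes_from_file(outdir / "lanes.tsv")
        by_key = {(l.replicate_id, l.assay): l for l in lanes}
        for m in manifest["lanes"]:
            lane = by_key[(m["replicate_id"], m["assay"])]
            est = estimate_lane(lane)
            if manifest["noise_cv"] == 0:
                assert abs(est.percent - m["true_percent"]) < 1e-9
    elif kind == "chain":
        pass  # structure is validated by the chain parser on read
    else:
        raise ValueError(f"unknown manifest kind {kind!r}")


def cobra_lanes_from_file(path) -> list[GelLane]:
    from .cobra import lanes_from_table

    return lanes_from_table(io.read_lane_table(path))
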