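"""End-to-end orchestration: synthesize/load -> ingest -> associate -> report.

A run is fully described by a :class:`RunConfig`; the resolved config is
serialized verbatim into the report bundle, and a run contains no wall-clock
state, so rerunning the same config + seed reproduces the bundle
bit-for-bit. Every filtering stage logs its in/out counts so the analysis
funnel (probes, reads, sites, promoters) is auditable.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import association as assoc
from . import clip as clip_mod
from . import cobra as cobra_mod
from . import io
from . import synth
from .intervals import GenomicInterval
from .liftover import liftover_interval, read_chain_file

log = logging.getLogger("agomet")


class PipelineError(RuntimeError):
    """A stage-named pipeline failure."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """All settings of an association or COBRA run, with analysis defaults.

    Exactly one of ``generate``/``probes`` drives the association study:
    either a synthetic dataset is generated under ``out_dir`` or existing
    probe/site files are consumed.
    """

    out_dir: str = "agomet_run"
    seed: int = 0
    # inputs
    generate: Optional[str] = None  # 'association' | 'correlation'
    probes: Optional[str] = None
    promoters: Optional[str] = None
    sites: Optional[str] = None  # BED6
    clip_mapped: Optional[str] = None
    clip_mappings: Optional[str] = None
    clip_protein: str = "AGO4"
    chain: Optional[str] = None
    lanes: Optional[str] = None  # COBRA lane TSV
    ct_table: Optional[str] = None
    # ingest filters
    max_locations: int = clip_mod.MAX_LOCATIONS_DEFAULT
    min_length: int = clip_mod.MIN_LENGTH_DEFAULT
    min_length_sweep: Optional[Sequence[int]] = None
    match_mode: str = "include_approximate"
    sweep_match_modes: bool = False
    # association settings
    d_max: int = assoc.D_MAX_DEFAULT
    d_max_sweep: Sequence[int] = tuple(assoc.D_MAX_SWEEP)
    met_rule: str = "median"
    met_threshold: Optional[float] = None
    exclusivity: bool = True
    summary: str = "sum"
    profile_bin_width: int = 50
    # COBRA comparison
    paired: bool = True
    # synthetic-truth overrides (nested dict of SyntheticTruth fields)
    truth: dict = field(default_factory=dict)
    log_level: str = "INFO"

    def resolved_truth(self) -> synth.SyntheticTruth:
        params = dict(self.truth)
        params.setdefault("seed", self.seed)
        for key in ("intergenic_gap", "multiplicity_range", "read_length_range",
                    "line1_pattern_probs", "alu_pattern_probs"):
            if key in params and isinstance(params[key], list):
                params[key] = tuple(params[key])
        return synth.SyntheticTruth(**params)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["d_max_sweep"] = list(self.d_max_sweep)
        if self.min_length_sweep is not None:
            d["min_length_sweep"] = list(self.min_length_sweep)
        return d

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise PipelineError("config", f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def _config_hash(config: RunConfig) -> str:
    # the hash identifies the analysis settings, not where output lands
    d = config.to_dict()
    d.pop("out_dir", None)
    payload = json.dumps(d, sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def _lift_probes(probes: pd.DataFrame, chain_path, source="", target=""
                 ) -> tuple[pd.DataFrame, int]:
    """Lift probe intervals; promoters losing any probe are dropped whole
    (a promoter needs all 15 probes). Returns (lifted_probes, n_unmapped)."""
    chain_file = read_chain_file(chain_path, source, target)
    new_start = np.empty(len(probes), dtype=np.int64)
    new_chrom = np.empty(len(probes), dtype=object)
    ok = np.zeros(len(probes), dtype=bool)
    for i, row in enumerate(probes.itertuples()):
        res = liftover_interval(
            GenomicInterval(row.chrom, int(row.start), int(row.end),
                            row.strand if row.strand in "+-" else "."),
            chain_file,
        )
        if res.ok:
            ok[i] = True
            new_start[i] = res.mapped.start
            new_chrom[i] = res.mapped.chrom
    n_unmapped = int((~ok).sum())
    lifted = probes[ok].copy()
    lifted["chrom"] = new_chrom[ok]
    lifted["start"] = new_start[ok]
    lifted["end"] = lifted["start"] + 50
    complete = lifted.groupby("promoter_id")["probe_index"].transform("size") == 15
    return lifted[complete].copy(), n_unmapped


def run_association_study(config: RunConfig) -> dict:
    """Execute the colocalization pipeline and write the report bundle.

    Stages: (generate|load) -> liftover -> ingest -> exclusivity ->
    dichotomize -> contingency sweep -> correlation -> profiles -> report.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    counts: dict = {}
    manifest = None

    # ---- stage: inputs
    try:
        if config.generate:
            truth = config.resolved_truth()
            indir = out / "inputs"
            if config.generate == "association":
                manifest = synth.emit_association_dataset(truth, indir)
            elif config.generate == "correlation":
                manifest = synth.emit_correlation_dataset(truth, indir)
            else:
                raise ValueError(f"unknown generator {config.generate!r}")
            probes = io.read_probe_table(indir / "probes.tsv")
            promoters = io.read_promoter_table(indir / "promoters.tsv")
            sites = io.read_bed(indir / "sites.bed")
        elif config.probes:
            probes = io.read_probe_table(config.probes)
            promoters = (io.read_promoter_table(config.promoters)
                         if config.promoters else None)
            sites = io.read_bed(config.sites) if config.sites else None
        else:
            raise ValueError("config needs either 'generate' or 'probes'")
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("inputs", str(exc)) from exc
    counts["probes_in"] = len(probes)
    log.info("inputs: %d probes", len(probes))

    # ---- stage: liftover
    if config.chain:
        try:
            probes, n_unmapped = _lift_probes(probes, config.chain)
        except Exception as exc:
            raise PipelineError("liftover", str(exc)) from exc
        counts["probes_unmapped_by_liftover"] = n_unmapped
        counts["probes_after_liftover"] = len(probes)
        log.info("liftover: %d probes unmapped (excluded, reported)", n_unmapped)

    # ---- stage: ingest
    site_variants: dict[tuple[str, int], pd.DataFrame] = {}
    try:
        if config.clip_mapped and config.clip_mappings:
            reads = clip_mod.read_clip_pair(config.clip_mapped,
                                            config.clip_mappings)
            counts["clip_reads_in"] = len(reads)
            kept, removed = clip_mod.filter_multimappers(
                reads, max_locations=config.max_locations)
            counts["clip_reads_removed_multimapper"] = removed
            modes = (["perfect_only", "include_approximate"]
                     if config.sweep_match_modes else [config.match_mode])
            lengths = list(config.min_length_sweep or [config.min_length])
            for mode in modes:
                for min_len in lengths:
                    s = clip_mod.reads_to_sites(
                        kept, config.clip_protein, min_length=min_len,
                        match_mode=mode)
                    site_variants[(mode, min_len)] = clip_mod.sites_to_frame(s)
        elif sites is not None:
            site_variants[(config.match_mode, config.min_length)] = sites
        else:
            site_variants[(config.match_mode, config.min_length)] = pd.DataFrame(
                columns=io.BED6_COLUMNS)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("ingest", str(exc)) from exc

    # ---- stage: exclusivity (on the primary site variant)
    primary_key = (config.match_mode, config.min_length)
    if primary_key not in site_variants:
        primary_key = next(iter(site_variants))
    primary_sites = site_variants[primary_key]
    if config.exclusivity:
        try:
            probes, excl_report = assoc.select_exclusive_promoters(
                probes, primary_sites)
        except Exception as exc:
            raise PipelineError("exclusivity", str(exc)) from exc
        counts["promoters_after_exclusivity"] = int(excl_report["kept"].sum())
        counts["promoters_excluded_multi_protein"] = int(
            (~excl_report["kept"]).sum())
        counts["probes_after_exclusivity"] = len(probes)

    if len(probes) == 0:
        raise PipelineError("exclusivity", "no probes left to classify")

    # ---- stage: dichotomize
    try:
        met, dich = assoc.dichotomize_methylation(
            probes["methylation"].to_numpy(), rule=config.met_rule,
            threshold=config.met_threshold)
    except Exception as exc:
        raise PipelineError("dichotomize", str(exc)) from exc
    counts["met_pos"] = dich.n_met_pos
    counts["met_neg"] = dich.n_met_neg
    if dich.all_identical:
        log.warning("dichotomize: all methylation values identical; all MET-")

    # ---- stage: contingency sweep (always includes the primary d_max)
    d_values = sorted(set(list(config.d_max_sweep) + [config.d_max]))
    rows = []
    for (mode, min_len), site_df in sorted(site_variants.items()):
        proteins = sorted(site_df["name"].unique()) if len(site_df) else ["none"]
        for protein in proteins:
            psites = (site_df[site_df["name"] == protein]
                      if len(site_df) else site_df)
            for d_max in d_values:
                ago = assoc.label_probes_by_proximity(probes, psites, d_max)
                table = assoc.build_contingency(met, ago)
                degenerate = table.has_degenerate_margin
                res = assoc.association_stats(table)
                rows.append({
                    "protein": protein, "match_mode": mode,
                    "min_length": min_len, "d_max": d_max,
                    "a": table.a, "b": table.b, "c": table.c, "d": table.d,
                    "odds_ratio": res.odds_ratio, "ci_low": res.ci_low,
                    "ci_high": res.ci_high, "chi_square": res.chi_square,
                    "p_value": res.p_value,
                    "zero_cell_corrected": res.continuity_note,
                    "degenerate_margin": degenerate,
                })
    association_df = pd.DataFrame(rows)

    # ---- stage: correlation
    corr_rows = []
    for (mode, min_len), site_df in sorted(site_variants.items()):
        proteins = sorted(site_df["name"].unique()) if len(site_df) else []
        for protein in proteins:
            res = assoc.promoter_correlation(
                probes, site_df[site_df["name"] == protein],
                summary=config.summary)
            corr_rows.append({
                "protein": protein, "match_mode": mode, "min_length": min_len,
                "r": res.r, "p_value": res.p_value, "n_promoters": res.n,
                "degenerate": res.degenerate,
            })
    correlation_df = pd.DataFrame(corr_rows)

    # ---- stage: profiles
    profile_df = assoc.proximity_profile(probes, primary_sites,
                                         sorted(config.d_max_sweep))
    tss_df = None
    if config.generate or config.promoters:
        tss_df = assoc.tss_binding_profile(primary_sites, promoters,
                                           bin_width=config.profile_bin_width)

    # ---- stage: report
    comments = [f"seed={config.seed}", f"config_hash={_config_hash(config)}"]
    io.write_tsv(association_df, out / "association.tsv", comments)
    io.write_tsv(correlation_df, out / "correlation.tsv", comments)
    io.write_tsv(profile_df, out / "proximity_profile.tsv", comments)
    if tss_df is not None:
        io.write_tsv(tss_df, out / "tss_profile.tsv", comments)
    report = {
        "config": config.to_dict(),
        "config_hash": _config_hash(config),
        "counts": counts,
        "dichotomy": dataclasses.asdict(dich),
        "association": association_df.to_dict(orient="records"),
        "correlation": correlation_df.to_dict(orient="records"),
        "proximity_profile": profile_df.to_dict(orient="records"),
    }
    if manifest is not None:
        report["generator_manifest"] = manifest
    (out / "report.json").write_text(
        json.dumps(report, indent=2, sort_keys=True, allow_nan=True,
                   default=float) + "\n")
    return report


def run_cobra_study(config: RunConfig) -> dict:
    """Per-lane COBRA estimates plus optional labeled group comparisons."""
    if not config.lanes:
        raise PipelineError("inputs", "COBRA study requires 'lanes'")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    try:
        table = io.read_lane_table(config.lanes)
    except Exception as exc:
        raise PipelineError("inputs", str(exc)) from exc
    has_group = "group" in table.columns
    lanes = cobra_mod.lanes_from_table(
        table.drop(columns=["group"]) if has_group else table)
    estimates = [cobra_mod.estimate_lane(l) for l in lanes]
    est_df = cobra_mod.estimates_to_frame(estimates)
    comparisons = []
    if has_group:
        groups = sorted(table["group"].unique())
        if len(groups) != 2:
            raise PipelineError(
                "compare", f"need exactly 2 groups, got {groups}")
        key = table[["replicate_id", "assay", "group"]].drop_duplicates()
        merged = est_df.merge(key, on=["replicate_id", "assay"])
        for assay, grp in merged.groupby("assay"):
            ga = grp[grp["group"] == groups[0]].sort_values("replicate_id")
            gb = grp[grp["group"] == groups[1]].sort_values("replicate_id")
            if config.paired:
                unpaired = set(ga["replicate_id"]) ^ set(gb["replicate_id"])
                if unpaired:
                    raise PipelineError(
                        "compare",
                        f"{assay}: replicates without a pair: {sorted(unpaired)}")
            res = assoc.compare_groups(ga["percent"].to_numpy(),
                                       gb["percent"].to_numpy(),
                                       paired=config.paired)
            comparisons.append({
                "assay": assay, "group_a": groups[0], "group_b": groups[1],
                "mean_a": float(ga["percent"].mean()),
                "mean_b": float(gb["percent"].mean()),
                "statistic": res.statistic, "p_value": res.p_value,
                "paired": res.paired, "n": res.n_a,
            })
    comments = [f"seed={config.seed}", f"config_hash={_config_hash(config)}"]
    io.write_tsv(est_df, out / "estimates.tsv", comments)
    comp_df = pd.DataFrame(comparisons)
    if len(comp_df):
        io.write_tsv(comp_df, out / "comparisons.tsv", comments)
    report = {
        "config": config.to_dict(),
        "config_hash": _config_hash(config),
        "estimates": est_df.to_dict(orient="records"),
        "comparisons": comparisons,
    }
    (out / "report.json").write_text(
        json.dumps(report, indent=2, sort_keys=True, allow_nan=True,
                   default=float) + "\n")
    return report
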