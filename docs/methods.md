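# Methods

This note documents the statistical model, the defaults and why they were
chosen, the synthetic-data generators' assumptions, and the numerical and
design choices made where the design was genuinely open.

## Coordinate model

All genomic features are 0-based half-open intervals `[start, end)`
(BED-compatible), and chain files follow the public UCSC chain format. The
distance between two features is the absolute difference of their centers,
with the center of an interval defined as `floor((start + end)/2)` — the
floor keeps all arithmetic in integer base pairs and is the only point where
an odd-length interval needs a tie-break. Features on different chromosomes
are at infinite distance (a sentinel value, so a cross-chromosome pair can
never satisfy a proximity threshold by accident).

Liftover maps an interval to the target assembly only when it lies wholly
inside a single aligned block of a single chain; an interval that straddles
an alignment gap, or that no block covers, is reported as unmapped with a
reason code rather than truncated or silently dropped. This mirrors the
reject behavior of the standard liftOver tool. Reverse-strand chains
re-express coordinates on the forward strand of the target and flip the
feature's strand. In the pipeline, promoters that lose any of their 15
probes to liftover are excluded whole, and the exclusion count is logged;
how such partial promoters "should" be handled is not derivable from the
data model, and dropping them keeps every retained promoter structurally
identical.

## Probe-level association

A promoter tile carries exactly 15 non-overlapping 50-bp probes; the
promoter boundary runs from the start of probe 1 to the end of probe 15.

* **MET± dichotomization.** The continuous probe value is split at the
  median of all classified probes by default (scale-free and reproducible
  across array normalizations), with an absolute-threshold override for data
  whose scale is meaningful. Values exactly at the cutoff go to MET− —
  deterministic, stated once. If all values are identical everything is
  MET− and a warning is emitted.
* **AGO± labeling.** A probe is AGO+ iff the nearest site center is within
  `d_max` bp of the probe center. The single-table default is
  `d_max = 500 bp`, with a sweep {50, 100, 200, 500, 1000} bp always
  reported, because "proximity" has no canonical radius for 50-bp probes
  against short binding sites; reporting the sweep makes the choice visible
  instead of baked in.
* **Statistics.** OR = ad/(bc); 95% CI = exp(ln OR ± z·√(1/a+1/b+1/c+1/d))
  with z = Φ⁻¹(0.975); χ² is the uncorrected Pearson statistic on the raw
  cells with its p-value from the χ²(1) upper tail. Yates continuity
  correction is deliberately not applied — at genome scale (10⁴–10⁵ probes)
  it is negligible and the uncorrected statistic is the conventional choice.
  When any cell is zero, 0.5 is added to all four cells for the OR and CI
  (Haldane–Anscombe) and the result is flagged; a zero row or column margin
  makes χ² undefined and it is reported as NaN, never imputed. No
  multiple-testing correction is applied across the sweep (raw p-values are
  reported; a Bonferroni pass is trivial for the caller given the report
  table).
* **Exclusive promoters.** Before tabulation, promoters whose boundary
  overlaps sites of two or more distinct protein labels are excluded, to
  avoid attributing methylation to one protein when several bind; promoters
  with no binding at all are retained as the AGO− background. The filter is
  a flag (`exclusivity`) so the unfiltered variant is one switch away.
* **Promoter correlation.** x = number of sites overlapping the boundary,
  y = sum of the 15 probe values (sum and mean are scale-equivalent for
  Pearson r; sum is the default summary). p-values come from the exact
  t-transform t = r·√((n−2)/(1−r²)) on n−2 df.
* **Profiles.** The proximity profile reports the mean methylation of
  probes whose nearest site is within each threshold of an increasing list;
  membership is cumulative by construction. The TSS profile bins site
  centers by signed offset from the TSS along the gene's transcriptional
  orientation (bin width 50 bp, matching the probe pitch), split by
  sense/antisense site strand.

## CLIP ingest

A binding site is a mapped read location — no peak calling, no cluster
merging: with short CLIP reads the mapped interval itself is the most
conservative definition of "where the protein sat". Reads mapping to more
than 30 genomic locations (strictly greater) are discarded as repeat-derived;
the count of removed reads is always reported. Multimapping is counted
genome-wide. A location is `perfect` iff its recorded mismatch, insertion
and deletion counts are all zero (edit counts are taken from the mapping
records and never recomputed from sequence); `include_approximate` mode
keeps all locations and is therefore a superset of `perfect_only`, a
containment asserted by a property test. Sites shorter than `min_length`
(default 15 bp, sweep {1, 5, 10, 15, 20, 25}) are dropped, and identical
intervals aggregate their supporting copy counts. Protein labels are
open-ended tokens (AGO1–4, PUMILIO2, …), not a closed enum, so control
proteins flow through the same code path.

The two-file input dialect (read_id/sequence/copies +
read_id/chrom/start/end/strand/mismatches/insertions/deletions) is normative
for this package; the synthetic generator emits exactly this dialect.

## COBRA estimators

The two lane formulas are implemented exactly as given in the module
docstring, including the LINE-1 divisors (92, 56, 48, 40, 28) that differ
from the fragment sizes (92, 60, 50, 42, 32) and the Alu letter order
(A↔133, B↔58, C↔75, D↔90, E↔43). The divisors are treated as effective
fragment lengths: the synthetic gel generator emits
intensity = molar count × divisor, which makes the normalization recover
molar counts exactly and the estimators provably unbiased on the forward
model. The forward models — LINE-1: fully methylated → fragments 50+42,
fully unmethylated → 60+32, singly methylated → uncut 92; Alu: both CpGs
cut when methylated, mm → 58+43 counted bands (the middle fragment is not a
counted band), mu → 58+75, um → 90+43, uu → 133 — were derived by solving
for the unique band assignment under which each printed formula equals the
true methylated-CpG fraction for every composition. They are modeling
constructs chosen for estimator consistency, not claims about the digestion
chemistry, and every gel manifest carries a note saying so.

Numerical behavior: estimators are scale-invariant in the lane intensities;
a zero denominator yields NaN with an `undefined` flag; percents outside
[0, 100] (possible on inconsistent real lanes, since F can be negative) are
reported as-is with an `out_of_range` flag, never clamped — silent clamping
would hide QC problems. Negative input intensities (over-subtracted
background) are clamped to zero with a warning at parse time, before the
estimator. Missing bands count as zero intensity and are listed in the
estimate. ΔΔCT fold change is the closed form 2^−ΔΔCT on finite CT values.

## Synthetic data: what it emulates, and what it does not

All randomness flows from one seeded `numpy` generator per emitted dataset;
outputs are byte-identical under a fixed seed, seeds are recorded as `#`
comments in every output header, and each dataset carries a JSON manifest
whose every quantity is recomputable from the emitted files
(`verify-manifest` asserts this).

* **Promoter array**: non-overlapping promoters on a synthetic chromosome
  (`chrS1`; multi-chromosome generation exists to exercise the
  cross-chromosome distance sentinel), each with 15 evenly spaced 50-bp
  probes across a 1500-bp span (contiguous tiling at the minimal 750-bp
  span), random strand, TSS placed 80% of the way into the span along the
  transcription direction (most of the tile upstream of the TSS, the usual
  promoter-array layout). Intergenic gaps are uniform on 1–5 kb.
* **Association plant**: a chosen fraction of probes (default 0.5) gets one
  binding site whose center is within 15 bp of the probe center; latent
  MET is drawn with P(MET+|AGO+) = 0.6367 and P(MET+|AGO−) = 0.3000
  (planted OR ≈ 4.089); continuous values are Gaussian around 80 (MET+) or
  20 (MET−) with sd 5 on a 0–100 scale, clipped at 0. Because the two
  components are ~12 sd apart, an absolute threshold at 50 recovers the
  latent labels essentially exactly; a median split only does so when the
  overall MET+ fraction is 0.5, so planted-recovery checks use the
  threshold rule. The labeling radius is 30 bp with site-center offsets
  ≤ 15 bp; since probe centers are ≥ 50 bp apart, a planted site can never
  fall within the radius of a neighboring probe, making the manifest AGO±
  counts exactly recoverable (the generator validates this geometric
  constraint).
* **Correlation plant**: per promoter, k ~ Poisson(2) sites placed
  uniformly inside the boundary and methylation
  y = 300 + 5·k + N(0, 41²) spread evenly over the 15 probes. The implied
  Pearson r = slope·√var(k) / √(slope²·var(k) + σ²) ≈ 0.170 is recorded
  alongside the realized sample r. The baseline 300 exists only to keep
  per-probe values non-negative (≈7 sd above zero); a location shift does
  not affect r.
* **CLIP reads**: read lengths uniform on 10–40 bp (straddling the 15-bp
  filter), 20% multimappers with 2–40 locations (so some exceed the
  30-location cutoff), 30% of locations carrying at least one edit. The
  manifest records the >30-location count and the surviving-site count for
  every (min_length, match_mode) sweep point, computed by running the real
  ingest path at generation time.
* **Gel lanes**: molecule patterns drawn multinomially (defaults: LINE-1
  60/20/20% mm/hemi/uu, Alu 25% each, 1000 molecules per lane), pushed
  through the forward model; optional multiplicative log-normal intensity
  noise with configurable CV, default 0 so exact-recovery tests are
  meaningful.

Not emulated, deliberately: real promoter sequence content, CpG islands,
repeat consensus sequences, read quality scores, array spatial artifacts,
partial digestion, or bisulfite conversion failure. Passing tests therefore
demonstrate that the estimators are correct on data matching their model
assumptions — not that those assumptions hold on any particular real
dataset.

## Problem sizes

The recovery checks run at sizes where sampling error is small but runtimes
stay in seconds: 100,000 probes (50,000 per arm) for odds-ratio recovery,
where the Wald SE of ln OR is ≈ 0.013 so the estimate lands within ±0.15 of
the plant with large margin; 20,000 promoters for correlation recovery
(SE(r) ≈ 0.007); 500 simulated tables at 2,000 probes per arm for CI
coverage; 1,000 random compositions per assay for the COBRA identity.

## Known limitations

* The Wald CI is first-order; for tables with very small cells an exact
  (conditional) interval would behave better. The Haldane-corrected CI is
  not guaranteed to bracket the uncorrected OR.
* Liftover requires an interval to sit inside one aligned block; intervals
  spanning two blocks separated by a zero-length target gap are treated as
  gap-straddling, which is conservative.
* The sequential per-chromosome mapping-stop nuance of some CLIP processing
  pipelines is not emulated; multimapper counting is genome-wide.
* The COBRA forward models are identifiability constructs; on real gels the
  band→pattern assignment and the effective-length divisors embody
  lab-specific calibration that this package takes as given.
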