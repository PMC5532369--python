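# Methods

This note documents the models, defaults and numerical choices behind
`methylguide`, and what the synthetic-data tests do and do not establish
about real data.

## Helical-geometry model

The angular position of the split-MTase fusion point around the B-DNA axis,
viewed down the helix from the dCas9 C-terminus, is modelled as a linear
function of the PAM–CpG gap *g* (bp):

θ(g, strand) = θ₀(strand) + s · τ · (g − g₀)  (mod 360°)

with twist τ = 34.3°/bp, anchor gap g₀ = 8 bp, and anchor angles
θ₀ = 20° (trans strand) and 290° (cis strand) taken from structural models
of DNA-bound dCas9 and an M.SssI homolog. The implied period of one helical
turn is 360/34.3 ≈ 10.5 bp, matching the observed ~11 bp oscillation of
methylation efficiency with gap length.

The rotation sense s (±1) is not determined by the anchor data alone; the
default is +1 (angle grows with gap) and it is exposed as a parameter. This
choice only affects polar-plot presentation: efficiency prediction is
empirical (below) and never consumes the sign. Relatedly, a single rotation
sense cannot simultaneously place the trans anchor at 20° and make "angle
near 0°" coincide exactly with the observed gap-12 optimum, which is why the
geometry module is descriptive and the angle-to-efficiency mapping is left
to the measured gap profile rather than derived from θ.

Gaps are base-pair counts: non-integer and negative gaps are rejected, never
interpolated. Angles are normalized to [0°, 360°); "same side of the helix"
proximity is measured as separation from 0°, in [0°, 180°].

## Scanner conventions

* Coordinates are 0-based half-open on the forward strand internally;
  1-based positions appear only in human-readable report columns; BED output
  uses BED conventions.
* PAMs are strict NGG (no NAG); an input `N` never satisfies any PAM
  position. Protospacers are fixed at 20 nt; a PAM without room for a
  full-length protospacer (respecting topology) is not reported.
* The **gap** is the number of bases strictly between the PAM's 3'-terminal
  base and the **cis-strand C** of the CpG, counted along the cis strand
  moving away from the protospacer. An exclusive count measured to the C
  (not the G) is one of four defensible conventions; it is fixed here,
  used consistently, and round-trips through the synthetic generator, so
  all cross-module results are convention-independent.
* CpGs on the protospacer side of the PAM, or overlapping the 23-bp
  protospacer+PAM footprint, have no gap for that PAM (they remain visible
  to the multiplex checker as blockable sites).
* Circular records wrap: PAM/protospacer windows, origin-spanning CpGs and
  gap arithmetic all use modular coordinates.

## Efficiency profile

Per-strand methylation fractions as a function of gap are a packaged
empirical *shape*, not measured data: the shipped default is

p_trans(g) = 0.02 + 0.38 · max(0, cos τ(g − 12))²,
p_cis(g) = 0.01 + 0.19 · max(0, cos τ(g − 12))²

for g in [8, 25] and zero outside. This curve was chosen once to satisfy
every externally established constraint — zero outside gaps 8–25; combined
maxima at gap 12 and one helical turn later (22); trans ≥ cis at every gap;
combined probability above 20% at both peaks; a small floor so every gap in
the window is predicted methylatable — while remaining smooth. Users with
calibration data can replace it via a three-column table (`gap`, `p_cis`,
`p_trans`); values are validated to [0, 1] on load and written/read at full
float precision.

Strand combination assumes independence: p_any = 1 − (1 − p_cis)(1 − p_trans).
Predictions map to transfer classes low (< 5%), medium (5–20%) and high
(> 20%); the medium class is closed on both ends, reading the 5–20% band
literally. Tied argmax gaps are all returned (the second-turn peak is
genuinely a 22–23 pair).

## Multiplex interference rules

dCas9 occupies the 23-bp protospacer+PAM footprint. Pair evaluation:

1. a targeted CpG whose nearer cytosine lies within `block_margin` bp of
   (or inside) the partner's footprint is **blocked**;
2. otherwise overlapping footprints are **competing** (fast exchange of the
   two complexes; each guide retains its single-guide efficiency on its own
   CpG);
3. otherwise the pair is **compatible**.

`block_margin` defaults to 4 bp — the largest distance at which blocking has
been demonstrated (blocking is also observed at 1 nt; independence is
demonstrated at 33 bp on the same strand). Any value between 5 and 32 bp is
an unmeasured extrapolation, and the checker says so in its output.
Competing guides are modelled as fully exchangeable: the effective per-
cytosine prediction is the maximum single-guide prediction, with no
occupancy-splitting factor. Blocked cytosines predict 0. dCas9's physical
footprint beyond 23 bp is folded into the margin rather than modelled.

## Synthetic-data generator

The generator emulates the structure of a reporter-plasmid methylation
experiment:

* **Reference** — CG-free random filler interleaved with planted elements:
  per target, a 20-nt protospacer + `TGG` PAM + filler + `TGCGCA` FspI site
  whose internal CpG sits exactly at the requested gap; `n_offtarget_cpgs`
  isolated background CpGs; at least two FspI-embedded CpGs total. Filler is
  generated CG-free (and junctions checked) so the CpG census is exactly
  what was planted — 240 background CpGs plus one non-target FspI CpG gives
  482 off-target cytosines, plasmid-like in scale (~2.2 kb).
* **Methylation truth** — each cytosine of each CpG, on each strand, is an
  independent Bernoulli per molecule. Target defaults are 34.4% (trans) and
  10% (cis), the characterized single-guide level at gap 12. Background
  probabilities are drawn per site from Beta(mean = 0.005, concentration
  = 100), keeping the simulated median off-target below the 1% specificity
  bound; an optional proximity mode inflates background within a window of
  the target to emulate topology-driven off-target methylation.
* **Bisulfite chemistry** — unmethylated C → T with conversion efficiency
  1.0 by default (no failed-conversion rate is modelled unless requested);
  methylated C is protected; both strands converted independently. Non-CpG
  cytosines are never methylated (the MTase is CpG-specific).
* **Reads** — single-end, uniform starts (wrapping on circular records),
  equal strand probability, substitution errors at a configurable rate,
  constant base quality. Read names encode molecule id, strand and forward
  start, so every read's true origin is available to tests. Identical seeds
  give byte-identical FASTQ.
* **FspI protection assay** — each TGCGCA copy is cut (blunt, after site
  offset 2) unless its CpG is methylated on either strand; fragment lengths
  are conserved per molecule (circular molecules with one cut linearize to
  a single full-length fragment).

Not emulated: PCR bias, quality-score structure, paired-end inserts,
fragment-size selection, supercoiling-dependent off-target topology beyond
the distance-decay option. Passing tests therefore demonstrate correctness
of the pipeline's arithmetic and statistics under idealized sequencing, not
robustness to real library artefacts.

## Quantification

Alignment is a native three-letter (bisulfite-aware) seed-and-verify scan:
reads are compared in C→T space against the converted top strand and, after
reverse complementing, in G→A space against the converted bottom strand.
Mismatches are counted in collapsed space, so methylation-state differences
are never penalized (a true C↔T sequencing error on a cytosine is likewise
forgiven — inherent to three-letter alignment). Seeds are `max_mismatches+1`
non-overlapping k-mers (pigeonhole: one must be error-free), k ≤ 16. The
best placement wins; ties are discarded as ambiguous. This is exact and fast
for plasmid-scale references and deliberately unsuitable for genomes.

Calling: at each reference cytosine on the read's assigned strand, read base
C = methylated, T = unmethylated, anything else = no call. Fractions are
reported as NaN (never 0) at zero coverage. Sites below 10 calls
(configurable) are excluded from medians and correlations; the threshold
avoids unstable ratios at thin coverage.

Summary statistics:

* **fold preference** = max fraction over target cytosines / max(median
  off-target CpG fraction, pseudo-floor), with pseudo-floor one half call
  over the total off-target calls — keeps the ratio finite when the
  finite-sample background median is exactly zero;
* **profile comparison** = squared Pearson correlation of raw fractions over
  shared covered positions (≥ 3 required; zero variance → NaN). No
  transformation is applied, and no multiple-testing machinery — the
  pipeline reports estimates and descriptive statistics only;
* **co-methylation** = per molecule (via read provenance), the fraction of
  molecules methylated at both members of a position pair among molecules
  informative for both; the diagonal is the per-molecule marginal.

## Problem sizes and determinism

The test suite and the acceptance script run the full pipeline on a ~2.2-kb
reference with ~240 background CpGs, 2 000 molecules and mean coverage
500–1000× (tens of thousands of 75-nt reads) — deep enough that the target
fraction is recovered within ±2–3 binomial standard errors of truth, and the
whole run completes in seconds. All stochastic steps take explicit seeds;
generator, read sampler and simulator are reproducible to the byte.

## Known limitations

* The efficiency profile's numeric values between the constrained features
  are a modelling choice; calibrating them from user data is future work.
* The blocking threshold between 4 and 33 bp is an engineering default, not
  a measurement.
* The aligner is exhaustive and in-memory; it is not a genome-scale mapper
  and emits no SAM/BAM.
* Human-cell-scale effects (chromatin accessibility, endogenous maintenance
  methylation) are outside the model; a promoter site can underperform its
  gap-based prediction for reasons the toolkit cannot see.
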