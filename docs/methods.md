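# Methods

`amptox` quantifies the standard experimental readouts of a cytotoxic-peptide
study: sequence descriptors of the peptide itself, plate-based hemolysis /
LDH-release / MTT assays with dose-response fitting, annexin V / propidium
iodide (AV/PI) flow-cytometry quadrant analysis, and a pathway activation
strength (PAS) score over targeted expression data. This note records the
models, the parameters that matter, and the choices made where the design was
open.

## Peptide descriptors

Masses are sums of per-residue constants plus one water, for the 20 canonical
residues only; the residue tables and water/proton constants come from
pyteomics (monoisotopic water 18.010565 Da, proton 1.007276 Da). C-terminal
amidation is the single supported modification, applied as a constant shift
of −0.984 Da (−OH → −NH2). The protonated-ion m/z is
(M + z·m_proton)/z. GRAVY is the plain arithmetic mean of Kyte–Doolittle
hydropathy values (Biopython's table); basicity counts Arg, Lys and His —
His is weakly basic at physiological pH but is conventionally included in
the cationicity census of host-defense peptides. Display conventions follow
the field: monoisotopic mass to one decimal, average mass to the nearest
integer, GRAVY to three decimals; full precision is kept internally.

An ambiguity worth recording: for an amidated 27-mer the average mass rounds
one dalton lower than for the free acid. The recombinant peptide analysed
here is the non-amidated form, and the free-acid average mass is what the
descriptor bundle reports by default.

## Plate assays and dose-response

All three percentage readouts are the same affine normalization
`100·(signal − low)/(high − low)` with assay-specific control roles
(hemolysis: 0%/100% lysis; LDH: spontaneous/maximal release; MTT:
blank/untreated). Percentages are not clipped: the formulas can leave
[0, 100] on noisy wells and clipping would hide that. Controls that fail to
separate (high ≤ low) raise immediately rather than producing a sign-flipped
scale.

Dose-response curves are summarized by a four-parameter logistic on log10
dose, `y = bottom + (top − bottom)/(1 + 10^(hill·(log c − log m)))`,
fitted by bounded Levenberg–Marquardt (scipy `curve_fit`) on all replicate
wells jointly — pooling preserves the error structure that averaging per
dose would erase. Initialization: top/bottom from the response extremes,
midpoint from the dose nearest the half-signal level, |hill| = 1; the
midpoint is bounded within ±2 decades of the tested range so the optimizer
cannot wander off-scale. Because the fit lives on log dose it is exactly
equivariant under unit relabeling (μM → nM multiplies the midpoint by 1000).

The midpoint `m` is the headline (relative) IC50; the dose where the fitted
curve crosses 50% of control is reported alongside as the absolute IC50 —
for a symmetric 0–100% curve the two coincide. A fit needs ≥ 4 distinct
doses and ≥ 20 percentage points of response span; less span is a no-signal
error, not a number. Monotonically increasing viability with dose on a
falling-curve fit yields a warning and an undefined IC50. A fitted midpoint
beyond the highest tested dose is censored and printed as `> max` (the
"ND (>10)" convention of cytotoxicity tables); censored values propagate
through the selectivity index (IC50_normal / IC50_tumor) as lower bounds.
Profile-likelihood confidence intervals and IC50 hypothesis tests are out
of scope.

## Cytometry

Quadrant classification is a strict per-channel threshold comparison
(positive means strictly above the gate; on-gate events are negative, a
deterministic tie-break). Gates are either supplied or set at the 99.5th
percentile of an unstained-control cloud per channel; no density-based
auto-gating. The AV−PI+ quadrant is kept as its own reported class rather
than merged into the necrotic count. "Dead" for all aggregate comparisons is
the complement of the viable (AV−PI−) quadrant.

The death-mode signature formalizes the kinetic argument that separates
membrane-lytic (necrotic) from apoptotic killing on a concentration × time
panel of dead fractions: *necrosis-like* if the dead fraction is flat in
time at every concentration (range ≤ `time_tol`, default 10 points) while
spreading by ≥ `conc_min_effect` (default 20 points) across concentrations
at some time; *apoptosis-like* if it rises monotonically in time by more
than `time_tol` at some concentration; otherwise inconclusive. The defaults
are package choices — the underlying biology is stated qualitatively in the
literature — and both are arguments. Caspase independence compares the dead
fraction with and without a pan-caspase inhibitor (Z-VAD-FMK): unchanged
within `tol` (default 5 points) argues for caspase-independent death.

## Pathway activation scoring

The transcriptomic pipeline is: (1) probe signals floored at 1.0 (raw
intensity scale, to keep zeros out of logs) and geometrically averaged per
gene; (2) quantile normalization across samples — each column's sorted
values are replaced by the across-sample mean of sorted values, with ties
receiving the mean of their target quantiles (the tie behaviour was checked
against limma's `normalizeQuantiles(ties=TRUE)` and frozen into a test);
the transform is idempotent and rank-preserving; (3) case-to-normal ratios
(CNR): each treated sample's gene intensity over the *arithmetic* mean of
the pooled control group (geometric averaging is reserved for probe
replicates); (4) pathway activation strength for pathway p,

    PAS_p = Σ_n ARR_np · log10(CNR_n) / N,

where ARR ∈ {−1, −0.5, 0, 0.5, 1} encodes each gene's activator/repressor
role and both the sum and N run over pathway genes present in the data —
genes absent from the panel are excluded from numerator and denominator, so
a sparsely measured pathway is not shrunk toward zero; a pathway with no
measured gene is reported missing, not 0. "lg" is log10 throughout; another
base would only rescale the score. Positive PAS means activation relative
to controls, negative repression. PAS carries no null model: calls are
sign-based only, there are no p-values, and no multiple-testing machinery is
attached. Treated samples are scored individually against the pooled
controls; a group-level PAS is also reported as the replicate mean per
concentration.

## Synthetic data

The expression generator emulates a targeted-chip cytotoxicity study:
untreated controls in triplicate plus treatment in triplicate at 1.25, 2.5
and 5 μM; the full-scale default is a 2016-gene panel in 334 pathways, and
tests use a proportionally reduced 200-gene / 20-pathway panel. Baseline
gene intensities are log2-normal (mean 8, sd 1.5 — a realistic microarray
intensity scale) with probe/sample log2 noise sd 0.25. Perturbations are
planted per pathway as a log2 fold-change and propagated to genes through
the ARR weights (activators shift by +lfc, repressors by −lfc, half-weight
genes by half, ARR = 0 genes not at all), which makes the expected PAS
analytic: `lfc · log10(2) · ΣARR² / N`. Generated pathways cycle the weights
(1, 1, −1, 0.5, −0.5, 0) so every pathway contains all role classes, and
tile the gene panel without overlap.

Each generator consumes one integer seed driving a single `numpy` Generator
stream; same inputs give byte-identical output. At zero noise every analysis
stage returns its planted truth exactly — with one deliberate caveat:
quantile normalization forces all samples onto a common distribution, so a
perturbed sample's planted magnitudes are slightly reshaped even at zero
noise (signs are untouched at the planted effect sizes). The exact
zero-noise round-trip is therefore stated, and tested, with normalization
off; the default pipeline keeps it on, as real studies do.

What the generator does not emulate: spatial chip artifacts, probe GC bias,
background gradients, biological co-expression beyond pathway blocks,
cytometry spectral overlap, or plate-edge effects. Recovery tests passing on
this generator show the estimators are correct under the stated noise model,
not that real data meet that model.

## Problem sizes in tests

The scaled-down study emulation (200 genes, 20 pathways, 12 samples, 50
seeds), the 100-dataset dose-response recovery, and 10,000-event cytometry
mixtures run in a few seconds total; the full-scale 2016-gene design is the
generator default and runs in well under a minute when wanted.
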