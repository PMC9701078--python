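# Methods

## Oxygen transport model

### Physical picture

The chip is a gas-permeable PDMS device with two parallel channels
(apical 1 × 1 mm, basal 1 × 0.2 mm, length 16.7 mm) separated by a 50 µm
porous membrane. An 80 µm stratified vaginal epithelium sits on the membrane
in the apical channel; a 50 µm fibroblast stroma hangs from its lower face in
the basal channel. Oxygen enters by two routes — saturated medium perfused
through both channels at 40 µL/h, and diffusion through the PDMS blocks from
the incubator — and leaves only by aerobic consumption in the two tissue
layers. The question the model answers is how hypoxic the epithelial lumen
becomes under these culture conditions.

### Governing equations and discretization

We model the longitudinal section (x = channel length, y = vertical stack;
channel width enters only through the flow-rate→velocity conversion) and
solve

    ∂c/∂t = ∇·(D ∇c) − u ∂c/∂x − V_max c/(K_m + c)·1_tissue

with a cell-centered finite-volume scheme on a structured grid. Rows are
allocated to the seven material bands (basal PDMS, basal medium, stroma,
membrane, epithelium, apical medium, apical PDMS) proportionally to band
thickness with at least one row each; every band is internally uniform, so
band heights match the geometry exactly. Face diffusivities are harmonic
means, which preserves flux continuity across material interfaces.

At 40 µL/h the channel Reynolds number is ≪ 1 and the channels are long, so
the incompressible-flow problem reduces to the fully developed
plane-Poiseuille profile over each *open* gap (channel height minus the
tissue layer): u(y) = 6·ū·ξ(1−ξ), sampled at cell centers. Advection is
first-order upwind; the upwind diffusion this introduces is small relative to
molecular diffusion at these Péclet numbers and keeps the operator an
M-matrix, which guarantees the discrete maximum principle (all concentrations
in [0, c_sat]).

Boundary conditions: Dirichlet saturation c_sat = k_H·pO₂ on the outer
top/bottom PDMS faces (incubator contact) and at both channel inlets;
advective outflow with zero diffusive flux at the outlets; zero flux on the
lateral PDMS ends. Concentration is treated as continuous across material
interfaces (no PDMS/medium solubility jump); a partitioned model could shift
the PDMS contribution somewhat and is a known difference from solver setups
that include it.

The Michaelis–Menten sink is Picard-linearized (rate = [V_max/(K_m+c_prev)]·c),
iterated to max|Δc| < 1e-8 mol/m³ for steady solves; the linearization keeps
the system an M-matrix, so iterates stay nonnegative. Transient runs use
backward Euler (default dt = 10 s) with the sink coefficient lagged one step —
unconditionally stable and monotone, appropriate for the 200-minute
relaxation from a saturated initial state.

Mass closure: at steady state, advective inflow + net diffusive influx
through the saturation boundaries = advective outflow + total consumption.
The solver reports |residual|/influx as a diagnostic; it closes to ~1e-8 on
the reference grid. Note the diffusive boundary term is part of the influx —
with tissue consumption active the incubator faces are a net O₂ source, not
a zero.

### Parameters

| parameter | default | unit | rationale |
|---|---|---|---|
| D_medium | 3.0e-9 | m²/s | O₂ in aqueous medium at 37 °C |
| D_pdms | 3.4e-9 | m²/s | O₂ in PDMS (literature range 3–4e-9) |
| D_epithelium, D_stroma | 1.5e-9 | m²/s | ~half of water, typical soft tissue |
| membrane porosity φ | 0.05 | — | 7 µm pores; D_eff = φ·D_medium + (1−φ)·D_pdms |
| k_H (Henry) | 1.3e-3 | mol·m⁻³·mmHg⁻¹ | aqueous O₂ solubility at 37 °C |
| K_m | 1.0e-3 | mol/m³ | typical cellular O₂ uptake half-saturation |
| V_max (epithelium) | 2.642059e-3 | mol·m⁻³·s⁻¹ | calibrated, see below |
| V_max (stroma) | = epithelial value | mol·m⁻³·s⁻¹ | no separate datum |
| Q (both channels) | 40 | µL/h | culture perfusion rate |
| ambient pO₂ | 145 | mmHg | incubator at 37 °C |

None of the transport or kinetic constants is a measured property of this
specific tissue; they are literature-scale values, all overridable through
the config file. The shipped V_max was obtained once by bisection
(`calibrate_uptake`, nx = 200, ny = 120, relative tolerance 1e-4) so that the
steady concentration at the epithelium apical surface at mid-length equals
0.11 mol/m³, the lumen oxygen level the chip is designed to sustain
(≈ 11% O₂; `oxygen_percent` converts via percent of one 760 mmHg
atmosphere). The calibration anchors the model's one free kinetic scale to
the device's operating point; the resulting value, ~2.6e-3 mol·m⁻³·s⁻¹, is
within the physiological range for metabolically active epithelia. The
continuous-apical-flow configuration is modeled (the culture protocol's
intermittent apical flow can be emulated by setting Q_apical to zero, but is
not part of the standard runs).

"On top of the epithelial layer" is read as the mid-length point of the
epithelium's apical face; a channel-averaged probe (`..._mean`) is also
provided and differs from the mid-length value by a few percent.

### Verification

The steady solver is checked against the closed-form 1D slab with zero-order
consumption (c(y) = c₀ − (q/D)(Ly − y²/2), matched within 1% at ny = 200,
with monotone error decay under refinement), the uniform no-sink solution
(exact), a zero-flow 2D/1D consistency test, and a randomized 20-configuration
maximum-principle sweep. Transient runs are required to land within 2%
pointwise of the steady solution after 200 min and to relax monotonically.
Calibration is verified by round-trip recovery of a known V_max to 1%.

## Strain composition

### Marker selection

For a defined consortium of sequenced strains, a gene is a strain-specific
marker iff (i) it matches no other gene of its own strain (single-copy) and
(ii) it matches no gene of any other strain (unique). "Matches" is evaluated
on the best local alignment (exact Smith–Waterman dynamic programming,
match +1, mismatch −1, gap −2, via Biopython's PairwiseAligner): identity ≥
70% of alignment columns and coverage ≥ 70% of the shorter sequence by
aligned positions. The shorter-sequence denominator is the reciprocal-
coverage convention; it is configurable (`overlap_denominator="longer"`) for
pipelines that normalize by the longer gene. A shared-k-mer prescreen
(k = 11) skips alignments for pairs that cannot plausibly reach the
threshold; it is exact in practice well above the identity cutoff and can be
disabled (`prescreen_k=None`) for exhaustive all-vs-all. This rule operates
at defined-consortium scale (tens of genes per strain); genome-scale ortholog
clustering is out of scope, and precomputed coverage tables or SAM
alignments can be supplied instead.

### Trimming

FASTQ reads are quality-trimmed with a 5'→3' sliding window (4 bp, mean
Phred ≥ 20): at the first failing window the read is cut before the window's
start, so output is always a prefix; reads shorter than the window are
evaluated as one window; results below 15 bp are dropped. Window-edge
semantics differ between trimmer implementations and flags; this dialect is
fixed by an independent brute-force oracle test.

### Assignment and quantification

The built-in mapper assigns a read to a marker gene iff they share at least
one exact canonical 31-mer; reads hitting more than one gene (within or
across strains) are discarded as ambiguous — markers are unique by
construction, so collisions indicate repeats or errors. Uniform substitution
errors thin k-mer matches roughly uniformly across genes, leaving median
ratios approximately unbiased (verified end-to-end). Host reads share no
31-mer with the markers and surface as the unassigned fraction; host-read
*removal* is an upstream concern. External alignments are ingested from SAM
(primary records, configurable MAPQ floor, reference-aligned bases / gene
length).

Per-gene coverage under the uniform model is reads × read_length /
gene_length. Strain relative abundance is the median coverage over the
strain's markers divided by the sum of medians across strains (even counts:
mean of the central pair). The median makes the estimate robust to
individual outlier genes; it is invariant to global coverage rescaling and
strain permutation. No genome-size or GC correction is applied. An all-zero
table yields an explicit no-signal result rather than NaN ratios silently.

## Assay calculators

Apparent permeability: P_app = (V_r·C_r)/(A·t·C̄_d) with C̄_d =
(C_d_out·V_d + C_r·V_r)/(V_d+V_r), in cm/s with volumes in mL, area in cm²,
time in s. The printed form of this equation is ambiguous in its
parenthesization; this reading divides by the volume-weighted mean donor
concentration, the cited standard form, and puts barrier-forming chips in
the expected 1e-6–1e-7 cm/s range. P_app is invariant to rescaling both
concentrations (unit freedom).

CFU accounting: each record contributes cfu/mL × collected volume; the
cumulative total is all effluent collections plus the 72-h epithelial digest
(requesting a cumulative total without a digest is an error). Percent
adherence = 100 × digest CFU / T0 inoculum CFU. Percent viability = 100 ×
live cells / control live cells. Cytokine fold changes are per-analyte
condition-mean over control-mean with per-group s.e.m.; hypothesis testing
is deliberately excluded (done downstream in standard tools).

## Synthetic data

The generators produce every pipeline input with known ground truth:

- **Gene sets**: core genes copied across strains at ~95% identity (they
  cross-match and are excluded from markers), unique genes as independent
  random sequences; marker selection is re-run at generation time to verify
  the construction. Default 4 strains × (6 core + 8 unique) × 600 bp.
- **Reads**: 150 bp, strains sampled at the specified ratios, positions
  uniform, strand random, substitution errors (default 0.5%), Q35 bases with
  an optional Q10 tail on 10% of reads to exercise trimming, and a host
  fraction drawn from 20 random 2-kb decoy contigs (up to the ~97% host
  content seen in epithelial digest libraries). The total bacterial read
  count is set so the consortium-wide mean gene depth equals
  `mean_marker_depth_x` (default 60×).
- **Tracer experiments**: the receiver relaxes toward the pooled equilibrium
  concentration C_eq = C_d_in·V_d/(V_r+V_d) at rate P_app·A/V_r, with the
  dosing effluent fixed by exact mass conservation. This defines P_app
  against the same volume-weighted mean donor concentration the estimator
  divides by, so the estimator recovers P·(1−e⁻ˣ)/x, x = P·A·t/V_r — the
  true value to first order in the transferred fraction (<1% bias in the
  small-transfer regime used for validation).
- **CFU tables**: exponential growth from a 10⁵ CFU / 35 µL inoculum
  (default rate 0.05 h⁻¹), a fixed adherent fraction recovered in the 72-h
  digest, the rest in 160 µL effluents at 24/48/72 h, with multiplicative
  lognormal plating noise (σ = 0.3 natural-log units).

What the generators do **not** emulate: real gene phylogeny and shared
accessory content beyond the uniform-identity core, instrument-specific
error and quality profiles, PCR/GC coverage bias, genome-size differences
between strains, and partial tracer mixing. Passing closed-loop tests
therefore demonstrates correctness of the estimators under their stated
models, not robustness to every artifact of real libraries.

## Problem sizes

The reference oxygen solve uses nx = 200, ny = 120 (24 000 cells), chosen
because the probe value changes by well under 1% on further refinement.
Routine tests use coarser grids (nx 20–60) and the transient consistency
check runs at nx = 60, ny = 80 with dt = 20 s; the strain-recovery benchmark
uses 4 strains × 8.4 kb of genes at 50× consortium-mean depth with 90% host
reads (~112 000 reads).
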