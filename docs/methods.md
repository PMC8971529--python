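# Methods

## Model

The covalent modification cycle (CMC) treats a transcription factor
interconverted between inactive and phosphorylated forms by a kinase
(total `K_t`) and a phosphatase (total `P_t`), each following
Michaelis–Menten kinetics. Conservation is implicit: the unphosphorylated
pool is `X_t − X*`, so `X + X* = X_t` holds identically at all times.
The closed loop couples the cycle to a gene-expression process in which
the phosphorylated factor activates a Hill promoter (cooperativity fixed
at 2, since the phosphorylated regulator binds DNA as a dimer) driving
production of the phosphatase, with the output co-transcribed at
stoichiometry `ρ` (`Y = ρ P_t`). The disturbance `w ∈ [0, 1)` is a fold
reduction of production, lumping post-transcriptional knockdown and
transcriptional-resource loading into one parameter.

Assumptions worth making explicit:

* single-timepoint steady-state reasoning — transient transfection
  dynamics (DNA dilution, decaying setpoints) are out of scope;
* no retroactivity from downstream promoter sites on `X*`;
* free-enzyme Michaelis–Menten forms, valid when substrate is not
  sequestered appreciably by either enzyme;
* all concentrations in arbitrary consistent units (no absolute
  calibration is attempted; fluorescence is MEFL-like linear units).

## Steady states and numerics

The cycle balance cross-multiplies to a quadratic
`A X² + B X + C = 0` with `A = θ_p P − θ_k K_t`,
`B = θ_k K_t (X_t − K_Mp) − θ_p P (X_t + K_Mk)`, `C = θ_k K_t K_Mp X_t`.
Since the balance function is positive at 0 and negative at `X_t`,
exactly one root is physical; it is taken from the numerically stable
root pair, with a bracketed `brentq` polish if the selected root's
residual exceeds `1e-10` of the rate scale. Degenerate corners:
`K_t = 0 → X* = 0`, `P = 0 → X* = X_t`, and both absent returns 0 with
an explicit warning (the balance does not determine the state).

The closed-loop fixed point is unique because production
`α(1−w)φ(h(P))` is non-increasing in `P` (φ′ > 0, h′ < 0) while removal
`γP` increases; it is bracketed on `P ∈ [0, α(1−w)/γ]` and solved with
`brentq` at machine-precision tolerances. A vectorised variant
(`closedloop_output`) runs 100 monotone bisection steps simultaneously
over per-cell parameter arrays; at ~1e-30 relative bracket width this is
exact to double precision and is what makes per-cell rendering of 10⁴+
cells fast.

Time integration uses LSODA (stiff-capable; the zero-order cycle regime
is stiff) at rtol 1e-8. The test-suite ODE oracle integrates in doubling
time chunks until the state moves less than `1e-10 X_t` per chunk, which
bounds the remaining transient by the same order.

Sensitivity to disturbance: `S_OL = 1/(1−w)`;
`S_CL = S_OL/(1+T)` with `T = (α/γ)(1−w)|φ′(X*) · dX*/dP|`, where
`dX*/dP` comes from the implicit function theorem on the cycle balance.
Written against the output variable the chain-rule factor `1/ρ` from
`d/dY` cancels against the output production rate `ρα`, so the gain is
independent of `ρ`; this form agrees with a central finite-difference
oracle (`Δw = 1e-4`, chosen to balance truncation against cancellation
given machine-precision fixed-point solves) to better than 1e-4
relative across random parameter sweeps. When the promoter is deeply
saturated φ′ underflows and `S_CL = S_OL` is reported — feedback cannot
act through a flat promoter.

## Hill fitting

Activation `y = α₀ + (α−α₀)x²/(K² + x²)` and the mirrored repression
form are fitted by least squares on the linear output scale (the
objective is the plain sum of squared residuals), with n never fitted.
Initialisation is `α₀ = min y`, `α = max y`, `K = geometric mean of x`,
with five starts jittered ±0.5 dex in `K`; bounds keep all parameters
non-negative. Non-positive observations are excluded with a warning,
mirroring the pipeline discard rule. Flat data degenerate to `α = α₀`
with `K` flagged unidentifiable, as is a fitted `K` more than a decade
outside the sampled dose range.

CV(RMSE) is reported in two labelled variants: `sqrt((1/ȳ) Σ r²)/ȳ`
(dimensionally odd — the inner factor is conventionally 1/n — but a
normalisation existing analysis toolkits report, kept as primary for
comparability) and the conventional `sqrt((1/n) Σ r²)/ȳ`. The
discrepancy is noted, not silently fixed.

## Synthetic data generator

The generator emulates poly-transfection flow cytometry: each DNA-lipid
complex is taken up independently, so per-cell dosages of different
complexes decorrelate apart from a shared per-cell transfectability
factor. Per complex, dosage = `10^(shared + draw)` with the complex draw
`N(median_dex, sd_dex)`; a log-normal dosage law is a modelling choice
(the delivery literature reports heavy-tailed uptake but no canonical
form). Defaults, chosen once as typical lipofection heterogeneity and
exposed as config rather than constants:

| parameter | default | meaning |
|---|---|---|
| dosage sd | 0.8 dex | per-complex uptake spread |
| transfectability sd | 0.4 dex | shared per-cell factor |
| untransfected fraction | 0.3 | zero dosage across all complexes |
| autofluorescence | N(100, 50) MEFL | additive; makes some events ≤ 0 |
| measurement CV | 25% | multiplicative log-normal per channel |
| kinase potency | 0.01 /MEFL | `K_t` per unit kinase-plasmid dosage |
| phosphatase potency | 0.05 /MEFL | constitutive `P_t` per unit dosage |
| basal dephosphorylation | 1.0 conc. units | background activity, OL only |
| α per output dosage | 1.0 | closed-loop production scale |
| output gain | 50 MEFL/conc. | reporter brightness |

The 5:1 phosphatase:kinase potency ratio reflects the engineered
phosphatase being the more potent enzyme per copy (its half-deactivation
dosage is severalfold below the kinase's half-activation); together with
a miR-21 retained fraction of 0.05 it places the classifier's two
switching thresholds at K:P ≈ 0.25 and ≈ 5, whose geometric mean (≈1.1)
is the planted ratio-scan optimum near 1:1.

Rendering is steady-state per cell (measurements are 48 h snapshots).
`X_t` is clamped to a constant, idealising the endoRNase feedforward
loop that holds the transcription factor dosage-invariant; it is an
idealisation, not a mechanistic endoRNase model. Open loop (OL), the
phosphatase level is constitutive (its own complex dosage times the
miRNA retained fraction) plus a small background dephosphorylation
activity — without it, zero phosphatase would pin `X* = X_t` and
erase kinase responsiveness, which real OL circuits retain. Closed loop
(CL), the output/phosphatase pair is co-transcribed with `α` scaled by
output-plasmid dosage and the fixed point solved per cell; the
background term is omitted there as negligible against the feedback
phosphatase. Post-transcriptional perturbations enter as `w` on the
shared transcript (CL) or on the output mRNA (OL); resource loading is
`α → α/(1 + λG)` with `G` the perturbation dosage — the simplest
saturating competition form.

What the generator does **not** emulate: spectral overlap and
compensation, bead-based MEFL calibration, instrument-specific
saturation, transfection-reagent chemistry, cell-cycle and volume
effects, or mechanistic resource competition. Passing tests therefore
demonstrate internal consistency of the analysis chain and the
qualitative model predictions (feedback lowers noise and fold-response),
not quantitative agreement with any particular instrument dataset.

## Pipeline conventions

Binning assigns a cell to a bin iff every binned channel value is
greater than the low edge and ≤ the high edge; out-of-range values are
unassigned, never clamped. Bins with ≤ 3 cells are dropped. Non-positive
fluorescence values are discarded before medians and IQRs (uniformly, in
every stage). All quantiles interpolate linearly between order
statistics. Fold-changes divide per-bin medians; across repeats the
central value is the mean of log2 fold-changes (not log2 of the mean).
Robustness = `100(1 − |1 − fold|)` percent, which goes negative beyond
twofold deviation — documented, not clipped. Noise is the IQR of log10
of positive values. Default bin edges are log-spaced with a configurable
density (6/decade default; a package convention, not a protocol value).
Transfected-cell gating keeps cells above threshold in ANY listed
channel; the threshold defaults to the 99.9th percentile of a designated
negative-control population.

## Classifier machinery

ROC curves use the fixed 17-threshold schedule (−10⁸, 0, then 15
log-spaced values 10³–10⁸) with trapezoidal AUC over points sorted by
FPR (ties broken by TPR) and anchored at (0,0) and (1,1). The bi-normal
model fixes the negative class at N(0,1) and fits (μ₂, σ₂) of the
positive class by least squares in TPR space on interior points
(endpoints would need infinite probits); closed-form
AUC = Φ(μ₂/√(1+σ₂²)). The biexponential transform is
`asinh(x/2w)/ln 10` with default width 150 MEFL — an arcsinh
transform that is ~log10 for bright cells and tolerates negatives; the
exact instrument transform is not recoverable, so the width and
transform are pluggable. The ratio scan walks component ratios in
powers of 2 from ~1024:1 to 1:1024 ("roughly halving"; the 1000:1
endpoints are honoured within one step), selects cells within 0.25
biexponential units (Euclidean, over all marker dimensions present) of
the dosage trajectory for each ratio, and reports accuracy
(mean of sensitivity and specificity) per ratio.

## Orthogonality scoring

Reference assignment is greedy — repeatedly take the global maximum of
the unblocked crosstalk matrix, block its row and column — with ties
broken by first occurrence in row-major order (determinism the original
description leaves open). The score multiplies, over references, the
reference divided by every other entry in its row and column; the
subset search enumerates either matched HK–RR index sets
(`cognate_pairs`, the default reading of "protein pairs") or independent
row/column subsets — both provided since the original wording is
ambiguous. Search internals work in log10 scores to avoid overflow for
large contrast ratios; zero entries are rejected rather than floored
(callers may pre-floor at a detection limit).

## Problem sizes and limitations

The shipped test and acceptance runs use 1000-draw parameter sweeps for
the solver and sensitivity checks, 50 seeds × 5000 cells for the
noise comparison, 3 repeats × 20 000 cells for perturbation
fold-changes, and 10⁴ cells per class for the classifier — sizes at
which every stochastic margin in the suite is comfortably stable while
the whole suite stays fast on a laptop-class single core.

Known limitations: no stochastic (SSA) or spatial simulation; no
multi-step phosphorelays; no receptor/ligand layer upstream of `K_t`;
no reading of binary cytometry files (event tables are CSV); reported
AUC/robustness numbers on synthetic data characterise the method, not
any biological dataset.
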