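# phosphocycle

Models and analysis tools for engineered phosphorylation-based signal
processing in mammalian cells.

Synthetic covalent modification cycles (CMCs) built from bacterial
two-component signaling proteins — a kinase and a phosphatase derived
from EnvZ acting on the response regulator OmpR fused to an activation
domain — give tunable, analog control over transcription in mammalian
cells. Co-expressing the phosphatase with the output gene closes a
negative feedback loop that suppresses cell-to-cell noise and buffers
the output against disturbances such as miRNA knockdown or
transcriptional-resource loading. This package implements the
computational core of that programme for modellers and cytometry
analysts: the cycle/feedback ODE model and its sensitivity theory, the
poly-transfection flow-cytometry pipeline, miRNA cell-classifier
metrics, Hill dose–response fitting, orthogonal kinase/regulator subset
selection, and a synthetic data generator so every stage runs without
instrument data.

## The model

The phosphorylated transcription factor `X*` follows Goldbeter–Koshland
kinetics with total substrate `X_t`, kinase `K_t` and phosphatase `P_t`:

    dX*/dt = θ_k (X_t − X*) K_t / ((X_t − X*) + K_Mk)
           − θ_p X* P_t / (X* + K_Mp)

`X*` activates a Hill promoter φ(X*) (cooperativity 2) driving the
phosphatase itself, with the output co-transcribed (`Y = ρ P_t`):

    dP_t/dt = α (1 − w) φ(X*) − γ P_t

`w ∈ [0, 1)` is a disturbance — a fold reduction of production. The
relative sensitivity of the output to `w` is `S_OL = 1/(1 − w)` open
loop and `S_CL = S_OL / (1 + T)` closed loop, with loop gain
`T = (α/γ)(1 − w)|φ′ · h′|` through the cycle transfer curve `h`. With
saturated enzymes (`K_Mp ≪ X*`, `X_t ≫ K_Mk`) and an unsaturated
promoter the loop approximates integral control and the output settles
near the setpoint `ρ θ_k K_t / θ_p`, independent of `α`, `γ` and `w`.

Modules: `cmc_model` (steady states, time courses, sensitivities),
`dose_response` (Hill fits, CV(RMSE)), `synthetic_data` (poly-transfection
event generator), `flow_pipeline` (gating, multi-dimensional binning,
fold-change, robustness, log10-IQR noise), `classifier` (threshold
metrics, ROC/AUC, bi-normal model, biexponential ratio scan),
`orthogonality` (crosstalk-matrix scoring, exhaustive subset search).

## Worked example

```python
import numpy as np
from phosphocycle import (
    CMCParams, PromoterHill, closedloop_steady_state,
    quasi_integral_setpoint, sensitivity_cl,
)
from phosphocycle.flow_pipeline import bin_events, log_bin_edges, summarize_bins
from phosphocycle.synthetic_data import feedback_experiment

params = CMCParams(
    theta_k=1.0, theta_p=1.0, K_Mk=1.0, K_Mp=1.0,
    X_t=1000.0, K_t=100.0, alpha=1e4, gamma=1.0,
    phi=PromoterHill(K_D=500.0),
)
ss = closedloop_steady_state(params)
print(f"closed-loop output Y = {ss.Y:.1f}  "
      f"(quasi-integral setpoint {quasi_integral_setpoint(params):.1f})")
res = sensitivity_cl(params.with_(w=0.5))
print(f"S_OL = {res.S_OL:.2f}, S_CL = {res.S_CL:.4f}  (loop gain T = {res.T_gain:.0f})")

edges = log_bin_edges(3, 6, 2)
for topology, weight in [("CL", 1.0), ("OL", 1/27)]:
    events = feedback_experiment(20_000, seed=1, topology=topology, output_weight=weight)
    summary = summarize_bins(bin_events(events, ["K_marker"], edges), events, "output")
    hi = [b for b in summary.index if b[0] >= 4]
    print(f"{topology}: median output {np.nanmedian(summary.loc[hi,'median']):9.0f} MEFL, "
          f"log10-IQR noise {np.nanmean(summary.loc[hi,'iqr_log10']):.2f} dex")
```

prints

```
closed-loop output Y = 101.9  (quasi-integral setpoint 100.0)
S_OL = 2.00, S_CL = 0.0140  (loop gain T = 142)
CL: median output    132454 MEFL, log10-IQR noise 0.33 dex
OL: median output     26418 MEFL, log10-IQR noise 1.19 dex
```

The closed loop sits within 2% of the quasi-integral setpoint and
attenuates a 50% production disturbance about 140-fold relative to open
loop. On synthetic poly-transfection populations binned by kinase
marker, the feedback circuit is roughly 0.9 dex quieter cell-to-cell
than an open-loop variant at high kinase dosage.

A command-line interface mirrors the library:
`phosphocycle simulate|sensitivity|fit-hill|generate|analyze|classify|ratio-scan|ortho`
(see `phosphocycle --help`).

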