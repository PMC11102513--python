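# nettdcs

Network-targeted transcranial direct current stimulation (net-tDCS)
planning and readout, in Python.

Conventional tDCS places one anode and one cathode over a single target.
Network-targeted montages instead drive many small electrodes jointly so
that the induced electric field matches the *sign pattern of a brain
network*: excite cortex positively coupled to a seed region, inhibit
cortex negatively coupled to it. This package implements that workflow
for a hypothalamus ("appetite-network") seed, together with the
behavioral readout used to probe it — the stop-signal task — and the
seed-based resting-state functional-connectivity (FC) analysis that
defines the network in the first place.

## Who this is for

Researchers prototyping multichannel-tDCS protocols who want an
inspectable, scriptable pipeline: FC map in, per-electrode currents out,
with safety constraints enforced and every step testable on synthetic
data (no scanner data or proprietary optimizers required).

## What it computes

**Montage optimization.** Given a lead field `L` (normal component of
the E-field at cortical samples per mA of electrode current) and an FC
map `r_v`, the target field is `t_v = ±E0·sign(r_v)` outside a small
deadband, weighted by connectivity strength

    w(r) = 10            for r ≥ 0.225
    w(r) = 4             for r ≤ −0.09
    w(r) = 4 + 6(r + 0.09)/0.315   in between,

and the currents `c` solve the convex program

    min_c  Σ_v w_v (Σ_e L[v,e] c_e − t_v)²
    s.t.   Σ_e c_e = 0,  |c_e| ≤ 2.0 mA,  Σ_e |c_e| ≤ 2 × 4.0 mA,

with electrode count limited to a channel budget (default 12) by greedy
backward elimination plus a dead-channel completion pass. Cathodal
(inhibitory) protocols are the exact sign inversion of the anodal
solution.

**Forward model.** An analytic four-layer concentric-sphere head model
(brain/CSF/skull/scalp) with a Legendre-series point-current solution
supplies the lead field; electrodes sit at ideal-sphere 10–20/10–10
coordinates.

**Seed FC.** Spherical seed extraction (default hypothalamus, MNI
(6, 2, −10), 4 mm), nuisance regression, 0.01–0.08 Hz zero-phase
band-pass, voxelwise Pearson correlation, Fisher z, network-mask
averages, and age-adjusted partial correlation for brain–behavior
association.

**Stop-signal task.** Trial scheduling (5 × 64 test trials, 25% stop),
a one-up/one-down SSD staircase converging to 50% inhibition, an
independent-race simulation agent (ex-Gaussian go, Gaussian stop), and
both canonical stop-signal reaction time (SSRT) estimators (mean and
integration methods).

## Worked example

```python
import numpy as np
import nettdcs as nt
from nettdcs.fixtures import generate_fixture_study

# 1. published 12-electrode montage: arithmetic checks
anodal = nt.table1_montage("anodal")
print("total injected   :", anodal.total_injected_uA(), "uA")
print("FPZ density      : %.2f mA/cm^2" % nt.current_density(anodal)["FPZ"])

# 2. sphere-model field induced by that montage
L = nt.compute_leadfield(nt.build_sphere_model(), nt.standard_positions("10-20"))
print("peak |E_n|       : %.3f V/m" % np.abs(nt.en_field(L, anodal)).max())

# 3. optimize a fresh montage against the synthetic study fixture
study = generate_fixture_study()
target = nt.build_target(study.fc_on_cortex, polarity="anodal", e0=0.25)
result = nt.select_channels(study.leadfield, target)
print("objective        : %.2f" % result.objective_value)
print("active electrodes:", result.diagnostics["n_active_electrodes"])

# 4. behavioral readout: one simulated stop-signal session
sess = nt.simulate_session(nt.make_schedule(seed=1), seed=2)
print("stop-success rate: %.2f" % sess.stop_success_rate())
print("SSRT (integration): %.1f ms" % nt.ssrt_integration(sess))
```

Output:

```
total injected   : 4000.0 uA
FPZ density      : 0.64 mA/cm^2
peak |E_n|       : 0.612 V/m
objective        : 18.87
active electrodes: 12
stop-success rate: 0.50
SSRT (integration): 207.6 ms
```

The montage injects exactly 4 mA in total and 0.64 mA/cm² under the
FPZ contact; the sphere model puts its peak normal field near 0.6 V/m,
the expected order for a 4 mA multichannel protocol. The optimizer fills
its 12-channel budget, and the simulated task converges to the 50%
inhibition point with an SSRT close to the agent's true 200 ms stop
latency.

A command-line interface mirrors the library
(`nettdcs optimize`, `nettdcs leadfield`, `nettdcs fc-map`,
`nettdcs simulate-sst`, `nettdcs fixtures`); run `nettdcs --help`.

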