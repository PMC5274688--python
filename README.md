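# boneguide

Guided-wave evaluation of long-bone fractures by simulation: a 2D
elastic finite-difference time-domain (FDTD) model of an obliquely
fractured long bone under low-frequency axial-transmission ultrasound,
with Rayleigh–Lamb dispersion analysis and S0/A0 amplitude-ratio
measurement.

**Who it is for.** Quantitative-ultrasound researchers studying cortical
bone fracture assessment and healing monitoring: the package lets you ask
how the width w and obliquity θ of a soft-tissue-filled crack reshape the
two fundamental guided-wave packets a surface receiver records, and
whether an amplitude ratio can read those geometric parameters back.

## The model and the statistic

A long bone is modeled as three plane layers — 2 mm soft tissue, 4 mm
cortical bone, 10 mm marrow — with a free top surface, absorbing (PML)
edges, and a parallelogram crack of axial width w tilted by θ from the
vertical spanning the cortical layer. A 5-cycle Gaussian-modulated
100 kHz toneburst applied as a vertical surface traction at z = −60 mm
excites, at f·h = 0.4 MHz·mm, only the two fundamental Lamb modes of the
cortical plate:

* **S0** (symmetric, extensional), group velocity ~3.4 mm/µs here,
* **A0** (antisymmetric, flexural), slower and strongly excited by
  normal surface forcing.

Their dispersion follows the Rayleigh–Lamb equations

tan(qh/2)/tan(ph/2) = −4k²pq/(q²−k²)²  (symmetric)
tan(qh/2)/tan(ph/2) = −(q²−k²)²/4k²pq  (antisymmetric)

with k = ω/v_p, p² = ω²/V_L² − k², q² = ω²/V_T² − k². A receiver at
distance z2 past the crack records the two packets; they are separated
by arrival-time windows built from the predicted group delays, and each
packet's amplitude is its Hilbert-envelope peak. The fracture statistic
is

    ratio_db = 20·log10(S0_peak / A0_peak),

which cancels coupling and excitation strength. Widening a transverse
crack suppresses the flexural A0 much more than S0 and drives the ratio
up; steep oblique cracks let A0 through while cutting S0, driving the
ratio down — so the (w, θ) plane is mapped onto a measurable quantity.

## Worked example

```python
import numpy as np
from boneguide import (
    CrackSpec, ElasticPlate, ReceiverSpec, SourceSpec,
    build_layered_grid, carve_crack, default_layers,
    fundamental_branches, make_sim_config, run_simulation,
    plan_windows, measure_modes,
)
from boneguide.materials import CORTICAL_BONE

# dispersion: window velocities at f·h = 0.4 MHz·mm
s0, a0 = fundamental_branches(ElasticPlate(CORTICAL_BONE, 4.0), fh_max=0.6)
v_s0, v_a0 = s0.v_group_at(0.4), a0.v_group_at(0.4)
print(f"v_g(S0) = {v_s0:.3f} mm/us, v_g(A0) = {v_a0:.3f} mm/us")

# intact model and a 1 mm transverse fracture, receiver at z = 120 mm
base = build_layered_grid(default_layers(), length_z=240.0, dx=0.1)
src = SourceSpec(center_z=-60.0)
cfg = make_sim_config(base, src, [ReceiverSpec(center_z=60.0)], v_slowest=1.4)
plan = plan_windows(120.0, v_s0, v_a0, pulse_duration=50.0, t0=25.0)

for label, grid in [
    ("intact", base),
    ("w=1 mm, theta=0", carve_crack(base, CrackSpec(width_w=1.0))),
]:
    ts = run_simulation(cfg, grid)
    m = measure_modes(ts.traces[0], ts.time, plan, z=120.0)
    print(f"{label:18s} S0={m.s0_peak:.3e}  A0={m.a0_peak:.3e}  "
          f"ratio={m.ratio_db:+.1f} dB")
```

prints (about a minute per simulation):

```
v_g(S0) = 3.445 mm/us, v_g(A0) = 1.938 mm/us
intact             S0=5.386e-03  A0=7.008e-03  ratio=-2.3 dB
w=1 mm, theta=0    S0=3.241e-03  A0=2.623e-03  ratio=+1.8 dB
```

The intact record is A0-dominated (negative ratio); the transverse crack
blocks the flexural mode more than the extensional one and shifts the
ratio by about +4 dB at this grid resolution.

The same pipeline is scriptable from the shell — `boneguide dispersion`,
`model`, `simulate`, `analyze`, `sweep`, `report` — driven by a YAML
configuration whose defaults reproduce the reference model
(`boneguide --config my.yaml sweep`).

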