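# doseshape

Interactive dose shaping (IDS) for IMRT treatment planning, on fully
synthetic pelvic phantoms.

Conventional inverse planning steers a treatment plan indirectly,
through the penalty weights of an objective function. Interactive dose
shaping inverts the interface: the planner asks for a *local* change of
the 3D dose distribution — "lower this voxel by 5 Gy", "push this
isodose surface inward" — and the system computes the fluence change
that enforces it, then repairs the collateral damage elsewhere. This
package implements that operator and everything needed to exercise it
end to end, with no external data: seeded synthetic phantoms, a
pencil-beam dose engine, a goal-driven shaping loop, the standard
plan-quality metrics, and step-and-shoot MLC sequencing with an exact
deliverability check. It is aimed at medical-physics researchers who
want a transparent, fully testable sandbox for local dose-manipulation
algorithms.

## The core operator

Dose is linear in the bixel weights, `d = D w`, with `D` the sparse
dose-influence matrix. One **dose modification and recovery** (DMR)
instance is:

1. **Modification** — for a requested change Δd at voxel v with
   influence row `a`, apply the minimum-norm fluence patch
   `P = Δd · a / ‖a‖²` (clamped so `w + P ≥ 0`), which enforces
   `a · P = Δd`.
2. **Recovery** — rank the voxels outside the intended modification
   region whose dose moved more than a tolerance τ, keep the worst
   N_R (default 15), and give each its own counteracting patch, in
   rank order, single pass.

Shaping gestures (single voxel, sphere push/pull with raised-cosine
falloff, isodose-line drag) expand into sequences of DMR instances. A
scripted planner pursues goals hierarchically — the nine Quantec
dose-volume constraints for rectum and bladder first, then target
coverage and organ sparing — accepting an instance only if a scalar
objective strictly improves. Plan quality is reported as DVHs, D98%/
D2%/median/mean, the van't Riet conformity index CI = CI1·CI2 at 95%
of prescription, the homogeneity index (dose standard deviation), the
non-tumor integral dose (litre·Gy), and the Quantec pass/fail table.

## Worked example

```python
from doseshape import *

spec = PhantomSpec(seed=1, dims=(64, 64, 64), spacing=(4.0, 4.0, 4.0))
grid, vois, rx = generate_phantom(spec)          # body/PTV/boost/rectum/bladder
vd = voi_dict(vois)
D = build_influence(grid, vd["body"], BeamSet()) # 9 co-planar beams
state = init_plan(grid, vd, rx, D)               # open fields, D50% condition
goal_script_run(state)                           # Quantec-first shaping
report = compute_report(state.dose, grid, vd, rx)
print(report.quantec[["structure", "x_gy", "vx_percent", "passed"]])
print("boost CI1 =", round(report.conformity["boost"]["ci1"], 3))
seq = deliverability_delta(state, n_levels=7)
print("segments =", seq["segment_counts"]["total"])
```

prints (seed 1):

```
  structure  x_gy  vx_percent  passed
0    rectum  50.0    9.636872    True
1    rectum  60.0    2.234637    True
2    rectum  65.0    1.117318    True
3    rectum  70.0    0.000000    True
4    rectum  75.0    0.000000    True
5   bladder  65.0    0.038775    True
6   bladder  70.0    0.000000    True
7   bladder  75.0    0.000000    True
8   bladder  80.0    0.000000    True
boost CI1 = 1.0
segments = 111
```

Every rectum and bladder dose-volume constraint is met (`vx_percent`
is the organ fraction at or above each threshold, the limit is the
published Quantec bound; the sparing phase of the goal script pushed
bladder V65 from 0.66% down to 0.04%), the boost volume is fully
covered at 95% of its 76 Gy prescription, and the shaped fluence
sequences into 111 deliverable MLC apertures across the nine beams.

The same pipeline is scriptable from the shell:

```sh
doseshape study --seeds 1,2,3 runs/
```

writes, per seed, the phantom masks (NRRD), the influence operator,
the shaped and baseline plans (HDF5), DVH curves and a table-shaped
`comparison.csv` of shaped-vs-baseline quality indicators.

## Layout

- `src/doseshape/phantom.py` — voxel grid, structure set, seeded phantom generator
- `src/doseshape/dose.py` — beam geometry, pencil-beam influence matrix, incremental dose
- `src/doseshape/dmr.py` — fluence patches, recovery, shaping gestures
- `src/doseshape/planner.py` — plan state, initialization, goal script, baseline optimizer, persistence
- `src/doseshape/metrics.py` — DVH, D_q%/V_x, CI, HI, NTID, Quantec
- `src/doseshape/sequencer.py` — stratification, sweep sequencing, deliverability
- `src/doseshape/io.py`, `src/doseshape/cli.py` — containers and the pipeline CLI
- `docs/methods.md` — models, assumptions, parameter choices, limitations
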