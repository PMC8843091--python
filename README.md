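# zipperkit

Toolkit for quantifying how **differential adhesion repositions neurite
shafts** between layered neuropil neighborhoods, built around the
developmental relocation of interneuron neurites in the *C. elegans* nerve
ring. During embryogenesis a neurite shaft can be peeled off one
fasciculated bundle ("unzippering") while progressively adhering to another
("retrograde zippering"), repositioning the whole shaft without tip-directed
outgrowth. zipperkit provides:

- **`zipperkit.model`** — the two-fork force-balance model. With adhesion
  strengths S, tensions T, friction η and approach angle θ,

      v_zip   = [S_ant − T_ant (1 − cos θ)] / η
      v_unzip = [T_post (1 − cos θ) − S_post] / η
      v_zip + v_unzip = ΔS/η − ΔT (1 − cos θ)/η

  with forward simulation (explicit Euler, optional ramping adhesion
  schedule, midline cap, length conservation) and inverse estimation of
  the differential adhesion per unit friction ΔS/η from tracked fork
  positions under the uniform-tension assumption ΔT = 0. Only S/η and T/η
  (μm/min) are identifiable from velocities; absolute forces are not.
- **`zipperkit.kinematics`** — forward-difference velocities,
  percent-zippered time courses, window displacements, and early/late
  window acceleration ratios from position–time series.
- **`zipperkit.connectome`** — contact-profile cosine similarity
  ΣAᵢBᵢ/(√ΣAᵢ²·√ΣBᵢ²) across developmental adjacency datasets over their
  common neuron set, and normalized binary betweenness centrality
  BC_v = Σ λ_stv/λ_st ÷ (N−1)(N−2)/2 for connector-hub identification.
- **`zipperkit.contacts`** — the dilate-and-overlap membrane contact
  mapper for labeled EM section stacks (default 9-px dilation; at
  4.5 nm/px that is a ~40 nm juxtaposition criterion), pair grouping,
  area summaries, and marching-cubes OBJ export of contact patches.
- **`zipperkit.morphometrics`** — the scalar quantification formulas:
  % detachment L_d·100/L_t, % distal-in-posterior (L_p/L_t)·100, anterior
  enrichment I_a/I_p, background-subtracted means, 3-D chiasm length
  √(d_z² + d_xy²), exact polyline minimum distance, penetrance.
- **`zipperkit.synthetic`** — seeded generators with planted ground truth
  for every analysis: model trajectories with Gaussian position noise,
  label stacks with exact planted Chebyshev gaps, modular connectomes with
  planted connector hubs, and two-band intensity time courses with a
  planted enrichment ramp.

## Worked example

Estimate differential adhesion from a noisy synthetic trajectory:

```python
from zipperkit.model import infer_differential_adhesion
from zipperkit.synthetic import gen_trajectory

bundle = gen_trajectory(noise_sd=0.5, seed=1)   # 485-545 min, dt = 5 min
est = infer_differential_adhesion(*bundle.payload)
print(round(est.aggregate, 4), est.direction)
print(bundle.ground_truth["delta_s_over_eta_um_per_min"])
```

prints

```
0.2054 anterior
0.19999999999999996
```

i.e. from fork positions carrying 0.5 μm measurement noise the estimator
recovers the planted ΔS/η = 0.2 μm/min to within 3%, and reports that net
adhesion favors the anterior neighborhood. On noiseless input
(`noise_sd=0.0`) the recovery is exact, because forward-difference
velocities are exact for the piecewise-constant-velocity model.

The same pipeline is available from the shell:

```sh
zipperkit synth trajectory --seed 1 --out run/
zipperkit simulate --config params.yaml --out traj.csv
zipperkit infer --traj traj.csv --out estimate.json
zipperkit connectome bc --in adjacency.csv --undirected --focal AIBL --out bc.csv
zipperkit contacts --stack stack.tif --meta meta.json --dilate 9 --out patches.csv
```

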