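# stridesim

Muscle-driven predictive simulation of walking via direct collocation.

`stridesim` generates periodic, left-right symmetric walking motions *de
novo* by trajectory optimization over a planar musculoskeletal model:
Hill-type muscle-tendon units with an adjustable series-elastic (tendon)
stiffness, two-segment feet whose toe (MTP) joints are actuated only by a
passive spring-damper, smooth compliant sphere-plane foot-ground contact,
and a smoothed phenomenological metabolic-energy model. The cost is the
distance-normalized integral of squared metabolic rate, muscle activations,
coordinate accelerations and passive torques; constraints impose muscle and
skeleton dynamics, left-right symmetric periodicity and the target gait
speed. The transcription uses third-degree right-Radau collocation; the
resulting nonlinear program is solved with an augmented-Lagrangian method
over a sparse trust-region least-squares inner solver with colored
complex-step Jacobians (pure numpy/scipy, no external NLP solver).

Three model-variation studies are built in:

* **toe study** — two-segment feet vs. toes locked (welded);
* **tendon sweep** — triceps-surae tendon stiffness at 30..100% of the
  generic value, with the force-at-slack-length invariance shift;
* **mass/contact study** — torso/leg mass redistribution x vertical
  contact-sphere placement.

Everything needed is generated on the fly: a 62 kg / 1.70 m planar fixture
model (11 coordinates with toes, 9 muscles per leg, 3 contact spheres per
foot) and a synthetic periodic reference-gait dataset (joint angles,
torques, GRFs, EMG envelopes with mean and SD bands) used for hot-start
guesses and RMSE evaluation.

## Command line

```sh
stridesim simulate --out out/ --n-mesh 8 --guess hot       # one gait solve
stridesim toe-study --out out/toes --n-mesh 8
stridesim tendon-sweep --out out/sweep --fractions 1.0,0.7,0.4 --n-mesh 6
stridesim mass-contact-study --out out/mass --n-mesh 6
stridesim converge --meshes 4,6,8 --tols 1e-4,1e-5 --out out/conv
stridesim synth-ref --seed 0 --out out/ref                 # reference dataset
stridesim synth-model --out model.yaml                     # fixture as YAML
```

States/GRFs are written as tab-delimited motion-storage files (header with
`nRows`/`nColumns`/`endheader`, `time` first column, SI units, radians);
outcome metrics and solver statistics as JSON/CSV with the configuration,
model hash and seed echoed for provenance.

## Package layout

| module | contents |
| --- | --- |
| `stridesim.model` | declarative model spec, passive joint torques, variants |
| `stridesim.muscle` | Hill curves, tendon law + stiffness shift, activation dynamics, polynomial muscle geometry |
| `stridesim.metabolics` | smooth + piecewise metabolic model, cost of transport |
| `stridesim.contact` | smooth Hunt-Crossley spheres, GRF/CoP analysis |
| `stridesim.dynamics` | planar kinematic-tree dynamics as an implicit residual |
| `stridesim.collocation` | Radau scheme coefficients and utilities |
| `stridesim.ocp` | transcription: variables, constraints, objective, Jacobians |
| `stridesim.guesses` | cold/hot/warm initial guesses |
| `stridesim.solver` | augmented-Lagrangian solve, multi-guess driver, convergence study |
| `stridesim.studies` | toe / tendon / mass-contact studies and metrics |
| `stridesim.synth` | fixture model + synthetic reference gait generators |
| `stridesim.motionio`, `stridesim.cli` | motion-file dialect and CLI |
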