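# stickreach

Simulation and analysis of a kinematically redundant bimanual reaching task:
moving the right tip of a rigid virtual stick (length 40 cm, hands 15 cm
apart, left hand 40 cm and right hand 25 cm from the tip) to targets 10 cm
away. Because the same tip displacement can be produced with many final
stick-tilt angles, the task separates an *end-effector relevant* dimension
(tip-movement direction, TMD) from an *end-effector irrelevant* one
(stick-tilt angle, STA), and lets one ask how the motor system corrects
visual errors in each.

The package is for motor-control researchers who want to simulate this task,
prototype trial-by-trial learning rules on it, or run its analysis chain on
their own trial tables.

## What it implements

**Baseline strategy model.** For a target at direction φ and distance d, the
summed straight-line path length of the two hands as a function of the final
stick tilt θ is

    f(φ, θ) = |d·u(φ) − L(u(θ) − u(0))| + |d·u(φ) − R(u(θ) − u(0))|,

with u(a) = (cos a, sin a), L = 40 cm, R = 25 cm. Solving ∂f/∂θ = 0 gives the
cost-minimising tilt θ*(φ). Across targets this traces a monotone baseline
TMD–STA relationship g: the stereotyped way the stick is tilted when reaching
in different directions.

**Perturbations.** Three visual manipulations of the displayed stick:
rotation of the tip about the start position (gradual, 1°/trial up to 30°, or
abrupt), rotation of the stick about the tip proportional to tip displacement
(0.6°/cm, i.e. ±6° at the target), and their combination — the six arms
E1A, E1B, E2CCW, E2CW, E3CCW, E3CW.

**Constrained-correction learner.** A state-space learner whose planned
(TMD, STA) intent is updated from two visual errors — the task error
(target − seen TMD) and the tilt error (g(seen TMD) − seen STA) — with the
weighted error vector projected onto the tangent of g, so corrections move
*along* the baseline relationship. This reproduces the task's signature
phenomena: adaptation along g under tip rotation, a residual TMD error when
tilt errors are also corrected, sign-coupled TMD/STA shifts under pure tilt
perturbations, and slower adaptation when the tilt perturbation opposes the
tip-rotation compensation.

**Analysis chain.** 10 Hz fourth-order zero-phase Butterworth filtering,
peak-velocity TMD/STA read-outs, movement-offset tilt, the nine-segment trial
scheme, late-phase trial-by-trial variability, and paired-t / Pearson /
Cohen's-d statistics.

**Synthetic study generator.** Protocols (360 baseline trials over nine
targets at 0°, ±10°, ±20°, ±30°, ±40°; 240 adaptation trials at 0°),
heterogeneous populations of synthetic participants (relation slopes
~ N(0.2, 0.07²) truncated at zero), and full 1 kHz trial synthesis with
bell-shaped (minimum-jerk) tip speed inside the 300–450 mm/s feedback band.

## Worked example

Tabulate the cost-optimal tilt per target:

```sh
$ stickreach baseline-optimum
direction_deg,optimal_tilt_deg,min_cost_cm,parallel_cost_cm
-40.0,-8.701858197981274,16.506534413000864,20.0
-30.0,-6.6407673758592685,18.012851275158596,20.000000000000004
...
30.0,6.6407673758592685,18.012851275158596,20.000000000000004
40.0,8.701858197981274,16.506534413000864,20.0
```

Translating the stick without tilting always costs 20 cm (10 cm per hand);
tilting reduces it, e.g. to 18.01 cm at ±30° with a ±6.64° tilt — which is
why a ±6° tilt perturbation matches the natural tilt for ±30° targets. In
Python, the same numbers plus the learner:

```python
import stickreach as sr

r = sr.optimal_tilt(sr.TargetSpec(direction=30))
print(r.optimal_tilt, r.minimum_cost)   # 6.640767375859269 18.012851275158596

_, spec = sr.make_protocol("E1A")       # gradual 30-deg tip rotation
params = sr.LearnerParams(eta_tmd=0.2, eta_sta=0.2,
                          motor_noise_tmd=0, motor_noise_sta=0)
sim = sr.simulate_adaptation(240, params, sr.linear_relation(0.2), spec)
print(sim["exec_tmd_deg"].iloc[-1])     # -28.799999999999994
```

The learner counter-rotates toward −30° but stops 1.2° short: its attempts to
correct the seen stick-tilt error de-adapt the tip direction — the residual
error characteristic of this task. Learner parameters are recoverable from
noisy series:

```sh
$ stickreach recover --n-seeds 3 --seed 2
truth: eta_tmd=0.1 eta_sta=0.1 retention=0.0
median recovered: eta_tmd=0.100 eta_sta=0.100 retention=0.000 (n=3)
```

Simulate a full arm and analyse trajectories:

```sh
stickreach simulate --experiment E2CCW --seed 1 --n 10 --out runs/e2ccw
stickreach analyze --input runs/e2ccw/participant01_trajectories.csv --out runs/measures.csv
```

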