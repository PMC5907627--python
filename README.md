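# kneesim

Quasi-static simulation of a cruciate-retaining total knee arthroplasty
(CR-TKA), built to answer a surgical question: **when a surgeon adds
posterior tibial slope to loosen a tight flexion gap, how much does the
choice of referencing technique matter?**

Two techniques are compared.  *Anterior tibial cortex referencing* (ACR)
pivots the tibial resection at the anterior tibia, so adding slope lowers
the whole joint line; *centre-of-plateau referencing* (CPR) pivots at the
middle of the plateau, preserving the joint line there.  The package
rebuilds the complete in-silico experiment around that contrast: a
synthetic patient-specific knee, slope variants of −3°, 0°, +3°, +6°, +9°
under both techniques, anterior/posterior (70 N) and varus/valgus (15 N·m)
laxity batteries at 0/30/60/90° of flexion, and a squat simulation
reporting quadriceps, quadriceps–femur and patellofemoral forces.

## The model

Femur, tibia and patella are rigid bodies.  Knee flexion is prescribed;
the remaining eleven degrees of freedom settle where ligament, contact,
tendon and external loads balance (*force-dependent kinematics*): the
equilibrium residual is driven below 0.5 N per force component and
0.01 N·m per moment component.  Kinematics are reported in the
Grood–Suntay joint coordinate system.  The knee itself is a conforming
lipped polyethylene insert (two toroidal dished compartments) articulating
with spherical femoral condyles, a grooved trochlea carrying a spherical
patellar button and the wrapping quadriceps tendon, and eight
piecewise-quadratic/linear spring ligaments (MCL, LCL, two-bundle PCL,
antero-lateral complex, posterior capsule, MPFL, patellar ligament).
Articular contact is an elastic foundation (`p = k_c·δ`) whose resultant
and centre of pressure come from a fixed sampling grid.  `docs/methods.md`
documents every parameter, the numerical design and the limitations.

There is no external data dependency: the `synthetic` module generates a
complete, calibrated knee model from a seed, and the whole pipeline is
deterministic given that seed.

## Worked example

```python
from kneesim import generate_knee, run_laxity_battery, simulate_squat

model = generate_knee()                      # default synthetic knee, seed 42
table = run_laxity_battery(model)            # 2 techniques x 5 slopes x 4 tests x 4 angles
df = table.to_dataframe()
ant = df[(df.test == "anterior") & (df.technique == "ACR")]
print(ant.pivot_table(index="slope_deg", columns="flexion_deg", values="value").round(2))
```

prints the anterior laxity (mm) of the ACR variants:

```
flexion_deg  0.0   30.0  60.0  90.0
slope_deg
-3.0         1.07  1.35  0.89  0.61
 0.0         2.15  2.06  2.08  1.44
 3.0         3.05  2.84  2.65  2.72
 6.0         3.39  3.35  3.14  2.93
 9.0         3.40  3.40  3.34  3.13
```

Reading down a column: anterior laxity grows monotonically as ACR adds
posterior slope, at every flexion angle — the joint line drops with the
pivot at the anterior cortex, slackening the entire ligament envelope.
The same table for CPR (swap the technique filter) stays within ~0.3 mm of
the neutral row and actually *tightens* slightly with more slope, because
the joint line is preserved at the plateau centre.  That asymmetry between
techniques — large, flexion-and-extension laxity changes under ACR, minor
ones under CPR — is the study's headline result, and it emerges here from
geometry alone.

The squat shows the extensor-mechanism side of the story:

```python
out = simulate_squat(model)                  # 0->90->0 deg, 750 N body weight
print({k: round(v, 1) for k, v in out.peaks.items()})
```

```
{'quad_force_pbw': 206.4, 'quad_femur_force_pbw': 199.2, 'pfj_force_pbw': 215.8,
 'pcl_force_n': 5.3, 'mcl_force_n': 41.4, 'lcl_force_n': 19.1}
```

Peak quadriceps demand is ~206 % body weight at 90° flexion, with almost
all of it borne between the wrapping tendon (quadriceps–femur force) and
the patellofemoral joint.  Re-running per slope variant, the peak
quadriceps force falls with added posterior slope under both techniques
(the tibia shifts anteriorly, lengthening the extensor moment arm), but
the *pathway* differs: under ACR the patella rides ~1.5 mm higher on the
femur at +9° (the femur has dropped with the joint line), unloading the
tendon wrap by ~8.5 %BW per 3° while the patellofemoral force barely
changes; under CPR patellar height is preserved (+0.3 mm) and the
patellofemoral contact force falls by ~3.9 %BW per 3°.

The shell interface wraps the same functions:

```bash
kneesim generate --seed 42 --out model.yaml
kneesim laxity --model model.yaml --slopes -3,0,3,6,9 --techniques acr,cpr --out laxity.csv
kneesim squat --model model.yaml --out squat.csv
kneesim run-study --seed 42 --out results/
```

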