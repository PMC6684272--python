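# perchgrip

Models of how birds grasp complex perches: traced-surface claw–asperity
engagement, stick–slip friction statistics with Monte Carlo load sharing,
a 2D rigid-body grasp-stability (wrench space) model with directional
safety margins, and tau-theory landing kinematics — plus synthetic-data
generators with embedded ground truth for every pipeline stage.

## Modules

| module | what it does |
| --- | --- |
| `perchgrip.synthetic_data` | self-affine rough surfaces (exact RMS contract), sawtooth stick–slip drag traces, constant-τ̇ landing trials, circular-arc claw profiles |
| `perchgrip.surface_metrology` | 1D profile conditioning (zero-phase high-pass detrend) and RMS roughness |
| `perchgrip.claw_surface_model` | tip-path tracing, usable-surface fraction n_a, elastic-penetration angle correction, exponential-with-offset and sphere-tip fits |
| `perchgrip.friction_stats` | slip-peak extraction, through-origin Coulomb fit, load-sharing SD, expected-max-friction vs drag distance |
| `perchgrip.grasp_wrench` | five-contact static-grasp feasibility as a linear program, wrench-space volumes, bisection safety margins |
| `perchgrip.landing_kinematics` | τ(t) = s/v computation and τ̇ fitting, landing-stage segmentation, superfast claw-movement detection, zero-phase Butterworth filtering |
| `perchgrip.units` | bodyweight/newton conversion, arc-to-angle geometry |

## CLI

```bash
# generate a 30 um RMS rough surface and trace a 50 um claw tip over it
echo '{"target_rms_um": 30.0, "length_mm": 5.0, "spacing_um": 5.0}' > surface.json
perchgrip gen surface --config surface.json --seed 1 --out prof.csv
perchgrip trace --profile prof.csv --tip-radius 50 --out traced.csv
perchgrip usable --profile prof.csv --tip-radius 50 --theta-min 10 --depth-ratio 0.05
perchgrip sweep --profile prof.csv --tip-radii 10,20,50,100 --theta-mins 5,10,20 \
    --dr-policy isometric --dr-value 0.05 --out sweep.csv

# stick-slip friction statistics
perchgrip gen drag --seed 3 --out drag.csv
perchgrip friction peaks --in drag.csv
perchgrip friction loadshare --in drag.csv --claws 4 --trials 10000 --seed 1
perchgrip friction emax --in drag.csv --distances 0.5,1,2,5 --trials 10000 --seed 1

# grasp wrench space and safety margins
echo '{"perch_diameter_in": 0.75, "mu_pad": 0.4, "mu_claw": 1.5}' > layout.json
perchgrip wrench --layout layout.json --grid "Fx=-2:2:0.25,Fy=-2:2:0.25,Tz=0:0:0" \
    --squeeze 0.5 --out vol.csv
perchgrip margins --layout layout.json --trace forces.csv --out margins.csv

# landing kinematics
perchgrip gen landing --seed 2 --out trial.csv
perchgrip stages --trial trial.csv --sidecar trial.csv.sidecar.json
perchgrip superfast --trial trial.csv --sidecar trial.csv.sidecar.json
perchgrip tau --trace approach.csv
```

## Conventions

- Forces in bodyweight units (bw), torques in bw·mm, lengths in mm
  (profiles) and μm (heights/claw geometry), angles in degrees.
- Wrench queries are expressed in a perch-fixed frame (y up from the perch
  centre); the foot frame rotates with the landing angle, and squeeze
  constraints and safety margins act along the foot axes.
- All Monte Carlo operations take an explicit seed and are bit-reproducible.
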