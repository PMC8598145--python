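# insertfactors

Prediction of electron insert (cutout) factors for linear accelerators from
a small set of measured output factors.

## The problem

Clinical electron fields are shaped with patient-specific Cerrobend inserts
mounted in the applicator (cone). The insert changes the machine output at
d_max — mostly through loss of lateral scatter for narrow fields and extra
scatter from the insert edge — by a factor

    InsertFactor = Output(insert, treatment SSD) / Output(open cone, treatment SSD)

which enters the electron monitor-unit calculation

    MU = Dose / (1 cGy/MU · PrescribedIsodoseLine · ConeFactor · InsertFactor).

Measuring the insert factor for every patient is laborious; purely
analytical methods reach 1–6 % accuracy. This package implements the
empirical-interpolation alternative: every cutout shape is reduced to an
**equivalent ellipse** — the width is the diameter of the largest circle
fully enclosed by the shape, the length is set so the ellipse area equals
the shape area — and a **bivariate spline** is fitted to a small set
(≥ 8 points) of measured insert factors in the plane of ellipse width *w*
and perimeter-to-area ratio *P/A*, one model per machine, energy, cone and
SSD combination. The factor for a new cutout is then interpolated from the
fitted surface, at sub-percent accuracy across clinical energies (6–20 MeV),
cones (6–20 cm) and SSDs (100–110 cm).

Intended users are clinical medical physicists commissioning an electron
insert-factor model or running a secondary MU check.

## What's in the box

- `geometry` — polygon handling, largest-inscribed-circle search
  (pole-of-inaccessibility grid refinement), equivalent-ellipse
  parameterization with Ramanujan's ellipse-perimeter approximation for the
  P/A axis.
- `rtplan` — extraction of beam context and insert outline from a DICOM
  RT Plan exported by the planning system, plus a fixture writer.
- `database` — the measurement CSV dialect, grouping by
  (machine, energy, cone, SSD), recommended bounding measurement-shape
  designs per cone, and parameter-space coverage diagnostics.
- `model` — the least-squares tensor-product B-spline fit over (w, P/A),
  prediction with extrapolation flagging, leave-one-out uncertainty, JSON
  serialization.
- `clinical` — MU calculation, quadratic insert-factor interpolation in
  SSD (preliminary), and PDF + plain-text prediction reports.
- `validation` — agreement statistics (signed/absolute means, SDs, Gaussian
  histogram fit) and two shipped clinical validation datasets: 22 patient
  cutouts (Varian iX) and 26 standard cutouts (Varian TrueBeam).
- `synthetic` — seeded synthetic factor surfaces and simulated measurement
  sessions so the whole pipeline is testable without a linac.

## Worked example

```python
import insertfactors as ifa

# a 4 x 4 cm square cutout
square = ifa.rectangle_polygon(4, 4)
ellipse = ifa.parameterize_shape(square)
print(ellipse.width_cm, ellipse.length_cm, ellipse.pa_ratio_per_cm)
# 3.999999999999999 5.092958178940652 0.895926345660688
```

The inscribed circle of the square has diameter 4 (its side), and the
length 16/π ≈ 5.093 cm preserves the 16 cm² area. Fitting a model to a
simulated measurement session and predicting:

```python
surface = ifa.SyntheticSurface(noise_sd=0.002, seed=1)
ctx = ifa.BeamContext("SYNTH-TB", 12.0, 10.0, 100.0)
shapes = ifa.design_measurement_shapes(10.0, augment=True)   # 11 shapes
records = ifa.sample_measurements(surface, shapes, ctx)
model = ifa.fit_model(records)
result = ifa.predict(model, ellipse)
print(round(result.insert_factor, 3), result.extrapolated)
# 0.937 False

rx = ifa.PrescriptionInputs(dose_cgy=200.0, insert_factor=result.insert_factor,
                            cone_factor=1.02, prescribed_isodose_fraction=0.9)
print(round(ifa.compute_mu(rx), 1))
# 232.6
```

The 0.937 insert factor says this cutout passes 93.7 % of the open-cone
output; the 232.6 MU deliver 200 cGy to the 90 % isodose line with that
insert and a 1.020 cone factor. The same flow is available from the shell:

```sh
insertfactors simulate --noise-sd 0.002 --seed 3 --out db.csv
insertfactors fit db.csv --machine SYNTH-TB --energy 12 --applicator 10 \
    --ssd 100 --out model.json
insertfactors predict model.json --width 4 --length 8
insertfactors report --rtplan plan.dcm --database db.csv --out-prefix case01
insertfactors validate
```

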