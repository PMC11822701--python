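# uvfield

Simulation of germicidal-UV **fluence-rate, irradiance, fluence and dose
fields** on the surface of a moving convex 3D object, for evaluating surface
disinfection processes (e.g. UV treatment of food items on a conveyor) before
building them.

UV disinfection of solid surfaces is hard to dimension: bench-scale
inactivation experiments are run under homogeneous illumination, while
industrial lamp banks produce strongly non-uniform fields over curved, moving
objects. `uvfield` bridges the two. It takes

* a triangulated **convex** surface mesh (binary or ASCII STL),
* a light environment of arbitrarily posed sources — collimated beams,
  LED **point sources** with datasheet relative-intensity profiles, and
  cylindrical low-pressure mercury lamps as **diffuse line sources** (LSDE),
* a motion plan of key poses at normalized timestamps (linear position /
  SLERP orientation interpolation),

and computes, per surface element and timestamp, the fluence rate `E'` and
irradiance `E`, integrating them over time (trapezoidal rule) into fluence
and dose maps in mJ/cm². Downstream it maps fluence to pathogen log₁₀
reduction (Weibull `log₁₀(N/N₀) = −(F/α)^β` or Chick–Watson
`log₁₀(N/N₀) = −kF`), weights source spectra by germicidal-factor curves,
and inverts the line-source model (Keitz formula
`E = P(2α + sin 2α)/(2π²LD)`, `α = arctan(L/2D)`) to estimate lamp optical
power from multi-distance irradiance readings.

Convexity matters: a convex body never shadows itself, so every surface
element is independent and the whole field evaluates as vectorized
closed-form expressions — no ray tracing. Only direct radiation is modeled
(no reflection or scattering), and the line model is far-field.

## Worked example

A 6 cm icosphere held static under a 50 × 5 grid of 110 mW UVC LEDs
(27.5 W toward the base plane, 0.1 m overhead) for 20 minutes:

```bash
uvfield make-fixture --shape icosphere --size 0.06 --out sphere.stl
uvfield evaluate --mesh sphere.stl --preset led --steps 50 --duration 1200 \
    --out results/
```

prints

```
fluence [mJ/cm^2] min 0.0 max 11597.1 mean 4880.0 (area-weighted 4879.7)
```

the upward-facing pole receives ~11.6 J/cm² while the underside, which never
faces the grid, receives nothing — exactly the non-uniformity that motivates
flipping the object mid-process (pass a `--motion` key-pose plan to model
that). Feeding the field into an inactivation model turns the map into a
coverage statement — with the Weibull parameters α = 290.48 mJ/cm²,
β = 0.58 (a published *Salmonella*/UVC-LED dose-response on chicken breast):

```bash
uvfield inactivation-map --field results/field.csv --family weibull \
    --alpha 290.48 --beta 0.58 --threshold -2.0
# area-weighted pass fraction at threshold -2.0: 0.8444
```

84% of the surface area reaches 2-log (99%) reduction; the shadowed
underside does not, and no exposure time fixes that without motion. Library use
mirrors the CLI: `load_mesh` → `extract_surface_elements` →
`build_environment` → `sample_poses` → `evaluate_field` →
`summarize_field` / `inactivation_map`.

Lamp power measurement works in reverse: given irradiance readings at
several distances from a twin-tube lamp,

```bash
uvfield estimate-power --measurements readings.csv
```

divides each reading by the modeled unit-power irradiance of the two
parallel line sources and averages the per-distance power estimates.

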