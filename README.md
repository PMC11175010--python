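# goniotwin

A Monte Carlo **digital twin** of an optical goniometer, and the inverse
solver that goes with it.

Goniometers measure how strongly a turbid sample — a tissue phantom, a
particle suspension, a scattering ceramic — redirects light into each angle.
Turning such angle-resolved signals into the sample's optical parameters
(absorption coefficient μa, scattering coefficient μs, and the
Henyey–Greenstein anisotropy factor g) is an inverse problem: multiple
scattering, cuvette windows, the finite source spot and the detector
acceptance all shape the measured curve, so no closed-form model fits it.
`goniotwin` solves this by simulating the *entire* measurement chain —
fiber source, imaging lens, apertures, layered sample, angular detection —
and fitting the simulation to the data.

The package provides:

* **Photon transport** through the instrument's optical train (spherical
  lens interfaces with Fresnel/Snell physics, AR coatings, stochastic
  surface scattering) and through layered cylindrical samples
  (Beer–Lambert free paths, arbitrary phase functions, boundary refraction),
  with a numba-compiled kernel that runs millions of photons per second on
  one core.
* **Variance-reduced detection** for rotationally symmetric runs: each
  exiting photon is credited to every detector angle its azimuthal circle
  can reach, with the analytic weight w = arccos Φ/π, where
  Φ = (cos ϑr − cos ϑD cos ϑS)/(sin ϑD sin ϑS) and tan ϑr = r/d is the
  detector's half-opening angle.  This is >100× more efficient than
  simulating the 2D detector chip (which is also implemented, for oblique
  geometries).
* **Perturbation Monte Carlo (pMC)**: one simulation yields the signal *and*
  its derivatives with respect to μa, μs and g by reweighting recorded paths
  (w_μa = e^(−l δ μa), w_μs = (1+δ)^N e^(−l δ μs), w_g = Π P_g'(ϑi)/P_g(ϑi)),
  so a Jacobian costs no extra transport runs.
* **A bounded Levenberg–Marquardt fitter** operating on the log-relative
  cost C = (log MC − log E)/log E with MINUIT-style parameter transforms,
  common-random-number iterations and random multi-start.
* **Phase-function models** (Henyey–Greenstein, Reynolds–McCormick, double
  HG, tabulated, cubic spline) and a **Lorenz–Mie module** for predicting
  μs and P(θ) of microsphere calibration suspensions from first principles.

## Worked example

Simulate a "measurement" of a 2 mm scattering liquid (μa = 0.1 mm⁻¹,
μs = 0.15 mm⁻¹, g = 0.75, n = 1.33) in a glass cuvette, then recover the
parameters from the signal alone:

```python
from goniotwin.studies import study_cuvette_model, generate_synthetic_measurement
from goniotwin.inverse import FitProblem, levenberg_marquardt

model = study_cuvette_model()          # instrument source, 150 angles
meas = generate_synthetic_measurement(
    model, {"mua": 0.1, "mus": 0.15, "g": 0.75},
    n_photons=20_000_000, seed=42,
)
fit = levenberg_marquardt(FitProblem(
    measurement=meas, model=model,
    n_photons_iter=2_500_000, n_photons_final=20_000_000, seed=7,
))
print(fit.summary())
```

Output from this exact run:

```
fit converged: mua=0.0994843, mus=0.150831, g=0.74972; |C|=0.02516,
eps_fit=1.37%, sigma=0.895%, restarts=0, simulations=7
```

The fitter starts from random parameters and lands on the truth in about
five damped Gauss–Newton steps.  `eps_fit` is the rms relative deviation
between the fitted and the "measured" signal; `sigma` is the counting-noise
level of the two runs being compared — a converged fit's error approaches
this noise floor, so the 1.4% here simply reflects the modest 2×10⁷-photon
budget.  The recovered parameters are within 0.6% of the truth.

The same machinery is scriptable from the shell:

```bash
goniotwin synth --photons 20000000 --seed 42 --out meas.txt
goniotwin fit --measurement meas.txt --photons-per-iter 2500000 --seed 7
goniotwin scan-g --out scan.txt          # E(g) landscape, two basins
goniotwin mie --diameter-um 2.0 --wavelength-nm 550 --volume-fraction 9.7e-5
```

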