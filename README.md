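# dxduo

Dual-probe **diffracted X-ray blinking (DXB)** and **diffracted X-ray
tracking (DXT)** analysis.

Both assays watch a nanocrystal bound to a specific site of a protein.
Under a monochromatic beam the crystal diffracts only while it satisfies the
Bragg condition, so rotational motion makes pixels on its Debye–Scherrer
ring *blink* (DXB); under a pink beam every crystal throws a Laue spot whose
on-detector trajectory maps the probe's angular motion (DXT). With two
chemically distinct probes — cubic **Au** (a = 4.08 Å) and hexagonal **ZnO**
(a = 3.25 Å, c = 5.2 Å) — two domains of one protein can be recorded
simultaneously: their rings (Au 111/200, ZnO 100/002/101/102) land at
well-separated radii and are analysed independently.

`dxduo` is for people who have such detector movies (or pre-tracked spot
tables) and want the published observables with full provenance:

* **geometry** — predicted ring radii from lattice constants, annular pixel
  ROIs with masking, unambiguous probe routing (`dxduo.geometry`);
* **DXB** — per-pixel intensity autocorrelation
  `ACF(τ) = ⟨I(t)I(t+τ)⟩/⟨I(t)²⟩` fitted with `k + A·exp(−T·τ)`
  (accepted iff k, A, T > 0), box statistics of decay constants, two-Gaussian
  low/high-mobility decomposition with exact area percentages, Wilcoxon
  rank-sum condition comparisons, first-half/second-half radiation-damage
  check (`dxduo.dxb`);
* **DXT** — spot detection and greedy nearest-neighbour linking, the
  twisting/bending decomposition χ = Δazimuth, θ = ½·Δ(2θ_scatter),
  lifetime filtering, temporal-MSD anomalous-diffusion fits
  `δ²(t) = D_α t^α + 2β²`, and θ–χ motion histograms with peak/FWHM,
  hotspot superposition and normalized subtraction maps (`dxduo.dxt`);
* **synthetic data** — a ground-truth-known generator for both modalities
  (confined-tilt blinking with a closed-form ACF oracle; ring-walking Laue
  spots with geometric lifetimes), so the whole pipeline is testable with no
  beamline data (`dxduo.synthetic`);
* **I/O + CLI** — TIFF/HDF5 stacks, trajectory/I₀ CSVs, a single YAML
  geometry config, reconciled run reports, and a `dxduo` command
  (`simulate`, `dxb-run`, `dxt-run`).

See `docs/methods.md` for the models, conventions, default parameters and
their rationale, and known limitations.

## Worked example

Simulate two blinking recordings of the Au-labelled domain at the standard
cadence (100 ms × 2000 frames) — free motion with a 5 s intensity
correlation time, and a ligand condition with motion suppressed fourfold —
then run the DXB chain on the ring pixels:

```python
import numpy as np

from dxduo.geometry import (BeamSpec, CrystalPhase, DetectorGeometry,
                            build_ring_roi)
from dxduo.synthetic import dxb_config_for_decay, render_dxb_movie
from dxduo.dxb import (ACFCurve, DecaySample, acf_matrix, decay_stats,
                       fit_acf_exponential, compare_distributions)

au = CrystalPhase("Au", "cubic", 4.08)
beam = BeamSpec(energy_keV=17.7)                      # mono beam for DXB
geom = DetectorGeometry(pixel_pitch_mm=0.172, n_rows=120, n_cols=120,
                        beam_center_px=(60.0, 60.0), distance_mm=30.0,
                        frame_interval_s=0.1)
roi = build_ring_roi(au, (1, 1, 1), beam, geom, half_width_px=2.0)
print(f"{roi.label}: d = {roi.d_spacing_A:.4f} A, "
      f"radius = {roi.radius_px:.1f} px, {len(roi.pixels)} pixels")

samples = {}
for name, t_decay, seed in (("ligand-free", 0.20, 1), ("ligand", 0.05, 2)):
    cfg = dxb_config_for_decay(t_decay, 100).replace_with(seed=seed,
                                                          n_crystals=150)
    stack, truth = render_dxb_movie(cfg, roi, geom, return_truth=True)
    px = truth["crystal_pixels"]
    lags, acfs, _ = acf_matrix(stack[:, px[:, 0], px[:, 1]].T.astype(float),
                               100, cfg.frame_interval_s)
    ts = [f.T for f in (fit_acf_exponential(
              ACFCurve(lags=lags, values=a, n_pairs=np.ones(101)))
          for a in acfs) if f.accepted]
    samples[name] = DecaySample(values=np.array(ts), condition=name,
                                domain_label=roi.label)
    s = decay_stats(samples[name])
    print(f"{name:12s} n={len(ts):3d} accepted fits; "
          f"T median = {s.median:.3f}/s (q25 {s.q25:.3f}, q75 {s.q75:.3f})")

res = compare_distributions(samples["ligand-free"], samples["ligand"])
print(f"rank-sum W = {res.statistic:.0f}, p = {res.p_value:.2e} ({res.tier})")
```

Output:

```
Au(111): d = 2.3556 A, radius = 53.7 px, 1332 pixels
ligand-free  n=145 accepted fits; T median = 0.203/s (q25 0.129, q75 0.298)
ligand       n= 96 accepted fits; T median = 0.098/s (q25 0.042, q75 0.172)
rank-sum W = 20554, p = 1.36e-08 (***)
```

Reading it: the median ACF decay constant of the free condition (0.203 s⁻¹)
recovers the generating correlation rate (0.2 s⁻¹); suppressing the
rotational diffusion fourfold halves the measured median (the per-pixel
estimator compresses slow rates — see the operating-range discussion in
`docs/methods.md`), and the rank-sum test calls the two distributions apart
at p < 0.001 (`***`), the threshold this workflow uses.

The same stages run from the shell:

```sh
dxduo simulate dxb --config geom.yaml --out fixtures/ --seed 5
dxduo dxb-run --stack control=fixtures/dxb_movie.h5 --config geom.yaml \
              --out results/ --max-lag 100 --seed 1
dxduo dxt-run --stack control=movie.h5 --i0 control=i0.csv \
              --config geom.yaml --min-life 5 --lag 1 --out results/
```

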