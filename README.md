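# tightdock

Quantitative analysis of tightly docked membrane–membrane interfaces —
the metastable state in which two bilayers sit less than a nanometre
apart just before hemifusion. Tight docking has a structural
signature: the contact is cleared of protein, and the bilayers
*thicken* locally. `tightdock` implements the measurement pipeline for
that signature, for people working on membrane fusion with cryoEM
images of docked vesicles, fluorescence images of docked GUV pairs, or
coordinate trajectories of apposed bilayers:

- **Image analysis** — membrane thickness as the peak-to-peak distance
  between the two headgroup intensity ridges of a bilayer, from radial
  profiles (free membranes) or line profiles (docking interfaces);
  loose/tight docking classification from protein-signal depletion at
  the contact; one-tailed unpaired t and Wilcoxon matched-pairs
  signed-ranks comparisons of thickness groups.
- **Trajectory metrics** — from labeled particle frames: leaflet
  assignment, P-layer thickness and inter-membrane distance, lateral
  area and area per lipid, membrane volume, headgroup tilt
  cos φ = (P→N)·ẑ/|P→N| per leaflet, chain order
  S = (3⟨cos²θ⟩ − 1)/2, gap hydration, and the cutoff-Coulomb
  electrostatic energy within each leaflet.
- **Relaxation kinetics** — per-replica fits of
  f(t) = x∞ + (x0 − x∞)·e^(−t/τ), normalisation between single- and
  double-bilayer equilibria, and a bootstrap-supported ordering of
  τ_tilt < τ_area < τ_thickness, the timing fingerprint of
  dehydration-driven headgroup tilt causing area shrinkage causing
  thickening.
- **Angle restraint** — the tilt bias E(φ) = k(1 − cos(φ − φ0)) with
  analytic forces, plus a toy overdamped relaxation for generating
  bias-driven series.
- **Synthetic data** — seeded generators for vesicle-pair images
  (ground-truth thickness maps, docking labels, protein ratios),
  bilayer frames (exact layer spacings and tilts), and relaxation
  ensembles, so the whole pipeline runs and is scored with no external
  data.

## Worked example

```python
from tightdock.synthetic import free_vesicle_spec, docked_pair_spec, \
    generate_vesicle_pair_image
from tightdock.pipeline import measure_free_thickness, \
    measure_interface_thickness, _free_membrane_segment
from tightdock.imaging import classify_interface, interface_line_endpoints

# a free vesicle with 4.0 nm membranes, 0.5 nm pixels, default noise
spec = free_vesicle_spec(membrane_thickness_nm=4.0, seed=7)
img, _, truth = generate_vesicle_pair_image(spec)
m = measure_free_thickness(img, truth)[0]
print(f"free membrane thickness: {m.thickness_nm:.3f} nm (true 4.000)")

# a tightly docked pair: +0.6 nm thickening, protein-depleted contact
spec = docked_pair_spec("tight", seed=7)
density, protein, truth = generate_vesicle_pair_image(spec)
for m in measure_interface_thickness(density, truth):
    print(f"membrane {m.membrane_id} interface thickness: "
          f"{m.thickness_nm:.3f} nm (true {truth.interface_thickness_nm:.3f})")
call = classify_interface(protein, interface_line_endpoints(truth, 16.0),
                          _free_membrane_segment(truth))
print(f"docking call: {call.label} "
      f"(interface/free protein ratio {call.interface_ratio:.2f})")
```

prints

```
free membrane thickness: 3.989 nm (true 4.000)
membrane 0 interface thickness: 4.734 nm (true 4.600)
membrane 1 interface thickness: 4.766 nm (true 4.600)
docking call: tight (interface/free protein ratio 0.21)
```

The free-membrane readout is accurate to ~0.01 nm; interface readouts
carry a known +0.1 nm bias from overlapping ridge tails at the
four-peak interface geometry (see `docs/methods.md`). The protein
ratio 0.21 ≪ 0.6 marks the contact as protein-depleted, hence tight.

The kinetics side, on a 100-replica synthetic ensemble:

```python
from tightdock.synthetic import default_ensemble_spec, generate_relaxation_ensemble
from tightdock.kinetics import fit_ensemble, tau_ordering

t, ens = generate_relaxation_ensemble(default_ensemble_spec(seed=7, n_replicas=100))
fits = {k: fit_ensemble(t, v) for k, v in ens.items()}
res = tau_ordering(fits, n_bootstrap=1000, seed=8)
print(res.median_tau_ns)          # {'tilt': 0.0500, 'area': 0.1499, 'thickness': 0.3990}
print(res.declared_order)         # ('tilt', 'area', 'thickness')
print(min(res.pair_support.values()))  # 1.0
```

Median fitted τ recover the true 0.05 / 0.15 / 0.40 ns within 1 %, and
the ordering tilt < area < thickness is declared with full bootstrap
support — headgroup tilt relaxes first, thickening last.

A CLI wraps the same functionality
(`tightdock synth-image | synth-frame | synth-relax | thickness |
classify | fit | order | stats | run`); `tightdock run --seed 1
--out-dir out/` executes the whole pipeline and writes CSV/JSON
artifacts plus a run log with the exact configuration.

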