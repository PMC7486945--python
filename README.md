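# coroalign

Transmural orientation analysis of the coronary microvasculature and the
surrounding cardiomyocytes in the embryonic heart wall.

Cardiac muscle fibers wrap the left ventricle helically, with the helical
angle rotating progressively from the epicardium to the endocardium.
`coroalign` quantifies whether the coronary *microvessels* follow the same
organization, directly from cleared-and-imaged whole hearts:

* **Vessel orientation (3D).** For every skeletonized vessel segment, a
  surface-anchored orthonormal frame is built at the segment midpoint:
  g₁ points toward the nearest epicardial surface point,
  g₂ = g₁ × (V_AB × g₁) is the manually identified apex→base axis
  projected onto the local tangent plane, and g₃ = g₂ × g₁ is the
  circumferential direction.  The segment's depth is its distance to the
  nearest surface point.  The vessel-vector V_v (start node → end node)
  yields the **helical angle** α_H = 90° − arccos(V_v·g₂ / |V_v|)
  (0° = circumferential, ±90° = apex→base) and the **projection angle**
  α_P of the tangent-plane projection V_p = g₁ × (V_v × g₁) relative to
  g₃, comparable with 2D nuclei orientations.
* **Nuclei orientation (2D).** Each nuclei image slice is summarized by
  the Fourier angular amplitude A(θᵢ) = Σ|F(k_x,k_y)|²·h_θᵢ(k_x,k_y),
  with wedge masks every 5° from 0° to 180°, normalized to minimum zero
  and unit area.
* **Axial circular statistics.** Orientations are axial (θ ≡ θ + 180°):
  means use the angle-doubling construction, dispersion is fit with the
  bimodal von Mises density
  pdf(θ) = e^{κcos(θ−μ)}/(2πI₀(κ)) + e^{κcos(θ+π−μ)}/(2πI₀(κ)) by least
  squares over κ, and error bars use the standard uncertainty u defined by
  P(−u < θ < u) = 68% under that density.
* **Morphometry and comparison.** Vessel volume fraction and length
  density (mm⁻²), depth-resolved moving-window profiles (±15 μm), 0–1
  wall-depth normalization, Pearson correlation of vessel and nuclei
  profiles after 200-point resampling, and F-test / Welch T-test group
  comparisons.

Because suitable public datasets of cleared embryonic hearts do not
exist, the package ships a first-class synthetic-phantom module (slab and
hemispherical-shell walls with prescribed orientation profiles, plus
elongated-nuclei image stacks) that provides exact ground truth for
end-to-end validation.

## Worked example

Generate a hemispherical-shell phantom whose mean helical angle climbs
linearly from −30° at the epicardium to +80° at the endocardium with
concentration κ = 8, then recover the transmural profile:

```python
import numpy as np
import coroalign as ca

spec = ca.WallPhantomSpec(geometry="shell", n_segments=2000, kappa=8.0, seed=1)
phantom = ca.make_wall_phantom(spec)

v_ab = ca.AnalysisConfig(apex_um=phantom.apex_um, base_um=phantom.base_um).v_ab
vectors, counts = ca.analyze_segments(phantom.graph, phantom.surface, v_ab)
profile = ca.depth_profile(
    np.array([v.helical_deg for v in vectors]),
    np.array([v.depth_um for v in vectors]),
    half_width_um=15.0,
)
for i in range(0, len(profile), 20):
    if profile.valid()[i]:
        print(f"depth {profile.depth[i]:6.1f} um  mean {profile.mean_deg[i]:+6.1f} deg  "
              f"kappa {profile.kappa[i]:5.2f}  u {profile.u_deg[i]:5.1f} deg  n {profile.n[i]}")
```

prints

```
depth   15.1 um  mean  -24.8 deg  kappa 12.89  u  16.1 deg  n 52
depth  115.1 um  mean   -5.7 deg  kappa  7.44  u  21.4 deg  n 117
depth  215.1 um  mean  +10.6 deg  kappa  6.98  u  22.1 deg  n 123
depth  315.1 um  mean  +30.2 deg  kappa  7.49  u  21.3 deg  n 114
depth  415.1 um  mean  +50.1 deg  kappa  8.65  u  19.8 deg  n 110
depth  515.1 um  mean  +75.7 deg  kappa  8.82  u  19.6 deg  n 118
```

Each row is one moving-window depth bin: the axial circular mean helical
angle climbs from negative (vessels tilted toward the apex) through
circumferential (0°) to strongly positive near the endocardium, tracking
the generator's −30°→+80° profile; κ ≈ 8 reflects the prescribed angular
dispersion of individual vessels around that mean (the shallowest bin
overshoots because its window is half empty), and u is the 68% standard
uncertainty implied by the fitted κ.

The same workflow is available from a shell:

```sh
coroalign simulate --preset ed9 --seed 1 --out phantom/
coroalign vessels --skeleton phantom/skeleton --surface phantom/surface.csv \
    --config phantom/config.yaml --out vessels.csv
coroalign nuclei --stack phantom/nuclei.tif --out nuclei.csv
coroalign correlate --vessels vessels.csv --nuclei nuclei.csv --n 200
```

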