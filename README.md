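# retdefocus

Tools for building and comparing **retinal defocus pattern maps** — for
researchers in visual optics and myopia control who want to ask: *given
a real-world visual environment, a subject's peripheral refraction, and
an optical treatment, how much defocus does each part of the retina
actually see, and where do treatments change it?*

Near-sighted eyes are thought to respond to the sign and amount of
defocus across the retina, which is why multifocal contact lenses impose
myopic defocus in the periphery.  Whether that imposition is significant
for a given wearer depends on three interacting fields, each a 400×400
dioptric map over the central ±20° of a right eye at 0.1°/pixel:

* the **scene defocus map** `E(x, y) = 1/d_gaze − 1/d_obj(x, y)`, the
  vergence mismatch of the environment relative to the accommodative
  plane (flipped from visual-field into retinal coordinates);
* the **eye power map**, a tensor-spline surface through the subject's
  peripheral refraction measured along five horizontal parallels
  (5 × 81 points, 4 repeats, 1 D repeat-SD acceptance filter), sign
  inverted to power; the equatorial parallel also classifies the eye's
  profile as NPS / TPS (nasal / temporal positively skewed), RPM / RPH
  (relative peripheral myopia / hyperopia) against a 0.25 D threshold;
* the **lens power map**, the in-situ lens profile from over-refraction
  subtraction (on-wear minus naked refraction), or a blank matrix for
  the naked eye.

The combined maps — 3 scenes × 3 optics × 4 profile classes = 36
conditions — are segmented into four 5° rings × four diagonal-bounded
quadrants (superior / inferior / nasal / temporal) and compared
region-wise with the Kruskal-Wallis test followed by familywise-error
corrected pairwise contrasts (Tukey-Kramer on mean ranks; Holm
optional), plus Mann-Whitney-U / Benjamini-Hochberg machinery for
per-meridian baseline comparisons.  Because no public dataset exists
for any input class, a first-class synthetic generator module emulates
all three (scene archetypes, shell classes, lens designs) with seeded
determinism.  See `docs/methods.md` for conventions, formulas and
caveats.

## Worked example

```python
import retdefocus as rd

# 1. a synthetic nasal-skewed myopic eye, measured 4x along 5 parallels
scans = rd.make_shell(rd.shell_preset("NPS", seed=42))
avg = rd.average_scans(scans)                      # 1 D repeat-SD filter
cls = rd.classify_profile(avg)
print(f"profile: {cls.label.value}  "
      f"(nasal {cls.nasal_edge_mean:+.2f} D, centre {cls.central_mean:+.2f} D, "
      f"temporal {cls.temporal_edge_mean:+.2f} D)")

# 2. eye power map and an on-eye near-centre lens profile
eye = rd.invert_to_power(rd.fit_surface(avg))
lens_spec = rd.LensSpec(rd.LensDesign.NEAR_CENTRE)
on_eye = rd.average_scans(rd.make_lens_scans(lens_spec, scans))
lens = rd.lens_power_map(rd.over_refraction(on_eye, avg))
print(f"lens power at centre: {lens.values[200, 200]:+.2f} D "
      f"(nominal -0.25 + 2.25 add)")

# 3. combine with an office scene and segment
scene = rd.flip_to_retinal(rd.make_scene(rd.scene_preset("OFFICE", seed=42)))
naked = rd.combine_condition(scene, eye, rd.blank_map())
with_lens = rd.combine_condition(scene, eye, lens)
masks = rd.make_region_masks()
r_naked = rd.extract_regions(naked, masks)
r_lens = rd.extract_regions(with_lens, masks)
key = rd.RegionKey(rd.Ring.R15_20, rd.Quadrant.INFERIOR)
print(f"outer inferior region ({r_naked[key].size} px): "
      f"naked {r_naked[key].mean():+.2f} D, with lens {r_lens[key].mean():+.2f} D")

# 4. is the lens's effect in that region significant?
kw = rd.kruskal_wallis([r_naked[key], r_lens[key]])
pw = rd.posthoc_pairwise(kw, labels=["naked", "near-centre"])
row = pw.table.iloc[0]
print(f"Kruskal-Wallis H = {kw.H:.1f}, post-hoc adjusted p = {row.adjusted_p:.3g} "
      f"-> {'significant' if row.significant else 'not significant'}")
```

prints

```
profile: NPS  (nasal -2.51 D, centre -3.23 D, temporal -3.29 D)
lens power at centre: +2.00 D (nominal -0.25 + 2.25 add)
outer inferior region (13747 px): naked +4.79 D, with lens +4.76 D
Kruskal-Wallis H = 155.8, post-hoc adjusted p = 0 -> significant
```

Reading the output: the generated eye is correctly recognised as
nasal-positively-skewed (its nasal edge is ~0.7 D more hyperopic than
centre and temporal edge); the over-refraction recovers the lens's
central power (−0.25 D distance power + 2.25 D add); in the outer
inferior retina the office desk dominates (≈ +4.8 D of myopic defocus at
0.5 m gaze) while the near-centre lens adds almost nothing that far out
(−0.03 D) — yet with ~13 700 pixels per region the rank test still calls
that tiny shift significant, a deliberate feature of the pixel-level
comparison convention discussed in `docs/methods.md`.

The `retdefocus` command line mirrors the library
(`simulate`, `shell`, `lens`, `combine`, `segment`, `stats`, `report`);
`retdefocus --help` lists the stages.

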