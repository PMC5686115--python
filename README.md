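# punctakit

Quantitative image analysis for clustered IP₃ receptors and their Ca²⁺
signals. IP₃ receptors (IP₃Rs) are tetrameric Ca²⁺-release channels of
the endoplasmic reticulum that assemble into small clusters — puncta of
roughly 1–40 channels — visible as diffraction-limited spots in TIRF
movies of cells with fluorescently tagged receptors. Most puncta are
mobile, moving within the ER membrane by diffusion
(D ≈ 0.03 µm² s⁻¹) or by microtubule-motor transport
(v ≈ 0.3 µm s⁻¹), while a minority sit immobile next to ER–plasma-membrane
junctions marked by STIM1; local Ca²⁺ release events ("puffs", ~200 ms)
arise almost exclusively at the immobile pool. punctakit provides the
full analysis chain needed to make those measurements, for cell
biologists and microscopists working with punctate TIRF data:

- **detection** — difference-of-Gaussians spot detection with sub-pixel
  (parabolic) localization, background correction, and SR-Tesseler-style
  Voronoi density tessellation of single-molecule localization tables;
- **tracking** — linear-assignment-problem linking (400 nm gate),
  gap closing (600 nm, one missing frame), split/merge annotation
  (300 nm), verified against an exhaustive assignment oracle;
- **mobility** — time-averaged MSD profiles; motion classification into
  immobile / sub-diffusive / diffusive / directed from the 40 nm
  frame-displacement floor, the MSD exponent α and straightness S;
  directed speed from the fit MSD = v²τ² + 4Dτ; per-cell state
  fractions; two-frame overlay identification of immobile puncta;
- **frap** — double normalization, mobile fraction Mf = F₃₀₀/F₀,
  model-free half-time, and D = r²γ/(4t½);
- **stoichiometry** — change-point bleach-step detection, fluorophore
  counts n = round(F₀/final step), and the random-tetramer-assembly
  model (with 61% tagged subunits, 1−0.39⁴ ≈ 98% of tetramers carry a
  tagged subunit; with 80% fluorescent maturation, ≈ 93%);
- **puffs** — ΔF/F₀ computation, spatiotemporal event detection,
  colocalization with immobile puncta (0.96 µm = 6 px criterion), and
  release-site recurrence;
- **junctions** — nearest-neighbour distances, proximity fractions and
  densities for STIM1/IP₃R point patterns, and the store-depletion
  translocation signal ΔF = (F_Tg−F₀)/F₀ in per-punctum ROIs;
- **simulate** — ground-truthed generators for every input above
  (movies, traces, curves, point fields), bit-reproducible from a seed.

The science, estimators and their numerical behaviour are documented in
[docs/methods.md](docs/methods.md).

## Worked example

Run the whole pipeline on a simulated cell — 80 puncta in a
20.48 µm field, 10 fps for 10 s, the default 21/10/62/7% motion
mixture — then detect, track, classify, and run the FRAP, bleaching,
puff and junction stages:

```bash
punctakit run-all --seed 1 --out out/
```

`out/summary.json` from that command (abridged):

```json
{
  "seed": 1,
  "n_spots": 7494,
  "n_tracks": 84,
  "state_fractions": {
    "immobile": 0.095,
    "subdiffusive": 0.190,
    "diffusive": 0.631,
    "directed": 0.083
  },
  "directed_speed_um_s": 0.305,
  "diffusion_coefficient_um2_s": 0.0328,
  "frap": {"Mf": 0.740, "t_half_s": 60.1, "D_um2_per_s": 0.0141},
  "bleach": {"mean_tetramers_per_punctum": 8.22,
             "prob_tagged_tetramer": 0.977,
             "prob_fluorescent_tetramer": 0.931}
}
```

Reading the numbers: 84 trajectories survived the 30-frame minimum;
28.5% of them are immobile or sub-diffusive, 63% diffusive and 8%
directed — the planted mixture (31/62/7) recovered within a few points
at this cell size. Diffusing tracks give D = 0.033 µm² s⁻¹ (planted
0.0308; the localization jitter adds a small positive offset) and
directed tracks move at 0.305 µm s⁻¹ (planted 0.324). The FRAP stage
reads Mf = 0.74 for a curve planted at 0.77 — the F₃₀₀/F₀ estimator
samples 4.8 half-lives of a t½ = 62 s recovery, i.e. ~96.5% of the
asymptote — with t½ = 60 s and D = r²/(4t½) = 0.014 µm² s⁻¹ for the
1.84 µm bleach spot. Bleaching traces average 8.2 tetramers per punctum,
and the assembly model puts 97.7% (93.1% counting only fluorescent tags)
of tetramers in reach of the tag.

Every stage is also usable as a library:

```python
from punctakit import simulate as sim
from punctakit.detection import detect_spots_movie
from punctakit.tracking import track
from punctakit.mobility import classify_tracks

cfg = sim.SceneConfig(seed=1)
trajectories, truth = sim.simulate_trajectories(cfg)
movie = sim.render_movie(trajectories, cfg, intensities=400.0)
spots = detect_spots_movie(movie, cfg.psf_sigma_um)
tracks, summary = track(spots)
classes = classify_tracks(tracks, cfg.frame_interval_s)
print(classes["label"].value_counts())
```

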