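# swirphantom

Simulation and analysis of short-wave-infrared (SWIR, 900–1700 nm)
hyperspectral images of tissue-mimicking phantoms: collagen (agar) slabs with
embedded or sloped lipid (lard) inclusions. The package couples a seeded
phantom-scene generator with the two classical hyperspectral analysis chains
used to validate such phantoms:

* **CEM subpixel target detection** — constrained energy minimization designs
  a filter `w` minimizing the image's average output energy `wᵀRw` subject to
  unit response on the target signature, `dᵀw = 1`, where
  `R = (1/N) Σᵢ rᵢrᵢᵀ` is the sample autocorrelation matrix over all pixel
  spectra. The closed form is `w* = R⁻¹d / (dᵀR⁻¹d)`; the per-pixel output
  `A = w*ᵀr` is an abundance-like detection map, binarized with Otsu's
  threshold and scored against ground truth with the Tanimoto (Jaccard)
  index `TI = |X∩Y| / |X∪Y|`.

* **FCLS spectral unmixing** — under the linear mixing model `r = Mα + n`
  (columns of `M` are endmember spectra), abundances are estimated by least
  squares (`α̂ᴸˢ = (MᵀM)⁻¹Mᵀr`), by sum-to-one-constrained least squares, and
  by fully constrained least squares (`α ≥ 0`, `Σα = 1`) via an active-set
  iteration.

The scene generator emulates four phantom geometries (slab thickness series,
embedded target blocks at depth, concentration panels, a sloped lipid wedge)
under a simple two-way attenuation model `f(z) = exp(−2 μ_eff z)`, with exact
ground-truth masks and abundances — so every stage of the analysis chain is
testable against known truth at desk scale. See `docs/methods.md` for the
forward model and its limits.

## Worked example

Detect a lipid block embedded 7–68 mm deep in a collagen phantom:

```python
from swirphantom import run_depth_experiment

res = run_depth_experiment(seed=0)
print(res.rows)
```

```
   depth_mm  fraction  threshold        ti  ti_interior
0       7.0  0.571209   0.044230  1.000000     1.000000
1      15.0  0.301194   0.013183  1.000000     1.000000
2      20.0  0.201897   0.008614  1.000000     1.000000
3      55.0  0.012277   0.004695  0.969531     0.967003
4      60.0  0.008230   0.002338  0.630886     0.611397
5      68.0  0.004339   0.000242  0.239307     0.223733
```

Each row is one simulated scene: `fraction` is the target's true mixing
weight `exp(−2 μ_eff · depth)` under the default attenuation
(μ_eff = 0.04 mm⁻¹), `threshold` the Otsu cut on the CEM map, `ti` the
Tanimoto index of the binarized detection against the ground-truth block, and
`ti_interior` the same index with a 1-pixel ring around the block boundary
excluded (detection errors concentrate at the boundary). Shallow targets are
recovered perfectly; detection degrades once the target's spectral
contribution falls toward the noise floor.

The same pipelines are available from the shell:

```sh
swirphantom simulate --geometry embedded_target --depth 20 --seed 7 --out d20/
swirphantom experiment depth --seed 0 --out depth.csv
swirphantom experiment concentration --seed 11 --out conc.csv
```

Every output directory carries a `provenance.json` sufficient to re-run the
command; cubes are written as ENVI-style float32 rasters (`.dat` + `.hdr`).

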