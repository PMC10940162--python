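# minusend

Quantification toolkit for in vitro reconstitution assays of microtubule
minus-end regulation — the kind of experiment in which purified
γ-tubulin ring complexes (γ-TuRCs) are immobilized on a coverslip,
microtubule nucleation is watched by TIRF microscopy, and minus-end
binding proteins (CAMSAPs) and nucleation-promoting factors compete for
the nucleated minus ends.

It is written for microscopists and biochemists who today stitch this
analysis together from ImageJ plugins (ComDet, DoM, KymoResliceWide,
Particle Analysis) and ad hoc scripts.  The package provides the same
operations as a tested, scriptable Python library with a thin CLI, plus
a synthetic-data generator with known ground truth so that every stage
can be validated by parameter recovery.

## What it computes

**Single-molecule GFP counting** (`minusend.counting`) — the core
algorithm.  A punctum containing *N* independent fluorophores has
intensity distributed as the *N*-fold convolution of the
single-fluorophore intensity PDF *f*:

> p(x) = Σ_N  w_N · f^{*N}(x),   w_N ≥ 0,  Σ w_N = 1.

The monomer PDF is estimated from a monomeric control (e.g. purified
GFP), the basis members f^{*N} are built by iterated self-convolution,
and the weights w_N are fitted by nonnegative weighted least squares on
the punctum intensity histogram.  Exposed as the sklearn-style
estimator `NmerMixture` (with `fit`, `weights_`, `get_params`).

**Spot detection and colocalization** (`minusend.spots`) —
difference-of-Gaussians detection with a robust MAD noise estimate,
minimum-size filtering, sub-pixel 2D-Gaussian refinement with
background-corrected integrated intensity (A·2πσ²), mutual
nearest-neighbour channel colocalization, and thresholded-stretch
counting in an ROI.

**Event scoring** (`minusend.events`) — nucleation efficiency (% active
complexes), CAMSAP colocalization, microtubule release frequency (per
active or per bound complex), re-nucleation frequency, binding→growth
delay histograms, the minus-end capping rule (slow end stably bound
≥ 120 s), and control/reference normalization utilities.

**Microtubule dynamics** (`minusend.dynamics`) — kymograph resampling
along a path, segmentation of end-position tracks into
growth/shrinkage/pause phases, plus growth rate (mean ± s.d. over
growth events) and catastrophe frequency f = N_cat / Σ t_growth with
relative standard error 1/√N_cat.

**Ring geometry** (`minusend.rings`) — ideal 13-protofilament-lattice
reference rings, Kabsch rigid superposition with an anchor subunit
fixing index registration, and per-subunit radial/axial displacement
profiles (values near zero = microtubule-like template geometry).
Reads subunit centres of mass from CSV or from Cα records of PDB files.

**Synthetic data** (`minusend.simulate`) — generators for every input
above with ground truth attached: right-skewed single-fluorophore
intensities, N-mer puncta with binomial fluorophore maturation,
Gaussian-PSF spot images with read/shot noise, Bernoulli-per-window
event processes, and two-state dynamic-instability tracks.

## Worked example

Count GFP-tagged subunits in a bimodal population (37% of puncta
carrying 1–2 fluorophores, 36% carrying 4–5 — a mixture of small
complexes with one tagged subunit and complete rings with five):

```python
from minusend import simulate
from minusend.counting import NmerMixture

model = simulate.MonomerModel(family="lognormal", mean=1000.0, cv=0.35)
mono = simulate.gen_monomer_intensities(model, 10_000, seed=1)
scen = simulate.scenario_bimodal_gcp3(n_puncta=20_000, seed=2)
puncta = simulate.gen_oligomer_dataset(scen, model)

est = NmerMixture(monomer=mono.intensities, n_max=8).fit(puncta.intensities)
for n, w in est.weights_.items():
    if w > 0:
        print(f"N={n}: weight {w:.3f}")
low = est.weights_[1] + est.weights_[2]
high = est.weights_[4] + est.weights_[5]
print(f"1-2 GFPs: {100*low:.1f}%   4-5 GFPs: {100*high:.1f}%")
```

Output:

```
N=1: weight 0.185
N=2: weight 0.189
N=3: weight 0.137
N=4: weight 0.186
N=5: weight 0.170
N=6: weight 0.134
1-2 GFPs: 37.3%   4-5 GFPs: 35.5%
```

The fitted weights recover the generating composition (truth: 0.185,
0.185, 0.14, 0.18, 0.18, 0.13): from intensities alone the method
reports that 37% of the puncta contain one or two fluorophores and 36%
contain four or five.  `est.plot(puncta.intensities)` draws the
histogram, the fitted sum, and the weighted N-mer members beneath it.

The same analyses are available from the shell, e.g.:

```sh
minusend sim intensities --kind oligomer --n 20000 --out puncta.csv
minusend count --monomer mono.csv --test puncta.csv --nmax 8 --out report.json
minusend detect image.tif --sigma 1.5 --snr 5 --out spots.csv
minusend score nucleation --in events.csv --window 600
```

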