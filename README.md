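# corticalhue

A hierarchical model of local hue representation in the primate visual
system.  The package builds the LGN → V1 → V2 → V4 colour pathway as a
feedforward network of model neurons ("mLGN", "mV1", "mV2", "mV4"):
single-opponent centre–surround cells over LMS cone images, half-wave
rectification, multiplicative S-cone gating in mV2, and hue-selective mV4
cells that combine mV2 responses by tuning-peak proximity on the
MacLeod–Boynton (MB) hue circle.  It is aimed at computational
neuroscientists studying how cone-opponent signals are transformed into
perceptual hue representations, and at anyone who wants a fully
reproducible, configuration-driven reference implementation of
single-opponent and multiplicatively modulated colour cells.

## The model in brief

Every layer applies normalized Gaussian receptive fields and the rectifier

    phi(P) = tau  if mP + b < tau;   mP + b  if tau <= mP + b <= s;   1 otherwise.

- **mLGN** (linear, tau = −1): six single-opponent types, e.g. L-on =
  phi(a_L (G(σ_L) ∗ R_L) − a′_L (G(σ′_L) ∗ R_L) − a′_M (G(σ′_M) ∗ R_M)).
- **mV1** (tau = 0): R = phi(G(σ_mV1) ∗ R_mLGN), six types.
- **mV2**: six single-opponent types R = phi(G(σ_mV2) ∗ R_mV1) plus eight
  multiplicative types R = phi(g · (G ∗ R_mV1{L,M}) × (G ∗ R_mV1{S})).
- **mV4**: R_i = phi(Σ_j w_ij (G(σ_mV4) ∗ R_mV2,j)) with
  w_ij = N(d_ij; 0, σ)/Z_i, where d_ij is the circular distance between the
  j-th mV2 tuning peak and the i-th target hue on the MB circle and each row
  of w sums to 1.

Analyses include tuning curves and half-height (Kiper) bandwidths, polar
peak histograms, single-opponent vs multiplicative contribution splits, a
hue-distance / cluster-patch-distance correlation, and sparse L1
reconstruction of arbitrary hues from the six mV4 responses.  See
`docs/methods.md` for conventions, calibration and limitations.

## Worked example

```python
from corticalhue import HueModel, hue_patch_correlation, reconstruct_hue
from corticalhue.analysis import bandwidth_table, contribution_split

model = HueModel().calibrate()

bt = bandwidth_table(model)
print(f"mean bandwidth: additive {bt['mean_additive']:.2f} deg, "
      f"multiplicative {bt['mean_multiplicative']:.2f} deg, "
      f"pooled {bt['mean_pooled']:.2f} deg")

split = contribution_split(model.weight_matrix)
print(f"multiplicative share: green {split['green']['multiplicative']:.1f}%, "
      f"magenta {split['magenta']['multiplicative']:.1f}%")

r, p, pairs = hue_patch_correlation(model)
print(f"hue-distance vs patch-distance: r = {r:.4f}, p = {p:.2e}")

res = reconstruct_hue(model, 360.0, seed=0)
print("red-hue read-out:", {k: round(v, 4) for k, v in res.weights.items() if v > 1e-3})
```

prints

```
mean bandwidth: additive 56.48 deg, multiplicative 27.80 deg, pooled 43.38 deg
multiplicative share: green 81.3%, magenta 82.0%
hue-distance vs patch-distance: r = 0.9294, p = 2.09e-29
red-hue read-out: {'red': 1.0}
```

Multiplicative gating roughly halves the tuning bandwidth of mV2 cells and
shifts their peaks toward intermediate hue directions, which is why the
green and magenta mV4 cells (off the cone-opponent axes) draw over 80% of
their input from multiplicative cells.  The strong correlation (r ≈ 0.93
over all 66 hue pairs) says that hues that are close in the HSL ordering
activate nearby patches in a stacked-mV4 "cluster", mirroring the sequential
colour maps reported in extrastriate cortex.  The reconstruction shows a red
field being read out almost entirely through the red-selective mV4 cell
across 500 random saturation/lightness conditions.

A command-line interface mirrors the library:

```sh
corticalhue stimuli --n 60 --out outputs/stimuli
corticalhue run --hue 120 --out outputs/run
corticalhue bandwidths
corticalhue correlate
corticalhue reconstruct --hue 270 --seed 0
corticalhue report --out outputs/report   # everything + plots + manifest
```

Each run writes CSV outputs and a `manifest.json` with the resolved-config
digest, seed and output paths; identical config and seed reproduce outputs
byte for byte.  Configuration is YAML over defaults
(`corticalhue.config.LayerConfig`); an empty file means the paper-scale
defaults (256 px inputs, receptive fields 19/38/76/152 px).

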