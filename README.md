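# isletnet

Network and circuit models of beta-cell-to-delta-cell coupling in pancreatic
islets, for researchers studying why counter-regulatory glucagon secretion
fails in type-1 diabetes (T1D).

In healthy islets at low glucose, K_ATP-channel-driven hyperpolarisation of
insulin-secreting beta-cells spreads through connexin-36 gap junctions into
somatostatin-secreting delta-cells and silences them; somatostatin in turn
paracrinally inhibits glucagon. Autoimmune destruction of beta-cells removes
this "electric brake": somatostatin rises, glucagon's response to
hypoglycaemia is lost. `isletnet` packages the three quantitative pieces of
that argument:

1. **Contact networks and ablation.** Cells contact when their nuclei lie
   within 30 um (strict `<`). Beta-cells are deleted one at a time in random
   order — mimicking T1D progression — tracking the fraction of delta-cells
   C(f) still touching at least one beta-cell. Because each delta-cell
   touches many beta-cells, C(f) stays above 0.90 until well past 75%
   deletion before collapsing.
2. **Coupling circuit.** The passive two-cell steady state: coupling
   coefficient k = gR/(1+gR) for junctional conductance g and follower input
   resistance R; its exact inverse g = k/((1−k)R); junctional current
   I = g·dV; Ohm's-law input resistance R = dV/dI; and the minimal
   hyperpolarising current |I| = dV/R needed to silence a delta-cell.
3. **Hill secretion fits.** Secretion versus islet insulin content
   y = A/(1 + (EC50/x)^h), rising for glucagon (h > 0), falling for
   somatostatin (h < 0), fitted by multi-start nonlinear least squares, plus
   the Pearson correlation between the two hormones.

Since real 3-D islet reconstructions and the underlying secretion
measurements are not redistributable, a first-class synthetic-data module
generates islet architectures (random sequential addition in a sphere,
human-like intermingled or mouse-like core-mantle composition) and secretion
datasets (forward Hill models plus truncated Gaussian noise) on which every
downstream stage is tested. See `docs/methods.md` for models, assumptions and
limitations.

## Worked example

Run the full connectivity-decay experiment (6 synthetic human-like islets of
1000 cells, 30 um contact rule, 20 random deletion orders per islet):

```sh
isletnet run --seed 1 --out demo_run
```

which prints (abridged):

```json
{
  "baseline_connected_fraction": 1.0,
  "connected_fraction_at_75pct_deleted": 0.9977777777777779,
  "crossing_fraction_deleted": 0.91,
  "crossing_level": 0.9,
  "n_islets": 6,
  "n_replicates_per_islet": 20
}
```

Every delta-cell starts in contact with a beta-cell; after deleting 75% of
beta-cells, 99.8% of delta-cells still touch one, and the across-islet mean
first drops below 0.90 only at 91% deletion — random beta-cell loss barely
dents delta-to-beta connectivity until almost all beta-cells are gone. The
run directory holds the curve (`curve.tsv`, deleted fraction in percent with
a 95% CI over islets), the architectures, and a summary with the config hash.

The circuit calculator inverts paired voltage deflections (78 mV in the
driver beta-cell, 15 mV arriving in the delta-cell, follower resistance
10.35 GOhm):

```sh
$ isletnet couple --dv-pre 78 --dv-post 15 --r-post 10.35
{
  "k": 0.19230769230769232,
  "g_gap_pS": 23.004370830457788
}
```

i.e. ~19% of the beta-cell deflection reaches the delta-cell through a
~23 pS junction. Hill fitting on a synthetic 60-group secretion dataset
(generating EC50 = 56 nmol, h = 1.9, noise sd 0.1):

```python
from isletnet import HillModel, fit_hill, correlate, generate_secretion_dataset

ds = generate_secretion_dataset(HillModel(1, 56, 1.9), HillModel(1, 53, -2.5),
                                n_groups=60, seed=1)
fit = fit_hill(ds["insulin_content_nmol"], ds["glucagon"])
# EC50 = 50.4 ± 2.1 nmol, h = 2.13 ± 0.18
res = correlate(ds["somatostatin"], ds["glucagon"])
# r = -0.961, p = 5.29e-34
```

The fit recovers the generating parameters to within a couple of standard
errors, and somatostatin and glucagon generated over shared insulin contents
are strongly negatively correlated, as the opposed signs of their Hill
coefficients dictate.

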