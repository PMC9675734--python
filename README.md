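# redoxkit

Quantitative analysis toolkit for single-molecule electron-transfer (ET)
and binding experiments on redox protein partners — the kind of
multimodal data set produced when cytochrome *c*₁ and cytochrome *c*
(wild type or a phosphomimetic variant) are probed by electrochemical
tunneling spectroscopy, break-junction blinking, AFM force spectroscopy
and SPR, with an ionic-environment model of the aqueous gap between the
redox sites.

It is written for experimentalists who need the complete chain from raw
curves to published quantities, and for methods developers who need
every stage testable: each analysis module is paired with a synthetic
generator (`redoxkit.simulate`) that produces data with exactly the
statistical structure the analysis assumes, carrying its ground truth in
metadata, so the whole pipeline is validated by parameter recovery.

## The five channels

| channel | model | estimate |
|---|---|---|
| `decay` | I(z) = A·e^(−βz) + I_leak | distance-decay factor β (nm⁻¹), β-population mixtures, β vs electrochemical gate |
| `blinks` | two-level telegraph noise | junction conductance G = I_blink/V_bias in units of G₀ = 2e²/h |
| `forcespec` | Bell–Evans: F\* = (k_BT/x_u)·ln(x_u·r/(k⁰_u·k_BT)) | rupture-force statistics, zero-force unbinding rate k⁰_u, barrier distance x_u, regime |
| `binding` | 1:1 Langmuir, R_eq(C) = R_max·C/(C + K_D) | global k_on, k_off, K_D = k_off/k_on |
| `ionfield` | Debye–Hückel screening + centrosymmetric Brownian dynamics | ion molarity maps, prism averages, equipotential fields, association-rate vs reaction-distance curves |

The fitting stages follow the model/results idiom: construct a model
from data, call `.fit()`, read estimates, standard errors and
`summary()` from the results object.

## Worked example

Generate 100 wild-type-like retraction curves (β = 1.3 nm⁻¹, 0.4 nA set
point, 2 pA leakage, 5 % noise), fit each, and model the β population:

```python
from redoxkit.simulate import IZGenConfig, gen_iz_ensemble
from redoxkit import decay

curves = gen_iz_ensemble(IZGenConfig(n_curves=100, seed=1))
betas = [decay.fit_decay(c).beta for c in curves]
print(decay.BetaMixture(betas).fit(max_components=1).summary())
```

```
Beta population: 1 component(s)
==========================================
  center  1.303 nm^-1   sd  0.021 nm^-1   weight  1.00
  BIC[1 comp] = -481.73
```

The ensemble center recovers the generating β = 1.3 nm⁻¹ to 0.3 %.
A single-curve fit shows the per-curve diagnostics:

```
Exponential decay fit
==========================================
beta               1.3179  nm^-1  (+/- 0.0117)
amplitude          0.4014  nA
leakage           0.00261  nA
fit window     0.029 - 3.519 nm  (239 points)
R^2                0.9969
```

Global 1:1 SPR fit of two noiseless sensograms (5 and 2.5 µM) generated
with k_on = 10⁴ M⁻¹s⁻¹, k_off = 3.58·10⁻³ s⁻¹:

```python
from redoxkit.simulate import SPRGenConfig, gen_sensogram
from redoxkit import binding

fit = binding.fit_global_1to1(
    gen_sensogram(SPRGenConfig(kon=1.0e4, koff=3.58e-3, seed=1)))
print(fit.summary())
```

```
1:1 Langmuir binding kinetics (global fit)
==============================================
n sensograms  2   at 5e-06 M, 2.5e-06 M
kon          1e+04  (+/- 5.56e-11)  M^-1 s^-1
koff       0.00358  (+/- 6.62e-18)  s^-1
Rmax           100  (+/- 1.15e-13)  RU
K_D       3.58e-07  M
R^2       1.000000
```

K_D = k_off/k_on = 3.58·10⁻⁷ M: tighter binding (smaller K_D) than the
wild-type rates give (3.18·10⁻³/6.54·10³ = 4.86·10⁻⁷ M).

Dynamic force spectroscopy — invert most-probable forces at four loading
rates back to the unbinding kinetics:

```python
from redoxkit import forcespec

pts = [(r, forcespec.most_probable_force(48.0, 0.31, r))
       for r in (28e3, 56e3, 112e3, 224e3)]
print(forcespec.bell_evans_fit(pts).summary())
```

```
Bell-Evans dynamic force spectroscopy
==========================================
slope          13.2710  pN / ln(pN s^-1)  (+/- 0.0000, p=1e-20)
intercept     -85.6877  pN
regime      kinetic
k0_u                48  s^-1
x_u             0.3100  nm
```

The inversion is exact: k⁰_u = 48 s⁻¹ and x_u = 0.31 nm are recovered to
machine precision.

## Command line

```sh
redoxkit simulate iz --seed 1 --out data/iz
redoxkit analyze iz --in data/iz --out results/iz.json
redoxkit simulate spr --seed 1 --out data/spr
redoxkit analyze spr --in data/spr --out results/spr.json
```

`simulate` also covers `blink`, `force` and `ions`; `analyze` covers
`blink`, `force` and `ions` (density maps, prism averages, OpenDX
export). Generator settings come from a YAML file via `--config`.

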