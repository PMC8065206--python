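# ntekinetics

Dose–response modeling of radiation-induced cognitive dysfunction with
**targeted (TE)** and **non-targeted (NTE)** effect components.

## The problem

Rats exposed to space-relevant ion beams (protons through iron, linear
energy transfer 0.22–181 keV/µm, absorbed doses 0.001–2 Gy) show deficits
in novel-object recognition (NOR): they spend a smaller fraction of
exploration time `F_nov` at a novel object. Two damage mechanisms compete
to explain the dose dependence:

* **TE** — damage in cells traversed by ionizing tracks; dose responses
  are linear or quadratic in dose `D`;
* **NTE** — responses of *non-traversed* cells to signals released by
  traversed ones; dose responses rise steeply at very low doses and
  saturate.

Working on the transformed scale `R = −ln(F_nov)`, the package fits the
family

```
R = B + kNTE · (1 − exp(−kNTE_r · D)) + Σ_i kTE_i · D_i^q
```

with baseline `B`, NTE plateau `kNTE`, a fixed NTE rise constant
`kNTE_r = 10³ Gy⁻¹` (saturation below ~0.01 Gy), and TE slopes `kTE_i`
(`q` = 1 or 2) that may differ across four LET categories
(L/M/H/VH). Eighteen named variants — with/without NTE, linear/quadratic
TE, six LET groupings — are compared by AICc.

The audience is radiation biophysicists and biostatisticians who want to
ask, for their own NOR-style datasets or simulations: *is a saturating
low-dose (NTE) component required by the data, and how large is it
relative to the dose-linear (TE) component?*

## What is implemented

| module (`src/ntekinetics/`) | contents |
| --- | --- |
| `data` | CSV ingest, `R = −ln(F_nov)` transform, LET binning, Spearman predictor screen |
| `synthetic` | study-design emulator with known generative truth (per-rat baselines, noise, contamination) |
| `models` | the 18-variant registry; linear-in-parameters design matrices |
| `robust` | Huber/bisquare M-estimation by IRLS with MAD scale; sandwich Wald inference |
| `selection` | AICc, support weights, goodness metrics, 300-split stability analysis |
| `quantile` | nonlinear quantile regression (smoothed check loss + simplex polish, case bootstrap) |
| `mixed` | exact-marginal-likelihood random-intercept fit with dose/LET variance function, residual diagnostics, Fligner–Killeen screens |
| `importance` | shadow-feature (Boruta-style) screen with per-tree OOB permutation importance; tuned random-forest evaluation |
| `pipeline`, `cli` | end-to-end orchestration and the `ntekinetics` command line |

The numbered scripts under `analysis/` run the full study on synthetic
data and write tables under `results/`.

## Worked example

```sh
python analysis/01_simulate_dataset.py        # ~920 simulated NOR tests
python analysis/03_compare_models.py          # 18-variant AICc table
```

The comparison ends with (abridged):

```
best-supported variant: NTE_TE_quad_S2
closest NTE-free variant trails by dAICc = 34.6

best-model robust estimates (sandwich SEs):
parameter  estimate     se  p_value
        B    0.4067 0.0306   0.0000
     kNTE    0.1965 0.0335   0.0000
  kTE_LMH    0.0106 0.0078   0.1766
   kTE_VH    0.0480 0.0119   0.0001
```

Read: the baseline response of unirradiated rats is ≈ 0.41 (so sham rats
spend `exp(−0.41) ≈ 66%` of their time at the novel object); radiation
adds a ≈ 0.20 response-unit step that is already complete at ~0.01 Gy
(the NTE plateau), plus a dose-proportional TE term that is several-fold
steeper for very-high-LET ions. Every variant within AICc striking
distance of the best contains the NTE term, while the best TE-only
variant trails by ΔAICc ≈ 35 — overwhelming support for a non-targeted
component. Which *sibling* wins (linear vs quadratic TE, exact LET
grouping) varies from dataset to dataset; the NTE term's presence does
not.

The same dataset can then be pushed through quantile regression
(`analysis/05_…`), the mixed-effects fit (`analysis/06_…`, which also
recovers the between-rat baseline SD), and the feature-importance screen
(`analysis/07_…`, where the NTE functional form `nte_f = 1 − exp(−10³·D)`
and dose rank as the top two predictors). Or in one shot:

```sh
ntekinetics run --seed 1 --out results/run
```

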