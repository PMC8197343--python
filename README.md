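# isoquantal

Isobolographic analysis of fixed-ratio drug combinations from quantal
dose–response data.

`isoquantal` is aimed at pharmacologists running in-vivo combination screens
— the motivating use case is triple antiseizure-drug combinations in the
mouse maximal-electroshock (MES) seizure model, where the per-animal outcome
is binary (protected from tonic-clonic seizures or not) and each dose group
contains a handful of animals.  The package covers the full analysis chain:

1. **Log-probit fitting** — maximum-likelihood binomial probit regression of
   protection on log10 dose, `p(d) = Φ(β₀ + β₁ log₁₀ d)`, reported in the
   classical probit convention (`probit = 5 + Φ⁻¹(p)`, so 50% protection is
   5 probits).  The median effective dose is
   `log₁₀ ED₅₀ = (5 − intercept)/slope`, with a delta-method SEM on the
   mg/kg scale, `SEM = ED₅₀ · ln 10 · SE(log₁₀ ED₅₀)`, and the
   informative-animal count n (animals at doses whose fitted effect lies in
   the 4–6 probit band, i.e. 16–84% protection).
2. **Loewe additivity for fixed-ratio mixtures** — in a 1:1:1 design each
   drug contributes an equal fraction of its *own* ED₅₀, and the additive
   expectation is `ED₅₀,add = Σᵢ fᵢ·ED₅₀,ᵢ` with
   `SEM_add = √(Σᵢ fᵢ²·SEMᵢ²)` propagated across the independent
   single-drug experiments.
3. **Interaction classification** — the experimental mixture ED₅₀ is
   compared against the additive prediction with an unpaired t test in the
   Welch form computed directly from the SEMs
   (`t = |ED₅₀,add − ED₅₀,exp| / √(SEM²exp + SEM²add)`, Welch–Satterthwaite
   df with per-estimate df = n − 1).  Significance plus direction gives
   **Synergy** / **Additivity** / **Antagonism**; the interaction index
   `ED₅₀,exp / ED₅₀,add` grades the potency of the interaction.
4. **Visualisation** — per-combination fixed-ratio-ray isobologram plots
   (additive point A vs experimental point M, SEM bars, significance
   stars) and the polygonogram: drugs as polygon vertices with each
   classified triple drawn as a coloured translucent triangle.
5. **Synthetic experiments** — a seeded generator of binomial quantal
   datasets with a known true interaction index, so the whole pipeline can
   be validated (calibration, power, parameter recovery) without animal
   data.
6. **Behavioural side-effect statistics** — one-way ANOVA for grip strength
   and Kruskal–Wallis for ceiling-censored rotarod balance times.

## Worked example

A published screen of six LCM-based triple combinations is bundled as
summary records.  Re-analysing it end to end:

```python
from isoquantal import study_results, rank_by_index

for res in rank_by_index(study_results()):
    print(res.summary())
```

prints

```
LCM + OXC + TPM: ED50_exp = 31.06 ± 2.34 (n=24) vs ED50_add = 28.25 ± 3.37 (n=50); t_71.99 = 0.685, p = 0.496 -> Additivity (index 1.10)
LCM + LTG + OXC: ED50_exp = 7.50 ± 0.98 (n=32) vs ED50_add = 8.97 ± 0.51 (n=42); t_47.43 = 1.331, p = 0.19 -> Additivity (index 0.84)
LCM + LTG + PGB: ED50_exp = 35.59 ± 3.86 (n=24) vs ED50_add = 45.52 ± 4.46 (n=42); t_62.71 = 1.684, p = 0.0972 -> Additivity (index 0.78)
LCM + LTG + TPM: ED50_exp = 19.06 ± 2.70 (n=24) vs ED50_add = 26.47 ± 3.37 (n=34); t_55.91 = 1.716, p = 0.0917 -> Additivity (index 0.72)
LCM + OXC + PGB: ED50_exp = 33.04 ± 4.62* (n=24) vs ED50_add = 47.30 ± 4.45 (n=58); t_63.44 = 2.223, p = 0.0298 -> Synergy (index 0.70)
LCM + TPM + PGB: ED50_exp = 35.50 ± 5.28*** (n=24) vs ED50_add = 64.80 ± 5.02 (n=50); t_60.26 = 4.022, p = 0.000163 -> Synergy (index 0.55)
```

Each line compares the fitted mixture potency (M) against the mass-action
additive expectation (A): `t_{df}` is the Welch statistic at its
Satterthwaite degrees of freedom, stars mark significance (\*\*\* p < 0.001),
and the index below 1 quantifies how much less mixture than predicted was
needed — 0.55 means the LCM + TPM + PGB mixture protected half the animals
at 55% of the additive dose, the strongest synergy in the set.

Building an additive prediction from (here illustrative) single-drug
summaries works the same way:

```python
from isoquantal import SummaryEffectRecord, MixtureSpec, additive_ed50

lcm = SummaryEffectRecord("LCM", 9.76, 1.08, 16)
tpm = SummaryEffectRecord("TPM", 74.43, 10.25, 16)
pgb = SummaryEffectRecord("PGB", 110.20, 12.94, 18)
spec = MixtureSpec.equal_ratio([lcm, tpm, pgb], label="LCM + TPM + PGB")
print(additive_ed50(spec))
# AdditivePrediction(ed50_add=64.79666666666667, sem_add=5.514349966728223, n_add=50)
```

Raw quantal counts go through `read_quantal_csv` /
`QuantalProbitModel(...).fit()`, and the whole chain — fit singles, predict
additivity, fit the mixture, classify, plot — is driven by one config file
via `run_pipeline` or the CLI:

```sh
isoquantal run config.yaml        # full pipeline -> report + plots + manifest
isoquantal fit counts.csv --out fits.json
isoquantal simulate scenario.yaml --out synthetic.csv
isoquantal behavior grip.csv --test anova
```

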