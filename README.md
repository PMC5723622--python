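# bambooclim

Bioclimatic-envelope modelling of invasive bamboo (*Phyllostachys edulis*,
moso, and *P. bambusoides*, madake) for ecologists and climate-impact
analysts: from presence/absence records at weather stations to maps of
potential habitat under 1.5–4.0°C of global warming.

The pipeline has four stages, each usable on its own:

1. **Climatic indices** — from monthly station climatologies: mean annual
   temperature, Kira's warmth index WI = Σ max(tᵢ − 5, 0) and coldness
   index CI = Σ min(tᵢ − 5, 0) (°C·month), and the growing-season
   (months with tᵢ ≥ 5°C) precipitation split.
2. **Niche model** — a binomial GLM with logit link,
   P(presence) = logit⁻¹(β₀ + β_T·T + β_R·R), selected by all-subsets AICc
   search (AICc = −2ℓ + 2k + 2k(k+1)/(n−k−1)), validated by leave-one-out
   cross-validation with a Youden-J probability cutoff
   (J = sensitivity + specificity − 1), and scored with AUC, MCC,
   informedness, accuracy, sensitivity, specificity, PPV and NPV —
   conventions chosen for presence-heavy, imbalanced survey data.
3. **Scenario scaling** — pattern scaling: the per-cell change between a
   present and a future regional simulation, divided by the run's
   global-mean warming ΔT_g, gives change per 1°C; a scenario at X°C above
   preindustrial is baseline + (X − 0.5)·pattern, the 0.5°C being the
   warming already realised by the 1990-centred baseline. Exceedance years
   are read off a 20-year running-mean global anomaly series.
4. **Projection** — cellwise probability maps, inclusive thresholding
   (habitat iff p ≥ τ), habitat-area fractions over a focal region
   (default ≥ 35°N, ≥ 136°E), northern-limit shifts in km, and MESS
   (multivariate environmental similarity) surfaces flagging cells whose
   climate falls outside the calibration stations' range.

A synthetic-data module generates station networks, paired present/future
grids, and anomaly series with known ground truth, so the whole pipeline is
testable end to end without any external data.

## Worked example

```python
import numpy as np
from bambooclim import (SyntheticWorldSpec, make_stations, fit_logistic,
                        loocv_scores, roc_auc, youden_threshold, confusion, metrics)
from bambooclim.cli_io import station_summaries

spec = SyntheticWorldSpec(seed=42)          # 145 stations, known truth
table, truth = make_stations(spec)
s = station_summaries(table)
print(f"stations: {len(s)}, presences: {int(s.presence.sum())}")

model = fit_logistic(s[["mean_annual_temp", "radiation"]], s["presence"])
print("coefficients:", {k: round(v, 3) for k, v in model.coefficients.items()})
print(f"AICc: {model.aicc:.2f}")

scores = loocv_scores(["mean_annual_temp", "radiation"], s)
ok = ~np.isnan(scores)
labels = s["presence"].to_numpy()
tau = youden_threshold(scores[ok], labels[ok])
rep = metrics(confusion(scores[ok], labels[ok], tau),
              auc=roc_auc(scores[ok], labels[ok]), threshold=tau)
print(f"LOOCV AUC={rep.auc:.3f}  threshold={tau:.3f}  "
      f"accuracy={rep.accuracy:.3f}  MCC={rep.mcc:.3f}  J={rep.informedness:.3f}")
```

prints

```
stations: 145, presences: 117
coefficients: {'intercept': -22.736, 'mean_annual_temp': 2.118, 'radiation': 0.232}
AICc: 55.87
LOOCV AUC=0.956  threshold=0.666  accuracy=0.924  MCC=0.776  J=0.824
```

The generating truth was (β₀, β_T, β_R) = (−18.4, 1.5, 0.35); at n = 145
the fit lands within sampling error of it (3-SE coverage is tested
systematically at n = 5,000). The threshold 0.666 is the LOOCV-score
cutoff maximising J; accuracy, MCC and informedness then describe the
2×2 table of held-out classifications at that cutoff.

The same run from a shell, end to end:

```sh
bambooclim simulate --out world --seed 42      # stations, 4-member grids, anomaly series
bambooclim report --config world/config.yaml   # indices → fit → LOOCV → scenarios → maps
```

`report` writes `station_summaries.csv`, `collinearity.csv`, `dredge.csv`,
`model.json`, `exceedance_years.json` and `projection_summary.csv` (habitat
fraction, min–max across ensemble members, northern limit, northward shift
in km, and the MESS novel-climate fraction, per warming level).

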