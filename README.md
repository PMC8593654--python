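# streampulse

Analysis toolkit for **continuous high-frequency pesticide monitoring of
small agricultural streams**: hydro-meteorological event classification,
uncertainty-weighted robust positive matrix factorization (PMF) of
multi-compound concentration time series, and acute-exposure assessment
quantifying how time-composite regulatory sampling underestimates
concentration peaks and standard exceedances.

## Who this is for

Water-quality scientists and environmental modellers working with
multi-species concentration series measured at high temporal resolution
(here: 20-minute grab samples over a multi-week campaign) alongside
rainfall and water-level records.  The package answers three questions:

1. **When was the stream in which hydrological state?**  Storms are
   segmented from the 10-min rainfall record (events separated by ≥ 2 h
   without rain) and classified *large* vs *small* by whether the peak
   intensity exceeds 1 mm/10 min; rain-free days with a stable water
   level are *dry*.
2. **Which latent sources drive the concentration dynamics?**  The n × m
   concentration matrix X is factorized as X ≈ G F with G (n × p) and
   F (p × m) nonnegative, minimising the uncertainty-weighted objective

   Q = Σᵢⱼ [ (xᵢⱼ − Σₖ gᵢₖ fₖⱼ) / uᵢⱼ ]²

   with per-cell uncertainties
   uᵢⱼ = √((aⱼ xᵢⱼ)² + LOQⱼ²) for x > LOQ and uᵢⱼ = ⅚ · LOQⱼ otherwise
   (aⱼ = relative measurement error, LOQⱼ = limit of quantification).
   Values below LOQ enter the factorization as LOQ/2.  Species are
   screened by signal-to-noise S/N = mean d, with d = 0 for x ≤ LOQ and
   d = (x − u)/u above it: *bad* species (S/N ≤ 0.2) are excluded, *weak*
   ones (0.2 < S/N ≤ 1) keep their data with uncertainty tripled.
   Fitting runs in robust mode (cells with |e/u| > 4 have their influence
   capped; Q_robust excludes them), with 20 random restarts per factor
   number and the diagnostic ratio Q_robust/Q_exp,
   Q_exp = n·m_good − p(n + m_good), guiding the choice of p.
3. **What does composite sampling miss?**  Regulatory monitoring pools
   water over 3.5-day (or 14-day) windows.  The exposure module emulates
   such composites (values < LOQ set to LOQ, windows with > 10 % missing
   samples flagged), computes per-window **underestimation factors**
   (maximum 20-min concentration ÷ composite mean), sweeps the composite
   start time to bound the worst case, and tallies exceedances of acute
   quality standards (AQS) and regulatory acceptable concentrations (RAC)
   at both resolutions.

Because raw campaign data of this kind are rarely redistributable, the
package ships a **synthetic catchment generator** with known ground truth
(six sources over 17 compounds, 41 days at 20-min resolution by default):
event-driven concentration pulses with compound-specific lags riding on
low baselines, a legacy compound that dilutes during events, LOQ
censoring, and the same noise model the uncertainty matrix assumes.
Every downstream stage is tested against this ground truth.

## Worked example

The package bundles a published comparison of 20-minute concentration
maxima against 3.5-day composite concentrations for compounds that
exceeded their AQS in a small Swiss agricultural stream:

```python
from streampulse.datasets import load_peak_vs_composite_example
from streampulse.exposure import peak_vs_composite_assessment

table = peak_vs_composite_assessment(load_peak_vs_composite_example())
print(table[["compound", "max_20min", "composite", "underestimation",
             "is_bound", "aqs_highfreq", "rac_highfreq"]].round(2).to_string(index=False))
```

```
           compound  max_20min  composite  underestimation  is_bound  aqs_highfreq  rac_highfreq
       azoxystrobin     6300.0      490.0            12.86     False          True          True
             diuron      490.0        NaN            32.67      True          True         False
          fluopyram    30900.0     2690.0            11.49     False          True          True
       nicosulfuron      280.0       32.0             8.75     False          True          True
        thiacloprid     2280.0      270.0             8.44     False          True          True
        carbendazim        NaN      790.0              NaN     False         False         False
chlorpyrifos-methyl        NaN       10.0              NaN     False         False         False
```

Reading: azoxystrobin peaked at 6300 ng/l while the composite sample over
the same 3.5 days averaged 490 ng/l — the composite underestimates the
acute peak 12.9-fold.  The diuron composite was censored (< LOQ of
15 ng/l), so its factor 490/15 = 32.7 is a lower bound (`is_bound`).
Counting distinct compounds: 5 exceed their AQS and 4 their RAC at
20-minute resolution, but only 1 (thiacloprid) exceeds its RAC in the
composite record — the central bias this machinery quantifies.

A full synthetic study, end to end:

```python
from streampulse.pipeline import RunConfig, run_pipeline, make_report

cfg = RunConfig(out_dir="demo_run", seed=1, pmf_p=6, pmf_n_runs=8)
run_pipeline(cfg)
print(make_report("demo_run"))
```

```
streampulse run report — demo_run
events: 7 large, 13 small; total rain 116.0 mm
screening: {'good': 13, 'weak': 4}
pmf: p=6, Q_robust/Q_exp=0.69, mean R2=0.73, converged=True
pmf scan elbow: p=6
recovery vs truth: mean matched profile cosine 0.969
exposure 3.5d: 3 PPPs > AQS (20-min), 2 PPPs > RAC (20-min), 0 PPPs > RAC (composite)
worst underestimation: metolachlor x17.1 (3.5-day window)
```

The factor-number scan finds its elbow at the planted six sources, and the
estimated factor profiles match the ground truth with mean cosine 0.97.

The same stages are available on the command line:

```bash
streampulse simulate --seed 1 --out data/
streampulse classify-events --rain data/rain.csv --level data/level.csv
streampulse screen --conc data/concentrations.csv --meta data/compounds.csv
streampulse pmf --input pmf_X.csv --uncert pmf_U.csv --factors 6 --runs 20 --seed 1
streampulse exposure --conc data/concentrations.csv --meta data/compounds.csv --window 3.5d --sweep
streampulse run --seed 1 --out run/
```

## Layout

- `streampulse.data_model` — domain types (compound metadata,
  concentration matrix with censoring/gap masks, hydro series) and CSV I/O;
  mass-conserving grid alignment.
- `streampulse.synthetic` — the synthetic catchment generator.
- `streampulse.hydro_events` — event segmentation and dry-period search.
- `streampulse.screening` — `SpeciesScreener` (uncertainty matrix, S/N
  classes, factorization-input preparation).
- `streampulse.pmf` — `RobustPMF` estimator (scikit-learn style) plus
  factor-number scan, fingerprints, bootstrap and factor matching.
- `streampulse.exposure` — composite emulation, underestimation factors,
  offset sweep, exceedance assessment.
- `streampulse.pipeline` / `streampulse.cli` — orchestration and CLI.

See `docs/methods.md` for the modelling assumptions, parameter defaults
and numerical choices.
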