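# mmsurv

Single-cell lineage survival and drug-interaction analysis for
mother-machine time series.

`mmsurv` is for microbiologists and quantitative biologists who track
*E. coli* mother-cell lineages in microfluidic devices and want to know how
an antibiotic combination acts on single cells: does a combination improve
population growth because cells elongate faster, divide more — or simply
die less?  The package implements the full analysis chain for the
ciprofloxacin (CIP) + tetracycline (TET) antagonism: CIP is bactericidal
(DNA damage, SOS response, cell death), TET is bacteriostatic (slower
elongation), and their combination is *suppressive* — more cells survive
CIP+TET than CIP alone — with the strength of suppression depending on the
nutrient-set growth rate.

## What it computes

Given per-cell per-frame measurement tables (a BACMMAN-style segmentation
export: length, area, and total fluorescence of an SOS reporter
P_sulA-mGFP and a constitutive P_tetO1-mKate2), the pipeline produces:

* **Elongation rates** — per cell cycle, by least squares on
  ln length: S_t = S₀·e^(μt), with a ≥3-frame constraint; plus windowed
  instantaneous rates for non-dividing (filamenting) cells.
* **Lineage fates** — survived / died / censored.  A lineage is dead when
  its instantaneous rate falls below a small fraction of the drug-free
  median rate and never recovers; washout and hyper-filamentation beyond
  the channel length are right-censored.  Dead lineages are split into
  **low-SOS** and **high-SOS** classes by peak SOS expression
  (fluorescence / area) relative to the survivors' steady-state median —
  the two classes differ by roughly an order of magnitude.
* **Survival analysis** — Kaplan–Meier curves S(t) with Greenwood
  log(−log) 95% CIs, log-rank tests, and end-of-experiment survival
  fractions Sf per replicate.
* **Drug interaction** — the Bliss-independence expectation
  Bliss_ij = exp(ln Sf_CIP,i + ln Sf_TET,j) over replicate pairs, a
  one-sided ANOVA contrast test of
  H₀: ln Sf_CIP + ln Sf_TET − ln Sf_CIP-TET = 0, pairwise two-sided
  t-tests, and the suppression statistic
  Σ = (Sf_CIP-TET − Sf_CIP)/Sf_CIP.

Because the study's raw data are images, the package ships a calibrated
synthetic generator (`mmsurv.simulate`) that emulates the post-segmentation
tables for three growth media — glu-aa (fast, μ≈1.13 h⁻¹), glu (0.54 h⁻¹)
and gly (slow, 0.28 h⁻¹) — including the drug window (hours 2–14 of
retained time), the two death modes, post-death photobleaching,
filamentation, and channel-loss censoring.  Every stage of the pipeline is
tested against this generator's ground truth.

## Worked example

```python
from mmsurv.pipeline import PipelineConfig, run_pipeline

res = run_pipeline(PipelineConfig(
    media=("glu-aa",), n_lineages=500, n_replicates=2, seed=7,
    out_dir="mmsurv-out",
))
r = res["glu-aa"]
print(r["interaction"][["stratum", "sf_cip_mean", "sf_combo_mean",
                        "bliss_mean", "sigma", "p_bliss_one_sided"]])
```

prints (seed 7):

```
 stratum  sf_cip_mean  sf_combo_mean  bliss_mean  sigma  p_bliss_one_sided
     all       0.3648         0.7350      0.3562 1.0150             0.0000
 low-sos       0.4743         0.8154      0.4630 0.7191             0.0005
high-sos       0.8725         0.9044      0.8725 0.0365             0.1504
```

Reading: under CIP alone 36% of glu-aa lineages survive; under CIP+TET 74%
survive, against a Bliss-independence expectation of 36% — the combination
rescues cells (Σ ≈ 1.0, one-sided p < 10⁻⁴), so the interaction is
suppressive.  The rescue is carried by the low-SOS death mode
(Σ ≈ 0.72, p = 0.0005); high-SOS deaths are barely affected (p = 0.15).
The same run writes, per medium, CSVs for generation fits, windowed
elongation distributions, lineage fates, fate fractions, survival curves
(whole-population and SOS-stratified), replicate Sf values, log-rank tests
(CIP vs CIP-TET: p ≈ 9·10⁻⁵⁷ here) and the interaction report, each
stamped with the config hash and seed.

The same stages are available from the shell:

```bash
mmsurv simulate --medium glu-aa --condition CIP --seed 7 --out out/
mmsurv fit      --obs out/observations_CIP.csv --out out/fits.csv
mmsurv classify --obs out/observations_CIP.csv --out out/fates.csv
mmsurv pipeline --paper-defaults --media glu-aa,glu,gly --seed 7 --out out/
```

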