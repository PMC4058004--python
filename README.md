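# tamoxsim

Virtual clinical trials of tamoxifen–endoxifen dosing under CYP2D6
phenotype stratification.

## The problem

Tamoxifen, the endocrine backbone of estrogen-receptor-positive early
breast cancer treatment in postmenopausal women, is a prodrug: its
anti-estrogenic activity is carried mostly by the secondary metabolite
endoxifen, formed from N-desmethyltamoxifen (NDM) by the highly
polymorphic enzyme CYP2D6. Patients with one functional *CYP2D6* allele
(intermediate metabolizers, IM) or none (poor metabolizers, PM) reach
substantially lower endoxifen steady-state trough concentrations than
normal (extensive) metabolizers (EM), which has been linked to poorer
outcome. Two remedies have been proposed: escalating the tamoxifen dose,
or co-administering a small oral dose of endoxifen itself.

`tamoxsim` simulates both strategies *in silico*. It implements a
linear metabolite-cascade pharmacokinetic model of tamoxifen (TAM) and
its three measured metabolites — NDM, 4-hydroxytamoxifen (4OH) and
endoxifen (END) — with first-order oral absorption, one apparent
compartment per analyte, and CYP2D6-dependent formation steps scaled by
phenotype activity (EM 1.0, IM 0.5 on the gene-dose scale, PM 0.0).
For an edge with CYP2D6 share *f*, the effective rate constant is

    k_eff = k_base · (f · a · η_2D6 + (1 − f)),

where *a* is the phenotype activity and η_2D6 a lognormal, median-1
subject multiplier; a second multiplier η_abs scales oral exposure.
Because the system is linear and constant-coefficient, troughs are
exactly dose-proportional and concurrent tamoxifen + endoxifen dosing
superposes — properties the model exploits for calibration and that the
test suite asserts numerically.

The cascade is calibrated so the typical subject reproduces
phenotype-specific median trough concentrations at the 20 mg/day
reference regimen (e.g. EM 4OH 3.8 µg/L, EM END ≈ 21.8 µg/L as implied
by the reported EM endoxifen 5th/25th percentiles of 7.5/14.08 µg/L),
and the population variability is calibrated so an EM population
reproduces exactly that percentile spread. On top of the model sits a
trial engine with the fifteen simulation protocols of the study design:

* **Group A** – 20 mg tamoxifen q.d. for 12 months in EM/IM/PM
  (the EM arm defines the reference band);
* **Group B** – 4 months at 20 mg q.d., then 4 months escalated
  (20 mg b.i.d. / 40 mg q.d. in IM and PM, 60 mg q.d. in PM);
* **Group C** – 20 mg tamoxifen q.d. plus concomitant once-daily oral
  endoxifen (0.5–1.5 mg in IM, 1–4 mg in PM), with a dose-finding
  search for the smallest dose matching the EM endoxifen median.

## Worked example

```python
from tamoxsim import build_default_model, find_minimal_dose

model = build_default_model()          # calibrates cascade + variability
best, table = find_minimal_dose(model, "PM")
print(best)
print(table)
```

prints

```
3.0
   end_dose_mg  median_end_ugL  em_reference_ugL  rel_deviation  passes
0          1.0        9.985437         21.814156      -0.542250   False
1          2.0       15.899437         21.814156      -0.271143   False
2          3.0       21.814156         21.814156       0.000000    True
3          4.0       27.728875         21.814156       0.271143   False
```

Each mg/day of oral endoxifen adds k_END ≈ 5.91 µg/L to the trough, so
3 mg/day lifts the typical PM from its median of 4.07 µg/L to the EM
reference median of 21.8 µg/L (within the ±10 % criterion), while for
IMs 1 mg/day suffices — the phenotype-adjusted dosing result. The
`examples/` directory has one narrative script per capability
(time course, phenotype comparison, dose escalation, dose finding,
full 15-arm trial); each prints the numbers it computes and what they
mean.

A thin CLI wraps the same library:

```bash
tamoxsim calibrate -o model.yaml
tamoxsim run-trial --group all --n 1000 --seed 42 -o trial_out
tamoxsim find-dose --phenotype PM
```

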