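# methclock

DNA methylation age ("epigenetic clock") estimation from beta-value
matrices, with a sensitivity analysis for cross-array probe loss.

Epigenetic clocks predict age as a linear combination of CpG
methylation fractions: `m = a + Σⱼ wⱼ βⱼ`, optionally mapped to years
through the inverse of Horvath's log-linear age transform
`F(t) = log(t+1) − log(A+1)` for `t ≤ A`, `(t−A)/(A+1)` otherwise
(adult age `A` = 20 y).  Clocks built for the Illumina 27k/450k arrays
lose probes on the EPIC (850k) array — 17 of the 353 Horvath CpGs
(4.8%), 6 of the 71 Hannum CpGs (8.5%) — and imputing the lost probes
biases DNAm-age estimates.  This package is for epigenomics researchers
who need to (a) apply linear clocks to beta matrices with explicit,
reproducible handling of missing probes (reference-mean, cohort-mean,
deterministic kNN), and (b) quantify the bias a restricted probe set
introduces: paired full-vs-reduced deviation summaries, age-stratified
regressions with slope/intercept tests, age-acceleration analyses, and
age-adjusted cross-platform offset regressions.

A synthetic-cohort generator produces beta matrices whose probes track
transformed age linearly plus Gaussian noise, together with clocks that
are *exactly* consistent with the generative model — so every pipeline
stage has an analytic oracle, and no controlled-access data is needed to
validate an analysis plan.

## Worked example

Simulate a 1000-sample cohort (ages uniform on 0–100 y, beta noise
SD 0.01), score it with the full 353-probe clock and with the 336-probe
set remaining after platform dropout (dropped probes imputed from
reference means), and summarise the bias:

```python
import methclock as mc

scen = mc.horvath_like_scenario(seed=1, n_samples=1000)
betas, annotation = mc.generate_cohort(scen.spec)
full, reduced = mc.emulate_platforms(betas, scen.dropped_probes)

policy = mc.ImputationPolicy(method="reference_mean",
                             reference_means=scen.reference_means)
res_full = mc.apply_clock(scen.clock, full)
res_red = mc.apply_clock(scen.clock, reduced, policy)

report = mc.paired_deviation_summary(res_full, res_red, annotation)
print(f"mean deviation {report.deviation_mean:.2f} y "
      f"(SD {report.deviation_sd:.2f})")
print(f"correlation full vs reduced: {report.corr_full_reduced:.4f}")

ages_full = mc.results_to_frame(res_full)["dnam_age"]
ages_red = mc.results_to_frame(res_red)["dnam_age"]
fits_full = mc.stratified_clock_regression(ages_full, annotation.ages)
fits_red = mc.stratified_clock_regression(ages_red, annotation.ages)
for stratum in ("below", "above"):
    t, p = mc.compare_slopes(fits_full[stratum], fits_red[stratum])
    print(f"{stratum} cutoff: full slope {fits_full[stratum].slope:.3f}, "
          f"reduced slope {fits_red[stratum].slope:.3f}, "
          f"slope-equality p = {p:.3g}")
shift = fits_full["above"].intercept - fits_red["above"].intercept
print(f"adult intercept shift: {shift:.2f} y")
```

Output:

```
mean deviation 3.10 y (SD 1.36)
correlation full vs reduced: 0.9990
below cutoff: full slope 0.994, reduced slope 0.848, slope-equality p = 2.43e-45
above cutoff: full slope 1.000, reduced slope 1.001, slope-equality p = 0.791
adult intercept shift: 3.50 y
```

Read: restricting the clock to the surviving probes underestimates
DNAm age by ~3 y on average while leaving the ranking essentially intact
(r = 0.999).  Below the transform's 20-y knee the reduced clock's slope
against chronological age is significantly shallower (0.85 vs 0.99);
above it the slopes are indistinguishable and the bias appears purely as
a ~3.5-y intercept shift — exactly the failure mode that matters when
absolute DNAm ages are compared across array generations, and the reason
age-adjusted residuals (age acceleration) travel across platforms better
than raw DNAm ages.

## Command line

The same stages are exposed as a CLI; every run echoes a
`run_config.yaml` for exact re-runs:

```sh
methclock simulate --seed 7 --out-dir sim/
methclock compute-age --clock sim/clock.csv --betas sim/betas.csv \
    --imputation none --out-dir full/
methclock mask --betas sim/betas.csv --drop-list sim/dropped_probes.txt \
    --out reduced_betas.csv
methclock compute-age --clock sim/clock.csv --betas reduced_betas.csv \
    --imputation reference_mean --reference-means sim/reference_means.csv \
    --out-dir reduced/
methclock compare --full full/dnam_age.csv --reduced reduced/dnam_age.csv \
    --annotation sim/annotation.csv --out-dir compare/
methclock diff-manifest --clock my_clock.csv --manifest epic_probes.txt
```

Clock coefficient tables are user-supplied data (`probe_id,weight` CSV
with an `(Intercept)` row; published supplement layouts are recognised).
The package bundles only the probe *ID lists* missing from the EPIC
manifest (`methclock.load_epic_missing_probes("horvath"|"hannum")`).

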