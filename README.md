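# netflex

Whole-brain network indices from parcellated resting-state fMRI signals —
static **modularity** and sliding-window **flexibility** — plus a
**moderation analysis** testing whether a baseline network index conditions
group differences in cognitive change. Built for studies that ask not just
*does an intervention change cognition* but *for whom*: the motivating use
case is a two-arm music-intervention trial in older adults where the
cognitive benefit appeared only among participants with high baseline
network flexibility.

## What it computes

Starting from a region × volume signal matrix (by default 84 Brodmann-area
parcels × 216 volumes):

1. **Functional network** — Pearson correlation between all region pairs,
   then retention of the strongest *K* links (default *K* = 400, i.e.
   400/3486 = 11.5% density on 84 nodes). The result is binary and
   undirected; fixing the link count keeps density comparable across
   subjects.
2. **Modularity** — Newman's divisive spectral algorithm recursively bisects
   the network along the leading eigenvector of the modularity matrix
   *B<sub>ij</sub>* = *A<sub>ij</sub>* − *k<sub>i</sub>k<sub>j</sub>*/2*m*,
   with Kernighan–Lin refinement, accepting splits only while

   &nbsp;&nbsp;*Q* = Σ<sub>c</sub> (*e<sub>cc</sub>* − *a<sub>c</sub>*²)

   increases. The number and composition of modules is data-driven.
3. **Flexibility** — the same network construction and module detection is
   applied to a 40-volume window slid one volume at a time (176 snapshots
   for a 216-volume run). Modules are matched across consecutive windows by
   maximum node overlap (exact assignment, deterministic tie rules), and a
   region's flexibility is its rate of module-membership change per window
   transition; the subject's overall flexibility is the mean over regions.
   Both are in [0, 1].
4. **Moderation analysis** — residualized-change regression

   &nbsp;&nbsp;`followup ~ baseline + group + index + group:index [+ covariates]`

   with simple effects probed through estimated marginal means at −1 SD /
   mean / +1 SD of the moderator, plus assumption diagnostics
   (Shapiro–Wilk, Breusch–Pagan, VIF).

A synthetic-data module generates (a) signals with planted, optionally
time-varying modular structure (shared-factor model with an analytic map
from factor loading to within-module correlation) and (b) cohorts with a
planted group × flexibility interaction, so every stage has a
ground-truth recovery test.

## Worked example

```python
import netflex as nf

# a subject whose regions reorganize mid-run: 10 of 84 regions switch
# modules at volume 109
schedule = nf.PlantedModuleSchedule(
    seed=1, within_module_corr=0.9,
    switch_events=[(109, r, 2) for r in range(10)],
)
ts = nf.generate_timeseries(schedule, subject_id="sub-01")
cfg = nf.PipelineConfig(k_links=840, window_step=16)
print(nf.subject_indices(ts, cfg))
```

```
{'subject': 'sub-01', 'modularity_q': 0.6758475056689341,
 'flexibility': 0.011904761904761904, 'n_windows': 11,
 'k_links': 840, 'window_length': 40}
```

`modularity_q` ≈ 0.68 reflects the four planted modules; the non-zero
flexibility (≈ 0.012) is exactly the planted reorganization: 10 of 84
regions change module once across 10 window transitions
(10/84 × 1/10 ≈ 0.0119). A no-switch schedule gives flexibility 0. (Here
`k_links=840` matches the planted design's 840 within-module pairs and
`window_step=16` subsamples the run; the study-scale defaults are
`k_links=400`, step 1.)

```python
table = nf.generate_cohort(nf.CohortSpec(seed=1))   # 52 subjects: 25 music, 27 control
fit = nf.fit_moderation(table, index_name="flexibility")
print(fit.coef_table().round(3))
print(nf.simple_effects(fit, table).table.round(3))
```

```
             term  estimate    se  ci_low  ci_high     p
        intercept    10.821 1.556   7.690   13.951 0.000
    mmse_baseline     0.682 0.057   0.568    0.796 0.000
            group    -4.331 1.026  -6.396   -2.266 0.000
      flexibility   -10.535 4.925 -20.444   -0.627 0.038
group:flexibility    24.400 6.774  10.774   38.027 0.001

level  moderator  emm_control  emm_music  contrast    se      t  df     p      d
-1 SD      0.105       28.455     26.677    -1.778 0.391 -4.542  47 0.000 -1.811
 mean      0.146       28.021     27.249    -0.772 0.273 -2.830  47 0.007 -0.786
+1 SD      0.187       27.586     27.821     0.234 0.389  0.602  47 0.550  0.239
```

The fitted coefficients recover the generator's planted values within
sampling error (n = 52, residual df = 47), and the group contrast at
moderator value *m* is exactly β<sub>group</sub> + β<sub>interaction</sub>·*m*:
with these planted coefficients it rises from −1.78 at low flexibility to
+0.23 at high flexibility. Cohen's *d* is the contrast divided by the
fit's residual RMSE.

## Command line

```bash
netflex simulate timeseries --seed 1 -o sub01.tsv
netflex indices --timeseries-dir data/ -o indices.csv --k-links 400 --window-length 40
netflex moderation --cohort cohort.csv --index flexibility --covariates age,sex,education -o results/
```

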