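# radarcyto

Star-coordinate ("radar") flow-cytometry analysis of pediatric B-cell
precursor acute lymphoblastic leukemia (BCP-ALL) bone marrow.

Multicolor flow cytometry is the first diagnostic step in childhood
ALL and the workhorse of minimal-residual-disease (MRD) monitoring
during induction therapy. Conventional analysis reads one pair of
markers at a time on bivariate dot-plots, which demands experience —
leukemic blasts closely resemble normal regenerating B-cell precursors
(hematogones). A radar (star-coordinate) plot instead shows **all**
markers of a tube at once: each marker is an axis at angle θ_j with
weight w_j, and an event with scaled intensities s_ij lands at

    x_i = Σ_j w_j s_ij cos θ_j ,   y_i = Σ_j w_j s_ij sin θ_j .

If axis angles and lengths are optimized so normal and pathological B
cells separate, blasts are identified purely by *position*, six (tube 1)
and four (tube 2) predilection positions link to recurrent cytogenetic
subgroups (high hyperdiploidy, t(12;21)/ETV6-RUNX1, "B-other"), and a
PCA-based automatic-population-separator (APS) view splits seemingly
homogeneous blast populations into subclones — more frequent in the
B-other group. `radarcyto` implements this whole protocol as a tested
pipeline: FCS/CSV event I/O, pre-gating and sample QC, layout
optimization, position gating, subclone counting, MRD quantification
and the statistics battery (Shapiro–Wilk-routed paired tests,
Spearman's correlation, chi-square association, two-proportion
z-tests). Because patient data of this kind are confidential, a
first-class synthetic-data module generates bone-marrow samples and
cohorts with the planted structure the analysis assumes, so every stage
is verifiable end to end.

Intended users: cytometry bioinformaticians and method developers who
want a reproducible, scriptable reference implementation of
multidimensional gating analysis — not a clinical device.

## Worked example

```python
from radarcyto.synthetic_data import SyntheticSpec, generate_bm_sample
from radarcyto import gating, mrd_stats, aps, pipeline

# Day-15 follow-up marrow with 0.4% residual blasts
m = generate_bm_sample(SyntheticSpec(
    n_events=50_000, blast_fraction=0.004, timepoint="day15",
    subtype="hyperdiploid", seed=7, position=3))
singlets = gating.gate_singlets(m)
nucleated = gating.gate_nucleated(m, parent=singlets)
qc = gating.qc_check(m)
print("QC passed:", qc.passed, "| syto+ events:", qc.syto_positive_count)

thr = pipeline.MRD_GATE_THRESHOLD
blasts = nucleated.mask & (m.get("CD19") > thr) & (m.get("CD10") > thr)
res = mrd_stats.quantify_blasts(blasts, nucleated.mask, "day15")
print(f"blast %: {res.blast_pct:.3f}  category: {res.category}")

# diagnosis marrow of a two-subclone B-other case
diag = generate_bm_sample(SyntheticSpec(
    n_events=20_000, blast_fraction=0.7, subtype="B_other", seed=7,
    n_subclones=2))
blast_events = diag.subset(pipeline.blast_mask(diag))
proj = aps.aps_project(blast_events)
call = aps.count_clusters(proj, seed=0)
print("APS call:", call.call, "| clusters:", call.n_clusters)
```

This prints:

```
QC passed: True | syto+ events: 49988
blast %: 0.392  category: FMR
APS call: heterogeneous | clusters: 2
```

Reading the output: the sample passes acquisition QC (≥ 30,000
syto-positive events, adequate erythroid precursors); the LAIP gate
recovers 0.392% blasts against the 0.4% planted, which falls in the
intermediate flow-MRD risk category (FMR, 0.1–<10%); and the APS
projection correctly splits the two planted subclones of the
diagnosis sample.

A command-line surface wraps the same pipelines:

```bash
radarcyto simulate --n-events 50000 --blast-fraction 0.6 sample.csv
radarcyto mrd --timepoint day15 sample.csv
radarcyto aps sample.csv
radarcyto optimize-layout --seed 0 layout.yaml
radarcyto report --seed 0 --out-dir report/
```

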