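# batglut

Comparative analytics linking bat diet to body condition, blood-glucose
handling, and the evolution of the *SLC2A2* (Glut2) proximal promoter.

Frugivorous bats eat sugar-rich food yet keep blood glucose under
control; insectivorous bats are small and spike high under a glucose
load. This package reimplements, as a tested and reusable pipeline, the
analyses used to compare these dietary groups:

- **Morphometrics** — body mass index (BMI = mass kg / body length m²)
  and the bat-specific forearm mass index (FMI = mass kg / forearm
  length m²), per-diet group summaries, small-body filters, one-way
  ANOVA with Tamhane T2 post hoc tests (pairwise Welch *t* with Šidák
  adjustment), and Pearson regressions of index against blood glucose.
- **Glucometrics** — intraperitoneal glucose tolerance test (IPGTT)
  analytics: dose volume at 2 g glucose/kg (100 mg/ml), total
  trapezoidal AUC in h·mmol/L, percent excess between cohorts, and
  per-timepoint Levene + Student's *t* comparisons.
- **Promoter evolution** — column-conservation profiling of a grouped
  promoter alignment, discovery of group-shared deletions, bases
  homologous to human diabetes SNPs (rs5393/rs5394), Tajima's relative
  rate test (χ² = (m₁−m₂)²/(m₁+m₂), df 1), and a neighbor-joining tree
  (p or K2P distances) as a quick phylogeny surrogate.
- **Motif scanning** — JASPAR-style PFM → log-odds PWM conversion and
  window scanning with the relative profile score
  (raw − min)/(max − min), plus inference of binding sites lost or
  truncated by a deletion (e.g. the ZNF354C repressor site removed by
  an 11-bp fruit-bat deletion).
- **Expression (qPCR)** — Livak 2^−ΔΔCt relative quantification,
  rescaled so the lowest-expressing species is 1.
- **Synthetic data** — seeded generators for every input above, with
  defaults calibrated to the study conditions, so the whole pipeline is
  testable without any downloads.

## Worked example

```python
import batglut as bg

# IPGTT: two synthetic cohorts, nine fruit bats vs six insect bats
specs = bg.default_ipgtt_specs(seed=1)
fruit = bg.gen_ipgtt_cohort(specs["Rousettus leschenaultii"])
insect = bg.gen_ipgtt_cohort(specs["Hipposideros armiger"])
auc_f = bg.cohort_auc(fruit).value    # 24.81 h*mmol/L
auc_i = bg.cohort_auc(insect).value   # 38.25 h*mmol/L
print(bg.percent_excess(auc_f, auc_i))  # 54.2

# promoter alignment: conservation and the shared 11-bp deletion
aln = bg.gen_promoter_alignment(bg.default_promoter_spec(seed=1))
profile = bg.conservation_profile(aln, ["NWFB", "OWFB", "NONFRUG"])
print(profile.universal_count)          # 75 universally conserved columns
print(profile.levels)                   # {'NWFB': 71.3, 'OWFB': 76.0, 'NONFRUG': 59.3}
(event,) = bg.find_shared_indels(aln, ("NWFB", "OWFB"))
print(event.start, event.length)        # 227 11
```

The insect-eating cohort's glucose AUC is ~54% larger than the
fruit-eating cohort's (the generator is calibrated to cohorts whose
noiseless AUCs are 24.9 and 38.0, i.e. a 52.6% excess); the fruit-bat
promoter groups are more conserved than the non-frugivorous group, and
both fruit-bat groups share an 11-bp deletion starting at alignment
column 227 that removes the embedded repressor-site word.

A `batglut` command-line tool exposes the same operations
(`batglut simulate|morpho|ipgtt|promoter|scan|qpcr --help`).

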