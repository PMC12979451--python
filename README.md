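# richclubkit

Rich-club analysis of weighted structural brain connectomes, built for
case-control studies that stratify by an exposure — the motivating design is
major depressive disorder (MDD) versus healthy controls (HC), each split by
childhood-maltreatment exposure (CM / nCM) from Childhood Trauma
Questionnaire (CTQ) cut-offs, giving four groups analyzed over an AAL-90
parcellation.

The pipeline starts from subject-level symmetric streamline-count matrices
(tractography and registration are upstream and out of scope) and covers:

- **edge thresholding** — connections with fewer than 3 streamlines are
  treated as absent (inclusive boundary);
- **rich-club coefficient** — for each degree level *k*, nodes with degree
  < *k* are removed and Φ(*k*) = *E*/( *S*(*S*−1)/2 ) is the edge density
  among the *S* survivors; the curve runs from the minimum to the maximum
  degree;
- **normalization** — Φ_norm(*k*) = Φ(*k*) / ⟨Φ_random(*k*)⟩ over
  degree-preserving random networks (Maslov–Sneppen edge swaps, 1000 nulls
  by default); Φ_norm > 1 across a range of *k* indicates rich-club
  organization;
- **hubs and edge classes** — the top 12% of nodes by degree on a
  60%-prevalence group-averaged network are rich-club regions; every edge is
  then *rich* (hub–hub), *feeder* (hub–nonhub) or *local* (nonhub–nonhub),
  summarized per subject by class connectivity **strength** (sum of edge
  weights) and **density** (class strength / whole-network strength);
- **inference** — label-permutation tests (10,000 permutations by default)
  on all pairwise group contrasts with Benjamini–Hochberg FDR, and partial
  correlations between class metrics and clinical scores (CTQ, HAMD, HAMA)
  with age, sex and education regressed out;
- **summary-statistics reconstruction** — one-way ANOVA, Tukey HSD, pooled
  two-sample *t* and Pearson χ² recomputed from printed group summaries
  (mean, SD, n), for checking a cohort-description table without raw data;
- **synthetic cohorts** — a generator that plants a rich-club topology,
  group effects on edge classes, and CTQ–feeder couplings of opposite sign
  in patients and controls, so the whole pipeline is testable without any
  imaging data.

## Worked example

Reconstructing the published four-group cohort table from its printed
summaries (built into `richclubkit.reference`):

```sh
$ richclubkit table1
 variable                    test  statistic            p
      sex                    chi2   7.019153 7.128980e-02
      age                 anova_F   0.866912 4.588241e-01
education                 anova_F   0.874580 4.548300e-01
     HAMD                       t   2.420090 1.692097e-02
     HAMA                       t   2.379620 1.880683e-02
      CTQ                 anova_F 110.571010 1.795280e-45
      CTQ tukey:MDD-CM-vs-MDD-nCM  18.270000 3.441691e-14
...
```

The sex χ² (7.019), the CTQ ANOVA F (110.57) and the HAMD/HAMA *t*
statistics (2.42, 2.38) match the published values to printed rounding;
Tukey rows give the pairwise mean differences and adjusted p values.

Running the full pipeline on a synthetic cohort at the published group
sizes (84/46/32/90 subjects, 90 nodes):

```python
from richclubkit.synthetic import SimulationConfig, generate_cohort
from richclubkit.pipeline import RunConfig, run_analysis

mats, pheno = generate_cohort(SimulationConfig(master_seed=7))
bundle = run_analysis(mats, pheno, RunConfig(n_random=100, n_perm=2000, seed=1))
```

prints (via the result tables):

```text
common rich-club regions: 11
max phi_norm: 2.013
rich-club strength MDD-CM vs MDD-nCM: diff=-352.6, p_fdr=0.0007
CTQ ~ feeder density (MDD): r=0.905
CTQ ~ feeder density (HC):  r=-0.927
```

i.e. all four groups share the same 11 rich-club regions (round(0.12 × 90)),
the group-averaged networks show rich-club organization (Φ_norm well above
1), the planted rich-club strength deficit in maltreated patients is
detected with the correct sign after FDR, and the CTQ–feeder-density partial
correlation is positive in patients and negative in controls, as planted.

The same run is available from the shell: `richclubkit simulate` writes
matrices + manifest + phenotypes, `richclubkit analyze` consumes them and
writes TSV result tables plus a JSON run manifest; `richclub` and `stats`
expose the two halves separately.

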