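# kincare

Pedigree kinship, brood allelic values, and mixed-model analysis of
parental care under extra-pair paternity.

## The problem

In socially monogamous birds with extra-pair paternity (EPP), a male may
rear offspring he did not sire. Classical treatments assume his relatedness
to each nestling is either ½ (his offspring, no inbreeding) or 0 (someone
else's). In small, kin-structured populations that dichotomy breaks down:
a cuckolded male can still be related to an extra-pair offspring through
its mother (his social mate, kinship k_ij) or its genetic sire (k_iq), and
parents related to their mates or inbred themselves are related to their
own offspring by more than ½. Inclusive fitness theory then predicts that
parental care should track these graded relatedness values, not just brood
size or paternity share.

`kincare` implements that analysis end to end for anyone studying
parental care in pedigreed populations:

- **pedigree** — exact kinship k(i,j) and inbreeding f from a pedigree
  table, via the standard recursion, with a Monte Carlo gene-dropping
  estimator as an independent cross-check;
- **allelic_value** — per-offspring relatedness
  (r_iWPO = ½ + k_ij + ½f_i, r_iEPO = k_ij + k_iq,
  r_jEPO = ½ + k_jq + ½f_j) and the brood statistics
  TAV (total allelic value: the expected number of copies of a focal
  parental allele in the brood), PAV = BS·r_iWPO (potential value had the
  male sired everything), LAV = PAV − TAV_i (value lost to EPP), P_EPO, and
  TAV_z (TAV standardized within brood-size class);
- **synthetic** — a generator emulating a small island songbird study
  (138 nests, 79:30:29 monogamous/primary/secondary-polygynous split, 28%
  per-offspring EPP, kin-biased mating producing realistic k and f);
- **models** — Gaussian linear mixed models of feeding rate (feeds/hour)
  with crossed individual/mate/nest random intercepts, fitted by ML, and
  compared by AICc (support = focal model undercuts the null by ≥ 2 units);
- **pipeline / CLI** — config-driven end-to-end run, simulated or ingested.

See `docs/methods.md` for the model, conventions and limitations.

## Worked example

Simulate a study-sized dataset, compute brood metrics, and compare the
male/female feeding-rate models TAV, BS and k_ij against the null:

```
kincare --mode simulate --seed 11 --out demo --suite TAV,BS,kij
```

`demo/comparison_male.csv`:

```
label,n_obs,n_params,loglik,aicc,delta_aicc,supported
null,329,13,-727.464,1482.084,0.000,False
TAV,329,14,-722.447,1474.232,-7.852,True
BS,329,14,-726.954,1483.245,1.161,False
kij,329,15,-720.946,1473.425,-8.659,True
```

Read: with this seed the male TAV model undercuts the null by 7.9 AICc
units (supported) while brood size alone does not (ΔAICc = +1.2) — male
care tracks relatedness-weighted brood value rather than brood size, and
pair kinship adds further support (−8.7), exactly the signature the
generator's default effect sizes (TAV slope 0.9 feeds/hour per
allelic-value unit, k_ij slope 5.0 for males) should produce.
`demo/brood_metrics.csv` holds the per-brood table (BS, N_WPO, P_EPO,
TAV_i, TAV_j, PAV, LAV, k_ij, f_i, f_j, TAV_z), e.g. its first brood:

```
nest_id=N0000  BS=4  P_EPO=0.25  TAV_i=1.978  TAV_j=2.291  PAV=2.224  LAV=0.246
```

a brood of four with one extra-pair nestling, where the male nevertheless
keeps 89% of the brood's potential allelic value because the pair are kin
(k_ij = 0.035) and he is related to the cuckolder.

To analyse your own data, provide three delimited files and run ingest
mode (`kincare --mode ingest --pedigree ped.csv --broods broods.csv
--sessions sessions.csv --out report`): a pedigree (`id,sire,dam,sex[,cohort]`,
missing parents coded `0`), a parentage table (one row per offspring:
`nest_id,social_male,social_female,status,offspring_id,genetic_sire,lay_date`)
and a session table (`nest_id,nestling_age,lay_date,time_of_day,male_rate,
female_rate,status`). A tiny fully hand-checked example lives in
`tests/data/toy/`.

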