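# kincensus

Census population size estimation for harvested terrestrial mammals from
genetically identified parent–offspring pairs (POPs), evaluated by
individual-based pedigree simulation.

Hunting bags are an attractive sampling frame: every harvested animal can be
genotyped, and kin pairs found among the carcasses act as "recaptures"
without any physical marking. But the classic kin-based estimators assume a
sample of one parental and one offspring generation, while the bag of a
long-lived species mixes many cohorts — the same animal can be somebody's
parent and somebody's offspring. `kincensus` quantifies what that does to
the four POP-based census-size estimators:

| method | pair information used | estimates |
|---|---|---|
| CKMR (naive close-kin mark-recapture) | all POPs, adult–adult included | adult population size |
| g-CMR | all POPs + demographic age classes | total population size |
| Moment | mother–daughter pairs among females | breeding-female count |
| CRE (Creel–Rosenblatt) | sampled breeders + pedigree-inferred unsampled parents | adult population size |

The package has four parts:

- **`kincensus.demography`** — an annual-cycle, individual-based pedigree
  simulator with overlapping generations: seasonal mating (polygynous males;
  monandrous or multiply-mating females), Normal litter sizes, age-class
  mortalities, density-dependent adult mortality, and a carrying-capacity
  ceiling. Presets for red deer (*Cervus elaphus*) and wild boar
  (*Sus scrofa*) parameterized from the ungulate literature.
- **`kincensus.sampling`** — uniform "hunting-bag" samples of the standing
  population and exact POP detection (perfect kin assignment).
- **`kincensus.estimators`** — the four estimators above, written over
  ordered kin comparisons (each pair counts once per direction) so that
  individuals with dual parent/offspring roles are handled symmetrically.
- **`kincensus.evaluation`** — the experiment grids: species benchmark,
  fecundity sweep (means 1–14), fecundity-SD sweep (0/2/4), sampling
  intensities 10–90%, with relative-bias (N̂/N) and CV% summaries.

## Worked example

```python
import kincensus as kc

params = kc.make_species_params("wild_boar")
ped = kc.simulate(params, n_years=200, seed=1)      # full multi-generation pedigree
print(kc.truth_sizes(ped))
# TruthSizes(n_total=500, n_adult=180, n_breeding_females=140)

sample = kc.draw_sample(ped, fraction=0.3, seed=7)  # 150 of 500 animals
pops = kc.find_pops(sample, ped)
counts = kc.kin_counts(sample, pops, ped)
print(counts.h_total, counts.h_mother, counts.h_father)
# 39 19 20

for est in kc.estimate_all(sample, ped):
    print(f"{est.method:7s} -> {est.n_hat:6.1f}  (target: {est.target})")
# CKMR    ->  135.0  (target: adult)
# gCMR    ->  411.5  (target: total)
# Moment  ->  147.3  (target: breeding_females)
# CRE     ->  124.0  (target: adult)
```

With 39 POPs among 150 sampled boar, the naive CKMR Lincoln–Petersen puts
the adult population at 135 against a truth of 180 (relative bias 0.75 for
this draw); g-CMR inflates its age-class estimate to a total of ~412 vs 500;
the Moment estimator puts the 140 breeding females at 147, and CRE counts
124 of the adults it can see or infer. Averaged over replicate populations and
resamples (`run_species_comparison`), these single-draw numbers become the
systematic pattern: the Lincoln–Petersen methods underestimate (mildly for
the fecund boar, by roughly half for red deer, whose multi-cohort bags are
saturated with adult–adult pairs), the Moment estimator overestimates, and
CRE underestimates at 30% sampling but is by far the most precise.

The same pipeline is scriptable:

```
kincensus simulate --species red_deer --seed 1 --out ped.tsv
kincensus estimate --pedigree ped.tsv --fraction 0.3 --resamples 100 --out est.csv
kincensus experiment --kind comparison --out results/
kincensus summarize --records results/records.csv --out results/ --bin-pops 10
```

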