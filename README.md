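# indelred

Detect **redundant indel annotations** — distinct database records that
produce the identical mutated sequence when applied to a reference genome —
and model the distributions of indel sizes and adjacent-variant distances.

## The problem

When an insertion or deletion sits inside a tandem repeat, shifting the
annotated position by one repeat unit leaves the mutated sequence unchanged:
inserting `CA` before position 2 of `GCACACAG` and inserting `CA` before
position 4 both yield `GCACACACAG`. Equally optimal alignments therefore
report the "same" variant at different coordinates, and variant databases
accumulate multiple records for a single underlying mutation. Such
redundancy inflates variant counts and can mislead downstream association
analyses. `indelred` finds these records in three phases:

1. **Candidate grouping** — indels are partitioned by (chromosome, type,
   length) and chained into candidate groups whenever adjacent positions
   differ by at most a threshold *D* (default 100 bp); only indels of the
   same type and length can possibly be redundant.
2. **Template-substring comparison** — for an ordered candidate pair A, B
   with positions *P_A ≤ P_B*, allele length *L*:
   - insertions: template = reference[*P_A* .. *P_B* − 1]; compare
     `allele_A + template` with `template + allele_B`;
   - deletions: template = reference[*P_A* .. *P_B* + *L* − 1]; compare the
     template minus its first *L* bases with the template minus its last
     *L* bases.

   Equality of the two variant substrings is *exactly* equivalent to
   equality of the full mutated chromosomes (a brute-force oracle verifies
   this on every randomized test pair).
3. **Clustering and rates** — redundant pairs are merged by union–find into
   equivalence clusters; each cluster of size *m* contributes *m* − 1
   redundant indels, and rates are reported overall and per type.

For the statistical side, indel sizes are fitted with a Pareto distribution
with location fixed at 1 (shape MLE `n / Σ ln x`), and distances between
adjacent variants with Gamma, exponential, and Weibull distributions — the
Gamma being the inter-arrival law of a Gamma count (renewal) process that
reduces to a Poisson process at shape 1.

## Worked example

Generate a synthetic 250 kb chromosome with planted repeat tracts and 300
indel annotations of which 20% are redundant copies, then run the check:

```sh
indelred simulate --seed 7 --out-dir demo
indelred check --indels demo/indels.tsv --reference demo/reference.fa --out-dir demo
```

prints

```
max_distance    100
total_indels    300
redundant_total 60
redundancy_rate_total   20.00
total_ins       144
redundant_ins   26
redundancy_rate_ins     18.06
total_del       156
redundant_del   34
redundancy_rate_del     21.79
n_clusters      48
```

The pipeline recovered all 60 planted redundant annotations (the planted
rate was 20%), grouped into 48 equivalence clusters; `demo/truth.json`
holds the planted partition for comparison. A threshold sweep
(`indelred sweep ...`) reports one summary row per *D* in {1, 5, 10, 100};
for this instance the redundant count rises from 40 at *D* = 1 to 60 at
*D* = 5 and stays flat beyond — redundant annotations of the same mutation
tend to be close together.

Distribution fits work on plain number-per-line files:

```sh
indelred fit --sizes sizes.txt --family pareto
indelred fit --positions positions.txt --family gamma --family exponential
```

and print the fitted parameters, sample size and log-likelihood as JSON
(side-by-side log-likelihoods when several families are requested).

The same functionality is available as a library: `indelred.simulate`,
`indelred.cluster_candidates`, `indelred.find_clusters`,
`indelred.summarize`, `indelred.fit_pareto`, `indelred.fit_gamma`, etc.

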