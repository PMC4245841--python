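# Methods

## Redundancy model

Two indel annotations are *redundant* when applying either to the
reference yields the identical chromosome sequence. This is string
equality, not biological identity: the package makes no attempt to decide
which of several equivalent annotations reflects the "true" mutational
event, because no experiment can distinguish them — the resulting sequence
is the same.

### Coordinates and conventions

Positions are 1-based and inclusive everywhere. A deletion's position is
its first deleted base; an insertion's allele is inserted immediately
*before* the base at its position. The insertion convention is not
arbitrary: it is the unique choice under which the local
template-substring comparison below is exactly equivalent to comparing
full mutated chromosomes, and the randomized oracle-equivalence property
test fails under any other convention. `N` is treated as a literal fifth
character (N matches N only); ambiguity-aware matching would make
"equality" non-transitive and break the clustering.

### The decision procedure

Only same-type, same-length indels can be redundant, and equivalent
annotations of one mutation are necessarily close (they differ by shifts
within a repeat tract), so the all-pairs comparison is restricted to
*candidate groups*: per (chromosome, type, length), records sorted by
position are chained while adjacent positions differ by at most
`max_distance` D. The comparison is `<= D`, so co-positioned duplicates
group at any D ≥ 0, and the trailing chain is flushed like any other.
Partitioning *before* chaining means the chain distance is measured
between indels that could actually be redundant; chaining a mixed list
would only merge groups through members that can never match.

Within a group, each ordered pair (A before B, length L) is tested on a
template substring:

* INS: template = ref[P_A .. P_B − 1]; V_A = allele_A + template,
  V_B = template + allele_B. When P_A = P_B the template is empty and the
  test reduces to allele equality.
* DEL: template = ref[P_A .. P_B + L − 1]; V_A drops the template's first
  L characters, V_B its last L.

V_A = V_B iff the two full mutated chromosomes are equal: outside the
template window both mutations leave the sequence untouched, so the local
comparison loses nothing. `apply_indel` constructs the full mutated
chromosome and serves as the independent oracle in tests; it is never on
the production path.

Because full-sequence equality is transitive, redundant pairs are merged
by union–find into genuine equivalence clusters. Each cluster's
representative is its leftmost member (ties broken by id) — a
deterministic choice matching the left-normalised convention — and a
cluster of size m contributes m − 1 redundant indels. Pairs spanning two
candidate groups are never tested: residual redundancy between indels
farther apart than D is a known, deliberately accepted blind spot of the
distance cutoff.

Deletion records whose allele does not occur at their annotated position
cannot represent a deletion of the reference; they are flagged to a
rejects file and excluded before grouping, never silently dropped.
Insertions are not checked against the reference since an inserted allele
need not occur there. Raw alignment-type codes (loctype 1/3) are resolved
as 1 → deletion, 3 → insertion relative to the reference, with an audit
operation that counts allele presence per loctype; range types (4, 6) are
rejected as out of scope.

## Distribution models

All samples are positive integers (base pairs) modelled with continuous
densities and no discretisation correction — this reproduces the
conventional estimators for these data. Zero distances (co-located
records) carry no density mass and are dropped by default; an option
retains them shifted by +0.5.

* **Pareto (sizes)** — location fixed at 1 because the smallest indel is
  one base. Shape MLE is the closed form α̂ = n / Σ ln x, degenerate when
  every size is 1. A test checks the closed form against direct numerical
  likelihood maximisation.
* **Gamma (distances)** — profile equation ln α − ψ(α) = ln x̄ − mean(ln x),
  Newton iteration from the moment-style start α₀ = 0.5 / (ln x̄ − mean ln x)
  with halving/doubling fallback when a step leaves (0, ∞); convergence at
  |Δ ln α| < 1e−10 or 200 iterations. The rate is β̂ = α̂ / x̄, so the
  fitted mean equals the sample mean exactly. At shape 1 the Gamma count
  process reduces to a Poisson process; fits on exponential data recover
  shape 1, a nesting the tests exploit.
* **Exponential** — λ̂ = 1 / x̄.
* **Weibull (distances)** — scale eliminated analytically
  (scale^k = mean(x^k)); the remaining monotone profile equation in the
  shape is solved by bracketed root finding (bracket doubled until it
  straddles the root, xtol 1e−10, 200 iterations). Weights x^k are
  computed in log-space to avoid overflow on heavy-tailed samples.

Gamma fits are cross-checked against an independent fitting routine
(`scipy.stats.gamma.fit` / `weibull_min.fit` with the location pinned) in
the test suite; the estimators themselves are self-contained. The
mean/variance ratio helper compares two Gamma fits via
(α_i/β_i)/(α_s/β_s) and (α_i/β_i²)/(α_s/β_s²); with genome-wide average
parameters (0.4, 8.09×10⁻⁴) for indel distances and (0.86, 0.017) for SNP
distances this gives a mean ratio of 9.77 and a variance ratio of 205.38 —
adjacent indels are roughly ten times sparser and far more over-dispersed
than adjacent SNPs.

## Synthetic data

The generator is the package's ground-truth instrument, not a fixture. It
emulates the mechanism that creates redundancy in real catalogues:

* a uniform-random ACGT background of 250 kb (desk-scale stand-in for a
  chromosome) with homopolymer (4–12 copies) and di-/tri-nucleotide (4–10
  copies) tandem tracts planted to a target density (default 15%,
  reflecting that indels concentrate in repeat-rich sequence);
* *redundant classes* built by sliding a unit-length indel along a repeat
  tract one period at a time — the generative mirror of equally optimal
  alignments. Every planted class is re-verified with the full-sequence
  oracle before emission, so the truth partition cannot contain a false
  equivalence. Tracts are re-detected by scanning the finished sequence,
  so placement does not depend on private generator state;
* *singleton* indels at Gamma(0.4, 8.09×10⁻⁴)-distributed gaps (mean
  ≈ 494 bp) with Pareto(1.43) sizes rounded up so the minimum is exactly
  1; deletion alleles are copied from the reference and are therefore
  always valid. Defaults are the genome-wide average parameter estimates
  for human indel catalogues. 300 annotations with a planted redundancy
  rate of 0.2 keep the whole pipeline under a second per run.

What the generator does *not* emulate: sequencing or mapping error, read
coverage, imperfect (mutated) repeat copies, and redundancy between indels
farther apart than the cluster spacing. Passing the planted-truth tests
therefore shows the pipeline is exact on its own definition of redundancy,
not that any particular real database has a given redundancy rate.

Because the Gamma gap distribution puts substantial mass at 1–3 bp, two
singletons occasionally land inside the same chance short repeat and are
*genuinely* equivalent although planted as distinct. The recovery tests
treat these strictly: every recovered cluster must be internally
equivalent under the full-sequence oracle, planted classes must never be
split, and the redundant count must decompose exactly into planted plus
oracle-verified accidental merges.

## Numerical and design choices

* Determinism: every entry point that uses randomness takes a seed; two
  runs with the same seed produce byte-identical outputs.
* Sorting tie-breaks are lexicographic on id at equal position, making
  grouping, cluster ids and representatives order-independent.
* Variant-substring equality is exact character comparison after
  uppercasing; no mismatch tolerance.
* Degenerate inputs fail loudly: all-ones Pareto samples, zero-variance
  distance samples, out-of-bounds template windows, deletion alleles
  absent from the reference.
* CLI exit codes: 0 success, 2 input validation, 3 computation error.

## Known limitations

* Redundancy beyond the distance cutoff D is not searched (quadratic cost);
  the sweep command quantifies the effect of D on one dataset.
* The VCF adapter handles anchored simple indels only; complex and
  symbolic records are counted as skipped, not converted.
* Database flat-file formats are out of scope; the canonical TSV carries
  exactly the five fields the pipeline needs (id, chrom, pos, type,
  allele).
* The Gamma count process is used only as the distance model; no renewal
  simulation is provided.
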