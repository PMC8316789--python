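# Methods

## Data model

A haplotype table has one row per male sample with columns `SampleID`,
`Population`, and one column per marker of a panel. Alleles are repeat
counts; microvariants (e.g. `17.2`: 17 repeats plus 2 bases) are stored
exactly as integer tenths, so equality, ordering and hashing never touch
floating point. The fractional part must be .0/.1/.2/.3, following STR
nomenclature. Multi-copy markers (DYS527a/b, DYS385a/b, DYF387S1 in the
AGCU37 panel) hold an unordered allele combination, canonicalized by
sorting; two haplotypes are equal iff every canonical genotype matches.
Missing data is an empty cell or `NA`. `-` is accepted as an alternate
multi-copy separator on input (both conventions occur in forensic data
exchange); `,` is canonical on output, so write∘read is the identity on
canonical tables.

Panel membership is configuration, not code: the three shipped YAML panels
follow the kits' documented marker lists, and a "locus count" (17/27/37)
counts each copy of a multi-copy marker. Users whose local convention
differs can edit or supply their own YAML.

Samples with a missing panel marker are excluded from that panel's
haplotype-level statistics — direct counting requires complete profiles —
and the exclusion count is carried in the summary (`n_excluded`).
`validate_dataset` only reports problems (missing markers, unexpected copy
numbers, implausible repeat counts outside 1–99); it never drops or edits
samples, so any exclusion policy is explicit and auditable.

## Forensic parameters

All frequencies come from direct counting. Gene diversity and haplotype
diversity use Nei's unbiased estimator `n(1 − Σp²)/(n − 1)`; match
probability is `Σp²` over *haplotype* frequencies (its per-locus analogue
is exposed separately as `locus_match_probability`, equal to
`1 − GD·(n−1)/n`); discrimination capacity is distinct haplotypes over n.
MP at the haplotype level is the definition consistent with the identity
`HD = n(1 − MP)/(n − 1)`, which the implementation preserves to machine
precision because both statistics sum squared frequencies over the counts
in the same (sorted) order. Values are kept exact internally; rounding (4
d.p. for HD/MP/DC, optional 5 d.p. MP and percent DC) happens only in
reporting.

## Rst by AMOVA

The molecular distance between two haplotypes is
`δ² = Σ_markers Σ_copies (r_a − r_b)²` on repeat counts, with multi-copy
markers pairing sorted allele lists copy by copy (rank matching; an
`exclude` mode drops them, since haplotype-database practice varies).
Markers with unequal copy number for a pair, or missing in either sample,
are skipped for that pair (pairwise deletion; an `exclude_sample` mode
drops incomplete samples instead). Microvariants enter at numeric value by
default (17.2 − 17 = 0.2); a truncation mode is provided because the
repeat-step semantics of partial repeats are genuinely ambiguous.

The single-level AMOVA computes, for N samples in P populations of sizes
n_p:

```
SS_total  = (1/(2N)) Σ_ij δ²_ij
SS_within = Σ_p (1/(2 n_p)) Σ_{ij∈p} δ²_ij
SS_among  = SS_total − SS_within
σ²_w = SS_within/(N−P)
σ²_a = (SS_among/(P−1) − σ²_w) / n̄,   n̄ = (N − Σ n_p²/N)/(P−1)
Rst  = σ²_a/(σ²_a + σ²_w)
```

On haploid single-locus data this is algebraically identical to classical
one-way ANOVA on allele values, which is how the tests cross-check it. A
negative σ²_a (sampling noise around zero differentiation) clamps Rst to 0
by default, the floor convention of standard AMOVA reports; `report_raw`
keeps the signed estimate. Zero total variance defines Rst = 0. Rst is
invariant to sample order, to adding a constant to every allele at a
marker, and to scaling all repeat differences (which scales both variance
components by the square of the factor).

Significance uses a label permutation test preserving sample sizes:
`p = (1 + #{Rst* ≥ Rst_obs})/(1 + n_perm)`, with the δ² matrix computed
once and only the group index permuted, seeded for reproducibility. At
least 100 permutations are required; 999 is the sensible default.

No exact numerical agreement with any particular online AMOVA service is
claimed — such tools do not publish their marker inclusion or missing-data
policies — which is why those choices are explicit configuration here.

## Structure summaries

Classical (Torgerson) MDS: double-center −½D², eigendecompose, scale the
top-k eigenvectors by √λ. Only positive eigenvalues are embeddable; asking
for more axes returns fewer with a warning. Metric MDS was chosen over
stress-minimizing variants for determinism and testability. PCA treats
each population's row of the distance matrix as its feature vector,
centers columns and eigendecomposes the covariance; explained fractions
are over the full trace and sum to 1. Both embeddings fix axis signs by
making the largest-magnitude loading positive, so plots reproduce across
runs.

UPGMA merges the closest pair of clusters at height = half their distance,
with size-weighted (arithmetic mean over all cross pairs) distance
updates. Ties break on the lexicographically smallest cluster
representatives and children are ordered by smallest leaf label, making
the tree — and its Newick serialization (branch lengths at 12 significant
digits, labels with special characters quoted) — invariant to input label
order and byte-identical across runs. The output is ultrametric by
construction (to 1e-9), and on an ultrametric input the cophenetic matrix
equals the input exactly. Heatmap ordering permutes the matrix to UPGMA
leaf order so that related populations are contiguous.

## Synthetic data

`simulate_dataset` runs a forward Wright–Fisher simulation of haploid
lineages: every population starts as a copy of one ancestral pool
(monomorphic at the configured ancestral alleles, default 12 repeats, two
offset values for multi-copy markers), evolves independently for the
configured number of generations — each lineage copying a uniformly chosen
parent, each locus copy mutating with rate μ and stepping ±1 repeat with
equal probability, floored at 1 repeat (single-step SMM) — and is then
sampled without replacement. Forward simulation was preferred over a
coalescent for transparency at desk scale (Ne ≤ ~2000, ≤ ~1000
generations, where a replicate takes well under a second). Defaults: Ne =
500 males per population, μ = 2×10⁻³ per locus per generation (a typical
Y-STR order of magnitude), 100 samples per population. All randomness
flows from one integer seed through a PCG64 generator, so outputs are
byte-identical across runs and platforms.

What the simulator emulates: repeat-count variation, multi-copy markers,
divergence-driven between-population variance (expected δ² between
populations grows with separation time, which Rst picks up). What it does
not: founder haplotype diversity (populations start monomorphic, so
simulated DC is far below real surveys at these timescales), microvariant
creation, multi-step mutations, locus-specific mutation rates, migration.
Consequently, passing simulation tests demonstrates that the machinery
recovers known structure, not that real populations behave like the
simulated ones. Because the common ancestor is monomorphic, zero
divergence yields exactly duplicated populations and Rst = 0; with
divergence, clamping negative Rst estimates to 0 induces a small positive
bias near the null, visible in replicate means.

`make_counts_dataset` deterministically builds a dataset whose
haplotype-count multiset matches a requested profile (e.g. 238 singletons
plus 4 doubletons) by encoding a serial number into the first two
single-copy markers, keeping alleles in the realistic 10–99 range; that
caps the construction at 8100 distinct haplotypes, far above forensic
sample sizes. `two_population_fixture` gives two monomorphic populations
offset by a constant at every single-copy marker, for which Rst is 0
(offset 0) or exactly 1 (any positive offset — within-population variance
is zero).

## Numerical and testing choices

Tolerances: sums of squares conserve to 1e-9 relative; the HD–MP identity
holds to 1e-12; MDS reproduces Euclidean-embeddable matrices to 1e-6;
ultrametricity to 1e-9. Independent oracles in the test suite: exhaustive
ordered-pair counting for MP, exact-fraction one-way ANOVA for the AMOVA
components (frozen: SS_among = 50/3, SS_within = 4/3, Rst = 49/52 for
alleles 10,10,11 vs 13,14,14), scipy average-linkage cophenetic matrices
for UPGMA, and dendropy parsing for Newick round-trips. Simulation-based
checks use 50 seeded replicates per divergence time (0/200/800
generations) with 100 samples per population — sizes chosen so a full
validation run completes in well under a minute on one core while keeping
Monte Carlo error on mean Rst below ~0.005.

## Limitations

Single-level AMOVA only (no region/group hierarchy), no Fst/Φst
alternatives, no neighbour-joining or bootstrap support, no nonmetric MDS,
no haplotype-frequency estimators beyond direct counting (no kappa or
discrete Laplace), and no reading of chromatogram or genotyper exports —
input starts at called allele tables.
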