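# Methods

This note documents the models, algorithms, parameter choices and known
limitations behind `bryoparent`. Empirical claims below are the ones the
test suite and `scripts/acceptance.py` themselves compute.

## System and assumptions

The package targets mating experiments in dioicous mosses. Parents are
haploid gametophytes, so each contributes exactly one haplotype per locus
and a sporophyte's pooled spore DNA carries exactly two haplotypes per
amplicon. Everything downstream leans on that biology:

- phasing is a **two**-group problem, with a guard against a third group;
- parentage is set intersection over diagnostic alleles, not a likelihood
  model — a parent either carries the observed alleles or is excluded;
- a mother and father are of opposite sex, so a chaining of per-locus
  haplotypes that names the same individual on both sides is impossible
  and is discarded outright.

Indels, PCR chimeras, paired-read overlap merging and reference-genome
(rather than per-amplicon) alignment are out of scope; the simulator emits
none of these, and the aligner is substitution-only.

## Synthetic mesocosm generator

The generator is first-class, tested code: it defines the conditions under
which the inference is validated.

**Panel.** `simulate_panel` draws, per locus, a uniform-random reference
sequence and `snps_per_locus` diagnostic positions (kept ≥ 10 bp from the
amplicon ends); each parent receives a distinct multi-locus binary allele
vector over the `n_loci × snps_per_locus` biallelic sites. Capacity is
checked (`2^k` vectors for `k` sites) and exceeding it raises. With
`force_ambiguous_female_pair` the last two females share one vector,
creating a true ambiguity class — the merged-maternity mechanism. Defaults
mirror the experimental design: 6 males, 9 females, 5 loci of 300 bp with
3 SNPs each.

**Crosses.** Two treatment arms × 8 mesocosms. Sporophyte counts are either
a fixed total split multinomially across mesocosms (weights ∝ the
`treatment_effect` multiplier, default 839/228 ≈ 3.68) or per-mesocosm
Poisson rates scaled by the same multiplier. Mothers are drawn ∝ female
fertility weights; fathers ∝ male weights, with an optional distinct weight
set for the arthropod arm so the treatment can reorder male fitness.
Fertilization distance is drawn from the father's kernel — lognormal with
μ = 2.3, σ = 0.4 log-cm by default (median ≈ 10 cm) — truncated by
rejection sampling to the annulus between the male disc edge (5.25 cm, a
10.5 cm disc) and the pot wall (18 cm); a guard raises if the annulus
captures too little kernel mass instead of looping. Angles are uniform.

**Reads.** Amplicon sequencing reads start at the primer sites, so each
fragment yields an R1 anchored at the locus start and (in paired mode, the
default) a reverse-complemented R2 anchored at the locus end — giving flat
coverage rather than a random-tiling lottery. Each fragment derives from
the maternal or paternal haplotype with probability 0.5 (a `parent_skew`
knob exists because germination bias is plausible). Substitution errors are
i.i.d. per base (default 0.5%), uniform over the three alternative bases.
Qualities decay linearly from Q38 to Q32 with Gaussian jitter σ = 3,
clamped to [2, 40] — enough texture to exercise the Q30 trimming rule
without destroying most reads; errors are simulated independently of the
emitted qualities (a simplification: real miscalls concentrate at low-Q
cycles). Dual 8 bp indexes come from pools with pairwise Hamming distance
≥ 3, so the one-mismatch demultiplexing rule is collision-free; index bases
get their own error rate (default 0.1%). A sidecar table records every
fragment's source parent, making read-level truth available to tests.

What the generator does **not** emulate: chimeric amplicons, index
hopping between samples, contamination between pools, coverage dropout from
primer-site variants, and quality-correlated errors. Passing tests
therefore show the inference machinery is correct under its stated model,
not that the laboratory protocol is robust to those artefacts.

## Preprocessing

**Demultiplexing** assigns a read to a sample iff *both* index distances
are ≤ `max_mismatch` (default 1). The sheet is rejected when any sample
pair is within `2·max_mismatch` on *both* indexes — the condition under
which a read could satisfy two samples — which permits combinatorial dual
indexing (shared i5 pools). Malformed index lengths are logged and sent to
`undetermined`; read counts are conserved by construction.

**Trimming** slides a `window` (10 bp) in 1 bp steps 5'→3' and cuts at the
first base of the first window whose mean quality is below `min_mean_q`
(30); reads shorter than `min_len` (50 bp, chosen to avoid near-zero-length
alignments) are dropped. Reads shorter than one window are kept intact.
Only this 3' cut is performed — no leading-window trim — keeping locus
coordinates monotone. The operation is idempotent and is tested against
brute-force enumeration of every window mean.

## Genotyping

**Alignment** seeds each read by exact 21-mer lookup against both strands
of every amplicon and verifies candidates by mismatch count over the fully
contained placement; reads with no seed fall back to an exhaustive
all-offset scan. A read is kept iff best identity ≥ 0.9; ties break by
locus id, then leftmost offset, then forward strand. With 0.5% errors an
error-free 21-mer among ~11 disjoint anchors is effectively guaranteed, so
the fallback is cold.

**Variant sites** are positions with aligned depth ≥ `min_site_depth` (10)
where ≥ 2 bases each reach `min_minor_frac` (0.2) of the depth. More than
two qualifying alleles flags the site `multiallelic`; such sites are
reported but excluded from phasing. At depth 200 and 1% error the binomial
tail probability of an erroneous base reaching the 20% floor is below
10⁻⁶ per position.

**Phasing** works on *fragments*: aligned reads sharing a read id (mate
pairs) derive from one template molecule and hence one parent, and pooling
their coverage is what links diagnostic sites that no single read spans.
Groups are seeded from the two alleles of a site and fragments are
iteratively reassigned to the group whose consensus allele vector they
agree with at the majority of covered sites (ties → unassigned). The
iteration restarts from every usable site, highest depth first, and keeps
the restart with the least within-group disagreement (deterministic
tie-break on seed order) — on pools of ≤ 12 fragments × ≤ 3 sites this
partition attains the exhaustive minimum-disagreement bipartition cost
(verified against enumeration over all 2^(n−1) bipartitions). When more
than `cluster_warn_frac` (30%) of site-covering fragments agree with
neither consensus at more than half their sites, a `PhasingError` is raised
rather than silently merging a third haplotype. With zero usable sites the
pool is homogeneous and all reads go to one group; the other haplotype is
all N and the locus abstains downstream.

**Consensus** per group and position: the majority base when the group's
read depth is ≥ `min_depth`, else `N`. The boundary follows the rule that
depth *strictly below* 25 marks insufficient data: depth 24 masks, depth 25
calls. Ties break to the lexicographically smallest base and are logged
(at realistic depths they arise only from errors and are measure-zero).
Site-blind fragments (covering no variant site) are split between groups in
proportion to group support: they contribute sequencing depth everywhere
and votes at invariant positions, but never votes at variant sites, so the
depth gate keeps meaning "sequencing support" without letting unphaseable
reads influence diagnostic alleles. Bases are counted unweighted by quality
(whether the original pileup weighted them is unknowable; a quality floor
can be applied upstream at trimming instead).

## Parentage

**Per-locus matching.** Distance between a consensus haplotype and a panel
parent counts mismatches over positions where both are non-N, restricted to
the locus's diagnostic positions plus any other position where the two
differ — so foreign haplotypes are penalised for private variants that
diagnostics would not see. Candidates are the minimal-distance parents with
distance ≤ `max_mismatch` (default 0: diagnostic SNPs are definitional; a
tolerance exists for degraded data). A locus abstains when fewer than
`min(min_overlap, n_diagnostic_positions)` diagnostic positions are
comparable: the cap means a fully observed locus never abstains merely for
carrying few diagnostic sites (with 3 SNPs per locus a flat threshold of 5
could never be met), while N-masked diagnostics still trigger abstention.
The pipeline's study-mimic configuration sets `min_overlap = 3`, equal to
its SNPs per locus.

**Cross-locus bundling.** Pools carry no physical linkage between loci, so
the per-locus a/b labels are chained into two multi-locus bundles by
enumerating all 2^(L−1) orientations and ranking: (1) non-degenerate (the
two bundles must not resolve to the same individual/class — haploid,
opposite-sexed parents cannot both be one plant); (2) more precise
identifications (singleton or ambiguity class); (3) fewer cross-locus
conflicts; (4) the most *specific* consistent reading (smallest total
candidate intersection); (5) no same-sex clash. Orientations tying at the
top with different outcomes yield an `ambiguous` call — never a guess.
This consistency-maximising rule is this package's own definition of the
chaining step, stated so the exhaustive oracle can check it; it is one of
several defensible choices for a step that set-intersection parentage needs
but does not uniquely determine.

**Classification.** Per bundle, candidate sets are intersected over
informative loci: a singleton resolves a parent; an intersection equal to
an ambiguity group resolves the merged class (`class-resolved`, the `F9'`
mechanism — sound because group members are identical at every diagnostic
position, any candidate set containing one member contains all); an empty
intersection is a `conflict`; a sufficient-data locus where *no* parent
matches excludes the whole panel, so the bundle is a foreign `unknown`
parent — reported with a stable anonymous id (U1, U2, …) from an
exact-sequence registry so recurring volunteers can be counted, never
imputed. Errors can therefore demote an assignment to ambiguous or unknown
but cannot redirect it to a wrong parent, and the acceptance suite asserts
exactly that (zero wrong-parent resolutions across 20 × 100 simulated
sporophytes, with ≥ 99% resolved).

## Statistics

- **Genotype success:** Pearson χ² against uniform success with the
  genotype list taken from the *design*, so a male who sired nothing
  contributes a full expected count (his zero is evidence). df = k − 1.
  Under null simulation the test's type-I error at α = 0.05 sits within
  5% ± 1.5% (2000 replicates).
- **Treatment effect on counts:** Poisson log-linear `count ~ treatment`,
  likelihood-ratio (deviance difference) on 1 df, via statsmodels GLM. A
  quasi-Poisson flag rescales by the Pearson dispersion and refers the
  statistic to F(1, n−2) — counts of biological colonies are routinely
  overdispersed, and the plain Poisson LR is then anticonservative. At
  rates 10 vs 50 with 8 + 8 mesocosms, power exceeds 99%.
- **Dispersal goodness-of-fit:** one-sample KS with parameters ML-fitted
  from the same sample. The KS distance to a fitted lognormal equals that
  of the log-data to a fitted normal, so both families share one path.
  Estimating parameters makes the classical asymptotic p conservative
  (rejection well under 5% at the null); the parametric-bootstrap p — valid
  because the statistic is location-scale pivotal, so standard-normal
  resamples suffice — is calibrated to 3–7% rejection at α = 0.05. Extras
  carry the bias-corrected excess kurtosis (leptokurtosis being the
  classical dispersal-kernel signature).
- **ANOVA:** fixed-effects OLS with Type II sums of squares (factor tests
  do not depend on factor order under the unbalanced designs these
  experiments produce, and no interactions are fitted). Aliased factors
  raise with a clear message; a constant response returns F = 0 exactly
  rather than 0/0 noise. Merged maternal classes are treated as single
  factor levels.

No multiple-testing correction is applied; raw p-values are reported.

## Pipeline and reproducibility

`RunConfig` holds every knob (panel, design, sequencing, thresholds) and
round-trips through TOML. One root seed fans out to per-stage child streams
via `numpy.random.SeedSequence`, so stages are individually rerunnable and
a rerun with the same config is byte-identical (the manifest records sha256
of every artifact; outputs carry no timestamps). All tabular artifacts are
TSV; FASTA/FASTQ via Biopython; optional SAM/VCF exports are minimal plain
text. A failing stage aborts with the stage name in the error.

Problem sizes used by the test suite and acceptance script — e.g. 20 × 100
sporophytes for recovery, 2000 null replicates for χ² calibration, 1000
(test) / 500 (script) replicates with 199 bootstrap resamples for KS,
300–500 power simulations — were chosen as the smallest sizes at which the
binomial noise of each estimated rate is comfortably inside the asserted
band.

## Known limitations

- Set-intersection parentage is exact but brittle to systematic consensus
  errors: one wrong called base at a diagnostic site (vanishingly rare at
  the default depth gate) excludes the true parent and demotes the
  sporophyte to unknown rather than resolving it.
- The bundling rank is a heuristic over an under-determined step; genuinely
  adversarial panels (extensive profile sharing across sexes) increase
  `ambiguous` calls, though never wrong-parent calls.
- The contamination guard detects a *large* third read group; low-level
  contamination below the minor-allele floor is absorbed silently.
- The quality model's independence of the error process means trimming is
  exercised syntactically, not as an error-reduction step.
- Paired mates are linked only through shared read ids; if upstream tools
  rename mates, phasing degenerates gracefully to per-read units (sites
  separated by more than a read length then become unlinkable, and affected
  loci abstain or lose one haplotype to N).
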