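# Methods

## Scope and data model

The package analyses binary site × species incidence tables on nested
spatial sampling designs. The two core containers are `IncidenceMatrix`
(validated 0/1 table; duplicate labels rejected; a species must occur at
≥1 site; sites with zero species are accepted but flagged) and
`SiteHierarchy` (ordered levels, lowest first; nesting must be consistent:
a unit belongs to exactly one parent). Sites and species keep
first-appearance order throughout, which makes every downstream artifact
reproducible from the input alone. Species labels are matched exactly after
trimming surrounding whitespace — no fuzzy taxon matching, because silent
merges corrupt richness counts.

Empty sites are a deliberate edge: 0/0 dissimilarities are undefined, so
every β computation refuses empty sites unless `drop_empty=True` is passed,
in which case they are removed and the site count reported reflects that.

## Sørensen-family decomposition

Pairwise, from the shared/exclusive counts (a, b, c):
β_sor = (b+c)/(2a+b+c), β_sim = min(b,c)/(a+min(b,c)), β_sne = β_sor −
β_sim. When b = c = 0 with a > 0 (identical sites) all three are exactly 0.
The multiple-site forms use Σmin = Σ_{i<j} min(b_ij, b_ji), Σmax the
analogous maximum, and K = Σ_i S_i − S_T:
β_SIM = Σmin/(Σmin+K), β_SOR = (Σmin+Σmax)/(2K+Σmin+Σmax), β_SNE = β_SOR −
β_SIM. Both are computed from one integer Gram matrix (X·Xᵀ), so the values
are exact up to float division; the identity β_SOR = β_SIM + β_SNE holds to
1e−12 and is asserted in tests. The implementation is cross-checked against
an independent set-based brute force and against vegan's
`nestedbetasor`/`betadiver` through Rscript.

Multiple-site dissimilarity grows with the number of sites, so sets of
different sizes are compared by resampling (`beta_sample`): `n_reps`
subsets of `subset_size` sites drawn without replacement, independently per
replicate, from a named `numpy` Generator seeded explicitly; the seed is
embedded in every output artifact. Distribution comparisons report
P(X > Y) over all cross pairs with ties counted 0.5 (so identical
distributions give exactly 0.5), the central 95% intervals, and an
interval-overlap flag — several summaries rather than one verdict, since
no single test is canonical for resampling distributions that share draws.

Headline β components are reported **two ways** — the full-matrix
multiple-site value and the mean of the resampling distribution. Published
single numbers of this kind are often ambiguous between the two
provenances, and they differ systematically (the resample mean sits below
the full-set value), so both are always computed and labelled.

## Additive partitioning

For levels l = 1…K (plot, mountain, range): α_l is the mean richness of the
level-l units, a unit's richness being that of the union of its member
plots; β_l = α_{l+1} − α_l, with the top β = γ − α_top. The identity
α₁ + Σβ_l = γ is exact in species units (unions and means of integers), and
percentages of γ sum to 100.

Significance uses **sample-based randomization**: at each level transition,
child units are permuted among parent units with unit sizes fixed
(plots shuffle among mountains, mountains among ranges), and the partition
is recomputed. This is the standard null for presence/absence plot data
with no abundance information; an individual-based null is out of scope.
Each plot keeps its species list under every permutation, so α₁ has a
degenerate null (expectation = observed, p = 1) — asserted in tests as a
structural property. The default is 999 permutations plus the observed
value. The two-tailed Monte-Carlo p-value with add-one correction is
p = min(1, 2(1+k)/(n_null+1)), where k counts null values at least as
extreme as the observed one in the direction of its deviation from the
null mean; the minimum attainable value is 2/(n_null+1). Components whose
null cannot move (single parent unit) report p = 1 with a warning.

## Local–regional regression

One point per regional unit (default: mountain): x = the unit's pooled
richness, y = the mean richness of its member plots. Using unit means keeps
the regional units as the independent replicates (no pseudoreplication);
`n_points` always equals the number of units and the F test of the slope
has df (1, n−2). Perfect fits (SS_res ≈ 0) report R² = 1, F = ∞, p = 0;
zero variance in x raises a `DegenerateFitError` rather than returning a
meaningless slope. The plot output draws the local = regional diagonal for
visual reference only — it is never fitted.

## UPGMA clustering

Unweighted average linkage, hand-implemented rather than delegated, for two
reasons: node heights and labelled subtree merges are needed for Newick
export, and ties in the minimum distance must break deterministically — by
lexicographic order of the clusters' smallest member labels — so the same
matrix yields the same tree on every platform. Cluster-to-cluster distance
is maintained as the size-weighted mean of member distances (equivalent to
the arithmetic mean over all cross pairs); node height is half the merge
distance, making the tree ultrametric by construction. Agreement with
scipy's average linkage is verified on tie-free random matrices, and with
an exhaustive re-averaging brute force on small ones. Newick labels
containing structural characters are single-quoted.

## Synthetic metacommunity generator

The generator reproduces the survey geometry the analysis assumes —
2 ranges holding (7, 4) mountains, 10 plots per mountain on a
within-mountain gradient, 100 individuals censused per plot — and mixes
the two mechanisms that create β-diversity:

* **Turnover fraction w** of the species pool lies on a 1-D gradient. Each
  mountain occupies a contiguous block of it; mountains of a range are
  adjacent, and block overlap shrinks as w grows (at w = 1 blocks tile the
  gradient nearly disjointly), so the pool fraction shared between
  mountains is controlled implicitly by w. Within a mountain the block is
  tiled into equal windows of `plots_per_window` (default 2) consecutive
  plots, so adjacent windows replace species completely.
* **Nested fraction 1 − w** is ranked once; a plot at gradient position t
  holds exactly ranks 1…k_t with capacity declining linearly along the
  gradient — species-poor plots are strict subsets of species-rich ones,
  and the ranking is global, so nestedness operates across mountains too.

Realized incidence passes a sampling filter: the plot's census individuals
are drawn multinomially from a geometric-series (Motomura) relative
abundance over the locally available species (shape 0.25; a single
parameter creating realistic rarity and sampling-induced absences, which is
why it was preferred to a log-series). Turnover and nested species are
interleaved evenly in the local abundance ranking so both mechanisms span
the rarity spectrum. Each plant species carries Poisson(λ = 0.7) strictly
monophagous gall morphotypes (the morphotype-on-host operational species
concept), each recorded with probability 0.8 per plot given host presence.

Defaults were fixed once to emulate a realistic survey of this design:
pool 600, w = 0.9, shape 0.25, λ = 0.7, detection 0.8 give ≈ 13–14 plant
species per plot, ≈ 270–300 realized plant and ≈ 180 gall species, α ≈ 5%
of γ, and a turnover-dominated β ≈ 95% — the magnitudes such surveys
report. What the generator does **not** emulate: environmental covariates,
spatially autocorrelated detection, polyphagous gallers, and between-
mountain richness differences — mountains are statistically exchangeable,
so the local–regional regression has no built-in signal on synthetic data
(R² near 0 is the expected outcome there); the regression module is
validated on constructed designs with known closed-form fits instead.
Passing tests on synthetic data therefore demonstrate correctness of the
estimators and the recoverability of the turnover/nestedness mixture, not
field realism.

`exhaustive=True` switches off the sampling filter and detection noise,
making the limiting cases exact and assertable: at w = 1 all plots have
equal richness, every pairwise (b, c) balances and β_SNE = 0 for plants
(gall richness still varies by Poisson load, so the gall share only
approaches 1); at w = 0 plots form strict nested chains and β_SIM = 0.
`recovery_curve` sweeps w and reports the mean ± sd turnover share
β_SIM/β_SOR across replicate seeds — monotone non-decreasing in w, with
exact endpoints in exhaustive mode. Under the sampling filter the curve is
compressed toward high shares (≈ 0.95 even at w = 0): random non-detection
creates pseudo-turnover, a known artifact of incidence sampling, which the
exhaustive mode isolates.

## Pipeline, determinism, problem sizes

`run_full_analysis` applies every stage per community and per site set (all
plots, then each range separately by subsetting the hierarchy and rerunning
identical code paths). All randomness flows from one master seed, split per
(community, scope, stage) by SHA-256 hashing — order-independent, below
2³¹ — and the summary JSON is written with sorted keys and floats rounded
at 10 decimals, so a rerun with identical configuration is byte-identical;
`log.txt` records package/library versions, seeds, and SHA-256 input
checksums. Stage preconditions that a given input cannot meet (e.g. a
range with fewer than 3 mountains for the regression) are recorded as
skipped with a reason; genuine failures are recorded per stage without
aborting independent stages.

Default problem sizes — 110 plots, 1000 resamples of 10 plots, 999
partition permutations — run the full pipeline in a few seconds; the test
suite uses reduced replicate counts (30–200) where only determinism or an
identity is at stake, and the full sizes where a distributional claim is.

## Known limitations

* Presence/absence only: no abundance-weighted (Shannon/Simpson-number or
  Bray–Curtis) partitions, by design.
* Only the Sørensen family is implemented (no Jaccard-family analogues).
* The sample-based null is the only partition null; conclusions about
  "higher/lower than expected" depend on that choice.
* UPGMA is the only linkage; no bootstrap support on trees.
* The workbook reader requires the caller to map columns; it makes no
  attempt to guess the layout of arbitrary spreadsheets.
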