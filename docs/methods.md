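# Methods

`microbenet` analyses two-group (case vs control) gut microbiome taxon
tables and links the resulting signed microbe signature of a disease to
other diseases through a microbe-based similarity network. This note
records the models, the defaults and why they were chosen, the numerical
conventions, and the limits of what the synthetic benchmarks demonstrate.

## Community model and synthetic data

Counts are modelled as Dirichlet-multinomial. Each group g has an expected
composition p_g; a sample from group g draws

    theta ~ Dirichlet(phi * p_g),    counts ~ Multinomial(N, theta),

where phi (`dispersion`, default 200) is the total Dirichlet concentration
controlling between-sample overdispersion (phi → ∞ recovers a plain
multinomial; phi ≈ 200 gives the 10–100% coefficients of variation typical
of 16S gut profiles at moderate abundance). Library sizes N are lognormal
(mean 50 000 reads, log-scale sigma 0.5), rounded and floored at 1000 so
no sample is empty — typical amplicon depths after quality filtering.

Effects are planted multiplicatively: the case composition is the control
baseline with per-taxon fold changes applied, then renormalised. For a
single perturbed taxon with baseline p and fold f the case proportion has
the closed form f·p / (1 + (f−1)·p), which unit tests use as an oracle.
Every taxon with a fold entry appears exactly once in the ground-truth
table with direction sign(f − 1).

All randomness flows from a single scenario seed through a
`SeedSequence` split deterministically per sample, so identical seeds give
byte-identical tables.

### The default 35-vs-6 scenario

The default scenario emulates an unbalanced autism-spectrum (ASD) vs
typically-developing cohort: 35 cases, 6 controls, 24 genus-level taxa
with full Greengenes-style lineages. The control baseline is a
Bacteroidetes ≈ 0.30 / Firmicutes ≈ 0.60 gut; the case group receives a
4× enrichment of the Bacteroidetes genera (Bacteroides, Prevotella,
Parabacteroides) — which raises the per-sample Bacteroidetes/Firmicutes
ratio — and a 4× depletion of eight genera (Streptococcus, Veillonella,
Escherichia, Clostridiaceae_unclass, Actinomyces, Parvimonas, Bulleidia,
Peptoniphilus). Genus baselines are plausible paediatric-gut magnitudes;
the rarest planted genera are deliberately kept in the fraction-of-a-
percent range because taxa much below ~10⁻³ relative abundance are not
resolvable at realistic sequencing depth, and planting undetectable
effects would make recovery benchmarks vacuous. These numbers are an
*emulation* of a study design, not an estimate of any real cohort.

A further trio of case-group increases (Sutterella, Odoribacter,
Butyricimonas) — genera often described as enriched in ASD guts without a
clear significance level — is available behind
`include_reported_increases=True` and excluded from the default truth
table. `null=True` removes all planted effects for calibration studies.

What the generator does **not** emulate: read-level noise (chimeras, PCR
bias), phylogenetic structure (so no UniFrac/DPCoA), covariates (age,
diet), or zero-inflation beyond what the Dirichlet-multinomial induces.
Passing benchmarks therefore demonstrate the statistical machinery is
correct and calibrated under this model, not that any real cohort will
show these effect sizes.

### Association lists

`simulate_associations` emulates a curated microbe–disease association
database: each (disease, microbe) cell is associated independently with
probability `density`, with a uniform ±1 direction. Planted disease pairs
share exactly `n_shared` microbes of which a fraction `consistency` agree
in sign, giving network-recovery tests a known answer (expected similarity
sign = sign(2·consistency − 1)).

## Differential abundance

Testing is per taxon on **relative abundances** (rank-based, so the
normalisation affects only tie structure), after collapsing the table to
one taxonomic rank. Taxa unresolved at that rank pool into
`<deepest named ancestor>_unclass` buckets (e.g. `Bacteria_unclass`,
`Clostridiaceae_unclass`), which conserves per-sample mass exactly.

The two-sided Wilcoxon rank-sum test is exact whenever
C(n1+n2, n1) ≤ 2·10⁵: the rank-sum statistic (midranks for ties) is
enumerated over all group assignments and the p-value is twice the smaller
tail, capped at 1 (a |W − E[W]|-deviation variant is available via
`two_sided="deviation"`). Larger designs — including the default 35 vs 6,
where C(41, 6) ≈ 4.5·10⁶ — use the normal approximation with
tie-corrected variance and continuity correction; this path agrees with
`scipy.stats.mannwhitneyu(method="asymptotic")` to 9 digits in tests.

Benjamini–Hochberg adjustment is applied within each rank, over the taxa
actually tested (configurable family size `m` for larger families).
Before testing, taxa detected in fewer than `prevalence_min` (default
10%) of samples are dropped: an (almost) all-zero taxon yields a fully
tied, uninformative test and only dilutes the FDR correction. The
degenerate fully tied case returns p = 1.

Taxa with q < alpha and unequal group means form the disease's *signed
profile* (+1 enriched in cases, −1 depleted).

## Diversity

* Shannon entropy, base 2 by default, after renormalising the profile.
  No rarefaction by default; the comparison is on proportions.
* Bray–Curtis dissimilarity via `scipy.spatial.distance.pdist`.
* PCoA is Gower's classical scaling: eigendecomposition of the doubly
  centred −D²/2. Negative eigenvalues (non-Euclidean input) are reported
  unaltered and their axes dropped — no Lingoes/Cailliez correction, to
  keep the spectrum interpretable. Proportions of variance are over the
  positive part of the spectrum.
* Group separation uses the two-group PERMANOVA pseudo-F
  (among- vs within-group sums of squared dissimilarities) with label
  permutations at fixed group sizes and add-one smoothing,
  p = (1 + #{F_perm ≥ F_obs}) / (1 + n_perm), so p is never 0 and the
  minimum attainable p is 1/(n_perm+1). The statistic matches
  scikit-bio's `permanova` to 10 digits in tests. Note that for very
  small groups a permutation can reproduce the observed bipartition and
  tie the statistic, so the minimum p is only attained when group sizes
  make that improbable.

## Functional groups

Genera map to four SCFA-related guilds: butyrate producers
(Fusobacterium, Eubacterium, Anaerostipes, Subdoligranulum,
Faecalibacterium, Roseburia), lactate producers (Lactobacillus,
Bifidobacterium, Streptococcus, Lactococcus), mucin degraders (Prevotella,
Akkermansia), and an *other SCFA* guild that ships empty: no canonical
genus list exists for it, so membership is user-supplied rather than
invented. Guild abundance is the per-sample sum of member genera
(computed per sample, then averaged per group — the only order compatible
with a rank-based group test), matched by exact genus label.

## Disease network

Each disease's associations condense to a signed profile by majority vote
(exact ties drop the microbe with a warning). Microbe names are
normalised — rank prefix stripped, lowercased, genus token of a binomial —
so `g__Veillonella` and `Veillonella parvula` share a key.

Similarity is a signed cosine over {−1, 0, +1} microbe vectors:

    S(a,b) = Σ_{m ∈ Ma∩Mb} sign_a(m)·sign_b(m) / sqrt(|Ma|·|Mb|).

It is symmetric, bounded in [−1, 1], +1/−1 for perfectly
consistent/reversed profiles and 0 for disjoint ones. This is a
reimplementation choice: it is the simplest score with those semantics,
not a formula lifted from any one database paper.

Significance is a support-preserving permutation: each profile's microbe
set is redrawn uniformly from a microbe *universe* with its size and sign
counts preserved, and the two-sided p compares |S|. The universe matters:
it should be the catalogue of microbes that *could* have been recorded.
The default — the union of all profile supports — is the only universe
derivable from the input alone and is conservative (it overstates null
overlap when the true catalogue is larger); pass the full catalogue when
it is known. The permutation p-value is discrete; with sparse profiles it
is markedly conservative, which is inherent to the statistic, not a bug.

An edge enters the network when the pair shares ≥ `min_shared` microbes
(default 1), the score is nonzero, and p < alpha (default 0.05,
uncorrected; BH across pairs behind `adjust="bh"`). Edges are labelled
positive/negative by score sign. Neighbor rankings sort by |score| with
sign retained. Pair-level permutation seeds derive from one root seed via
`SeedSequence.spawn`, and each p-value is computed symmetrically in the
pair, so the network is order-independent and reproducible.

## Pipeline

`run_pipeline` chains simulate (or load) → differential abundance →
diversity → functional groups → profile extraction → network, writing
plain-text outputs plus a `manifest.json` with package/library versions,
the full configuration, and SHA-256 digests of every output. The manifest
contains no timestamps, so a repeated run with the same configuration is
byte-identical — that is the reproducibility contract the tests enforce.

## Benchmark problem sizes

The test suite and `scripts/acceptance.py` use: 1000 random datasets for
the exact-test and BH oracles; 1000 exchangeable 6-vs-6 communities
(n_perm = 199) for permutation-test calibration; 20 seeds of the default
35-vs-6 scenario for recovery and the B/F-ratio contrast, and 50
effect-free seeds for the empirical FDR; 50 seeds of the association
scenarios (n_perm = 999) for network recovery and null edge rate. These
sizes give binomial standard errors comfortably inside the asserted
bands while keeping a full run to a few seconds per block.

## Known limitations

* Compositional effects: planting strong fold changes shifts *all*
  renormalised proportions, so taxa with fold 1 can show genuine (not
  false-positive) secondary shifts; recovery is scored only on planted
  taxa, and FDR control is asserted only under the global null.
* No compositional-aware testing (CLR/ALDEx-style), no covariate
  adjustment, no paired designs.
* No phylogeny: UniFrac and DPCoA are out of scope.
* The disease network depends on the curation quality and coverage of the
  input association list; the package ships no database contents.
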