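# Methods

`mirsite` predicts miRNA binding sites on mRNAs from the statistical
signatures that Argonaute CLIP experiments reveal: candidate sites are found
by duplex energy minimization, described by sequence / thermodynamic /
structural-accessibility / conservation features, contrasted between
AGO-crosslinked (IP+) and background (IP−) sites by binned odds ratios, and
classified by a nonlinear logistic ensemble trained on balanced subsamples.
This note records the models, the parameters that matter, and the design
choices made where more than one reasonable option existed.

## Candidate site discovery

Sites are the union of two searches, deduplicated afterwards:

* **Threshold mode.** One intermolecular dynamic program per
  (miRNA, transcript) finds, at every target start position, the
  minimum-free-energy monotone duplex; non-overlapping local optima with
  `dG_hybrid ≤ −15 kcal/mol` (configurable) become candidate sites. This
  captures seedless sites, including centered-type sites, with no seed
  requirement.
* **Seed-forced mode.** For each span (miRNA nt 2–7, 2–8, 3–8) every exact
  Watson–Crick seed-complement match on the transcript anchors a
  constrained duplex in which the span must pair contiguously; no energy
  threshold is applied. This guarantees recovery of every offset-6mer,
  6mer, 7mer-A1, 7mer-m8 and 8mer site even with negligible 3′ pairing.

The threshold search runs once over the whole transcript rather than in
overlapping fixed windows; the emitted site set is the same (local optima),
an order of magnitude faster.

**Energy model.** A bundled plain-text nearest-neighbor table
(`data/nn_params.tsv`): Watson–Crick/Watson–Crick stacking free energies are
the published Turner 2004 values at 37 °C; wobble-containing stacks carry
Turner-style magnitudes. Duplex energy = initiation (+4.09) + stacks +
linear loop penalties (1.8 kcal/mol per bulged nucleotide, 1.1 per
internal-loop nucleotide, ≤15 nt per side). Dangling ends and terminal
mismatches are omitted. Absolute energies therefore approximate, but do not
bit-match, other hybridization programs; the −15 kcal/mol threshold is a
configurable default, not a universal constant.

**Seed taxonomy.** 8mer = contiguous WC pairing of nt 2–8 plus an A in the
target opposite nt 1 (the A is read from the sequence whether or not nt 1
pairs); 7mer-m8 = WC 2–8 without the A; 7mer-A1 = WC 2–7, the A, and nt 8
unpaired or non-WC; 6mer = WC 2–7 only; offset-6mer = WC 3–8 only. A G:U
pair anywhere in the claimed span disqualifies that span. Overlapping sites
of one miRNA are reduced to a single survivor per overlap cluster by the
hierarchy 8mer > 7mer-m8 > 7mer-A1 > 6mer > offset-6mer > seedless, ties
broken by lower `dG_hybrid`.

## Target structure and accessibility

Each site is folded in a local window (default 200 nt, centered; windows at
transcript edges are shifted, not shrunk). The ensemble model is a
simplified stacking model: structures are non-crossing WC/GU pair sets with
a minimum hairpin loop of 3 nt; every pair carries a constant
loop/entropy surcharge (+1.1 kcal/mol) and adjacent pairs gain the same
nearest-neighbor stack energies used for duplexes. For this model the
partition function, base-pair probabilities and per-position
single-strandedness are computed **exactly** by inside/outside recursions —
the exact expectation of what stochastic structure sampling estimates, with
no sampling noise — and the test suite verifies them against exhaustive
structure enumeration to 1e-9. The surcharge-per-pair form was chosen over
loop-type-resolved penalties deliberately: it keeps the configuration space
simple enough that the enumeration oracle and the dynamic program provably
score identical quantities, which is the property the package's guarantees
rest on. RT = 0.6163 kcal/mol (310.15 K). A seeded Boltzmann
sampling mode (`sample_structures`, stochastic traceback with exact
weights) is available for fidelity experiments; the pipeline itself
always uses the exact quantities.

Derived features:

* accessibility of a block = mean single-strandedness over its nucleotides
  (site, seed-complementary block, and 5′/3′ flank blocks of
  5/10/15/20/25/30 nt; flanks truncated at edges, empty blocks missing);
* `dG_disruption` = constrained (site forced single-stranded) minus
  unconstrained ensemble free energy, a non-negative opening cost;
* `dG_total = dG_hybrid + dG_disruption`, the accessibility-aware net
  energy of hybridization — the headline energy feature;
* `dG_nucl` = minimum over 4-pair contiguously stacked duplex blocks of
  (block helix energy − RT·ln mean single-strandedness of the block's
  target nucleotides); no such block, or a best block above zero, means no
  nucleation site (missing). The precise nucleation recipe is not uniquely
  fixed by the literature; block length and the probabilistic opening cost
  are explicit, configurable choices here.

## Sequence and conservation features

Flank AU fraction at the same window sizes as accessibility; site location
= fractional start position within the site's own region (5′UTR, CDS or
3′UTR, chosen by site midpoint), normalized so 0/1 are the region ends —
start-normalization (rather than midpoint) makes both anchors attainable.
Conservation features are plain means of per-nucleotide scores over the
site, the seed-complementary block, and the site minus that block; a block
containing any unscored nucleotide is missing, and a site with missing site
conservation is excluded from conservation-using models. Seed-block
features exist only for seed-typed sites.

## Enrichment analysis

Sites fully contained in a CLIP interval (tag/CCR) are IP+ (the containment
fraction is configurable); the rest are IP−. For every feature, continuous
values are binned (1 kcal/mol for energies, 0.1 for bounded scores) and
each bin's enrichment is the odds ratio
`[p⁺/(1−p⁺)] / [p⁻/(1−p⁻)]` with p the within-set frequency; zero cells
get the Haldane–Anscombe +0.5 correction (flagged). A feature is called
enriched when its bins with OR ≥ 1.2 jointly cover ≥ 10 % of IP+ sites —
an explicit, configurable stand-in for a selection rule the source
protocols leave unstated — and windowed families contribute their
best-window member. Categorical features (seed class, 3′ supplementary
pairing) enter models OR-encoded from training data.

## The logistic ensemble

log-odds(IP+) = α + Σβ᷈ᵢXᵢ + Σγᵢⱼ XᵢXⱼ over the enriched features, with all
pairwise interaction terms by default (correlated features such as AU
content and accessibility motivate the quadratic terms). Covariates are
standardized with training-set constants; fitting is maximum likelihood
(L-BFGS then Newton polishing to gradient norm ≤ 1e-6) with a tiny ridge
(1e-6, never on the intercept) so complete separation stays finite. Because
IP− typically dwarfs IP+, ten members are each fitted on the whole IP+ set
plus a fresh equal-sized IP− subsample (without replacement, seeded); the
ensemble probability is the member average, and a site is called bound when
it reaches the threshold q (default 0.5).

**Evaluation.** ROC (TPR vs FPR over all score thresholds), Youden's
J = TPR − FPR, and precision among the top-ranked fraction. Intra-dataset
validation is stratified 10-fold cross-validation with encoders and
standardization refitted inside each fold; inter-dataset validation trains
on all of one dataset and scores another with no information flowing back.
CV reports carry two max-J numbers: the mean of per-fold maxima (the
protocol average) and the max-J of the pooled out-of-fold predictions. The
pooled statistic is the headline: the per-fold maximum is a one-sided
Kolmogorov–Smirnov-type statistic whose null expectation,
≈ 0.63·√(1/n⁺ + 1/n⁻) per fold, is materially above zero at desk-scale
fold sizes, while the pooled version is unbiased at the null and less
variable.

## Synthetic data

The generator builds the conditions the pipeline is validated under:
100 transcripts (regions 60/1000/2580 nt ± 10 %), 10 random 22-nt miRNAs,
and per transcript 20 "wrapped" plants covered by a CLIP region
(width ~50 nt, jittered) plus 20 decoy plants outside any region; plants
are exact seed-type complements (17 nt with a 3′-supplementary block,
10 nt without) written into slots spaced so neighboring footprints cannot
collide. Effect sizes separate the wrapped and decoy neighborhoods:
AU-elevated vs AU-depleted flanks (±au_shift/2 around 0.5), stem clamps
over the decoy site and upstream flank sized from the ΔG_total and
accessibility shifts, and beta-distributed conservation elevated over
wrapped sites (seed block highest). Per-transcript site density is far
above real transcriptomes; this is deliberate, trading per-transcript
realism for dataset-level class sizes (~2000 per label at 100 transcripts)
comparable to real CLIP site collections while keeping the corpus small.

Two properties are enforced by construction. First, determinism: one seeded
generator drives everything; identical config+seed gives byte-identical
files. Second, an exhaustive truth table: accidental seed-complement
matches and accidental stable duplexes (below −14 kcal/mol) in background
sequence are mutated away — by complement swaps (A↔U, C↔G, preserving
local AU/GC content) in the first passes, escalating to non-pairing bases
for low-complexity tracts where a swap merely reshuffles complementarity.
Planted blocks and clamps are never touched; a stable site overlapping its
own miRNA's plant is recognized as that plant and left intact; and
candidate plant blocks are screened so they contain neither another
miRNA's seed complement nor a stable cross-duplex, since such signal would
sit in protected sequence the scrub may not reach. Without all this,
background hits — covered by CLIP regions at a different rate than
plants — make even the zero-shift configuration non-null by composition
alone. With it, setting all four effect sizes to zero renders the IP+ and
IP− neighborhoods exchangeable, and every downstream statistic (odds
ratios, CV max-J) is verified to sit at its null value. A
`background_per_transcript` knob plants neutral-context, never-wrapped
sites for experiments that want a background universe.

`generate_feature_table` separately emits covariates with a known logistic
law (standard-normal features, chosen α/β/γ) for parameter-recovery and
calibration tests.

What passing on synthetic data does **not** show: real CLIP data carry
crosslink biases, expression-dependent coverage, genome↔transcript mapping
artifacts and miRNA-identity ambiguity that the generator does not emulate;
results here validate the machinery, not transcriptome-scale accuracy.

## Numerical choices and limitations

* Partition-function arithmetic is scaled per nucleotide
  (σ = e^{1.7/RT}) to keep doubles in range for windows up to ~300 nt.
* Ranking ties in top-fraction precision are broken by stable input order
  and logged.
* Pseudoknots, intramolecular pairing during hybrid search,
  co-transcriptional folding and functional (repression-magnitude)
  prediction are out of scope; the model predicts binding only.
* The 10-fold CV sizes used throughout (100-transcript datasets,
  ~4,000 sites) are the package's default study conditions; all of them
  are configuration, not constants.
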