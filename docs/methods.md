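# Methods

## Structure model

A polysaccharide is a rooted tree: residues are nodes, glycosidic linkages
are edges, and the root is the reducing-end residue.  Reading direction is
non-reducing → reducing, so exo-acting glycosidases operate on leaves.
Each residue carries a monosaccharide code, its carbon count (pentose 5,
hexose 6 — drawn as polygon sides in DOT output), its anomeric carbon
(2 for ketoses such as fructose, 1 otherwise; inulin's β-2,1 fructan chain
falls out of this rather than being special-cased), a backbone flag and a
set of ester/ether substituents (acetyl, methyl, feruloyl) each bound to a
distinct free ring carbon.  The validator enforces tree shape
(|E| = |V|−1, connected, acyclic, single root), anomeric consistency of
every linkage, and single occupancy of every ring carbon.

The sixteen packaged structures are finite representative instances
(backbone length 20) generated at fixed seeds: real polymers are orders of
magnitude longer and the schematics they come from depict repeating units,
so a length-20 instance is a unit cell large enough to contain every bond
class while keeping digestion and rendering instant.  Carbon numbers are
plain integers; no stereochemistry or 3-D conformation is modelled.

## Generators

Each generator decorates a backbone according to per-carbon substitution
probabilities.  Where the source substrate is chemically defined the
defaults follow its documentation:

- **sugar-beet arabinan** — 1,5-α-L-arabinan; every main-chain residue is
  branched with probability 0.5 by a single arabinofuranosyl residue, 1,2-
  or 1,3-linked with equal odds, matching the "about 50 % substituted"
  description.  The galactose, rhamnose and galacturonic acid of the
  preparation (target ratios Ara:Gal:Rha:GalA = 88:4:2:6) are modelled as
  a short rhamnogalacturonan-like stub at the reducing end with a small
  galactan side chain; stub counts are stochastically rounded from the
  exact ratio against the realized arabinose count, which makes the pooled
  arabinose fraction unbiased at 88 %.  A feruloyl ester rides on ~5 % of
  main-chain residues (the preparation is ferulic-acid-containing).
- **oat-spelt xylan** — β-1,4 xylan whose C2 carries an arabinosyl (0.10)
  or 4-O-methyl-glucuronosyl (0.10) branch and whose C3 carries an
  arabinosyl branch (0.10) or an acetyl ester (0.15).  Expected xylose
  share ≈ 77 %, inside the "≥70 % xylose" specification.
- Other structures default to their schematic repeating-unit stoichiometry
  (e.g. xyloglucan XXXG: three of four backbone glucoses xylosylated, with
  optional β-1,2 galactosyl and α-1,2 fucosyl extensions; RG-I: strictly
  alternating GalA/Rha with galactosyl/arabinosyl groups on rhamnose).
  Branch-frequency details that exist only in figure artwork (GGM galactose
  rate, AG-II side frequencies) are stated choices in
  `generators._DEFAULT_SUBSTITUTION`, picked to put every expected bond
  class in a length-20 instance with comfortable probability.

Galactoglucomannan backbones never place two glucosyl units adjacently.
Dispersed glucose keeps the cellulosic Glc-β-1,4-Glc bond class out of the
mannan maps, so the required-activity join yields exactly the six-activity
mannanolytic set rather than additionally demanding cellulases — consistent
with how the glucomannan literature assigns these backbones to the
mannanase system.

All randomness flows through `numpy.random.default_rng(seed)`; identical
parameters give byte-identical JSON.  Ensembles derive per-structure seeds
from a `SeedSequence`, so an ensemble is reproducible from one master seed.

## Activities and the bond-class join

An activity matches bonds by (child sugar, anomeric configuration, linkage
carbons, backbone/side role) — not by CAZy family, since one EC spans
several families and vice versa.  Modes: `endo` (backbone interior),
`exo_nonreducing` (removes a leaf), `debranching` (removes a leaf on a
side-chain linkage only), `esterase` (removes a substituent class).
`required_activities` is a pure function of the structure's bond-class set;
classes matching nothing are returned as `unmapped`, never dropped.

Design choices worth knowing:

- Disaccharide-releasing exo enzymes (cellobiohydrolases) are not in the
  registry: completeness counts free monomers only, and a DP-2-releasing
  rule has no place in the monomer-closure semantics.  Cellulose therefore
  requires {endo-glucanase, β-glucosidase}.
- The xyloglucan backbone is assigned to the same EC 3.2.1.4
  endo-glucanase as cellulose.  A xyloglucan-specific endo activity would
  need to see *other* classes of the same structure (is the glucan
  xylosylated?), which the per-class join deliberately cannot express.
- α-L-arabinofuranosidase (EC 3.2.1.55) is split by context: the general
  activity acts on arabinan/galactan/pectin parents, while arabinoxylan
  arabinofuranohydrolase (same EC, axhA-type) debranches xylose-backbone
  parents.  Esterases are similarly split by host sugar (acetyl on
  mannan / xylan / galacturonan are three activities).

## Digestion closure

Digestion is a reachability computation — no kinetics, rates, synergy or
product inhibition.  Four rules run to a fixpoint: esterases strip matching
substituents; exo/debranching activities release unsubstituted leaves whose
linkage matches; endo activities cleave a backbone bond when both flanking
residues were interior in the *original* backbone and both are currently
free of substituents.  Substituents block cleavage at the substituted
residue; this is what makes esterases and debranching enzymes operative
requirements rather than decorations.  Judging endo interiority against the
original backbone (a static property) makes the rule system monotone and
hence confluent: the fixpoint is independent of application order, which
the tests check against a one-rule-at-a-time randomized oracle.  An
optional processive mode re-evaluates interiority within the current
fragment under a canonical deterministic order; it is order-sensitive by
construction and excluded from the confluence guarantee.  A fragment
reduced to one residue counts as a free monomer; completeness is the
fraction of input residues released as monomers, so oligomeric end products
count as incomplete conversion.  Whether an endo enzyme tolerates
substituted neighbours is a per-activity possibility the pattern role
field can express; the default is "blocked".

`minimal_sufficient_sets` enumerates subsets exhaustively up to 15
candidate activities (smallest first, supersets pruned); above that it
falls back to one greedy pruning pass and says so in its docstring.

## Expression statistics

The module consumes either probe-level or gene-level TSV matrices; CEL
parsing and convolution background correction are out of scope.  Quantile
normalization maps every column onto the mean distribution of order
statistics, ties receiving the mean of their tie run's target values.
Median polish is Tukey's alternating row/column sweep (tol 0.01, max 10
iterations; non-convergence is flagged, not fatal), with the expression
index = overall + column effect.

The moderated t-test pools within-group variance on d_g = n_A + n_B − 2
degrees of freedom and shrinks it toward a prior estimated across genes by
method of moments on log s²_g under a scaled-F model: the excess variance
of log s²_g beyond trigamma(d_g/2) determines d₀ through the inverse
trigamma; non-positive excess collapses to d₀ = ∞ (all genes share s²₀,
normal reference distribution), and a non-estimable prior falls back to no
shrinkage.  Comparisons are strictly pairwise — no global linear model
across the six conditions — and unequal replicate counts (the starch
duplicate) are supported.  BH adjustment delegates to
`statsmodels.stats.multitest` and is verified in the tests against a
textbook step-up implementation.  Significance is adjusted p < 0.05 with
direction from the sign of the log2 fold change; summaries print as
"n (k↑/m↓)".

## Clustering

Profiles are per-gene condition means over replicates (clustering all
replicate columns individually is the documented alternative; means are
the default).  Standardization to zero mean and unit norm makes the
Pearson distance 1 − r equal to half the squared Euclidean distance, so a
spherical k-means — centroids re-standardized every iteration — minimizes
Pearson dispersion directly.  "Accounting for biological replicates" is
implemented as optional per-gene weights = inverse mean within-condition
variance (floored at the smallest positive variance observed), applied in
centroid updates and dispersion; `weighted=False` disables it.
Constant-profile genes are flagged and excluded from standardization, not
silently dropped.  Runs are best-of-50 restarts (seeded), empty clusters
are re-seeded at the worst-fit point, and `scan_k` additionally
warm-starts k+1 from the best k solution plus the worst-fit profile, which
guarantees non-increasing best dispersion in k.  k itself is always the
user's choice.

## Coverage overlay

"Covered" means at least one up-regulated isoenzyme per required activity
(`require_n` generalizes); down-regulated genes never count.  Genes in the
same ambiguous probe group (near-identical sequences an array cannot
distinguish) count as a single unit.  Activities with no catalog gene are
excluded from the coverage denominator but reported prominently —
otherwise a curation gap would make a full set unreachable by definition.
Esterase activities sit in the denominator whenever the structure instance
carries the corresponding modification.  A structure with no mapped
required activity cannot be a full set.  Rendering is DOT text (validated
structurally in tests); a gene without a counterpart identifier in the
second genome renders gray regardless of status.

## Synthetic experiments

The simulator emulates the six-carbon-source design: glucose, xylose,
arabinose, starch, arabinan, xylan; biological triplicates except a starch
duplicate.  Gene values are baseline_g + effect·1[condition ∈ inducing
set] + N(0, σ) on the log2 scale — Gaussian, because expression indices,
not counts, are being emulated.  Defaults: baseline N(6, 1), effect 2.0
log2, noise σ = 0.3, 100 decoy genes; the stock scenario induces the xylan
regulon on xylan *and* arabinose (cross-induction) and the starch regulon
on starch.  What the generator does **not** emulate: probe-level effects,
intensity-dependent variance, correlated gene programs beyond the planted
regulons, or carbon-repression dynamics.  Passing tests therefore show the
pipeline recovers planted structure under microarray-like noise — they are
not evidence about any particular real dataset, whose headline counts
depend on the exact arrays, preprocessing stack and biological noise.

## Problem sizes and numerical choices

Packaged structures have 20–41 residues; ensembles in tests and the
acceptance script use 200 structures; statistical tests use 2000-gene
simulations; clustering recovery uses 80 genes × 20 seeds.  These sizes
give stable statistics (ensemble standard errors below 1 percentage point)
while the whole suite runs in seconds.  Tolerances: ensemble checks accept
3 standard errors; hyperparameter recovery 25 % at d₀ = 4, s²₀ = 0.04;
uniformity via Kolmogorov–Smirnov p > 0.01.  Ties in k-means assignment
break toward the lowest cluster index; BH and quantile normalization tie
handling are described above.

## Known limitations

- Structures are single molecules; crystallinity, cross-linking and
  cell-wall architecture are out of scope, as is rhamnogalacturonan II.
- The digestion engine is qualitative: it answers "can this enzyme set
  finish the job", not "how fast".
- The gene catalog beyond the fifteen published mannanolytic records uses
  placeholder sequence identifiers (file marked synthetic); counts derived
  from it are illustrative, and tags (`mapped_to_structure`,
  `polysaccharide_acting`, `ghplce`) exist so a fully transcribed catalog
  can reproduce published gene-set sizes.
- Ortholog pairs between the two genome annotations are data, not
  computation; a missing pair renders gray.
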