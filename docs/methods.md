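# Methods

`nbmature` turns sequencing counts from a single round of affinity sorting
into trained sequence-function models, ranked single substitutions, and
designed multi-mutant binders. This note records the models, the parameter
choices that matter, the numerical decisions taken where the design was
genuinely open, and what the synthetic campaign generator does and does not
emulate.

## Data model: from counts to enrichment labels

Each selection round *r* of a campaign yields a table of protein sequences
with read counts. Sequences with count < *c* (default **c = 5**) are removed
from every round independently: spurious low-count sequences are
overwhelmingly sequencing-error artefacts, and the simulator confirms that
at 2×10⁵ reads/round and 10⁻³ per-residue error more than 90 % of
error-bearing reads fall below this threshold.

For a sequence *s* with post-threshold abundance fractions `f_FACS(s)` and
`f_MACS(s)`, the log enrichment is

    e(s) = ln( f_FACS(s) / f_MACS(s) )

where an abundance missing from one round (sub-threshold) is replaced by a
floor **ε = 10⁻⁶** before the ratio is formed. Sequences sub-threshold in
*both* rounds are excluded. Because inter-round overlap of unique sequences
is low, most sequences hit the floor on one side and the e distribution is
strongly bimodal; the binary label is `enriched` for e > 0 and `depleted`
otherwise (exact zero is labeled depleted so ties are deterministic).

*Floor semantics.* An alternative convention imputes the log value itself
(rather than the abundance) when a sequence is missing from one round.
Flooring the abundance is the default here because imputing the log value to
a small positive constant would label every MACS-absent sequence enriched by
fiat and every FACS-absent sequence depleted by a hair, collapsing the
continuous signal; the literal alternative is retained behind
`EnrichmentParams(floor_mode="log_value")`.

*Denominator convention.* Abundance fractions are computed after
thresholding, i.e. sub-threshold sequences are removed from a round before
its total is formed.

## Sequence coordinates and encoding

All variants are expressed in the lead's coordinate system. Reads are
translated in the forward frame that best matches the lead's 9-residue
prefix anchor (ties → lowest frame), and sequences whose prefix/suffix
anchors exceed 3 mismatches or that are >10 residues shorter than the lead
are discarded. Error-prone PCR introduces essentially no indels, so
length-preserved sequences map by identity; length-changed ones are globally
aligned to the lead (match +1, mismatch 0, gap −2, end gaps penalized),
insertion columns relative to the lead are dropped, and unmatched lead
positions become gaps. This reproduces a numbering-scheme alignment
("keep only the columns present in the lead") without an external
antibody-numbering tool; CDR positions are supplied by the user in
`LeadSpec.cdr_mask` rather than inferred.

One-hot encoding uses a 21-letter alphabet (20 amino acids + gap), columns
ordered position-major with residues alphabetical and gap last. For linear
models the lead's own residue column is dropped at every site
(`wt_dropped`): the lead encodes to the zero vector and every feature is one
substitution away from WT, which removes the perfect correlation among WT
indicator columns.

## Models

**L1 logistic regression** (binary label) and **L1 linear regression**
(continuous e) are the core models; both are sparse additive models with one
weight per (position, residue) substitution, so a model's score of any
variant is the intercept plus the sum of its substitutions' weights.

*Penalty conventions.* The linear model minimizes
`mean squared loss + λ‖w‖₁` with **λ = 5×10⁻⁴** (mapped exactly onto
scikit-learn's Lasso, α = λ/2). For the logistic model the default strength
is expressed in scikit-learn's native inverse-regularization convention,
**C = 2** (objective `‖w‖₁ + C·Σ log-loss`). A mean-loss convention with
strength 2 is provably degenerate: at w = 0 the subgradient bound
|∂(mean log-loss)/∂w_j| ≤ ½ < 2 holds for every binary feature, so the
global optimum is exactly the null model. Since the reference models in this
field are built with scikit-learn, whose logistic parameter *is* C, the
inverse convention is the default; both models expose a `convention` switch
(`TrainConfig.logistic_convention` / `linear_convention`).

**CNN.** A 1-D convolution over positions (kernel 5, 32 channels, ReLU),
global max-pool, a 64-unit ReLU layer, and a linear/logit head; Adam
(lr 10⁻³, batch 256), L1 weight 10⁻⁴ applied to all weight matrices via the
subgradient, up to 1000 epochs with early stopping (seeded 90/10 split,
patience 20, best-validation weights restored). The trainer is a compact
numpy implementation (`nbmature/_nn.py`) and is bit-reproducible from the
seed. The CNN is optional for the core pipeline.

**Embedding-MLP.** The same dense trainer over a pluggable embedding
provider (`sequences -> (N, D)` array). The bundled default provider is a
seeded random projection of the one-hot features — a synthetic stand-in
with the call signature of a pretrained protein-language-model encoder;
real embeddings can be plugged in without code changes.

**Distance baselines.** Hamming distance to the lead, and median Hamming
distance to the (optionally subsampled) MACS round. Distances carry no
intrinsic sign convention for classification, so evaluation reports the AUC
under both orientations and flags the better one.

**Evaluation.** ROC-AUC (rank statistic, tie-averaged), PR-AUC (step
integration / average precision), Spearman with average ranks, plus
per-class Spearman within the enriched and depleted classes. In the
retrospective protocol (train on FACS1/MACS, test on FACS2/MACS) metrics are
also recomputed with training-set sequences removed from the test set; note
that any test sequence outside the training universe was necessarily absent
from MACS and is therefore labeled enriched, so the overlap-removed panel is
emitted only when both classes survive the removal.

## Singles ranking and NDCG

The substitution score matrix holds Δscore = score(single mutant) −
score(lead) for all 19·L substitutions (for a linear model this is exactly
the weight). Ranking is by (Δscore desc, position asc, mutant alphabetical).
Against a validated set (each hit gain 1, all else 0):

    DCG  = Σ_{rank ≤ k} gain / log2(rank + 1),   NDCG = DCG / IDCG

The standard log2(rank+1) discount is used because a log2(rank) discount is
undefined at rank 1; a `discount="paper-style"` variant that clamps the
rank-1 discount to 1 and uses log2(rank) thereafter is available (it differs
from the standard discount only at rank 2). NDCG is undefined (error) when
no item has gain 1.

**Liability screen.** Deterministic motif scan for N-x-S/T glycosylation
sequons (x ≠ P by default — the standard sequon rule; configurable), DG and
NG isomerization dipeptides, and cysteines introduced relative to the lead.
The bundled polyreactivity scorer (introduced cysteines + hydrophobic
3-windows) is a clearly labeled synthetic stand-in exposing the same
interface as a trained polyreactivity model; `filter_by_scorer` accepts any
`sequence -> float` callable and keeps candidates no worse than the WT
reference score.

**Count-based selection.** Greedy leader clustering on Hamming distance
(visit by count desc, lexicographic tie-break; join the first leader within
radius, default 2, else found a cluster), returning the top-n leaders by
count. The clustering algorithm and radius were open choices; greedy leader
clustering is the simplest deterministic scheme that de-duplicates
near-identical high-count clones.

## Gibbs design

A trajectory starts at the lead. Each step scores the current state and all
single-residue changes at CDR positions (reversions included); options that
would push the Hamming distance to WT beyond the goal distance d_goal are
masked out entirely, and one option is drawn from
`softmax((score − α·hamming)/T)`. The option set includes *keeping the
current state*: Gibbs resampling of a site may retain its residue, and
without this option a trajectory sitting on the score optimum would be
forced off it at every step (at d_goal = 1 this creates a parity artefact in
which the endpoint deterministically abandons the best mutant). The
distance regularizer weight α defaults to 0 (hard constraint only), since
the only firm requirement is never stepping beyond the goal distance; α > 0
additionally biases trajectories back toward the lead.

Defaults: 100 steps, temperature series (5, 1.0, 0.5) spread evenly across
the steps (earlier blocks absorb the remainder: 34/33/33), goal distances
{3, 5, 7}, 100 trajectories per distance. Per-trajectory RNG streams derive
from (master seed, goal distance, trajectory index), so batches are
reproducible and order-independent. The design set takes the top 30 per
distance by model score after deduplication (keep first in seed order), then
the pooled top 30; ties break by (fewer substitutions, lexicographic).

Design sets assembled per campaign: `LR_gibbs` (sampled designs), `LR_score`
(top observed campaign sequences by model score after the polyreactivity
filter), and `FACS2_count` (clustered top FACS2 counts).

## Synthetic campaign generator

The simulator provides planted ground truth so every stage is testable
without campaign data. Per variant, k ~ Poisson(mutation rate, default 2)
distinct positions are mutated to uniform non-WT residues; copy numbers
carry a log-normal expression bias (σ = 0.5) to create the
"highly expressed but modest affinity" confounder. True fitness is additive
over planted effects (lead = 0; optional pairwise epistasis terms).
Selection acts at the phenotype level: each copy survives a round with
probability `sigmoid(fitness − stringency)`; stringency plays the role of
decreasing antigen concentration. Sequencing draws `depth` reads
multinomially and corrupts each read per-residue at the error rate.

**Default study conditions** (chosen once, at design time, from the
selection model's arithmetic): library 5×10⁴, mutation rate 2, six
beneficial CDR substitutions at +4 and six deleterious (proline)
substitutions at −4, stringencies MACS 0 / FACS1 4 / FACS2 6, depth 2×10⁵,
error 10⁻³. The ±4 / (0, 4, 6) combination realizes a *strong* selection
regime — a beneficial substitution moves first-gate survival from ~2 % to
~50 % — which is what makes late-round enrichment predictable from
early-round data: under weaker gates the FACS2-enriched class is dominated
by lucky neutral survivors and no model (nor the true landscape itself) can
exceed ROC-AUC ≈ 0.6 against those labels. Under the defaults the simulator
also reproduces the qualitative pathologies of real campaigns: all pairwise
inter-round Jaccard overlaps of unique sequences < 0.3, and a strongly
bimodal log-enrichment distribution.

What the generator does **not** emulate: codon-level mutation spectra
(mutagenesis acts on amino acids), PCR chimeras, polyreactivity
counter-sorts, and any biophysical binding model — stringency is an
abstract gate position, not an antigen concentration. Consequently, passing
recovery tests demonstrates that the pipeline's statistics behave correctly
under a known additive landscape with realistic count sparsity; they do not
certify performance on real campaigns, where epistasis, expression-affinity
correlations and codon bias are all present.

A consequence of strong selection worth noting: deleterious variants are
eliminated *before sequencing*, so most deleterious planted substitutions
never appear above threshold in any round. Sign-recovery checks therefore
condition on observability (substitutions carried by ≥ 5 training
sequences); unobserved substitutions are unrecoverable by any method.

## Determinism and numerics

Every stochastic stage takes an explicit seed; a master seed fans out to
per-stage seeds via `numpy.random.SeedSequence` so stages can be rerun
independently, and a full run regenerates every output file byte-identically
from (config, seed). Solver tolerances: logistic/lasso 10⁻⁶; softmax is
max-shifted for stability; proposal probabilities sum to 1 within 10⁻¹².
Degenerate inputs raise informative errors rather than propagating NaNs:
empty rounds after thresholding, single-class training labels, all-zero
NDCG gains, extinguished selection pools.

## Problem sizes used in the test suite

The shared simulated campaign runs at the full default conditions above
(~25 s including model training). Unit tests use a 20-residue lead and
desk-scale campaigns (library 3–4×10³, depth 2–4×10⁴). The acceptance
script runs the full campaign, 300 design trajectories, design-set
construction, and a duplicate desk-scale run for the byte-identity check.
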