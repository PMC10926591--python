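# Methods

This package implements a two-arm pipeline for predicting Gene Ontology
(GO) annotations of proteins of unknown function (PUFs) in a single
organism, together with the downstream analyses that characterize the
predictions: network modularity of the similarity graph, Bayesian
enrichment of terms among predictions, and bootstrap quantile–quantile
comparisons of protein properties. Everything runs end to end on synthetic
data with a planted, maskable functional signal, so every stage is testable
offline and the realized false discovery rate (FDR) of the whole pipeline
can be measured against a hidden truth.

## Ontology semantics

The GO DAG is parsed from OBO 1.2 (obsolete terms dropped; `is_a` edges
always, `part_of` optionally — both by default, following the usual "true
path" propagation convention). The three namespaces are treated
equivalently; each namespace root has depth 0 and a term's **depth** is the
number of edges on the longest root-to-term path. Annotation sets are
**ancestor-closed** before use anywhere: the deepest-shared-term target,
the PUF rule, candidate labeling and the final predictions all operate on
closed sets, which is the only reading under which parent propagation of
accepted terms is coherent.

A protein is a **PUF** when its (closed) annotation set is empty or
reaches no deeper than depth 1 — unannotated, or annotated only with
uninformative near-root terms. The merge of annotation sources keeps
per-source provenance and drops score-bearing assignments with score
≤ 0.9 (strict), the conventional high-confidence cutoff for NetGO-style
predictions.

The depth of the deepest shared term of two proteins' closed sets is the
pairwise similarity target. Empty annotation sets give a shared depth of 0
rather than an undefined value so every pair is scoreable.

## Pair model (guilt-by-association arm)

Each unordered protein pair carries a registry of ~20 similarity measures:
Shannon-information-weighted Jaccard distance over sequence-motif
presence/absence (weights $-\log_2(n_f/N)$, in bits), sequence bitscore,
operon co-membership, orthogroup species-set overlap, a phylogenetic tree
distance, proteomic co-expression (per-experiment Spearman of
condition-level profiles averaged over experiments, plus a presence/absence
Jaccard distance across all conditions), max-normalized TM-score and RMSD,
and STRING-style sub-scores (direct co-expression and experiments excluded
for sparsity; their transferred variants retained; all rescaled from the
0–1000 integer scale to [0, 1]). Missing evidence fills with 0 for numeric
channels and 1 for distance-type channels; the registry records each fill
value and is configuration-editable, so the exact measure count is not
hard-coded.

A random forest regresses the deepest-shared depth on these features. Ten
percent of annotated proteins are held out at the protein level; any pair
touching a held-out protein is excluded from training (the training-table
builder enforces this by construction). Pairs with target depth in (6, 8]
receive training multiplicity 2 and pairs deeper than 8 multiplicity 4
(the deeper stratum's factor replaces the shallower one). Pairs with
predicted depth strictly greater than 6 become edges of the **hit
network**, carrying their feature vector and predicted depth as payload.
The regressor's quality is summarized as trapezoid-rule AUC-ROC for
detecting true depth > 6 on held-out (test-tainted) pairs.

Default forest settings (500 trees, unlimited depth, sqrt features) are
exposed; the test-suite and acceptance runs use smaller forests (100–300
trees), which we found indistinguishable in ranking quality at desk scale.

## Annotation transfer with FDR calibration (both arms)

For a query protein, candidate terms are exactly the union of its hits'
closed annotation sets — a term is assessed only if some hit carries it.
Each (protein, term) candidate is described by summary statistics (count,
sum, max, mean — sum and max being the canonical pair for TM-scores) of
every similarity measure over the hits annotated with that term; the
statistic registry is configurable per arm.

Labeling precedence: candidates of test proteins and of PUFs are
unlabeled; a candidate whose term is deeper than the protein's deepest
known term is unlabeled (the incomplete annotation database cannot falsify it);
otherwise the candidate is positive iff the protein carries the term. A
seeded random 10% of the remaining labeled training candidates is then
deliberately unlabeled and reserved for FDR calibration — the classifier
never sees their labels, which guards against the overfitting of an
FDR estimate taken on training data. A random forest classifier is fit on
the positive/negative candidates only and scores every candidate in [0, 1].

The decision threshold is the **smallest observed score** t such that
FP/(FP+TP) among calibration-holdout candidates scoring ≥ t is at most the
target FDR (default 1%); if no observed score qualifies, the threshold is
+∞ and no calls are made. The realized calibration FDR is ≤ target by
construction and asserted on every run. The same holdout mechanics yield
an honest report of the realized FDR/precision/recall on the test-protein
stratum, computed from labels the model never used; on noisy synthetic
data this realized FDR exceeds the calibration target, and the pipeline
reports the overshoot rather than hiding it.

Terms passing the threshold are propagated to all ancestors; closure-added
ancestors carry `arm:closure` provenance and inherit the maximum score of
their accepting descendants. Final predictions are the per-protein set
union of the two arms with dual provenance; no consensus weighting is
attempted.

"Semi-supervised" here means positive/unlabeled-aware training — fit on
labeled candidates, use the unlabeled strata for calibration and
prediction. No self-training loop is implemented, and one classifier is
shared across all (protein, term) candidates rather than one per term; the
summary-statistic feature design implies per-candidate granularity.

## Structural arm

Structure-search hits (TM-score, RMSD, hit sequence, taxonomy lineage,
annotations) are filtered at TM-score strictly above 0.3 with self-hits
removed. Query structures are first screened by pLDDT trimming: residues
are removed from both termini up to the first residue with pLDDT strictly
above 70, and the structure is kept only if the remaining core is strictly
longer than 30 residues; interior low-confidence residues are untouched.

Each surviving hit gains sequence predictors from an optimal global
alignment (Needleman–Wunsch with affine gaps, Gotoh recurrences; BLOSUM62,
gap open 11, gap extend 1, a gap of length L costing `open + (L-1)·extend`;
deterministic diagonal > up > left tie-breaking): percent identity and
percent non-gap, both normalized by alignment length (the conservative
denominator — percent non-gap then measures gap burden independently). A
coarse phylogenetic predictor is the rank of the most specific shared
taxonomic level (species 0, genus 1, family 2, …, superkingdom 6, nothing
shared 7). The per-hit score map {TM, RMSD, % identity, % non-gap,
taxonomic rank} feeds the same transfer engine as the other arm.

The alignment is implemented in-package rather than through a wrapper
because the tie-breaking order and the percentage definitions are part of
the contract; it is verified against exhaustive enumeration of all global
alignments for short sequences.

## Network modularity

Functional coherence of a node set S is the generalized Newman modularity
of the binary partition {S, S̄} of the unweighted hit network,
Q = Σ_c [e_c/m − γ(d_c/2m)²], computed with NetworkX and verified against
the adjacency double-sum. The resolution γ defaults to 0.81 and is a plain
configuration scalar (no resolution-selection procedure is included). The
PUF partition is compared against 1000 size-matched uniform node sets and
against partitions defined by GO terms annotated to strictly more than a
configured number of network proteins (counted within the network's nodes;
default mirrors the published threshold of 400 but scales down for desk-
scale data). Edges are unweighted: a hit either exists or does not.

## Bayesian enrichment models

Both models are **reconstructions** built to satisfy the stated
constraints (depth-aware odds ratios; PKF frequencies as prior), isolated
behind this module's interface so alternatives can be swapped; they are
not copies of any external model.

**Odds-ratio model.** For term t with depth d(t):
k_{g,t} ~ Binomial(n_g, p_{g,t}) for g ∈ {PKF, PUF};
logit p_{PKF,t} = α_t, logit p_{PUF,t} = α_t + β_t;
β_t ~ Normal(μ_{d(t)}, σ), μ_d ~ Normal(μ₀, τ);
α_t ~ Normal(0, 2), μ₀ ~ Normal(0, 1), σ, τ ~ HalfNormal(1).
The reported enrichment is OR_t = exp(β_t), partially pooled across terms
of equal depth and across depths. Counts are protein-level and terms need
at least 4 observations in both groups (≥ 6 for the sequence-feature
variant of the same analysis).

**Expected-count model.** The PKF frequency prior is
p_t ~ Beta(k_pkf+1, n_pkf−k_pkf+1), updated by k_puf ~ Binomial(n_puf, p_t);
the reported quantity is total_PUFs × p_t. The posterior is conjugate
(Beta), and that closed form is used as an independent oracle in the tests
— the implementation itself samples.

**Sampling.** Posteriors are drawn by blocked adaptive random-walk
Metropolis on a non-centered parameterization, with an interleaved
centered update of the hierarchy scales (holding the β's fixed), which
keeps mixing healthy in both the data-weak and data-dominated regimes.
Chains (default 8) are fully independent; proposal scales adapt only
during burn-in. Split-R̂ and effective sample size come from arviz;
R̂ > 1.05 flags the affected summaries as unconverged (`converged=False`
plus a logged warning) without suppressing them. Summaries are the
posterior median and 0.1/0.9 quantiles, which are ordered by construction.
This sampler is implemented in-package: of the available samplers, the
general-purpose ensemble sampler mixed too slowly on this posterior's
funnel geometry to support calibration studies, while the blocked
structure of the model admits a simple, fast, exactly-targeted kernel.
Simulation-based calibration (parameters drawn from the prior, 80%
intervals checked against the planted values) is part of the acceptance
suite.

**Bootstrap QQ.** Distributional comparisons resample both groups with
replacement (default 500 times), evaluate both quantile curves on a fixed
grid of 99 equally spaced quantiles, and form a pointwise 95% band on the
quantile difference. The null line y = x is reported "excluded" only when
it falls outside the band at every grid point; constant samples give
"indeterminate". Group medians are reported alongside.

## Synthetic data: what is planted and what is not

The generator emulates every input format the pipeline reads. Proteins
belong to functional groups nested in term families: a family owns a term
at depth `max_depth − 2` (default 7) and each group a chain below it
(depths 8 and 9), so true deepest-shared depth is 9 within a group, 7
across sibling groups, and shallow otherwise (background terms at depths
3–6 provide realistic mid-depth sharing). Default scale is 300 proteins,
150 terms, 8 families × 2 groups (the strong preset; the noisy and null
presets use 160 proteins and 120 terms to keep repeated runs cheap).

Every evidence channel couples to this structure only through the signal
strength α, via per-channel "channel groups" (a protein's channel group
equals its true group with probability α, else uniform) and, for the
continuous channels, a blended term α·(shared depth)/max_depth. At α = 0
all channels are therefore exactly independent of the planted truth while
retaining realistic within-channel structure — the null preset. The noisy
preset (α = 0.5, higher noise) represents partial signal; the strong
preset (α = 0.9, low noise) approaches the information ceiling.

PUF masking selects whole groups and masks 70% of each selected group's
members down to their namespace root (at least one group per family is
left untouched). Masked proteins are PUFs under the depth rule; their real
annotations are retained only for the evaluator. This choice makes the
masked set a planted community of the hit network — under-annotated
functions cluster — while the remaining annotated group-mates and sibling
groups keep guilt-by-association recovery possible. Structure-search hits
come from a synthetic foreign pool whose annotation overlap with the
query's hidden truth rises with the drawn TM-score
(p = 1 − (1−α)(1−TM) above TM 0.6), with each foreign protein returned at
most once per query; hit sequences are TM-coupled mutants of the query and
lineages share the query's upper ranks from a TM-coupled level. A fraction
of foreign proteins is unannotated and a fraction of query structures is
entirely low-confidence, exercising the corresponding filters.

Annotation sources include a score-bearing NetGO-like source whose noise
assignments rarely survive the 0.9 cutoff, plus three score-free sources
with per-source dropout; a protein's deepest term is guaranteed to survive
in at least one source so that unmasked proteins remain PKFs.

What the generator does **not** emulate: realistic sequence or structure
content (sequences are random; structures are reduced to pLDDT traces),
spectral data (quantification matrices are generated at the protein
level), biased PUF property distributions (PUF and PKF lengths and pLDDT
are exchangeable, so the QQ machinery's "excluded" verdict is exercised on
explicit shifted samples in tests, not on the presets), and real-database
idiosyncrasies (evidence codes, term obsolescence churn). Passing tests
therefore demonstrate the correctness and calibration of the machinery
under the planted model, not performance on any real proteome.

## Numerical and procedural choices

- Thresholds are restricted to observed scores; score ≥ threshold accepts.
- Ties at the hit-depth cutoff and at the TM filter are resolved by strict
  inequality; the observation thresholds ("at least 4/6") are inclusive.
- Spearman uses average ranks; a constant profile yields correlation 0;
  a pair's correlation in an experiment missing either protein is 0.
- Weighted Jaccard with zero-weight union is defined as distance 0 and
  logged; proteins with no motif data are maximally distant (1).
- Candidate summary statistics sort hit values before reduction so the
  vector is exactly invariant to hit ordering.
- All randomness flows from explicit integer seeds through
  `numpy.random.default_rng`; dataset generation is byte-deterministic
  (the manifest records SHA-256 of every written file).
- Desk-scale problem sizes used by the tests and the acceptance script
  (300-protein strong preset, 160-protein noisy/null presets, 100–300-tree
  forests, 200 calibration replicates) were chosen as the smallest sizes
  at which the planted-signal properties are stable across seeds.

## Known limitations

- The FDR guarantee is a calibration-set property; the realized FDR on
  differently-distributed strata (PUFs, test proteins) is reported but not
  controlled, and on noisy data it exceeds the target — the same caveat
  applies to the published procedure this mirrors.
- The enrichment models assume predictions are an unbiased sample of true
  PUF annotations; this assumption is documented, not tested.
- One classifier is shared across all candidate terms; per-term models are
  not implemented.
- The hit network treats all hits equally; predicted depth is not used as
  an edge weight.
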