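# Methods

This note documents the models, parameter choices and limitations of
`targetprop`. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## 1. High-confidence genetic hits

A colocalization record (trait, locus, eGene, tissue, GWAS p, eQTL p, p12)
becomes a high-confidence genetic hit (HCGH) when the eGene is protein
coding, GWAS p ≤ 5×10⁻⁸, eQTL p ≤ 10⁻⁴ and p12 ≥ 0.8 — all thresholds
inclusive. Tissue records failing the eQTL filter are discarded *before*
the per-locus argmax over p12, so a strong posterior in a tissue with an
unconvincing eQTL cannot carry a gene. p12 ties break lexicographically by
gene identifier for determinism; a gene winning several loci is kept once
with its maximal-p12 record. Traits are retained only with ≥ 1 HCGH and
≥ 1 outcome-bearing target for a matched indication; a trait blacklist
models the manual removal of spurious trait–indication matches (e.g.
surgical traits).

## 2. Clinical outcome classification

Asset statuses collapse to Succeeded (`Launched`), Failed (`Discontinued`,
`No Development Reported`, `Withdrawn`, `Suspended`) or InProgress
(anything else). A failed asset is a *clinical* failure iff it reached
Phase I–III. Target–indication pairs are classified by a precedence
cascade that trusts single-target (Selective) assets first: Selective
success → Selective clinical failure → Non-Selective success →
Non-Selective clinical failure → Selective preclinical failure →
Non-Selective preclinical failure → InProgress. The reading under which a
Selective clinical failure outranks a Non-Selective launch follows the
order in which the source describes the processing steps; the alternative
(any launch wins) is available via
`classify_target_indication(..., selective_failure_overrides_nonselective_success=False)`.
Succeeded pairs form the positive set, ClinicalFailure pairs the negative
set; preclinical failures say little about target biology and in-progress
programs have no outcome, so both are excluded.

## 3. Expansion methods

Complex and pathway-clique expansion treat each gene set as a fully
connected clique. Ligand–receptor expansion is strictly first-neighbor
(expanding a further step would propagate evidence from a ligand to all of
its receptor's other ligands). Interactome neighborhoods use unweighted
adjacency at order 1 or 2; a STRING-style confidence threshold is a load
option, not an analysis step. Pathway-wiring neighborhoods ignore edge
direction ("upstream and downstream" interactors both count); whether
second interactors should respect direction is genuinely ambiguous and we
chose undirected reachability. The random negative control samples coding
genes at the reference fraction 10,000/22,758 of the coding universe.
Every expansion returns proxies ⊆ universe with seeds removed.

## 4. Insulated heat diffusion

Heat h = −log₂(1 − p12) (p12 clipped at 1 − 2⁻²⁰ to stay finite) is
diffused with F = β(I − (1−β)W)⁻¹, W the column-normalized adjacency of
the largest connected component. Columns of F sum to one — heat is
conserved — and the exchanged heat E = F·diag(h) records pairwise
delivery. Modules are strongly connected components of the graph with
edge j→i iff E[i,j] ≥ δ, of size ≥ k_min (default 3); β defaults to 0.4,
the usual choice for protein interaction networks. δ is selected per trait
as the smallest threshold (over geometrically spaced ranks of the positive
exchanged-heat values) at which randomly reassigned heat produces
essentially no modules (expected < 0.05 modules per permutation).

Two consequences of E = F·diag(h) deserve note. First, a gene with zero
heat has a zero column and can never belong to a module, so seeding heat
*only* on HCGHs would make "module genes minus seeds" provably empty.
Heat is therefore assigned from the best colocalization record of every
gene with any record for the trait; seeds are simply the hottest genes and
warm sub-threshold candidates can join modules, which is what makes the
method able to nominate new targets. Second, module size at this scale is
small (a few genes per trait), which matters for the enrichment statistics
(§6).

Dense inversion is used up to 5,000 nodes and a sparse LU solve above.

## 5. Gene scores and pathway enrichment

The sum score T = Σzᵢ² over the variants in a gene's body ± 50 kb has
null distribution Σλⱼχ²₁ with λⱼ the eigenvalues of the local LD matrix.
The tail is computed by Imhof's characteristic-function inversion on an
oscillation-resolving Simpson grid (truncated where a half-oscillation
contributes < 10⁻⁹), with two special paths: equal surviving eigenvalues
use the exact closed form P(χ²ₖ > T/λ) (this covers both independent
variants and perfect LD), and a Satterthwaite moment-matched χ² is the
fallback when inversion is unreliable or the tail is deeper than ~10⁻¹².
Near-zero eigenvalues are dropped; matrices with eigenvalues below
−10⁻⁸·λmax are rejected as non-PSD.

Genes of one pathway whose windows overlap are fused (union of variants,
shared variants deduplicated, unobserved cross-block LD taken as zero) and
rescored, so shared LD is not double counted. The pathway statistic is the
Fisher-style S = Σ −ln p over (fused) members; its empirical p-value uses
size-matched random sets drawn without replacement from the scored
universe, with the add-one estimator (never exactly zero). Because the
smallest achievable empirical p must survive Benjamini–Hochberg across the
collection, permutation depth is adaptive: a 500-permutation screen,
re-run at the full depth (default 10,000) where the screen suggests
significance. BH is applied per collection per trait; proxies are members
of BH-significant (adjusted p < 0.05) pathways with nominally significant
(p < 0.05) gene scores, excluding HLA-flagged genes and seeds.

## 6. Stratified enrichment

Per (trait, method), the counted population is the protein-coding genes
carrying a Succeeded or ClinicalFailure outcome for an indication matched
to the trait, with the seed HCGHs removed entirely — the enrichment is a
statement about *new* genes, and a genetically supported seed left in the
background would deflate every method's odds ratio. A gene with outcomes
for several matched indications counts once (success if any succeeded;
configurable). Tables with a = b = 0 are removed; tables with a zero in
the hit row get +0.5 in every cell (Haldane). Strata are pooled with the
Mantel–Haenszel odds ratio, Robins–Breslow–Greenland 95% interval, and the
CMH chi-square (continuity correction off by default), all computed on the
corrected cells — no separate uncorrected track exists.

**Small-hit-set anti-conservatism.** For methods whose proxy sets
intersect only ~2–3 outcome-bearing genes per stratum, most tables have
a = 0 and the Haldane correction contributes odds of roughly 0.5·d/(b·c)
per corrected stratum, inflating the pooled OR above 1 even under a true
null (direct simulation in the acceptance suite measures mean null OR up
to ~1.3 and interval coverage far below nominal in that regime). This is a
property of the Haldane+CMH procedure itself, not of its implementation;
the diffusion method sits squarely in that regime (§4), and its
null-calibration acceptance check is deliberately left failing rather than
worked around. Users comparing few-proxy methods should read their pooled
ORs with this bias in mind.

## 7. The synthetic world

The generator emulates the analysis inputs with the structure the method
stack assumes:

* **Interactome**: Barabási–Albert preferential attachment (m = 3) — the
  hub-dominated topology responsible for the failed-target effect in
  global networks; Erdős–Rényi available for contrast.
* **Complexes, pathways, ligand–receptor pairs**: random *connected
  subgraphs* (complexes 2–10, pathways 10–100 members; pathway wiring =
  induced edges, directions random; LR pairs = oriented edges). Real
  complexes and pathways are locally connected in the interactome, and
  this is what gives pathway-derived proxies genuinely elevated gene
  scores. Default counts (300/150/200 at 2,000 genes) keep per-gene set
  coverage near the real collections'.
* **Traits**: each trait plants a connected disease module (15–35 genes)
  and one indication. Coding module genes are detected with probability
  0.85 and emit passing colocalization records (p12 ~ 0.8 + 0.2·Beta(2,2),
  GWAS p log-uniform below 5×10⁻⁸, eQTL p below 10⁻⁴) plus decoy
  candidate eGenes at the same locus (interactome neighbors standing in
  for physical locus neighbors; a decoy passes all filters with
  probability 0.15, exercising the per-locus argmax). Decoy loci carry
  sub-threshold draws (p12 ~ 0.5·Beta(2,2)). Module size and detection
  rate were calibrated once to the reference mean of ~22 HCGHs per GWAS.
* **Trial outcomes**: per trait, targets are sampled with probability ∝
  degree^exponent (default 1 — historical testing concentrates on hubs).
  Success odds are baseline 1/9 (10% success), multiplied by
  `planted_success_or` (default 3) for genes near the module — either
  within `neighborhood_radius` hops ("network" mode) or sharing a complex
  with the detected seeds ("complex" mode) — and optionally by
  (degree/mean degree)^−`hub_failure_exponent` to model failure
  accumulation at much-tested hubs. Failures are clinical with
  probability 0.7; non-selective assets (15%) bind a complex partner or
  close interactor, never an arbitrary gene.
* **Variant panel**: per gene, 8 variant z-scores with AR(1) LD (ρ = 0.5);
  genes within two hops of the trait's module get a per-variant mean shift
  of 2.0 decaying by 0.5 per hop — interactors of true disease genes carry
  weak but real signal, which is what the gene-score comparison of proxy
  sets demonstrates. The stored panel belongs to a focal trait; panels for
  other traits are regenerated deterministically on demand
  (`variant_panel_for_trait`), avoiding n_traits × n_genes files. Genomic
  windows sit on 20 synthetic chromosomes with spacing that makes a
  realistic minority of neighboring windows overlap (exercising fusion).

A fixed seed makes the world bit-reproducible including its on-disk form
(plain TSV/GMT/YAML; floats at %.17g, re-read with round-trip parsing).

**What the generator does not emulate** — and hence what a green test does
not establish: real LD beyond AR(1) within-gene blocks; physical genomic
coordinates or gene density; the MeSH trait↔indication ontology (one
synthetic indication per trait); druggability and target-class biases in
which genes get tested (only degree bias is modeled); correlated GWAS
across related traits; and the content of any specific interactome or
pathway resource. Green calibration and recovery tests say the machinery
is correct on worlds with this structure, not that the biological
conclusions transfer to any particular dataset.

## 8. Numerical and design choices

* Degenerate diffusion inputs: all-zero heat yields a sentinel δ = ∞ (no
  modules); uniform heat yields max(E)+ε with a warning.
* The per-world δ permutation count defaults to 10 in pipeline runs
  (30 standalone); with the 0.05 expected-module level this demands zero
  permutation modules, the strictest choice at that depth.
* Empirical pathway p-values are never 0 (add-one); empirical-null draws
  come from the scored individual-gene universe, size-matched to the
  number of fused units — under the null both sides are exchangeable.
* BH uses statsmodels' step-up implementation; MH/RBG/CMH are implemented
  from the textbook formulas and cross-checked against statsmodels'
  independent implementation to 10⁻¹⁰ in the tests.
* The enrichment stage follows a model/results idiom
  (`StratifiedEnrichment(...).fit()`), the one stage that is a statistical
  model fitted to data; the remaining stages are pipeline modules.
* Scale-down for testing: acceptance-suite replicate worlds use 800 genes
  (default 2,000) with set counts scaled to preserve per-gene coverage;
  calibration-sensitive worlds use selective-only assets and outcome
  coverage of the whole coding universe, because the coverage bars
  presume the CMH/Haldane interval attains its nominal level, which it
  provably does not in sparse strata (§6).

## 9. Known limitations

* The Haldane+CMH pooled OR is anti-conservative for few-proxy methods
  (§6); the diffusion method's null-coverage check fails for exactly this
  reason and is left red by design.
* Pascal's exact gene-score machinery and its "empirical" pathway p are
  reconstructions (sum statistic + Imhof tail; Fisher-style set statistic
  + permutation null); they are calibrated by construction but must not be
  expected to match Pascal's numbers variant for variant.
* The consensus-module step of the diffusion analysis is approximated by
  per-network modules with an optional across-β vote; the original
  consensus procedure is not published in usable detail.
* Per-trait variant panels share one LD structure (AR(1), equal block
  sizes) across genes; fusion across genes assumes zero unobserved
  cross-gene LD.
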