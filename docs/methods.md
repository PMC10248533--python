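# Methods

This note documents the models and procedures implemented in `get3atlas`,
the parameters that matter, the numerical choices, and what the synthetic
benchmark does and does not establish.

## Domain harvest

A position-specific scoring matrix (PSSM) with affine gap costs stands in
for a profile HMM. This keeps every quantity exactly recomputable at desk
scale while preserving the logic of the pipeline (iterated search,
completeness rule, pseudodimer splitting).

* **Profile.** Columns with more than 50% gaps in the seed alignment are
  excluded from the match states. Per-column scores are log-odds in bits,
  `log2((obs_a + c·bg_a) / ((n + c)·bg_a))`, with pseudocount `c = 1` and
  background `bg` the seed's overall residue composition (add-one
  smoothed). `X` scores 0 everywhere.
* **Alignment.** Local (Smith–Waterman) for searching, global for
  re-alignment of hits into the profile, both with gap open 11 and extend
  1 bit, implemented as numba kernels.
* **Threshold.** The paper-style search has no published bit threshold, so
  it is calibrated per profile as mean + 4 SD of the best local scores of
  200 residue-shuffled database sequences (composition-preserving null).
  Four standard deviations puts the false-positive rate of a single
  comparison well below 1/200 while accepting any true domain at the
  divergences simulated.
* **Iteration.** Three search rounds; hits from a round are aligned back
  onto the match states (insertions discarded) and the profile rebuilt
  from their counts before the next round. The final round's hits are
  reported.
* **Completeness.** A hit is complete when its span over the query
  profile's match columns covers at least 90% of the query width — the
  span is measured on the profile, not the parent sequence, because the
  rule is about coverage *of the query*.
* **Pseudodimers.** Two complete non-overlapping hits on one parent are
  split at `s = floor((end1 + start2)/2)`; the halves tile the parent
  exactly (`1..s`, `s+1..L`) and reference each other symmetrically. More
  than two hits split recursively at successive midpoints left to right;
  this case is a generalisation beyond the two-domain rule and its
  provenance tags (first half N, the rest C) are a package convention.
* **Single-domain parents** are trimmed to the hit interval, so accessory
  domains (the αCD) do not leak into the domain alignment.

## Clustering and alignment

* **Identity** = identical aligned pairs / aligned columns (terminal gaps
  included, double gaps impossible in pairwise global alignment), from a
  BLOSUM62 global alignment with gap open 11 / extend 1. One convention
  had to be fixed; this is the most common one, and the published "31%
  identity" figure is checked with tolerance for exactly this reason.
* **Greedy clustering** visits sequences longest-first (ties by id) and
  joins the first representative at or above the threshold — the
  centroid-greedy behaviour of common clustering tools, without their
  coverage criterion (identity alone decides). A post-hoc verification
  pass recomputes every member→representative identity.
* **Tiers.** Plants 85%, αCD-bearing photosynthetic bacteria 70%, other
  photosynthetic bacteria 65%, everything else 60%; pseudodimer partners
  of representatives are retained; anchor proteins are always kept.
* **Seed-anchored alignment.** The seed rows are frozen homology: new
  sequences are aligned to the profile of the growing alignment and can
  only add shared all-gap columns, never rearrange seed columns. Guide
  order is decreasing profile score. Keep-length addition aligns a query
  to the profile at fixed width; query residues falling in insertions are
  reported and dropped.

## Phylogenetics

* **Models.** LG and VT exchangeabilities with their published
  frequencies are bundled as data files; frequencies may instead be
  counted from the alignment ("empirical"). A 3-state toy model (TOY3)
  with deliberately unequal exchangeabilities and frequencies makes
  exhaustive-enumeration oracles tractable in tests. Q is normalised to
  one expected substitution per unit time; P(t) comes from the symmetric
  eigendecomposition (π^½ similarity transform).
* **Likelihood.** Felsenstein pruning over unique column patterns with
  multiplicities; gaps and unknowns are missing data (partial vector of
  ones); per-node, per-pattern rescaling prevents underflow. Rate
  heterogeneity is off by default (the model strings this pipeline mirrors
  name no gamma term); a discrete-gamma mixture (category medians,
  renormalised to mean one) is available on the likelihood function.
* **Distances.** Pairwise ML distances under the same model, by a
  geometric grid over [1e-4, 20] then vectorized golden-section
  refinement. The equilibrium-frequency term is constant in t and dropped
  during optimization.
* **Search.** NJ start tree (negative branch lengths clamped to zero,
  ties broken toward the smallest taxon-id pair), then sweeps of exact
  per-branch Brent optimization in [1e-8, 20] — partials are updated
  ancestor-first within a sweep so every one-dimensional problem is the
  true current likelihood and lnL is monotone — then best-improving NNI
  moves evaluated from cached partials at current branch lengths, with a
  short branch-length sweep after each accepted move.
* **Bootstrap.** Plain nonparametric column resampling (multinomial over
  patterns). Each replicate is inferred with a fast fixed recipe — NJ on
  ML distances, one branch-length sweep, one NNI round — and an edge's
  support is the percentage of replicates containing its bipartition.
  Supports live on non-trivial bipartitions only (both sides ≥ 2 leaves).
  The rapid-bootstrap heuristic and convergence stopping of the original
  large-scale runs are not emulated; replicate counts are explicit.
* **Collapse.** Internal edges with support strictly below the threshold
  (default 70) contract into polytomies; edges at exactly the threshold
  survive.
* **Placement (EPA).** For each edge of the reference tree the query
  attaches at the edge midpoint by a pendant branch whose length is the
  only parameter optimized; the per-edge log-likelihood table and argmax
  are reported.
* **Rooting.** On the unrooted tree, the MRCA clade of the two anchor
  taxa is the smallest edge-side containing both; the root splits the
  edge above it at its midpoint. This is deterministic (ties break
  lexicographically), idempotent, and preserves leaf-to-leaf path
  lengths.

## Clade mapping

A subfamily's clade is the **largest clade containing all of its anchors
and no anchor of any other subfamily** — the single rule that formalises
"assigned by the presence of the corresponding anchor protein in that
clade". Assignment runs on the collapsed tree, so weakly supported
attachments fall to "unassigned" rather than forcing a label; placed
queries take the unanimous label of the leaves on one side of their best
edge, else "unassigned". Organisms count as photosynthetic when their
proteome has strictly more than 10 proteins under the photosynthesis GO
term; proteomes pass the quality filter when flagged reference or
nonredundant or when BUSCO completeness exceeds 75% (missing BUSCO does
not pass). Presence is recorded per genus (a filled cell means at least
one member of the genus has the subfamily); copy numbers are plain
per-organism tallies.

## Structure comparison

* **Superposition** by Kabsch SVD with the reflection excluded
  (det = +1); inputs must be ≥ 3 non-collinear paired points.
* **Backbone RMSD** pairs chains greedily by sequence identity, takes
  residue correspondences from a global sequence alignment, uses N, CA,
  C, O of aligned pairs with all four atoms present on both sides, and
  performs one rigid superposition over the whole dimer. Which residues
  the published number included is not recoverable, so agreement with it
  is tolerance-based.
* **SASA** by Shrake–Rupley sphere sampling: 960 deterministic
  golden-spiral points, probe 1.4 Å, fixed radii C 1.70 / N 1.55 /
  O 1.52 / S 1.80 / H 1.20 / P 1.80 Å (unknown elements fall back to
  1.70 Å with a warning). Interface burial is
  ΔSASA = SASA(A) + SASA(B) − SASA(A∪B); both the total and the half
  convention are always reported because published interface areas use
  either without saying which.
* **Salt bridges**: side-chain N of Arg/Lys/His within 4.0 Å of a
  side-chain carboxylate O of Asp/Glu across the partition.
* **Cis peptides**: ω = dihedral(CAᵢ, Cᵢ, Nᵢ₊₁, CAᵢ₊₁) with |ω| ≤ 30°;
  bonds across chain breaks (C–N > 2.5 Å) are skipped. The 30° and 2.5 Å
  values are standard conventions, stated here because no source fixes
  them.
* **Chamber volume**: 0.5 Å grid, probe-inflated atoms blocked, flood
  fill from the bounding box; interior voids are unreachable free cells.
  The helix-capacity estimate divides by 170 Å³ per helical residue — an
  explicit order-of-magnitude constant; the "fits a TMD of ~22 residues"
  style of statement is treated as qualitative.

## Synthetic families: what they emulate, and what they don't

The default family (`FamilyConfig`) is the package's study condition:

* a fixed ultrametric 8-species backbone — two cyanobacteria, two
  single-celled plants, four land plants (depth 1.0 time units, 0.4
  substitutions/site per unit);
* four subfamilies (Get3a, Get3b/c, Get3d, ArsA) radiating before the
  species root with stems 0.35–0.5 substitutions/site, then evolving by
  duplication/loss (λ = μ = 0.15 per lineage per unit time) inside the
  species tree. One copy per species lineage is exempt from loss, so
  every subfamily is present in every species unless deliberately lost —
  the conditioning that matches the observed "at least one per genome"
  pattern and guarantees the anchors exist; the unconditioned process
  (used when checking the analytic birth–death mean) is also available;
* forced Get3d loss in the single-celled plants, αCD appended to every
  Get3d gene, and ArsA tandem fusions (probability 0.6 per species with
  two or more copies, 16-residue linker);
* 500-site domains (and 110-site αCDs) evolved under LG, indel-free by
  default so true alignments are exact; proteome tables whose GO
  photosynthesis counts are ≥ 11 for photosynthetic species and ≤ 10
  otherwise.

Inference in the pipeline uses VT with model frequencies — mirroring the
focused reconstruction this pipeline reproduces — while generation uses
LG, so a mild, realistic model misfit is part of the default condition.
Bootstrap uses 30 replicates in the pipeline default; this desk-scale
count (support granularity 3.3%) is a deliberate problem-size choice, as
are the 20-seed panel, 50 placement trials and 20 NJ trees in the
acceptance script.

Passing on these families shows the chain of inference is correct under
its own assumptions: site-independent substitution, no indels by default,
no horizontal transfer, no alignment error in the seed, clean taxonomy.
Real proteomes violate all of these to varying degrees — fragmentary gene
models, domain-boundary noise, rate heterogeneity across sites and
lineages, and biased taxon sampling are the main effects the generator
does not emulate — so the benchmark validates the machinery, not the
biological conclusions one would draw from any particular real dataset.

## Known limitations

* The PSSM is not a full profile HMM: no position-specific gap costs, no
  local/glocal distinction; E-values are replaced by the empirical null.
* NNI-only topology search can stop at local optima that SPR would
  escape; the start tree is NJ, not parsimony.
* Progressive alignment is not consistency-based; its optimum equals the
  exhaustive sum-of-pairs optimum only on easy instances.
* Interface areas inherit the point-sampling resolution of SASA (~1–2%)
  and the unstated convention (total vs half) of published numbers.
* Checks against values printed for deposited crystal structures require
  the coordinate files locally; they are not redistributed with the
  package.
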