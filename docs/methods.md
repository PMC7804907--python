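# Methods

## Model and assumptions

The screen treats the interactome as an undirected, unweighted graph of gene
symbols; evidence labels (structure3D, Y2H, kinase_substrate, signaling,
literature) annotate edges but never weight them. The unit of analysis is a
(drug target set *A*, disease module *B*) pair, scored by the closest
proximity

    <d_AB> = ( Σ_{a∈A} min_{b∈B} d(a,b) + Σ_{b∈B} min_{a∈A} d(a,b) ) / (|A|+|B|)

standardized as z = (d − d̄)/σ_d against a degree-preserving permutation
null, with significance at z < −1.5 and p < 0.05. The null's premise is that
degree is the dominant confounder of network distance: resampling both sets
with matched degrees asks whether *these particular* genes are closer than
generic genes of the same connectivity. By default the proximity universe is
the full loaded graph; a `restrict_to_lcc` / `--lcc-only` flag restricts it
to the largest connected component for users who prefer a fully reachable
universe.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `n_perm` | 1000 | permutation count; p-resolution is 1/(n_perm+1) |
| `z_cut` | −1.5 | z threshold of the significance call |
| `p_cut` | 0.05 | empirical p threshold of the significance call |
| `min_bin_size` | 100 | minimum nodes per degree bin for the null |
| `cutoff_nM` | 10000 | affinity cutoff (10 μM, inclusive) for curation |
| `cpm_threshold` | 0.5 | per-sample expression floor (CPM) |
| `sample_fraction` | 0.9 | strict fraction of samples that must pass |
| `radius` | 1 | EGO neighborhood radius (hops) |

## Numerical and procedural choices

* **Degree binning.** Nodes are sorted by degree, grouped by exact degree
  value, and adjacent groups merge until every bin holds ≥ `min_bin_size`
  nodes (the last bin merges backward). A template gene's replacement is
  drawn uniformly, without replacement within one set, from its own bin.
  Because a template gene is always a member of its bin, bins cannot be
  exhausted and no widening step is ever needed. On small graphs the merging
  degrades toward a single bin, i.e., uniform resampling.
* **Both sets are permuted** each iteration, independently; the A-sample and
  B-sample may overlap each other, as the observed sets may.
* **p-value.** One-sided, add-one estimator p = (#{d_perm ≤ d_obs} + 1) /
  (n_perm + 1); never exactly 0. σ_d uses the population (divide-by-N) form,
  the usual convention for standardizing against an empirical null. These
  choices are stated rather than inherited: the sidedness and estimator of
  the original screen are not documented, so the package fixes and labels
  its own.
* **Degenerate null.** σ_d = 0 (e.g., both templates cover the whole node
  set) sets z = 0 and flags the row `degenerate_null` instead of dividing by
  zero.
* **Infinite distances.** A gene of one set with no finite distance to the
  other set is excluded from both the numerator and the |A|+|B| normalizer;
  the excluded counts are reported on every result so data loss is visible.
  A pair with no finite cross-distance at all is an error (observed) or a
  dropped permutation (null).
* **Shortest paths** come from per-source BFS, cached per graph and shared
  across all permutations of a screen; memory grows only with the number of
  distinct BFS sources actually visited, never the full all-pairs matrix.
* **Seeding.** The screen derives one child seed per pair from a SHA-256
  hash of (master seed, drug_id, set_id), so row results are independent of
  screen ordering; every generator and test uses explicit
  `numpy.random.default_rng` seeds, and same-seed reruns are byte-identical.
* **Specificity.** Tissue values are arithmetic means of per-sample CPM
  within tissue (optional log2(x+1) first); δ_E is the sample (n−1) standard
  deviation — the upstream convention is undocumented, so this one is pinned
  by an oracle test. Constant profiles score 0 with a flag. Brain regions
  are pooled (mean of region means) *before* scoring; pooling after scoring
  gives different numbers, and a regression test pins the order. "Positive
  brain specificity" means z_E(gene, brain) > 0.
* **Curation.** Affinities are normalized to nM at ingest (nM, μM, M
  accepted); the ≤ 10 μM cutoff is inclusive. A drug keeps a target if ANY
  of its records for that target passes — an inclusive rule chosen because
  source databases report conflicting measurements and the screen favors
  recall at this stage.
* **Views.** All three views are exact induced subgraphs. EGO defaults to
  radius 1 and includes edges among neighbors (induced, not just spokes).
  LCC ties on component size break toward the component containing the
  lexicographically smallest gene. MOA keeps isolated nodes, flagged, with a
  prune option.

## Synthetic data

The fixture generators stand in for a real interactome, expression atlas,
and affinity databases; every planted quantity is written to a YAML manifest
so tests compare against construction-time truth.

* **Graphs** default to Barabási–Albert (n = 300–500, m = 3) because
  degree-matched permutation behavior is only meaningfully exercised on
  heavy-tailed degree distributions like a real interactome's. The planted
  screen (5 drugs × 4 modules of 12 genes, 6 targets per drug) makes MOD0 a
  connected cluster (internal density 0.6) and DRUG0's targets direct
  neighbors of it; the remaining drugs are planted negatives whose targets
  sit at distance ≥ 2 from every module, so the ground truth covers
  negatives as well as the positive. With the permutation null, exclusive
  recovery of the planted pair holds with high probability but not
  certainty: a planted negative can still cross both thresholds by chance on
  some seeds, which is the screen's real false-positive behavior, not a
  defect.
* **Expression** fixtures use a log-normal background (floor 0.6 CPM so
  expressed calls are unambiguous), planted tissue-specific genes at a
  stated fold elevation (default 8×), planted below-threshold gene×tissue
  blocks, and an optional exact-90% edge-case gene.
* **Affinity tables** plant an exact survivor count including rows at
  exactly 10,000 and 10,001 nM.

What the fixtures do **not** emulate: real modular biology, correlated
expression across tissues, measurement noise in affinities, or the size of a
production interactome (~17,000 nodes). Passing tests therefore demonstrate
correctness of the statistics and plumbing, not biological recall on real
data; problem sizes (300–500-node graphs, 200–1000 permutations, 500
calibration repetitions) were chosen as the smallest at which the null's
calibration and the planted signal are statistically unambiguous.

## Known limitations

* Only the "closest" proximity variant is implemented (no shortest, centre,
  kernel, or separation variants), and distances are unweighted.
* Gene identity is symbol normalization (upper-case, strip) plus the
  user-supplied ortholog table; there is no identifier-mapping service.
* The expressed-call rule needs per-sample values; data supplied only as
  tissue means cannot be re-thresholded.
* The permutation p-value's resolution is bounded by n_perm; ranking very
  significant pairs by p alone saturates at 1/(n_perm+1).
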