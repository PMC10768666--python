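# Methods

## Problem and model

The package quantifies the overlap between two metabolome measurements of
one plant holobiont: (i) the host leaf, profiled through a crude extract and
a set of preparative (MPLC) fractions that enrich minor constituents, and
(ii) a community of fungal endophyte strains isolated from the same leaf and
profiled individually after culture. All samples are untargeted LC-MS/MS
runs in analytical triplicate, accompanied by solvent blanks and
uninoculated-culture-medium blanks. The unit of analysis is the *feature*:
an aligned ion with consensus m/z and retention time, a representative MS/MS
spectrum, and per-sample presence calls. "Overlap" is deliberately defined
on presence calls rather than raw detections, so that single-replicate
noise cannot create spurious host-fungus sharing.

## Feature-table processing

Order of operations: per-injection deduplication → isotopologue grouping →
MS2-required filter → join alignment → blank filter → replicate filter →
replicate averaging + row normalization → origin split. The order follows
the upstream processing conventions of MZmine-style workflows; every step is
idempotent, and the replicate/blank rules are validated against independent
brute-force rule oracles in the test suite.

Parameters (defaults):

| parameter | default | meaning |
|---|---|---|
| dedup | 8 ppm / 0.03 min | duplicate collapse within one injection |
| isotope grouping | 8 ppm / 0.02 min, charge ≤ 2 | merge M+1/M+2 at spacing n·1.003355/z |
| alignment | 10 ppm / 0.04 min, weights 10/10 | join-aligner tolerances and score weights |
| blank ratio | 0.1 | row dropped when blank mean > ratio × best biological sample mean |
| retention | 3 of 3 replicates in ≥ 1 sample | feature kept in the table |
| co-occurrence | ≥ 2 replicates | feature called present in a sample |

ppm tolerances are evaluated on the mean of the two masses; RT tolerances
are absolute minutes. Alignment assigns candidate (feature, row) pairs
greedily best-score-first with deterministic tie-breaks (higher score, lower
row index, lower feature id); row consensus is the running member mean. The
replicate-retention wording in the source protocol is ambiguous; it is
implemented as "all replicates of at least one biological sample" and
exposed as `n_replicates_required`. Sub-threshold co-occurrence intensities
are zeroed rather than kept, which makes presence calls and intensities
consistent; this is a package choice, exposed by the same filter. Blank
subtraction removes rows entirely (no intensity subtraction), with the
ratio 0.1 configurable since no threshold is standard. The optional spectral
gate on alignment (representative-MS2 similarity ≥ 0.7 to merge) exists but
is off by default; its role in the original join aligner is ambiguous.

## Modified cosine and networking

Intensities are √-scaled and L2-normalized; peaks i of spectrum a and j of
spectrum b are pairable when |mz_a(i) − mz_b(j)| ≤ 0.02 Da directly, or
after shifting by Δ = precursor(b) − precursor(a). The score is the exact
maximum-weight one-to-one matching over pairable pairs, computed with the
Hungarian algorithm (`scipy.optimize.linear_sum_assignment`); scores within
1e-12 of 1 are snapped to exactly 1 so self-similarity is 1.0. An exhaustive
recursive matcher serves as the oracle in tests; matchms's greedy
ModifiedCosine is used only as an external cross-check on spectra where
greedy and optimal coincide.

Edges require score > 0.7 and ≥ 7 matched peaks (the strict reading of
"more than six"; a compatibility flag restores ≥ 6), must be mutual top-10
neighbors (ties at rank 10 all kept), and families larger than 100 nodes are
reduced by repeatedly deleting the globally lowest-scoring edge inside any
oversized component (ties broken lexicographically on node ids). The
fragment tolerance for networking (0.02 Da) is the common GNPS default; the
annotation searches use their own stated 0.01 Da.

## Annotation cascade

1. **MS1**: adduct match (0.01 Da) over five common positive-mode adducts,
   restricted to library compounds reported in the taxonomic family of the
   analyzed sample.
2. **MS2**: modified-cosine library search at 0.01 Da with parent-mass gate
   0.01 Da, σ ≥ 0.2, ≥ 6 matched peaks, top 50 candidates.
3. **Taxonomic re-ranking**: `final = σ + τ·(R−d)/R`, τ = 1, R = 7, d = the
   0-based rank index (species…kingdom) of the lowest common ancestor
   between the sample's taxa and the candidate's closest source taxon
   (d = 7 when only the root is shared). The exact functional form of
   published taxonomically-informed scoring varies; this linear bonus keeps
   the stated property — a bonus inversely related to taxonomic distance —
   is monotone in σ and d, and never changes the candidate set. The re-sort
   is stable.
4. **Consensus class**: each node pools the rank-1 candidate votes of itself
   and its 1-hop network neighbors (radius configurable), weighted by final
   score, per ontology level; ties go to the lexicographically smallest
   label. Candidates matching the consensus gain 0.1 per matched level (an
   invented, configurable magnitude), are re-sorted, and the top 3 are kept.
   Re-ranking order is reweight → consensus.
5. **Identity**: standards match at 20 ppm precursor and plain cosine ≥ 0.8
   gives the confirmed tier.

## Synthetic studies

The generator mirrors the field campaign it stands in for: 15 strains × 2
extracts, 47 host fractions + 1 crude extract, triplicates, 2 solvent + 2
media blanks (82 samples, 246 injections), mass window 130–1950 Da, RT
domain 0–8 min (7-min gradient + 1-min isocratic). Metabolites are drawn
with ≥ 0.05 Da mass separation (so parent-mass gates are unambiguous),
random fragment templates of 8–14 peaks with ≥ 0.5 Da spacing, lognormal
base abundances (median 5e6, σ 0.8) against a limit of detection of 4e5.
Host-produced metabolites elute over fractions as a discretized Gaussian
(center uniform over fractions, width 0.8–2.5 fractions, rows sum to 1);
the crude extract sees the base abundance scaled by a dilution factor of
0.05, which makes fractionation genuinely enriching (most metabolites clear
the LOD only in fractions). Only the protonated adduct is emitted by
default, plus an M+1 isotope feature (no MS/MS) at 0.25 relative intensity.
Noise: multiplicative lognormal intensity scatter (σ 0.3 default), uniform
m/z jitter (±2 ppm), RT jitter (±0.005 min), per-detection dropout (0.1),
and ≤ 5%-intensity decoy fragments. Solvent contaminants appear in every
injection and media metabolites in media blanks and fungal extracts, so the
blank filter has real work to do.

What the generator does **not** emulate: chromatographic peak shapes, raw
scans, isotope fine structure, adduct diversity, in-source fragmentation,
retention-time drift, or real spectral similarity structure between related
compounds (fragment templates are independent, so molecular families are
mostly singletons at zero noise). Passing recovery tests therefore
demonstrates that the *rules* of the pipeline are implemented correctly and
are recoverable under the stated noise — not that the pipeline would achieve
these rates on real chromatograms.

The ground truth exposes `effective_membership()`: the category each
metabolite can be recovered as, given the LOD (a metabolite whose host-side
abundance never clears the LOD in any fraction or the crude extract is not
recoverable as host-detected by any method). Recovery precision/recall are
scored against this detectability-aware truth; noise and dropout losses
still count against recall.

## Numerical choices

- Reported percentages use decimal half-up rounding; 0 decimals for the
  headline shared share, 1 decimal for enrichment shares.
- All tie-breaks (duplicate groups, alignment, top-K, edge removal,
  consensus labels) are deterministic: score first, then lexicographic ids.
- Every generator output is fully determined by (design, seed); fixtures
  serialize byte-identically across runs.
- Degenerate inputs: empty spectra score 0; empty studies write valid
  header-only files; all-zero intensity rows are rejected before
  normalization; samples with missing replicates are an explicit error.

## Problem sizes used in validation

The test and acceptance runs use the full design (246 injections) with 90
ground-truth metabolites (40 host-only / 30 strain-specific / 10
multi-strain / 10 shared), which yields feature tables of ~80 aligned
features — large enough to exercise every rule, small enough that the whole
validation chain runs in seconds. Oracle-equivalence checks run on 500
random spectrum pairs (≤ 8 peaks), 200 random graphs (≤ 60 nodes) and 1,000
random detection tensors.

## Known limitations

- Negative-ionization runs are supported by configuration (the mode tag is
  carried through) but all validation is on positive-mode conventions.
- The headline counts of the emulated study (tens of thousands of features)
  derive from its deposited raw data and are not reproducible from a desk;
  the package reproduces the study's *arithmetic* exactly and its *rules*
  at synthetic scale.
- The CLI's non-simulate stages recompute the in-memory chain from the
  simulated fixture rather than re-reading lossy intermediate CSVs; the
  written intermediates are for inspection and downstream tools.
- Consensus-class scope, bonus magnitude, shared-cluster node evidence
  (one node suffices) and the blank ratio are package choices where the
  emulated protocol is underspecified; all are parameters, and none should
  be read as the original authors' definitions.
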