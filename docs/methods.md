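# Methods

## Coordinate and data conventions

All intervals are 0-based half-open on the sense strand of an rRNA
reference; probe FASTA headers alone use 1-based inclusive coordinates.
Coverage depth at a position is the number of aligned read bases covering
it: only primary, mapped, non-supplementary alignments above a configurable
MAPQ floor (default 0) contribute; read deletions contribute nothing at the
deleted positions and insertions contribute nothing anywhere. The MAPQ
floor is configurable precisely because depth-input provenance varies
between mappers; 0 is the least-surprising default.

## Region discovery

A position is *covered* when its depth reaches `min_base_depth` (default 1:
any coverage seeds an interval). Maximal covered runs separated by at most
`max_merge_gap` uncovered bases (default 3) are merged transitively. A
region's score is the arithmetic mean depth over its interval — mean rather
than peak or total because it is scale-free with respect to region length —
and regions with mean depth strictly below `min_region_depth` (default
500×) are removed, so a region at exactly 500× survives. The
`top_k_per_sample` (default 50) deepest regions per sample are pooled
across samples; overlapping or touching intervals are unioned, the merged
score is the maximum of the contributors (preserving "most abundant
anywhere" semantics for downstream ranking), and the sense sequence is
extracted from the reference.

With the default `min_base_depth` of 1, any nonzero sequencing background
makes an entire reference one covered run; when coverage tracks carry a
background (as the synthetic tracks with `background_depth > 0` do),
`min_base_depth` should be set above the background level. The planted-
hotspot recovery experiments use background 80× and `min_base_depth` 150.

Ties in depth ranking break toward the longer interval, then the smaller
`(ref_id, start)`; every stage is deterministic.

## Pairwise identity and redundancy

Region-versus-region comparison uses semi-global alignment with affine gaps
(match +1, mismatch −1, gap open −2, gap extend −1): the shorter sequence
must align end to end while the longer sequence's terminal overhangs are
penalty-free, so a length difference does not depress identity but a short
spurious overlap cannot masquerade as redundancy (with both ends free on
both sequences, the score-optimal alignment of two unrelated regions is a
tiny perfect overlap — a failure mode this convention removes). Identity is
matches divided by alignment columns between the first and last aligned
base pair; internal gap columns count as non-matching, terminal overhang
columns are excluded. Both strands are compared and the higher identity
kept. The pair is canonically ordered before alignment, so identity is
exactly symmetric even when co-optimal alignments disagree.

Pairs at identity ≥ `identity_threshold` (default 0.80, inclusive) form
edges of an undirected graph; connected components (single-linkage, so
chains collapse) each contribute one representative: the deepest region,
ties broken as above. All-versus-all alignment is quadratic but cheap at
the intended scale (≤ 450 candidates).

Existing-probe exclusion aligns each probe *locally* to each region and its
reverse complement; a region is eliminated at identity ≥ the same threshold
over a span of at least 80% of the probe length, so a ~10-nt fluke match
cannot eliminate a region. The alignment engine is Bio.Align's pairwise
aligner; the test suite checks it against an independent exhaustive
enumeration of all alignments of short sequence pairs.

## Probe tiling

Regions are tiled with non-overlapping `probe_length` (default 50 nt)
windows from the region start; a remainder of at least half a probe length
earns one extra window right-anchored at the region end. Regions shorter
than one probe are extended symmetrically on the reference (clipped at
reference ends). The tiling rule is a package design choice — probe spacing
of the published pools is not public — chosen to cover each region with the
fewest oligos, matching the practical constraint that total probe mass per
reaction is limited. Windows containing non-ACGT bases are shifted by up to
±5 nt (smaller magnitude first, leftward preferred) to find a clean frame,
else skipped with a warning. Exact duplicate probe sequences are emitted
once. No melting-temperature, GC or secondary-structure filtering is
applied: the probes are plain 50-mers of standard DNA bases.

## In-silico evaluation

A read is classified rRNA when it shares at least one canonical 31-mer
(lexicographic minimum of k-mer and reverse complement) with the reference
index — the simplest membership rule, sufficient for error-free or
low-error synthetic reads; it is not a reimplementation of production
classifiers, whose sensitivity/specificity trade-offs are out of scope.
Reads shorter than k are classified clean.

RNase H depletion is modeled geometrically: an rRNA read with reference
footprint `[s, e)` is *depletable* when the union of probe source intervals
on its reference covers at least `min_overlap_fraction` (default 0.5,
inclusive) of the footprint. The report separates `rrna_fraction` (what a
classifier would call rRNA) from `residual_rrna_fraction` (rRNA not
predicted to be depleted), because in real data the two are conflated by
classifier error. Two deliberate simplifications: hybridization
thermodynamics are ignored, and a probe only credits intervals on its own
source reference — cross-hybridization to homologous rRNAs of other taxa is
not modeled. The latter makes the evaluator *conservative* whenever the
redundancy filter collapses homologous regions from different species: in
reality the retained representative's probes would also deplete the
homologs, but the evaluator scores those reads as residual.

## Synthetic data

`simulate_community` draws one random ancestral SSU (1,500 nt) and LSU
(2,900 nt) and derives each species by independent per-site substitution at
rate `divergence`. The default divergence of 0.15 per lineage gives an
expected inter-species identity of `(1−d)² + d²/3 ≈ 0.73`, below the 0.80
redundancy threshold, so distinct species legitimately require distinct
probes — appropriate given the evaluator's no-cross-hybridization
simplification above. Real rRNA conservation is domain-structured rather
than uniform; the simulator does not model secondary structure or conserved
cores.

`plant_coverage` writes a flat background with disjoint hotspot intervals
at target depths (optionally with ±10% per-position integer jitter; jitter
is off in unit tests and on in the demo bundle). `simulate_reads`
partitions the read count exactly (`round(clean_fraction·n)` clean reads),
draws rRNA reads from references proportional to abundance with uniform
starts — restricted to given source intervals when the study models reads
concentrating in undepleted segments — and applies substitution-only errors
so footprints stay exact (no indels; a documented limitation). Clean reads
are rejection-sampled random sequences sharing no canonical k-mer with the
reference index: they test the classifier's contract adversarially rather
than imitating mRNA.

The default study (`default_scenario`) is a 10-species community, 3 samples
sharing two planted hotspots per reference (120–220 nt, mean depth
600–1500×, per-sample depth draws), and 4,000 reads (30% clean, rRNA reads
drawn from the hotspot intervals). These sizes keep a full
design-and-evaluate cycle under ten seconds while leaving every stage
non-trivial (40 pooled regions, ~130 probes). All randomness flows from one
seed through `numpy.random.SeedSequence`-derived streams; identical seeds
give byte-identical outputs, and the CLI manifests contain no timestamps
for the same reason.

## Known limitations

- The depletion model is binary interval overlap; it cannot rank probes by
  affinity or predict partial depletion.
- No off-target (mRNA cross-reactivity) screening of designed probes.
- The redundancy filter's quadratic all-vs-all alignment is not intended
  for candidate sets orders of magnitude beyond the per-sample top-50
  design point.
- The simulator's uniform substitution model understates the conserved-core
  structure of real rRNA; passing recovery tests demonstrate correctness of
  the interval logic, not performance on real alignments.
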