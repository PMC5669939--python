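# Methods

## Scope and design

`evcargo` models the computational analysis of EV small-RNA cargo from a
multi-cell-line experiment: read-level assignment to a miRNA reference,
isomiR identification, compositional quantification, sample clustering,
dual-library snoRNA profiling, and two vesicle-level biophysical summaries.
It deliberately works in *miRNA space*: reads are assigned directly against
mature miRNAs in their hairpin context rather than via a genome alignment
step. A genome pass mainly filters foreign sequence; for libraries known (or
simulated) to derive from the reference transcriptome it adds nothing to
isomiR resolution, while cross-miRNA ambiguity is handled explicitly by the
assignment tie rules. Numerical concordance with any specific aligner's
counts is not a goal.

## Read assignment

Alignment is ungapped: the isomiR concept used here covers end
addition/trimming and internal substitutions, not indels within the read
body. A placement of read r on mature m is indexed by the 5' offset
δ₅ = read_start − mature_start on the hairpin; the 3' offset
δ₃ = read_end − mature_end then follows from the read length. Conventions:

- δ₅ < 0 is a 5' extension and must be templated (copied from the hairpin);
  biogenesis changes 5' ends by alternative cleavage, not tailing, so a
  placement starting before the hairpin is invalid rather than tailed.
- δ₃ > 0 is a 3' extension, which may be templated or non-templated. A
  suffix of the extension that mismatches the hairpin — or lies beyond its
  end — is recorded as tail; tail length is bounded by
  min(max_tail, max(δ₃, 0)), i.e. the tail can never reach into the
  canonical span. δ₃ includes the tail.
- Any other mismatch in the non-tail span is a substitution at a
  canonical-relative, 0-based position (positions may be negative for
  mismatches within a templated 5' extension).

For a fixed placement the tail split is chosen to minimize
(n_substitutions, tail_length): the longest admissible tail absorbs the most
terminal mismatches, after which the tail is shrunk while its innermost base
matches the hairpin (a matching base is templated extension, not tail).
Across placements the score (n_subs, |tail|, |δ₅| + |δ₃|) is minimized
lexicographically; exact ties resolve by ascending miRNA id, then ascending
δ₅, so results are independent of reference file order. Reconstructing the
read from hairpin + offsets + substitutions + tail is exact and tested.

Default bounds (|δ₅| ≤ 3, |δ₃| ≤ 5, tail ≤ 3, subs ≤ 2, reads ≥ 16 nt) are
package choices covering the bulk of reported isomiR variation while keeping
spurious cross-assignment of unrelated reads negligible.

`assign_library` computes the same result as per-read search; a vectorized
prefilter (total mismatch count against each candidate window, counting
positions beyond the hairpin as mismatches) discards placements that provably
violate the bounds, since the tail can absorb at most `max_tail` terminal
mismatches. Equivalence to a brute-force enumeration over all (miRNA, δ₅,
tail split) placements is asserted in the test suite on ~10⁴ enumerated
reads.

## isomiR identity, classes and names

An isomiR is the tuple (miRNA, δ₅, δ₃, substitutions, tail); the canonical
read is (m, 0, 0, ∅, ""). Six classes partition key space according to which
ends differ and whether substitutions are present; a non-templated tail
counts as a 3'-end variation (tailing is end modification, not editing).
Names follow an invertible grammar
`id|5e{±n|0}|3e{±n|0}|s:{pos}{ref}>{alt};…|t:{tail}` with `-` for empty
fields and the bare id for the canonical key; parse(name(k)) = k is tested
over random keys.

Variant-class histograms are computed per (miRNA, sample) among isomiR
reads only, so percentages sum to 100 for any miRNA with at least one
isomiR read; whether such compositions should include canonical reads is
ambiguous in general, so the inclusive variant is available behind a flag.

## Quantification

Expression is compositional: percent of total assigned counts per sample.
Group values are replicate means (columns still sum to 100); a feature is
retained when its group mean reaches the threshold — default 0.05%,
inclusive — in at least one group. Top-N lists rank by descending percent
with ties broken by feature id; a feature is "shared" when it reaches the
top-N of ≥ 2 groups (membership, not above-threshold presence — the
alternative reading exists but is not implemented as the default). The
isomiR fraction is isomiR reads / (canonical + isomiR reads) per sample.
Percent normalization stands in for count-model normalizations (e.g.
TMM-style) deliberately: all downstream statistics here are defined on
compositions, and no differential testing is performed.

## Clustering and replicate coherence

Profiles are log2(percent + pseudocount) with pseudocount 0.01 percent —
half the retention threshold, so zeros map to a finite floor just below the
least-expressed retained features. Sample distance is 1 − Pearson over
features (in [0, 2]); linkage is average (UPGMA). The agglomeration is
implemented directly (O(n³), trivially fast at sample scale) so that ties
merge the lexicographically smallest pair of clusters, keyed by minimum leaf
id, making the tree invariant to feature and sample order; the merge
heights equal the mean pairwise distance between the joined leaf sets,
which the tests verify against an independent oracle that recomputes those
means from the raw distance matrix. Trees serialize to Newick. A group is
replicate-coherent when its samples form a clade (a subtree containing them
and nothing else). Distance and linkage are configuration, not science: no
claim is made that a particular published dendrogram used the same choices.

## snoRNA dual-library profiling

snoRNAs (60–300 nt) appear both as full-length molecules in
whole-transcriptome (WTA) libraries and as sub-40-nt fragments in
size-selected small-RNA libraries. Library type is a given label, not
inferred; fragments are attributed to their parent snoRNA species by exact
substring match (exact because the simulator introduces no errors into
fragments; real fragment data would need a tolerant matcher). For each
library the union of the per-group top-20 species is summarized by box
class; the overlap between the WTA and small unions is reported as
intersection size and Jaccard index.

## Biophysics

AI = A(519 nm)/A(650 nm) from a UV-Vis spectrum, linearly interpolating
off-grid wavelengths (spectra are acquired at 1 nm steps, so interpolation
error is negligible); AI is scale-invariant in absorbance. The weighted mean
diameter is Σdᵢnᵢ/Σnᵢ over histogram bins with dᵢ ≥ 30 nm (inclusive:
objects *below* 30 nm are excluded). Count-weighting and
fraction-of-particles weighting coincide under this formula. Concentration
calibration against a liposome standard curve is out of scope.

## The synthetic-data generator

The generator defines the study conditions: 4 groups (cell lines) × 2
biological replicates, 60 miRNAs of which 14 form a shared abundant core and
3 per group are group-specific, a log-normal(0, 1.5) abundance background,
20,000 reads per sample by default (tests and the acceptance script size
runs between 800 and 25,000 reads per sample depending on what the check
needs), and a 10% snoRNA-fragment admixture from 40 snoRNAs (classes drawn
0.5/0.4/0.1 CD/HACA/scaRNA, lengths uniform on [60, 300] nt).

Abundance construction is deliberately guaranteed, not merely probable: core
miRNAs draw values strictly above the global background maximum in every
group, and group-specific miRNAs do the same in their own group with exactly
zero elsewhere, so recovery tests (core always in the top ranks; unique
top-N flags identify the planted features; replicates coherent) are
deterministic properties of the construction, with only multinomial sampling
noise between replicates.

The isomiR process per read: a templated ±1 5' shift with probability 0.05;
a 3' offset drawn from {−2…+2} with probabilities (0.03, 0.09, 0.78, 0.07,
0.03) — 3'-skewed, as end variation is in real libraries; with probability
0.05 (given a 3' extension) a 1–3 nt non-templated A/U tail replacing the
outermost templated bases; substitutions at rate 0.002 per canonical-span
base. Under these defaults ~29% of miRNA reads are isomiRs. Two
canonical-form constraints keep ground truth identifiable: tail bases are
resampled to differ from the templated hairpin base at their position
(otherwise the base *is* templated extension and the generative record would
not be the canonical description of the read), and substitutions are
restricted to the canonical mature span (a substitution inside a 3'
extension is indistinguishable from tailing). With these constraints the
assigner recovers the generative key — and hence the variant class — exactly
for every read, which the acceptance tests assert at 100% on 50,000 reads.

What the generator does not emulate: sequencing-error quality profiles,
adapter read-through, ligation bias, colorspace chemistry, cross-mapping
between homologous miRNA family members (reference sequences are i.i.d.
random, so family structure is absent), and any real isomiR generative
mechanism — its parameters are knobs, not estimates. Passing recovery tests
therefore demonstrates correctness of the pipeline's bookkeeping and
statistics under controlled variation, not performance on real libraries.

Biophysics inputs are generated as a two-Lorentzian plasmon spectrum
(peak 519 nm, aggregation shoulder 650 nm) whose mixture weight is solved so
the true AI is exact, and a log-normal size histogram (median ≈ 65 nm,
σ_log = 0.35, ≈ 230 particles — the small-EV regime peaking at 60–70 nm)
retaining sub-30 nm bins so the exclusion rule is exercised.

## Determinism and numerics

One `numpy` generator seeded from the single run seed drives each simulation
stage (stage offsets +1…+4 keep streams disjoint but all derive from the one
seed); identical config + seed gives byte-identical outputs, and the
pipeline manifest records SHA-256 digests to make this checkable. Percent
columns sum to 100 within 1e-9; correlation distances are clipped to [0, 2]
against rounding; counts are integers and fractional count inputs are
rejected rather than rounded. Degenerate inputs fail loudly: zero-total
samples, constant expression columns (undefined correlation), empty
references, unannotated snoRNA ids, spectra not covering 519–650 nm, and
histograms with no ≥ 30 nm mass all raise with the offending item named.

## Known limitations

- Ungapped assignment cannot represent indel-bearing variants.
- Multi-mapping is resolved to a single best assignment; abundant paralogs
  in a real reference would make that attribution order-dependent in ways
  the content-based tie rules only partially mitigate.
- The 0.05% retention threshold and all percent statistics inherit the
  closure constraint of compositional data; no log-ratio analysis is
  offered.
- Fragment attribution by exact substring match is simulator-faithful but
  too strict for error-containing real reads.
- The clustering oracle guarantees correctness of average linkage on
  1 − Pearson; other metrics/linkages are intentionally not configurable.
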