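# Methods

## The model

`immunopep` works with an immunopeptidome database: a proteome plus the set
of unique HLA class I and class II peptide sequences identified by MS in a
collection of biological samples. Three structures are derived from it.

**Density profiles.** For a protein of length `L` and a class selector
(`I`, `II`, `I/II` = detected in both classes, `I_short` = class-I peptides
shorter than 15 residues), the profile is the integer vector
`h[i] = number of peptide placements of the selector covering residue i`.
Placements are exact substring matches of unique peptide sequences; a
peptide placed twice in one protein contributes at both placements, and a
peptide matching several proteins contributes to each (razor-style single
assignment is available as a switch). Consequently
`sum(h) = Σ placement lengths`, which is checked as an invariant.

**Hotspots.** The data motivate "hotspots" — sub-sequences repeatedly
sampled for presentation — but no canonical boundary definition exists. We
use threshold-and-merge segmentation: threshold
`t = max(min_height, ceil(min_frac_of_max · max(h)))`, maximal runs with
`h ≥ t`, runs separated by fewer than `merge_gap` positions merged.
Defaults `min_height=2, min_frac_of_max=0, merge_gap=0`: the simplest rule
under which a hotspot is a region covered by at least two distinct peptide
placements. Profile similarity ("main-peak correlation") binarizes each
profile at `peak_frac=0.5` of its own maximum and returns the Jaccard index
of the masks, which encodes "overlap of the main peaks, ignoring smaller
peaks".

**MS-based neoantigen features.** For a candidate neoantigen with wild-type
(wt) peptide `p` on protein `q`:

* `nrMatchingPeptides_I(q)` — unique class-I database peptides with at
  least one placement in `q`;
* `matchScore_I(p)` — the class-I profile summed over `p`'s placement
  interval, maximized over all placements of `p` in the proteome
  (equivalently: total overlap length with all class-I placements); ties
  between placements are broken by `(protein_id, start)`;
* `exactMatchScore_I(p)` — `matchScore_I(p)` if `p` itself is a class-I
  database peptide, else 0.

Match taxonomy: **exact** (wt in either class set), **included** (wt a
proper substring of a longer detected peptide), **partial** (some detected
peptide covers the absolute position of the mutation at a placement of wt),
**none**. Exactness for `exactMatchScore_I` checks the class-I set only,
matching the `_I` suffix; `classify_match` checks both classes. No length
normalization is applied to `matchScore_I` (a raw sum); a normalized
variant can be derived by the caller.

## The evaluation harness

Candidates are compared by three routes:

1. **Rank-sum scans**: two-sided Mann–Whitney/Wilcoxon test per feature
   between immunogenic and control candidates, reported as −log10 p. A
   feature constant across all candidates is reported as 0 (no separation),
   not an error.
2. **Recovery curves**: candidates stably sorted by one feature (ascending
   for affinities, where low nM is strong), cumulative immunogenic count
   versus rank; the protein-presence filter removes candidates whose source
   protein has no mapped class-I peptide before ranking.
3. **SVM cross-validation**: control and immunogenic lists are each split
   into random halves (odd counts send the extra element to training, so 16
   immunogenic split 8/8 and the per-repeat score is bounded by 8 when
   `top_k=20`). An RBF-kernel SVM regressor is trained on the training half
   with targets +1/−1 and pinned LIBSVM-style defaults
   (`C=1, epsilon=0.1, gamma=1/n_features`); features are standardized with
   training-half mean/sd (no leakage; a flag disables it and the result
   records which mode was used). The test half is ranked by predicted value
   descending and the immunogenic count in the top 20 is averaged over
   repeats (default 2,000). With/without-MS comparisons share the seed, so
   the same split sequence is used for both runs (paired comparison).

Ties in the predicted value are broken by the repeat's random draw order
rather than a fixed canonical order. This is deliberate: with a completely
uninformative (constant) feature the ranking must be random-equivalent so
that performance lands at the hypergeometric chance level
`top_k · K/N`; a fixed canonical tie-break would instead freeze an
arbitrary subset into the top ranks. The procedure remains bit-reproducible
for a fixed seed and invariant to input order, because candidates are
canonically sorted by id before any randomness is drawn. Recovery curves
(`rank_by_feature`) keep the stable input-order tie-break, where
determinism for the reader matters more than tie randomization.

## The synthetic study

The generator emulates the statistical structure the analyses rely on, at
desk scale, with one `seed` driving three independent child streams
(proteome, peptidome, candidates). Defaults:

* 80 proteins of 200–600 residues, i.i.d. uniform over the 20 residues
  (real proteomes have biased composition and homology; nothing downstream
  depends on composition, only on exact matching);
* 10 samples in four groups (B-cells, T-cells, melanoma, other); the
  "other" group yields no class-II peptides, modelling HLA-II non-expressing
  samples (a sample counts as expressing at ≥ 100 class-II peptides);
* class-I lengths 8–14 with mode 9 and 4.8% mass at ≥14; HLA-II-expressing
  samples get +0.8 points of long-peptide mass (5.6% vs 4.8%, the reported
  group difference); class-II lengths 12–20 centered on 15;
* background peptides are globally non-overlapping within each class, so
  background coverage is ≤1 and planted hotspots are unambiguous;
* 12 class-I hotspots (25 residues, depth 6) and 10 shared hotspots
  (depth 2) are planted by greedy window selection: repeatedly cover the
  least-covered position with the window of smallest boundary spill and
  least excess coverage. This keeps profiles near-rectangular at the target
  depth; recovered boundaries match planted intervals with Jaccard ≈ 0.93
  (spill of 1–2 residues where edge depth needs overhanging windows);
* 3.4% of class-I sequences are shared with class II (shared-hotspot
  windows first, then re-emission of class-I background peptides whose
  placements are still free in the class-II occupancy mask);
* the candidate table mirrors the published screen's dimensions: 1,034
  candidates, 16 immunogenic, 872 on database proteins, 7 exact / 12
  included / 47 partial wt matches. Immunogenic labels are concentrated in
  the matched classes (2 exact, 3 included, 5 partial, 6 unmatched of 16 —
  a stronger association than the screen's realized 1-of-7 exact, chosen so
  the MS-feature signal is a clear planted condition at this scale), and
  every immunogenic candidate lies on a database protein. Immunogenic
  candidates draw `mutAffinity` from a log-normal shifted ~1σ toward strong
  binding, with smaller planted shifts on stability, wt-affinity ratio and
  RNA abundance; cleavage and read-count features carry no signal.

**Overlap asymmetry.** Shared peptides belong to both class sets, so under
a flat absolute threshold every I/II hotspot trivially coincides with both
a class-I and a class-II hotspot. Planted overlap rates below 1 therefore
only exist under a *relative* threshold: per shared-hotspot protein the
generator plants a deep (depth 8) class-II-only decoy hotspot elsewhere
with probability `1 − p_overlap_ii` (default rate 0.7) and a class-I-only
decoy with probability `1 − p_overlap_i` (default 0.3). With
`min_frac_of_max = 0.5` the decoy lifts that class's segmentation threshold
above the shared peak, removing the overlap; `hotspot_overlap_stats` called
with that setting recovers the realized (Bernoulli-drawn) rates recorded in
the truth manifest exactly, and reproduces the II > I asymmetry.

What the generator does **not** emulate: identification error and FDR
structure, real length-dependent binding motifs, homologous or repeated
protein sequence, peptide abundance, modified peptides, or shared-peptide
biology (re-emission is random). Passing tests therefore demonstrate the
correctness of the machinery — exact matching, counting, segmentation,
scoring, the harness — and the recoverability of planted structure, not
biological performance on real data. In particular, the published
improvement percentages for the three feature groups depend on the external
candidate feature table and the full-size database and are replaced here by
the directional property that adding the two peptide-level MS scores raises
mean top-20 recovery across generator seeds.

## Numerical choices and degenerate inputs

* Coordinates are 0-based half-open internally, 1-based inclusive in
  human-readable exports (TSV profile positions, hotspot tables).
* Shared-peptide percentage uses the sum of the class counts as denominator
  (`100·|I∩II| / (|I|+|II|)`) and returns 0 when either class set is empty;
  this is the definition under which the published counts give 3.4%.
* `enrichment_fraction` returns full precision; display rounding to one
  decimal happens only in reports.
* Peptide rows with non-alphabet characters or length < 7 are dropped at
  load with a logged count; unknown sample ids, duplicate protein ids,
  missing columns and malformed mut/wt pairs are hard errors (the last per
  row, with the remainder processed).
* Unmapped peptides stay in the class sets (they affect counts) but never
  contribute to profiles or scores.
* I/L collapse for matching is opt-in; default preserves exactness.
* Constant features in the rank-sum scan return p = 1; the Wilcoxon
  signed-rank p-value in the overlap statistics is 1.0 when all paired
  differences are zero or fewer than two proteins qualify.
* Candidate rows with missing feature values are dropped with a logged
  count before CV.

## Problem sizes

The default synthetic study (80 proteins, ~2,900 unique peptides, 1,034
candidates) is the package's reference condition; the oracle-equivalence
tests use 100 random databases of 8 proteins × ≤60 peptides over a reduced
alphabet (which forces repeated and multi-protein matches), and the
cross-validation boundary checks run the full 2,000 repeats. These sizes
were chosen so the whole suite and the acceptance script each finish in a
few minutes on a single core while still exercising every code path at the
published candidate-table scale.

## Known limitations

* Hotspot boundaries and the main-peak correlation are package definitions
  of qualitatively described concepts; alternative segmentations will move
  hotspot counts.
* The included-match scan is linear in the number of database peptides per
  query; at very large database × candidate scales it would want an index.
* Modified peptide forms are not represented; sequences are plain strings.
* The SVM harness intentionally performs no hyperparameter search; results
  are only comparable across feature sets under the pinned defaults.
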