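# Methods

This note records the models behind each pipeline stage, the defaults and
why they were chosen, what the synthetic data does and does not emulate,
and the numerical conventions a user extending the package should know.
Coordinates are 0-based and half-open throughout; sequences are stored in
the DNA alphabet (U→T on input, restored on output).

## Homolog screen

A reference mature miRNA (18–24 nt) hits an EST when some ungapped
placement of the full reference — on either strand by default, since an
EST may read antisense to the precursor — satisfies all of:

* at least one exact shared word of `word_length` (default 6) nt,
* at most `max_mismatches` (default 3) substitutions,
* identity `100·(L−mism)/L ≥ min_identity` (default 80%).

No alignment-statistics (E-value) machinery is reimplemented: at query
lengths of ~21 nt the word/mismatch/identity constraints dominate any
E-value cutoff, and the scan is exhaustive rather than heuristic, so the
result equals a brute-force placement enumeration (property-tested).
"Repeat removal" is exact-duplicate collapse of candidate mature
sequences, which also merges the rediscovery of one hairpin from its
complementary arm. The protein-coding filter is a 6-frame longest-ORF
heuristic: an EST is coding when some frame contains an ATG followed by
≥ `orf_codon_threshold` (default 100) stop-free codons. This is a
deliberately database-free stand-in for a protein-homology search; the
threshold is the knob to tighten when ESTs are long.

## Folding model and hairpin criteria

The built-in fold is an exact dynamic program over a simplified
nearest-neighbour *stacking* model, not a Turner-parameter
implementation:

* pair strengths G:C = 3.0, A:T = 2.0, G:T (wobble) = 1.0; a stack of two
  adjacent pairs contributes −(s₁+s₂)/2,
* hairpin loops (≥ 3 unpaired nt) cost +3.0; bulge/internal loops cost
  +2.0 + 0.25 per unpaired nt, capped at 8 unpaired nt per loop,
* multibranch loops are excluded inside closed pairs: the structure space
  is single stems with bulges and internal loops, with any number of
  stems side by side at the external level. A cloverleaf therefore cannot
  be represented — acceptable for miRNA-precursor detection, whose
  signature is a single stem-loop, and it keeps the DP at O(n²·c + n³)
  with small constants (≈ 0.1 s for a 222-nt window).

Energies are in model units: magnitudes are comparable to kcal/mol but
not calibrated to them, so every energy-dependent decision in the
pipeline is either structural or normalised (MFEI), and printed
kcal/mol values from the reference tables are treated as data, not as
something the model should reproduce. Exact ViennaRNA output can be
injected through the `external-energies` backend when absolute energies
matter. Isolated pairs are never produced (they would close a
positive-energy loop with no stack), and ties in the traceback prefer
pairings with smaller 5' index, making structures deterministic.
On sequences short enough to enumerate every nested structure, the DP
optimum equals the enumeration optimum (the suite checks 200 random
sequences; at those lengths the excluded multiloops are provably never
optimal because their inner hairpins are isolated pairs).

Precursor candidates are the hit ± 100 nt, clipped at EST ends with the
truncation recorded. The five hairpin criteria, each an independent flag
with its threshold in `HairpinThresholds`:

(a) exactly one hairpin loop in the window's optimal structure;
(b) ≤ `max_substitutions` (default 2) substitutions against the
    reference mature — deliberately stricter than the screen's ≤ 3, since
    the screen bounds candidate generation while this bounds what is
    finally called a miRNA;
(c) the mature region neither overlaps the terminal loop nor contains an
    unpaired run longer than `max_bulge` (default 3) nt;
(d) |MFEI| ≥ `mfei_min` (default 0.85), with
    MFEI = ((ΔG/length)·100)/GC%;
(e) every paired mature base pairs to the opposite arm (the arm, 5p or
    3p, is assigned from the mature's position relative to the loop).

The packaged reference table itself contains rows with |MFEI| below
0.85, so the verdict and the per-row values are both exposed rather than
hard-wiring one cutoff. Renaming replaces the species prefix with `cac`
and normalises the hyphen after the miR token; the operation is
idempotent.

## Target scanning

Scoring is positional and gapless: miRNA position i (5'→3') faces site
base L−1−i (site read 5'→3'). Watson–Crick = 0, G:U = 0.5, mismatch =
1.0, doubled inside the seed region (positions 2–13, 1-based). The
expectation E of a site is the sum; sites with E ≤ 3 and ≤ 4 mismatches
are retained, at most 2 (the multiplicity) per miRNA–transcript pair,
lowest E first with leftmost tie-break. The penalty weights, seed window
and multiplier are all parameters of `TargetParams`, so alternative
weightings are one object away. A non-Watson-Crick state at miRNA
positions 9–11 classifies the site as translational inhibition; whether
G:U counts as "non-Watson-Crick" there is a documented toggle
(`gu_breaks_central`, default on).

UPE (unpaired energy) is the accessibility cost of a site:
`E(fold with site forced unpaired) − E(free fold)` over the site ± 17/13
nt window (both flanks configurable), computed with the same folding
backend; it is non-negative by construction for an optimal fold, and the
suite checks it against constrained enumeration on short windows.

## Enrichment and disease mapping

Enrichment is the plain upper-tail hypergeometric probability
P[X ≥ k] for overlap k between the query and a term, population = the
gene universe (default: all genes in the annotation table), with
Benjamini–Hochberg adjustment (statsmodels) reported alongside the raw
p. No server-specific background correction is applied, so p-values from
annotation servers with proprietary backgrounds are comparable only in
rank, not in value. Disease mapping deduplicates associations by
(gene, CUI) before counting, then groups by disease name with an
optional case-insensitive keyword filter and CUI allow-list; the result
is invariant to input row order and duplication.

## Network analysis

Complexes are clique-expanded (matrix model) and merged with binary
pairs; cleaning removes duplicate edges, self-loops and isolated nodes,
each counted, and the counts conserve the raw candidate total. The
centrality conventions follow the source formulas literally:

* betweenness and stress sum over **ordered** (s,t) pairs — twice the
  familiar unordered values on undirected graphs; `ordered_pairs=False`
  restores the unordered convention;
* radiality uses (component diameter + 1 − distance), denominator
  |C|−1, and a |C|/|V| prefactor so disconnected graphs remain
  comparable (the printed formula's max-distance denominator disagrees
  with its own prose; the prose — the standard definition — is
  implemented and the convention is recorded in the report metadata);
* eigenvector centrality is the principal adjacency eigenvector per
  component, unit Euclidean norm, computed by power iteration **on
  A + I**: plain adjacency iteration oscillates on bipartite components
  (a 3-path alternates between two vectors forever), and the shift
  preserves eigenvectors while forcing convergence;
* bridging = bridging coefficient × betweenness, with
  BCoeff(v) = (1/deg v)/Σ_{u∈N(v)} 1/deg u;
* the bottleneck score of w counts BFS shortest-path trees (one per
  root) in which w's subtree holds strictly more than |C|/4 nodes;
  parent ties go to the lexicographically smallest predecessor so the
  score is deterministic.

Hub ranking uses competition ranking (tied scores share a rank) and
returns everything ranked ≤ k.

The null model is G(n, m) — uniform simple graphs with the observed node
and edge counts — chosen over G(n, p) because it conditions on the edge
count, the natural negative control for one observed network. The KS
statistic D compares the observed degree sequence with the pooled
replicate degrees. The default p-value is ensemble-calibrated: each
replicate's D against the pool of the remaining replicates forms the
null distribution, and p = (1 + #{D_r ≥ D_obs})/(n_reps + 1). The
textbook two-sample KS p (available via `p_method="asymptotic"`) is
severely conservative here because degree sequences are discrete and
heavily tied — in a 500-run experiment under the ER null it rejected at
rate 0.0 at α = 0.05, while the ensemble p rejects at ≈ 0.04, within
Monte-Carlo error of nominal. The smallest attainable ensemble p is
1/(n_reps+1), so "p < 10⁻¹⁶"-style claims are out of reach by design;
with 200–1000 replicates the test still cleanly separates
preferential-attachment networks from the ER null.

## Synthetic data: what it does and does not emulate

All generators are pure functions of (parameters, seed); the ground
truth they return is verified against the generated data at generation
time (positions index correctly, Hamming distances are exact, planted
site expectations are recomputed with the production scorer).

* Backgrounds are i.i.d. uniform over {A,C,G,T}. The screening and
  scoring stages threshold on mismatch counts and penalty sums, not
  composition, so uniform background exercises them faithfully — but it
  means no repeat families, no codon structure, no EST error profiles.
* Planted homolog substitutions are uniform *conditioned on leaving one
  intact seed word* (default 6 nt, `preserve_word=None` disables): a
  homolog whose every word is destroyed is undetectable by any seeded
  search, so unconditioned planting would make "recall = 100%" false for
  a small fraction of plants for reasons unrelated to the implementation.
* Hairpin cassettes embed mature + extension, an {A,C} loop, and the
  reverse-complement arm inside {A,C} flanks, because {A,C} cannot pair
  with itself — guaranteeing the extraction window folds into exactly one
  stem-loop. Side effect worth knowing: {A,C} (and its complement
  {G,T}) runs contain no stop codons, so the ORF-based coding filter
  occasionally eats a cassette EST (the analysis scripts report when
  this happens). Real flanking sequence is not stop-free; this is a
  generator artifact, not a pipeline defect.
* Interaction sets draw ER edges uniformly without replacement (exact
  edge count, no cleaning losses) or grow a preferential-attachment
  graph; the recorded "planted hub" is the realised maximum-degree node
  of the grown graph, which is exact for that instance.

Consequently, passing recovery tests demonstrates that the
implementation applies its stated rules exactly; it does not demonstrate
sensitivity or specificity on real EST collections, where repeats,
chimeras and composition bias dominate the error budget.

## Problem sizes and determinism

The analysis scripts run 20 references × 200 ESTs (330 nt), 20
transcripts (300 nt), and a 150-node interaction set, with 200–1000
randomization replicates — sizes chosen so a full desk run of every
stage, including ~20 full-window folds, completes in seconds while still
giving every filter a non-trivial population to act on. One master seed
drives each script; per-stage seeds derive from it by fixed offsets, and
rerunning any stage reproduces its outputs byte-for-byte.

## Known limitations

* The folding model's absolute energies are not Turner energies; use the
  external backend for thermodynamic fidelity.
* Gapped miRNA/target alignments (bulged targets) are out of scope; the
  scanner is strictly positional.
* GO-graph propagation, server-specific enrichment backgrounds, and live
  database clients are out of scope; annotation inputs are plain tables.
* The printed reference tables carry their source's printing quirks: one
  MFEI value is truncated rather than rounded, and printed mature
  lengths count alignment gap characters; the fixture loader preserves
  both faithfully rather than "correcting" them.
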