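# Methods

## Assignment model

A stereotyped subset `s` is a tuple (IGHV gene set and its clan `c(s)`,
CDR3 length `L(s)`, consensus CDR3 `K(s)`, motif `m(s)` with offset
`o(s)`, canonical mutation class U/M, optional light-chain V gene). All
coordinates are amino acids in the IMGT CDR3 — the junction with the
conserved C104 and W118/F118 anchors removed — and `o(s)` is the 0-based
index of the motif's first residue.

A heavy-chain rearrangement `r` with CDR3 `x` is a **standard** match to
`s` iff

1. clan(V(r)) = c(s);
2. identity(x, K(s)) ≥ 0.5 and similarity(x, K(s)) ≥ 0.7;
3. |x| = L(s);
4. `m(s)` matches `x` at exactly offset `o(s)`.

It is a **satellite** match iff clan(V(r)) is associated with c(s),
||x| − L(s)| ≤ 2, and `m(s)` matches at some offset `o` with
|o − o(s)| ≤ 2. The satellite tier applies no identity/similarity
thresholds (the printed criteria have none); the values are still recorded
for reporting. Standard therefore implies satellite for the same subset,
and assignment resolves the overlap by precedence: a clonotype with any
standard match is never counted as a satellite, so the two tiers partition
the matched clonotypes. Where a clonotype matches several subsets within
a tier, the tie is broken by highest similarity, then highest identity,
then lexicographic subset id, and the event is logged.

**Identity and similarity.** Identity is the fraction of aligned positions
with equal residues. Similarity additionally accepts positions whose
residues fall in the same conservative-substitution group; the default
partition is {G,A,V,L,I}, {F,Y,W}, {C,M}, {S,T}, {K,R,H}, {D,E,N,Q}, {P},
and it is fully configurable because published subset definitions do not
fix one. Identity ≤ similarity holds by construction (grouping refines
equality). For satellite matches with unequal lengths or shifted motifs,
identity/similarity are computed with the two CDR3s aligned on the matched
motif (position `i` of the query against `i − Δo` of the consensus, over
the overlap); with Δo = 0 and equal lengths this reduces to the plain
positionwise comparison. When the motif occurs at several admissible
offsets, the minimal |Δo| wins, ties resolved toward the more negative Δo.

**Clans.** The IGHV family→clan map defaults to the standard immunogenetic
convention: clan I = {IGHV1, IGHV5, IGHV7}, clan II = {IGHV2, IGHV4,
IGHV6}, clan III = {IGHV3}. "Phylogenetically associated" for the
satellite criterion defaults to same-clan; `ClanMap.associations` can
declare cross-clan associations if a finer or looser relation is wanted.
Allele suffixes (`*01`) are ignored everywhere genes are compared.

## Counting and summaries

Rearrangements are collapsed to clonotypes keyed by (allele-stripped V
gene, allele-stripped J gene, amino-acid junction) before any counting;
amino-acid-level collapsing is conservative with respect to sequencing
error. A collapsed clonotype's germline V identity is the mean over the
duplicates that report one; rows lacking it participate in matching but
are excluded from SHM analyses. Per sample × population frequencies are
matched clonotypes over total unique clonotypes in that group, computed
per donor and averaged unweighted across donors where an aggregate is
reported. SHM class is U when germline V identity ≥ 0.98 (the conventional
CLL cutoff; configurable, and the boundary value is U by the ≥ rule).
Concordance for a subset × population is the fraction of its assigned
clonotypes with known SHM class whose class equals the subset's canonical
class. Concordance profiles are grouped into patterns by agglomerative
clustering (Euclidean distance, average linkage) of the per-population
concordance vectors, cut at a user-chosen k — a reproducible,
deterministic stand-in for groupings that are otherwise drawn by eye.
Light-chain restriction compares each assigned cell's allele-stripped
light V gene with the subset's declared gene; subsets without a
declaration yield "no-restriction".

**Statistics.** Group comparisons use the tie-corrected Kruskal-Wallis H
with a chi-square p-value (scipy); the degenerate all-identical input is
defined as H = 0, p = 1. Post-hoc pairs use Dunn's rank-sum z statistics
with the standard tie correction, Holm-adjusted by default (implemented
here; adjustment method configurable through statsmodels' `multipletests`).

## Synthetic repertoires

The generator emulates the sampling design the analysis assumes: donors ×
subpopulations, each population with a size (unique sequences attempted),
an SHM rate per amino acid, and a TdT flag. Background CDR3s are composed
of a V-encoded stub, N regions (lengths Poisson with mean 2.5 per side
when TdT is on, absent when off), a D-encoded core and a J-encoded tail,
over a 12-gene V pool spanning all three clans. Turning TdT off collapses
junctional diversity to the finite stub×core×tail space — the
cord-blood-like regime — which also means far fewer unique background
clonotypes and hence higher per-clonotype frequencies for anything
planted there. SHM is a uniform per-position substitution process (no
hotspots); germline V identity is drawn as 1 − Binomial(300, rate)/300
over a nominal 300-nt V segment, so a 6%-per-aa memory-like rate lands
near 0.94, well below the U/M cutoff, while naive-like populations stay
at 1.0.

Plants copy the subset consensus (standard tier) or a consensus variant
with a length edit and/or motif shift of up to 2 (satellite tier). Every
plant receives at least one substitution at a non-motif position —
escalating when the low-substitution neighbourhood is exhausted — so each
plant is a distinct clonotype, as distinct cells' rearrangements are in
real data; without this, unique-clonotype frequencies could not reflect
planted rates. After perturbation each plant is re-verified: a standard
plant must still satisfy, and be best-assigned to, its subset at the
standard tier; a satellite plant must satisfy the satellite but not the
standard criteria for any subset, and best-assign to its subset. Failed
constructions are resampled with a bounded retry budget (error beyond
it). Planting decisions are Bernoulli per sequence, so planted counts are
binomial around frequency × population size. The default conditions
(`default_config`) use three donors, naive/memory/cord-blood-like
populations, and standard/satellite plantings at total frequencies 1e-3
and 1e-2 — the ~10:1 satellite excess reported for normal repertoires.

**What the generator does not emulate:** nucleotide-level junctions
(matching operates on amino acids and v_identity only; the aa-level
back-fill is a deliberate simplification), SHM hotspot targeting, clonal
expansion/lineages, isotype switching, or realistic gene-usage skews.
Passing tests on synthetic data therefore validate the *decision rules
and bookkeeping*, not biological realism of the background model.

## Numerical and design choices

- Thresholds (0.5 identity, 0.7 similarity, ±2 length, ±2 offset) are the
  assignment criteria themselves and are exposed as parameters end to end;
  raising the similarity threshold can only shrink the standard set
  (tested as a monotonicity property).
- Assignment output is sorted by clonotype key, so it is independent of
  input row order; simulation is driven by a single seeded generator, so
  identical seeds give byte-identical outputs.
- Problem sizes in the test suite and acceptance script (10⁵-sequence
  recovery runs, 2 × 20,000 concordance runs, 5–10 × 10³ null replicates
  for test calibration) were chosen as the smallest sizes at which binomial
  sampling error is well inside the margins being checked.
- Empty repertoires, empty catalogs, motifs longer than the CDR3, and
  all-identical statistical groups are all defined (empty result, error,
  no match, H = 0 respectively) rather than left to downstream exceptions.

## Limitations

- The shipped starter catalog's consensus sequences and motifs are
  synthetic placeholders; real analyses need a real subset catalog.
- Satellite identity/similarity over motif-anchored overlap is one of
  several defensible conventions for unequal-length comparison; it is
  recorded metadata only and never gates a satellite decision.
- Whether satellite "association" should be finer than same-clan is left
  as configuration; the default reproduces the coarse clan relation.
- Uniqueness is amino-acid-level; nucleotide-level collapsing can be
  approximated by keeping distinct junction strings upstream, but no
  nucleotide bookkeeping exists in the package.
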