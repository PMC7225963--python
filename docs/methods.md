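# Methods

This note documents the models and procedures implemented in `caspcons`,
the parameters that matter, the numerical conventions, and what the
synthetic corpus does and does not establish about real data.

## Cleavage sites, windows and octamers

A cleavage site is identified by a protein accession and the 1-based
position of the P1 residue (the residue N-terminal of the scissile bond).
The octamer spans P4…P4′ (protein positions `p1-3 … p1+4`); the query
window spans `p1-29 … p1+30` — 60 residues with P1 at window position 30
(1-based) — matching the geometry of the original ortholog search queries.
Sites closer than 29/30 residues to a terminus keep truncated windows with
a recorded start offset rather than being dropped; all block statistics
downstream renormalise by the residues actually present. Curation keeps
only sites whose catalogue position carries an aspartate in the supplied
sequence (glutamate cuts exist but their physiological role is unsettled,
so they are excluded from the conservation analysis), collapses duplicate
(accession, position) pairs, and records a reason for every dropped row.
Obsolete-accession and readthrough filtering is reduced to a caller-supplied
exclusion list; no live database lookups are performed.

## Hamming anchoring

Orthologous cleavage sites are located without alignment: the human
60-residue window slides over every offset of the subject segment
(including partial overhangs, with absent positions treated as `-`), and
the placement minimising the Hamming distance wins. Ties prefer the offset
that puts an aspartate under the window's P1 position — the aspartate is
the anchor, and this bias is deliberate and logged — then the leftmost
offset. Matching is strict: a position matches only when both characters
are identical standard residues; gaps and ambiguity codes (X, B, Z, U)
mismatch everything, including an identical ambiguity character, because
the underlying residues are unknown. Consequently the octamer distance of
a D-retaining hit is at most 7 and an all-gap octamer scores 8.

When the hit table carries aligned query/subject strings, their gap
columns are honoured instead (subject insertions are skipped, deletions
appear as `-` and land in the gap category); both paths produce identical
hit records otherwise. The sliding scan is vectorised with a byte-matrix
comparison over all offsets, and the test suite holds it equal to a naive
per-offset oracle.

## Species filter, best hit, distributions

Species with at most 8000 annotated proteins are excluded before anything
else: sparse proteomes understate ortholog presence and would contaminate
the %-species criterion with false negatives. The species universe for
percentage coverage is exactly the filtered set. One hit per
(site, species) is kept — minimal e-value at a 1e-16 cut-off, ties broken
by longer then lexicographically smaller subject segment so the result is
independent of input order.

The corpus distributions are: residue (plus gap/ambiguity categories) at
the anchored P1; octamer Hamming distance cross-tabulated by P1-aspartate
retention; and the P1′ residue with its Arg/N-degron nature. Percentages
are reported to two decimals; comparisons against published prose figures
round to integers.

## Per-target metrics

* **median HD** — median octamer Hamming distance over hits that retain
  P1 aspartate only ("D-cuts"); hits with substituted P1 still count
  toward species and class coverage, since ortholog presence is a BLAST
  fact, not a P1 fact. Even-count medians average the two middle values.
  A site with no D-cut hit has an undefined median and cannot pass
  selection.
* **coil prevalence** — from a Q3 (helix/strand/coil) string aligned to
  the human window, `2c/(l+r)` where `c`, `l`, `r` are the coil
  percentages of the central/left/right 20-residue blocks. The window is
  partitioned symmetrically (left 1–20, centre 21–40 with P1 at block
  position 10, right 41–60). Degenerate flanks: if `l+r = 0` while
  `c > 0` the value is +inf (a fully coiled centre between fully
  structured flanks is the motivating geometry and passes any ">1"
  threshold, logged); if both are 0 the value is 1 (no contrast).
  Q3 strings are inputs; no structure predictor is bundled.
* **hydrophobicity prevalence** — same centre-over-flanks construction on
  block *sums* of cyclohexane→water side-chain transfer free energies
  (kcal/mol, pH 7). Because block sums can be negative, all values are
  first shifted by `|minimum block value over the whole corpus| + 1`
  (the +1 also prevents division by zero), making every shifted value at
  least 1; the ratio `(c+shift)/((l+r)/2+shift)` is then < 1 exactly when
  the cleavage region is more hydrophilic than its flanks. The shift is a
  corpus-level constant: regenerating it on a superset can only grow it,
  and per-target values are only comparable within one corpus. The
  per-target statistic is the median prevalence over the target's
  ortholog windows; the human window's own value is reported alongside.
  Gap/ambiguity characters contribute the scale median (0.4) so they bias
  neither direction. Truncated blocks are rescaled to a 20-residue
  equivalent.
* **destabilizing fraction** — share of orthologs whose P1′ residue is
  destabilizing under the Arg/N-degron pathway (primary R K H L F Y W I;
  secondary D E C; tertiary N Q; everything else stabilizing —
  Nt-acetylation-dependent fates are out of scope). Gaps and ambiguity at
  P1′ are excluded from the denominator rather than counted as failures,
  to avoid penalising sites with alignment gaps.

### The hydrophobicity scale

The 20 per-residue values are embedded constants validated at load against
the published anchors: Arg −14.92 (so polyarginine-20 sums to −298.4, the
hydrophilic limit), Ile 4.92 (polyisoleucine-20 sums to 98.4, the
hydrophobic limit), Gly 0.94, and a 20-value median of 0.4. The source
measurements cover the 19 side chains with a primary backbone amine;
proline is not measured and is imputed at +3.0 (an aliphatic three-carbon
bridge, between the methyl and isopropyl side chains). No reported
statistic depends on the proline entry, and any imputation outside
(−0.14, 0.94) leaves the scale median unchanged.

The Kendall correlation between per-site hydrophobicity sums and cleavage
rates uses tau-b (tie-corrected, two-sided p), since both sums and rate
measurements tie in practice; real rate data is an external input and the
operation ships with synthetic demonstrations only.

## Selection and validation

A target is selected when all enabled criteria hold, every comparison
strict: median HD < 2, coil prevalence > 1, median hydrophobicity
prevalence < 1, orthologs in > 96% of the species universe, and presence
in every vertebrate class. The destabilizing-P1′ criterion (> 50% of
orthologs) is computed and reported in the validation table but disabled
in selection by default: in the reference set of 24 cleavage sites with
proven proapoptotic fragments only 4 satisfy it, too few to justify
imposing it. An undefined metric fails its criterion. The vertebrate
class list is configuration, not code; the default enumeration
(Mammalia, Aves, Reptilia, Amphibia, Actinopterygii, Chondrichthyes,
Coelacanthimorpha) is an explicit assumption of what "every class" means
for the species that survive the proteome filter. Relaxing any single
threshold can only grow the selected set; this monotonicity is
property-tested.

## Species clustering and Baker's Gamma

Species are clustered on a species × character matrix: concatenated
anchored octamers, concatenated anchored 60-mers, or one HD digit per
site. Distance is the normalised Hamming mismatch over columns where both
species are non-missing (a pair with no comparable column is an error
naming the pair); linkage defaults to average. Trees are exported as
Newick with merge heights as branch lengths.

Baker's Gamma compares two dendrograms on the same leaves: for every
unordered leaf pair, the merge level at which the pair first co-clusters
is computed in each tree (levels are dense ranks of merge heights, so
equal-height joins tie), and the Goodman–Kruskal gamma
`(C − D)/(C + D)` is taken over all pairs of leaf pairs, ties counting to
neither side. The implementation recovers `C − D` from the tie-corrected
Kendall statistic in O(m log m) and is held equal to an O(n⁴) brute-force
concordance counter in the tests. Note that γ = −1 is unattainable
between binary four-leaf dendrograms: a caterpillar against its leaf-order
reversal yields C = 1, D = 6 with 8 ties, γ = −5/7.

## The synthetic corpus

The generator emulates the output of the ortholog search, not protein
evolution. Its defaults encode the study conditions the pipeline targets:
100 sites × 328 well-represented species in seven classes (plus 25
sparse-proteome species the filter must reject), P1 drawn per hit as
aspartate 0.92 / glutamate 0.05 / gap 0.002 / other residues the
remainder, destabilizing P1′ fraction 0.2, class-specific substitution
rates rising from Mammalia (2% per octamer position, 5% per flank
position) to the fish classes (≈12% / 20%), 2% hit dropout, 20% duplicate
hits with clearly worse e-values, and Q3 coil fractions of 0.45/0.65/0.45
per window third (three-quarters of non-coil positions helical) — a
coil-enriched centre consistent with the observed preference of cleavage
sites for loops. Proteome sizes are log-normal above the threshold;
e-values decay exponentially in the realised substitution count, so only
their ordering is meaningful.

Each class's substitution process is split (default 50/50) between a
shared per-class ancestor window and independent per-species mutations;
the shared component is what gives hierarchical clustering a class signal
to recover. P1 and P1′ never mutate at the ancestor level, so their
per-hit probabilities remain exactly as configured. P1′ is redrawn per
hit by default (`p1prime_resample_prob = 1`), making the destabilizing
fraction a directly controlled binomial parameter with √(p(1−p)/n)
recovery error; setting it to 0 recovers the inherit-everything limit in
which a zero-noise configuration yields byte-identical windows, octamer
distance 0 everywhere, and zero recovery error.

What passing tests on this corpus establishes: correct curation and
filtering arithmetic, exact anchoring at the generated divergence levels,
unbiased recovery of the planted P1 and P1′ fractions within binomial
bounds, and class recovery by clustering when a shared divergence
component exists. What they do not establish: behaviour under real indel
patterns (the generator produces no indels beyond P1 gaps), realistic
amino-acid substitution preferences (replacements are uniform over the
other 19 residues), composition bias (background residues are uniform by
default), or BLAST search sensitivity — those belong to the upstream
search, which this package deliberately does not run.

## Problem sizes and determinism

Default test and analysis runs use 12–100 sites against 47–353 species
(≈0.5k–33k hits), sizes chosen so the complete suite and the analysis
scripts run in well under a minute while keeping binomial recovery bounds
meaningful at the stated tolerances (±0.01 on the P1-aspartate fraction at
~32k draws, ±0.02 on the destabilizing fraction). All randomness flows
through one integer seed; a fixed seed reproduces every file byte for
byte, and pipeline reruns on identical inputs are byte-identical.
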