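# Methods

This note documents the models, parameter choices and numerical decisions
behind `beanmir`, and what the synthetic studies do and do not demonstrate.

## Pipeline model

The analysis treats a four-organ small-RNA experiment (leaf LL, root RL,
seedling SL, flower FL) as a staged classification of collapsed sequence
tags. Each tag is a unique 16–30-nt RNA string with per-organ read counts;
stages remove tags from the pool in a fixed order, so the outputs partition
the input: ncRNA fragments → exact reference matches → isomiRs → residual
(novel-candidate) reads. All sequences are held internally in the RNA
alphabet; DNA input is converted on read. Coordinates are 0-based
half-open internally and 1-based inclusive in reports. Tag tables are
emitted in a deterministic order (descending total, then sequence), and
every stage is a pure function of its inputs and parameters, so a seeded
run reproduces byte-identical artifacts.

### Filters and matchers

* **ncRNA filter** — a tag is removed iff its full extent occurs verbatim
  inside a non-miRNA ncRNA entry. Rationale: ncRNA database entries are
  full-length molecules while tags are fragments, so "perfect match" must
  mean the tag's whole sequence; one mismatch retains the tag.
* **Exact annotation** — hash lookup of tag sequence against a
  deduplicated mature/mature-star reference set. This is equivalent to an
  alignment requiring identical length and composition, and it forces one
  canonical name per distinct reference sequence.
* **Conservation filter** — keep iff detected in ≥ 2 libraries and
  ≥ 15 total reads, both inclusive. Discarded hits are retained in a side
  table because validated precursor evidence can rescue them for the
  expression analysis.
* **isomiR matcher** — ungapped alignment with signed terminal offsets
  capped at 2 nt per end; substitutions are counted only inside the
  overlap (≤ 2); overhangs are offsets, never mismatches. Ties prefer
  fewer substitutions, then smaller total offset, then the more abundant
  reference, then name. The candidate prefilter is a strict total > 10
  across libraries (a per-library reading would reject catalogued
  variants detected in only two organs). The abundance rule is inclusive
  (≥ 1.5× the reference total — the catalogued 24-vs-16 case passes only
  under inclusive comparison); for an unobserved reference only the
  single most abundant variant survives. Family promotion requires
  retained-variant totals ≥ 1000 reads (default, configurable): the four
  families this promotes on the bundled tables are each supported by
  thousands of reads while the rejected ones have ≤ ~400.
* **Loci** — equivalence classes of a family's mature sequences under
  zero-substitution offset alignment, closed transitively, so the count
  is order-invariant. The bundled miR159 family illustrates a known
  limitation: the published count (6) is not reproduced by this collapse
  alone, and no special-casing is attempted.

On the bundled isomiR table the chain is run against that table's own
reference set. One variant (the 19-nt miR156 isoform) is catalogued under
a reference that differs from its nearest neighbour in the full conserved
catalogue — against the full set it would be a 0-substitution length
variant of ath-miR156a. Group membership (the 7/9/10 split) is identical
either way for all other rows; the bundled-fixture run reproduces the
printed table exactly.

## Energy model and folding

Folding uses an exact dynamic program over a deliberately simplified
nearest-neighbor model shipped as a versioned data file
(`data/stack_energies_v1.tsv`):

* the ten canonical Watson–Crick stack free energies (kcal/mol, 37 °C);
* three category constants for stacks involving G:U wobbles (−1.4 with a
  G:C neighbour, −0.9 with A:U, −0.5 for G:U/G:U) — real wobble stacks are
  orientation-dependent and occasionally positive, but the validator only
  needs them pairable and weaker than Watson–Crick;
* positive hairpin/bulge/internal-loop penalties with logarithmic
  extrapolation (1.08·ln(n/n_max)) beyond the tabulated sizes; minimum
  hairpin loop 3 nt.

The structure space is multiloop-free: any number of side-by-side external
stems, each a nested chain of pairs separated by stacks, bulges or
internal loops (sides capped at 6 nt) and closed by one hairpin loop.
Pre-miRNA validation needs only single stem-loop geometry plus a stability
score, and restricting the grammar makes the optimum independently
checkable: the tests compare the DP against exhaustive enumeration of the
same grammar on hundreds of random 8–20-nt sequences, and recompute each
reported energy from the emitted dot-bracket. MFE values from this model
are not comparable to full Turner-model folders and are used only
relatively (validation threshold, shuffle nulls, candidate ranking).

**Validation criteria** (common plant-miRNA annotation practice): mature
on a single arm, clear of the terminal loop; ≥ 60 % of mature bases
paired; ≤ 2 asymmetric bulges of ≤ 3 nt in the mature/star duplex; window
MFE ≤ −0.25 kcal/mol/nt. The star interval is the pairing partner of the
mature's last paired base shifted by the 2-nt 3′ overhang convention
(star_start = partner(mature_end−1) + 2), a rule that is its own inverse
on clean hairpins — validated as an involution in the tests.

**Novel scoring** is a transparent additive surrogate for read-signature
probabilistic scoring: reads mapping into a validated window are binned
mature/star/loop (a read must place ≥ 90 % of its bases in one bin to be
consistent), and score = log(1+mature) + 2·1[star>0] − 4·(inconsistent
fraction), keep threshold 1.0. Star evidence therefore strictly dominates
among otherwise equal candidates, and diffuse siRNA/degradation
signatures are pushed below threshold.

## Duplex (target) model

Hybridization considers intermolecular pairing only: Watson–Crick and G:U
stacks from the same table, +1.1 kcal/mol per internal mismatch column,
+2.0 kcal/mol per bulged nucleotide (bulges ≤ 3 nt, flanked by pairs),
unpaired ends free. The DP is a four-state local alignment (last column
pair / mismatch / target-bulge / miRNA-bulge) and is tested against
exhaustive alignment enumeration on ≤ 12-nt instances. A perfect
21-nt duplex under this table lands near −40 kcal/mol, inside the range
reported for conserved plant miRNA:mRNA hybrids.

Because absolute hybrid energies vary with miRNA length and GC content, a
site passes at a *ratio*: MFE ≤ 0.7 × MFE(miRNA vs exact complement)
(configurable). TAS3-like transcripts are detected directly as ESTs with
two non-overlapping miR390 sites at a relaxed ratio (0.55) rather than by
homology to a foreign TAS3 sequence, since the package ships no external
database. Diagram notation: `|` pair, `x` wobble (never a mismatch),
`*` mismatch.

## Expression

Counts of mature (never star) miRNAs are pooled by family; rescued
low-abundance miRNAs with validated precursors and the retained variants
of promoted families join the matrix. Size factors are median-of-ratios
over families with all-positive counts. Note the estimator is defined up
to a common rescaling: multiplying one library by c multiplies its factor
by c^(1−1/m) and every other factor by c^(−1/m), so equivariance holds
exactly for factor *ratios* (and for a duplicated-then-scaled column
within one matrix); the tests assert those exact forms.

Without replicates the dispersion is fitted "blind": treating the organ
libraries as pseudo-replicates, α is the median of per-family moment
estimates (var − mean)/mean², clamped at 0. The transform is the closed
NB variance stabilizer t = (2/√α)·asinh(√(α·q)), which tends to 2√q as
α → 0 — a parametric substitute for a locally fitted variance function,
chosen for transparency and testability (the NB simulation check shows it
flattens the variance–mean slope to 0 ± 0.1). On the bundled tables the
blind α is large (≈ 1.2) because organ differences are real biology, not
replicate noise; the transform is used only to put counts on a comparable
scale for clustering. Clustering is Euclidean distance with complete
linkage on both axes (the common defaults of R's `hclust`); the organ
tree's leaf–root adjacency on the bundled tables is reported as a soft
qualitative check, not a hard contract, because it depends on the exact
input matrix and transform variant.

## Synthetic studies

The generator plants everything the pipeline is supposed to find:

* 40 reference genes + 6 novel genes (absent from the reference set) in
  18 families, each with a precursor u₂+mature+loop+star-arm where the
  star arm is the reverse complement of (u₂+mature) with 0–2
  G:U-compatible substitutions — an imperfect duplex with exact 2-nt 3′
  overhang geometry — embedded in an EST with 25–40-nt flanks;
* per-gene totals lognormal (median 300 reads, σ = 1), split across
  organs by a Dirichlet(2) profile, drawn per organ as negative binomial
  with dispersion 0.25 (var = μ + 0.25 μ²);
* reads distributed over the canonical mature (65 %), templated isomiRs
  (3′ extension 10 %, 3′ truncations 14 %, 5′ variants 6 %, one
  substitution variant 5 % — 3′ heterogeneity dominant, as in real data)
  plus Poisson star reads at 12 % of the gene count;
* five "reference-shifted" genes whose reference entry is the 3′-truncated
  form of the expressed mature, so the isomiR abundance rule has genuine
  positives (the situation the catalogued 21-nt miR1511 variant
  exemplifies);
* 30 decoy reference matures with zero reads; 20 ncRNA sequences
  (80–200 nt) feeding contamination fragments; contamination at 30 % of
  emitted reads with a 21/24-nt length mixture (24 nt weighted 0.45) that
  reproduces the empirical pattern of 24-nt tags being the most *diverse*
  class while ~21-nt miRNA reads dominate redundancy;
* perfect-complement target sites for ten genes (three carrying two G:U
  wobbles) inside dedicated ESTs, plus decoy ESTs.

Problem sizes were chosen so a full study (generation through expression)
completes in about a minute while keeping ≥ 90 genes across the two
acceptance replicates; the scaled-down per-test configuration (12+3
genes) preserves every structural feature.

What passing synthetic tests shows: the stages implement their stated
rules, compose without leakage (annotation, isomiRs, ncRNA removals and
novel candidates are disjoint), the folding validator accepts exactly the
planted geometry and rejects dinucleotide-shuffled windows, and recovery
is near-perfect under the assumed noise model. What it does not show:
robustness to sequencing error profiles, adapter chemistry variants,
genomic repeat structure, cross-mapping between paralogous families, or
any property of real common-bean data beyond the bundled printed tables.

## Known limitations

* The folding engine excludes multiloops and suboptimal structures; it is
  a precursor validator, not a general RNA folder.
* The published genome-scale outcomes that depend on 2010-era database
  snapshots (precursor and novel-candidate counts, EST target counts,
  raw-read yields) are out of reach by construction and are not targets.
* The exact quality criterion and adapter tolerance of the original
  base-calling pipeline are unknown; preprocessing defaults (mean Phred
  ≥ 20, exact ≥ 8-nt adapter-prefix match, discard on no match) are
  documented surrogates, and retained-read percentages are not asserted.
* The bundled isomiR table carries one internal inconsistency (one
  variant's per-library counts do not sum to its printed total); both
  values clear every threshold involved, and totals are computed from
  per-library counts throughout.
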