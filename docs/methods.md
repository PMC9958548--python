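# Methods

## The pipeline in outline

`ickkit` analyses inhibitor cystine knot (ICK) toxin candidates from
venom-gland transcriptomes in six stages: candidate screening, cysteine
framework classification, gene-family clustering, disulfide-connectivity
consensus, cysteine-anchored loop alignment with codon back-translation,
and site-wise selection summaries. A synthetic-data generator provides
ground-truthed inputs for every stage, so the pipeline's guarantees are
stated and tested as properties of known answers rather than of any one
dataset.

## Candidate screen

A precursor is kept iff it passes every enabled rule, evaluated in a fixed
audit order:

| rule | default | meaning |
|---|---|---|
| `complete_cds` | on | CDS starts with ATG, ends with a stop, no internal stop, length ≡ 0 (mod 3) |
| `signal` | on | signal peptide called on the precursor |
| `max_len` | 200 aa, exclusive | applied to the full precursor (`length_scope="mature"` restricts it) |
| `min_cys` | 6, inclusive | counted on the mature peptide (post-cleavage region) |
| `homology` | e ≤ 10⁻³ | best hit over all sources; passing any one search suffices |

The length bound is read as a strict `<` on the precursor because the
boundary between precursor- and mature-scale bounds is ambiguous in
practice; the scope switch makes the other reading available. The mature
peptide is everything after the signal cleavage site — no propeptide region
is modelled.

Signal peptides are expected from an external predictor's table; the
built-in heuristic (Met start, ≥ 8 hydrophobic residues in positions 6–15,
small residues at the −3/−1 positions before a fixed cleavage after residue
22, no cysteine in the signal) is a deterministic stand-in that detects
textbook signal-peptide architecture. It makes self-contained runs and
testing possible; it does not reproduce a neural predictor's behaviour on
borderline real sequences.

The built-in homology fallback (ungapped seeded search, word size 3,
BLOSUM62, ungapped Karlin–Altschul e-values) against a bundled *synthetic*
knottin reference set is used only when no hit tables are supplied. Real
analyses should ingest BLAST/HMMER results; the fallback exists so the
screen is runnable and testable offline.

## Framework grammar and catalog

Consecutive cysteines are tokenized by gap: 0 → `CC`, 1 → `CXC`, ≥ 2 →
`C-C`; a peptide with *n* cysteines carries *n − 1* tokens and renders to a
motif numbering cysteines C1..Cn. Framework identity is the exact token
list, not the cysteine count — two ten-cysteine classes differ precisely in
one spacing token. Novel patterns are minted as `n.k` with the smallest
unused variant index for that cysteine count, continuing from the packaged
catalog so identifiers are stable. The coverage filter sorts classes by
descending count (ties lexicographically) and keeps the shortest prefix
reaching the requested share.

## Families

Gene families are connected components of a homology graph whose edges pass
both an identity and an overlap threshold (defaults 0.35 / 0.8, the
customary values for single-linkage protein clustering; configurable —
note that same-framework families always share their cysteine scaffold, so
separating recent duplicates from scaffold coincidence can warrant a
stricter identity cutoff). Pairwise identity is matches over aligned
(non-gap) columns of a global BLOSUM62 alignment with gap open/extend
−11/−1; overlap is aligned span over the shorter length.

## Connectivity consensus

All complete pairings of *n* cysteines number (n−1)!!, which is why
enumeration is refused above n = 8 and predictions are combined instead.
Each of the three bridges homologous to every framework class is a slot
anchored at one of the first three distinct bounding cysteines of the loop
schema (C1, C2, C3 for the six- and eight-cysteine classes); the slot's
partner is the majority vote over all submitted maps, with reference
(published) maps breaking ties and the lowest partner ordinal breaking
what remains. Partners consumed by an earlier slot are skipped, so the
consensus is always a valid partial matching. Chord-diagram export weights
every submitted map equally.

## Knot alignment

Every framework class shares four loops bounded by eight structurally
homologous cysteines; because loop 1 shares its right bound with loop 2
(and loop 3 with loop 4), six distinct anchor ordinals remain, and the
assembled alignment has the layout
`A1 loop1 A2 loop2 A3 · A4 loop3 A5 loop4 A6` — six single, all-cysteine,
gap-free anchor columns plus the four loop alignments. Residues outside
the loops (tails, the loop2–loop3 linker, trailing elaboration cysteines
of the 12- and 14-cysteine classes) are excluded.

Loops are aligned independently after replacing each flanking cysteine
with the barcode `WWYHWYYHMM`; the barcode's high self-match score pins
the flanks so inner cysteines cannot migrate onto them, and unwrapping
verifies the barcode columns survived intact. The built-in aligner is
center-star: the sequence with the largest summed 3-mer similarity is
aligned pairwise (BLOSUM62, gap open/extend −10/−1) against every other,
and the pairwise alignments are merged on center coordinates
(once-a-gap-always-a-gap). On the generator's indel-free data this is
exact; on real data it is a serviceable baseline, and any external aligner
that reads and writes FASTA can be substituted for it upstream of
assembly.

The composition filter tests each sequence's pooled loop residues against
the gap-excluded composition of the remaining set with a χ² statistic on
df = 19 (20 amino-acid classes, fixed), removes sequences with p < α
(default 0.05), recomputes the pooled composition, and repeats up to five
rounds. Because the statistic depends only on residue counts, loops are
realigned once on the survivors rather than after every round — the
results are identical. The test is asymptotic; calibration simulations use
sequence length 100 so expected class counts sit near 5, and the measured
false-positive rate tracks α to within about two points.

Back-translation replaces each non-gap residue by its source codon via the
alignment's per-row position maps and verifies that every codon translates
to the aligned residue. Note that the degapped codon row is a
concatenation of disjoint CDS segments, not one contiguous substring — the
inter-loop linkers are excluded by design.

## Selection summaries

The built-in estimator is deliberately modest: per codon column, the
pathway-averaged synonymous and nonsynonymous differences and site counts
of every sequence pair (Nei–Gojobori counting; mutations to stops count as
nonsynonymous, pathways through stops are excluded) are pooled, and the
column's dS and dN are the ratios of summed differences to summed sites.

Two numerical choices matter here. First, pooling before any transformation
(ratio of sums, not mean of per-pair ratios): per-pair proportions move in
jumps of one difference over a site count of at most three, and averaging
nonlinear functions of such coarse ratios biases the result. Second, **no
multiple-hit correction is applied at single-codon resolution**. The
standard −3/4 ln(1 − 4p/3) transform has a pole at p = 3/4, and a codon's
synonymous site count never exceeds 4/3, so a single synonymous difference
already reaches the pole; simulations under ω = 1 put the uncorrected
pooled estimator's mean dN − dS within ±0.01 while every corrected variant
tried (per-pair, pooled, pole-linearized) biased it by −0.06 to +0.09 and
degraded direction recovery at positively selected sites. The estimator is
therefore documented as a *direction* tool — valid at the low-to-moderate
divergence of recently duplicated gene families — never as a rate
estimator, and never as a substitute for the external phylogenetic tests
whose results the importers ingest (site posteriors at 0.9, episodic
p-values at 0.05 after Holm correction — Holm chosen as the conservative
default where no procedure is mandated — branch LRTs at 0.05, coevolution
posteriors at 0.95).

Classification precedence is pervasive-positive, episodic-positive,
negative, neutral. The loop report regresses dN on dS by ordinary least
squares over sites where both are finite (sites with dS = 0 are included;
they carry real information about purifying columns) and reports slope,
R², the implied F statistic and p.

## Synthetic data: what it emulates and what it does not

Generated precursors are a constructed 22-residue signal (Met, hydrophobic
core at 6–15, small residues at −3/−1) plus a mature peptide realizing a
chosen framework motif exactly, reverse-translated with uniform synonymous
codon usage and a random stop. Families evolve along random bifurcating
trees (exponential branch lengths, default mean 0.05 expected
substitutions per codon site — keeping within-family protein identity
near 0.9–0.95, as in recently duplicated venom gene families, and inside
the counting estimator's validity range) under a Gillespie codon model:
per-neighbour rate 1/9 (so the neutral total is about one substitution per
unit branch length), nonsynonymous rates scaled by the site's ω, stops
forbidden. Structural-cysteine codons and the signal region are held
invariant, and substitutions *to* cysteine are rejected, so every
descendant retains its framework and the classifier's 100 % recovery is a
meaningful invariant rather than an accident. No indels are simulated, so
the ungapped homology map is the exact alignment truth and the dN/dS
oracle is exact. The default ω profile is 85 % purifying (ω = 0.1), 10 %
neutral (ω = 1) and 5 % positive (ω = 5); the default framework mix follows the relative class abundances of
lycosoid venom-gland surveys, dominated by the eight-cysteine class.

Consequences for interpretation: passing tests demonstrate correctness of
the bookkeeping and the stated statistical properties under this model.
They do not demonstrate robustness to assembly artefacts, alternative
splicing, propeptides, indel-rich alignments, biased codon usage or
predictor noise — none of which the generator emulates.

Decoys violate exactly one screen rule each (stop codon dropped; signal
hydrophobic core replaced by lysines; padded to 250 residues; five
cysteines only; or denied a significant hit in the emitted table) while
satisfying all others, which is what makes rejection-reason audits exact.

## Problem sizes

The shipped tests run the complete suite in well under a minute on one
core: calibration uses 500 replicates of 50 sequences, direction recovery
200 replicates of 20-tip families, the clustering oracle 100 random graphs
of up to 30 nodes. These sizes give the binomial assertions comfortable
Monte-Carlo margins while keeping the suite quick to iterate on.

## Known limitations

- The signal heuristic and the built-in homology search are construction-
  matched stand-ins, not re-implementations of the external predictors.
- The center-star aligner is exact only for the generator's indel-free
  loops; real loop alignments should come through the external-aligner
  path when indel placement matters.
- The counting estimator has no tree, so shared ancestry inflates the
  effective weight of early substitutions; per-site synonymous signal
  rests on at most ~1.3 synonymous sites per codon and is intrinsically
  noisy at single-site resolution.
- Outgroup rows are appended pre-aligned only; profile-add alignment is
  out of scope.
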