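# ickkit

Annotation and molecular-evolution analysis of **inhibitor cystine knot
(ICK) venom peptides** from venom-gland transcriptome data.

Spider venoms are dominated by short cysteine-rich peptides built on the ICK
scaffold: three core disulfide bridges (C1–C4, C2–C5, C3–C6 in the
six-cysteine case) of which one threads the macrocycle formed by the other
two plus the backbone, giving an unusually stable fold that larger
frameworks elaborate with extra cysteine pairs. `ickkit` implements the
analysis stages such a survey needs, as a plain Python library:

- **screen** — the candidate filter cascade: complete CDS (start codon,
  terminal stop, no internal stop), signal peptide present, total length
  < 200 aa, ≥ 6 cysteines in the mature peptide, and a knottin-database
  homology match at e ≤ 10⁻³; plus per-sample proteome/TPM composition
  summaries (%ICK, %TPM).
- **frameworks** — the cysteine-spacing grammar (`CC` adjacent, `CXC` one
  apart, `C-C` further apart), motif rendering/parsing, assignment against
  a packaged seven-class catalog (6.0 … 14.0), novel-framework minting, and
  the top-80 %-coverage retention rule.
- **families** — single-linkage gene families as connected components of an
  identity/overlap-thresholded homology network; CDS deduplication.
- **connectivity** — disulfide-prediction ensembles, perfect-matching
  enumeration ((n−1)!! pairings), majority-vote consensus for the three
  bridges homologous to all classes, chord-diagram JSON export.
- **knot_align** — per-loop alignment of the four loops shared by all
  classes, with flanking cysteines replaced by the barcode `WWYHWYYHMM`
  during alignment so inner cysteines cannot misalign onto anchors; a
  per-sequence amino-acid-composition χ² filter with removal and
  realignment; assembly around gap-free all-cysteine anchor columns; exact
  codon back-translation.
- **selection** — per-codon-site dN/dS summaries: a built-in
  pairwise Nei–Gojobori counting estimator (pooled substitution
  proportions; direction-only validation tool), importers for external
  phylogenetic test results (site posteriors, episodic p-values with Holm
  correction, branch tests, coevolving pairs), threshold classification and
  per-loop reports with the dN-on-dS least-squares fit.
- **synthgen** — a generator of venom-gland-like datasets with full ground
  truth: precursors realizing any catalog framework, families evolved along
  random trees under per-site ω with structural cysteines held invariant,
  and decoys violating exactly one screen rule each.

In site-wise terms, selection is read from ω = dN/dS per codon column of
the knot alignment: ω < 1 purifying, ω ≈ 1 neutral, ω > 1 positive
selection (pervasive when supported across the tree, episodic when
confined to some branches).

## Worked example

```bash
python examples/01_screen_candidates.py
```

prints, for a generated batch of three toxin families plus ten decoys:

```
candidates screened : 35
kept as ICKs        : 25
rejected            : 10
rejections per rule : {'complete_cds': 2, 'homology': 2, 'max_len': 2, 'min_cys': 2, 'signal': 2}
ground-truth ICKs   : 25 (screen agrees: True)
```

Each decoy was built to violate exactly one rule, and the audit recovers
that assignment rule-for-rule. The other examples walk the remaining
stages: `02` framework classification (the motif `C1-C2-C3C4-C5XC6-C7XC8`
is class 8.0), `03` family clustering (four generated families recovered
exactly), `04` connectivity consensus (majority vote returns the canonical
C1–C4, C2–C5, C3–C6 core), `05` the anchored knot alignment (27 sequences,
53 residue columns of which 6 are all-cysteine anchors) and its codon twin,
and `06` a selection summary in which the three sites simulated under
ω = 5 show dN > dS while the purifying background shows dN < dS.

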