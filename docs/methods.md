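# Methods

## The measurement model

A tag digital gene expression (DGE) library represents each polyadenylated
transcript by a single 21-mer: the anchoring enzyme cuts at every `CATG`,
the tagging enzyme releases the 17 bases immediately 3′ of the cut, and
oligo-dT priming means the fragment that survives library construction is
the one nearest the poly-A tail. `tagdge` therefore defines the **canonical
tag** of a gene as `CATG` plus the 17 bases after the *3′-most* `CATG` that
has at least 17 downstream bases; sites whose 21-mer window contains an `N`
are ineligible, and no reverse-complement tags are indexed (cDNA tags carry
mRNA orientation). Genes may share a canonical tag verbatim; such reference
tags are *ambiguous* and their observations are discarded rather than
fractionally assigned — counting only unambiguous tags is what makes the
per-gene counts interpretable as transcript counts.

Whether the original base-calling pipelines used every `CATG` site or only
the terminal one is not documentable from the protocol alone; the 3′-most
choice follows from the oligo-dT chemistry and keeps exactly one tag per
gene, so per-gene counts never double-count a transcript.

## Cleaning

Raw reads are partitioned, in fixed priority order, into: adaptor-only
(no `CATG` anywhere in the read), bad-length (a `CATG` present but the read
is not a 21-mer starting with it), low-quality (any `N`, or any base below
Phred 10 when qualities are available), singleton-removed (aggregate
library-wide tag count exactly 1), and clean. The Phred-10 cutoff is a
deliberate, configurable convention: the protocol's "low sequence quality"
has no published definition, and a permissive per-base floor mimics the
>97% clean-tag yields typical of these libraries. Singleton removal
operates on aggregate per-library counts, not per lane. The partition is
asserted at run time: the five categories always sum to the raw read count,
and cleaning an already-clean library is a no-op.

## Quantification

Observed clean tags are assigned with best-hit semantics:

1. exact match to a unique reference tag → counted for that gene;
2. exact match to an ambiguous reference tag → excluded;
3. otherwise all reference tags at Hamming distance 1 over the 17-bp
   variable region are collected — the anchor must match exactly, since a
   mismatched anchor implies a cleaning failure rather than a sequencing
   error inside the tag — and the tag is counted only if those hits belong
   to exactly one gene;
4. otherwise the tag is unmapped.

Exact matches take strict priority over one-mismatch matches (no mixing of
the two tiers). Expression is `TPM = count × 10⁶ / N` with `N` the
library's **total clean tags**, not the assigned subset, so TPM values are
comparable across libraries with different mapping rates; consequently
`Σ TPM ≤ 10⁶`, with equality only if every clean tag maps unambiguously.
"Expressed" means unambiguous count ≥ 1 by default; one threshold is shared
between the expressed-set (Venn) accounting and the DEG screen so the two
can never diverge.

Saturation curves subsample the library without replacement (nested
prefixes of one seeded permutation, so the curve is non-decreasing by
construction) and count genes with ≥ 1 assigned tag at each depth. At
full depth the curve reproduces the profile's detected-gene count exactly.

## The differential screen

For a gene with `x` tags in a library of `N1` clean tags and `y` tags in a
library of `N2`, the exact conditional (Audic–Claverie) model gives

    P(y | x) = (N2/N1)^y · (x+y)! / ( x! · y! · (1+N2/N1)^(x+y+1) ),

a negative binomial with `x+1` successes and success probability
`N1/(N1+N2)`, evaluated through `scipy.stats.nbinom` in log space.

The textbook two-sided construction `2·min(P(Y≤y|x), P(Y≥y|x))` is **not**
invariant under relabelling the two libraries (the observed point enters
one orientation's lower tail and the other's upper tail asymmetrically;
the discrepancy can reach ~0.1 for moderate counts). A differential test
should not depend on which library is called "first", so `tagdge` uses the
symmetrized form

    p = min(1, 2 · min of the four tails over both orientations).

This is exactly swap-symmetric, coincides with the usual construction when
the libraries are balanced, is marginally anti-conservative relative to a
single orientation (these discrete exact tests are strongly conservative to
begin with), and its family-wise null behaviour is verified empirically
(below). Identical observations in equal-size libraries give p = 1.

Benjamini–Hochberg step-up adjustment (via `statsmodels`) is applied per
transition over all genes tested in that transition — not globally across
transitions, since each transition is a separate biological question. A
gene is declared differentially expressed when `q ≤ 0.001` and
`|log2FC| ≥ 1` (both configurable). Fold changes are computed on TPM; a
gene detected in exactly one stage has infinite |log2FC| and is classed
`on`/`off` (no pseudocounts — the on/off bracket is reported separately,
and such genes automatically satisfy the fold criterion while still
requiring a significant q-value). Finite classes are half-open: 2–4× is
[2, 4), 4–8× is [4, 8), ≥8× is [8, ∞); the boundary value 4 belongs to
4–8×.

## Synthetic data: what it emulates and what it does not

The generator reproduces the study conditions the pipeline targets:
~10⁴ genes of 300–3,000 bp, four stage libraries of millions of 21-mer
tags, baseline abundances lognormal(0, σ=1.5) (a realistic tag-DGE dynamic
range of ~4 orders of magnitude), 1% per-base substitution error by
default, 3% of genes without any `CATG` site, 5% of genes expressed in
exactly one stage, and a per-transition differential design (~9% of genes)
with designed fold factors drawn uniformly inside each class interval
(2–4, 4–8, and 8–16 for the open-ended class) in both directions, plus
outright on/off switching. Disjoint gene sets carry each role, so every
designed label is unambiguous; designed fold factors persist into all later
stages. Per-stage abundances are renormalized to sum to 1 over expressed
genes. Reads are emitted directly as 21-mers — the sequencer and adaptor
trimming are not modelled — with an optional malformed-read injection
(adaptor-only and wrong-length reads) to exercise the cleaning stage.
Sequencing error is substitution-only, matching the one-mismatch mapping
tolerance; indels, PCR duplication, rRNA contamination and poly-A selection
efficiency are not modelled. One root seed drives separate, documented
streams for catalog, truth and each library, so every piece is
independently reproducible.

**Compositional caveat.** Because abundances are renormalized per stage, a
mass-asymmetric differential design (e.g. more up- than down-regulation)
compresses every realized *relative* fold by the stage-sum ratio (~1.2×
under the defaults). TPM is relative, so this compression is what the data
genuinely show — it is the same effect that motivates robust normalization
in modern RNA-seq. The recovery experiments therefore judge fold-class
agreement against the class of the *realized* truth abundance ratio, with
a boundary allowance: the measured class bin must intersect the ±2·SE
interval of the realized log2 fold (SE = sqrt(1/x + 1/y)/ln 2 from the two
counts). Passing tests on this synthetic data demonstrate correct
bookkeeping, calibrated error control and power under multinomial sampling
with substitution error; they do not demonstrate robustness to biological
replicate variability (the exact test models sampling, not dispersion —
negative-binomial dispersion tests postdate this design and are out of
scope).

## Operating characteristics (computed by the tests and acceptance script)

* **Null FDR** (`scripts/acceptance.py`, `tests/test_acceptance.py`):
  20 replicate pairs of libraries (5,000 genes, 2·10⁶ tags each, zero
  error) drawn from one identical truth, each run through the complete
  cleaning/mapping/screening pipeline. Realized FDR per replicate is
  `V/max(R,1)`; the mean across replicates must not exceed the 0.001
  screening threshold.
* **Recovery**: on the designed four-stage truth at 2·10⁶ tags and zero
  error, ≥95% of designed ≥8-fold genes with earlier-stage truth abundance
  ≥ 20 TPM must be recovered as DEGs with the correct direction, with
  TPM–truth Spearman > 0.99 per stage and ≥90% realized-class agreement.
* **Oracle equivalence**: tag extraction vs an exhaustive position scan
  (10⁴ random sequences), tag mapping vs an exhaustive observed×reference
  Hamming comparison (10³ genes × 10⁴ tags), the exact test vs direct tail
  summation to y = 10⁴ (within 10⁻¹⁰ over the x, y ≤ 200 grid at library
  ratios 0.5/1/2; swap symmetry within 10⁻¹²), BH vs the hand-written
  step-up formula, Venn/category tables vs per-gene enumeration.

Problem sizes for these experiments (5,000 genes, 2·10⁶ tags, 20
replicates) are the package's standard validation scale: large enough that
multinomial noise is at the level where the screen's thresholds bind, small
enough to run routinely.

## Numerical and design choices

* Tail probabilities come from `scipy`'s negative-binomial CDF/SF (regularized
  incomplete beta), accurate in the extreme tails; the brute-force oracle
  used in tests sums the pmf in log space.
* BH preserves ties and restores input order; `q ≥ p` elementwise always.
* Saturation subsampling is without replacement; the closed-form
  with-replacement detection probability `1-(1-p)^d` is used only as a test
  approximation at depths well below library size.
* `log2FC` direction ties (identical TPM) get direction `none`; such genes
  can never pass the fold criterion.
* qPCR replicates are averaged on the Ct scale before differencing (Livak
  convention), no amplification-efficiency correction; the calibrator's RQ
  is exactly 1 by construction, and adding a constant to all Ct values of
  one stage (target and reference alike) cancels exactly.
* The category report multi-counts a DEG once per category it carries
  (single-counting within a category) and tallies unannotated DEGs
  separately; sparse categories are dropped only by the cross-transition
  minimum-total filter (default 4), never silently.

## Known limitations

* Biological replication is absent from both model and simulator; p-values
  describe sampling noise between two libraries, as in the original
  two-library tag-DGE designs.
* Only the terminal (3′-most) tag per gene is indexed; genes whose terminal
  tag is ambiguous are invisible to quantification even if internal sites
  would be informative.
* The one-mismatch tolerance is substitution-only; an indel inside a tag
  makes it unmappable.
* Genome-coordinate (intergenic/antisense) tag mapping is out of scope; the
  catalog is transcript-scoped.
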