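# Methods

## The phasing problem

A diploid genotype over *m* biallelic SNP sites is a string over
`{0, 1, 2, ?}`: `0` homozygous for the major allele, `1` homozygous minor,
`2` heterozygous, `?` missing.  A pair of haplotypes *h′, h″* over `{0, 1}`
*resolves* a genotype *g* when, at every non-missing site, both haplotypes
equal the genotype value where it is 0 or 1, and carry `{0, 1}` in some
order where it is 2.  Phasing a population of *n* genotypes means choosing
one resolving pair per individual.  Because every heterozygous site doubles
the number of candidate pairs, exact inference is intractable; this package
implements a fast three-step heuristic that exploits the block structure of
real populations, in which a few *common haplotypes* carry almost all the
frequency mass of each short block of consecutive SNPs.

All containers are `int8` numpy arrays (`-1` encodes `?`); rows `2i` and
`2i+1` of the working `2n x m` haplotype matrix belong to individual *i*.
The whole pipeline is single-threaded and deterministic.

## Step 1 — cis/trans chaining over adjacent heterozygous pairs

For an ordered site pair *(i, j)* the two-site haplotype counts
F00/F01/F10/F11 are accumulated from every individual whose two cells are
unambiguous: homozygous/homozygous individuals contribute their (identical)
haplotype twice, individuals with one heterozygous cell contribute both
implied haplotypes once, and individuals with `2|2` or any `?` at the pair
contribute nothing.  A heterozygous pair is *cis*-phased (resolved 00/11)
when `F00*F11 >= F01*F10` and *trans*-phased (01/10) otherwise; the product
comparison is the certainty statistic of pairwise phasers in this family,
and the tie (including the no-evidence case) goes to cis because pairing
the two major alleles is the a-priori likelier configuration.

Each individual's first heterozygous site is fixed to 0 on row `2i` and 1 on
row `2i+1` (the canonical orientation); every later heterozygous site keeps
the previous site's row assignment under cis and flips it under trans.
Homozygous sites are copied to both rows and `?` cells stay `?`.  Pair
decisions are cached by site pair, so the step costs O(nm).

## Step 2 — scalable sliding windows

A window `(start, length)` is shared by all individuals.  The current
haplotype rows define a frequency table of window segments (segments
containing `?` are excluded — they are not realized haplotypes, and counting
them would inflate wildcard matches).  For one individual's genotype segment
g^w, the *compatible pairs* are the unordered pairs of observed segments
whose site-wise combination reproduces g^w, with `?` in g^w matching any
allele pair.  Pair *i* with segment frequencies F1_i, F2_i gets weight

    w_i = F1_i * F2_i / Σ_j F1_j * F2_j .

On the classic uneven five-SNP block (seven haplotypes with counts
66/24/10/6/1/1/1) the genotype segment `02002` has exactly two compatible
pairs, and this weight gives 1584/1590 ≈ 0.996 to (00000, 01001) — the
"99% / 1%" split of the worked example.  When the top weight exceeds the
threshold τ the individual's two window segments are overwritten by that
pair; `?` cells inside the window thereby receive alleles.  The replacement
is oriented to minimize the Hamming distance to the current rows (ties give
row `2i` the lexicographically smaller segment), which avoids spurious
switches at window borders.

Windows of every length from `l_min` to `l_max` slide one position at a
time, left to right.  The frequency table is recomputed from the current,
progressively corrected solution at each `(start, length)` window and held
fixed while that window's individuals are processed — a greedy in-place
sweep.  Defaults: τ = 0.70 (the commonest block haplotype is typically more
than 3x as frequent as the rare ones), `l_min` = 3, `l_max` = 10 (block
lengths rarely exceed 10 SNPs).

### Long heterozygote gaps

When two consecutive heterozygous sites of an individual are more than
`l_max` sites apart, no window covers both, so their relative orientation is
decided separately.  Every other haplotype row with known alleles at the two
sites is classified by those alleles (00/11/01/10) and contributes the
Hamming distance between its segment strictly inside the gap and the
individual's (homozygous) genotype segment there (`?` positions skipped,
unnormalized count, own rows excluded).  The cis weight is the product of
the 00 and 11 class sums, the trans weight the product of the 01 and 10
sums; smaller distance means greater similarity, so the smaller weight wins
and, if it contradicts the current phasing, the rows exchange their
suffixes from the right heterozygous site onward.  An empty class makes its
pattern's weight +∞ (a zero product from an *absent* class would otherwise
always win); two infinite weights keep the current phasing.  Gap correction
runs once per qualifying gap after the window sweep.

## Step 3 — imputation and maximum-parsimony refinement

**Imputation.**  Each residual `?` in a haplotype row is voted on inside a
length-9 window centered on the missing column (truncated near chromosome
ends).  Rows carrying 0 at the column add their Hamming distance to the
target row (missing positions excluded) to W0, rows carrying 1 to W1; the
allele with the smaller sum wins.  Ties and empty classes fall back to 0,
the major allele.  The class sums are used literally, without normalization
by class size (a `normalize` option was considered and left out: the
unnormalized sum is the cited classical rule, and the bias toward small
classes only matters when both classes are nearly equidistant).  Cells are
processed in row-major order, so an imputed allele participates in later
votes; both rows of an individual at a missing genotype cell are voted
independently — any resulting pair is legal there.

**Parsimony.**  A *recombination* exchanges the suffixes of an individual's
two rows at a heterozygous site (prefixes kept, suffixes swapped), which
preserves compatibility by construction.  Passes visit individuals in input
order; for each individual the heterozygous sites are scanned left to right
and the first switch that strictly decreases the number of distinct
haplotype rows in the whole solution is accepted — at most one per
individual per pass, with passes iterated until none is accepted.  The
per-pass cap is the reading of "at most one recombination per genotype"
that is consistent with iterating to a fixpoint; since the distinct count
(exact string equality, no mismatch tolerance) strictly decreases on every
accepting pass, termination is guaranteed within the initial distinct
count.  The count is maintained incrementally with a multiset of row
hashes, so each candidate move costs O(m).

## Accuracy metrics

**IER** (individual error rate): the fraction of individuals whose unordered
haplotype pair differs from the truth anywhere over the evaluated sites.
**SER** (switch error rate): pooled switch errors divided by pooled
heterozygous loci, where a switch error is a flip of the predicted
orientation relative to truth between consecutive evaluated heterozygous
sites (the first anchors).  Variant 1 of each metric excludes cells masked
to `?` in the genotype matrix; variant 2 includes them and therefore also
penalizes imputation mistakes.  Conventions the definitions leave open,
resolved here: heterozygous loci are taken from the truth; the denominator
pools *all* evaluated heterozygous loci (not hets−1 per individual); sites
where the prediction is not heterozygous — possible only at masked cells —
are skipped in the orientation chain but kept in the denominator.  Both
metrics are invariant to swapping the two rows of any individual.

## Synthetic populations

The generator emulates block-structured panels: block lengths uniform on
[3, 10]; per block, 4 common haplotype segments drawn without replacement
and given Dirichlet frequencies (decreasing concentration 4,3,2,1, matching
the one-dominant-pattern shape of observed blocks) scaled to 97% total
mass, plus 3 rare segments sharing the remainder; each chromosome follows a
lineage index through the block pools, redrawn with probability
`recomb_rate` (default 0.02, a modest between-block shuffling) at each
boundary; individuals pair two independent chromosomes; genotype cells are
masked to `?` at `missing_rate`; allele 0 is recoded to the per-site major
allele.  Everything derives from one integer seed.

What this does *not* emulate: coalescent genealogies, mutation, linkage
decay within blocks, genotyping error, and realistic minor-allele-frequency
spectra.  Tests passing on these populations therefore demonstrate the
mechanics of the algorithm under its own modelling assumptions (strong
block structure, few common haplotypes), not accuracy on real panels.

A deterministic fixture builds the classic uneven five-SNP block: the seven
haplotypes are expanded by their counts into 109 chromosomes and paired
round-robin (chromosome *i* with *i*+55, cyclically; the single unpaired
chromosome is dropped), giving 54 genotypes with known truth.

## Problem sizes and numerical choices

The test suite exercises the invariants on matrices up to 30 individuals x
50 sites (1000 random cases for the compatibility property) and the
recovery experiments on 200 individuals x 100 sites over 20 seeds —
comfortable interactive sizes for a pure-Python/numpy implementation; the
pipeline scales as O(nm) + O(n²m) like its pairwise ancestor.  Degenerate
inputs are handled explicitly: all-homozygous individuals pass through
unchanged; a population with no usable voter anywhere imputes the major
allele; empty compatible-pair lists leave the phasing untouched; windows
never extend past the chromosome.

## Known limitations

- Step 2 corrects against frequencies of the *current* solution: when step 1
  mis-phases a common pair so consistently that one of its haplotypes never
  appears among the working rows, the sweep cannot restore it (visible on
  the deterministic block fixture, where every individual shares the
  dominant haplotype).  The method's strength is majority correction, not
  recovery from correlated initialization error.
- One recombination per individual per pass bounds the refinement's reach;
  multi-breakpoint rearrangements are out of scope.
- Only biallelic sites are supported; multi-allelic VCF records are skipped.
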