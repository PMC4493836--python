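# Methods

This note documents the models, parameter choices and numerical
conventions behind `methamark`, and what the synthetic benchmarks do and
do not demonstrate about real amplicon data.

## Degenerate-sequence algebra

A degenerate oligo is a string over the 15-letter IUPAC nucleotide
alphabet; each code denotes a base set (R = {A,G}, …, N = {A,C,G,T}).
Its *degeneracy* — the number of concrete oligos in the pool — is the
product of per-position set sizes and is always computed
multiplicatively; explicit expansion is capped at 10⁶ members and
refuses beyond that, since enumerating an N-rich oligo is invariably a
caller error. Reverse complement maps each code to the code of the
complemented base set, making it an involution that commutes with
expansion.

Base matching between a primer code and a template code defaults to
*non-empty expansion intersection*: a template `N` (common in draft
genomes) binds any primer base at zero mismatch cost. A strict mode
(`strict_template_ambiguity`) instead requires the template set to be
contained in the primer set. Input is case-insensitive and `U` is read
as `T`.

## Primer design

"Conserved region" is operationalised as a gap-bounded alignment window
whose *minimal covering consensus* stays under a degeneracy cap. Per
column, bases are accumulated most-frequent-first until they cover at
least `min_coverage` of the sequences (default 1.0 — every observed
base), and the smallest IUPAC code containing that set becomes the
consensus. Candidate windows span the primer length range (16–25 nt)
and drop out when any column's gap fraction exceeds `max_gap_fraction`
(default 0) or window degeneracy exceeds `max_primer_degeneracy`
(default 1024).

Pairs are ranked by pair degeneracy ascending (lowest-degeneracy pools
amplify most evenly), ties broken by product length descending (longer
amplicons carry more phylogenetic signal), then leftmost start — a fixed
order that makes output deterministic. Expected product length on a
gapped alignment is ill-defined under indels; we use the **median
ungapped distance** from forward-window start to reverse-window end
across member sequences, which is robust to outlier insertions. The
default product cap is 500 bp (compatibility with short-read amplicon
sequencing); `min_product_bp` (default 0) exists because a library
destined for 250-bp paired-end sequencing needs products long enough to
yield ≥ 30 aa translated fragments and short enough for the mates to
overlap — the synthetic sequencing experiments design with
`min_product_bp=250, max_product_bp=480`, mirroring the 350–440 bp
range of the published marker amplicons.

Hypervariable families that admit no pair are partitioned along a
neighbor-joining guide tree built from pairwise p-distances (fraction of
differing shared non-gap columns). The non-designable group is bisected
at its longest internal branch (both sides ≥ 2 leaves) until every group
is designable or `max_groups` is reached. NJ on p-distance is a
deliberate approximation to a full ML guide tree; for the clustering
decision only the deepest split matters, which NJ recovers reliably at
the divergences involved. The two-clade benchmark uses a degeneracy cap
of 1: with ~30% between-clade divergence scattered uniformly, windows of
low but non-trivial degeneracy still occur by chance in a 900-column
alignment, so only the strictest cap makes "designable" equivalent to
"clade-homogeneous" — which is precisely the situation that forces a
family split in practice.

## In-silico PCR

Binding sites are found by positional Hamming scanning (no indels),
matching iPCRess semantics: a window is a site when the number of
positions failing `base_match` is within the per-primer budget
(default 2; the longer *mcrG* primers use 4). IUPAC-compatible
positions cost zero mismatches. Scanning is vectorised over 4-bit base
masks. Products require both primers bound convergently, non-overlapping
sites, and product length within ±`product_tolerance_bp` (default 50)
of the pair's expected length; both template orientations are examined
and amplicons are reported 5′→3′ from the forward primer. No 3′-clamp
is applied by default; `clamp_3prime=N` optionally requires zero
mismatches in the primer's last N bases. Templates shorter than the
primer yield no sites, not an error.

## Amplicon validation pipeline

**Merging.** For each read pair, read 2 is reverse-complemented and all
overlaps ≥ `min_overlap` (default 10 nt) are scored by matched bases;
the best overlap is kept if its mismatch fraction is ≤ 0.25. Overlap
conflicts resolve to the higher-quality base (ties to read 1). This
maximum-matched-bases objective approximates FLASH's scoring; on
substitution-only synthetic data with constant qualities it is exact
and deterministic. Note one corner case: on periodic fragments the
maximum-matches objective can prefer a shorter self-similar overlap —
irrelevant for real amplicons but worth knowing when constructing toy
examples.

**Translated search.** Merged reads are translated in all six frames
(standard code, `*` marks stops) and locally aligned against every
reference peptide with BLOSUM62 and BLAST-style affine gaps (a gap of
length k costs 11 + k). The best HSP's E-value follows the
Karlin–Altschul form E = K·m·n·e^(−λS) with the standard gapped
BLOSUM62 constants λ = 0.267, K = 0.041, m the frame's peptide length
and n the configured effective database size (default 10⁶ letters, kept
in config so results are self-contained). Hits with E > 0.001 are
no-hits. This replaces an external BLASTX dependency while preserving
the threshold semantics; the constants are matrix-specific, so changing
the matrix without adjusting them shifts the E-value scale.

**Filters and sensitivity.** A read survives when its best HSP has a
reference hit, a stop-free peptide, and ≥ 30 aa (30 kept, 29 dropped).
The E-value cut is applied before the no-hit category is counted.
Primer sensitivity is `floor(100·peptides/merged)` — truncation, not
rounding, which reproduces the published validation percentages
exactly for every internally consistent run. Counts always satisfy
`peptides + no_hit + stop + short == merged`.

**Nucleotide QC** (for 16S-style reads): drop reads < 50 nt, with > 2%
ambiguity codes, or with > 2% of bases inside homopolymer runs. "2%
homopolymers" is not precisely defined upstream; we count bases within
runs ≥ 8 nt (configurable), a common operationalisation.

## Phylogenetic placement

Queries are projected into the fixed reference protein alignment by
locally aligning against each ungapped row and inheriting the columns of
the best row (insertions relative to that row are dropped); queries
placing < 10 residues are unalignable and count as unclassified.
Identity to every leaf is computed over mutually non-gap columns;
leaves within `near_tie_margin` (default 2 percentage points) of the
best are candidates. One candidate → placement at that leaf, mass 1;
several → placement at their last common ancestor, mass 1. An optional
multi-placement mode spreads mass over the top k leaves proportional to
identity. The 2% margin absorbs alignment noise without collapsing
distinct genera in the synthetic benchmarks.

This scorer deliberately replaces full ML evolutionary placement
(PROTGAMMAWAG EPA) with an interface-compatible approximation
(query → node + mass); an ML backend can be swapped in without touching
callers. It ignores branch lengths and rate heterogeneity, so its
accuracy claims are limited to the clean synthetic regime below.

Mass trimming removes placements at nodes whose aggregated mass is
below `min_mass` (default 0.01) of the total; a node exactly at the
threshold survives. This is a flat per-node simplification of guppy's
leaf-to-root mass trimming; the threshold is configurable.
Classification uses the composite score `(%identity + %coverage)/2 > 93`
(strictly exceeding). Abundance tables attribute an internal-node
placement to the deepest rank shared by its subtree's leaves; counts
that cannot honestly be attributed at the requested rank stay at the
shared shallower taxon, and classified + unclassified fractions sum to
1 (± 1e-9). Fat-tree PhyloXML export sets branch width proportional to
assigned read count and colors root-to-placement paths red, everything
else black.

## Synthetic data: what it emulates, and what it does not

Families evolve from a random stop-free codon ancestor (900 nt, 12
leaves by default) down a random bifurcating tree with exponential
branch lengths (mean 0.08), substitution rate 1.0 per site per unit
branch length, and two planted conserved blocks (60 nt at multiplier
0.05) — a caricature of the conserved regions that real marker-gene
primers target. Substitutions only: no indels, so positional Hamming
PCR and truth-table checks remain exact (an indel mode is out of scope
of the benchmarks). Libraries emulate 250-bp MiSeq pairs with a planted
on-target fraction, per-base substitution errors (default 0.002,
MiSeq-like after quality trimming) and random-fragment contamination;
qualities are constant (Phred 35) so merging is deterministic.
Identical seeds give identical outputs.

Passing benchmarks therefore show that the statistics recover planted
truth under substitution noise and random contamination. They do not
demonstrate robustness to indel sequencing errors, PCR chimeras,
abundance skew, conserved off-target homologs, or base-quality
variation — all absent from the generator by design.

The end-to-end sensitivity recovery (on-target fractions 0.3/0.6/0.9,
2,000 pairs) lands 1–4 points *below* 100p because a fraction of
on-target reads is lost to error-induced stop codons — the same
frameshift/stop leakage the real pipeline's discard rules exist for.
The 5-point tolerance accommodates this bias plus binomial noise
(~1 point at n = 2,000).

## Problem sizes

Benchmarks use 12-leaf families (20 leaves for the two-clade
partition), 2,000 read pairs per library, 20 design/partition
replicates and 200 placement trials — sizes at which every statistic's
sampling error is well inside its acceptance band while the full test
suite runs in a few minutes on one CPU.

## Known limitations

- E-value calibration is anchored to BLOSUM62 11/1; other matrices
  reuse the same Karlin–Altschul constants.
- Placement ignores branch lengths; identities, not likelihoods.
- Merge scoring is an approximation of FLASH's objective.
- The degeneracy-1 requirement in the two-clade benchmark makes
  "designable" a sharp proxy for clade homogeneity; with relaxed caps
  the correct behaviour is often *not* to split, and the partitioner
  honors that.
- No thermodynamic screening (melting temperature, hairpins, dimers):
  annealing behaviour is taken as an experimental, not computational,
  property.
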