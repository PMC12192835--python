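# Methods

This note documents the models, algorithms and numerical choices behind
`plastobarcode`, and what the synthetic-data tests do and do not establish
about behaviour on real plastomes.

## Coordinates and records

All internal coordinates are 0-based half-open on the forward strand.
Circularity is handled explicitly: a feature that wraps the origin is an
interval pair `[(start, n), (0, end)]`, and region intervals may be stored
unwrapped (`end > n`).  Conversion to and from GenBank's 1-based inclusive
locations happens only in `genome_io`, via Biopython.  Gene symbols are
normalised on input (qualifier prefixes stripped; tRNA anticodon
hyphenation unified, e.g. `trnMCAU` → `trnM-CAU`) because public
annotations spell these inconsistently.  IR-duplicated genes keep both
copies with a `copy_tag` (`IRb`/`IRa`) for structure reports but are
counted once in the shared-locus table, so a duplicated gene cannot be
double-counted as two barcode candidates.  Trans-spliced `rps12` is
excluded from barcode candidates by default (its exons are not contiguous;
a concatenated "locus" would be chimeric).  Intergenic loci are gaps of at
least `min_intergene_len` (default 10 bp — shorter spacers are unalignable
noise) between consecutive genes in circular order, named
`upstream-downstream`.

## Quadripartite structure detection

The IR pair is found by exact 25-mer seeding between the sequence and its
reverse complement.  Seed matches for an inverted pair share the
anti-diagonal constant `a + b + k − 1 (mod n)`; the anti-diagonal with the
longest run of consecutive seeds gives an exact core, which is then
extended outward with an X-drop rule (match +1, mismatch −3, give up when
the running score falls 12 below its maximum) subject to the global
mismatch fraction staying within `max_mismatch_frac` (default 0.01).  The
furthest running-max position is the reported boundary, so a crisp
boundary — a mismatching base immediately outside the repeat — is
recovered exactly, while isolated interior mismatches and small clusters
are crossed.  Ties between equal-length candidates go to higher identity,
then lower start.  The two single-copy stretches between the IR copies are
labelled LSC (longer) and SSC (shorter), and the partition is reported in
the conventional LSC → IRb → SSC → IRa order; detection is
rotation-invariant because seeding works on circular k-mers.  Genomes
shorter than `4 × min_ir_len` or without an inverted pair of at least
`min_ir_len` (default 1000 bp) raise `NoIRFound` rather than returning a
degenerate partition.

The choice of X-drop extension (rather than a fixed mismatch-run jump) is
deliberate: with 0.5% divergence between the copies, mutation clusters a
few bases apart occur regularly, and a rule requiring a long clean stretch
after every crossed run truncates the repeat at the first such cluster.

## Repeat detection

**SSRs.**  Maximal perfect tandem runs are found per period p (1–6) from
the match vector `s[i] == s[i+p]`; a run qualifies if its repeat count
meets the per-period minimum (10/5/4/3/3/3, the MISA-style convention for
plastomes) and its motif is primitive (not itself a repetition of a
shorter motif), which implements "report at the smallest period": a poly-A
run is never also reported as an AA dimer.  The reported span includes a
partial trailing repeat (count·period ≤ length < (count+1)·period).
Circular genomes are scanned on the doubled sequence with hits
deduplicated by start modulo n and lengths capped at n.  Compound SSRs
(adjacent different motifs) are reported separately, not merged.  Motif
classes are canonical under rotation and strand, displayed as
`smallest-rotation/its-reverse-complement` (`A/T`, `AAT/ATT`, …).

**Long repeats.**  Four copy relations are searched, following REPuter's
vocabulary: the second copy equals the first (F), its reverse (R), its
complement (C) or its reverse complement (P).  All four reduce to diagonal
matching between the sequence and a transformed copy (F/C on diagonals,
R/P on anti-diagonals), so one scanner serves all types.  A hit is a
maximal window with at most `max_mismatch` (default 3) interior
mismatches, at least `min_len` (default 20 bp), match-bounded at both
ends.  Enumeration is exact but avoids O(n²) work: any qualifying window
must contain an exact k-mer with `k = min_len // (max_mismatch + 1)`
(pigeonhole), so k-mer seed pairs are generated by hashing, merged into
per-diagonal segments, and a numba kernel runs the maximal-window queue
scan only around segments.  Two post-processing rules define the reported
hit set: copies must be disjoint (tandem arrays are SSR territory, and a
near-palindromic centre would otherwise self-pair), and overlapping
candidate windows on one diagonal collapse to the single best (longest,
then fewest mismatches, then leftmost) — without this, one planted repeat
surfaces as a cluster of shifted windows, one per mismatch quadruple in
its flanks.  A brute-force per-diagonal enumerator (tests/oracles.py) is
the correctness authority; detector ≡ oracle on hundreds of random and
planted sequences, including the 3-vs-4 mismatch boundary.  `N` never
matches anything, including another `N`.  The genome's own IR pair
naturally appears as one long P hit; `exclude_ir=True` with the partition
intervals removes it.  Length spectra use the conventional plastome bins
(20–30, 31–40, 41–50, 51–60, >61; lengths above 60 fall in the last bin,
whose label follows the field's printing).

Note on background rates: in random sequence the expected number of
≥20 bp/≤3-mismatch hits grows as n² (≈90 chance hits in a 40 kb genome).
Real and synthetic plastome repeat counts therefore depend on length and
composition, and ground-truth tests assert that planted repeats are
recovered at their coordinates, not that no other hits exist.

## Variant calling

Deposited plastomes differ in origin and occasionally strand, so the query
is first rotated/flipped onto the reference frame: shared unique 21-mers
vote for an offset `(ref_pos − query_pos) mod n`; the orientation with
more shared k-mers wins, and the winning offset is refined to the shared
anchor nearest the reference origin so the circular seam aligns exactly
even when indels shift downstream anchors.  Fewer than 10% shared unique
k-mers raises `UnrelatedSequence`.

Alignment then chains unique 21-mer anchors (longest strictly increasing
subsequence), merges same-diagonal anchors into blocks, and closes
inter-anchor gaps up to a band (default 5000 bp, enough to bridge the IRs,
which contain no unique k-mers) with Biopython global alignment (match +1,
mismatch −1, gap −4 to open plus −1 per base; identical gap flanks are
stripped before the DP, which makes IR-sized identical gaps free).  Chain
coverage below 50% raises `ChainFailure`.

Each mismatch column becomes one SNP (transition = purine↔purine or
pyrimidine↔pyrimidine, else transversion); each maximal gap run becomes
one indel event — per-event counting keeps per-genome indel totals on the
scale practitioners report, instead of inflating them per base.  Indels
are left-normalised (VCF convention): the allele is rotated leftward while
the preceding reference base equals its last base, so any
shift-equivalent placement maps to one canonical record.  The synthetic
generator records its planted indels through the same normalisation
convention, which is what makes exact sensitivity/precision accounting
well-defined in homopolymer contexts.  Sites with N on either side are
excluded.  Variants carry a region label (from the quadripartite
partition) and a locus context (containing gene, flanking intergene, or
`-`).

## K2P divergence and barcode resolution

For two aligned sequences, sites with a gap or N in either are excluded;
with P and Q the transition and transversion proportions over the
remaining sites, `d = −½·ln(1−2P−Q) − ¼·ln(1−2Q)`.  Saturated pairs
(non-positive log arguments) are flagged undefined, never capped.  To
first order d → P + Q as divergence → 0, asserted numerically at 10⁻⁴.

**Resolution** of a locus set is the percentage of accessions carrying a
unique haplotype there.  This per-accession reading is adopted because
published intraspecific resolution percentages on 34-accession panels are
all integer multiples of 100/34 (8.82 = 3/34, 44.12 = 15/34, …); a
clade-based alternative would not produce that granularity.  The
uniqueness test uses exact haplotype string equality on the locus
alignment rather than `d > 0`: it is robust to undefined-distance masking
and counts indel-only differences as divergence, which matters for
intergenes.  The matrix route (`resolution_score`, positive distance to
every other accession) is kept for K2P-matrix workflows and agrees with
the haplotype route whenever differences are substitutions.

Loci of unequal length are aligned progressively: every sequence is
globally aligned to the longest one and insertion columns are merged,
left-aligned, gap-padded.  Conspecific loci are near-identical, so this
pairwise-to-reference strategy is adequate and keeps the pipeline
deterministic with no external aligner.  For panels of diverged species a
proper MSA tool should replace it; that is the main known limitation of
the barcode module.

**Concatenation search** enumerates locus sets exhaustively for every size
k with C(n, k) ≤ budget (default 20,000; always for k ≤ 2) and switches to
beam search (default width 50) above that, expanding each kept set by one
locus at a time.  Concatenation can only grow the resolved set (adding
columns never merges two distinct haplotypes), so resolution is monotone
in set inclusion — the property that makes greedy/beam search sensible and
that the tests assert.  Results are ranked by resolution, then fewer loci,
then shorter concatenation, then name; evaluated pair counts are reported
by category (gene_gene, gene_intergene, intergene_intergene).  The module
is deterministic; there is no RNG anywhere in the search.

## Trees

Neighbor joining follows the Saitou–Nei agglomeration with the textbook
Q-criterion; ties go to the smallest index pair.  A negative branch-length
estimate is clamped to zero with the deficit moved to its sister edge, so
the joined pair keeps its estimated total length.  NJ recovers the true
topology on additive matrices (tested at RF = 0 over random 4–12 taxon
trees) and matches dendropy's independent NJ on arbitrary matrices.
Bootstrap resamples alignment columns with replacement (numpy generator
seeded from the single run seed), rebuilds the K2P matrix and NJ tree per
replicate, and maps bipartition frequencies onto the full-data tree (not a
consensus tree); replicates whose resampled matrix contains undefined
distances are dropped from the denominator.  Outgroup rooting places the
root mid-edge on the split of the smallest clade containing all outgroup
taxa; a non-monophyletic outgroup roots on the best-overlap edge with a
warning.  Newick I/O goes through dendropy with supports as internal node
labels and 6-decimal branch lengths.  Distance-based NJ is used throughout;
likelihood inference is out of scope.

## Synthetic data: what it emulates

The generator builds a circular quadripartite reference: random
single-copy regions, a random IRb with IRa set to its exact reverse
complement after all planting (so anything written into the IR region is
mirrored consistently), genes tiled with intergenic gaps (CDS-like
content: ATG + uniform sense codons + stop), junction-flanking genes as in
real plastomes (one spanning LSC/IRb, one spanning SSC/IRa, one just
inside SSC, one near IRa/LSC), IR-internal duplicated genes, and planted
SSRs and long repeats written into intergenic gaps with flanking breaker
bases so the planted run is maximal by construction.  Complementarity is
likewise broken just outside the IR boundaries, making "exact boundary
recovery" a well-posed assertion.  Defaults are 40 kb genomes with 5 kb
IRs (fast tests); `paper_scale()` gives 160,928 bp with 26,353 bp IRs and
real-plastome region proportions.

The population derives accessions from the reference with per-accession
Poisson SNP counts (default 0.4/kb, transition:transversion 2:1), indel
events (default 0.2/kb, 1–7 bp), shared group-level transition SNPs at
diagnostic loci, and start-coordinate rotations (two accessions get large
displaced starts, emulating off-origin database deposits).  Events land
only in single-copy regions, at least 25 bp from feature boundaries and
20 bp from planted repeat tracts, with minimum spacing (10 bp between
SNPs, 60 bp around indels) — these margins are what make exact
sensitivity/precision = 1.0 a fair target, mirroring the usual exclusion
of repeat-tract calls from benchmark accounting.  All events are recorded
on the reference coordinate frame and verified against the emitted
sequences at generation time.  Randomness comes from one seed with
numbered substreams per stage; the same seed reproduces byte-identical
output.

What passing these tests does **not** show: performance on diverged
(interspecific) panels, on annotation errors beyond what parsing tests
cover, on IR length polymorphism between accessions, or under
non-uniform base composition (real plastomes are AT-rich; the background
here is uniform, so absolute chance-repeat rates differ from real
genomes).

## Pipeline

`run_pipeline` executes extract → structure → rscu → repeats → variants →
barcode → tree, writing TSV/FASTA/Newick only — no binary state — each
file headed by a comment naming the config hash and seed.  A genome that
fails parsing or a stage is quarantined in the manifest and the run
continues; zero parseable genomes abort.  Re-running with unchanged
inputs and config reproduces every file byte-identically.  RSCU pools
single-copy CDS annotations only (IRa copies excluded), so duplicated
genes are not counted twice.  The bootstrap tree is built on the
best-ranked locus combination.  Default problem sizes in the test suite
(20–40 kb genomes, 4–12 accessions, 30–200 bootstrap replicates) are
chosen so the whole suite exercises every stage in a few minutes; all of
them scale up by configuration.
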