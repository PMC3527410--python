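# Methods

This note documents the generative model behind the simulator, the
algorithmic definitions used by each pipeline stage, the defaults and
why they were chosen, and what the tests do and do not demonstrate.

## Library-prep model (simulator)

One synthetic run draws:

* **Genome.** `genome_length` i.i.d. uniform bases (default 2 Mb), plus a
  fragmentation into `n_scaffold_breaks + 1` scaffolds (default 20) at
  uniform random breakpoints; each scaffold is stored reverse-complemented
  with probability 0.5 and the true order/orientation is recorded for
  scoring the scaffolder. The 2 Mb desk scale keeps every experiment in
  seconds while leaving ≥ 10 insert lengths of genome, the minimum the
  generator enforces.
* **Clones.** `n_clones` clones; a fraction `negative_clone_fraction`
  (default 0.12, the insert-free rate of the library the defaults
  emulate) carry no insert. Positive clones get an insert of length
  Normal(`insert_mean` = 95 kb, `insert_sd` = 10 kb) truncated to
  (0, genome length], uniform start, uniform orientation relative to the
  vector. 95 kb is the *observed* mean span of that library; its earlier
  plate-sampling estimate was ~80 kb, a discrepancy we note but do not
  resolve. The 10 kb spread is a modelling choice consistent with a
  library built from 97–145 kb digested fragments.
* **Shearing and circularisation.** Each positive clone is represented by
  one sheared window of size Uniform(`shear_min` = 8 kb, `shear_max` = 10 kb)
  that must contain the whole `vector_length` = 8,128 bp vector
  (windows smaller than the vector are lost). The window's placement is
  uniform subject to containment, so the two genomic stubs flanking the
  vector have complementary uniform lengths summing to window − vector.
* **Amplicon.** `primerA tail (25) + 5' flank (27) + left stub + 44-nt
  hairpin adaptor + right stub + 3' flank (92) + rc(primerB tail) (25)`;
  the fixed part is 213 bp, which is also the full length of a
  negative-clone amplicon. Size selection keeps amplicons in
  [`amplicon_min`, `amplicon_max`] = [400, 500] bp, which removes the
  negatives — the same mechanism the double SPRI selection implements at
  the bench — and implies retained stub totals of 187–287 bp.
* **Chimeras.** With probability `chimera_fraction` a fragment's right
  stub is replaced: half the time by its own reverse complement
  ("flip", the wrong-orientation class), half by an equally long stub
  from another clone's right terminus ("partner"); `chimera_flip_fraction`
  controls the mix. The default 0.14 makes the flip class ≈ 7% of
  same-scaffold pairs, matching the ~6.9% wrong-orientation rate
  observed for this chemistry.
* **Duplication and reads.** Each retained fragment is copied
  Poisson(`duplication_mean`) + 1 times (default mean 34, i.e. ~35
  copies per fragment — the redundancy of the real run: 443,353 pairs
  over 12,670 distinct). Every copy yields one read: a prefix of the
  amplicon of length min(amplicon, Normal(`read_len_mean` = 350,
  `read_len_sd` = 30)), with substitutions at `subst_rate` = 0.005 and
  ±1 homopolymer-length errors at `homopolymer_indel_rate` = 0.003 per
  run of ≥ 2 identical bases — a light 454-style error profile.
  Qualities are a constant Q30 placeholder; nothing downstream reads
  them. An optional `bidirectional` flag sequences from the B end
  (reverse-complemented amplicon) with probability 0.5; it is off by
  default since read directionality of the original protocol is not
  documented.

Everything is driven by one seed through named `numpy` SeedSequence
streams, so identical configurations give byte-identical FASTQ and
truth tables.

### What the simulator does not model

Real flowgram noise (error rates that grow along the read, quality
values with information), vector rearrangements, incomplete methylation
or exonuclease digestion, MID barcodes, and — most importantly — a
*repetitive* genome: with i.i.d. bases nearly every 16-mer is unique, so
multi-mapping ends are far rarer than on a real genome. Tests passing
here therefore demonstrate correctness of the machinery, not mapping
performance on repeat-rich genomes.

## Read dissection

The 44-nt adaptor is located by minimum-edit infix alignment
(edlib) with at most `max_adaptor_edits` = 4 edits; the adaptor is its
own reverse complement (verified at model construction), so one search
covers both strands. Ties break to the leftmost site. The flanks are
then matched with an edit budget of 1 per 10 nt of flank (2 for the 27-nt
5' flank, 9 for the 92-nt 3' flank). Because reads are usually shorter
than the amplicon, the 3' flank often appears only as a prefix hanging
off the read end; a suffix-anchored dynamic programme (free prefix on
the read side, free suffix on the flank side, minimum 10 anchored bases
within the same edit budget) finds such partial flanks, and a final
polish trims any shorter exact flank-prefix suffix (1–9 bases) so the
right end is never contaminated by vector sequence. Ends are the
regions between flank matches (or read edge) and the adaptor; a pair is
kept iff both ends are ≥ `min_end_len` = 40 nt (the boundary value 40
is kept — the protocol description states the rule both as "greater
than 40" and "less than 40 discarded"; the discard reading is adopted),
and *full length* iff both flanks were located. Every input read falls
in exactly one of {no adaptor, end too short, kept}.

## Redundancy clustering

Ends are clustered greedily: sorted by decreasing length (ties by id),
each end joins the **first** existing centroid (founding order) whose
identity reaches `identity_threshold` = 0.90, else founds a cluster.
Identity is defined on the minimum-edit semi-global alignment of the
shorter sequence into the longer (terminal gaps on the longer side free
and excluded): identity = matching columns / alignment columns. An
exact prefix therefore has identity 1.0, which is what truncated
454-style reads require. One identity definition serves both left and
right ends. A k-mer (k = 6) presence matrix prunes candidate centroids;
its bound — at least `(m − k + 1) − k·e_max` of the query's k-mer
windows survive `e_max` edits, with `m` the shorter length — is
conservative, so pruning never changes the result; a brute-force
quadratic oracle in the test suite confirms exact agreement.

Pairs are grouped by (left cluster, right cluster); each group emits the
pair maximising summed end length (ties to the smaller pair id).

**Saturation.** For each replicate a random permutation of the pair pool
is drawn and sampled at increasing sizes as nested prefixes. The
clustering is *extended incrementally* from one size to the next (new
ends are assigned against existing centroids; assignments never change),
so the non-redundant count is non-decreasing within a replicate by
construction. Independent re-clustering of nested samples is almost —
but not exactly — monotone once sequencing errors exist (a longer end
arriving in a bigger sample can absorb two previously distinct
centroids), which is why the incremental scheme is used. For a single
size the incremental and one-shot clusterings coincide.

## Mapping and pair classification

Exact 16-mer seeds (forward index; the reverse strand is queried by
aligning the reverse-complemented end) are grouped per (scaffold,
strand, 32-diagonal band); each group's window, padded by 40 bp, is
aligned with banded edit-distance alignment, and the aligned path is
trimmed to its best local sub-segment under unit scores (match +1,
mismatch/gap −1), which equals the exhaustive local optimum for the
substitution-dominated error regime (checked against a Smith–Waterman
oracle in the tests). Hits with identity < `min_identity` = 0.90 or
fewer than `min_aln_len` = 35 aligned columns are discarded. The best
hit is chosen by score (ties: longer alignment, lexicographic scaffold,
smaller start); an end is *multiple* when a second retained hit at a
distinct locus scores ≥ `multi_margin` = 0.95 of the best. A pair is
unique iff both ends are unique; locality (same/different scaffold) is
taken from best hits for *all* both-mapped pairs.

Orientation follows from the circularisation geometry: the amplicon
traverses vector end A → terminus 1 → adaptor → terminus 2 → vector
end B, so the two ends of a clone read out on the **same genomic
strand, head to tail** (forward strand: left start < right start;
reverse: left start > right start). Anything else on one scaffold is a
wrong-orientation (chimeric) pair. The span is max(end) − min(start) of
the two best hits and estimates the insert size; span statistics are
computed over proper same-scaffold pairs. Derived percentages are
always recomputed from counts: both-mapped % of kept pairs,
same/different-scaffold % of both-mapped, wrong-orientation % of
same-scaffold.

## Scaffolding

Each different-scaffold pair with both ends uniquely mapped contributes
one link. The hit strand determines which physical scaffold end the
mate points past, and the per-link gap estimate is
`insert_size_estimate − d_A − d_B`, with `d` the distance from the hit
to that scaffold end and the insert estimate taken from the
same-scaffold span median. Links agreeing in (scaffold pair,
orientation class) form a bundle; bundles need ≥ `min_support` = 2
links, and bundles whose median gap is below −0.5 × insert are dropped
as internally inconsistent.

Chains are grown greedily with cycle rejection, taking bundles in
**increasing absolute median gap** (ties: support, then ids). With a
single ~95 kb library over ~100 kb scaffolds, an insert regularly spans
a whole intermediate scaffold, producing a perfectly consistent "skip"
bundle whose gap estimate is about the skipped scaffold's length — and
such bundles often carry *more* links than the direct adjacency, so a
support-first greedy orphans intermediate scaffolds. Nearest-neighbour
ordering resolves this: direct joins have |gap| of the order of the gap
noise (median over ≥ 2 links of a ±10 kb spread), skips of the order of
a scaffold length. Junction gaps are clamped below by `min_gap` =
100 bp because AGP cannot express overlap. Output is gapped FASTA plus
AGP v2.1 (1-based, W and N lines, linkage evidence `paired-ends`);
singleton scaffolds pass through. N50 is the standard
cumulative-half-total definition. Non-gap bases are conserved exactly
and scaffold count never increases.

## Problem sizes used by tests and the acceptance script

All experiments run on the 2 Mb / 20-scaffold desk scale: 10,000 clones
(error-free, 3× duplication) for dissection/dedup fidelity and span
recovery; 195,000 clones (≈ 5,000 kept pairs after the ~4.4% joint
retention of positivity × size selection) for chimera-rate recovery;
2,600 clones (≈ 2× physical coverage) for scaffold recovery; and 7,000
clones at 40× duplication with 500 nt reads for the saturation curve,
sampled at 1k–7k pairs — about 25 samples per distinct fragment, the
sampling depth at which a saturation analysis is informative (a pool
with more distinct fragments than the largest sample cannot plateau by
construction).

## Known limitations

* The identity definition approximates, but is not bit-identical to,
  any particular external clustering tool; borderline pairs near 90%
  can differ from such tools.
* Gap estimates inherit the full insert-size spread; with ≥ 2 links the
  median still scatters by several kb, so AGP gap lengths are rough.
* Uniform-random genomes understate multi-mapping; the unique/multiple
  split is exercised by construction in unit tests, not by realistic
  repeat content.
* The mapper performs no split alignment, so a stub crossing a scaffold
  boundary is usually lost rather than partially mapped.
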