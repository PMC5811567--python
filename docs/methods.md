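# Methods

## Scope and data model

The pipeline operates on collapsed unique small-RNA tags (sequence + count
per tissue library), a transcript reference, a set of known mature miRNAs
with miRBase-style names, a labelled ncRNA set, degradome tags and a Ct
table. All sequences are held in the RNA alphabet; DNA input is normalised
(T→U) on ingestion. Coordinates are 0-based half-open internally and
1-based inclusive in report tables.

## Preprocessing

Adapter removal takes the read prefix before the leftmost full occurrence
of the 3' adapter; when no full occurrence exists, a ≥8 nt adapter prefix
flush with the read end counts as evidence. Reads without adapter evidence
are discarded (they cannot be length-resolved), as are reads containing
ambiguity codes and reads whose insert falls outside 18–30 nt; each reason
is tallied so that input reads = kept + Σ discards holds exactly.
Contaminant filtering removes a tag when it aligns ungapped inside any
labelled ncRNA record within a configurable mismatch budget (default 0).
A full-database E-value screen is out of scope at desk scale; the contract
(remove the four ncRNA classes, tally per class in the fixed priority
rRNA > tRNA > snRNA > snoRNA) is preserved.

## Folding model

Hairpin search uses an intentionally small, fully declared energy model so
that every fold is exactly reproducible and checkable against exhaustive
enumeration:

| term | energy (kcal/mol) |
|---|---|
| stacked pair, keyed by outer pair | GC/CG −3.0, AU/UA −2.0, GU/UG −1.0 |
| isolated pair (no adjacent pair) | half its stack energy |
| hairpin loop | +4.0, +0.5 per unpaired nt beyond 3 |
| bulge/internal/multibranch loop | +2.0, +0.3 per unpaired nt |
| exterior unpaired | 0 |

Structures are non-crossing with a minimum hairpin loop of 3. Energies are
handled as integers in 0.1 kcal/mol units, so the dynamic program, the
re-scoring function and the brute-force enumerator agree exactly (no
floating-point ties). The O(n³) fill is numba-compiled; traceback runs in
Python with a fixed option order. Ties are broken toward more pairs, then
by the deterministic leftmost-pairing traceback, making output bit-stable.
The multibranch term reuses the internal-loop coefficients; no separate
multiloop parameters are introduced.

This model is *not* a thermodynamic nearest-neighbour table: absolute
energies (and hence quantities derived from real precursors, such as mean
hairpin MFE) are not comparable to mfold/ViennaRNA values. What carries
over is the ranking of strongly paired stems above background, which is
what stem-loop validation needs. A consequence worth knowing: random
sequence under this model folds into long bulgy quasi-helices more readily
than under a full thermodynamic model, so structure alone separates genuine
precursors from background less sharply (see "Synthetic data" below).

AMFE is (MFE/length)×100; MFEI is AMFE divided by GC percentage on the
0–100 scale, reported as undefined for GC-free sequence.

## Duplex geometry and stem-loop validation

The miRNA* interval is derived from the fold: partners of the mature
positions are extrapolated linearly from the nearest paired position (the
partner index falls by one per mature position on a nested stem), the star
5' end pairs mature position L−2 counted 1-based (2-nt mature 3' overhang)
and the star 3' end runs 2 nt past the partner of the mature 5' end — the
canonical 2-nt 3' overhang on both strands of the Dicer duplex. The star is
undefined when under 60% of the mature is paired, when partners fall on
both sides of the mature, or when the mature reaches more than 4 nt past
its duplex into the terminal loop.

A candidate precursor is accepted when (a) the mature lies on one arm,
(b) at most 8 mature nucleotides are unpaired, (c) the mature's pairing
partners form a contiguous opposite-arm block (bulges up to 6 nt are
tolerated inside the block), and (d) the fold is stabilising (MFE < 0).
Every violated clause is reported.

## Conserved and novel calling

Homology distance is Hamming distance at equal length; for unequal lengths
the minimum over ungapped offsets of overlap mismatches plus the length
difference, requiring ≥18 nt overlap. A tag's best family is its
minimum-distance hit, ties resolved toward the lower MIR family number.
Anchored tags are excised with a window schedule of mature±250 nt plus the
two asymmetric 250 nt windows (clipped at transcript ends), each folded and
annotated; among accepted windows the lowest-MFEI one is kept. Star support
is granted when a sequenced tag matches the computed star interval within
±2 nt.

Novel calling clusters exact tag placements within 30 nt into loci
(minimum 3 reads), requires stem-loop acceptance for the dominant tag and a
read-stack consistency of ≥0.75: the fraction of locus reads whose 5' ends
sit within ±2 nt of the dominant 5' end or inside the star/loop regions.
Identical matures at several loci are deduplicated to the lowest-MFEI
precursor (optionally kept separate to mirror per-locus accounting). The
probabilistic scoring of the original discovery tools is deliberately
replaced by these explicit, testable thresholds.

## Target scoring and degradome categorisation

Duplexes are scored per alignment column from the miRNA 5' end: match 0,
G:U 0.5, mismatch 1.0, gap 2.0, doubled over columns 2–13; default cutoff
4.0. Sites are seeded by an exact Watson–Crick complement of miRNA
positions 2–8; extension evaluates the gapless alignment and every
placement of a single gap 3' of the seed (the band), so the seeded scan is
by definition equivalent to exhaustive all-offset scoring, which the tests
verify. Overlapping sites of one miRNA are merged to the best-scoring one.

Degradome tags map by exact match; multi-mapping tags split their count
equally, so fractional counts occur. The expected cleavage coordinate is
the target nucleotide paired to miRNA position 10 (slicing between 10 and
11); signal within ±1 nt at or above 1 read calls a site. Categories follow
the established degradome ranking, frozen as: with c the site count, M the
transcript maximum and med the median over expressed positions — 4 iff
c ≤ 1; else 0/1 for a unique/tied maximum; 2 for med < c < M; 3 for
1 < c ≤ med. A fractional multi-mapped count at or below one read is
treated as category 4. The clause order makes the five categories a
partition, verified exhaustively over small count multisets.

## Expression quantification

2^−ΔΔCT with a configurable reference assay (e.g. 5.8S rRNA) and calibrator
tissue; the calibrator maps to exactly 1 by construction and the whole
statistic is invariant to adding a constant to every Ct. Replicate SD of
the assay Ct is propagated as a multiplicative 2^±sd band. Anti-correlation
of miRNA and target levels across ≥3 tissues is reported as Spearman rho
with an "opposite" flag for rho < 0 (undefined for constant vectors).
Multiple-range testing of tissue differences is left to general-purpose
statistics packages.

## Synthetic data

The generator emulates the study conditions: four tissue libraries
(flower/leaf/bulblet/bulb), heavy-tailed per-tissue abundances (log-normal
around a per-miRNA base level, sigma 0.4–0.6, matching read counts that
span 1 to >1000 across tissues), 3' adapters on every read, ~10% 1-nt end
jitter (isomiR-like), star reads at ~20% of mature abundance, ncRNA
contaminant fragments from a miniature synthetic labelled set (not a real
database), random noise reads and a few adapterless reads. Planted
conserved matures sit 0–2 substitutions from a synthetic known set; decoys
sit at exactly 3; novel matures are unrelated to the known set; planted
targets are exact reverse complements whose degradome scenarios are
constructed per intended category and self-verified against the categoriser
before emission. Default scale: 20 conserved, 15 novel, 4 decoys, 4 noise
loci, 10 targets (2 per category) on ~60 transcripts of 320–480 nt — sizes
chosen so a full round trip folds a few hundred windows in seconds.

"Expression noise" is modelled as degradation-like fragments whose 5' ends
scatter over ~90 nt, which the read-consistency rule rejects. This is the
appropriate noise model here: under the simplified energy model random
flanking sequence can satisfy the geometric stem-loop clauses, so a clean
single-position read stack in random context is not reliably separable by
structure alone — a known limitation of the folding model, not of the
calling rules. Passing round-trip tests therefore demonstrate correct
plumbing, thresholds and geometry on realistic read stacks; they do not
certify discrimination performance on real transcriptomes, where a
thermodynamic folding backend would sharpen the structural filter.

Everything is driven by one seed; identical seeds give byte-identical
libraries.

## Evaluation conventions

Discovery recovery is scored on the pipeline's own calls (a planted
conserved mature counts as recovered only with the correct family; novel
recovery is assessed over plants with ≥5 realised reads). Target finding
and degradome categorisation are scored per planted pair with the scanner
handed the planted mature directly, so these stage scores are not
confounded by upstream discovery misses.

## Known limitations

- Energies are model units, not kcal/mol comparable to mfold; per-precursor
  MFE/AMFE/MFEI values are internally consistent but not literature
  comparable.
- Forward-strand transcript scanning by default (assembled transcripts);
  reverse-complement scanning is a flag.
- No isomiR aggregation: counts attach to the exact tag sequence.
- The Rfam/GenBank E-value screen is replaced by substring matching against
  a labelled miniature set.
- qPCR efficiency correction and primer design are out of scope.
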