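# Methods

## The editing-site model

U-indel editing changes only the uridine content of a transcript, so the
pre-edited and the canonically edited ("fully edited") sequence share an
identical non-U backbone. `uindel` canonicalizes input (case-insensitive,
T ≡ U, alphabet {A,C,G,T,U}) and represents the pair as that backbone plus
two integer vectors: the U count in every inter-backbone gap for each state.
Every interior gap is an editing site (ES); with a backbone of length B there
are exactly B − 1 ESs, numbered 3′→5′ because editing progresses in that
direction. A site is an *insertion* site if the edited state carries more Us
than the encoded state, a *deletion* site if fewer, and *shared* if equal.

Two conventions need fixing that the ES definition alone does not:

- **Terminal U runs.** Us before the first or after the last backbone
  character have only one non-U neighbour and are therefore not ESs. They are
  stored as two extra integers on the template and on each read, participate
  in exact read reconstruction, and are excluded from all statistics.
- **5′ truncation (`max_es`).** When the canonical reference is only trusted
  up to some ES (as for amplicons whose 5′ region suffers sequencing
  discrepancies), "fully edited" is declared at `max_es` rather than at the
  last ES. Default: the full amplicon.

## Read calling

A read is *standard* iff its U-stripped sequence equals the backbone exactly;
anything else (substitutions, non-U indels, partial length) is nonstandard,
counted, and excluded downstream. Full-length amplicons are assumed because
the libraries are produced with fixed primers; optional exact-match primer
trimming is available and off by default.

For a standard read the alignment is unambiguous: the per-ES U counts are the
U run lengths between consecutive backbone characters. Each ES gets one of
four states by comparing the read count u with the template counts
(u_pre, u_full): *shared* if u = u_pre = u_full, *canonical* if
u = u_full ≠ u_pre, *pre* if u = u_pre ≠ u_full, else *noncanonical*.

- **Stop site**: the largest k such that ESs 1..k are all
  canonical-compatible (canonical or shared); k = 0 when ES 1 already fails.
- **Junction length**: 0 if every ES 5′ of the stop is pre-compatible (pre or
  shared); otherwise j − stop, where j is the 5′-most ES that is not
  pre-compatible. The span convention is used deliberately: internal
  pre-edited ESs inside the junction count toward its length, and canonical
  islands beyond the stop open a junction.

Shared sites extend a canonical run and never terminate one or open a
junction — they carry no information about editing progression. A consequence
we accept: a fully pre-edited read whose 3′-most ESs happen to be shared gets
a stop site > 0. Both choices are stated in output metadata because the
one-line field definitions ("5′-most ES after contiguous canonical editing")
do not resolve them.

## Population statistics

Stop-site counts per sample (rows 0..n_es; row 0 = no canonical editing, row
n_es = fully edited up to `max_es`) are normalized to 100 000 reads so
replicates of different depth are comparable; normalized values stay
real-valued.

**EPS test.** Each induced replicate is a single observation against a small
control set (m ≥ 2), so the per-replicate test is the single-case
(Crawford–Howell) t: t = (x − m̄c)/(sc·√(1+1/m)) with m − 1 df, one-sided
(overrepresentation only), followed by Benjamini–Hochberg adjustment across
all stop-site rows within the replicate. An ES is an exacerbated pause site
iff adjusted p < α (default 0.05) and the induced value exceeds the control
mean in both replicates. The test is a named, pluggable strategy recorded in
the run manifest, since overrepresentation could defensibly be tested other
ways. Rows where the controls have zero variance are tested on add-one
smoothed counts (raw + 1, renormalized over the correspondingly inflated
total) to avoid infinite t statistics at sparse sites; reported counts are
unaffected.

**Overlap.** EPS sets of two knockdowns are compared by Fisher's exact test
on the 2×2 membership table over the testable universe, defined as ESs
1..`max_es` (row 0 is excluded from the universe; whether never-pausing ESs
should also be excluded is undecidable from the data, so the full universe is
the default and is recorded in metadata). One-sided enrichment by default,
two-sided by flag.

**Junction lengths.** Per stop site, reads are binned by JL with inclusive
edges [0], [1,10], [11,20], [21,∞). Per-sample bin percentages (rows with at
least one read in every sample; others are not testable) are compared between
conditions by a two-sided pooled-variance Student's t-test per (ES, bin), BH
adjusted across ESs within each bin. Degenerate rows with zero pooled
variance are resolved explicitly: identical groups give p = 1, constant but
different groups p = 0.

Implementation notes: BH comes from statsmodels, the Fisher test and t
distributions from scipy; the test suite checks both against hand-written
brute-force oracles (literal step-up recipe; hypergeometric tail from exact
binomial coefficients), and the aligner against an edit-distance dynamic
program restricted to U indels.

## Synthetic experiments

The generator emulates the structure of MiSeq amplicon libraries of
pan-edited transcripts: a ~300 nt, 60-ES template, 2 induced replicates vs 7
controls, 50 000 reads per sample, ~2% nonstandard reads, a mixture of
pre-edited (15% of reads), fully edited (5%), and partially edited sequences
with and without junctions. Those defaults are the study conditions; every
read is drawn as:

1. stop site s from the condition's stop distribution. Controls put 2% at
   each of five planted sites and spread the rest uniformly over the other
   interior sites; induction raises the planted sites to exactly
   baseline + effect (default 2% → 10%) and rescales only the non-planted
   mass. The planting is additive and the truth table records the realized
   per-condition fractions.
2. a JL bin from the condition's junction profile, then a uniform length
   within the bin (clipped to the 5′ headroom; unattainable bins are dropped
   and the remaining mass renormalized). The induced profile applies only at
   the phenotype sites (default: the planted EPSs). "organizer_like" moves
   mass to JL = 0 and away from JL > 20; "resc13_like" moves mass to JL > 20.
3. ESs 1..s take fully edited counts; the junction's 5′-terminal ES gets a U
   count matching neither template state (so the caller sees the junction end
   exactly where planted); interior junction ESs are pre-edited; everything
   5′ of the junction is pre-edited.
4. with the nonstandard rate, one backbone character is substituted, which
   guarantees the read is classified nonstandard.

Generated templates have no shared sites (pan-edited domains are edited at
essentially every site), which makes the planted (stop, JL) ground truth
exact rather than approximate: with shared sites a planted stop could
silently extend through an adjacent shared run. Shared-site behaviour of the
caller is exercised by unit tests instead. The default planted sites
(8, 15, 22, 29, 36) sit in the 3′ two-thirds of the amplicon because a
junction longer than 20 ES is geometrically impossible within 20 ESs of the
5′ end; phenotype sites must keep headroom for all four JL bins.

Determinism: one root seed spawns independent integer-seeded RNG streams
(template, then one per sample), so identical config + seed gives
byte-identical FASTA output, independent of platform float behaviour. Reads
are emitted as unique sequences with `;count=N` multiplicities.

What the generator does not emulate: sequencing errors beyond whole-read
corruption (no per-base error model, no quality scores), PCR duplicates and
chimeras, partially covered amplicons, gRNA-block structure in where pauses
occur, and correlated biological variation between replicates (samples are
independent multinomial draws). Passing recovery tests therefore shows the
statistics behave correctly under idealized sampling noise at realistic
depths, not that they are robust to artifact-laden real libraries.

## Problem sizes in the shipped analyses

The analysis scripts and acceptance checks run the full study geometry
(9 × 50 000 reads, 60 ESs) for recovery claims, a 200-experiment null
calibration at reduced scale (30 ESs, 5 000 reads per sample) for the
type-I-error check, and 1 000 random instances with n_es ≤ 30 for the
alignment-oracle comparison. Collapsing reads to unique sequences makes the
per-sample workload proportional to sequence diversity rather than depth.

## Known limitations

- The alignment model admits only full-length standard reads; real pipelines
  may wish to salvage reads with isolated non-U mismatches.
- The per-replicate overrepresentation test is a choice among defensible
  alternatives (e.g. count-based GLMs); the strategy name is recorded in all
  outputs so results are interpretable.
- EPS coordinates from real published datasets are not reproduced here; that
  requires the original read data.
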