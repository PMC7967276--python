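# Methods

## Signal model

5'-end-specific RNA-seq libraries enrich read starts at transcription start
sites, so the informative signal is not coverage but the per-position,
per-strand count of aligned-read 5' termini. The pipeline therefore reduces
alignments to a sparse "5'-end pileup": a plus-strand alignment contributes
its leftmost reference position, a minus-strand alignment its rightmost
(computed by walking the CIGAR over reference-consuming operations
M/D/N/=/X). Soft-clipped bases do not shift the counted position; since only
perfect-match alignments survive filtering, clipping is rare and the aligned
end is the defensible choice.

Only reads matching the genome exactly are counted: a record must be mapped,
primary (secondary 0x100 and supplementary 0x800 alignments are excluded so
no read is counted twice) and carry both `XM:i:0` and `NM:i:0`. Records
missing either tag, or carrying a non-integer value, fail the filter; the
malformed ones are logged rather than silently kept.

Adapter trimming removes everything from the leftmost **full** occurrence of
the adapter onward. This is exact full-string search: no 3'-anchored prefix
matching, no error tolerance. That is the minimal deterministic reading of
"the adapter was cut off"; it is recorded here as this package's convention
rather than a claim about how the original libraries were processed. Reads
shorter than 16 nt after trimming are discarded (`min_len`, default 16).

## Replicate normalization

Replicates within one growth condition are made comparable by scaling each
replicate's counts by c_i = N_av/N_i, where N_i is the replicate's
perfect-match read count and N_av the mean over the condition's replicates.
The condition-level track is the per-position mean of the scaled replicate
tracks, with absent positions contributing zero. Two identities pin the
implementation down and are property-tested: Σ_i c_i·N_i = n·N_av exactly,
and the averaged track is invariant under replicate reordering. Coefficients
are kept at full precision internally and rounded to 4 decimals only in
report output. The "series of experiments" over which N_av is taken is the
condition group (replicates sharing a growth condition), not the whole run
collection — the published per-run coefficients are reproduced only under
this grouping. Note that for two of the ten public runs the published
4-decimal coefficients disagree with exact rounding of N_av/N_i by one unit
in the last digit (in opposite directions within the same condition group, so
no alternative N_av can explain both); the package reports the exactly
rounded values.

## TSS calling and shifts

Manual inspection of superimposed profiles is replaced by an explicit rule:
within ±`window` (default 300 bp, wide enough to cover shifts >150 bp with
margin) of a feature's annotated transcript 5' end, every strand-matching
local maximum with height ≥ `min_height` (default 5 normalized counts)
becomes a call. The leftmost point of an exact plateau is reported once. The
highest peak is primary; ties break toward the annotated position, then
upstream. Both knobs are configuration-exposed: they are a reproducible
surrogate for curation, not measured properties of any particular library.

Signed offsets follow the transcription direction on either strand:
offset = called − annotated on plus, annotated − called on minus, so a
negative offset always means the transcript is extended upstream and a
positive one that it is shortened. Transcript variants from multiple TSSs
are lengths to the shared annotated 3' end, so pairwise length differences
equal pairwise TSS separations by construction. Condition dependence (a
secondary promoter overtaking the primary in stationary phase) is reported
by emitting one call set per condition; no differential test is performed.

For protein-coding genes the "annotated 5' end" is the mRNA TSS when the
annotation records one (GFF3 attribute `mrna_tss`), else the coding start.
This is also what defines the neighbor's transcript span in the orientation
taxonomy, and it is exactly what turns some ncRNAs into potential antisense
RNAs: a long 5'UTR can reach across the intergenic region and under the
ncRNA.

## Orientation taxonomy

Each ncRNA is paired with the protein-coding gene whose transcript 5' end is
closest to the ncRNA's 5' end (ties break toward the ncRNA's upstream side).
Same strand → codirected. Opposite strands with intersecting spans (ncRNA
gene span vs neighbor transcript span including the 5'UTR) →
overlapping_5prime, with the coordinate overlap reported as the potential
antisense duplex length — a coordinate overlap, not a hybridization
calculation. Opposite strands, disjoint, with the plus-strand partner to the
right of the minus-strand partner → divergent (head-to-head); otherwise
convergent (tail-to-tail), which is kept as its own label rather than forced
into the three-way divergent-ncRNA taxonomy. A *bona fide* ncRNA overlaps no
opposite-strand transcript span anywhere in the annotation. Inter-TSS
distances of divergent pairs are plain absolute differences of the refined
primary TSS coordinates (no ±1 adjustment); the summary reports n, min,
median (mean of the central pair for even n) and max.

## REP screen

The REP consensus is modeled three ways: the mirror-symmetric degenerate
motif as two half-sites (`GCKGATGGCGRGCK` + `RCGYCTTATCMGGCCTAC`) joined by
a 0–3 nt spacer of N positions (the motif's center is not fixed in the
literature, so the spacer bound is configuration-exposed), plus the two
literal full-length variants (35-mer and 36-mer) as ungapped patterns.
Scanning is IUPAC-aware on both strands with up to `max_mismatches`
substitutions (default 3); a genome N matches nothing unless the pattern
position is N. The scanner is vectorized (per-pattern-position lookup over
an integer-encoded sequence) and is cross-checked in the tests against an
all-offsets per-character brute-force oracle.

For an intergenic region between two collinear genes, the candidate
divergent transcript runs on the opposite strand. Its TSS is the highest
5'-end peak on that strand inside the IGR; the TSS-to-REP distance is
measured in the transcription direction to the nearest downstream REP 5'
boundary. Between TSS and REP the screen looks for maximal poly-T tracks of
≥ `min_t_run` (default 4) on the transcribed strand (runs of A on the plus
strand when transcription is on minus) and, within `hairpin_window`
(default 20 nt) upstream of each track, for a stem-loop with stem ≥
`min_stem` (default 4), loop between `min_loop` (default 3, the physical
minimum) and `max_loop` (default 8) — common intrinsic-terminator heuristics,
all configuration-exposed, with every stem/loop placement enumerated
exhaustively. Read-through is possible iff no track has such a hairpin. No
thermodynamic scoring and no rho-dependent termination model is attempted.

One footnote on the default fixture: a planted copy of the 35-mer variant
always also matches the 36-mer variant one position downstream with ≤3
mismatches (they differ at one internal position, and the 36-mer's two tail
positions can at worst both mismatch), so the scanned REP footprint extends
2 nt beyond the planted copy and the planted TSS-to-REP distances account
for that.

## Synthetic data

The generator emulates what the analysis assumes about real 5'-end libraries:
read 5' ends drawn multinomially over planted TSSs with per-condition
weights; per-replicate depths that differ (so normalization is exercised —
default 6000/9000 and 5000/7500 reads across two conditions × two
replicates, a deliberate ~2000× scale-down of the public runs' 3–11 M
perfect-match depths to keep a full study in seconds); a configurable
fraction of reads carrying 1–2 substitutions (default 0.1; 0 for the
noise-free recovery study; 0.3 for the filter-contract check) which the
perfect-match filter must remove; 3'-adapter read-through (default 0.05)
leaving 19 genome-derived nt; and sub-16-nt fragments (default 0.02) removed
by the length filter. Reads are planted exactly at TSS positions — primary
TSSs in 5'-enriched data are single-nucleotide peaks — which makes recovery
tests sharp; read length is fixed at 30 nt. Alignments are written by an
oracle directly from read provenance (position, strand, substitution count),
so no aligner runs in the tests and the SAM tags are true by construction.

The default 52-kb design plants 13 ncRNA/gene pairs covering every
orientation class, TSS shifts of −26 and +60 nt, duplicated promoters 26 and
71 bp apart with condition-switched dominance, divergent-pair TSS
separations of 7–290 bp with median 84, and four REP loci (read-through
without poly-T; terminator with hairpin+T6; poly-T without hairpin; REP
without TSS). Spans between a planted divergent TSS and its REP copy are
rejection-sampled until their poly-T/hairpin content matches the planted
flags, using the package's own detectors as generation-time validators (the
detectors themselves are validated independently against brute force).

What the generator does **not** emulate: quality-score-dependent error
models, rRNA/tRNA background, 5'-end jitter from ragged processing,
multi-replicon genomes, or origin-spanning features. Passing the recovery
tests therefore shows the pipeline is correct under its own signal model, not
that curation of a real, noisy transcriptome is automated away.

## Numerical and degenerate-input choices

Coordinates are 1-based and inclusive throughout; BED/bedGraph conversion
happens only at I/O. Interval arithmetic across a circular origin is
rejected with a clear error (no origin-spanning features are in scope).
Empty replicates (N_i = 0) are an error, not a silent skip. A flat track
yields no TSS calls; an IGR without flanking genes, or with flanking genes
on opposite strands, is an error for the REP screen. All report writers use
fixed float formatting and sorted keys, so identical inputs reproduce
byte-identical outputs; the run manifest records every parameter and input
checksum.

## Known limitations

Annotated ncRNA 3' ends are stored verbatim (whether they are
terminator-trimmed is unknowable from the annotation alone), so transcript
variant lengths inherit any 3'-end annotation error. The orientation
taxonomy pairs each ncRNA with a single nearest neighbor; dense gene
clusters with several plausible partners are reduced to one row. Thresholds
separating a weak-but-real secondary promoter from noise are configuration,
not biology. Genome-scale claims (copy numbers of REP elements, counts of
divergent vs codirected ncRNAs in a given annotation release) depend on the
annotation release and scan parameters and are intentionally not asserted.
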