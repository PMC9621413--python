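# Methods

## The construction model

`splintlig` targets splint-ligation ("ligation & elongation") assembly of
degenerate-codon gene libraries. A sense-strand gene of length L is tiled
by k short synthetic oligos NF1…NFk; each of the J = k−1 junctions is
bridged by an antisense splint whose two arms anneal to the upstream and
downstream sense oligos, templating their ligation. Oligos are grouped
into consecutive blocks (default 3) that are ligated in a first stage;
splints spanning block boundaries are added in a second stage to join the
blocks. A reverse primer annealing to the 3′ constant region plus a
strand-displacing polymerase converts the single-stranded product to
dsDNA. Only molecules spanning fragment 1 (which carries the T7 promoter)
through the final fragment, with completed extension, contain the
antisense promoter strand and can transcribe; every shorter by-product is
transcriptionally silent, which is what removes the need for
purification.

Phosphorylation is part of the logic, not an afterthought: every sense
oligo except the first carries a 5′-phosphate (so NF1's end cannot accept
a ligation), and every splint carries a 3′-phosphate (so splints can
never be ligated into the product).

## Design constraints and the partition algorithm

Three hard criteria drive oligo design:

1. sense oligo length ≤ `max_oligo_len` (default 90 nt, a practical
   synthesis limit);
2. each splint arm melts near `target_arm_tm` (default 40 °C, window
   ±4 °C) — warm enough to hold at the 37 °C ligation temperature,
   cool enough to release during the later extension;
3. splint arms bind framework only — an arm may never overlap a
   randomized codon, where no defined complement exists.

Candidate junction positions are every template coordinate at which some
arm pair (lengths `min_arm_len`–`max_arm_len`, defaults 8–20 nt) is
randomized-codon-free and lands in the Tm window; each arm is tuned
independently to minimize |Tm − target| (ties: shorter arm). The tiling
is then an exact dynamic program over candidates choosing k−1 cuts with
all segments in [`min_oligo_len`, `max_oligo_len`], minimizing the
lexicographic objective (summed arm-Tm deviation, summed squared segment
lengths, leftmost cut tuple) — the second term prefers even tilings at
equal thermodynamic cost, the third makes results deterministic. The
oligo count is the smallest multiple of `group_size` with a feasible
tiling; a template that fits one oligo is returned unsplit (no ligation
is needed); if no group-size multiple is feasible the minimal feasible
count is used with a warning. `min_oligo_len` (default 25) must be at
least `max_arm_len` so an arm can never reach past its neighbour oligo.

## Melting temperatures

Tm uses the unified nearest-neighbor ΔH/ΔS parameter set with the
Owczarzy 2008 monovalent+Mg²⁺ correction (Biopython's `Tm_NN`,
`DNA_NN3`, `saltcorr=7`). Default conditions model a splint-ligation
buffer: 0.25 µM total strand, 50 mM monovalent salt, 8 mM Mg²⁺, no
dNTPs; all are explicit fields of `DuplexContext` and echoed into design
provenance. Two behaviours worth knowing: with 8 mM Mg²⁺ the correction
is Mg-dominated, so Tm is legitimately insensitive (and not monotone) in
monovalent salt near the regime crossover — the monotonicity sanity test
is therefore pinned at Mg = 0; and while appending a G:C pair never
lowers Tm, extending an arm with arbitrary (AT-rich) sequence
occasionally can, so "longer arm ⇒ higher Tm" is not assumed anywhere.
Degenerate bases are rejected inside Tm computations by contract; the
designer guarantees arms avoid them.

## Library arithmetic

- Molecule counts: m_ng·10⁻⁹ / (L_bp · 660 g mol⁻¹ bp⁻¹) · N_A and
  pmol·10⁻¹² · N_A. N_A is stored at full CODATA precision
  (6.02214076×10²³); figures quoted at lower precision are produced by
  the display renderer (`render_scientific`, significant-figure
  rounding), never by degrading the constant. One consequence: an
  overall yield of 1.07×10¹²/9×10¹² renders as 11.9 % at one decimal.
- Stop-codon models: the additive estimate n·p is the number usually
  quoted for NNK libraries (62.5 % at n = 20, p = 1/32) but over-counts
  multi-stop reads; the exact independent-position value 1 − (1−p)ⁿ is
  47.0 % at the same settings. Real machine-mixed libraries typically
  land between the exact value and the linear over-estimate, so both are
  always reported side by side.
- Per-junction efficiency inverts the independent-junction yield model:
  p = (overall yield)^(1/J).

## Assembly simulation

Each junction ligates independently with probability p. A chain's
junction outcomes split it into maximal runs; species (i, j) is the
product spanning fragments i…j, giving up to (J+1)(J+2)/2 spectrum bins
(45 for 9 fragments — the gel "smear"). Analytic mode returns expected
counts in closed form; Monte-Carlo mode draws every junction from a
seeded `numpy` generator (cap 10⁷ molecules; use analytic beyond).
Fragment bookkeeping is conservative: Σ count·(run length) = n·(J+1).
Transcribable fraction = p^J × `extension_success_p`; extension success
defaults to 1.0 because the protocol gives no separate estimate for the
extension step — the parameter exists so users can model it.

## Synthetic reads and what they do and do not emulate

`sample_library_reads` draws each randomized codon per read from its
per-position base distribution and applies uniform substitution errors;
a ground-truth codon table (pre-error) accompanies every read set.
The default bias emulates machine mixing — unequal phosphoramidite
coupling at degenerate positions — with N ≈ {A 0.30, C 0.20, G 0.27,
T 0.23} and K ≈ {G 0.44, T 0.56}, values inside the envelope typical of
machine-mixed NNK synthesis (N bases ~19–34 %, K ~38–61 %);
`base_mix_bias=None` gives ideal uniform mixing. Not modeled: indels,
quality decay along the read, position-dependent error, chimeras,
reverse-transcription/PCR bias, and abundance skew from assembly — so
passing QC recovery tests demonstrates the pipeline's correctness on
substitution-only data, not robustness to every real-library artifact.
Paired layout emits overlapping mates (R1 = 5′ prefix, R2 = reverse
complement of the 3′ suffix).

## QC pipeline

Funnel order: merge (ungapped best-overlap, consensus by higher quality)
→ exact deduplication (first occurrence kept) → exact length filter →
constant-flank anchoring (exact prefix/suffix match, default 12 nt).
Reads with indels fail the length filter or the anchor and are excluded
rather than aligned: full-length-only analysis keeps codon coordinates
fixed. Unique-variant counts are reported after stop removal at both
nucleotide and protein level, since "unique variants" is ambiguous
between the two. Internal stop = any ORF codon before the designed
terminal position translating to `*`; expectations use each randomized
codon's own mix (linear: Σpᵢ; exact: 1 − Π(1−pᵢ)), valid because
framework codons are stop-free by template invariant. Frequency grids
report per-codon, per-position A/C/G/T frequencies plus the mean ± SD
across randomized codons per position class, next to the ideal-mixing
expectation. The merge step is O(length²) per pair — adequate for
QC-scale inputs; merged-layout simulation is preferred for large n.

## Problem sizes and determinism

Statistical self-consistency checks run at 10⁵ reads / 10⁵ molecules
with 3-standard-error tolerances; smaller unit tests use 10³–2×10⁴.
Every stochastic API takes an explicit seed (no global RNG); identical
config + seed gives byte-identical outputs, including FASTQ files. The
worked 620-nt template is generated from a fixed internal seed and is
itself synthetic — a repeat-protein-style stand-in of the reference
architecture (9 oligos, 3 groups, 20 NNK codons in five clusters), not a
published scaffold sequence.

## Known limitations

- The independent-junction model ignores kinetic coupling between
  adjacent ligations and any length-dependence of splint annealing.
- Tm conditions during ligation are declared, not fitted; the ±4 °C
  window is a design choice exposed in `DesignConstraints`.
- No secondary-structure (hairpin/cross-dimer) screening of oligos.
- The QC pipeline is indel-intolerant by design and does not correct
  sequencing error when estimating base frequencies; at the default
  error rates used in simulations this bias is below the reported SDs.
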