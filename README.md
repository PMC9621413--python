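# splintlig

Design and QC toolkit for **splint-ligation assembly of degenerate-codon
(NNK) synthetic gene libraries** — the PCR-free route to the very large
(10¹¹–10¹⁴-variant) DNA libraries used in mRNA- and ribosome-display
protein engineering.

In this construction strategy a randomized gene is assembled from short
synthetic **sense oligos** (NF1…NFk) ligated end-to-end on antisense
**splint oligos** (SP1…SPj) that bridge each junction, in two staged
ligations (within groups of oligos, then between groups). A single
reverse primer (CR) and a strand-displacing polymerase then produce the
double-stranded gene; because only full-length assemblies carry the
antisense strand of the T7 promoter, partial products never transcribe
and no purification is needed.

`splintlig` covers the desk work around that protocol:

- **codon_math** — degenerate-codon algebra and library arithmetic:
  NNK expands to 32 codons encoding all 20 amino acids plus one stop
  (TAG), so a library with *n* randomized codons has nucleotide diversity
  32ⁿ and an expected stop-containing fraction of *n*/32 (linear
  approximation) or 1 − (31/32)ⁿ (exact). Mass/mole/molecule conversions
  (m/(L·660 g·mol⁻¹·bp⁻¹)·N_A) quantify what a PCR reaction or a ligation
  input can actually sample.
- **thermo** — nearest-neighbor duplex melting temperatures (unified
  ΔH/ΔS parameters, Owczarzy Na⁺/Mg²⁺ salt correction) used to size
  splint annealing arms to a ~40 °C target.
- **design** — partitions an annotated template into ≤90-nt sense oligos
  grouped for staged ligation, places junctions only where splint arms
  can bind framework (never a randomized codon) inside the Tm window,
  and emits a vendor-ready order sheet with 5′-/3′-phosphate codes.
- **assembly_sim** — independent-junction ligation model (overall yield
  = p^J for J junctions), analytic or Monte-Carlo, plus a synthetic
  amplicon-read generator with machine-mixing base bias and sequencing
  error.
- **qc** — the sequencing funnel (merge → deduplicate → length filter →
  anchor) and per-position nucleotide / amino-acid frequency grids at the
  randomized codons, with observed-vs-expected stop statistics.

## Worked example

The package ships a deterministic 620-nt worked template (T7 promoter +
RBS + 516-bp repeat-protein-style ORF with 20 NNK codons in five loop
clusters + 3′ constant region):

```bash
splintlig example --out ex
splintlig design --fasta ex/template.fasta --config ex/template.yaml --out des
```

`des/design_report.json` (excerpt):

```json
{
  "n_sense_oligos": 9,
  "n_splints": 8,
  "n_groups": 3,
  "junction_positions": [50, 137, 221, 288, 370, 398, 482, 542],
  "bridging_splints": ["SP3", "SP6"]
}
```

Nine sense oligos (all ≤90 nt) tile the template in three groups; eight
splints bridge the junctions, with SP3 and SP6 tagged `bridging` because
they span group boundaries and are added in the second ligation stage.
The order sheet marks NF2–NF9 with `/5Phos/` (NF1 is left
unphosphorylated so the 5′ end cannot ligate) and every splint with
`/3Phos/`. Library arithmetic:

```bash
splintlig stats --mass-ng 10 --length-bp 500 --moles-pmol 15
```

```json
{
  "expansion_size": 32,
  "stop_fraction_linear_pct": 62.5,
  "stop_fraction_exact_pct": 47.00507153168765,
  "molecules_from_mass_rendered": "2e10",
  "molecules_from_moles_rendered": "9e12"
}
```

i.e. a 50-µL PCR seeded with 10 ng of a 500-bp template tops out near
2×10¹⁰ molecules, while a 15-pmol ligation input is 9×10¹² molecules —
the scale argument for PCR-free assembly. Simulated reads and QC:

```bash
splintlig make-reads --fasta ex/template.fasta --config ex/template.yaml \
    --out reads --n-reads 500 --uniform-mix
splintlig qc --fasta ex/template.fasta --config ex/template.yaml \
    --reads reads/reads.fastq --out qcout
```

```
total_reads=500  merged=500  deduplicated=500  full_length=500  anchored=500
stop_free=261  unique_full_length_variants=261  unique_protein_variants=261
```

With 20 uniform NNK codons roughly half of all reads (expected 47.0 %)
carry at least one internal TAG stop; the funnel and the frequency grids
in `qcout/` quantify exactly that.

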