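"""Stochastic model of splint-ligation assembly and synthetic read generation.

The assembly model treats each of the J junctions of an n-fragment sense
tiling as an independent Bernoulli ligation event with probability p.
A "chain" (one slot of co-annealed fragments) then shatters into maximal
ligated runs: species (i, j) is the product spanning fragments i..j.  The
full-length fraction is p**J, and only full-length products that complete
the primer-extension step carry the antisense promoter strand and can be
transcribed — partial products are retained in the spectrum (they are the
gel smear) but never transcribe, which is what makes purification
unnecessary in this workflow.

:func:`sample_library_reads` generates synthetic amplicon reads from a
library template for the QC pipeline: each randomized codon is drawn from
its (possibly machine-mixing-biased) base mix, substitution errors are
applied, and a ground-truth table of the drawn codons is emitted for
oracle testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .design import LibraryTemplate
from .thermo import revcomp

__all__ = [
    "AssemblyModel",
    "ProductSpectrum",
    "ReadSimConfig",
    "ReadSimResult",
    "MACHINE_MIX_BIAS",
    "simulate_assembly",
    "transcribable_fraction",
    "sample_library_reads",
]

_MC_CAP = 10_000_000


@dataclass
class AssemblyModel:
    """Parameters of the independent-junction ligation model."""

    n_junctions: int
    per_junction_p: float
    n_input_molecules: int
    extension_success_p: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_junctions < 0 or self.n_input_molecules < 0:
            raise ValueError("counts must be ≥ 0")
        for name in ("per_junction_p", "extension_success_p"):
            p = getattr(self, name)
            if not 0 <= p <= 1:
                raise ValueError(f"{name} must be in [0, 1]")


@dataclass
class ProductSpectrum:
    """Histogram of ligation products keyed by (first, last) fragment index.

    Keys are 1-based inclusive fragment ranges; values are molecule counts
    (expected counts in analytic mode, realized counts in Monte-Carlo
    mode).  Fragment bookkeeping is conservative: summed over species,
    count × run length equals n_input × n_fragments.
    """

    counts: dict[tuple[int, int], float]
    n_input: int
    n_fragments: int
    extension_success_p: float = 1.0
    mode: str = "analytic"

    @property
    def full_length_count(self) -> float:
        return self.counts.get((1, self.n_fragments), 0.0)

    @property
    def transcribable_count(self) -> float:
        return self.full_length_count * self.extension_success_p

    def total_molecules(self) -> float:
        return sum(self.counts.values())


def simulate_assembly(model: AssemblyModel, mode: str = "analytic") -> ProductSpectrum:
    """Assemble n_input chains across J independent junctions.

    ``analytic`` returns expected species counts in closed form (the
    full-length expectation is ``n_input * p**J``); ``monte_carlo`` draws
    every junction per chain from a seeded generator, so replays are
    deterministic.  For 9 fragments the spectrum has up to 45 species —
    the contiguous sub-runs (i ≤ j) of the fragment chain.
    """
    J, p, n = model.n_junctions, model.per_junction_p, model.n_input_molecules
    nf = J + 1
    if mode == "analytic":
        counts: dict[tuple[int, int], float] = {}
        for i in range(1, nf + 1):
            for j in range(i, nf + 1):
                e = p ** (j - i)
                if i > 1:
                    e *= 1 - p
                if j < nf:
                    e *= 1 - p
                if e > 0:
                    counts[(i, j)] = n * e
        return ProductSpectrum(counts, n, nf, model.extension_success_p, "analytic")
    if mode == "monte_carlo":
        if n > _MC_CAP:
            raise ValueError(
                f"monte_carlo mode capped at {_MC_CAP:.0e} molecules; "
                "use analytic mode for larger inputs"
            )
        rng = np.random.default_rng(model.seed)
        if J == 0:
            return ProductSpectrum({(1, 1): float(n)}, n, 1, model.extension_success_p, "monte_carlo")
        closed = rng.random((n, J)) < p  # chain × junction ligation outcomes
        counts = {}
        for i in range(1, nf + 1):
            for j in range(i, nf + 1):
                mask = np.ones(n, dtype=bool)
                if i > 1:
                    mask &= ~closed[:, i - 2]
                if j < nf:
                    mask &= ~closed[:, j - 1]
                if j > i:
                    mask &= closed[:, i - 1 : j - 1].all(axis=1)
                c = int(mask.sum())
                if c:
                    counts[(i, j)] = float(c)
        return ProductSpectrum(counts, n, nf, model.extension_success_p, "monte_carlo")
    raise ValueError(f"mode must be 'analytic' or 'monte_carlo', got {mode!r}")


def transcribable_fraction(spectrum: ProductSpectrum) -> float:
    """Fraction of input chains yielding a transcribable molecule.

    Only products spanning fragment 1 (the promoter) through the last
    fragment, and completing extension, carry the antisense promoter
    strand; analytically this equals p**J × extension_success_p.
    """
    if not spectrum.counts:
        raise ValueError("empty product spectrum")
    if spectrum.n_input == 0:
        return 0.0
    return spectrum.transcribable_count / spectrum.n_input


# ---------------------------------------------------------------------------
# synthetic sequencing reads

#: Default machine-mixing base bias at degenerate positions: phosphoramidite
#: coupling is uneven, so N positions deviate from 25 % each and K positions
#: from 50/50 (values chosen inside the envelope typical of machine-mixed
#: NNK synthesis, N bases ~19–34 %, K bases ~38–61 %).
MACHINE_MIX_BIAS: dict[str, dict[str, float]] = {
    "N": {"A": 0.30, "C": 0.20, "G": 0.27, "T": 0.23},
    "K": {"A": 0.0, "C": 0.0, "G": 0.44, "T": 0.56},
}


def _uniform_bias() -> None:
    return None


@dataclass
class ReadSimConfig:
    """Configuration for synthetic library-read generation.

    ``base_mix_bias`` maps IUPAC symbols to base-frequency tables applied
    at randomized positions; ``None`` uses each codon's own mix (uniform
    by default — ideal mixing).  The default emulates machine mixing.
    ``layout`` is ``merged`` (one full-length read per molecule) or
    ``paired`` (overlapping mates R1/R2 of ``read_len`` each).
    """

    n_reads: int = 1000
    base_mix_bias: dict[str, dict[str, float]] | None = field(
        default_factory=lambda: {k: dict(v) for k, v in MACHINE_MIX_BIAS.items()}
    )
    substitution_error_rate: float = 0.0
    layout: str = "merged"
    read_len: int | None = None
    quality: int = 35
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_reads < 0:
            raise ValueError("n_reads must be ≥ 0")
        if not 0 <= self.substitution_error_rate <= 0.1:
            raise ValueError("substitution_error_rate must be in [0, 0.1]")
        if self.layout not in ("merged", "paired"):
            raise ValueError("layout must be 'merged' or 'paired'")
        if self.base_mix_bias is not None:
            for sym, table in self.base_mix_bias.items():
                total = sum(table.values())
                if abs(total - 1.0) > 1e-9:
                    raise ValueError(f"bias for {sym!r} sums to {total}, expected 1")


@dataclass
class ReadSimResult:
    """Synthetic reads plus the ground-truth codon table.

    ``truth`` has one row per read (index = read id) and one column
    ``codon_<orf_index>`` per randomized codon holding the drawn codon.
    """

    reads: list[SeqRecord] | None
    r1: list[SeqRecord] | None
    r2: list[SeqRecord] | None
    truth: pd.DataFrame


def sample_library_reads(template: LibraryTemplate, cfg: ReadSimConfig) -> ReadSimResult:
    """Draw synthetic amplicon reads from the template's randomized mixes.

    Every read is the full template with each randomized codon drawn from
    its per-position base distribution (optionally overridden by
    ``cfg.base_mix_bias``), then substitution errors applied uniformly.
    Paired layout emits R1 (template 5' prefix) and R2 (reverse complement
    of the 3' suffix) with an overlap determined by ``read_len``.
    """
    rng = np.random.default_rng(cfg.seed)
    L = template.length
    seq = template.full_sequence
    bases = np.frombuffer(b"ACGT", dtype="S1")

    intervals = template.randomized_intervals()
    rand_cols: list[int] = [p for s, e in intervals for p in range(s, e)]
    dists: list[np.ndarray] = []
    for (codon_idx, codon), (s, e) in zip(template.randomized_codons, intervals):
        for off in range(3):
            sym = codon.letters[off]
            table = None
            if cfg.base_mix_bias is not None and sym in cfg.base_mix_bias:
                table = cfg.base_mix_bias[sym]
            if table is None:
                table = codon.mix[off]
            dists.append(np.array([table.get(b, 0.0) for b in "ACGT"]))

    n = cfg.n_reads
    arr = np.tile(np.frombuffer(seq.encode(), dtype="S1"), (n, 1)) if n else np.empty(
        (0, L), dtype="S1"
    )
    for col, p in zip(rand_cols, dists):
        arr[:, col] = bases[rng.choice(4, size=n, p=p)]

    # ground truth records the drawn codons *before* sequencing error
    truth = pd.DataFrame(
        {
            f"codon_{codon_idx}": [
                arr[r, s:e].tobytes().decode() for r in range(n)
            ]
            for (codon_idx, _), (s, e) in zip(template.randomized_codons, intervals)
        }
        if n
        else {f"codon_{ci}": pd.Series(dtype=str) for ci, _ in template.randomized_codons}
    )
    truth.index.name = "read_id"

    if cfg.substitution_error_rate > 0 and n:
        err = rng.random((n, L)) < cfg.substitution_error_rate
        idx = np.nonzero(err)
        # substitute with a uniformly chosen *different* base
        cur = np.searchsorted(bases, arr[idx])
        shift = rng.integers(1, 4, size=len(idx[0]))
        arr[idx] = bases[(cur + shift) % 4]

    full_seqs = [arr[r].tobytes().decode() for r in range(n)]
    qual = [cfg.quality]

    def rec(name: str, s: str) -> SeqRecord:
        r = SeqRecord(Seq(s), id=name, description="")
        r.letter_annotations["phred_quality"] = qual * len(s)
        return r

    if cfg.layout == "merged":
        reads = [rec(f"read{r}", full_seqs[r]) for r in range(n)]
        return ReadSimResult(reads, None, None, truth)

    read_len = cfg.read_len or (L // 2 + 40)
    if read_len > L:
        read_len = L
    if 2 * read_len <= L:
        raise ValueError(
            f"paired reads of {read_len} nt cannot overlap on a {L}-nt template"
        )
    r1 = [rec(f"read{r}/1", full_seqs[r][:read_len]) for r in range(n)]
    r2 = [rec(f"read{r}/2", revcomp(full_seqs[r][-read_len:])) for r in range(n)]
    return ReadSimResult(None, r1, r2, truth)
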