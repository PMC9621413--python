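"""Degenerate-codon algebra and library diversity/quantity arithmetic.

This module is the numerical core of the toolkit: it expands IUPAC
degenerate codons (NNK and friends) into concrete codons, derives expected
amino-acid frequency tables, and converts between DNA mass, moles and
molecule counts for library-size budgeting.

Two models are provided for the fraction of library members carrying at
least one stop codon:

* :func:`stop_fraction_linear` — the additive approximation ``n * p``
  (the back-of-the-envelope number usually quoted for NNK libraries,
  62.5 % for 20 NNK codons), and
* :func:`stop_fraction_exact` — the exact complement ``1 - (1 - p)**n``
  under independent positions (47.0 % for 20 NNK codons).

Real machine-mixed libraries typically land between the exact prediction
and the linear over-estimate, so both are reported side by side.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

from Bio.Data.IUPACData import ambiguous_dna_values
from Bio.Seq import Seq

__all__ = [
    "DegenerateCodon",
    "QuantitySpec",
    "AVOGADRO",
    "expand_degenerate_codon",
    "expected_aa_frequencies",
    "stop_fraction_linear",
    "stop_fraction_exact",
    "theoretical_diversity",
    "molecules_from_mass",
    "molecules_from_moles",
    "pcr_volume_for_diversity",
    "ligation_yield",
    "per_junction_efficiency",
    "render_scientific",
    "render_percent",
]

#: CODATA value; printed outputs are rounded to the significant figures of
#: the context in which they are displayed (see :func:`render_scientific`),
#: never by degrading the constant itself.
AVOGADRO = 6.02214076e23

BASES = "ACGT"

#: IUPAC degenerate-base alphabet restricted to the 15 DNA symbols.
IUPAC_DNA: dict[str, str] = {
    k: "".join(sorted(v))
    for k, v in ambiguous_dna_values.items()
    if k in "ACGTMRWSYKVHDBN"
}

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})


def _uniform_mix(letter: str) -> dict[str, float]:
    allowed = IUPAC_DNA[letter]
    p = 1.0 / len(allowed)
    return {b: (p if b in allowed else 0.0) for b in BASES}


@dataclass(frozen=True)
class DegenerateCodon:
    """A 3-letter IUPAC degenerate codon with a per-position base mix.

    ``mix`` is a tuple of three probability tables over {A, C, G, T}; the
    default is uniform over the bases each IUPAC symbol allows (ideal
    mixing).  A non-uniform mix models machine-mixed phosphoramidite
    synthesis, where the four amidites couple at unequal rates.
    """

    letters: str
    mix: tuple[dict[str, float], ...] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        letters = self.letters.upper()
        if len(letters) != 3:
            raise ValueError(f"codon must have exactly 3 letters, got {self.letters!r}")
        for sym in letters:
            if sym not in IUPAC_DNA:
                raise ValueError(f"invalid IUPAC DNA symbol {sym!r} in codon {self.letters!r}")
        object.__setattr__(self, "letters", letters)
        if self.mix is None:
            object.__setattr__(self, "mix", tuple(_uniform_mix(s) for s in letters))
        else:
            mix = [dict(m) for m in self.mix]
            if len(mix) != 3:
                raise ValueError("mix must have one table per codon position")
            for pos, (sym, table) in enumerate(zip(letters, mix)):
                total = sum(table.get(b, 0.0) for b in BASES)
                if abs(total - 1.0) > 1e-9:
                    raise ValueError(f"mix at position {pos} sums to {total}, expected 1")
                for b in BASES:
                    p = table.get(b, 0.0)
                    if p < 0:
                        raise ValueError(f"negative probability for {b} at position {pos}")
                    if p > 0 and b not in IUPAC_DNA[sym]:
                        raise ValueError(
                            f"mix assigns mass {p} to base {b} at position {pos}, "
                            f"disallowed by symbol {sym!r}"
                        )
                mix[pos] = {b: table.get(b, 0.0) for b in BASES}
            object.__setattr__(self, "mix", tuple(mix))

    def __hash__(self) -> int:
        return hash((self.letters, tuple(tuple(sorted(m.items())) for m in self.mix)))

    def codon_probability(self, codon: str) -> float:
        """Probability of drawing a given concrete codon under the mix."""
        return math.prod(self.mix[i][codon[i]] for i in range(3))


def expand_degenerate_codon(codon: DegenerateCodon | str) -> set[str]:
    """All concrete codons reachable with nonzero probability.

    NNK expands to exactly 32 codons, NNN to 64, a plain codon to itself.
    """
    codon = _as_codon(codon)
    out: set[str] = set()
    for b0 in BASES:
        if codon.mix[0][b0] == 0:
            continue
        for b1 in BASES:
            if codon.mix[1][b1] == 0:
                continue
            for b2 in BASES:
                if codon.mix[2][b2] > 0:
                    out.add(b0 + b1 + b2)
    return out


def translate_codon(codon: str) -> str:
    """Standard-genetic-code translation; stop rendered as '*'."""
    return str(Seq(codon).translate())


def expected_aa_frequencies(codon: DegenerateCodon | str) -> dict[str, float]:
    """Expected residue frequencies (amino acids plus '*' for stop).

    Each concrete codon contributes its mix probability to its translation,
    so under a uniform NNK mix every frequency is (codon count)/32 —
    e.g. Leu 3/32, Trp 1/32, stop (TAG only) 1/32.
    """
    codon = _as_codon(codon)
    freqs: dict[str, float] = {}
    for concrete in expand_degenerate_codon(codon):
        aa = translate_codon(concrete)
        freqs[aa] = freqs.get(aa, 0.0) + codon.codon_probability(concrete)
    return freqs


def stop_fraction_linear(n_positions: int, per_position_stop_prob: float) -> float:
    """Additive stop-fraction approximation: ``n * p``.

    This is the commonly quoted estimate for randomized-codon libraries
    (20 NNK positions at 1/32 stop each → 62.5 %).  It over-counts reads
    with multiple stops; compare :func:`stop_fraction_exact`.
    """
    _check_stop_args(n_positions, per_position_stop_prob)
    est = n_positions * per_position_stop_prob
    if est > 1:
        warnings.warn(
            f"linear stop approximation n*p = {est:.3f} exceeds 1; "
            "use stop_fraction_exact instead",
            stacklevel=2,
        )
    return est


def stop_fraction_exact(n_positions: int, per_position_stop_prob: float) -> float:
    """Exact stop-containing fraction under independent positions.

    ``1 - (1 - p)**n``; always ≤ the linear approximation, with equality at
    n ≤ 1 or p = 0.  For 20 NNK codons this gives ≈ 47.0 %.
    """
    _check_stop_args(n_positions, per_position_stop_prob)
    if per_position_stop_prob > 1:
        raise ValueError("per-position probability must be ≤ 1")
    return 1.0 - (1.0 - per_position_stop_prob) ** n_positions


def _check_stop_args(n_positions: int, p: float) -> None:
    if n_positions < 0:
        raise ValueError("n_positions must be ≥ 0")
    if p < 0:
        raise ValueError("per-position stop probability must be ≥ 0")


def theoretical_diversity(
    n_positions: int, codon: DegenerateCodon | str, level: str = "nucleotide"
) -> int:
    """Theoretical library diversity as an exact big integer.

    ``nucleotide`` counts distinct DNA sequences (|expansion| ** n, e.g.
    32**20 ≈ 1.3e30 for 20 NNK codons); ``protein`` counts distinct
    residue strings including stop (21 ** n for NNK).
    """
    if n_positions < 0:
        raise ValueError("n_positions must be ≥ 0")
    codon = _as_codon(codon)
    expansion = expand_degenerate_codon(codon)
    if level == "nucleotide":
        base = len(expansion)
    elif level == "protein":
        base = len({translate_codon(c) for c in expansion})
    else:
        raise ValueError(f"level must be 'nucleotide' or 'protein', got {level!r}")
    return base**n_positions


@dataclass
class QuantitySpec:
    """DNA quantity for mass/mole/molecule conversions.

    Exactly one of ``mass_ng`` / ``moles_pmol`` is used per conversion.
    ``avg_bp_mw`` is the average molecular weight of one base pair of
    dsDNA in g/mol/bp (660 by convention).
    """

    mass_ng: float | None = None
    moles_pmol: float | None = None
    length_bp: int = 1
    avg_bp_mw: float = 660.0
    avogadro: float = AVOGADRO

    def __post_init__(self) -> None:
        if self.length_bp < 1:
            raise ValueError("length_bp must be ≥ 1")
        for name in ("mass_ng", "moles_pmol"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be ≥ 0")


def molecules_from_mass(q: QuantitySpec) -> float:
    """Molecule count from dsDNA mass: mass_g / (length · mw) · N_A.

    10 ng of a 500-bp template is ≈ 2e10 molecules — the diversity ceiling
    of a single 50-µL PCR seeded with that much template.
    """
    if q.mass_ng is None:
        raise ValueError("mass_ng must be set for molecules_from_mass")
    mass_g = q.mass_ng * 1e-9
    return mass_g / (q.length_bp * q.avg_bp_mw) * q.avogadro


def molecules_from_moles(q: QuantitySpec) -> float:
    """Molecule count from picomoles (15 pmol ≈ 9e12 molecules)."""
    if q.moles_pmol is None:
        raise ValueError("moles_pmol must be set for molecules_from_moles")
    return q.moles_pmol * 1e-12 * q.avogadro


def pcr_volume_for_diversity(
    target_variants: float, per_reaction_molecules: float, reaction_volume_ul: float
) -> float:
    """Total PCR volume (mL) needed to cover a target diversity.

    Whole reactions are counted (ceil), each of ``reaction_volume_ul``.
    1e12 variants at 2e10 molecules per 50-µL reaction → 2.5 mL;
    1e14 → 250 mL.
    """
    if per_reaction_molecules <= 0:
        raise ValueError("per_reaction_molecules must be > 0")
    if target_variants < 0 or reaction_volume_ul < 0:
        raise ValueError("quantities must be ≥ 0")
    n_reactions = math.ceil(target_variants / per_reaction_molecules)
    return n_reactions * reaction_volume_ul / 1000.0


def ligation_yield(full_length: float, input_per_oligo: float) -> float:
    """Overall assembly yield as a percentage of input molecules.

    4.25e11 full-length product from 9e12 input molecules → 4.7 %.
    Returns the raw percentage; use :func:`render_percent` for display.
    """
    if input_per_oligo <= 0:
        raise ValueError("input_per_oligo must be > 0")
    if full_length < 0:
        raise ValueError("full_length must be ≥ 0")
    return 100.0 * full_length / input_per_oligo


def per_junction_efficiency(overall_yield: float, n_junctions: int) -> float:
    """Constant per-junction ligation efficiency from an overall yield.

    Under independent junctions the overall yield is p**J, so
    p = yield**(1/J).  A 4.7 % overall yield across 8 junctions implies
    ≈ 68 % efficiency per ligation event.
    """
    if not 0 < overall_yield <= 1:
        raise ValueError("overall_yield must be in (0, 1]")
    if n_junctions < 1:
        raise ValueError("n_junctions must be ≥ 1")
    return overall_yield ** (1.0 / n_junctions)


# ---------------------------------------------------------------------------
# display rounding

def render_scientific(x: float, sig: int = 1) -> str:
    """Render to ``sig`` significant figures in compact scientific form.

    ``render_scientific(1.83e10) == '2e10'`` — the raw value is preserved
    by the computation functions; rounding happens only here.
    """
    if sig < 1:
        raise ValueError("sig must be ≥ 1")
    if x == 0:
        return "0"
    exp = math.floor(math.log10(abs(x)))
    mant = round(x / 10**exp, sig - 1)
    if abs(mant) >= 10:  # rounding carried over a decade
        mant /= 10
        exp += 1
    mant_s = f"{mant:.{sig - 1}f}".rstrip("0").rstrip(".")
    return f"{mant_s}e{exp}"


def render_percent(pct: float, decimals: int = 1) -> str:
    """Render a percentage for display, e.g. ``render_percent(62.5) == '62.5%'``."""
    return f"{pct:.{decimals}f}%"


def _as_codon(codon: DegenerateCodon | str) -> DegenerateCodon:
    return codon if isinstance(codon, DegenerateCodon) else DegenerateCodon(codon)
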