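"""Nearest-neighbor duplex melting temperatures for splint annealing arms.

Splint arms are sized so that each arm melts near 40 °C under the ligation
buffer conditions.  Tm is computed with the unified nearest-neighbor
ΔH/ΔS parameter set (Allawi & SantaLucia 1997, as used in the SantaLucia
1998 unified treatment) and the Owczarzy 2008 monovalent + magnesium salt
correction, via Biopython's ``MeltingTemp`` machinery.

Default conditions mirror a splint-ligation buffer: 0.25 µM total strand,
50 mM monovalent salt, 8 mM Mg2+, no dNTPs.  All conditions are explicit
on :class:`DuplexContext` and echoed into design reports.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.SeqUtils import MeltingTemp as _mt

__all__ = ["DuplexContext", "nn_tm", "tm_of", "revcomp"]

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    """Reverse complement of a plain A/C/G/T string."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class DuplexContext:
    """A DNA duplex (given by its sense strand, 5'→3') plus solution conditions.

    oligo_conc_M is the *total* strand concentration; the two strands are
    assumed equimolar, giving the standard CT/4 term for non-self-
    complementary duplexes.
    """

    sequence: str
    oligo_conc_M: float = 0.25e-6
    monovalent_mM: float = 50.0
    divalent_mM: float = 8.0
    dntp_mM: float = 0.0

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        if len(seq) < 2:
            raise ValueError("duplex must be at least 2 nt")
        for i, b in enumerate(seq):
            if b not in "ACGT":
                raise ValueError(
                    f"degenerate or invalid base {b!r} at position {i}; "
                    "Tm is defined for concrete A/C/G/T duplexes only"
                )
        object.__setattr__(self, "sequence", seq)
        for name in ("oligo_conc_M", "monovalent_mM", "divalent_mM", "dntp_mM"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be ≥ 0")


def nn_tm(ctx: DuplexContext, saltcorr: int = 7) -> float:
    """Duplex melting temperature in °C.

    ``saltcorr=7`` selects the Owczarzy 2008 correction, which handles
    monovalent and Mg2+ (with dNTP chelation) jointly; ``saltcorr=0``
    disables salt correction (1 M Na+ reference state), which is useful
    for checking against published nearest-neighbor tables directly.
    """
    half_nM = ctx.oligo_conc_M * 1e9 / 2.0
    return _mt.Tm_NN(
        ctx.sequence,
        nn_table=_mt.DNA_NN3,
        dnac1=half_nM,
        dnac2=half_nM,
        selfcomp=False,
        Na=ctx.monovalent_mM,
        K=0,
        Tris=0,
        Mg=ctx.divalent_mM,
        dNTPs=ctx.dntp_mM,
        saltcorr=saltcorr,
    )


def tm_of(sequence: str, **conditions: float) -> float:
    """Convenience wrapper: Tm of a sequence under (possibly default) conditions."""
    return nn_tm(DuplexContext(sequence, **conditions))
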