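"""Worked example: an ankyrin-repeat-style randomized library template.

:func:`worked_template` builds, deterministically, a 620-nt sense-strand
construct of the architecture this toolkit targets: a T7 promoter and
ribosome binding site, a 516-bp ORF encoding a repeat-protein-like
scaffold with 20 NNK-randomized codons clustered in five loop regions,
and a 3' constant region for the reverse (CR) primer.  The framework
sequence is synthetic (generated from a fixed seed, stop-free in frame);
it stands in for a real binder scaffold while exercising every design
constraint: the randomized clusters are separated by framework runs long
enough to host splint junctions, and a default design yields nine sense
oligos in three groups with eight splints.
"""

from __future__ import annotations

import numpy as np

from .codon_math import DegenerateCodon, STOP_CODONS
from .design import LibraryTemplate

__all__ = ["worked_template", "RANDOMIZED_CODON_INDICES"]

T7_PROMOTER = "TAATACGACTCACTATAGGG"
RBS = "AGGAGG"

#: 0-based codon indices of the 20 NNK positions, clustered in five
#: loop-like blocks of four, mimicking repeat-protein surface randomization.
RANDOMIZED_CODON_INDICES = (
    30, 31, 33, 35,
    60, 61, 63, 65,
    90, 91, 93, 95,
    120, 121, 123, 125,
    150, 151, 153, 155,
)

_SENSE_CODONS = sorted(
    {a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"} - STOP_CODONS
)

_SEED = 20221031  # fixes the synthetic framework sequence


def worked_template(cr_tail: str = "") -> LibraryTemplate:
    """Build the 620-nt worked library template (deterministic).

    Layout (0-based half-open template coordinates):

    * ``[0, 20)``   T7 promoter
    * ``[40, 46)``  ribosome binding site
    * ``[62, 578)`` ORF — 172 codons: ATG start, TAA terminal stop,
      NNK at :data:`RANDOMIZED_CODON_INDICES`
    * ``[578, 620)`` 3' constant region (CR-primer annealing site)

    ``cr_tail`` is an optional constant 5' extension carried by the CR
    primer into the double-stranded product.
    """
    rng = np.random.default_rng(_SEED)

    def draw_bases(n: int) -> str:
        return "".join(rng.choice(list("ACGT"), size=n))

    def draw_codons(n: int) -> str:
        # framework codons are stop-free so the constant ORF translates clean
        return "".join(rng.choice(_SENSE_CODONS, size=n))

    five_prime = T7_PROMOTER + draw_bases(20) + RBS + draw_bases(16)  # 62 nt
    assert len(five_prime) == 62

    rand = set(RANDOMIZED_CODON_INDICES)
    codons: list[str] = []
    for i in range(172):
        if i == 0:
            codons.append("ATG")
        elif i == 171:
            codons.append("TAA")
        elif i in rand:
            codons.append("NNK")
        else:
            codons.append(draw_codons(1))
    orf = "".join(codons)
    three_prime = draw_bases(42)
    seq = five_prime + orf + three_prime
    assert len(seq) == 620

    return LibraryTemplate(
        full_sequence=seq,
        promoter_span=(0, 20),
        rbs_span=(40, 46),
        orf_span=(62, 578),
        randomized_codons=[(i, DegenerateCodon("NNK")) for i in RANDOMIZED_CODON_INDICES],
        three_prime_constant_span=(578, 620),
        cr_tail=cr_tail,
        name="arp-nnk20-worked-example",
    )
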