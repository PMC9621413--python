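"""Shared builders for small synthetic templates used across test modules."""

import numpy as np

from splintlig.codon_math import DegenerateCodon
from splintlig.design import LibraryTemplate

_SENSE_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA")
]


def constant_seq(n: int, seed: int) -> str:
    rng = np.random.default_rng(seed)
    return "".join(rng.choice(list("ACGT"), n))


def make_template(n_codons, nnk_indices, five_prime=18, three_prime=12, seed=0):
    """Small synthetic template: constant flanks + ORF with NNK at given codons.

    The framework codons are stop-free so stop statistics are driven only
    by the randomized positions.
    """
    rng = np.random.default_rng(seed)
    nnk = set(nnk_indices)
    codons = [
        "NNK" if i in nnk else str(rng.choice(_SENSE_CODONS)) for i in range(n_codons)
    ]
    seq = constant_seq(five_prime, seed + 1) + "".join(codons) + constant_seq(
        three_prime, seed + 2
    )
    orf = (five_prime, five_prime + 3 * n_codons)
    return LibraryTemplate(
        full_sequence=seq,
        promoter_span=(0, min(3, five_prime)),
        rbs_span=(min(3, five_prime - 1), min(6, five_prime)),
        orf_span=orf,
        randomized_codons=[(i, DegenerateCodon("NNK")) for i in nnk_indices],
        three_prime_constant_span=(orf[1], orf[1] + three_prime),
    )
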