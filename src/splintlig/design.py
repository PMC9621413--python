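"""Partition a randomized template into sense oligos and design splints.

The construction strategy assembles a single-stranded sense gene from
short synthetic oligos ligated end-to-end on antisense "splint" bridges,
then converts it to dsDNA with one reverse primer and a strand-displacing
polymerase.  The designer enforces the three oligo criteria of that
architecture:

  i.   every sense oligo is shorter than a maximum synthesizable length
       (default 90 nt);
  ii.  each splint annealing arm melts near a target Tm (default 40 °C,
       within a configurable window);
  iii. splint arms bind only framework (constant) sequence — they never
       overlap a randomized codon.

Sense oligos are tiled contiguously (their concatenation reconstructs the
template exactly, degenerate letters included) and grouped into
consecutive blocks for staged ligation.  All sense oligos except the
first carry a 5'-phosphate; every splint carries a 3'-phosphate so it
cannot itself be ligated.

Junction placement is a dynamic program over candidate cut positions that
minimizes the summed arm-Tm deviation from target, breaking ties toward
more even oligo lengths and then toward leftmost junctions.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import pandas as pd

from .codon_math import DegenerateCodon, IUPAC_DNA, STOP_CODONS
from .thermo import DuplexContext, nn_tm, revcomp

__all__ = [
    "LibraryTemplate",
    "DesignConstraints",
    "SenseOligo",
    "SplintOligo",
    "CRPrimer",
    "OligoSet",
    "JunctionCandidate",
    "enumerate_junction_candidates",
    "partition_template",
    "design_splints",
    "design_oligo_set",
    "render_order_sheet",
    "parse_order_sheet",
]

Span = tuple[int, int]


@dataclass
class LibraryTemplate:
    """Annotated sense-strand construct with randomized codon positions.

    Coordinates are 0-based half-open on ``full_sequence``.  Randomized
    codons are indexed by codon within the ORF (0-based); the letters at
    those positions in ``full_sequence`` must match the degenerate codes.
    """

    full_sequence: str
    promoter_span: Span
    rbs_span: Span
    orf_span: Span
    randomized_codons: list[tuple[int, DegenerateCodon]]
    three_prime_constant_span: Span
    cr_tail: str = ""
    name: str = "template"

    def __post_init__(self) -> None:
        self.full_sequence = self.full_sequence.upper()
        self.randomized_codons = sorted(self.randomized_codons, key=lambda rc: rc[0])
        self.validate()

    # -- validation -----------------------------------------------------
    def validate(self) -> None:
        seq = self.full_sequence
        L = len(seq)
        spans = [
            ("promoter", self.promoter_span),
            ("rbs", self.rbs_span),
            ("orf", self.orf_span),
            ("three_prime_constant", self.three_prime_constant_span),
        ]
        for name, (s, e) in spans:
            if not (0 <= s < e <= L):
                raise ValueError(f"{name} span ({s}, {e}) out of bounds for length {L}")
        for (na, (_, ea)), (nb, (sb, _)) in zip(spans, spans[1:]):
            if ea > sb:
                raise ValueError(f"spans {na} and {nb} overlap or are out of order")
        orf_s, orf_e = self.orf_span
        if (orf_e - orf_s) % 3 != 0:
            raise ValueError("ORF length must be divisible by 3")
        n_codons = (orf_e - orf_s) // 3
        seen: set[int] = set()
        for idx, codon in self.randomized_codons:
            if not 0 <= idx < n_codons:
                raise ValueError(f"randomized codon index {idx} outside ORF (0..{n_codons - 1})")
            if idx in seen:
                raise ValueError(f"duplicate randomized codon index {idx}")
            seen.add(idx)
            start = orf_s + 3 * idx
            for off, sym in enumerate(codon.letters):
                if seq[start + off] != sym:
                    raise ValueError(
                        f"template letter {seq[start + off]!r} at position {start + off} "
                        f"does not match randomized code {sym!r} (codon {idx})"
                    )
        rand_nt = set()
        for s, e in self.randomized_intervals():
            rand_nt.update(range(s, e))
        for pos, b in enumerate(seq):
            if b not in "ACGT":
                if b not in IUPAC_DNA:
                    raise ValueError(f"invalid base {b!r} at position {pos}")
                if pos not in rand_nt:
                    raise ValueError(
                        f"degenerate base {b!r} at position {pos} lies outside "
                        "every randomized codon"
                    )
        tail = self.cr_tail.upper()
        if any(b not in "ACGT" for b in tail):
            raise ValueError("cr_tail must contain only A/C/G/T")
        self.cr_tail = tail

    # -- derived geometry -----------------------------------------------
    def randomized_intervals(self) -> list[Span]:
        """Template-coordinate nucleotide intervals of the randomized codons."""
        orf_s = self.orf_span[0]
        return [(orf_s + 3 * i, orf_s + 3 * i + 3) for i, _ in self.randomized_codons]

    @property
    def length(self) -> int:
        return len(self.full_sequence)

    def n_codons(self) -> int:
        return (self.orf_span[1] - self.orf_span[0]) // 3

    def constant_orf_codons(self) -> list[str]:
        """Concrete framework codons of the ORF (excluding randomized ones)."""
        orf_s, orf_e = self.orf_span
        rand = {i for i, _ in self.randomized_codons}
        return [
            self.full_sequence[orf_s + 3 * i : orf_s + 3 * i + 3]
            for i in range(self.n_codons())
            if i not in rand
        ]


@dataclass
class DesignConstraints:
    """Hard limits and targets for oligo partitioning and splint design."""

    max_oligo_len: int = 90
    min_oligo_len: int = 25
    target_arm_tm: float = 40.0
    arm_tm_window: float = 4.0
    group_size: int = 3
    min_arm_len: int = 8
    max_arm_len: int = 20
    tm_conditions: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.group_size < 2:
            raise ValueError("group_size must be ≥ 2")
        if self.max_oligo_len < 2 * self.min_arm_len:
            raise ValueError("max_oligo_len must be ≥ 2 × min_arm_len")
        if not self.min_arm_len <= self.max_arm_len:
            raise ValueError("min_arm_len must be ≤ max_arm_len")
        # arms anneal within the adjacent sense oligos, so oligos can never
        # be shorter than the longest permitted arm
        if self.min_oligo_len < self.max_arm_len:
            raise ValueError("min_oligo_len must be ≥ max_arm_len")


@dataclass
class SenseOligo:
    """A forward-strand fragment of the library gene (NF1, NF2, ...)."""

    name: str
    span: Span
    sequence: str
    five_prime_phosphate: bool
    group_index: int

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class SplintOligo:
    """Antisense bridge across a sense-oligo junction (SP1, SP2, ...).

    ``left_arm`` anneals to the upstream sense oligo, ``right_arm`` to the
    downstream one (spans in template coordinates).  The 3'-phosphate
    blocks the splint from being ligated itself.
    """

    name: str
    junction_index: int
    sequence: str
    left_arm: Span
    right_arm: Span
    arm_tms: tuple[float, float]
    stage: str  # "within-group" | "bridging"
    three_prime_phosphate: bool = True


@dataclass
class CRPrimer:
    """Reverse primer annealing to the 3' constant region.

    Its optional 5' tail is carried through to the double-stranded product
    (e.g. a hybridization handle for downstream display chemistry).
    """

    name: str
    sequence: str
    anneal_span: Span
    tm: float
    tail: str = ""


@dataclass
class OligoSet:
    """A complete design: sense tiling, splints, CR primer, constraints echo."""

    template_name: str
    sense: list[SenseOligo]
    splints: list[SplintOligo]
    cr: CRPrimer | None
    constraints: DesignConstraints

    @property
    def junction_positions(self) -> list[int]:
        return [o.span[1] for o in self.sense[:-1]]

    def n_groups(self) -> int:
        return max(o.group_index for o in self.sense)


@dataclass
class JunctionCandidate:
    """A legal cut position with its best splint-arm pair."""

    position: int
    left_arm_len: int
    right_arm_len: int
    left_tm: float
    right_tm: float

    def score(self, target_tm: float) -> float:
        """Summed absolute arm-Tm deviation from the target."""
        return abs(self.left_tm - target_tm) + abs(self.right_tm - target_tm)


def _candidate_score(c: JunctionCandidate, target: float) -> float:
    return c.score(target)


class _ArmScorer:
    """Finds and caches best annealing arms around candidate junctions."""

    def __init__(self, template: LibraryTemplate, constraints: DesignConstraints):
        self.seq = template.full_sequence
        self.c = constraints
        self.blocked = template.randomized_intervals()
        self._tm_cache: dict[Span, float] = {}

    def _tm(self, start: int, end: int) -> float:
        key = (start, end)
        if key not in self._tm_cache:
            ctx = DuplexContext(self.seq[start:end], **self.c.tm_conditions)
            self._tm_cache[key] = nn_tm(ctx)
        return self._tm_cache[key]

    def _clear(self, start: int, end: int) -> bool:
        if start < 0 or end > len(self.seq):
            return False
        if any(s < end and e > start for s, e in self.blocked):
            return False
        return all(b in "ACGT" for b in self.seq[start:end])

    def _best_arm(self, spans: list[Span]) -> tuple[Span, float] | None:
        """Arm minimizing |Tm − target| within the window; ties → shorter arm."""
        best: tuple[float, int, Span, float] | None = None
        for s, e in spans:
            if not self._clear(s, e):
                continue
            tm = self._tm(s, e)
            dev = abs(tm - self.c.target_arm_tm)
            if dev > self.c.arm_tm_window:
                continue
            key = (dev, e - s, (s, e), tm)
            if best is None or key < best:
                best = key
        if best is None:
            return None
        return best[2], best[3]

    def best_arms(self, j: int) -> JunctionCandidate | None:
        c = self.c
        left = self._best_arm([(j - la, j) for la in range(c.min_arm_len, c.max_arm_len + 1)])
        if left is None:
            return None
        right = self._best_arm([(j, j + ra) for ra in range(c.min_arm_len, c.max_arm_len + 1)])
        if right is None:
            return None
        (ls, le), ltm = left
        (rs, re), rtm = right
        return JunctionCandidate(j, le - ls, re - rs, ltm, rtm)


def enumerate_junction_candidates(
    template: LibraryTemplate, constraints: DesignConstraints
) -> list[JunctionCandidate]:
    """Every template position at which a legal splint could bridge a cut.

    A position qualifies if some arm pair within the length bounds avoids
    all randomized codons (framework-only binding) and both arms fall in
    the Tm window.  An empty list is a valid outcome, meaning the template
    has no frameworks runs long enough to host a junction.
    """
    scorer = _ArmScorer(template, constraints)
    L = template.length
    out: list[JunctionCandidate] = []
    lo, hi = constraints.min_arm_len, L - constraints.min_arm_len
    for j in range(lo, hi + 1):
        # cheap geometric reject: the minimal arms must already be clear
        if not scorer._clear(j - constraints.min_arm_len, j + constraints.min_arm_len):
            continue
        cand = scorer.best_arms(j)
        if cand is not None:
            out.append(cand)
    return out


def _solve_partition(
    L: int,
    cands: list[JunctionCandidate],
    n_oligos: int,
    constraints: DesignConstraints,
) -> list[JunctionCandidate] | None:
    """Exact DP over candidate cuts: minimize summed arm-Tm deviation.

    Lexicographic objective: (total Tm deviation, sum of squared segment
    lengths, cut-position tuple) — the second term prefers even tilings at
    equal deviation, the third makes ties deterministic and leftmost.
    """
    k = n_oligos - 1  # number of cuts
    if k == 0:
        return [] if constraints.min_oligo_len <= L <= constraints.max_oligo_len else None
    lo, hi = constraints.min_oligo_len, constraints.max_oligo_len
    target = constraints.target_arm_tm
    pos = [c.position for c in cands]
    m = len(cands)
    # dp[i] for current cut count: (dev_sum, sumsq, cuts) or None
    Cost = tuple[float, int, tuple[int, ...]]
    dp: list[Cost | None] = [
        (
            (_candidate_score(c, target), c.position**2, (i,))
            if lo <= c.position <= hi
            else None
        )
        for i, c in enumerate(cands)
    ]
    for _ in range(1, k):
        nxt: list[Cost | None] = [None] * m
        for i in range(m):
            p = pos[i]
            sc = _candidate_score(cands[i], target)
            best: Cost | None = None
            for j in range(i):
                prev = dp[j]
                if prev is None:
                    continue
                seg = p - pos[j]
                if seg < lo:
                    break  # pos sorted ascending; later j only shrink seg
                if seg > hi:
                    continue
                cand_cost = (prev[0] + sc, prev[1] + seg**2, prev[2] + (i,))
                if best is None or cand_cost < best:
                    best = cand_cost
            nxt[i] = best
        dp = nxt
    best_final: Cost | None = None
    for i in range(m):
        cur = dp[i]
        if cur is None:
            continue
        seg = L - pos[i]
        if not lo <= seg <= hi:
            continue
        total = (cur[0], cur[1] + seg**2, cur[2])
        if best_final is None or total < best_final:
            best_final = total
    if best_final is None:
        return None
    return [cands[i] for i in best_final[2]]


def partition_template(
    template: LibraryTemplate, constraints: DesignConstraints | None = None
) -> OligoSet:
    """Tile the template into named sense oligos NF1..NFk.

    The oligo count is the smallest multiple of ``group_size`` admitting a
    feasible tiling (a short template that fits in one oligo is returned
    as a single unphosphorylated oligo — no ligation is needed).  If no
    multiple of the group size is feasible, the minimal feasible count is
    used and a warning is issued.
    """
    constraints = constraints or DesignConstraints()
    L = template.length
    if L <= constraints.max_oligo_len:
        sense = [SenseOligo("NF1", (0, L), template.full_sequence, False, 1)]
        return OligoSet(template.name, sense, [], _make_cr(template, constraints), constraints)

    cands = enumerate_junction_candidates(template, constraints)
    n_min = math.ceil(L / constraints.max_oligo_len)
    n_max = L // constraints.min_oligo_len
    chosen: list[JunctionCandidate] | None = None
    k = math.ceil(n_min / constraints.group_size) * constraints.group_size
    while k <= n_max:
        chosen = _solve_partition(L, cands, k, constraints)
        if chosen is not None:
            break
        k += constraints.group_size
    if chosen is None:
        for k in range(n_min, n_max + 1):
            chosen = _solve_partition(L, cands, k, constraints)
            if chosen is not None:
                warnings.warn(
                    f"no tiling with a multiple of group_size={constraints.group_size} "
                    f"oligos; using minimal feasible count {k}",
                    stacklevel=2,
                )
                break
    if chosen is None:
        gaps = _framework_gap_report(template, constraints)
        raise ValueError(
            "template cannot be partitioned: no junction tiling satisfies "
            f"oligo length ≤ {constraints.max_oligo_len} with framework-only "
            f"arms in the Tm window ({gaps})"
        )
    cuts = [c.position for c in chosen]
    bounds = [0, *cuts, L]
    sense = []
    for i, (s, e) in enumerate(zip(bounds, bounds[1:]), start=1):
        sense.append(
            SenseOligo(
                name=f"NF{i}",
                span=(s, e),
                sequence=template.full_sequence[s:e],
                five_prime_phosphate=i != 1,
                group_index=(i - 1) // constraints.group_size + 1,
            )
        )
    return OligoSet(template.name, sense, [], _make_cr(template, constraints), constraints)


def _framework_gap_report(template: LibraryTemplate, constraints: DesignConstraints) -> str:
    """Diagnose infeasibility: the largest stretch without a legal junction."""
    cands = {c.position for c in enumerate_junction_candidates(template, constraints)}
    run, worst, start = 0, (0, 0), 0
    for j in range(template.length + 1):
        if j in cands:
            run = 0
            start = j
        else:
            run += 1
            if run > worst[1]:
                worst = (start, run)
    return (
        f"longest junction-free stretch spans positions {worst[0]}..{worst[0] + worst[1]} "
        f"({worst[1]} nt) vs max oligo length {constraints.max_oligo_len}"
    )


def _make_cr(template: LibraryTemplate, constraints: DesignConstraints) -> CRPrimer:
    s, e = template.three_prime_constant_span
    anneal = revcomp(template.full_sequence[s:e])
    tm = nn_tm(DuplexContext(anneal, **constraints.tm_conditions))
    return CRPrimer("CR", template.cr_tail + anneal, (s, e), tm, template.cr_tail)


def design_splints(
    oligos: OligoSet, template: LibraryTemplate, constraints: DesignConstraints | None = None
) -> OligoSet:
    """Attach one splint per junction of a sense tiling.

    Splints at junctions inside a group are tagged ``within-group``; those
    spanning a group boundary (every group_size-th junction — SP3 and SP6
    in a nine-oligo, three-group design) are tagged ``bridging`` and are
    added in the second ligation stage.  Each arm is tuned independently
    to the Tm target; all splints are 3'-phosphorylated.
    """
    constraints = constraints or oligos.constraints
    scorer = _ArmScorer(template, constraints)
    splints: list[SplintOligo] = []
    for i, j in enumerate(oligos.junction_positions, start=1):
        cand = scorer.best_arms(j)
        if cand is None:
            raise ValueError(
                f"junction {i} at position {j}: no arm pair reaches the Tm window "
                f"{constraints.target_arm_tm}±{constraints.arm_tm_window} °C"
            )
        la, ra = cand.left_arm_len, cand.right_arm_len
        window = template.full_sequence[j - la : j + ra]
        stage = "bridging" if i % constraints.group_size == 0 else "within-group"
        splints.append(
            SplintOligo(
                name=f"SP{i}",
                junction_index=i,
                sequence=revcomp(window),
                left_arm=(j - la, j),
                right_arm=(j, j + ra),
                arm_tms=(cand.left_tm, cand.right_tm),
                stage=stage,
            )
        )
    return replace(oligos, splints=splints)


def design_oligo_set(
    template: LibraryTemplate, constraints: DesignConstraints | None = None
) -> OligoSet:
    """Full design: partition into sense oligos, then attach splints."""
    constraints = constraints or DesignConstraints()
    oset = partition_template(template, constraints)
    if len(oset.sense) > 1:
        oset = design_splints(oset, template, constraints)
    return oset


# ---------------------------------------------------------------------------
# order sheet

_MOD_5P = "/5Phos/"
_MOD_3P = "/3Phos/"


def render_order_sheet(oligos: OligoSet) -> pd.DataFrame:
    """Vendor-style order sheet: one row per oligo, NF rows then SP then CR.

    The ``order_sequence`` column carries 5'/3'-phosphate modification
    codes inline; ``sequence`` is the bare 5'→3' sequence.
    """
    rows = []
    for o in oligos.sense:
        rows.append(
            {
                "name": o.name,
                "kind": "sense",
                "order_sequence": (_MOD_5P if o.five_prime_phosphate else "") + o.sequence,
                "sequence": o.sequence,
                "length": o.length,
                "start": o.span[0],
                "end": o.span[1],
                "group": o.group_index,
                "stage": "",
                "left_arm_len": "",
                "right_arm_len": "",
                "left_arm_tm": "",
                "right_arm_tm": "",
            }
        )
    for sp in oligos.splints:
        rows.append(
            {
                "name": sp.name,
                "kind": "splint",
                "order_sequence": sp.sequence + _MOD_3P,
                "sequence": sp.sequence,
                "length": len(sp.sequence),
                "start": sp.left_arm[0],
                "end": sp.right_arm[1],
                "group": "",
                "stage": sp.stage,
                "left_arm_len": sp.left_arm[1] - sp.left_arm[0],
                "right_arm_len": sp.right_arm[1] - sp.right_arm[0],
                "left_arm_tm": sp.arm_tms[0],
                "right_arm_tm": sp.arm_tms[1],
            }
        )
    if oligos.cr is not None:
        cr = oligos.cr
        rows.append(
            {
                "name": cr.name,
                "kind": "primer",
                "order_sequence": cr.sequence,
                "sequence": cr.sequence,
                "length": len(cr.sequence),
                "start": cr.anneal_span[0],
                "end": cr.anneal_span[1],
                "group": "",
                "stage": "",
                "left_arm_len": "",
                "right_arm_len": "",
                "left_arm_tm": cr.tm,
                "right_arm_tm": "",
            }
        )
    return pd.DataFrame(rows)


def parse_order_sheet(
    sheet: pd.DataFrame, constraints: DesignConstraints | None = None
) -> OligoSet:
    """Reconstruct an :class:`OligoSet` from a rendered order sheet."""
    constraints = constraints or DesignConstraints()
    sense, splints, cr = [], [], None
    for _, r in sheet.iterrows():
        if r["kind"] == "sense":
            sense.append(
                SenseOligo(
                    name=r["name"],
                    span=(int(r["start"]), int(r["end"])),
                    sequence=r["sequence"],
                    five_prime_phosphate=str(r["order_sequence"]).startswith(_MOD_5P),
                    group_index=int(r["group"]),
                )
            )
        elif r["kind"] == "splint":
            j = int(r["start"]) + int(r["left_arm_len"])
            splints.append(
                SplintOligo(
                    name=r["name"],
                    junction_index=int(str(r["name"]).removeprefix("SP")),
                    sequence=r["sequence"],
                    left_arm=(int(r["start"]), j),
                    right_arm=(j, int(r["end"])),
                    arm_tms=(float(r["left_arm_tm"]), float(r["right_arm_tm"])),
                    stage=r["stage"],
                )
            )
        elif r["kind"] == "primer":
            anneal_len = int(r["end"]) - int(r["start"])
            seq = r["sequence"]
            cr = CRPrimer(
                name=r["name"],
                sequence=seq,
                anneal_span=(int(r["start"]), int(r["end"])),
                tm=float(r["left_arm_tm"]),
                tail=seq[: len(seq) - anneal_len],
            )
    return OligoSet("template", sense, splints, cr, constraints)
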