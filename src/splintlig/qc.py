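"""Sequencing QC for randomized-codon libraries.

The pipeline mirrors the standard amplicon funnel for library quality
assessment: merge paired reads, deduplicate exact sequences, keep
full-length reads, anchor them to the template's constant flanks, then
tabulate per-position nucleotide frequencies at the randomized codons and
per-residue amino-acid frequencies, juxtaposed with the ideal-mixing
expectation (each NNK amino acid at codon-count/32).  Stop statistics
report the observed stop-containing fraction next to both the linear
(n·p) and exact (1 − (1−p)^n) expectations.

Reads carrying indels fail the exact length filter or the constant-flank
anchor and are excluded rather than aligned; this matches a
full-length-only analysis and keeps codon coordinates fixed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import codon_math
from .design import LibraryTemplate
from .thermo import revcomp

__all__ = [
    "QCReport",
    "merge_pairs",
    "deduplicate",
    "filter_full_length",
    "frequency_grids",
    "stop_statistics",
    "emit_report",
    "load_report",
    "run_qc",
]

_STOP_IDS = (48, 50, 56)  # TAA, TAG, TGA under base encoding A=0 C=1 G=2 T=3


# ---------------------------------------------------------------------------
# read-level operations

def merge_pairs(
    r1: list[SeqRecord],
    r2: list[SeqRecord],
    min_overlap: int = 20,
    max_mismatch_frac: float = 0.1,
) -> tuple[list[SeqRecord], int]:
    """Merge index-matched mates by best ungapped 3' overlap.

    R2 is reverse-complemented; the longest overlap ≥ ``min_overlap`` with
    mismatch fraction ≤ ``max_mismatch_frac`` wins, and overlap bases take
    the higher-quality call.  Unmergeable pairs are dropped and counted.
    Runtime is O(read length²) per pair — fine for QC-scale inputs.
    """
    if len(r1) != len(r2):
        raise ValueError(f"mate lists differ in length: {len(r1)} vs {len(r2)}")
    merged: list[SeqRecord] = []
    dropped = 0
    for a, b in zip(r1, r2):
        s1 = str(a.seq)
        q1 = np.asarray(a.letter_annotations["phred_quality"])
        s2 = revcomp(str(b.seq))
        q2 = np.asarray(b.letter_annotations["phred_quality"])[::-1]
        a1 = np.frombuffer(s1.encode(), dtype="S1")
        a2 = np.frombuffer(s2.encode(), dtype="S1")
        hit = None
        for o in range(min(len(s1), len(s2)), min_overlap - 1, -1):
            mism = np.count_nonzero(a1[len(s1) - o :] != a2[:o])
            if mism <= max_mismatch_frac * o:
                hit = o
                break
        if hit is None:
            dropped += 1
            continue
        o = hit
        take2 = q2[:o] > q1[len(s1) - o :]
        cons = np.where(take2, a2[:o], a1[len(s1) - o :])
        consq = np.maximum(q1[len(s1) - o :], q2[:o])
        seq = s1[: len(s1) - o] + cons.tobytes().decode() + s2[o:]
        rec = SeqRecord(Seq(seq), id=a.id.removesuffix("/1"), description="")
        rec.letter_annotations["phred_quality"] = (
            list(q1[: len(s1) - o]) + list(consq) + list(q2[o:])
        )
        merged.append(rec)
    return merged, dropped


def deduplicate(reads: list[SeqRecord]) -> tuple[list[SeqRecord], int]:
    """Exact-sequence deduplication, first occurrence kept; returns removed count."""
    seen: set[str] = set()
    unique: list[SeqRecord] = []
    for r in reads:
        s = str(r.seq)
        if s not in seen:
            seen.add(s)
            unique.append(r)
    return unique, len(reads) - len(unique)


def filter_full_length(
    reads: list[SeqRecord], expected_len: int, tolerance: int = 0
) -> list[SeqRecord]:
    """Keep reads whose length is within ``tolerance`` of the expected length."""
    if expected_len < 1:
        raise ValueError("expected_len must be ≥ 1")
    return [r for r in reads if abs(len(r.seq) - expected_len) <= tolerance]


# ---------------------------------------------------------------------------
# frequency grids

@dataclass
class QCReport:
    """Funnel counts plus observed/expected frequency grids.

    ``nt_grid`` is indexed by (ORF codon index, codon position 1–3) with
    A/C/G/T frequency columns; ``nt_avg`` averages each codon position
    class over the randomized codons (with SD), the usual summary plot for
    NNK libraries.  ``aa_table`` is per-residue amino-acid frequencies;
    ``aa_avg`` its mean ± SD across residues next to the ideal-mixing
    expectation.
    """

    stage_counts: dict[str, int] = field(default_factory=dict)
    nt_grid: pd.DataFrame | None = None
    nt_avg: pd.DataFrame | None = None
    aa_table: pd.DataFrame | None = None
    aa_avg: pd.DataFrame | None = None
    stop_containing_fraction: float | None = None
    stop_expected_linear: float | None = None
    stop_expected_exact: float | None = None
    expected_nt: pd.DataFrame | None = None
    expected_aa: pd.DataFrame | None = None

    def validate_funnel(self) -> None:
        counts = list(self.stage_counts.values())
        for a, b in zip(counts, counts[1:]):
            if b > a:
                raise ValueError(f"funnel counts must be non-increasing, got {self.stage_counts}")


def _read_matrix(reads: list[SeqRecord]) -> np.ndarray:
    joined = "".join(str(r.seq) for r in reads)
    L = len(reads[0].seq)
    return np.frombuffer(joined.encode(), dtype="S1").reshape(len(reads), L)


def _base_ids(arr: np.ndarray) -> np.ndarray:
    out = np.full(arr.shape, -1, dtype=np.int8)
    for i, b in enumerate(b"ACGT"):
        out[arr == bytes([b])] = i
    return out


def frequency_grids(
    reads: list[SeqRecord], template: LibraryTemplate, anchor_len: int = 12
) -> QCReport:
    """Per-position nucleotide and amino-acid grids at the randomized codons.

    Reads must be full-length; they are anchored by exact match of the
    template's constant prefix and suffix (``anchor_len`` nt each), so
    codon coordinates transfer directly.  Reads failing the anchor are
    excluded and counted in the funnel.
    """
    if not reads:
        raise ValueError("no reads to analyze")
    L = template.length
    bad = [r.id for r in reads if len(r.seq) != L]
    if bad:
        raise ValueError(f"reads not full-length (expected {L} nt): {bad[:3]}")
    prefix = template.full_sequence[:anchor_len]
    suffix = template.full_sequence[-anchor_len:]
    anchored = [
        r for r in reads if str(r.seq[:anchor_len]) == prefix and str(r.seq[-anchor_len:]) == suffix
    ]
    report = QCReport(stage_counts={"full_length": len(reads), "anchored": len(anchored)})
    if not anchored:
        return report
    arr = _read_matrix(anchored)
    n = arr.shape[0]

    nt_rows = []
    aa_rows = []
    intervals = template.randomized_intervals()
    for (codon_idx, codon), (s, e) in zip(template.randomized_codons, intervals):
        sub = arr[:, s:e]
        for off in range(3):
            col = sub[:, off]
            freqs = [(col == bytes([b])).sum() / n for b in b"ACGT"]
            nt_rows.append(
                {
                    "codon": codon_idx,
                    "position": off + 1,
                    "symbol": codon.letters[off],
                    **dict(zip("ACGT", freqs)),
                }
            )
        ids = _base_ids(sub)
        codon_ids = ids[:, 0] * 16 + ids[:, 1] * 4 + ids[:, 2]
        codon_ids[(ids < 0).any(axis=1)] = -1
        aa_counts: dict[str, int] = {}
        for cid, cnt in zip(*np.unique(codon_ids, return_counts=True)):
            if cid < 0:
                continue
            codon_str = "ACGT"[cid // 16] + "ACGT"[(cid // 4) % 4] + "ACGT"[cid % 4]
            aa = codon_math.translate_codon(codon_str)
            aa_counts[aa] = aa_counts.get(aa, 0) + int(cnt)
        aa_rows.append(
            {"codon": codon_idx, **{aa: c / n for aa, c in sorted(aa_counts.items())}}
        )

    report.nt_grid = pd.DataFrame(nt_rows).set_index(["codon", "position"])
    by_pos = report.nt_grid.reset_index().groupby("position")[list("ACGT")]
    means, sds = by_pos.mean(), by_pos.std(ddof=0)
    report.nt_avg = pd.DataFrame(
        {
            **{f"{b}_mean": means[b] for b in "ACGT"},
            **{f"{b}_sd": sds[b] for b in "ACGT"},
        }
    )

    aa_df = pd.DataFrame(aa_rows).set_index("codon").fillna(0.0)
    aa_df = aa_df[sorted(aa_df.columns)]
    report.aa_table = aa_df
    report.aa_avg = pd.DataFrame({"mean": aa_df.mean(), "sd": aa_df.std(ddof=0)})

    # ideal-mixing expectations for comparison
    exp_nt_rows = []
    exp_aa: dict[str, float] = {}
    for codon_idx, codon in template.randomized_codons:
        for off in range(3):
            exp_nt_rows.append(
                {"codon": codon_idx, "position": off + 1, **codon.mix[off]}
            )
        for aa, f in codon_math.expected_aa_frequencies(codon).items():
            exp_aa[aa] = exp_aa.get(aa, 0.0) + f / len(template.randomized_codons)
    report.expected_nt = pd.DataFrame(exp_nt_rows).set_index(["codon", "position"])
    report.expected_aa = pd.DataFrame({"expected": pd.Series(exp_aa).sort_index()})
    return report


def _internal_stop_mask(reads: list[SeqRecord], template: LibraryTemplate) -> np.ndarray:
    """Boolean per-read mask: any stop at an ORF codon before the terminal one."""
    arr = _read_matrix(reads)
    orf_s, orf_e = template.orf_span
    ids = _base_ids(arr[:, orf_s:orf_e])
    n_codons = (orf_e - orf_s) // 3
    ids = ids.reshape(arr.shape[0], n_codons, 3)
    codon_ids = ids[:, :, 0] * 16 + ids[:, :, 1] * 4 + ids[:, :, 2]
    codon_ids[(ids < 0).any(axis=2)] = -1
    internal = codon_ids[:, : n_codons - 1]  # terminal codon is the designed stop
    return np.isin(internal, _STOP_IDS).any(axis=1)


def stop_statistics(
    reads: list[SeqRecord], template: LibraryTemplate
) -> dict[str, float]:
    """Observed internal-stop fraction vs linear and exact expectations.

    A read counts as stop-containing if any ORF codon except the designed
    terminal one translates to stop.  Expectations come from the stop
    probability of each randomized codon's mix (the framework is
    stop-free by template invariant): linear is the sum of per-codon stop
    probabilities, exact is 1 − Π(1 − p_i).
    """
    if not reads:
        raise ValueError("no reads")
    observed = float(_internal_stop_mask(reads, template).mean())
    p_stops = [
        codon_math.expected_aa_frequencies(codon).get("*", 0.0)
        for _, codon in template.randomized_codons
    ]
    linear = sum(p_stops)
    exact = 1.0 - float(np.prod([1.0 - p for p in p_stops])) if p_stops else 0.0
    return {
        "observed": observed,
        "expected_linear": linear,
        "expected_exact": exact,
    }


# ---------------------------------------------------------------------------
# pipeline driver and serialization

def run_qc(
    template: LibraryTemplate,
    merged: list[SeqRecord] | None = None,
    r1: list[SeqRecord] | None = None,
    r2: list[SeqRecord] | None = None,
    min_overlap: int = 20,
    max_mismatch_frac: float = 0.1,
    length_tolerance: int = 0,
    anchor_len: int = 12,
) -> QCReport:
    """Full funnel: (merge) → deduplicate → length filter → grids → stops."""
    stage: dict[str, int] = {}
    if merged is None:
        if r1 is None or r2 is None:
            raise ValueError("provide either merged reads or both mate lists")
        stage["total_reads"] = len(r1) + len(r2)
        merged, _ = merge_pairs(r1, r2, min_overlap, max_mismatch_frac)
        stage["merged"] = len(merged)
    else:
        stage["total_reads"] = len(merged)
        stage["merged"] = len(merged)
    unique, _ = deduplicate(merged)
    stage["deduplicated"] = len(unique)
    full = filter_full_length(unique, template.length, length_tolerance)
    stage["full_length"] = len(full)
    if not full:
        report = QCReport(stage_counts=stage)
        report.validate_funnel()
        return report
    prefix = template.full_sequence[:anchor_len]
    suffix = template.full_sequence[-anchor_len:]
    anchored = [
        r for r in full if str(r.seq[:anchor_len]) == prefix and str(r.seq[-anchor_len:]) == suffix
    ]
    stage["anchored"] = len(anchored)
    if not anchored:
        report = QCReport(stage_counts=stage)
        report.validate_funnel()
        return report
    report = frequency_grids(anchored, template, anchor_len)
    stats = stop_statistics(anchored, template)
    stop_mask = _internal_stop_mask(anchored, template)
    stop_free = [r for r, bad in zip(anchored, stop_mask) if not bad]
    stage["stop_free"] = len(stop_free)
    stage["unique_full_length_variants"] = len({str(r.seq) for r in stop_free})
    orf = [str(r.seq[template.orf_span[0] : template.orf_span[1]]) for r in stop_free]
    stage["unique_protein_variants"] = len({str(Seq(s).translate()) for s in orf})
    report.stage_counts = stage
    report.stop_containing_fraction = stats["observed"]
    report.stop_expected_linear = stats["expected_linear"]
    report.stop_expected_exact = stats["expected_exact"]
    report.validate_funnel()
    return report


def emit_report(report: QCReport, out_dir: str | Path) -> dict[str, Path]:
    """Write funnel + grids as CSV and a summary JSON; deterministic ordering."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    funnel = pd.DataFrame(
        {"stage": list(report.stage_counts), "count": list(report.stage_counts.values())}
    )
    paths["funnel"] = out / "funnel.csv"
    funnel.to_csv(paths["funnel"], index=False)

    for attr, fname in [
        ("nt_grid", "nt_grid.csv"),
        ("nt_avg", "nt_avg.csv"),
        ("aa_table", "aa_table.csv"),
        ("aa_avg", "aa_avg.csv"),
        ("expected_nt", "expected_nt.csv"),
        ("expected_aa", "expected_aa.csv"),
    ]:
        df = getattr(report, attr)
        p = out / fname
        if df is not None:
            df.to_csv(p)
        else:
            p.write_text("")
        paths[attr] = p

    summary = {
        "stage_counts": report.stage_counts,
        "stop_containing_fraction": report.stop_containing_fraction,
        "stop_expected_linear": report.stop_expected_linear,
        "stop_expected_exact": report.stop_expected_exact,
    }
    paths["summary"] = out / "summary.json"
    # keys stay in insertion order so the funnel reads top-to-bottom
    paths["summary"].write_text(json.dumps(summary, indent=2))
    return paths


def load_report(out_dir: str | Path) -> QCReport:
    """Reload a report written by :func:`emit_report` (round-trip safe)."""
    out = Path(out_dir)
    summary = json.loads((out / "summary.json").read_text())

    def _read(fname: str, index_col) -> pd.DataFrame | None:
        p = out / fname
        if not p.exists() or p.stat().st_size == 0:
            return None
        return pd.read_csv(p, index_col=index_col)

    return QCReport(
        stage_counts=summary["stage_counts"],
        nt_grid=_read("nt_grid.csv", [0, 1]),
        nt_avg=_read("nt_avg.csv", 0),
        aa_table=_read("aa_table.csv", 0),
        aa_avg=_read("aa_avg.csv", 0),
        expected_nt=_read("expected_nt.csv", [0, 1]),
        expected_aa=_read("expected_aa.csv", 0),
        stop_containing_fraction=summary["stop_containing_fraction"],
        stop_expected_linear=summary["stop_expected_linear"],
        stop_expected_exact=summary["stop_expected_exact"],
    )
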