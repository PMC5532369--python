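"""Bisulfite read quantification against a small reference.

Implements toy-scale three-letter (bisulfite-aware) alignment and
per-cytosine methylation calling:

* reads from the converted *top* strand are compared against the
  C->T-collapsed reference; reads from the converted *bottom* strand
  are reverse-complemented and compared against the G->A-collapsed
  reference (a bottom-strand C appears as a forward-strand G);
* at each reference cytosine on the read's assigned strand the raw
  read base makes the call: C (protected) = methylated, T (converted)
  = unmethylated, anything else = no call;
* calls aggregate into a per-position, per-strand methylation table
  with CpG / non-CpG context, from which the summary statistics are
  computed: target-over-median-off-target *fold preference*, squared
  Pearson correlation between two off-target profiles, and
  same-molecule co-methylation frequencies.

The exhaustive seed-and-verify aligner is exact for plasmid-scale
references (tens of kb); it is deliberately not a genome-scale mapper.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from methylguide.scanner import Cytosine, SequenceRecord
from methylguide.simulate import SimulatedRead, parse_read_name

__all__ = [
    "Placement",
    "AlignmentResult",
    "align_bisulfite",
    "call_methylation",
    "fold_preference",
    "compare_profiles",
    "comethylation_matrix",
    "DEFAULT_MIN_COVERAGE",
]

DEFAULT_MIN_COVERAGE = 10

_RC = str.maketrans("ACGTN", "TGCAN")


def _revcomp(s: str) -> str:
    return s.translate(_RC)[::-1]


@dataclass(frozen=True)
class Placement:
    """One uniquely aligned read.

    ``strand`` is '+' for top-strand (C->T space) reads and '-' for
    bottom-strand (G->A space) reads.  ``start`` is the forward
    coordinate of the leftmost reference base; ``fwd_seq`` is the read
    in forward orientation (reverse-complemented for bottom reads).
    """

    read_name: str
    strand: str
    start: int
    mismatches: int
    fwd_seq: str


@dataclass
class AlignmentResult:
    placements: list[Placement]
    n_reads: int
    n_unaligned: int
    n_ambiguous: int


class _SeedIndex:
    """k-mer index over a collapsed reference (with circular extension)."""

    def __init__(self, collapsed: str, L: int, circular: bool, k: int, max_read_len: int):
        self.L = L
        self.k = k
        self.circular = circular
        self.ext = collapsed + (collapsed[: max_read_len - 1] if circular else "")
        index: dict[str, list[int]] = {}
        for i in range(L if circular else max(0, len(collapsed) - k + 1)):
            index.setdefault(self.ext[i : i + k], []).append(i)
        self.index = index

    def candidates(self, query: str, n_seeds: int) -> set[int]:
        """Candidate start positions from evenly spaced seeds."""
        m = len(query)
        seg = m // n_seeds
        out: set[int] = set()
        for si in range(n_seeds):
            off = si * seg
            kmer = query[off : off + self.k]
            if len(kmer) < self.k:
                continue
            for pos in self.index.get(kmer, ()):
                start = pos - off
                if self.circular:
                    out.add(start % self.L)
                elif 0 <= start <= self.L - m:
                    out.add(start)
        return out

    def mismatches(self, query: str, start: int, limit: int) -> int:
        window = self.ext[start : start + len(query)]
        mm = 0
        for a, b in zip(query, window):
            if a != b:
                mm += 1
                if mm > limit:
                    return mm
        return mm


def align_bisulfite(
    reads: list[SimulatedRead],
    record: SequenceRecord,
    max_mismatches: int = 2,
) -> AlignmentResult:
    """Three-letter alignment of bisulfite reads to a small reference.

    Every read is tested, at every candidate offset in both
    orientations, against the C->T-converted top strand and the
    G->A-converted bottom strand of the reference; mismatch counting
    happens in collapsed space, so converted-vs-protected cytosine
    differences are never penalized.  The best placement with at most
    ``max_mismatches`` is reported; reads whose best score is achieved
    at more than one placement are discarded as ambiguous.
    """
    seq = record.seq
    L = len(seq)
    max_len = max((len(r.seq) for r in reads), default=0)
    if max_len == 0:
        return AlignmentResult([], 0, 0, 0)
    k = min(16, max(8, max_len // (max_mismatches + 1)))
    ct_index = _SeedIndex(seq.replace("C", "T"), L, record.circular, k, max_len)
    ga_index = _SeedIndex(seq.replace("G", "A"), L, record.circular, k, max_len)
    n_seeds = max_mismatches + 1

    placements: list[Placement] = []
    n_unaligned = 0
    n_ambiguous = 0
    for read in reads:
        if len(read.seq) < k:
            n_unaligned += 1
            continue
        q_top = read.seq.replace("C", "T")
        rc = _revcomp(read.seq)
        q_bot = rc.replace("G", "A")
        hits: list[tuple[int, str, int, str]] = []  # (mm, strand, start, fwd_seq)
        for start in ct_index.candidates(q_top, n_seeds):
            mm = ct_index.mismatches(q_top, start, max_mismatches)
            if mm <= max_mismatches:
                hits.append((mm, "+", start, read.seq))
        for start in ga_index.candidates(q_bot, n_seeds):
            mm = ga_index.mismatches(q_bot, start, max_mismatches)
            if mm <= max_mismatches:
                hits.append((mm, "-", start, rc))
        if not hits:
            n_unaligned += 1
            continue
        best = min(h[0] for h in hits)
        top_hits = [h for h in hits if h[0] == best]
        if len(top_hits) > 1:
            n_ambiguous += 1
            continue
        mm, strand, start, fwd = top_hits[0]
        placements.append(Placement(read.name, strand, start, mm, fwd))
    return AlignmentResult(placements, len(reads), n_unaligned, n_ambiguous)


def _context(seq: str, pos: int, strand: str, circular: bool) -> str:
    L = len(seq)
    if strand == "+":
        nxt = seq[(pos + 1) % L] if (circular or pos + 1 < L) else ""
        return "CpG" if nxt == "G" else "CHH/CHG"
    prv = seq[(pos - 1) % L] if (circular or pos - 1 >= 0) else ""
    return "CpG" if prv == "C" else "CHH/CHG"


def call_methylation(
    placements: list[Placement],
    record: SequenceRecord,
    targets: set[Cytosine] | None = None,
) -> pd.DataFrame:
    """Aggregate per-cytosine methylation calls into a table.

    Returns one row per reference cytosine (both strands): position,
    strand, context (CpG vs non-CpG), methylated / unmethylated call
    counts, coverage, fraction (NaN when uncovered -- never reported as
    0), and a ``target`` flag for cytosines listed in ``targets``.
    """
    targets = targets or set()
    seq = record.seq
    L = len(seq)
    ref = np.frombuffer(seq.encode(), dtype=np.uint8)
    is_c = ref == ord("C")
    is_g = ref == ord("G")
    meth = {"+": np.zeros(L, dtype=np.int64), "-": np.zeros(L, dtype=np.int64)}
    unmeth = {"+": np.zeros(L, dtype=np.int64), "-": np.zeros(L, dtype=np.int64)}

    for pl in placements:
        m = len(pl.fwd_seq)
        idx = np.arange(pl.start, pl.start + m) % L
        readarr = np.frombuffer(pl.fwd_seq.encode(), dtype=np.uint8)
        if pl.strand == "+":
            sites = is_c[idx]
            calls_m = readarr == ord("C")
            calls_u = readarr == ord("T")
        else:
            sites = is_g[idx]
            calls_m = readarr == ord("G")
            calls_u = readarr == ord("A")
        np.add.at(meth[pl.strand], idx[sites & calls_m], 1)
        np.add.at(unmeth[pl.strand], idx[sites & calls_u], 1)

    rows = []
    for strand, mask in (("+", is_c), ("-", is_g)):
        for pos in np.nonzero(mask)[0]:
            pos = int(pos)
            mc = int(meth[strand][pos])
            uc = int(unmeth[strand][pos])
            cov = mc + uc
            rows.append(
                {
                    "position": pos,
                    "strand": strand,
                    "context": _context(seq, pos, strand, record.circular),
                    "methylated": mc,
                    "unmethylated": uc,
                    "coverage": cov,
                    "fraction": mc / cov if cov > 0 else np.nan,
                    "target": Cytosine(pos, strand) in targets,
                }
            )
    df = pd.DataFrame(rows, columns=[
        "position", "strand", "context", "methylated", "unmethylated",
        "coverage", "fraction", "target",
    ])
    return df.sort_values(["position", "strand"]).reset_index(drop=True)


def fold_preference(
    table: pd.DataFrame,
    target_positions: set[Cytosine],
    pseudo_floor: float | None = None,
    min_coverage: int = DEFAULT_MIN_COVERAGE,
) -> float:
    """Target-over-median-off-target fold preference.

    The target level is the maximum observed fraction over the listed
    target cytosines; the denominator is the median fraction across
    covered off-target CpG cytosines, floored at ``pseudo_floor``
    (default: one half call over the total number of off-target calls)
    so finite samples with an all-zero background stay finite.
    """
    covered = table[table["coverage"] >= min_coverage]
    is_target = covered.apply(lambda r: Cytosine(int(r["position"]), r["strand"]) in target_positions, axis=1)
    targets = covered[is_target]
    off = covered[~is_target & (covered["context"] == "CpG")]
    if targets.empty:
        raise ValueError("no covered target cytosine")
    if off.empty:
        raise ValueError("no covered off-target CpG cytosine")
    target_level = float(targets["fraction"].max())
    median_off = float(off["fraction"].median())
    if pseudo_floor is None:
        total_calls = int(off["coverage"].sum())
        pseudo_floor = 1.0 / (2.0 * total_calls)
    return target_level / max(median_off, pseudo_floor)


def compare_profiles(
    a: pd.DataFrame,
    b: pd.DataFrame,
    positions: list[Cytosine] | None = None,
    min_coverage: int = DEFAULT_MIN_COVERAGE,
) -> float:
    """Squared Pearson correlation of methylation fractions.

    Joins the two tables on (position, strand), restricted to
    ``positions`` when given and to sites covered in both; requires at
    least 3 shared sites.  Returns NaN when either profile has zero
    variance over the shared sites.
    """
    cols = ["position", "strand", "fraction", "coverage"]
    merged = a[cols].merge(b[cols], on=["position", "strand"], suffixes=("_a", "_b"))
    merged = merged[(merged["coverage_a"] >= min_coverage) & (merged["coverage_b"] >= min_coverage)]
    if positions is not None:
        keys = {(c.pos, c.strand) for c in positions}
        keep = merged.apply(lambda r: (int(r["position"]), r["strand"]) in keys, axis=1)
        merged = merged[keep]
    if len(merged) < 3:
        raise ValueError(f"need >= 3 shared covered positions, got {len(merged)}")
    x = merged["fraction_a"].to_numpy(dtype=float)
    y = merged["fraction_b"].to_numpy(dtype=float)
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        return float("nan")
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def comethylation_matrix(
    placements: list[Placement],
    record: SequenceRecord,
    positions: list[Cytosine],
) -> pd.DataFrame:
    """Pairwise same-molecule co-methylation frequencies.

    Placements are grouped by molecule via the simulator's read-name
    provenance.  For each ordered position pair (i, j) the entry is the
    fraction of molecules methylated at both sites among molecules
    informative for both; the diagonal is the per-molecule marginal.
    Pairs with no co-covering molecule are NaN.
    """
    seq = record.seq
    L = len(seq)
    pos_set = list(positions)
    # molecule id -> {Cytosine: bool methylated}
    calls: dict[int, dict[Cytosine, bool]] = {}
    for pl in placements:
        mol_id, _, _ = parse_read_name(pl.read_name)
        span = {( (pl.start + j) % L ): j for j in range(len(pl.fwd_seq))}
        for cyt in pos_set:
            if cyt.strand != pl.strand or cyt.pos not in span:
                continue
            base = pl.fwd_seq[span[cyt.pos]]
            ref_base = "C" if cyt.strand == "+" else "G"
            conv_base = "T" if cyt.strand == "+" else "A"
            if base == ref_base:
                calls.setdefault(mol_id, {})[cyt] = True
            elif base == conv_base:
                calls.setdefault(mol_id, {}).setdefault(cyt, False)
    n = len(pos_set)
    mat = np.full((n, n), np.nan)
    for i, ci in enumerate(pos_set):
        for j, cj in enumerate(pos_set):
            both = 0
            informative = 0
            for mol_calls in calls.values():
                if ci in mol_calls and cj in mol_calls:
                    informative += 1
                    if mol_calls[ci] and mol_calls[cj]:
                        both += 1
            if informative:
                mat[i, j] = both / informative
    labels = [f"{c.pos}{c.strand}" for c in pos_set]
    return pd.DataFrame(mat, index=labels, columns=labels)
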