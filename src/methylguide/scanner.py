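"""Enumeration of PAMs, protospacers and CpG sites on small sequences.

The scanner works on plasmid- or promoter-scale records (FASTA input,
linear or circular) and produces candidate :class:`TargetSite` objects:
an S. pyogenes NGG PAM with a full-length 20-nt protospacer, paired
with a CpG site at a given gap downstream of the PAM.

Coordinate conventions
----------------------
All coordinates are 0-based half-open on the forward strand of the
input record.  The *gap* is the number of nucleotides strictly between
the 3'-terminal base of the PAM and the cis-strand cytosine of the CpG,
counted along the cis strand moving away from the protospacer.  A CpG
on the protospacer side of the PAM (or overlapping the 23-bp
protospacer+PAM footprint) has no defined gap for that PAM.

For a ``+``-strand PAM the cis strand is the forward strand, so the
cis cytosine is the C of the forward ``CG``.  For a ``-``-strand PAM
the cis strand is the reverse strand and the cis cytosine is the
reverse-strand C, i.e. the base paired with the forward-strand G of the
CpG.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, NamedTuple

from Bio import SeqIO
from Bio.Seq import Seq

__all__ = [
    "SequenceRecord",
    "PamSite",
    "CpgSite",
    "Cytosine",
    "TargetSite",
    "find_pams",
    "find_cpgs",
    "gap_length",
    "enumerate_target_sites",
    "read_fasta",
]

PROTOSPACER_LEN = 20
PAM_LEN = 3
FOOTPRINT_LEN = PROTOSPACER_LEN + PAM_LEN  # 23 bp occupied by dCas9

_VALID = set("ACGTN")


@dataclass(frozen=True)
class SequenceRecord:
    """A DNA sequence with an identifier and a topology.

    The sequence is normalized to uppercase on construction and must be
    over the alphabet {A, C, G, T, N}.
    """

    id: str
    seq: str
    topology: str = "linear"

    def __post_init__(self) -> None:
        object.__setattr__(self, "seq", self.seq.upper())
        bad = set(self.seq) - _VALID
        if bad:
            raise ValueError(f"invalid bases in record {self.id!r}: {sorted(bad)}")
        if self.topology not in ("linear", "circular"):
            raise ValueError(f"topology must be 'linear' or 'circular', got {self.topology!r}")

    def __len__(self) -> int:
        return len(self.seq)

    @property
    def circular(self) -> bool:
        return self.topology == "circular"

    def fetch(self, start: int, length: int) -> str:
        """Subsequence of ``length`` bases from ``start``, wrapping if circular."""
        L = len(self.seq)
        if self.circular:
            start %= L
            if start + length <= L:
                return self.seq[start : start + length]
            return self.seq[start:] + self.seq[: (start + length) % L]
        if start < 0 or start + length > L:
            raise IndexError(f"[{start}, {start + length}) outside linear record of length {L}")
        return self.seq[start : start + length]

    def reverse_complement(self) -> "SequenceRecord":
        return SequenceRecord(self.id, str(Seq(self.seq).reverse_complement()), self.topology)


def read_fasta(path, circular: bool = False) -> list[SequenceRecord]:
    """Load a (multi-)FASTA file into :class:`SequenceRecord` objects."""
    topology = "circular" if circular else "linear"
    return [SequenceRecord(rec.id, str(rec.seq), topology) for rec in SeqIO.parse(path, "fasta")]


@dataclass(frozen=True)
class PamSite:
    """An NGG PAM with an available full-length protospacer.

    ``pam_start`` is the forward coordinate of the leftmost base of the
    3-nt PAM footprint on the forward strand (for a ``-`` strand PAM
    this is the position of the first C of the forward-strand ``CCN``).
    Intervals may extend past the record length for circular records;
    positions are then taken modulo the length.
    """

    record_id: str
    strand: str  # "+" or "-"
    pam_start: int

    @property
    def pam_interval(self) -> tuple[int, int]:
        return (self.pam_start, self.pam_start + PAM_LEN)

    @property
    def protospacer_interval(self) -> tuple[int, int]:
        if self.strand == "+":
            return (self.pam_start - PROTOSPACER_LEN, self.pam_start)
        return (self.pam_start + PAM_LEN, self.pam_start + PAM_LEN + PROTOSPACER_LEN)

    @property
    def footprint(self) -> tuple[int, int]:
        """Forward-coordinate interval of protospacer + PAM (23 bp)."""
        if self.strand == "+":
            return (self.pam_start - PROTOSPACER_LEN, self.pam_start + PAM_LEN)
        return (self.pam_start, self.pam_start + FOOTPRINT_LEN)

    def pam_seq(self, record: SequenceRecord) -> str:
        s = record.fetch(self.pam_start, PAM_LEN)
        return s if self.strand == "+" else str(Seq(s).reverse_complement())

    def protospacer_seq(self, record: SequenceRecord) -> str:
        start, _ = self.protospacer_interval
        s = record.fetch(start, PROTOSPACER_LEN)
        return s if self.strand == "+" else str(Seq(s).reverse_complement())


@dataclass(frozen=True)
class CpgSite:
    """A CpG dinucleotide; palindromic, one methylatable C per strand.

    ``c_forward_pos`` is the forward-strand C; ``c_reverse_pos`` is the
    forward coordinate of the G, whose paired base is the reverse-strand
    C.  For a CpG spanning the origin of a circular record the two
    positions wrap (``c_reverse_pos == 0``).
    """

    record_id: str
    c_forward_pos: int
    c_reverse_pos: int


class Cytosine(NamedTuple):
    """One of the two cytosines of a CpG: forward position + strand."""

    pos: int
    strand: str


@dataclass(frozen=True)
class TargetSite:
    """A PAM/protospacer candidate paired with a CpG at a given gap."""

    pam: PamSite
    cpg: CpgSite
    gap: int
    cis_cytosine: Cytosine
    trans_cytosine: Cytosine


def _pam_matches(triplet: str) -> bool:
    # strict NGG: wildcard position must be a real base, Gs literal
    return len(triplet) == 3 and triplet[0] in "ACGT" and triplet[1] == "G" and triplet[2] == "G"


def find_pams(record: SequenceRecord) -> list[PamSite]:
    """All NGG PAMs on both strands with a full 20-nt protospacer.

    Returned sorted by forward coordinate of the PAM footprint then by
    strand.  ``N`` bases never satisfy any PAM position.
    """
    L = len(record)
    out: list[PamSite] = []
    if L == 0:
        return out
    starts = range(L) if record.circular else range(L - PAM_LEN + 1)
    for s in starts:
        trip = record.fetch(s, PAM_LEN) if record.circular else record.seq[s : s + PAM_LEN]
        # + strand: forward reads NGG; protospacer is the 20 nt 5' (left)
        if _pam_matches(trip):
            if record.circular or s >= PROTOSPACER_LEN:
                out.append(PamSite(record.id, "+", s))
        # - strand: reverse strand reads NGG <=> forward reads CCN;
        # protospacer is the 20 nt to the right in forward coordinates
        if trip[0] == "C" and trip[1] == "C" and trip[2] in "ACGT":
            if record.circular or s + FOOTPRINT_LEN <= L:
                out.append(PamSite(record.id, "-", s))
    out.sort(key=lambda p: (p.pam_start, p.strand))
    return out


def find_cpgs(record: SequenceRecord) -> list[CpgSite]:
    """All CG dinucleotides, sorted by forward position.

    Circular records also report a CpG spanning the origin when the
    last base is C and the first is G.
    """
    out = [
        CpgSite(record.id, i, i + 1)
        for i in range(len(record) - 1)
        if record.seq[i : i + 2] == "CG"
    ]
    if record.circular and len(record) >= 2 and record.seq[-1] == "C" and record.seq[0] == "G":
        out.append(CpgSite(record.id, len(record) - 1, 0))
    return out


def _in_interval_mod(pos: int, interval: tuple[int, int], L: int, circular: bool) -> bool:
    start, end = interval
    if not circular:
        return start <= pos < end
    span = end - start
    return (pos - start) % L < span


def gap_length(pam: PamSite, cpg: CpgSite, record: SequenceRecord) -> int | None:
    """Gap (bp) between the PAM 3' end and the cis-strand C of the CpG.

    Counts the bases strictly between the PAM's 3'-terminal base and
    the cis-strand cytosine, moving along the cis strand away from the
    protospacer.  Returns ``None`` when the CpG lies on the protospacer
    side of the PAM or overlaps the 23-bp protospacer+PAM footprint.
    """
    if pam.record_id != record.id or cpg.record_id != record.id:
        raise ValueError("PAM and CpG must come from the queried record")
    L = len(record)
    if pam.strand == "+":
        cis_c = cpg.c_forward_pos
        raw = cis_c - (pam.pam_start + PAM_LEN)
    else:
        cis_c = cpg.c_reverse_pos
        raw = (pam.pam_start - 1) - cis_c
    if record.circular:
        raw %= L
        if _in_interval_mod(cis_c, pam.footprint, L, True):
            return None
        return raw
    if raw < 0:
        return None
    return raw


def enumerate_target_sites(
    record: SequenceRecord, min_gap: int, max_gap: int
) -> list[TargetSite]:
    """All PAM x CpG pairs whose gap falls in ``[min_gap, max_gap]``.

    Each returned site records which cytosine of the CpG lies on the
    cis strand (the PAM/protospacer strand) and which on the trans
    strand.
    """
    if min_gap > max_gap:
        raise ValueError(f"min_gap {min_gap} > max_gap {max_gap}")
    sites: list[TargetSite] = []
    cpgs = find_cpgs(record)
    for pam in find_pams(record):
        for cpg in cpgs:
            gap = gap_length(pam, cpg, record)
            if gap is None or not min_gap <= gap <= max_gap:
                continue
            if pam.strand == "+":
                cis = Cytosine(cpg.c_forward_pos, "+")
                trans = Cytosine(cpg.c_reverse_pos, "-")
            else:
                cis = Cytosine(cpg.c_reverse_pos, "-")
                trans = Cytosine(cpg.c_forward_pos, "+")
            sites.append(TargetSite(pam, cpg, gap, cis, trans))
    sites.sort(key=lambda t: (t.pam.pam_start, t.pam.strand, t.cpg.c_forward_pos))
    return sites


def target_sites_to_rows(sites: list[TargetSite], record: SequenceRecord) -> Iterator[dict]:
    """Flatten target sites into report rows (1-based positions in `pos_1based`)."""
    for t in sites:
        start, end = t.pam.pam_interval
        yield {
            "record": record.id,
            "pam_start": start % len(record) if record.circular else start,
            "pam_end": end,
            "strand": t.pam.strand,
            "protospacer_seq": t.pam.protospacer_seq(record),
            "cpg_forward_pos": t.cpg.c_forward_pos,
            "cpg_pos_1based": t.cpg.c_forward_pos + 1,
            "gap": t.gap,
            "cis_cytosine_strand": t.cis_cytosine.strand,
        }
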