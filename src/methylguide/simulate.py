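"""Synthetic bisulfite-experiment generator.

Builds plasmid-like references that emulate the structure of a
two-plasmid E. coli methylation reporter: one or two planted target
CpG sites, each embedded in an FspI recognition site (TGCGCA) at a
prescribed gap downstream of a planted NGG PAM, plus a few hundred
background (off-target) CpG sites.  On top of the reference it
simulates:

* per-molecule methylation states (independent Bernoulli per cytosine
  per strand, with target probabilities set explicitly and off-target
  probabilities drawn from a low-mean Beta background, optionally
  inflated near the target to emulate topological proximity);
* bisulfite conversion of both strands (unmethylated C -> T,
  methylated C protected);
* single-end short-read sampling with uniform starts and optional
  substitution errors, written as FASTQ with ground-truth provenance
  encoded in read names;
* the FspI restriction-protection assay (methylation of the embedded
  CpG on either strand protects the site from cutting).

Everything is seeded and deterministic so downstream quantification
can be validated against known truth.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field

import numpy as np

from methylguide.scanner import Cytosine, SequenceRecord

__all__ = [
    "MethylationSpec",
    "MoleculeState",
    "ReferenceBundle",
    "build_reference",
    "sample_molecules",
    "bisulfite_convert",
    "sample_reads",
    "digest_fsp1",
    "write_fastq",
    "parse_read_name",
    "DigestResult",
]

FSPI_SITE = "TGCGCA"  # palindromic; CpG at internal offsets 2-3; blunt cut after offset 2

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class MethylationSpec:
    """Ground-truth per-cytosine, per-strand methylation probabilities.

    ``probabilities`` maps :class:`Cytosine` (forward position +
    strand) to a fraction in [0, 1].  Cytosines absent from the map are
    never methylated.  ``target_labels`` marks the subset of positions
    belonging to planted target CpGs.
    """

    record: SequenceRecord
    probabilities: dict[Cytosine, float]
    target_labels: set[Cytosine] = field(default_factory=set)
    conversion_efficiency: float = 1.0

    def __post_init__(self) -> None:
        for cyt, p in self.probabilities.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} at {cyt} outside [0, 1]")
            base = self.record.seq[cyt.pos]
            expected = "C" if cyt.strand == "+" else "G"
            if base != expected:
                raise ValueError(f"{cyt} is not a cytosine on its strand (forward base {base})")
        if not 0.0 <= self.conversion_efficiency <= 1.0:
            raise ValueError("conversion_efficiency must be in [0, 1]")

    @property
    def sites(self) -> list[Cytosine]:
        return sorted(self.probabilities, key=lambda c: (c.pos, c.strand))


@dataclass(frozen=True)
class MoleculeState:
    """Binary methylation status of one DNA molecule at the spec's sites."""

    molecule_id: int
    methylated: frozenset[Cytosine]

    def is_methylated(self, cyt: Cytosine) -> bool:
        return cyt in self.methylated


@dataclass(frozen=True)
class PlantedTarget:
    """Coordinates of one planted PAM + FspI-embedded target CpG."""

    gap: int
    pam_start: int           # forward coord of planted "NGG" (on + strand)
    fspi_start: int          # forward coord of the TGCGCA site
    cpg_forward_pos: int     # forward-strand C of the embedded CpG
    cis_cytosine: Cytosine   # + strand (PAM is planted on +)
    trans_cytosine: Cytosine


@dataclass
class ReferenceBundle:
    """A synthetic reference plus everything planted in it."""

    record: SequenceRecord
    spec: MethylationSpec
    targets: list[PlantedTarget]
    offtarget_cpg_positions: list[int]   # forward C positions of background CpGs
    fspi_sites: list[int]                # starts of all planted TGCGCA sites


def _random_filler(rng: np.random.Generator, n: int, prev: str) -> str:
    """CG-free random sequence of length n given the preceding base."""
    out = []
    p = prev
    for _ in range(n):
        choices = "ACGT" if p != "C" else "ACT"  # never emit G after C
        b = choices[rng.integers(len(choices))]
        out.append(b)
        p = b
    return "".join(out)


def build_reference(
    n_offtarget_cpgs: int,
    target_gaps: list[int] | None = None,
    topology: str = "circular",
    seed: int = 0,
    offtarget_mean: float = 0.005,
    offtarget_concentration: float = 100.0,
    target_p_cis: float = 0.1,
    target_p_trans: float = 0.344,
    proximity_window: int = 0,
    proximity_factor: float = 1.0,
    spacer: int = 6,
    record_id: str = "synthetic_reporter",
) -> ReferenceBundle:
    """Construct a reporter-plasmid-like reference and its methylation spec.

    Plants, for each requested gap, a block ``protospacer(20) + TGG PAM
    + filler + TGCGCA`` so that the FspI-embedded CpG sits exactly
    ``gap`` bp downstream of the PAM on the cis (+) strand; scatters
    ``n_offtarget_cpgs`` additional CpG dinucleotides through CG-free
    filler; and guarantees at least two FspI-embedded CpGs total (extra
    unmethylated-background FspI sites are planted if needed).

    Off-target cytosines (both strands of every background CpG, and of
    non-target FspI CpGs) get probabilities drawn from a Beta
    distribution with the given mean; with ``proximity_window > 0``,
    off-target sites within that many bp of a target are inflated by
    ``proximity_factor`` (clipped to 1) to emulate topological
    proximity of the plasmid to the bound dCas9.

    Target cytosines get ``target_p_cis`` / ``target_p_trans``.
    """
    if n_offtarget_cpgs < 0:
        raise ValueError("n_offtarget_cpgs must be >= 0")
    target_gaps = list(target_gaps or [])
    for g in target_gaps:
        if g < 2:
            raise ValueError(f"planted target gap must be >= 2 (FspI prefix needs room), got {g}")
    rng = np.random.default_rng(seed)

    parts: list[str] = []
    pos = 0

    def emit(s: str) -> int:
        nonlocal pos
        start = pos
        parts.append(s)
        pos += len(s)
        return start

    def prev_base() -> str:
        for part in reversed(parts):
            if part:
                return part[-1]
        return "A"

    def emit_filler(n: int) -> None:
        emit(_random_filler(rng, n, prev_base()))

    targets: list[PlantedTarget] = []
    fspi_sites: list[int] = []

    emit_filler(spacer)
    for gap in target_gaps:
        proto = _random_filler(rng, 20, prev_base())
        emit(proto)
        pam_start = emit("TGG")
        pam_end = pam_start + 3
        # CpG of TGCGCA is at site offsets 2-3; cis C must land at pam_end + gap
        emit_filler(gap - 2)
        fspi_start = emit(FSPI_SITE)
        assert fspi_start == pam_end + gap - 2
        c_fwd = fspi_start + 2
        targets.append(
            PlantedTarget(
                gap=gap,
                pam_start=pam_start,
                fspi_start=fspi_start,
                cpg_forward_pos=c_fwd,
                cis_cytosine=Cytosine(c_fwd, "+"),
                trans_cytosine=Cytosine(c_fwd + 1, "-"),
            )
        )
        fspi_sites.append(fspi_start)
        emit_filler(spacer)

    # ensure >= 2 FspI-embedded CpGs in total
    extra_fspi = max(0, 2 - len(fspi_sites))
    extra_fspi_cpgs: list[int] = []
    for _ in range(extra_fspi):
        emit_filler(spacer)
        s = emit(FSPI_SITE)
        fspi_sites.append(s)
        extra_fspi_cpgs.append(s + 2)
        emit_filler(spacer)

    offtarget_positions: list[int] = []
    for _ in range(n_offtarget_cpgs):
        emit_filler(spacer)
        s = emit("ACG")  # leading A isolates the CpG from the previous block
        offtarget_positions.append(s + 1)
    emit_filler(spacer)

    seq = "".join(parts)
    if topology == "circular" and seq and seq[-1] == "C" and seq[0] == "G":
        seq = seq[:-1] + "A"  # no accidental origin-spanning CpG
    record = SequenceRecord(record_id, seq, topology)

    probabilities: dict[Cytosine, float] = {}
    target_labels: set[Cytosine] = set()
    for t in targets:
        probabilities[t.cis_cytosine] = float(target_p_cis)
        probabilities[t.trans_cytosine] = float(target_p_trans)
        target_labels.update((t.cis_cytosine, t.trans_cytosine))

    mean = float(offtarget_mean)
    conc = float(offtarget_concentration)
    a, b = mean * conc, (1.0 - mean) * conc
    background = offtarget_positions + extra_fspi_cpgs
    target_fwd = [t.cpg_forward_pos for t in targets]
    for c_fwd in background:
        for cyt in (Cytosine(c_fwd, "+"), Cytosine(c_fwd + 1, "-")):
            p = float(rng.beta(a, b))
            if proximity_window > 0 and target_fwd:
                d = min(abs(c_fwd - tf) for tf in target_fwd)
                if record.circular:
                    d = min(d, len(record) - d)
                if d <= proximity_window:
                    p = min(1.0, p * proximity_factor)
            probabilities[cyt] = p

    spec = MethylationSpec(record, probabilities, target_labels)
    return ReferenceBundle(record, spec, targets, offtarget_positions, sorted(fspi_sites))


def sample_molecules(spec: MethylationSpec, n_molecules: int, seed: int = 0) -> list[MoleculeState]:
    """Draw per-molecule methylation states, one Bernoulli per site per molecule."""
    if n_molecules < 1:
        raise ValueError("n_molecules must be >= 1")
    rng = np.random.default_rng(seed)
    sites = spec.sites
    probs = np.array([spec.probabilities[c] for c in sites])
    draws = rng.random((n_molecules, len(sites))) < probs
    return [
        MoleculeState(i, frozenset(c for c, hit in zip(sites, row) if hit))
        for i, row in enumerate(draws)
    ]


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_TOP_CONVERT = str.maketrans("C", "T")            # unmethylated C -> T on the top strand
_BOTTOM_CONVERT = str.maketrans("ACGTN", "TGTAN")  # complement, then bottom-strand C -> T


def bisulfite_convert(
    molecule: MoleculeState,
    spec: MethylationSpec,
    rng: np.random.Generator | None = None,
) -> tuple[str, str]:
    """Bisulfite-convert one molecule; returns (top, bottom) strand sequences.

    The top strand is in forward orientation; the bottom strand is the
    reverse complement of the reference, 5'->3'.  Every unmethylated
    cytosine converts to T with probability ``conversion_efficiency``
    (1.0 by default, i.e. deterministically); methylated cytosines are
    protected.  Non-CpG cytosines carry no methylation in the spec and
    convert like any unmethylated C.
    """
    seq = spec.record.seq
    eff = spec.conversion_efficiency
    if 0.0 < eff < 1.0 and rng is None:
        rng = np.random.default_rng(0)

    def survives() -> bool:
        if eff >= 1.0:
            return False
        if eff <= 0.0:
            return True
        return float(rng.random()) >= eff

    # fully converted templates, then restore protected (methylated) cytosines
    top = list(seq.translate(_TOP_CONVERT))
    bottom_fwd = list(seq.translate(_BOTTOM_CONVERT))  # complement + C->T, forward coords
    if eff < 1.0:
        for i, b in enumerate(seq):
            if b == "C" and not molecule.is_methylated(Cytosine(i, "+")) and survives():
                top[i] = "C"
            if b == "G" and not molecule.is_methylated(Cytosine(i, "-")) and survives():
                bottom_fwd[i] = "C"
    for cyt in molecule.methylated:
        if cyt.strand == "+":
            top[cyt.pos] = "C"
        else:
            bottom_fwd[cyt.pos] = "C"
    bottom = "".join(reversed(bottom_fwd))
    return "".join(top), bottom


def _format_read_name(molecule_id: int, strand: str, fwd_start: int) -> str:
    return f"mol{molecule_id}|{strand}|{fwd_start}"


def parse_read_name(name: str) -> tuple[int, str, int]:
    """Recover (molecule_id, strand, forward 5'-end coordinate) from a read name."""
    mol, strand, start = name.split("|")
    return int(mol.removeprefix("mol")), strand, int(start)


@dataclass(frozen=True)
class SimulatedRead:
    name: str
    seq: str


def sample_reads(
    molecules: list[MoleculeState],
    spec: MethylationSpec,
    read_length: int = 75,
    depth: float = 100.0,
    error_rate: float = 0.0,
    seed: int = 0,
) -> list[SimulatedRead]:
    """Sample single-end reads from bisulfite-converted molecules.

    Reads start uniformly along the reference (wrapping on circular
    records), come from the top or bottom converted strand with equal
    probability, and carry substitution errors at ``error_rate``.  Read
    names encode molecule id, strand (+ for top, - for bottom) and the
    forward coordinate of the read's leftmost reference base, so every
    read's true origin is recoverable.
    """
    record = spec.record
    L = len(record)
    if read_length > L:
        raise ValueError(f"read_length {read_length} exceeds reference length {L}")
    rng = np.random.default_rng(seed)
    n_reads = int(round(depth * L / read_length))

    converted = [bisulfite_convert(m, spec, rng=rng) for m in molecules]

    mol_idx = rng.integers(len(molecules), size=n_reads)
    strand_is_top = rng.random(n_reads) < 0.5
    if record.circular:
        starts = rng.integers(L, size=n_reads)
    else:
        starts = rng.integers(L - read_length + 1, size=n_reads)

    reads: list[SimulatedRead] = []
    for mi, is_top, s in zip(mol_idx, strand_is_top, starts):
        top, bottom = converted[mi]
        s = int(s)
        if is_top:
            strand = "+"
            fwd_start = s
            if s + read_length <= L:
                seq = top[s : s + read_length]
            else:
                seq = top[s:] + top[: (s + read_length) % L]
        else:
            strand = "-"
            # bottom-strand coordinate s corresponds to forward 3'->5'; report
            # the forward coordinate of the read's leftmost reference base
            if s + read_length <= L:
                seq = bottom[s : s + read_length]
            else:
                seq = bottom[s:] + bottom[: (s + read_length) % L]
            fwd_start = (L - s - read_length) % L if record.circular else L - s - read_length
        if error_rate > 0.0:
            arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
            hits = np.nonzero(rng.random(read_length) < error_rate)[0]
            for h in hits:
                current = arr[h]
                choices = _BASES[_BASES != current]
                arr[h] = choices[rng.integers(len(choices))]
            seq = arr.tobytes().decode()
        reads.append(SimulatedRead(_format_read_name(int(mi), strand, int(fwd_start)), seq))
    return reads


def write_fastq(reads: list[SimulatedRead], path) -> None:
    """Write simulated reads as FASTQ (constant quality)."""
    if hasattr(path, "write"):
        handle = path
        close = False
    else:
        handle = open(path, "w")
        close = True
    try:
        for r in reads:
            handle.write(f"@{r.name}\n{r.seq}\n+\n{'I' * len(r.seq)}\n")
    finally:
        if close:
            handle.close()


def read_fastq(path) -> list[SimulatedRead]:
    """Load reads (name, sequence) from a FASTQ file."""
    reads = []
    if hasattr(path, "read"):
        lines = path.read().splitlines()
    else:
        with open(path) as fh:
            lines = fh.read().splitlines()
    for i in range(0, len(lines) - 3, 4):
        reads.append(SimulatedRead(lines[i][1:].split()[0], lines[i + 1]))
    return reads


@dataclass(frozen=True)
class DigestResult:
    """Outcome of the simulated FspI protection assay."""

    fragment_lengths: list[tuple[int, ...]]  # per molecule
    protected_fraction: float
    n_sites: int


def digest_fsp1(
    molecules: list[MoleculeState], spec: MethylationSpec
) -> DigestResult:
    """Simulate FspI digestion of each molecule.

    Every TGCGCA occurrence is cut (blunt, between site offsets 2 and
    3) unless the embedded CpG is methylated on either strand.  Returns
    per-molecule fragment-length tuples and the overall fraction of
    site-copies protected.  Fragment lengths on a linear molecule sum
    to the molecule length; an uncut circular molecule yields a single
    full-length fragment.
    """
    record = spec.record
    seq = record.seq
    L = len(seq)
    site_starts = []
    search = seq + (seq[: len(FSPI_SITE) - 1] if record.circular else "")
    i = search.find(FSPI_SITE)
    while i != -1:
        site_starts.append(i % L)
        i = search.find(FSPI_SITE, i + 1)

    fragments: list[tuple[int, ...]] = []
    protected = 0
    total = 0
    for mol in molecules:
        cuts = []
        for s in site_starts:
            c_fwd = (s + 2) % L
            g_fwd = (s + 3) % L
            meth = mol.is_methylated(Cytosine(c_fwd, "+")) or mol.is_methylated(Cytosine(g_fwd, "-"))
            total += 1
            if meth:
                protected += 1
            else:
                cuts.append((s + 3) % L)  # blunt cut between offsets 2 and 3
        cuts.sort()
        if record.circular:
            if not cuts:
                frags = (L,)
            else:
                frags = tuple(
                    (cuts[(k + 1) % len(cuts)] - cuts[k]) % L or L
                    for k in range(len(cuts))
                )
                if len(cuts) == 1:
                    frags = (L,)
        else:
            bounds = [0] + cuts + [L]
            frags = tuple(b - a for a, b in zip(bounds, bounds[1:]) if b > a)
        fragments.append(frags)
    frac = protected / total if total else float("nan")
    return DigestResult(fragments, frac, len(site_starts))
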