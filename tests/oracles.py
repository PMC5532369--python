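"""Independent brute-force oracles used by the test suite.

Deliberately naive implementations, kept separate from the package so
they exercise none of its code paths.
"""

from __future__ import annotations

_RC = str.maketrans("ACGTN", "TGCAN")


def revcomp(s: str) -> str:
    return s.translate(_RC)[::-1]


def brute_force_pams(seq: str, circular: bool) -> set[tuple[str, int]]:
    """All (strand, pam_start) with NGG on the strand and a 20-nt protospacer."""
    L = len(seq)
    out = set()
    ext = seq + seq if circular else seq
    for s in range(L if circular else L - 2):
        trip = ext[s : s + 3]
        if len(trip) < 3:
            continue
        if trip[0] in "ACGT" and trip[1] == "G" and trip[2] == "G":
            if circular or s >= 20:
                out.add(("+", s))
        if trip[0] == "C" and trip[1] == "C" and trip[2] in "ACGT":
            if circular or s + 23 <= L:
                out.add(("-", s))
    return out


def brute_force_cpgs(seq: str, circular: bool) -> set[int]:
    """Forward positions of the C of every CG dinucleotide."""
    out = {i for i in range(len(seq) - 1) if seq[i : i + 2] == "CG"}
    if circular and len(seq) >= 2 and seq[-1] == "C" and seq[0] == "G":
        out.add(len(seq) - 1)
    return out


def brute_force_gap(strand: str, pam_start: int, c_fwd: int, L: int, circular: bool):
    """Gap by explicit base walking from the PAM 3' end along the cis strand.

    Returns None if the walk would enter (or start past) the 23-bp
    protospacer+PAM footprint before reaching the cis-strand C.
    """
    if strand == "+":
        cursor = pam_start + 3  # first base past the PAM 3' end
        cis_c = c_fwd
        step = 1
        footprint = {(pam_start - 20 + i) % L if circular else pam_start - 20 + i for i in range(23)}
    else:
        cursor = pam_start - 1
        cis_c = (c_fwd + 1) % L if circular else c_fwd + 1
        step = -1
        footprint = {(pam_start + i) % L if circular else pam_start + i for i in range(23)}
    if cis_c in footprint:
        return None
    gap = 0
    for _ in range(L):
        pos = cursor % L if circular else cursor
        if not circular and (pos < 0 or pos >= L):
            return None
        if pos == cis_c:
            return gap
        gap += 1
        cursor += step
    return None


def brute_force_target_sites(seq: str, circular: bool, min_gap: int, max_gap: int):
    """(strand, pam_start, c_fwd, gap) tuples from the exhaustive cross-product."""
    L = len(seq)
    out = set()
    for strand, pam_start in brute_force_pams(seq, circular):
        for c_fwd in brute_force_cpgs(seq, circular):
            gap = brute_force_gap(strand, pam_start, c_fwd, L, circular)
            if gap is not None and min_gap <= gap <= max_gap:
                out.add((strand, pam_start, c_fwd, gap))
    return out


def pearson_r_squared(xs, ys) -> float:
    """Textbook Pearson correlation squared, no library calls."""
    n = len(xs)
    mx = sum(xs) / n
    my = sum(ys) / n
    sxy = sum((x - mx) * (y - my) for x, y in zip(xs, ys))
    sxx = sum((x - mx) ** 2 for x in xs)
    syy = sum((y - my) ** 2 for y in ys)
    return (sxy * sxy) / (sxx * syy)
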