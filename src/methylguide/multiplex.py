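"""Pairwise interference rules for multiplexed sgRNA sets.

dCas9 occupies ~23 bp of DNA (protospacer + PAM) and distorts the
duplex around its binding site, so guides placed close together can
interfere.  Empirically:

* a target CpG within a few base pairs of (or inside) another guide's
  footprint is *blocked* -- it cannot be methylated while the other
  guide's dCas9 is bound (demonstrated at 1 and 4 nt proximity);
* two guides whose footprints overlap (typically on opposite strands of
  the same site) *compete* for occupancy, but exchange fast enough that
  each still methylates its own CpG nearly as well as alone;
* guides 33 bp apart on the same strand act independently.

The default blocking margin of 4 bp encodes the largest demonstrated
blocking distance; the true threshold between 4 and 33 bp is
unmeasured, so the margin is configurable and flagged in reports as an
extrapolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from methylguide.efficiency import GapEfficiencyProfile, score_target_site
from methylguide.scanner import FOOTPRINT_LEN, Cytosine, PamSite, TargetSite

__all__ = [
    "GuideCandidate",
    "PairStatus",
    "SetReport",
    "check_pair",
    "check_set",
    "effective_prediction",
    "DEFAULT_BLOCK_MARGIN",
]

DEFAULT_BLOCK_MARGIN = 4


@dataclass(frozen=True)
class GuideCandidate:
    """One sgRNA candidate: a PAM plus the CpG sites it targets."""

    id: str
    pam: PamSite
    targeted_cpgs: tuple[TargetSite, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "targeted_cpgs", tuple(self.targeted_cpgs))
        for t in self.targeted_cpgs:
            if t.pam != self.pam:
                raise ValueError(f"target site of guide {self.id!r} references a different PAM")

    @property
    def footprint(self) -> tuple[int, int]:
        """Forward-coordinate half-open interval of protospacer + PAM (23 bp)."""
        return self.pam.footprint

    @property
    def strand(self) -> str:
        return self.pam.strand


@dataclass(frozen=True)
class BlockedCpg:
    """A targeted CpG obstructed by a partner guide's dCas9 footprint."""

    guide_id: str            # the guide whose target is obstructed
    blocking_guide_id: str   # the guide doing the obstructing
    cytosine: Cytosine
    distance: int            # bp from cytosine to the blocking footprint (0 = inside)


@dataclass(frozen=True)
class PairStatus:
    """Pair-level compatibility verdict plus per-CpG blocking detail."""

    status: str  # "compatible" | "competing" | "blocked"
    reason: str
    blocked_cpgs: tuple[BlockedCpg, ...] = ()


def _distance_to_interval(pos: int, interval: tuple[int, int]) -> int:
    start, end = interval
    if start <= pos < end:
        return 0
    return start - pos if pos < start else pos - end + 1


def _intervals_overlap(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return a[0] < b[1] and b[0] < a[1]


def _blocked_by(a: GuideCandidate, b: GuideCandidate, margin: int) -> list[BlockedCpg]:
    """CpGs targeted by ``a`` whose nearer cytosine lies within ``margin`` of b's footprint."""
    out = []
    for t in a.targeted_cpgs:
        d = min(
            _distance_to_interval(t.cis_cytosine.pos, b.footprint),
            _distance_to_interval(t.trans_cytosine.pos, b.footprint),
        )
        if d <= margin:
            out.append(BlockedCpg(a.id, b.id, t.cis_cytosine, d))
    return out


def check_pair(
    a: GuideCandidate, b: GuideCandidate, block_margin: int = DEFAULT_BLOCK_MARGIN
) -> PairStatus:
    """Evaluate interference between two guides on the same record.

    A targeted CpG within ``block_margin`` bp of (or inside) the partner
    guide's 23-bp footprint is flagged blocked and the pair is
    ``blocked``.  With no blocked CpGs, overlapping footprints make the
    pair ``competing`` (fast-exchange co-occupancy) and disjoint
    footprints make it ``compatible``.
    """
    if a.pam.record_id != b.pam.record_id:
        raise ValueError("guides must target the same record")
    if block_margin < 0:
        raise ValueError("block_margin must be >= 0")
    blocked = _blocked_by(a, b, block_margin) + _blocked_by(b, a, block_margin)
    if blocked:
        names = ", ".join(f"{x.guide_id} CpG@{x.cytosine.pos} (d={x.distance})" for x in blocked)
        return PairStatus("blocked", f"target CpG obstructed by partner footprint: {names}", tuple(blocked))
    if _intervals_overlap(a.footprint, b.footprint):
        return PairStatus(
            "competing",
            f"footprints of {a.id} and {b.id} overlap; guides exchange without blocking targets",
        )
    return PairStatus("compatible", f"{a.id} and {b.id} bind independently")


_SEVERITY = {"compatible": 0, "competing": 1, "blocked": 2}


@dataclass(frozen=True)
class SetReport:
    """Verdict for a multiplexed guide set."""

    guide_ids: tuple[str, ...]
    pair_statuses: dict[tuple[str, str], PairStatus]
    blocked_cpgs: tuple[BlockedCpg, ...]
    verdict: str

    def status(self, a: str, b: str) -> PairStatus:
        key = (a, b) if (a, b) in self.pair_statuses else (b, a)
        return self.pair_statuses[key]


def check_set(
    guides: list[GuideCandidate], block_margin: int = DEFAULT_BLOCK_MARGIN
) -> SetReport:
    """Evaluate all unordered pairs of a guide set.

    Each CpG obstructed by any partner is reported once per blocking
    guide; the set-level verdict is the worst pair status.
    """
    if not guides:
        raise ValueError("need at least one guide")
    ids = tuple(g.id for g in guides)
    if len(set(ids)) != len(ids):
        raise ValueError("guide ids must be unique")
    statuses: dict[tuple[str, str], PairStatus] = {}
    blocked: list[BlockedCpg] = []
    seen: set[tuple[str, str, Cytosine]] = set()
    for i, a in enumerate(guides):
        for b in guides[i + 1 :]:
            st = check_pair(a, b, block_margin)
            statuses[(a.id, b.id)] = st
            for bc in st.blocked_cpgs:
                key = (bc.guide_id, bc.blocking_guide_id, bc.cytosine)
                if key not in seen:
                    seen.add(key)
                    blocked.append(bc)
    verdict = "compatible"
    if statuses:
        verdict = max((s.status for s in statuses.values()), key=_SEVERITY.__getitem__)
    return SetReport(ids, statuses, tuple(blocked), verdict)


def effective_prediction(
    guides: list[GuideCandidate],
    profile: GapEfficiencyProfile,
    block_margin: int = DEFAULT_BLOCK_MARGIN,
) -> dict[Cytosine, float]:
    """Per-cytosine predicted methylation fractions for a multiplexed set.

    A cytosine of a blocked CpG predicts 0.  Otherwise each targeting
    guide contributes its single-guide prediction; where several
    non-blocked guides target the same cytosine (competing guides) the
    maximum single-guide prediction is kept, modelling fast exchange of
    the alternative complexes.
    """
    report = check_set(guides, block_margin) if guides else None
    blocked_cyts: set[Cytosine] = set()
    if report is not None:
        by_id = {g.id: g for g in guides}
        for bc in report.blocked_cpgs:
            for t in by_id[bc.guide_id].targeted_cpgs:
                if bc.cytosine in (t.cis_cytosine, t.trans_cytosine):
                    blocked_cyts.update((t.cis_cytosine, t.trans_cytosine))
    pred: dict[Cytosine, float] = {}
    for g in guides:
        for t in g.targeted_cpgs:
            score = score_target_site(t, profile)
            for cyt, p in ((t.cis_cytosine, score.p_cis), (t.trans_cytosine, score.p_trans)):
                value = 0.0 if cyt in blocked_cyts else p
                pred[cyt] = max(pred.get(cyt, 0.0), value) if cyt not in blocked_cyts else 0.0
    return pred
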