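"""Gap-length efficiency profile and design-rule classification.

Methylation efficiency of the dCas9-split-MTase depends on the gap
between the PAM and the target CpG: no methylation occurs below 8 bp or
above 25 bp, and within that window efficiency oscillates with the
~10.5-bp helical period, peaking at gap 12 and again one turn later at
gaps 22-23.  The trans strand (sgRNA-complementary) is methylated at
least as well as the cis strand at every gap.

The default profile packaged here is a smooth parametric curve chosen
to satisfy those empirically established constraints -- it is a
configuration artifact, not measured data, and can be replaced with a
user-calibrated table via :func:`load_profile`.  Per-strand fractions
are combined under independence, and combined predictions are bucketed
into the low (<5%), medium (5-20%) and high (>20%) classes that
transfer from E. coli characterization to human cells.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from methylguide.helix import StrandRole
from methylguide.scanner import TargetSite

__all__ = [
    "GapEfficiencyProfile",
    "EfficiencyClass",
    "default_profile",
    "load_profile",
    "save_profile",
    "predict_strand",
    "predict_any_strand",
    "targetable_window",
    "peak_gaps",
    "classify",
    "score_target_site",
    "TargetSiteScore",
]

GAP_RANGE = range(2, 43)  # gaps characterized experimentally
WINDOW_MIN = 8
WINDOW_MAX = 25

LOW_MAX = 0.05   # fractions strictly below: low
HIGH_MIN = 0.20  # fractions strictly above: high; [0.05, 0.20] is medium


@dataclass(frozen=True)
class GapEfficiencyProfile:
    """Per-gap, per-strand predicted methylation fractions.

    ``entries`` maps gap (bp) to ``(p_cis, p_trans)`` fractions.  Gaps
    absent from the mapping predict zero.
    """

    entries: dict[int, tuple[float, float]]
    provenance: str = "unspecified"

    def __post_init__(self) -> None:
        for gap, (pc, pt) in self.entries.items():
            if gap not in GAP_RANGE:
                raise ValueError(f"profile gap {gap} outside characterized range 2..42")
            for p in (pc, pt):
                if not 0.0 <= p <= 1.0:
                    raise ValueError(f"fraction {p} at gap {gap} outside [0, 1]")


def default_profile() -> GapEfficiencyProfile:
    """The shipped default profile.

    A clipped squared cosine of the helical phase relative to the gap-12
    optimum, rescaled per strand and restricted to the 8-25 bp
    targetable window, with a small floor so every gap in the window is
    predicted methylatable.  Satisfies: zero outside [8, 25]; combined
    maxima at 12 and 22; trans >= cis everywhere; combined > 20% at both
    peaks.
    """
    entries: dict[int, tuple[float, float]] = {}
    for gap in GAP_RANGE:
        if WINDOW_MIN <= gap <= WINDOW_MAX:
            c = max(0.0, math.cos(math.radians(34.3 * (gap - 12))))
            shape = c * c
            entries[gap] = (0.01 + 0.19 * shape, 0.02 + 0.38 * shape)
        else:
            entries[gap] = (0.0, 0.0)
    return GapEfficiencyProfile(entries, provenance="packaged default (cosine shape)")


def load_profile(path) -> GapEfficiencyProfile:
    """Load a profile from a delimited table with columns gap, p_cis, p_trans."""
    with open(path) as fh:
        header = fh.readline()
    sep = "\t" if "\t" in header else ","
    df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    required = {"gap", "p_cis", "p_trans"}
    if not required <= set(df.columns):
        raise ValueError(f"profile table must have columns {sorted(required)}")
    entries = {
        int(row.gap): (float(row.p_cis), float(row.p_trans)) for row in df.itertuples()
    }
    return GapEfficiencyProfile(entries, provenance=str(path))


def save_profile(profile: GapEfficiencyProfile, path) -> None:
    rows = [
        {"gap": g, "p_cis": pc, "p_trans": pt}
        for g, (pc, pt) in sorted(profile.entries.items())
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.17g")


def predict_strand(profile: GapEfficiencyProfile, gap: int, strand: StrandRole) -> float:
    """Predicted methylation fraction for one strand at a gap; 0 outside 2..42."""
    if gap not in profile.entries:
        return 0.0
    pc, pt = profile.entries[gap]
    return pt if StrandRole(strand) is StrandRole.TRANS else pc


def predict_any_strand(profile: GapEfficiencyProfile, gap: int) -> float:
    """Probability of methylation on at least one strand, assuming independence."""
    pc = predict_strand(profile, gap, StrandRole.CIS)
    pt = predict_strand(profile, gap, StrandRole.TRANS)
    return 1.0 - (1.0 - pc) * (1.0 - pt)


def targetable_window(profile: GapEfficiencyProfile) -> tuple[int, int]:
    """Smallest and largest gap with nonzero combined prediction."""
    nonzero = [g for g in sorted(profile.entries) if predict_any_strand(profile, g) > 0.0]
    if not nonzero:
        raise ValueError("profile predicts zero methylation at every gap")
    return nonzero[0], nonzero[-1]


def peak_gaps(profile: GapEfficiencyProfile, gaps) -> list[int]:
    """Argmax gaps of the combined prediction over ``gaps``; ties all returned."""
    gaps = [g for g in gaps if g in GAP_RANGE]
    if not gaps:
        raise ValueError("gap range does not intersect the characterized range 2..42")
    vals = {g: predict_any_strand(profile, g) for g in gaps}
    best = max(vals.values())
    return sorted(g for g, v in vals.items() if v == best)


def classify(fraction: float) -> str:
    """Bucket a methylation fraction: low (<5%), medium (5-20%), high (>20%).

    The medium class is closed on both ends.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError(f"fraction {fraction} outside [0, 1]")
    if fraction < LOW_MAX:
        return "low"
    if fraction <= HIGH_MIN:
        return "medium"
    return "high"


@dataclass(frozen=True)
class TargetSiteScore:
    """Predictions for both cytosines of one candidate target site."""

    site: TargetSite
    p_cis: float
    p_trans: float
    p_any: float
    class_cis: str
    class_trans: str
    class_any: str


def score_target_site(site: TargetSite, profile: GapEfficiencyProfile) -> TargetSiteScore:
    """Score a candidate: per-strand fractions, combined, and classes."""
    pc = predict_strand(profile, site.gap, StrandRole.CIS)
    pt = predict_strand(profile, site.gap, StrandRole.TRANS)
    pa = 1.0 - (1.0 - pc) * (1.0 - pt)
    return TargetSiteScore(
        site=site,
        p_cis=pc,
        p_trans=pt,
        p_any=pa,
        class_cis=classify(pc),
        class_trans=classify(pt),
        class_any=classify(pa),
    )
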