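"""B-DNA helical geometry of the dCas9-MTase fusion point.

When a dCas9-MC fusion is parked at a protospacer, the split-MTase
C-terminal fragment must reach a CpG site some number of base pairs
(the *gap*) downstream of the PAM.  Because B-DNA twists ~34.3 degrees
per base pair, the angular position of the MC N-terminus around the
helix axis -- viewed down the axis from the dCas9 C-terminus -- rotates
as the gap grows.  Methylation is efficient when the two fusion points
sit on the same side of the duplex, so this angle is the geometric
variable underlying the gap-length design rules.

The model is anchored empirically: at a gap of 8 bp the MC N-terminus
sits at 20 degrees when the MTase engages the trans strand (the
sgRNA-complementary strand) and at 290 degrees when it engages the cis
strand (the PAM/protospacer strand).  Angles at other gaps follow by
ideal-B-DNA extrapolation.  The module is purely descriptive; the
angle-to-efficiency mapping lives in :mod:`methylguide.efficiency`.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

__all__ = [
    "StrandRole",
    "HelicalModel",
    "angle_at_gap",
    "angular_separation",
    "helical_period",
]


class StrandRole(enum.Enum):
    """Which strand of the target CpG the MTase fragment engages.

    ``CIS`` is the PAM/protospacer-containing strand; ``TRANS`` is the
    sgRNA-complementary strand.
    """

    CIS = "cis"
    TRANS = "trans"


@dataclass(frozen=True)
class HelicalModel:
    """Parameters of the ideal-B-DNA angular model.

    Parameters
    ----------
    twist_per_bp
        Helical twist in degrees per base pair; 34.3 for the B-DNA
        geometry used to anchor the model.
    anchor_gap
        Gap length (bp) at which the anchor angles were measured.
    anchor_angle_trans, anchor_angle_cis
        Angles (degrees, in [0, 360)) of the MC N-terminus at the anchor
        gap for trans- and cis-strand engagement.
    rotation_sign
        +1 if the angle increases with gap length, -1 otherwise.  The
        sense of rotation does not affect efficiency scoring, only the
        polar-plot presentation.
    """

    twist_per_bp: float = 34.3
    anchor_gap: int = 8
    anchor_angle_trans: float = 20.0
    anchor_angle_cis: float = 290.0
    rotation_sign: int = 1

    def __post_init__(self) -> None:
        if not 0.0 < self.twist_per_bp < 360.0:
            raise ValueError(f"twist_per_bp must be in (0, 360), got {self.twist_per_bp}")
        for name in ("anchor_angle_trans", "anchor_angle_cis"):
            a = getattr(self, name)
            if not 0.0 <= a < 360.0:
                raise ValueError(f"{name} must be in [0, 360), got {a}")
        if self.anchor_gap < 0:
            raise ValueError(f"anchor_gap must be >= 0, got {self.anchor_gap}")
        if self.rotation_sign not in (1, -1):
            raise ValueError(f"rotation_sign must be +1 or -1, got {self.rotation_sign}")

    def anchor_angle(self, strand: StrandRole) -> float:
        return self.anchor_angle_trans if strand is StrandRole.TRANS else self.anchor_angle_cis


def angle_at_gap(model: HelicalModel, gap: int, strand: StrandRole) -> float:
    """Angle (degrees, in [0, 360)) of the MC N-terminus at a given gap.

    The angle is the anchor angle for ``strand`` plus one helical twist
    per base pair of gap beyond the anchor gap, reduced modulo 360.
    Gaps are base-pair counts, so non-integer or negative gaps are
    rejected rather than interpolated.
    """
    if isinstance(gap, bool) or not isinstance(gap, (int,)):
        raise TypeError(f"gap must be an integer base-pair count, got {gap!r}")
    if gap < 0:
        raise ValueError(f"gap must be >= 0, got {gap}")
    strand = StrandRole(strand)
    raw = model.anchor_angle(strand) + model.rotation_sign * model.twist_per_bp * (gap - model.anchor_gap)
    return raw % 360.0


def angular_separation(angle: float) -> float:
    """Separation (degrees, in [0, 180]) of an angle from 0.

    Quantifies how far a fusion point sits from the "same side of the
    helix" reference direction; 0 means directly aligned, 180 means
    diametrically opposite.
    """
    a = angle % 360.0
    return min(a, 360.0 - a)


def helical_period(model: HelicalModel) -> float:
    """Gap-length period (bp) of one full turn, 360 / twist_per_bp.

    ~10.5 bp for the default 34.3 degrees/bp twist, consistent with the
    observed ~11 bp oscillation of methylation efficiency with gap
    length.
    """
    return 360.0 / model.twist_per_bp
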