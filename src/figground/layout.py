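"""Eccentric placement and proportional magnification.

Stimuli are shown centrally (0 deg) or 15/30 deg to the right of
fixation.  Peripheral presentation enlarges the stimulus in proportion
to a reference size; the admissible (eccentricity, size) pairs are the
rows of the study's size table:

=============  ==========================
eccentricity   sizes (deg)
=============  ==========================
0              4, 8, 16
15             8, 16, 20
30             16, 20, 30, 40
=============  ==========================

Magnification multiplies positions (relative to the stimulus centre),
dot diameters and hence all speeds; the stimulus centre -- defined as
the geometric centre of the bounding box prior to any stimulus motion
-- is translated to ``(eccentricity, 0)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .clip import StimulusClip

#: Admissible stimulus sizes (deg) per eccentricity (deg).
SIZE_TABLE: dict[float, tuple[float, ...]] = {
    0.0: (4.0, 8.0, 16.0),
    15.0: (8.0, 16.0, 20.0),
    30.0: (16.0, 20.0, 30.0, 40.0),
}

#: Reference size (deg) at which generators are calibrated: the
#: best-performing central walker size.
REFERENCE_SIZE = 16.0


@dataclass(frozen=True)
class Layout:
    """Placement of a stimulus: eccentricity, size and magnification."""

    eccentricity: float
    size: float
    reference_size: float = REFERENCE_SIZE
    strict: bool = True

    def __post_init__(self) -> None:
        if self.reference_size <= 0 or self.size <= 0:
            raise ValueError("sizes must be > 0")
        if self.strict:
            sizes = SIZE_TABLE.get(float(self.eccentricity))
            if sizes is None:
                raise ValueError(
                    f"eccentricity {self.eccentricity} deg is not in the size table "
                    f"(rows: {sorted(SIZE_TABLE)})"
                )
            if float(self.size) not in sizes:
                raise ValueError(
                    f"size {self.size} deg is not admissible at eccentricity "
                    f"{self.eccentricity} deg (allowed: {sizes})"
                )

    @property
    def magnification(self) -> float:
        return self.size / self.reference_size


def scale_to_layout(clip: StimulusClip, layout: Layout) -> StimulusClip:
    """Magnify a reference-size clip and place it at its eccentricity.

    Positions relative to the stimulus centre, dot diameters and (as a
    consequence) dot speeds are multiplied by ``layout.magnification``;
    the centre moves to ``(eccentricity, 0)``.  With magnification 1 the
    geometry is unchanged except for the translation.
    """
    m = layout.magnification
    center = clip.center
    new_center = np.array([layout.eccentricity, 0.0])
    out = clip.copy()
    out.positions = (clip.positions - center) * m + new_center
    out.diameters = clip.diameters * m
    x0, y0, x1, y1 = clip.bbox
    lo = (np.array([x0, y0]) - center) * m + new_center
    hi = (np.array([x1, y1]) - center) * m + new_center
    out.bbox = (float(lo[0]), float(lo[1]), float(hi[0]), float(hi[1]))
    out.size = clip.size * m
    out.eccentricity = float(layout.eccentricity)
    out.meta = dict(clip.meta, magnification=m)
    return out
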