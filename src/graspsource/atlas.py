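"""Region-of-interest atlas used throughout the pipeline.

The source space is summarised by 24 regions: a Brodmann-area subset covering
somatosensory (BA1, BA2, BA3a, BA3b), primary motor (BA4a, BA4p), premotor
(BA6) and Broca (BA44, BA45) cortex plus three visual areas (V1, V2, MT),
each in both hemispheres.
"""

from __future__ import annotations

AREAS = (
    "BA1", "BA2", "BA3a", "BA3b", "BA4a", "BA4p",
    "BA6", "BA44", "BA45", "V1", "V2", "MT",
)

#: Canonical ordering of the 24 ROI labels: left hemisphere first.
ROI_LABELS: tuple[str, ...] = tuple(f"{a}-{h}" for h in ("L", "R") for a in AREAS)

N_ROIS = len(ROI_LABELS)

MOTOR_ROIS = ("BA4a-L", "BA4p-L", "BA6-L", "BA4a-R", "BA4p-R", "BA6-R")
SOMATOSENSORY_ROIS = tuple(
    f"{a}-{h}" for h in ("L", "R") for a in ("BA1", "BA2", "BA3a", "BA3b")
)
VISUAL_ROIS = tuple(f"{a}-{h}" for h in ("L", "R") for a in ("V1", "V2", "MT"))


def roi_index(label: str) -> int:
    """Position of *label* in the canonical 24-ROI ordering."""
    try:
        return ROI_LABELS.index(label)
    except ValueError:
        raise KeyError(f"unknown ROI label: {label!r}") from None
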