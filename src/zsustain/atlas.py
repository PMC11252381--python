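"""Region-of-interest atlas for whole-brain gray-matter-volume tables.

The default atlas merges whole-brain anatomical regions into 17 ROIs spanning
the major cortical lobes and the subcortex, the granularity at which the
subtype/stage model operates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

DEFAULT_ROI_NAMES: tuple[str, ...] = (
    "frontal lobe",
    "temporal lobe",
    "parietal lobe",
    "occipital lobe",
    "insula",
    "cingulate",
    "sensorimotor",
    "Broca's area",
    "cerebellum",
    "hippocampus",
    "parahippocampus",
    "amygdala",
    "caudate",
    "putamen",
    "pallidum",
    "accumbens",
    "thalamus",
)


@dataclass(frozen=True)
class ROIAtlas:
    """Ordered ROI labels plus the direction in which disease moves each volume.

    ``loss_direction[i] = +1`` means the disease *lowers* volume in ROI ``i``
    (the usual case for gray-matter loss); ``-1`` means the measure already
    increases with pathology (e.g. an inverted or pre-flipped table).
    """

    names: tuple[str, ...] = DEFAULT_ROI_NAMES
    loss_direction: tuple[int, ...] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.loss_direction is None:
            object.__setattr__(self, "loss_direction", (1,) * len(self.names))
        if len(set(self.names)) != len(self.names):
            raise ValueError("ROI names must be unique")
        if len(self.loss_direction) != len(self.names):
            raise ValueError("loss_direction must have one entry per ROI")
        if any(d not in (-1, 1) for d in self.loss_direction):
            raise ValueError("loss_direction entries must be +1 or -1")

    def __len__(self) -> int:
        return len(self.names)

    def index(self, name: str) -> int:
        return self.names.index(name)


DEFAULT_ATLAS = ROIAtlas()
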