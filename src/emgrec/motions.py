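"""The six upper-limb rehabilitation motion classes.

Single-joint elbow and shoulder motions plus their compounds, recorded from
three muscles (biceps brachii, triceps brachii, anterior deltoid). The integer
encoding is stable and used everywhere (labels, confusion-matrix axes, CNN
output units).
"""

from __future__ import annotations

from enum import IntEnum


class MotionClass(IntEnum):
    """Motion-intent classes with a stable 0–5 encoding.

    EF/EE: elbow flexion/extension (one-DOF elbow joint).
    SF/SE: shoulder flexion/extension (upper-arm lowering/lifting).
    ESF/ESE: compound elbow+shoulder flexion/extension.
    """

    EF = 0
    EE = 1
    SF = 2
    SE = 3
    ESF = 4
    ESE = 5


#: Canonical channel order used by the whole pipeline.
CHANNEL_NAMES = ("biceps", "triceps", "deltoid")

N_CLASSES = len(MotionClass)


def as_motion(label) -> MotionClass:
    """Coerce an int, name string or MotionClass to a MotionClass.

    Raises ValueError for anything that is not one of the six classes.
    """
    if isinstance(label, MotionClass):
        return label
    if isinstance(label, str):
        try:
            return MotionClass[label.upper()]
        except KeyError:
            raise ValueError(f"unknown motion label: {label!r}") from None
    try:
        return MotionClass(int(label))
    except (ValueError, TypeError):
        raise ValueError(f"unknown motion label: {label!r}") from None
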