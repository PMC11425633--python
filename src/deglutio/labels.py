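"""The fixed seven-class label set and its canonical ordering.

The ordering is load-bearing: one-hot vectors, confusion-matrix axes and the
classifier output layer all index classes by position in ``CLASS_LABELS``.
"""

from __future__ import annotations

CLASS_LABELS: tuple[str, ...] = (
    "rest",
    "liquid",
    "soft_food",
    "dense_food",
    "silent_aspiration",
    "cough",
    "chewing",
)

N_CLASSES = len(CLASS_LABELS)

LABEL_INDEX: dict[str, int] = {lab: i for i, lab in enumerate(CLASS_LABELS)}

#: classes that correspond to an actual swallow with the three-sound sequence
SWALLOW_LABELS: tuple[str, ...] = ("liquid", "soft_food", "dense_food")

#: classes that appear as annotated events (everything except rest)
EVENT_LABELS: tuple[str, ...] = tuple(l for l in CLASS_LABELS if l != "rest")


def validate_label(label: str) -> str:
    """Return ``label`` unchanged or raise ``ValueError`` listing valid labels."""
    if label not in LABEL_INDEX:
        raise ValueError(
            f"unknown class label {label!r}; valid labels are {', '.join(CLASS_LABELS)}"
        )
    return label
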