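"""Muscle-group label taxonomy.

Nine bilateral trunk muscle groups encoded as 18 side-specific integer
labels (1..18); label 0 is background.  Group ``i`` (0-based position in
:data:`MUSCLE_GROUPS`) maps to labels ``2*i + 1`` (left) and ``2*i + 2``
(right).
"""

from __future__ import annotations

import json
from pathlib import Path

#: Canonical group names, in reporting order.
MUSCLE_GROUPS: tuple[str, ...] = (
    "psoas",
    "quadratus_lumborum",
    "paraspinal",
    "latissimus_dorsi",
    "iliacus",
    "rectus_femoris",
    "rhomboid",
    "trapezius",
    "vastus",
)

SIDES: tuple[str, str] = ("left", "right")

#: label -> (group, side) for labels 1..18
LABEL_TO_GROUP_SIDE: dict[int, tuple[str, str]] = {
    2 * i + 1 + s: (group, SIDES[s])
    for i, group in enumerate(MUSCLE_GROUPS)
    for s in (0, 1)
}

#: (group, side) -> label
GROUP_SIDE_TO_LABEL: dict[tuple[str, str], int] = {
    v: k for k, v in LABEL_TO_GROUP_SIDE.items()
}


def labels_for_group(group: str) -> tuple[int, int]:
    """Return the (left, right) labels for a muscle group name."""
    if group not in MUSCLE_GROUPS:
        raise KeyError(f"unknown muscle group: {group!r}")
    return (
        GROUP_SIDE_TO_LABEL[(group, "left")],
        GROUP_SIDE_TO_LABEL[(group, "right")],
    )


def default_taxonomy() -> dict[int, tuple[str, str]]:
    """A fresh copy of the default 18-label taxonomy."""
    return dict(LABEL_TO_GROUP_SIDE)


def write_taxonomy_json(path: str | Path) -> None:
    payload = {str(k): list(v) for k, v in LABEL_TO_GROUP_SIDE.items()}
    Path(path).write_text(json.dumps(payload, indent=2))


def read_taxonomy_json(path: str | Path) -> dict[int, tuple[str, str]]:
    payload = json.loads(Path(path).read_text())
    return {int(k): (v[0], v[1]) for k, v in payload.items()}
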