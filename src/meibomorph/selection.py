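"""Central-region gland selection and temporal-to-nasal numbering.

The 10 analyzed glands are the five nearest the midline of the overall
gland area on each side.  Gland 1 is the most temporal selected gland,
gland 10 the most nasal.  Which image side is temporal depends on
laterality: for a right eye (OD) imaged en face the temporal side is image
left, for a left eye (OS) it is image right.  Acquisition mirroring is
device-dependent, so the temporal side can always be overridden.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Sequence

from .morphometry import GlandComponent

__all__ = [
    "SelectionError",
    "GlandIndexMap",
    "temporal_side_for",
    "find_midline",
    "select_central_10",
]


class SelectionError(ValueError):
    """Raised when the central-10 selection is impossible."""


def temporal_side_for(laterality: str) -> str:
    """Default temporal image side for an en-face view: OD->left, OS->right."""
    lat = laterality.upper()
    if lat == "OD":
        return "left"
    if lat == "OS":
        return "right"
    raise SelectionError(f"laterality must be 'OD' or 'OS', got {laterality!r}")


@dataclass
class GlandIndexMap:
    """Mapping from gland index 1..10 (temporal to nasal) to components."""

    order: list[GlandComponent]  # order[i] holds gland index i+1
    laterality: str
    temporal_side: str

    def items(self) -> Iterator[tuple[int, GlandComponent]]:
        return ((i + 1, comp) for i, comp in enumerate(self.order))

    def component_labels(self) -> list[int]:
        return [c.label for c in self.order]


def find_midline(components: Sequence[GlandComponent]) -> float:
    """Area-weighted centroid column of the union of all gland pixels."""
    if not components:
        raise SelectionError("no gland components")
    total = sum(c.area for c in components)
    return sum(c.area * c.centroid_col for c in components) / total


def select_central_10(
    components: Sequence[GlandComponent],
    midline: float,
    laterality: str,
    temporal_side: str | None = None,
) -> GlandIndexMap:
    """Select the 5 glands nearest the midline on each side and number them.

    A centroid exactly on the midline is assigned to the side with fewer
    glands, ties going to the temporal side.  Raises
    :class:`SelectionError` naming the deficient side if either side has
    fewer than 5 glands.
    """
    if temporal_side is None:
        temporal_side = temporal_side_for(laterality)
    if temporal_side not in ("left", "right"):
        raise SelectionError(f"temporal_side must be 'left' or 'right', got {temporal_side!r}")

    left = [c for c in components if c.centroid_col < midline]
    right = [c for c in components if c.centroid_col > midline]
    for c in components:
        if c.centroid_col == midline:
            if len(left) < len(right):
                left.append(c)
            elif len(right) < len(left):
                right.append(c)
            elif temporal_side == "left":
                left.append(c)
            else:
                right.append(c)
    for side_name, side in (("left", left), ("right", right)):
        if len(side) < 5:
            raise SelectionError(
                f"only {len(side)} glands on the {side_name} side of the midline "
                "(need 5)"
            )
    nearest = lambda cs: sorted(cs, key=lambda c: abs(c.centroid_col - midline))[:5]
    chosen = nearest(left) + nearest(right)
    chosen.sort(key=lambda c: (c.centroid_col, c.topmost_row))
    if temporal_side == "right":
        chosen.reverse()
    return GlandIndexMap(order=chosen, laterality=laterality, temporal_side=temporal_side)
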