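"""Trigeminal partition of the 68-point facial landmark grid.

The face grid follows the OpenFace 68-landmark indexing (0-based). The three
subregions correspond to the sensory territories of the trigeminal nerve:

* ``V1`` (ophthalmic): eyebrows, eyes and upper nose bridge,
* ``V2`` (maxillary): lower nose, upper lip and upper inner mouth,
* ``V3`` (mandibular): jawline, lower lip and chin.

The membership table is configuration, not a constant: published listings of
these sets are not fully self-consistent (stated counts differ from the index
ranges by one, and one range is printed in descending order), so the default
below takes the index sets at face value under an ascending, 0-based reading.
The counts are V1=27, V2=16, V3=25, covering all 68 points exactly once.
"""

from __future__ import annotations

# Landmark order inside each region is the canonical pooling order.
DEFAULT_REGIONS: dict[str, tuple[int, ...]] = {
    "V1": tuple(range(17, 31)) + (33,) + tuple(range(36, 48)),
    "V2": (31, 32, 34, 35) + tuple(range(48, 55)) + tuple(range(60, 65)),
    "V3": tuple(range(0, 17)) + tuple(range(55, 60)) + tuple(range(65, 68)),
}

REGION_NAMES = tuple(DEFAULT_REGIONS)


def validate_regions(regions: dict[str, tuple[int, ...]]) -> None:
    """Check a region table covers disjoint subsets of the 68-point grid."""
    seen: set[int] = set()
    for name, idx in regions.items():
        if not idx:
            raise ValueError(f"region {name!r} is empty")
        for i in idx:
            if not 0 <= i <= 67:
                raise ValueError(f"region {name!r}: landmark index {i} outside 0..67")
            if i in seen:
                raise ValueError(f"landmark index {i} assigned to more than one region")
            seen.add(i)
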