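"""Space-group operator tables and Laue-group utilities.

Operators are stored as Jones-faithful triplets ("x,y,z" style) and parsed
into ``(R, t)`` pairs acting on fractional coordinates.  The reciprocal-space
rotation parts, which act on column vectors of Miller indices and generate
the intensity (Laue) symmetry of a diffraction pattern, are the transposes
of the real-space rotation parts.

Only a small table of groups is bundled -- enough to cover triclinic,
monoclinic, orthorhombic, tetragonal and hexagonal toy crystals as well as
the settings used by typical protein test cases.
"""

from __future__ import annotations

import re
from fractions import Fraction

import numpy as np

#: Jones-faithful symmetry operators per supported space group.
SPACE_GROUP_OPS: dict[str, list[str]] = {
    "P1": ["x,y,z"],
    "P21": ["x,y,z", "-x,y+1/2,-z"],
    "P212121": [
        "x,y,z",
        "x+1/2,-y+1/2,-z",
        "-x,y+1/2,-z+1/2",
        "-x+1/2,-y,z+1/2",
    ],
    "P4222": [
        "x,y,z",
        "-x,-y,z",
        "-y,x,z+1/2",
        "y,-x,z+1/2",
        "-x,y,-z",
        "x,-y,-z",
        "y,x,-z+1/2",
        "-y,-x,-z+1/2",
    ],
    "P6322": [
        "x,y,z",
        "-y,x-y,z",
        "-x+y,-x,z",
        "-x,-y,z+1/2",
        "y,-x+y,z+1/2",
        "x-y,x,z+1/2",
        "y,x,-z",
        "x-y,-y,-z",
        "-x,-x+y,-z",
        "-y,-x,-z+1/2",
        "-x+y,y,-z+1/2",
        "x,x-y,-z+1/2",
    ],
}

_VAR_RE = re.compile(r"([+-]?)([xyz])")


def parse_symop(triplet: str) -> tuple[np.ndarray, np.ndarray]:
    """Parse one Jones-faithful triplet into (rotation, translation).

    Returns an integer 3x3 rotation part and a float length-3 translation
    in fractional coordinates.
    """
    rows = triplet.replace(" ", "").lower().split(",")
    if len(rows) != 3:
        raise ValueError(f"malformed symmetry operator: {triplet!r}")
    rot = np.zeros((3, 3), dtype=int)
    trans = np.zeros(3)
    for i, comp in enumerate(rows):
        for sign, var in _VAR_RE.findall(comp):
            rot[i, "xyz".index(var)] += -1 if sign == "-" else 1
        const = _VAR_RE.sub("", comp)
        if const:
            trans[i] = float(Fraction(const))
    return rot, trans


def real_space_ops(label: str) -> list[tuple[np.ndarray, np.ndarray]]:
    """All (rotation, translation) operators of a supported space group."""
    try:
        triplets = SPACE_GROUP_OPS[label]
    except KeyError:
        known = ", ".join(sorted(SPACE_GROUP_OPS))
        raise ValueError(f"unknown space group {label!r}; known: {known}") from None
    return [parse_symop(t) for t in triplets]


def _unique(mats: list[np.ndarray]) -> list[np.ndarray]:
    seen: dict[bytes, np.ndarray] = {}
    for m in mats:
        seen.setdefault(np.asarray(m, dtype=int).tobytes(), np.asarray(m, dtype=int))
    return list(seen.values())


def reciprocal_rotations(label: str) -> list[np.ndarray]:
    """Unique reciprocal-space rotation parts (point group acting on hkl).

    For a real-space operator x -> R x + t, the equivalent-intensity
    condition I(h) = I(h R) means the hkl column vector transforms by R^T.
    """
    return _unique([rot.T for rot, _ in real_space_ops(label)])


def laue_operators(rotations: list[np.ndarray]) -> list[np.ndarray]:
    """Expand a reciprocal point group by Friedel inversion: {R} U {-R}."""
    mats = [np.asarray(r, dtype=int) for r in rotations]
    return _unique(mats + [-m for m in mats])


def is_closed(mats: list[np.ndarray]) -> bool:
    """True if the matrix set is closed under composition."""
    keys = {np.asarray(m, dtype=int).tobytes() for m in mats}
    for a in mats:
        for b in mats:
            if (np.asarray(a) @ np.asarray(b)).astype(int).tobytes() not in keys:
                return False
    return True
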