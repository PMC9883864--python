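"""Dinucleotide physicochemical property table used by PseDNC.

Six local B-DNA step parameters — helical twist, tilt, roll (degrees) and
shift, slide, rise (angstroms) — taken as consensus values from
crystallographic dinucleotide-step surveys.  Reverse-complement symmetry is
respected: symmetric parameters (twist, roll, slide, rise) are equal for a
step and its reverse complement, antisymmetric ones (tilt, shift) flip sign.

Before computing correlation factors the table is standardized column-wise
to zero mean and unit variance across the 16 dinucleotides, as is standard
for pseudo-composition encodings.
"""

from __future__ import annotations

import numpy as np

PROPERTY_NAMES = ("twist", "tilt", "roll", "shift", "slide", "rise")

# twist, tilt, roll, shift, slide, rise
DINUC_PROPERTIES: dict[str, tuple[float, float, float, float, float, float]] = {
    "AA": (35.5, -1.4, 0.7, -0.03, -0.08, 3.27),
    "AC": (33.1, -0.1, 0.7, 0.13, -0.58, 3.36),
    "AG": (30.6, -1.7, 4.5, 0.09, -0.25, 3.34),
    "AT": (29.8, 0.0, 1.1, 0.00, -0.59, 3.31),
    "CA": (36.9, 0.5, 4.7, 0.09, 0.53, 3.33),
    "CC": (33.4, -0.1, 3.6, 0.05, -0.22, 3.42),
    "CG": (31.1, 0.0, 5.4, 0.00, 0.41, 3.39),
    "CT": (30.6, 1.7, 4.5, -0.09, -0.25, 3.34),
    "GA": (39.3, -1.5, 1.9, -0.28, 0.09, 3.37),
    "GC": (38.3, 0.0, 0.3, 0.00, -0.11, 3.40),
    "GG": (33.4, 0.1, 3.6, -0.05, -0.22, 3.42),
    "GT": (33.1, 0.1, 0.7, -0.13, -0.58, 3.36),
    "TA": (40.0, 0.0, 3.3, 0.00, 0.05, 3.42),
    "TC": (39.3, 1.5, 1.9, 0.28, 0.09, 3.37),
    "TG": (36.9, -0.5, 4.7, -0.09, 0.53, 3.33),
    "TT": (35.5, 1.4, 0.7, 0.03, -0.08, 3.27),
}

_BASES = "ACGT"
DINUCLEOTIDES = tuple(a + b for a in _BASES for b in _BASES)


def standardized_property_matrix() -> np.ndarray:
    """16 x 6 matrix of properties, each column zero-mean / unit-variance.

    Rows follow lexicographic dinucleotide order (AA, AC, ..., TT).
    """
    raw = np.array([DINUC_PROPERTIES[d] for d in DINUCLEOTIDES], dtype=float)
    mean = raw.mean(axis=0)
    std = raw.std(axis=0)
    return (raw - mean) / std
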