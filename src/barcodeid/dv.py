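"""Dual-Vector (DV) Curve encoding of DNA sequences.

A DV-Curve maps a DNA sequence of length N to a 2-D lattice polyline of
2N + 1 points.  Each base contributes an ordered pair of unit-slope step
vectors drawn from u = (1, 1) and d = (1, -1); the four bases receive the
four distinct ordered pairs (u,u), (u,d), (d,u), (d,d) bijectively.  Because
x always advances by one, the curve is degeneracy-free, and because the pair
assignment is a bijection the curve decodes uniquely back to the sequence.

A sequence is summarised by its S/L descriptor: S is the area enclosed
between the curve's |y| profile and the x-axis (trapezoid rule), L is the
curve's arc length (2N * sqrt(2) for unit-slope steps).  Repeating this for
all 4! = 24 base-to-pair assignments yields a fixed 24-component feature
vector whatever the sequence length — the input of the RBF classifier.
"""

from __future__ import annotations

from itertools import permutations

import numpy as np

from .errors import DegenerateDescriptorError, EncodingError, MalformedCurveError

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}

# step pairs as (first dy, second dy); dx is always +1
PAIR_UU = (1, 1)
PAIR_UD = (1, -1)
PAIR_DU = (-1, 1)
PAIR_DD = (-1, -1)
#: canonical pair order used to enumerate assignments
PAIRS = (PAIR_UU, PAIR_UD, PAIR_DU, PAIR_DD)

#: canonical assignment: A->(u,u), G->(u,d), C->(d,u), T->(d,d)
CANONICAL_ASSIGNMENT: dict[str, tuple[int, int]] = {
    "A": PAIR_UU,
    "G": PAIR_UD,
    "C": PAIR_DU,
    "T": PAIR_DD,
}

#: the 24 assignments in canonical order: lexicographic over the tuple of
#: pairs given to (A, C, G, T), with pair order (u,u) < (u,d) < (d,u) < (d,d)
ALL_ASSIGNMENTS: tuple[dict[str, tuple[int, int]], ...] = tuple(
    dict(zip(BASES, perm)) for perm in permutations(PAIRS)
)

N_ASSIGNMENTS = len(ALL_ASSIGNMENTS)
assert N_ASSIGNMENTS == 24


def _sequence_indices(sequence: str) -> np.ndarray:
    if not sequence:
        raise EncodingError("cannot encode an empty sequence")
    try:
        return np.array([_BASE_INDEX[b] for b in sequence], dtype=np.intp)
    except KeyError as exc:
        raise EncodingError(
            f"sequence contains non-ACGT symbol {exc.args[0]!r}"
        ) from None


def _step_table(assignment: dict[str, tuple[int, int]]) -> np.ndarray:
    """(4, 2) int array of the two dy steps per base index."""
    return np.array([assignment[b] for b in BASES], dtype=np.int64)


def dv_curve(sequence: str, assignment: dict[str, tuple[int, int]] | None = None) -> np.ndarray:
    """Build the DV-Curve of ``sequence`` under ``assignment``.

    Returns an integer array of shape (2N + 1, 2): column 0 is x = 0..2N,
    column 1 the cumulative y.  The curve starts at the origin.
    """
    if assignment is None:
        assignment = CANONICAL_ASSIGNMENT
    idx = _sequence_indices(sequence)
    steps = _step_table(assignment)[idx].reshape(-1)  # 2N dy values
    y = np.concatenate(([0], np.cumsum(steps)))
    x = np.arange(y.size)
    return np.column_stack((x, y))


def dv_decode(curve: np.ndarray, assignment: dict[str, tuple[int, int]] | None = None) -> str:
    """Invert :func:`dv_curve`: recover the sequence from its curve."""
    if assignment is None:
        assignment = CANONICAL_ASSIGNMENT
    curve = np.asarray(curve)
    if curve.ndim != 2 or curve.shape[1] != 2 or curve.shape[0] < 3:
        raise MalformedCurveError("curve must be an (2N+1) x 2 point array with N >= 1")
    n_steps = curve.shape[0] - 1
    if n_steps % 2:
        raise MalformedCurveError("DV-Curve must have an even number of steps")
    dy = np.diff(curve[:, 1])
    if not np.all(np.abs(dy) == 1):
        raise MalformedCurveError("every step must change y by exactly +/-1")
    pair_to_base = {pair: base for base, pair in assignment.items()}
    pairs = dy.reshape(-1, 2)
    try:
        return "".join(pair_to_base[(int(a), int(b))] for a, b in pairs)
    except KeyError:
        raise MalformedCurveError("curve contains a step pair outside the assignment")


def sl_descriptor(curve: np.ndarray) -> float:
    """S/L descriptor of a DV-Curve.

    S is the trapezoid-rule area between |y| and the x-axis; L the polyline
    arc length.  Both are invariant to mirroring the curve through the
    x-axis, so the descriptor depends on the excursion profile only.
    """
    curve = np.asarray(curve, dtype=float)
    if curve.ndim != 2 or curve.shape[0] < 2:
        raise DegenerateDescriptorError("S/L undefined for a curve with < 2 points")
    x, y = curve[:, 0], np.abs(curve[:, 1])
    area = float(np.trapezoid(y, x))
    length = float(np.hypot(np.diff(curve[:, 0]), np.diff(curve[:, 1])).sum())
    return area / length


def dv_feature_vector(sequence: str) -> np.ndarray:
    """24-component DV characterization of a sequence.

    Component k is the S/L descriptor of the curve under the k-th assignment
    in the canonical enumeration (:data:`ALL_ASSIGNMENTS`).  The dimension is
    24 for every sequence, independent of its length.
    """
    idx = _sequence_indices(sequence)
    n = idx.size
    length = 2 * n * np.sqrt(2.0)  # unit-slope steps: each has length sqrt(2)
    out = np.empty(N_ASSIGNMENTS)
    for k, assignment in enumerate(ALL_ASSIGNMENTS):
        steps = _step_table(assignment)[idx].reshape(-1)
        y = np.concatenate(([0], np.cumsum(steps)))
        ay = np.abs(y)
        area = float((ay[:-1] + ay[1:]).sum()) / 2.0  # dx == 1 throughout
        out[k] = area / length
    return out


def dv_feature_matrix(sequences: list[str]) -> np.ndarray:
    """Stack :func:`dv_feature_vector` over many sequences (rows)."""
    return np.array([dv_feature_vector(s) for s in sequences])
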