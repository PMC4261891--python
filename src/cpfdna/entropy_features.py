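"""Partial-sum Shannon entropy of local word frequencies — the CPF core.

A word's occurrence positions within a mapped sequence are turned into a
non-negative *local frequency* (LF) sequence, and the feature value is the
Shannon entropy of that sequence's normalised partial sums.  For a
non-negative sequence ``x_1 .. x_n``::

    S_i = sum_{j<=i} x_j          (partial sums)
    Z   = sum_i S_i
    p_r = S_r / Z                 (position probabilities)
    h   = -sum_r p_r log2 p_r     (0 * log2 0 := 0)

Because ``x_r`` is counted ``n - r + 1`` times in ``Z``, mass near the front
of the sequence spreads probability evenly and raises the entropy, while
mass at the back concentrates it: ``h`` ranges over ``[0, log2 n]``, maximal
for ``(c, 0, ..., 0)`` and zero for ``(0, ..., 0, c)``.  The entropy is
invariant under positive scaling of ``x``.

The local frequency of the ``r``-th occurrence of a word at window position
``P_r`` (1-based, ``P_0 := 0``) is ``LF_r = 1 / (P_r - P_{r-1})``, the
reciprocal gap to the previous occurrence.  The LF values are embedded at
their occurrence positions into a length-``m`` sequence of zeros
(``m = n - k + 1`` windows) and the feature value is the partial-sum entropy
of that full embedded sequence, so both where a word occurs and how densely
it clusters shape the feature.

The CPF feature vector of a DNA sequence applies this to each of the
``2**k`` words under each of the three category schemes — 12 components at
the default window size ``k = 2``.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .category_mapping import SCHEMES, canonical_words, extract_words, map_category, scheme_words

__all__ = [
    "FeatureVector",
    "partial_sum_entropy",
    "local_frequencies",
    "embed_lf",
    "lf_entropy",
    "cpf_vector",
]


@dataclass(frozen=True)
class FeatureVector:
    """A model-tagged numeric feature vector for one sequence.

    Attributes
    ----------
    model : str
        One of ``"cpf"``, ``"ktuple"``, ``"dmk"``, ``"tsm"``.
    source_id : str
        Identifier of the featurised sequence.
    values : numpy.ndarray
        1-D float vector.
    k : int
        Sliding-window size used to build the vector.
    labels : tuple of str
        Component names, same length as ``values`` (the word axis).
    """

    model: str
    source_id: str
    values: np.ndarray
    k: int
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 1:
            raise ValueError("feature values must be a 1-D vector")
        if len(self.labels) != values.size:
            raise ValueError(
                f"{len(self.labels)} labels for {values.size} values"
            )
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "labels", tuple(self.labels))

    def __len__(self) -> int:
        return self.values.size


def partial_sum_entropy(x: Sequence[float]) -> float:
    """Shannon entropy (bits) of the normalised partial sums of ``x``.

    Parameters
    ----------
    x
        Non-negative sequence.  An all-zero sequence returns 0 by
        convention (the Z = 0 limit).

    Returns
    -------
    float
        ``h`` in ``[0, log2 n]`` for a length-``n`` input.

    Raises
    ------
    ValueError
        If any entry is negative.
    """
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        return 0.0
    if np.any(x < 0):
        raise ValueError("partial-sum entropy requires non-negative input")
    s = np.cumsum(x)
    z = s.sum()
    if z == 0:
        return 0.0
    p = s / z
    nz = p > 0
    return float(-np.sum(p[nz] * np.log2(p[nz])) + 0.0)  # +0.0 avoids -0.0


def local_frequencies(positions: Sequence[int]) -> list[float]:
    """Reciprocal gaps ``1 / (P_r - P_{r-1})`` with ``P_0 = 0``.

    ``positions`` must be strictly increasing positive integers; an empty
    input yields an empty output.
    """
    prev = 0
    out: list[float] = []
    for pos in positions:
        gap = pos - prev
        if gap <= 0:
            raise ValueError(
                f"occurrence positions must be strictly increasing and positive; "
                f"got {pos} after {prev}"
            )
        out.append(1.0 / gap)
        prev = pos
    return out


def embed_lf(positions: Sequence[int], m: int) -> np.ndarray:
    """Place each occurrence's LF value at its position in a length-``m`` row.

    All other entries are zero.  ``m`` is the window count of the mapped
    sequence; every position must lie in ``1..m``.
    """
    if m < 0:
        raise ValueError("window count m must be non-negative")
    lf = local_frequencies(positions)
    out = np.zeros(m, dtype=float)
    for pos, value in zip(positions, lf):
        if pos > m:
            raise ValueError(f"occurrence position {pos} exceeds window count m={m}")
        out[pos - 1] = value
    return out


def lf_entropy(positions: Sequence[int], m: int) -> float:
    """LF-based partial-sum entropy of a word's occurrence positions.

    Composition ``partial_sum_entropy(embed_lf(positions, m))``.  A word
    with no occurrences scores 0.  A single occurrence at position ``r``
    has the closed form ``log2(m - r + 1)``.
    """
    return partial_sum_entropy(embed_lf(positions, m))


def cpf_vector(record, k: int = 2, *, allow_ambiguous: bool = False) -> FeatureVector:
    """Build the CPF feature vector of a DNA sequence.

    For each category scheme (RY, MK, WS) and each of the scheme's ``2**k``
    words, the component is the LF-based entropy of the word's occurrence
    positions over the ``m = n - k + 1`` sliding windows.  At the default
    ``k = 2`` this yields 12 components in the canonical word order.

    Components are not length-normalised: each is bounded by ``log2 m`` and
    so grows slowly with sequence length, exactly as the underlying entropy
    leaves it.

    Raises
    ------
    ValueError
        If the sequence is shorter than ``k``.
    """
    residues = getattr(record, "residues", record)
    n = len(residues)
    if n < k:
        raise ValueError(
            f"sequence of length {n} is shorter than window size k={k}"
        )
    m = n - k + 1
    values: list[float] = []
    for scheme in SCHEMES:
        mapped = map_category(record, scheme, allow_ambiguous=allow_ambiguous)
        occurrences = extract_words(mapped, k)
        for word in scheme_words(scheme, k):
            values.append(lf_entropy(occurrences[word], m))
    return FeatureVector(
        model="cpf",
        source_id=getattr(record, "id", ""),
        values=np.asarray(values),
        k=k,
        labels=canonical_words(k),
    )
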