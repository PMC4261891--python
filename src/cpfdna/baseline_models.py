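"""Reference alignment-free featurisers: k-tuple, DMk and TSM.

These are the well-defined comparison models the CPF model is evaluated
against:

* **k-tuple** — relative frequency of each of the ``4**k`` DNA words over
  the ``m = n - k + 1`` sliding windows (frequency information only).
* **DMk** — the LF-based partial-sum entropy (the same operator as CPF's
  core, see :mod:`cpfdna.entropy_features`) of each DNA word's occurrence
  positions; dimension ``4**k`` (frequency + position, no categories).
* **TSM** — relative word frequencies over the three category mappings at
  window size 2; 12 dimensions in the canonical word order (frequency +
  categories, no position).
"""
from __future__ import annotations

import itertools
from functools import lru_cache

import numpy as np

from .category_mapping import SCHEMES, canonical_words, extract_words, map_category, scheme_words
from .entropy_features import FeatureVector, lf_entropy

__all__ = ["dna_words", "ktuple_vector", "dmk_vector", "tsm_vector"]

DNA_ALPHABET = "ACGT"


@lru_cache(maxsize=None)
def dna_words(k: int) -> tuple[str, ...]:
    """All ``4**k`` DNA words of length ``k``, lexicographic A < C < G < T."""
    if k < 1:
        raise ValueError("window size k must be >= 1")
    return tuple("".join(t) for t in itertools.product(DNA_ALPHABET, repeat=k))


def _dna_occurrences(residues: str, k: int) -> dict[str, list[int]]:
    """1-based window-start positions of every DNA word; windows containing
    a non-ACGT residue are skipped."""
    n = len(residues)
    if n < k:
        raise ValueError(f"sequence of length {n} is shorter than window size k={k}")
    occurrences: dict[str, list[int]] = {w: [] for w in dna_words(k)}
    for i in range(n - k + 1):
        word = residues[i : i + k]
        hits = occurrences.get(word)
        if hits is not None:
            hits.append(i + 1)
    return occurrences


def ktuple_vector(record, k: int = 3, *, counts: bool = False) -> FeatureVector:
    """Word-frequency vector over the four-letter DNA alphabet.

    Each component is ``count(w) / m`` with ``m = n - k + 1`` windows (raw
    counts with ``counts=True``); the relative-frequency form sums to 1 and
    keeps Euclidean distances comparable across sequence lengths.
    """
    residues = getattr(record, "residues", record)
    occurrences = _dna_occurrences(residues, k)
    values = np.array([len(occurrences[w]) for w in dna_words(k)], dtype=float)
    total = values.sum()
    if not counts and total > 0:
        values /= total
    return FeatureVector(
        model="ktuple",
        source_id=getattr(record, "id", ""),
        values=values,
        k=k,
        labels=dna_words(k),
    )


def dmk_vector(record, k: int = 3) -> FeatureVector:
    """LF-based entropy vector over the four-letter DNA alphabet.

    Applies the shared LF/partial-sum entropy operator to each DNA word's
    occurrence positions, over the full ``m``-window embedding — at k=2 on
    a two-letter sequence this coincides with the matching CPF scheme
    block.  Dimension ``4**k``; absent words score 0.
    """
    residues = getattr(record, "residues", record)
    occurrences = _dna_occurrences(residues, k)
    m = len(residues) - k + 1
    values = np.array(
        [lf_entropy(occurrences[w], m) for w in dna_words(k)], dtype=float
    )
    return FeatureVector(
        model="dmk",
        source_id=getattr(record, "id", ""),
        values=values,
        k=k,
        labels=dna_words(k),
    )


def tsm_vector(record, k: int = 2, *, allow_ambiguous: bool = False) -> FeatureVector:
    """Category-mapped word-frequency vector (12 dimensions at k=2).

    For each scheme, each of the ``2**k`` words scores its relative
    frequency among the scheme's counted windows, so every scheme block
    sums to 1.
    """
    residues = getattr(record, "residues", record)
    n = len(residues)
    if n < k:
        raise ValueError(f"sequence of length {n} is shorter than window size k={k}")
    values: list[float] = []
    for scheme in SCHEMES:
        mapped = map_category(record, scheme, allow_ambiguous=allow_ambiguous)
        occurrences = extract_words(mapped, k)
        block = np.array(
            [len(occurrences[w]) for w in scheme_words(scheme, k)], dtype=float
        )
        total = block.sum()
        if total > 0:
            block /= total
        values.extend(block)
    return FeatureVector(
        model="tsm",
        source_id=getattr(record, "id", ""),
        values=np.asarray(values),
        k=k,
        labels=canonical_words(k),
    )
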