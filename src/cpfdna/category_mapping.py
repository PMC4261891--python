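"""Chemical-category mappings of DNA and sliding-window word extraction.

The four nucleotide bases admit three two-class partitions by chemical
property:

* purine / pyrimidine:      R = {A, G},  Y = {C, T}
* amino / keto:             M = {A, C},  K = {G, T}
* weak / strong H-bonding:  W = {A, T},  S = {C, G}

Mapping a DNA sequence through one scheme yields a sequence over a two-letter
alphabet, shrinking the word universe for window size ``k`` from ``4**k`` to
``2**k``.  The three schemes together expose complementary structure that a
single four-letter word count misses.

Word order convention
---------------------
For each scheme the first-listed group letter sorts before the second
(R < Y, M < K, W < S) and words of length ``k`` are enumerated
lexicographically in that order.  Concatenating the schemes in the order
RY, MK, WS gives the canonical 12-word axis at ``k = 2``::

    RR RY YR YY  MM MK KM KK  WW WS SW SS

Any fixed order is equivalent under Euclidean distance; this one is normative
for file headers produced by :mod:`cpfdna.sequence_io`.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass
from types import MappingProxyType
from typing import Mapping

__all__ = [
    "CategoryScheme",
    "MappedSequence",
    "RY",
    "MK",
    "WS",
    "SCHEMES",
    "map_category",
    "scheme_words",
    "canonical_words",
    "extract_words",
]

# Symbol used for residues that no scheme can classify (IUPAC ambiguity
# codes kept under masking); windows containing it are never counted.
AMBIGUOUS_SYMBOL = "N"


@dataclass(frozen=True)
class CategoryScheme:
    """A two-class partition of {A, C, G, T}.

    Attributes
    ----------
    name : str
        Scheme identifier, one of ``"RY"``, ``"MK"``, ``"WS"``.
    alphabet : str
        The scheme's two symbols in canonical order (first < second).
    mapping : Mapping[str, str]
        Total base -> symbol substitution table.
    """

    name: str
    alphabet: str
    mapping: Mapping[str, str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "mapping", MappingProxyType(dict(self.mapping)))
        if set(self.mapping) != set("ACGT"):
            raise ValueError(f"scheme {self.name!r}: mapping must cover A,C,G,T")
        if set(self.mapping.values()) != set(self.alphabet) or len(self.alphabet) != 2:
            raise ValueError(f"scheme {self.name!r}: mapping must be two-valued")


RY = CategoryScheme("RY", "RY", {"A": "R", "G": "R", "C": "Y", "T": "Y"})
MK = CategoryScheme("MK", "MK", {"A": "M", "C": "M", "G": "K", "T": "K"})
WS = CategoryScheme("WS", "WS", {"A": "W", "T": "W", "C": "S", "G": "S"})

#: The three schemes in canonical order.
SCHEMES: tuple[CategoryScheme, ...] = (RY, MK, WS)

_SCHEMES_BY_NAME = {s.name: s for s in SCHEMES}


@dataclass(frozen=True)
class MappedSequence:
    """A DNA sequence rewritten in one scheme's two-letter alphabet."""

    scheme: str
    symbols: str
    source_id: str


def get_scheme(scheme: "CategoryScheme | str") -> CategoryScheme:
    """Resolve a scheme object or its name to the scheme object."""
    if isinstance(scheme, CategoryScheme):
        return scheme
    try:
        return _SCHEMES_BY_NAME[scheme]
    except KeyError:
        raise ValueError(
            f"unknown scheme {scheme!r}; expected one of {sorted(_SCHEMES_BY_NAME)}"
        ) from None


def map_category(
    record,
    scheme: "CategoryScheme | str",
    *,
    allow_ambiguous: bool = False,
) -> MappedSequence:
    """Substitute every base of ``record`` by its category symbol.

    Parameters
    ----------
    record
        A :class:`~cpfdna.sequence_io.DnaRecord` or a plain string of
        residues.
    scheme
        The category scheme (object or name).
    allow_ambiguous
        If true, residues outside {A, C, G, T} are carried through as
        ``"N"`` and later excluded from word counting; otherwise they raise.

    Returns
    -------
    MappedSequence
        Same length as the input; position-wise substitution.
    """
    scheme = get_scheme(scheme)
    residues = getattr(record, "residues", record)
    source_id = getattr(record, "id", "")
    table = scheme.mapping
    out = []
    for pos, base in enumerate(residues, start=1):
        sym = table.get(base)
        if sym is None:
            if allow_ambiguous:
                sym = AMBIGUOUS_SYMBOL
            else:
                raise ValueError(
                    f"invalid base {base!r} at position {pos}"
                    + (f" in record {source_id!r}" if source_id else "")
                )
        out.append(sym)
    return MappedSequence(scheme.name, "".join(out), source_id)


def scheme_words(scheme: "CategoryScheme | str", k: int = 2) -> tuple[str, ...]:
    """All ``2**k`` words of length ``k`` over one scheme's alphabet.

    Lexicographic in the scheme's canonical letter order, e.g. for RY at
    k=2: ``("RR", "RY", "YR", "YY")``.
    """
    scheme = get_scheme(scheme)
    if k < 1:
        raise ValueError("window size k must be >= 1")
    return tuple("".join(t) for t in itertools.product(scheme.alphabet, repeat=k))


def canonical_words(k: int = 2) -> tuple[str, ...]:
    """The concatenated word axis over all three schemes (12 words at k=2)."""
    return tuple(w for s in SCHEMES for w in scheme_words(s, k))


def extract_words(mapped: MappedSequence, k: int) -> dict[str, list[int]]:
    """Occurrence positions of every possible word in a mapped sequence.

    Slides a window of length ``k`` with step 1 over ``mapped.symbols``;
    the window starting at (1-based) position ``i`` covers symbols
    ``i .. i+k-1`` and there are ``m = n - k + 1`` windows.  Windows
    containing the ambiguity symbol are skipped.

    Returns
    -------
    dict
        Maps each of the scheme's ``2**k`` words to the ordered list of its
        1-based window-start positions (empty list if absent).

    Raises
    ------
    ValueError
        If ``k < 1`` or ``k`` exceeds the sequence length.
    """
    n = len(mapped.symbols)
    if k < 1:
        raise ValueError("window size k must be >= 1")
    if k > n:
        raise ValueError(f"window size k={k} exceeds sequence length n={n}")
    occurrences: dict[str, list[int]] = {w: [] for w in scheme_words(mapped.scheme, k)}
    symbols = mapped.symbols
    for i in range(n - k + 1):
        word = symbols[i : i + k]
        if AMBIGUOUS_SYMBOL in word:
            continue
        occurrences[word].append(i + 1)
    return occurrences
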