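"""Family-structured synthetic DNA datasets with known truth.

Emulates benchmark collections of homologous gene families: each of ``M``
families descends from an independent random ancestor, and each member is
the ancestor with independent point substitutions at rate ``mu`` per site.
Defaults (6 families x 20 members, 600 bp, mu = 0.03) give well-separated
families of moderate within-family divergence, the regime in which
alignment-free clustering is typically benchmarked.

Optionally, single-base indels emulate length variation between members,
and a GC bias skews base composition for harder cases.  The generator is
fully determined by its seed.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .sequence_io import DnaRecord

__all__ = ["SimulationConfig", "generate_families"]

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one synthetic dataset.

    Attributes
    ----------
    families : int
        Number of families ``M`` (>= 1).
    members : int
        Members per family (>= 1).
    length : int or (int, int)
        Ancestor length in bases, or an inclusive range from which each
        family's ancestor length is drawn uniformly.
    mutation_rate : float
        Per-site substitution probability ``mu`` in [0, 1]; a substituted
        site always changes to a different base.
    indel_rate : float
        Per-site probability of a single-base insertion or deletion
        (half each); default 0 keeps all lengths equal to the ancestor's.
    gc : float
        GC fraction of the ancestor base composition; 0.5 is uniform.
    seed : int
        Seed for the dataset's random generator.
    """

    families: int = 6
    members: int = 20
    length: "int | tuple[int, int]" = 600
    mutation_rate: float = 0.03
    indel_rate: float = 0.0
    gc: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.families < 1:
            raise ValueError("families must be >= 1")
        if self.members < 1:
            raise ValueError("members must be >= 1")
        lo, hi = self._length_range()
        if lo < 2 or hi < lo:
            raise ValueError("length must be >= 2 (and a non-empty range)")
        if not 0.0 <= self.mutation_rate <= 1.0:
            raise ValueError("mutation_rate must be in [0, 1]")
        if not 0.0 <= self.indel_rate <= 1.0:
            raise ValueError("indel_rate must be in [0, 1]")
        if not 0.0 < self.gc < 1.0:
            raise ValueError("gc must be in (0, 1)")

    def _length_range(self) -> tuple[int, int]:
        if isinstance(self.length, tuple):
            lo, hi = self.length
            return int(lo), int(hi)
        return int(self.length), int(self.length)


def _base_probabilities(gc: float) -> np.ndarray:
    at = (1.0 - gc) / 2.0
    return np.array([at, gc / 2.0, gc / 2.0, at])  # A, C, G, T


def _mutate(ancestor: np.ndarray, mu: float, rng: np.random.Generator) -> np.ndarray:
    """Substitute each site independently with probability ``mu`` to a
    uniformly chosen *different* base (bases encoded 0..3)."""
    child = ancestor.copy()
    mask = rng.random(child.size) < mu
    if mask.any():
        child[mask] = (child[mask] + rng.integers(1, 4, size=int(mask.sum()))) % 4
    return child


def _apply_indels(seq: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    out: list[int] = []
    for base in seq:
        u = rng.random()
        if u < rate / 2.0:
            continue  # deletion
        if u < rate:
            out.append(int(rng.integers(4)))  # insertion before the base
        out.append(int(base))
    if len(out) < 2:  # degenerate: keep the sequence usable
        out = [int(b) for b in seq[:2]]
    return np.asarray(out, dtype=seq.dtype)


def _to_string(encoded: np.ndarray) -> str:
    return _BASES[encoded].tobytes().decode("ascii")


def generate_families(config: SimulationConfig) -> tuple[list[DnaRecord], dict[str, str]]:
    """Draw a family-structured dataset and its truth labels.

    Returns
    -------
    (records, truth)
        ``records`` in family order with ids ``F<i>_S<j>``; ``truth`` maps
        each id to its family label ``F<i>``.  The same config (including
        seed) always returns an identical dataset.
    """
    rng = np.random.default_rng(config.seed)
    probs = _base_probabilities(config.gc)
    lo, hi = config._length_range()
    records: list[DnaRecord] = []
    truth: dict[str, str] = {}
    for i in range(config.families):
        length = int(rng.integers(lo, hi + 1)) if hi > lo else lo
        ancestor = rng.choice(4, size=length, p=probs)
        label = f"F{i:02d}"
        for j in range(config.members):
            member = _mutate(ancestor, config.mutation_rate, rng)
            if config.indel_rate > 0:
                member = _apply_indels(member, config.indel_rate, rng)
            seq_id = f"{label}_S{j:03d}"
            records.append(DnaRecord(seq_id, _to_string(member)))
            truth[seq_id] = label
    return records, truth
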