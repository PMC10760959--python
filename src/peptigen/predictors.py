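"""MHC I binding-rank predictors.

The pipeline only needs the eluted-ligand percentile rank of a
(peptide, allele) pair; anything that maps such a pair to a rank in
[0, 100) deterministically satisfies the interface. Two implementations
ship with the package: a stable hash-based mock (uniform ranks,
reproducible across platforms, with optional planted overrides) and a
dictionary-backed predictor for fully specified rank tables. An adapter
for an external predictor such as NetMHCpan can be plugged in by
implementing ``predict``.
"""

from __future__ import annotations

import hashlib
from typing import Iterable, Mapping, Protocol, runtime_checkable

__all__ = ["BindingPredictor", "MockBindingPredictor", "DictBindingPredictor", "min_rank"]

RANK_CUTOFF = 2.0  # percentile rank below which a peptide counts as a binder


@runtime_checkable
class BindingPredictor(Protocol):
    def predict(self, peptide: str, allele: str) -> float:
        """Percentile rank of (peptide, allele) in [0, 100); deterministic."""
        ...


class MockBindingPredictor:
    """Rank from a stable hash of (peptide, allele), uniform on [0, 100).

    Deterministic across runs and platforms (SHA-256, not Python's
    salted ``hash``). ``overrides`` plants exact ranks for chosen pairs
    so tests can force binders or non-binders.
    """

    def __init__(self, overrides: Mapping[tuple[str, str], float] | None = None):
        self.overrides = dict(overrides or {})

    def predict(self, peptide: str, allele: str) -> float:
        key = (peptide, allele)
        if key in self.overrides:
            return self.overrides[key]
        digest = hashlib.sha256(f"{peptide}|{allele}".encode()).digest()
        frac = int.from_bytes(digest[:8], "big") / 2**64
        return 100.0 * frac


class DictBindingPredictor:
    """Ranks from an explicit table; unknown pairs get ``default``."""

    def __init__(self, ranks: Mapping[tuple[str, str], float], default: float = 50.0):
        self.ranks = dict(ranks)
        self.default = default

    def predict(self, peptide: str, allele: str) -> float:
        return self.ranks.get((peptide, allele), self.default)


def min_rank(
    predictor: BindingPredictor, peptide: str, alleles: Iterable[str]
) -> tuple[float, str]:
    """Best (lowest) rank over the alleles and the allele achieving it."""
    best_rank = float("inf")
    best_allele = ""
    for allele in alleles:
        r = predictor.predict(peptide, allele)
        if r < best_rank:
            best_rank, best_allele = r, allele
    return best_rank, best_allele
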