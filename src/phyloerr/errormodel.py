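"""Sequencing-error-adjusted tip likelihoods.

A base is assumed to be miscalled as one of the three other bases, each with
probability ``epsilon / 3`` (uniform miscall model).  Ambiguity codes are
taken to arise *after* the error process: an observation of M (A or C) given
true base A can come from a correct call of A or a miscall to C, so its tip
value is ``1 - epsilon + epsilon/3 = 1 - 2*epsilon/3``.

In general, for an observed symbol whose resolution set S has k bases, the
tip vector holds

* ``1 - epsilon + (k - 1) * epsilon / 3``  for true bases inside S,
* ``k * epsilon / 3``                       for true bases outside S.

These are probabilities of the observation given the true base; they need not
sum to one (an N yields (1, 1, 1, 1)).  ``epsilon`` must lie in [0, 0.75):
at 0.75 every call would be uniformly random and the model carries no
information.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

from .substmodel import BASES

_EPS_MAX = 0.75

#: resolution set of every accepted symbol (uppercase; U accepted as T's RNA form)
AMBIGUITY_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "U": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
    "-": frozenset("ACGT"),
    "?": frozenset("ACGT"),
}


def ambiguity_set(symbol: str) -> frozenset[str]:
    """Resolution set of an IUPAC symbol; N, '-' and '?' resolve to all four bases.

    Case-insensitive.  Raises ``ValueError`` for symbols outside the alphabet.
    """
    try:
        return AMBIGUITY_SETS[symbol.upper()]
    except (KeyError, AttributeError):
        raise ValueError(f"unknown nucleotide symbol {symbol!r}") from None


def _check_epsilon(epsilon) -> None:
    if not (0.0 <= epsilon < _EPS_MAX):
        raise ValueError(f"epsilon must lie in [0, {_EPS_MAX}), got {epsilon!r}")


def tip_vector(symbol: str, epsilon) -> np.ndarray:
    """Tip likelihood 4-vector ``v[x] = Pr(observed symbol | true base x)``.

    Order (A, C, G, T).  ``epsilon`` may be any scalar supporting arithmetic
    (a float, or e.g. a symbolic quantity), as long as a float comparison with
    the valid range is possible.
    """
    if isinstance(epsilon, (int, float)):
        _check_epsilon(epsilon)
    s = ambiguity_set(symbol)
    k = len(s)
    inside = 1 - epsilon + (k - 1) * epsilon / 3
    outside = k * epsilon / 3
    return np.asarray([inside if base in s else outside for base in BASES])


@dataclass(frozen=True)
class ErrorSpec:
    """Declared (or true) miscall rate, global with optional per-taxon overrides."""

    epsilon: float = 0.0
    per_taxon: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        _check_epsilon(self.epsilon)
        for taxon, eps in self.per_taxon.items():
            if not taxon:
                raise ValueError("per-taxon override with empty taxon name")
            _check_epsilon(eps)

    def rate_for(self, taxon: str) -> float:
        """Effective epsilon for one taxon (override if present, else global)."""
        return self.per_taxon.get(taxon, self.epsilon)

    def validate_taxa(self, taxon_names: Iterable[str]) -> None:
        """Raise if a per-taxon override names a taxon absent from the data."""
        known = set(taxon_names)
        unknown = sorted(set(self.per_taxon) - known)
        if unknown:
            raise ValueError(f"per-taxon error rates name unknown taxa: {unknown}")

    def is_uniform_zero(self) -> bool:
        return self.epsilon == 0.0 and all(v == 0.0 for v in self.per_taxon.values())


def tip_partials(sequence: str, taxon: str, spec: ErrorSpec) -> np.ndarray:
    """Per-site tip vectors for one sequence, shape (n_sites, 4).

    Uses the taxon's effective epsilon from ``spec``.
    """
    eps = spec.rate_for(taxon)
    cache = {sym: tip_vector(sym, eps) for sym in set(sequence)}
    return np.array([cache[sym] for sym in sequence], dtype=float)
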