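"""Target segments, uniform random fragmentation and fragment concentrations.

The labelled target is fragmented uniformly at random: every inter-base
junction is cut independently with probability ``p``, so fragment lengths are
geometric with mean ``mu = 1/p``.  For a segment at overall concentration
``C`` the concentration of the specific fragment starting after base ``i``
and of length ``j`` is

    C_ij = C * p^2 * q^(j-1),        q = 1 - p

(cuts at both flanking junctions, none of the ``j-1`` internal ones).  A
fragment with a cut at one end that runs past the far end of the probe is
aggregated over its unseen extension,

    C_i  = C * p * q^j,

and a fragment running past both probe ends carries ``C * q^(j+1)``.  On a
finite segment the aggregated classes are evaluated with the finite-tail
factor ``(1 - q^E)``, ``E`` being the number of bases actually available for
the extension, which makes them exactly equal to summing the enumerable
fragments (see :mod:`probeforest.hybridization`).

Coordinates are 1-based and inclusive in all file formats: ``i`` is the index
of the last base before the leading cut plus one, i.e. the first base of the
fragment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

__all__ = [
    "TargetSegment",
    "FragmentationModel",
    "cut_probability",
    "fragment_concentration",
    "tail_concentration",
    "both_open_concentration",
    "enumerate_subsequences",
    "sample_fragment_lengths",
]

_DNA = set("ACGT")


@dataclass
class TargetSegment:
    """A target DNA segment (forward strand) with a relative concentration."""

    id: str
    sequence: str
    concentration_C: float = 1.0

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if len(self.sequence) < 2:
            raise ValueError(f"segment {self.id!r}: length must be >= 2")
        bad = set(self.sequence) - _DNA
        if bad:
            raise ValueError(f"segment {self.id!r}: non-ACGT characters {sorted(bad)}")
        if self.concentration_C < 0:
            raise ValueError(f"segment {self.id!r}: negative concentration")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class FragmentationModel:
    """Per-junction cut probability ``p`` with ``p = 1/mu`` and ``q = 1-p``."""

    mean_fragment_size_mu: float
    cut_probability_p: float = field(init=False)
    q: float = field(init=False)

    def __post_init__(self) -> None:
        mu = self.mean_fragment_size_mu
        if mu < 1:
            raise ValueError("mean fragment size must be >= 1 base")
        object.__setattr__(self, "cut_probability_p", 1.0 / mu)
        object.__setattr__(self, "q", 1.0 - 1.0 / mu)


def cut_probability(mu: float) -> FragmentationModel:
    """Fragmentation model for a mean fragment length of ``mu`` bases."""
    return FragmentationModel(mean_fragment_size_mu=mu)


def _check_j(j: int) -> None:
    if j < 1:
        raise ValueError("fragment length j must be >= 1")


def fragment_concentration(C: float, model: FragmentationModel, j: int) -> float:
    """Concentration of a fully cut-delimited fragment of length ``j``.

    C * p^2 * q^(j-1); independent of position under uniform cutting.
    """
    _check_j(j)
    p, q = model.cut_probability_p, model.q
    return C * p * p * q ** (j - 1)


def tail_concentration(C: float, model: FragmentationModel, j: int) -> float:
    """Aggregate concentration of fragments cut at one end and extending at
    least ``j`` bases without a cut (far end unobserved): C * p * q^j."""
    _check_j(j)
    p, q = model.cut_probability_p, model.q
    return C * p * q**j


def both_open_concentration(C: float, model: FragmentationModel, j: int) -> float:
    """Aggregate concentration of fragments spanning ``j`` observed bases and
    extending past both ends: C * q^(j+1)."""
    _check_j(j)
    return C * model.q ** (j + 1)


def enumerate_subsequences(
    segment: TargetSegment | str, min_len: int = 2
) -> Iterator[tuple[int, int]]:
    """All (start_i, length_j) subsequences with j >= min_len, 1-based.

    Yields each subsequence exactly once; for ``min_len == 2`` the count is
    (L-1) * L / 2.  A segment shorter than ``min_len`` yields nothing.
    """
    seq = segment.sequence if isinstance(segment, TargetSegment) else segment
    L = len(seq)
    for i in range(1, L + 1):
        for j in range(min_len, L - i + 2):
            yield i, j


def sample_fragment_lengths(
    model: FragmentationModel, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw ``n`` fragment lengths from the geometric cut process."""
    return rng.geometric(model.cut_probability_p, size=n)
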