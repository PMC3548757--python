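"""Probe synthesis-error model: truncations, abasic sites, variant weighting.

Light-directed synthesis proceeds from the 3' end (base 1 = 3'-most).  Each
base incorporates correctly with a base-specific probability (A_S..T_S); a
failure terminates growth, leaving a 3'-anchored prefix ("truncation").  An
incorporated base is later retained with probability A_B..T_B, otherwise the
backbone survives without the base ("abasic site").  A spot is therefore a
mixture of the full-length probe and error variants; probes with two or more
errors are assumed not to bind (occupancy zero), so only the zero- and
one-error variants are enumerated:

    p_F          = prod(S_b) * prod(B_b)                 (full length)
    p_abasic(m)  = p_F * (1 - B_m) / B_m                 (one abasic at m)
    p_trunc(m)   = prod_{b<m}(S_b * B_b) * (1 - S_m)     (growth stops at m)

The residual mass 1 - sum(emitted) is the >= 2-error class and carries
occupancy zero.  The spot-level occupancy is the probability-weighted mean
alpha = sum_x p_x * alpha_x.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn_thermo import ABASIC

__all__ = [
    "SynthesisModel",
    "ProbeVariant",
    "full_length_probability",
    "variant_set",
    "effective_alpha",
]

_BASES = "ACGT"


@dataclass(frozen=True)
class SynthesisModel:
    """Per-base incorporation (S) and base-retention (B) probabilities."""

    incorporation: dict[str, float]
    retention: dict[str, float]

    def __post_init__(self) -> None:
        for name, table in (("incorporation", self.incorporation), ("retention", self.retention)):
            for b in _BASES:
                if b not in table:
                    raise ValueError(f"{name} probability missing for base {b}")
                if not 0.0 <= table[b] <= 1.0:
                    raise ValueError(f"{name}[{b}]={table[b]} outside [0, 1]")

    @classmethod
    def uniform(cls, s: float = 1.0, b: float = 1.0) -> "SynthesisModel":
        return cls({x: s for x in _BASES}, {x: b for x in _BASES})

    @classmethod
    def from_vectors(cls, s: np.ndarray, b: np.ndarray) -> "SynthesisModel":
        """Build from length-4 vectors ordered A, C, G, T."""
        return cls(dict(zip(_BASES, map(float, s))), dict(zip(_BASES, map(float, b))))

    def as_vectors(self) -> tuple[np.ndarray, np.ndarray]:
        return (
            np.array([self.incorporation[b] for b in _BASES]),
            np.array([self.retention[b] for b in _BASES]),
        )


@dataclass
class ProbeVariant:
    """One member of a spot's probe mixture.

    ``variant_class`` is "full", "truncated_at_m", "abasic_at_m" or
    "residual" (the aggregated >= 2-error mass, occupancy zero).  ``m``
    counts from the 3' end, base 1 = 3'-most.  ``sequence`` is written
    5'->3', with ``_`` marking the abasic position; the residual class has no
    sequence.
    """

    variant_class: str
    sequence: str | None
    probability: float
    m: int | None = None
    alpha: float | None = None


def _check_seq(probe_seq: str) -> None:
    bad = set(probe_seq) - set(_BASES)
    if bad:
        raise ValueError(f"non-ACGT character(s) {sorted(bad)} in probe sequence")


def full_length_probability(probe_seq: str, model: SynthesisModel) -> float:
    """p_F: every base incorporated and retained; depends only on base counts."""
    _check_seq(probe_seq)
    p = 1.0
    for b in probe_seq:
        p *= model.incorporation[b] * model.retention[b]
    return p


def variant_set(probe_seq: str, model: SynthesisModel) -> list[ProbeVariant]:
    """Zero- and one-error variants of a probe with their probabilities.

    Probabilities of the emitted variants plus the residual sum to one
    exactly.  Synthesis numbering starts at the 3' end: truncation at m
    keeps bases 1..m-1 (the last m-1 characters of the 5'->3' string), an
    abasic at m blanks the character at 5'->3' index len-m.
    """
    _check_seq(probe_seq)
    n = len(probe_seq)
    by_pos = probe_seq[::-1]  # index 0 = synthesis base 1 = 3'-most
    s = np.array([model.incorporation[b] for b in by_pos])
    b = np.array([model.retention[b] for b in by_pos])

    p_f = float(np.prod(s * b))
    variants = [ProbeVariant("full", probe_seq, p_f)]

    # prefix products of (S_b * B_b) over bases 1..m-1
    prefix = np.concatenate([[1.0], np.cumprod(s * b)])
    for m in range(1, n + 1):
        p_trunc = float(prefix[m - 1] * (1.0 - s[m - 1]))
        seq = probe_seq[n - (m - 1) :] if m > 1 else ""
        variants.append(ProbeVariant(f"truncated_at_{m}", seq, p_trunc, m=m))

    for m in range(1, n + 1):
        # direct product form; equals p_F * (1 - B_m) / B_m whenever B_m > 0
        others = np.prod(np.delete(s * b, m - 1))
        p_ab = float(others * s[m - 1] * (1.0 - b[m - 1]))
        seq = probe_seq[: n - m] + ABASIC + probe_seq[n - m + 1 :]
        variants.append(ProbeVariant(f"abasic_at_{m}", seq, p_ab, m=m))

    emitted = sum(v.probability for v in variants)
    if emitted > 1.0 + 1e-9:
        raise ValueError("emitted variant probabilities exceed 1")
    variants.append(ProbeVariant("residual", None, max(0.0, 1.0 - emitted), alpha=0.0))
    return variants


def effective_alpha(variants: list[ProbeVariant]) -> float:
    """Probability-weighted occupancy alpha = sum_x p_x * alpha_x.

    The residual class contributes zero.  Every non-residual variant must
    have its ``alpha`` filled in [0, 1].
    """
    total = 0.0
    for v in variants:
        if v.variant_class == "residual":
            continue
        if v.alpha is None or not 0.0 <= v.alpha <= 1.0:
            raise ValueError(
                f"variant {v.variant_class}: alpha must be filled and within [0, 1]"
            )
        total += v.probability * v.alpha
    return total
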