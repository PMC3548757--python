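"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written for clarity, not speed: plain Python loops that
materialize every concrete fragment, alignment or synthesis state.  The
oracles deliberately avoid the vectorized scoring and table machinery; they
only rely on the scalar :func:`probeforest.delta_g` reference path (itself
cross-checked position by position in the nn_thermo tests).
"""

from __future__ import annotations

import itertools

from probeforest import (
    DuplexAlignment,
    FragmentationModel,
    TargetSegment,
    delta_g,
    enumerate_subsequences,
    keq,
    revcomp,
)


def brute_fraction_bound(
    probe: str,
    segments: list[TargetSegment],
    concentrations: dict[str, float],
    frag: FragmentationModel,
    wash_threshold: float,
    params,
    temp: float,
    na: float = 1.0,
) -> float:
    """Langmuir occupancy by materializing every fragment at every offset.

    Every subsequence of every segment (both strands) of length >= 2, at
    concentration C p^2 q^(j-1), is aligned at every offset with at least
    two paired (non-abasic) bases; overhangs past the probe ends are
    unpaired.  The washed numerator keeps K_eq >= threshold; the
    denominator keeps everything.
    """
    p, q = frag.cut_probability_p, frag.q
    num = den = 0.0
    for seg in segments:
        C = concentrations[seg.id]
        for presented in (seg.sequence, revcomp(seg.sequence)):
            for i, j in enumerate_subsequences(presented):
                fragment = presented[i - 1 : i - 1 + j]
                c_ij = C * p * p * q ** (j - 1)
                for offset in range(2, len(probe) + j - 1):
                    try:
                        aln = DuplexAlignment(probe, fragment, offset_k=offset)
                    except ValueError:
                        continue
                    k_eq = keq(delta_g(aln, params, temp, na), temp)
                    den += c_ij * k_eq
                    if k_eq >= wash_threshold:
                        num += c_ij * k_eq
    return num / (den + 1.0)


def brute_variant_probabilities(probe_seq: str, model) -> dict[str, float]:
    """Synthesis-outcome masses from the exhaustive 3^L per-base state space.

    Each synthesis position (1 = 3'-most) is ok / abasic / fail; a fail
    truncates everything 5' of it.  States are collapsed into the classes
    the one-error model emits: full, truncated_at_m, abasic_at_m, residual
    (>= 2 errors).
    """
    by_pos = probe_seq[::-1]
    s = [model.incorporation[b] for b in by_pos]
    b = [model.retention[b] for b in by_pos]
    n = len(by_pos)
    out: dict[str, float] = {}
    for states in itertools.product("oaf", repeat=n):
        prob = 1.0
        trunc_at = None
        abasic_at = []
        for m in range(n):  # synthesis proceeds 3' -> 5'
            st = states[m]
            if st == "f":
                prob *= 1.0 - s[m]
                trunc_at = m + 1
                # states above a truncation are vacuous; count each once
                if any(x != "o" for x in states[m + 1 :]):
                    prob = 0.0
                break
            prob *= s[m]
            if st == "a":
                prob *= 1.0 - b[m]
                abasic_at.append(m + 1)
            else:
                prob *= b[m]
        if prob == 0.0:
            continue
        n_err = (1 if trunc_at is not None else 0) + len(abasic_at)
        if n_err == 0:
            key = "full"
        elif trunc_at is not None and not abasic_at:
            key = f"truncated_at_{trunc_at}"
        elif trunc_at is None and len(abasic_at) == 1:
            key = f"abasic_at_{abasic_at[0]}"
        else:
            key = "residual"
        out[key] = out.get(key, 0.0) + prob
    return out
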