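"""Exhaustive probe/fragment K_eq tables and washed competitive occupancy.

A probe spot is a "forest" of identical oligos exposed to every fragment of
every target segment.  For one probe variant this module enumerates, for both
target strands, every gapless alignment of a fragment against the probe with
at least two paired bases, scores it with the nearest-neighbor model and
stores the equilibrium constant.  The fraction of probes carrying bound
target at equilibrium follows the competitive Langmuir isotherm

    alpha = sum(C * K_eq restricted to K_eq >= K_eqW) / (sum(C * K_eq) + 1)

where the wash is a hard K_eq threshold that empties the numerator of weak
complexes while the denominator keeps every complex, and each alignment's C
comes from the geometric fragmentation law (:mod:`probeforest.fragments`).

Enumeration is collapsed over unseen overhangs: alignments are indexed by the
*paired window* (the contiguous run of target bases opposite probe
positions).  A window whose edge reaches a probe end stands for every
concrete fragment extending past that end; its aggregated concentration is
the geometric tail sum with a finite-segment factor (1 - q^E), so the
collapsed table equals a brute-force enumeration of every concrete fragment
at every offset exactly, also on short segments.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd

from .fragments import FragmentationModel, TargetSegment
from .nn_thermo import (
    R_GAS,
    InvalidAlignmentError,
    NNParameterSet,
    ParameterTableError,
    encode,
    revcomp,
)

__all__ = ["KeqTable", "WashModel", "build_keq_table", "fraction_bound", "score_windows"]

_EXP_CLAMP = 700.0

TAIL_CLASSES = ("both_cut", "right_open", "left_open", "both_open")


@dataclass(frozen=True)
class WashModel:
    """Post-hybridization wash as a K_eq threshold; 0 disables the wash."""

    keq_threshold_KeqW: float = 0.0

    def __post_init__(self) -> None:
        if self.keq_threshold_KeqW < 0:
            raise ValueError("wash K_eq threshold must be >= 0")


@dataclass
class WindowSet:
    """Flat arrays describing every scored alignment window (0-based)."""

    keq: np.ndarray        # equilibrium constant per window
    jp: np.ndarray         # paired-window length (bases)
    i0: np.ndarray         # target start of the paired window on the presented strand
    k0: np.ndarray         # probe start of the paired window (5' side)
    at_left: np.ndarray    # window edge reaches probe position 1 (5' end)
    at_right: np.ndarray   # window edge reaches the probe 3' end
    target_len: int
    probe_len: int
    unparameterized_steps: int  # adjacent-double-mismatch steps scored as (0, 0)


@dataclass(frozen=True)
class _Geometry:
    """Precomputed alignment geometry for (probe length P, target length L).

    Windows are laid out in a dense (diagonal, length-offset, start) cube of
    shape (nd, maxn-1, maxn-1); ``flatidx`` gathers the valid windows from
    the raveled cube in a fixed order aligned with the flat coordinate
    arrays (``jp_all`` ascending, then diagonal, then start).
    """

    X: np.ndarray          # probe index per (diagonal, r); clipped in padding
    Y: np.ndarray          # target index per (diagonal, r)
    nd: np.ndarray         # usable length of each diagonal
    maxn: int              # longest diagonal = min(P, L)
    base: np.ndarray       # (O, W) gather index r1 + o, clipped
    flatidx: np.ndarray    # valid-window gather into the raveled cube
    jp_all: np.ndarray
    a_all: np.ndarray      # probe window start per valid window
    i0_all: np.ndarray     # target window start per valid window
    at_left: np.ndarray
    at_right: np.ndarray


@lru_cache(maxsize=512)
def _geometry(P: int, L: int) -> _Geometry:
    ds, xmins, nds = [], [], []
    for d in range(1, P + L - 2):
        xmin = max(0, d - L + 1)
        xmax = min(P - 1, d)
        n = xmax - xmin + 1
        if n >= 2:
            ds.append(d)
            xmins.append(xmin)
            nds.append(n)
    d_arr = np.array(ds)[:, None]
    xmin_arr = np.array(xmins)[:, None]
    nd = np.array(nds)
    maxn = int(nd.max())
    r = np.arange(maxn)[None, :]
    X = np.minimum(xmin_arr + r, xmin_arr + (nd[:, None] - 1))
    Y = d_arr - X

    O = W = maxn - 1
    base = np.minimum(np.arange(1, maxn)[:, None] + np.arange(W)[None, :], maxn - 1)
    flat, jps, aas, i0s, n_diag = [], [], [], [], len(nd)
    for jp in range(2, maxn + 1):
        o = jp - 2
        for di in range(n_diag):
            ncol = nd[di] - jp + 1
            if ncol <= 0:
                continue
            r1 = np.arange(ncol)
            flat.append(di * (O * W) + o * W + r1)
            a = X[di, 0] + r1
            aas.append(a)
            i0s.append((X[di, 0] + Y[di, 0]) - a - (jp - 1))
            jps.append(np.full(ncol, jp))
    jp_all = np.concatenate(jps) if jps else np.empty(0, np.int64)
    a_all = np.concatenate(aas) if aas else np.empty(0, np.int64)
    return _Geometry(
        X=X,
        Y=Y,
        nd=nd,
        maxn=maxn,
        base=base,
        flatidx=np.concatenate(flat) if flat else np.empty(0, np.int64),
        jp_all=jp_all.astype(np.int64),
        a_all=a_all.astype(np.int64),
        i0_all=(np.concatenate(i0s) if i0s else np.empty(0)).astype(np.int64),
        at_left=a_all == 0,
        at_right=a_all + jp_all - 1 == P - 1,
    )


def score_windows(
    probe_codes: np.ndarray,
    target_codes: np.ndarray,
    params: NNParameterSet,
    temp: float,
    na: float = 1.0,
) -> WindowSet:
    """Score every alignment window of a probe variant against one target strand.

    ``probe_codes`` encodes the variant 5'->3' (abasic = 4, at most one per
    variant); ``target_codes`` encodes the presented target strand 5'->3'.
    Windows with fewer than two paired non-abasic positions are excluded.
    Vectorized counterpart of :func:`probeforest.nn_thermo.delta_g`.
    """
    P, L = len(probe_codes), len(target_codes)
    if P < 2:
        raise InvalidAlignmentError("probe shorter than 2 bases")
    arr = params.as_arrays()
    geo = _geometry(P, L)
    X, Y, nd, maxn = geo.X, geo.Y, geo.nd, geo.maxn
    qx = probe_codes[X]
    ty = target_codes[Y]

    idx = (qx[:, :-1], qx[:, 1:], ty[:, :-1], ty[:, 1:])
    step_valid = np.arange(maxn - 1)[None, :] < (nd[:, None] - 1)
    if arr.missing.any() and np.any(arr.missing[idx] & step_valid):
        di, r = np.argwhere(arr.missing[idx] & step_valid)[0]
        bases = "ACGT_"
        step = (
            f"{bases[qx[di, r]]}{bases[qx[di, r + 1]]}/"
            f"{bases[ty[di, r]]}{bases[ty[di, r + 1]]}"
        )
        raise ParameterTableError(f"no NN table entry for step {step}")
    n_unparam = (
        int(np.sum(arr.unparameterized[idx] & step_valid))
        if arr.unparameterized.any()
        else 0
    )

    # pack dH (real) and dS (imag) so one cumsum/gather serves both
    step_hs = (arr.step_h[idx] + 1j * arr.step_s[idx]) * step_valid
    cs = np.concatenate(
        [np.zeros((len(nd), 1), complex), np.cumsum(step_hs, axis=1)], axis=1
    )
    # initiation value of the pair at each diagonal position (nd, maxn)
    pX = arr.init_h[qx, ty] + 1j * arr.init_s[qx, ty]

    # dense cube over (diagonal, window length offset o = jp-2, start r1)
    cube = cs[:, geo.base] - cs[:, None, : maxn - 1]
    init_c = pX[:, None, : maxn - 1] + pX[:, geo.base]  # pinit[a] + pinit[b]

    abasic_idx = np.flatnonzero(probe_codes == 4)
    if len(abasic_idx) > 1:
        raise InvalidAlignmentError("at most one abasic mark per variant is supported")
    x_m = int(abasic_idx[0]) if len(abasic_idx) else -1

    ln_na = float(np.log(na))
    rt = R_GAS * temp
    jp_all, a_all, i0_all = geo.jp_all, geo.a_all, geo.i0_all
    at_left, at_right = geo.at_left, geo.at_right

    if x_m >= 0:
        r_m_flat = np.where(
            (X[:, 0] <= x_m) & (x_m <= X[:, 0] + nd - 1), x_m - X[:, 0], -(10**9)
        )
        r_m = r_m_flat[:, None, None]
        r1v = np.arange(maxn - 1)[None, None, :]
        ov = np.arange(maxn - 1)[None, :, None]
        contains = (r1v <= r_m) & (r_m <= r1v + ov + 1)
        l_run = r_m - r1v
        r_run = (r1v + ov + 1) - r_m
        # pair-initiation values at the positions flanking the abasic mark,
        # per diagonal (the partner base differs between diagonals)
        rm_minus = np.clip(r_m_flat - 1, 0, maxn - 1)[:, None]
        rm_plus = np.clip(r_m_flat + 1, 0, maxn - 1)[:, None]
        p_before = np.take_along_axis(pX, rm_minus, axis=1)[:, :, None]
        p_after = np.take_along_axis(pX, rm_plus, axis=1)[:, :, None]
        init_ab = np.where(
            contains & (l_run >= 2), pX[:, None, : maxn - 1] + p_before, 0
        )
        init_ab = init_ab + np.where(
            contains & (r_run >= 2), p_after + pX[:, geo.base], 0
        )
        cube = cube + np.where(contains, init_ab, init_c)
        dg = cube.real - temp * cube.imag
        if ln_na != 0.0:
            nsteps = np.where(
                contains,
                np.maximum(l_run - 1, 0) + np.maximum(r_run - 1, 0),
                ov + 1,
            )
            dg = dg + arr.salt_coeff * nsteps * ln_na
        dg_all = dg.ravel()[geo.flatidx]
        # drop 2-windows straddling the abasic mark: one non-abasic pair left
        bad = (jp_all == 2) & ((a_all == x_m - 1) | (a_all == x_m))
        keep = ~bad
        jp_all, a_all, i0_all = jp_all[keep], a_all[keep], i0_all[keep]
        at_left, at_right = at_left[keep], at_right[keep]
        dg_all = dg_all[keep]
    else:
        cube = cube + init_c
        dg = cube.real - temp * cube.imag
        dg_all = dg.ravel()[geo.flatidx]
        if ln_na != 0.0:
            dg_all = dg_all + arr.salt_coeff * (jp_all - 1) * ln_na

    keq_all = np.exp(np.clip(-dg_all / rt, -_EXP_CLAMP, _EXP_CLAMP))
    return WindowSet(
        keq=keq_all,
        jp=jp_all,
        i0=i0_all,
        k0=a_all,
        at_left=at_left,
        at_right=at_right,
        target_len=L,
        probe_len=P,
        unparameterized_steps=n_unparam,
    )


@dataclass
class KeqTable:
    """All scored alignments of one probe variant against a set of segments.

    ``entries`` columns (1-based coordinates on the presented strand):
    segment, strand ("forward"/"reverse"), i (paired-window start), j
    (paired-window length), k (probe position of the fragment's first paired
    base, i.e. the 3'-side window edge), tail_class, keq.
    """

    probe_variant_id: str
    entries: pd.DataFrame
    seg_lengths: dict[str, int]
    temperature_k: float
    na_molar: float
    unparameterized_steps: int = 0

    def __post_init__(self) -> None:
        if len(self.entries):
            if (self.entries["keq"] <= 0).any():
                raise ValueError("all K_eq values must be positive")
            key = ["segment", "strand", "i", "j", "k", "tail_class"]
            if self.entries.duplicated(key).any():
                raise ValueError("duplicate (segment, strand, i, j, k, tail_class) entry")


def build_keq_table(
    probe_variant: str,
    segments: list[TargetSegment],
    params: NNParameterSet,
    temp: float,
    na: float = 1.0,
    prune: float = 1e-12,
    allow_left_overhang: bool = True,
    probe_variant_id: str | None = None,
) -> KeqTable:
    """Exhaustively score one probe variant against all fragments of all segments.

    Every segment is scanned on both strands (the reverse presentation is the
    reverse complement); every paired window of >= 2 bases is an entry, with
    tail classes emitted for windows whose edge reaches a probe end and whose
    segment actually continues beyond it.  ``prune`` drops entries whose K_eq
    falls below ``prune`` times the table maximum (K_eq is the only
    fragmentation-independent part of the C*K_eq contribution available at
    build time); ``prune=0`` guarantees exhaustive output.
    ``allow_left_overhang=False`` suppresses the classes in which the
    fragment dangles past the probe's 5' (left) end.
    """
    if not segments:
        raise ValueError("at least one target segment is required")
    if len(probe_variant) < 2:
        raise InvalidAlignmentError("probe shorter than 2 bases after truncation")
    probe_codes = encode(probe_variant)
    rows: list[pd.DataFrame] = []
    n_unparam = 0
    for seg in segments:
        for strand in ("forward", "reverse"):
            presented = seg.sequence if strand == "forward" else revcomp(seg.sequence)
            ws = score_windows(probe_codes, encode(presented), params, temp, na)
            n_unparam += ws.unparameterized_steps
            L = ws.target_len
            avail_lo = ws.i0                       # bases below the window on the target
            avail_hi = L - ws.i0 - ws.jp           # bases above the window
            emit = {
                "both_cut": np.ones(len(ws.keq), dtype=bool),
                "right_open": ws.at_right & (avail_lo >= 1),
                "left_open": ws.at_left & (avail_hi >= 1),
                "both_open": ws.at_left & ws.at_right & (avail_lo >= 1) & (avail_hi >= 1),
            }
            if not allow_left_overhang:
                emit["left_open"][:] = False
                emit["both_open"][:] = False
            for cls, mask in emit.items():
                if not mask.any():
                    continue
                rows.append(
                    pd.DataFrame(
                        {
                            "segment": seg.id,
                            "strand": strand,
                            "i": ws.i0[mask] + 1,
                            "j": ws.jp[mask],
                            "k": ws.k0[mask] + ws.jp[mask],  # 3'-side edge, 1-based
                            "tail_class": cls,
                            "keq": ws.keq[mask],
                        }
                    )
                )
    entries = (
        pd.concat(rows, ignore_index=True)
        if rows
        else pd.DataFrame(columns=["segment", "strand", "i", "j", "k", "tail_class", "keq"])
    )
    if prune > 0 and len(entries):
        entries = entries[entries["keq"] >= prune * entries["keq"].max()].reset_index(
            drop=True
        )
    return KeqTable(
        probe_variant_id=probe_variant_id or probe_variant,
        entries=entries,
        seg_lengths={s.id: len(s) for s in segments},
        temperature_k=temp,
        na_molar=na,
        unparameterized_steps=n_unparam,
    )


def tail_weights(
    jp: np.ndarray,
    tail_class: np.ndarray,
    avail_lo: np.ndarray,
    avail_hi: np.ndarray,
    frag: FragmentationModel,
) -> np.ndarray:
    """Concentration factor (C multiplier) per entry under a fragmentation model.

    both_cut: p^2 q^(j-1); one-sided open: p q^j (1 - q^E); both_open:
    q^(j+1) (1 - q^El) (1 - q^Er), with E the bases available for the unseen
    extension (the textbook tail forms are the E -> inf limit).
    """
    p, q = frag.cut_probability_p, frag.q
    jp = np.asarray(jp, dtype=float)
    w = np.empty_like(jp)
    bc = tail_class == "both_cut"
    ro = tail_class == "right_open"
    lo = tail_class == "left_open"
    bo = tail_class == "both_open"
    w[bc] = p * p * q ** (jp[bc] - 1)
    w[ro] = p * q ** jp[ro] * (1 - q ** avail_lo[ro])
    w[lo] = p * q ** jp[lo] * (1 - q ** avail_hi[lo])
    w[bo] = q ** (jp[bo] + 1) * (1 - q ** avail_lo[bo]) * (1 - q ** avail_hi[bo])
    return w


def fraction_bound(
    table: KeqTable,
    frag: FragmentationModel,
    concentrations: dict[str, float],
    wash: WashModel = WashModel(0.0),
) -> float:
    """Washed competitive fraction of bound probes for one spot.

    Numerator restricted to K_eq >= K_eqW; denominator sums every complex
    plus one.  Monotone non-decreasing in every segment concentration when
    the wash is disabled; always in [0, 1).
    """
    e = table.entries
    if len(e) == 0:
        return 0.0
    for seg in table.seg_lengths:
        if seg in set(e["segment"]) and seg not in concentrations:
            raise ValueError(f"missing concentration for segment {seg!r}")
    c_seg = e["segment"].map(concentrations).to_numpy(dtype=float)
    if np.any(c_seg < 0) or np.any(~np.isfinite(c_seg)):
        raise ValueError("segment concentrations must be finite and >= 0")
    seg_len = e["segment"].map(table.seg_lengths).to_numpy()
    i0 = e["i"].to_numpy() - 1
    jp = e["j"].to_numpy()
    w = tail_weights(
        jp, e["tail_class"].to_numpy(), i0, seg_len - i0 - jp, frag
    )
    ck = c_seg * e["keq"].to_numpy() * w
    den = ck.sum() + 1.0
    num = ck[e["keq"].to_numpy() >= wash.keq_threshold_KeqW].sum()
    return float(num / den)
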