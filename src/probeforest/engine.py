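"""Vectorized forward-model engine shared by prediction, simulation and fitting.

The fit loop re-evaluates spot occupancies at many synthesis-rate and
concentration values while the K_eq windows depend only on sequence,
temperature and salt.  The engine therefore pre-reduces, once per distinct
probe-variant *sequence* and per (fragmentation, wash) grid point, the two
scalars the Langmuir ratio needs per target segment:

    S_all[v, n]  = sum over windows of K_eq * w(p)          (denominator)
    S_wash[v, n] = same, restricted to K_eq >= K_eqW        (numerator)

where w(p) is the fragmentation concentration factor of the window's tail
class.  A spot's occupancy for any parameter point is then

    alpha_x = sum_n C_n S_wash[x, n] / (sum_n C_n S_all[x, n] + 1)
    alpha   = sum_x p_x(S, B) alpha_x

with p_x the synthesis-error variant probabilities, evaluated in closed form
from per-variant base counts.  Variant K tables are cached by sequence across
the chip, so designs that tile short segments (or carry replicate spots)
share most of the work.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .design import ChipDesign
from .fragments import cut_probability
from .hybridization import score_windows
from .nn_thermo import ABASIC, NNParameterSet, encode, revcomp
from .scanner import ScannerModel, expected_intensity
from .synthesis_errors import SynthesisModel

__all__ = ["PredictionEngine"]

_BASES = "ACGT"
_BIDX = {b: i for i, b in enumerate(_BASES)}


def _counts(seq: str) -> np.ndarray:
    c = np.zeros(4)
    for ch in seq:
        if ch != ABASIC:
            c[_BIDX[ch]] += 1
    return c


@dataclass(frozen=True)
class _VariantRow:
    sequence: str      # 5'->3', possibly with an abasic mark; "" for empty
    c_s: np.ndarray    # incorporation exponents per base A,C,G,T
    c_b: np.ndarray    # retention exponents per base
    sel: int           # 0: none; 1..4: factor (1 - S_base); 5..8: (1 - B_base)


def _variant_rows(seq: str) -> list[_VariantRow]:
    """Zero- and one-error variant descriptors of one probe sequence.

    Mirrors :func:`probeforest.synthesis_errors.variant_set` symbolically so
    probabilities can be re-evaluated at any rate vector without re-deriving
    the sequences (synthesis base 1 = 3'-most).
    """
    n = len(seq)
    full = _counts(seq)
    rows = [_VariantRow(seq, full, full.copy(), 0)]
    for m in range(1, n + 1):
        kept = seq[n - (m - 1):] if m > 1 else ""
        c = _counts(kept)
        rows.append(_VariantRow(kept, c, c.copy(), 1 + _BIDX[seq[n - m]]))
    for m in range(1, n + 1):
        b = seq[n - m]
        c_b = full.copy()
        c_b[_BIDX[b]] -= 1
        rows.append(
            _VariantRow(seq[: n - m] + ABASIC + seq[n - m + 1:], full, c_b, 5 + _BIDX[b])
        )
    return rows


class PredictionEngine:
    """Forward model for a chip design over a (fragmentation, wash) grid.

    Parameters
    ----------
    design : ChipDesign
    nn_params : NNParameterSet
    temp_k, na : hybridization temperature (K) and [Na+] (M)
    combos : list of (mean_fragment_size_mu, keq_threshold) grid points
    """

    def __init__(
        self,
        design: ChipDesign,
        nn_params: NNParameterSet,
        temp_k: float,
        na: float,
        combos: list[tuple[float, float]],
    ) -> None:
        if not combos:
            raise ValueError("at least one (mu, K_eqW) grid point is required")
        self.design = design
        self.nn_params = nn_params
        self.temp_k = float(temp_k)
        self.na = float(na)
        self.combos = [(float(m), float(w)) for m, w in combos]
        self.segment_ids = [s.id for s in design.segments]

        # distinct probe sequences -> groups; probes index into groups
        self._group_of: dict[str, int] = {}
        self.probe_group = np.array(
            [self._group_of.setdefault(p.sequence, len(self._group_of)) for p in design.probes]
        )
        group_seqs = list(self._group_of)
        self.n_groups = len(group_seqs)

        # flatten variant rows across groups; dedupe K-side work by sequence
        rows: list[_VariantRow] = []
        group_idx: list[int] = []
        for g, seq in enumerate(group_seqs):
            for row in _variant_rows(seq):
                rows.append(row)
                group_idx.append(g)
        self.var_group = np.array(group_idx)
        self.var_cs = np.array([r.c_s for r in rows])
        self.var_cb = np.array([r.c_b for r in rows])
        sel = np.array([r.sel for r in rows])
        self.sel_onehot = np.zeros((len(rows), 8))
        nz = sel > 0
        self.sel_onehot[np.flatnonzero(nz), sel[nz] - 1] = 1.0

        scored: dict[str, int] = {}
        vidx = np.full(len(rows), -1)
        for j, r in enumerate(rows):
            if len(r.sequence) >= 2:
                vidx[j] = scored.setdefault(r.sequence, len(scored))
        self.var_keq_index = vidx

        self._reduce_tables(list(scored), design)

    @staticmethod
    def _tally(ws, mask: np.ndarray, nb: int) -> np.ndarray:
        """Length-binned K_eq tallies for the fast per-grid-point reduction.

        The concentration factor of every tail class is a signed sum of pure
        powers of q, so sum(K * w) collapses to dot products between these
        tallies and a q-power table: row 0 bins the both_cut term q^(j-1),
        rows 1-2 the right-open pair q^j - q^(j+lo), rows 3-4 the left-open
        pair, rows 5-8 the four both-open terms.
        """
        K, jp, lo = ws.keq, ws.jp, ws.i0
        hi = ws.target_len - ws.i0 - ws.jp
        r = ws.at_right & mask
        l = ws.at_left & mask
        b = ws.at_left & ws.at_right & mask
        T = np.zeros((9, nb))
        T[0] = np.bincount(jp[mask] - 1, K[mask], nb)
        T[1] = np.bincount(jp[r], K[r], nb)
        T[2] = np.bincount(jp[r] + lo[r], K[r], nb)
        T[3] = np.bincount(jp[l], K[l], nb)
        T[4] = np.bincount(jp[l] + hi[l], K[l], nb)
        T[5] = np.bincount(jp[b] + 1, K[b], nb)
        T[6] = np.bincount(jp[b] + 1 + lo[b], K[b], nb)
        T[7] = np.bincount(jp[b] + 1 + hi[b], K[b], nb)
        T[8] = np.bincount(jp[b] + 1 + lo[b] + hi[b], K[b], nb)
        return T

    @staticmethod
    def _combine(d: np.ndarray, p: float, q: float) -> float:
        return (
            p * p * d[0]
            + p * (d[1] - d[2])
            + p * (d[3] - d[4])
            + (d[5] - d[6] - d[7] + d[8])
        )

    def _reduce_tables(self, scored_seqs: list[str], design: ChipDesign) -> None:
        nsc, nseg, ncombo = len(scored_seqs), len(design.segments), len(self.combos)
        self.s_all = np.zeros((nsc, nseg, ncombo))
        self.s_wash = np.zeros((nsc, nseg, ncombo))
        pq = [
            (cut_probability(mu).cut_probability_p, cut_probability(mu).q)
            for mu, _ in self.combos
        ]
        thresholds = sorted({thr for _, thr in self.combos} | {0.0})
        targets = []
        for seg in design.segments:
            for presented in (seg.sequence, revcomp(seg.sequence)):
                targets.append((len(targets) // 2, encode(presented)))
        nb = max(len(s) for s in design.segments) + 64
        qpow = {}
        for p, q in pq:
            if q not in qpow:
                qpow[q] = q ** np.arange(nb, dtype=float)
        for v, seq in enumerate(scored_seqs):
            codes = encode(seq)
            nbv = max(len(seq), *(len(s) for s in design.segments)) + 3
            for seg_i, tcodes in targets:
                ws = score_windows(codes, tcodes, self.nn_params, self.temp_k, self.na)
                tallies = {
                    thr: self._tally(ws, ws.keq >= thr, nbv)
                    if thr > 0
                    else self._tally(ws, np.ones(len(ws.keq), bool), nbv)
                    for thr in thresholds
                }
                dots = {
                    (thr, q): T @ qpow[q][:nbv]
                    for thr, T in tallies.items()
                    for _, q in pq
                }
                for c, ((mu, thr), (p, q)) in enumerate(zip(self.combos, pq)):
                    self.s_all[v, seg_i, c] += self._combine(dots[(0.0, q)], p, q)
                    self.s_wash[v, seg_i, c] += self._combine(dots[(thr, q)], p, q)

    # ------------------------------------------------------------------ #

    def _conc_vector(self, concentrations: dict[str, float]) -> np.ndarray:
        try:
            c = np.array([concentrations[s] for s in self.segment_ids], dtype=float)
        except KeyError as exc:
            raise ValueError(f"missing concentration for segment {exc}") from None
        if np.any(c < 0) or np.any(~np.isfinite(c)):
            raise ValueError("segment concentrations must be finite and >= 0")
        return c

    def variant_probabilities(self, synthesis: SynthesisModel) -> np.ndarray:
        """p_x for every variant row (grouped per distinct probe sequence)."""
        s, b = synthesis.as_vectors()
        p = np.prod(s[None, :] ** self.var_cs, axis=1) * np.prod(
            b[None, :] ** self.var_cb, axis=1
        )
        return p * (1.0 - self.sel_onehot @ np.concatenate([s, b]))

    def group_alpha(
        self,
        synthesis: SynthesisModel,
        concentrations: dict[str, float],
        combo: int = 0,
    ) -> np.ndarray:
        """Effective occupancy per distinct probe sequence at one grid point."""
        c = self._conc_vector(concentrations)
        num = self.s_wash[:, :, combo] @ c
        den = self.s_all[:, :, combo] @ c + 1.0
        alpha_scored = num / den
        alpha_x = np.where(
            self.var_keq_index >= 0, alpha_scored[self.var_keq_index], 0.0
        )
        p_x = self.variant_probabilities(synthesis)
        return np.bincount(self.var_group, weights=p_x * alpha_x, minlength=self.n_groups)

    def predict_alpha(self, synthesis, concentrations, combo: int = 0) -> np.ndarray:
        """Occupancy per probe spot (design order)."""
        return self.group_alpha(synthesis, concentrations, combo)[self.probe_group]

    def predict_intensity(
        self,
        synthesis: SynthesisModel,
        concentrations: dict[str, float],
        scanner: ScannerModel,
        combo: int = 0,
    ) -> np.ndarray:
        """Expected intensity per probe spot (design order)."""
        return expected_intensity(self.predict_alpha(synthesis, concentrations, combo), scanner)
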