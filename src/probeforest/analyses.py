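"""Model-driven analyses: mismatch positional scan and strand-ratio binning.

Two phenomena the physical model explains without positional weights:

* mismatches near the probe centre depress intensity more than edge
  mismatches, because more target fragments cover central positions than
  positions reachable only from one side; and
* forward and reverse probes of the same locus differ systematically in
  intensity, because base-specific synthesis failure rates make
  complementary probes unequal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import ChipDesign, ProbeSpot
from .engine import PredictionEngine
from .nn_thermo import load_nn_params
from .scanner import ScannerModel

__all__ = [
    "MismatchScanResult",
    "StrandRatioBins",
    "mismatch_scan",
    "single_base_variants",
    "strand_ratio_bins",
]

_BASES = "ACGT"


def single_base_variants(seq: str) -> list[tuple[int, str, str]]:
    """All single-base substitutions of a probe: 3L variants for length L.

    Returns (position 1-based from the 5' end, substituted base, variant
    sequence) triples.
    """
    out = []
    for pos in range(len(seq)):
        for sub in _BASES:
            if sub == seq[pos]:
                continue
            out.append((pos + 1, sub, seq[:pos] + sub + seq[pos + 1 :]))
    return out


@dataclass
class MismatchScanResult:
    """Per-variant predicted intensities and the positional summary.

    ``per_variant`` columns: probe_id, position (1-based from the probe's 5'
    end), substitution, intensity, pm_intensity, ratio
    (mismatch / perfect match).  ``per_position`` columns: position,
    mean_ratio, n.
    """

    per_variant: pd.DataFrame
    per_position: pd.DataFrame


@dataclass
class StrandRatioBins:
    """Per-pair log(forward/reverse) ratios and their composition bins.

    Bin key = (nA - nT) + (nG - nC) of the forward-strand probe.
    ``per_bin`` columns: bin, mean_observed, mean_expected, count, flagged
    (count below the requested minimum).
    """

    per_pair: pd.DataFrame
    per_bin: pd.DataFrame
    min_bin_count: int


def mismatch_scan(design: ChipDesign, params: dict) -> MismatchScanResult:
    """Predicted intensity of every single-base substitution of every probe.

    For a probe of length L there are exactly 3L variants; each is pushed
    through the *full* forward model (cross-hybridization, synthesis-error
    mixture, wash, scanner) at the supplied parameter point: ``params`` is a
    dict with synthesis, concentrations, scanner, mu, keqw and optionally
    nn_params / temperature_k / na_molar.  Intensities are reported as the
    ratio to the unmutated probe, aggregated per position.
    """
    nn = params.get("nn_params") or load_nn_params()
    scanner = params.get("scanner", ScannerModel())
    temp_k = params.get("temperature_k", 315.15)
    na = params.get("na_molar", 1.0)
    combo = [(params["mu"], params["keqw"])]

    spots: list[ProbeSpot] = []
    meta = []
    for p in design.probes:
        spots.append(ProbeSpot(p.probe_id, p.sequence, p.strand, p.segment_id))
        meta.append((p.probe_id, 0, "="))
        for pos, sub, var in single_base_variants(p.sequence):
            spots.append(
                ProbeSpot(f"{p.probe_id}@{pos}{sub}", var, p.strand, p.segment_id)
            )
            meta.append((p.probe_id, pos, sub))
    extended = ChipDesign(spots, design.segments)
    engine = PredictionEngine(extended, nn, temp_k, na, combo)
    intensity = engine.predict_intensity(
        params["synthesis"], params["concentrations"], scanner, 0
    )

    pm = {
        pid: float(v)
        for (pid, pos, _), v in zip(meta, intensity)
        if pos == 0
    }
    rows = [
        {
            "probe_id": pid,
            "position": pos,
            "substitution": sub,
            "intensity": float(v),
            "pm_intensity": pm[pid],
            "ratio": float(v) / pm[pid],
        }
        for (pid, pos, sub), v in zip(meta, intensity)
        if pos > 0
    ]
    per_variant = pd.DataFrame(rows)
    per_position = (
        per_variant.groupby("position")["ratio"]
        .agg(mean_ratio="mean", n="size")
        .reset_index()
    )
    return MismatchScanResult(per_variant=per_variant, per_position=per_position)


def _composition_key(seq: str) -> int:
    return (
        seq.count("A") - seq.count("T") + seq.count("G") - seq.count("C")
    )


def _as_chips(x) -> list[dict]:
    return list(x) if isinstance(x, (list, tuple)) else [x]


def strand_ratio_bins(
    design: ChipDesign,
    observed,
    expected,
    min_bin_count: int = 50,
) -> StrandRatioBins:
    """Forward/reverse intensity log-ratios binned by base composition.

    ``observed`` and ``expected`` are probe_id -> intensity mappings (or
    lists of them, one per chip; ratios are averaged across chips).  Probe
    pairing is resolved from the locus tag; spots sharing (locus, strand)
    -- replicates -- are averaged first.  Pairs with a missing partner or a
    non-positive intensity are skipped.  Natural logarithms.
    """
    obs_chips, exp_chips = _as_chips(observed), _as_chips(expected)
    if len(obs_chips) != len(exp_chips):
        raise ValueError("observed and expected must cover the same chips")

    by_locus: dict[str, dict[str, list[ProbeSpot]]] = {}
    for p in design.probes:
        if p.locus is None:
            continue
        by_locus.setdefault(p.locus, {}).setdefault(p.strand, []).append(p)

    rows = []
    n_skipped = 0
    for locus, strands in sorted(by_locus.items()):
        fwd, rev = strands.get("forward"), strands.get("reverse")
        if not fwd or not rev:
            n_skipped += 1
            continue

        def mean_ratio(chips):
            vals = []
            for chip in chips:
                f = np.mean([chip[p.probe_id] for p in fwd if p.probe_id in chip] or [np.nan])
                r = np.mean([chip[p.probe_id] for p in rev if p.probe_id in chip] or [np.nan])
                if not (np.isfinite(f) and np.isfinite(r)) or f <= 0 or r <= 0:
                    continue
                vals.append(np.log(f / r))
            return float(np.mean(vals)) if vals else np.nan

        lr_obs = mean_ratio(obs_chips)
        lr_exp = mean_ratio(exp_chips)
        if not (np.isfinite(lr_obs) and np.isfinite(lr_exp)):
            n_skipped += 1
            continue
        rows.append(
            {
                "locus": locus,
                "bin": _composition_key(fwd[0].sequence),
                "log_ratio_observed": lr_obs,
                "log_ratio_expected": lr_exp,
            }
        )
    per_pair = pd.DataFrame(rows)
    if len(per_pair):
        per_bin = (
            per_pair.groupby("bin")
            .agg(
                mean_observed=("log_ratio_observed", "mean"),
                mean_expected=("log_ratio_expected", "mean"),
                count=("locus", "size"),
            )
            .reset_index()
        )
        per_bin["flagged"] = per_bin["count"] < min_bin_count
    else:
        per_bin = pd.DataFrame(
            columns=["bin", "mean_observed", "mean_expected", "count", "flagged"]
        )
    return StrandRatioBins(per_pair=per_pair, per_bin=per_bin, min_bin_count=min_bin_count)
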