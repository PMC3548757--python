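"""Synthetic-chip factory: designs and observed intensities with known truth.

Emulates a resequencing-style array: short target segments ("PCR products")
tiled by forward/reverse 25-mer probe pairs, intensities generated by the
full forward model (fragmentation -> cross-hybridizing K_eq forest ->
competitive Langmuir binding -> wash -> synthesis-error mixture -> Gompertz
scanner) under known synthesis rates, concentrations, fragmentation, wash
and scanner settings, plus multiplicative log-normal replicate noise.  The
generated truth is returned alongside the data so parameter-recovery
harnesses can close the loop without any real chip files.

Default conditions mirror the modelled experiments: 25-mer probes, 42 C
hybridization, 1 M [Na+], scanner 100/65536 with shape 7, synthesis rates at
the FMR1-design point estimates, and noise calibrated so replicate spots
correlate at 0.906.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .design import ChipDesign, ProbeSpot
from .engine import PredictionEngine
from .fragments import FragmentationModel, TargetSegment, cut_probability, sample_fragment_lengths
from .hybridization import WashModel
from .nn_thermo import NNParameterSet, load_nn_params, revcomp
from .scanner import ScannerModel
from .synthesis_errors import SynthesisModel

__all__ = [
    "ChipDesign",
    "ProbeSpot",
    "NoiseModel",
    "make_design",
    "simulate_chip",
    "calibrate_sigma",
    "default_truth",
    "DEFAULT_TEMPERATURE_K",
    "DEFAULT_NA_MOLAR",
    "DEFAULT_MU",
    "DEFAULT_KEQW",
    "DEFAULT_REPLICATE_CORRELATION",
]

DEFAULT_TEMPERATURE_K = 315.15  # 42 C
DEFAULT_NA_MOLAR = 1.0
DEFAULT_MU = 50.0               # mean fragment size, bases
DEFAULT_KEQW = 1e6              # wash threshold (~ a weak 8-10-mer duplex)
DEFAULT_REPLICATE_CORRELATION = 0.906

#: Synthesis rates at the FMR1-design point estimates (A, C, G, T).
DEFAULT_INCORPORATION = {"A": 0.967, "C": 0.944, "G": 0.908, "T": 0.950}
DEFAULT_RETENTION = {"A": 0.959, "C": 0.941, "G": 0.953, "T": 0.962}

#: Per-segment concentration (arbitrary units matched to K_eq in 1/M-like
#: units).  Chosen so C * K_eq of a full-length perfect duplex is of order
#: one: spots sit mid-way up the scanner's dynamic range and remain
#: concentration-sensitive rather than saturated.
DEFAULT_CONCENTRATION = 1e-17


@dataclass(frozen=True)
class NoiseModel:
    """Multiplicative spot noise; log-normal with unit mean, sd ``sigma``."""

    kind: str = "lognormal_multiplicative"
    sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("none", "lognormal_multiplicative"):
            raise ValueError(f"unknown noise kind {self.kind!r}")
        if self.sigma < 0:
            raise ValueError("noise sigma must be >= 0")


def default_truth() -> dict:
    """The study conditions used by the simulator unless overridden."""
    return {
        "synthesis": SynthesisModel(dict(DEFAULT_INCORPORATION), dict(DEFAULT_RETENTION)),
        "mu": DEFAULT_MU,
        "keqw": DEFAULT_KEQW,
        "scanner": ScannerModel(),
        "temperature_k": DEFAULT_TEMPERATURE_K,
        "na_molar": DEFAULT_NA_MOLAR,
    }


def make_design(
    n_loci: int,
    probe_len: int = 25,
    segment_lengths: tuple[int, ...] = (56, 56),
    n_replicate_spots: int = 0,
    seed: int = 0,
    segment_seqs: list[str] | None = None,
) -> ChipDesign:
    """Random segments tiled by forward/reverse probe pairs.

    Each sampled locus (a ``probe_len`` window of a segment) yields one probe
    querying the forward strand (the window's reverse complement) and one
    querying the reverse strand (the window itself).  Loci are sampled
    without replacement while distinct windows remain, then with replacement
    -- dense tilings of short segments repeat sequences, as real designs
    tiling a handful of PCR products do.  ``n_replicate_spots`` extra spots
    duplicate randomly chosen probes under distinct ids, sharing a
    replicate_group.  Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    if segment_seqs is not None:
        seqs = [s.upper() for s in segment_seqs]
    else:
        seqs = [
            "".join(rng.choice(list("ACGT"), size=sl)) for sl in segment_lengths
        ]
    if any(len(s) < probe_len for s in seqs):
        raise ValueError("segment shorter than the probe length")
    segments = [TargetSegment(f"seg{si}", s) for si, s in enumerate(seqs)]

    windows = [
        (seg.id, start)
        for seg in segments
        for start in range(len(seg) - probe_len + 1)
    ]
    if n_loci <= len(windows):
        chosen = [windows[i] for i in rng.choice(len(windows), n_loci, replace=False)]
    else:
        base = list(rng.permutation(len(windows)))
        extra = list(rng.choice(len(windows), n_loci - len(windows), replace=True))
        chosen = [windows[i] for i in base + extra]

    seg_by_id = {s.id: s for s in segments}
    probes: list[ProbeSpot] = []
    for li, (seg_id, start) in enumerate(chosen):
        window = seg_by_id[seg_id].sequence[start : start + probe_len]
        locus = f"{seg_id}:{start + 1}"
        probes.append(
            ProbeSpot(f"L{li:05d}_F", revcomp(window), "forward", seg_id, locus=locus)
        )
        probes.append(ProbeSpot(f"L{li:05d}_R", window, "reverse", seg_id, locus=locus))

    if n_replicate_spots:
        picks = rng.choice(len(probes), n_replicate_spots, replace=True)
        for ri, pi in enumerate(picks):
            src = probes[pi]
            if src.replicate_group is None:
                src.replicate_group = src.probe_id
            probes.append(
                ProbeSpot(
                    f"{src.probe_id}_rep{ri:04d}",
                    src.sequence,
                    src.strand,
                    src.segment_id,
                    locus=src.locus,
                    replicate_group=src.replicate_group,
                )
            )
    return ChipDesign(probes, segments)


def simulate_chip(
    design: ChipDesign,
    true_synthesis: SynthesisModel,
    true_concentrations: dict[str, float],
    frag: FragmentationModel,
    wash: WashModel,
    scanner: ScannerModel,
    noise: NoiseModel = NoiseModel("none"),
    nn_params: NNParameterSet | None = None,
    temp_k: float = DEFAULT_TEMPERATURE_K,
    na: float = DEFAULT_NA_MOLAR,
    engine: PredictionEngine | None = None,
) -> dict[str, float]:
    """Observed intensities for one chip under the forward model plus noise.

    With ``noise.kind == "none"`` the output equals the noiseless forward
    prediction exactly.  Log-normal noise has unit mean; replicate spots
    draw independently.  Values are clamped to [0, MAX].  Pass a prebuilt
    ``engine`` to amortize K_eq work across chips sharing a design.
    """
    if engine is None:
        engine = PredictionEngine(
            design,
            nn_params if nn_params is not None else load_nn_params(),
            temp_k,
            na,
            [(frag.mean_fragment_size_mu, wash.keq_threshold_KeqW)],
        )
    expected = engine.predict_intensity(true_synthesis, true_concentrations, scanner, 0)
    if noise.kind == "none" or noise.sigma == 0:
        observed = expected
    else:
        rng = np.random.default_rng(noise.seed)
        factors = np.exp(
            rng.normal(-0.5 * noise.sigma**2, noise.sigma, size=len(expected))
        )
        observed = np.clip(expected * factors, 0.0, scanner.max_intensity)
    return {p.probe_id: float(v) for p, v in zip(design.probes, observed)}


def calibrate_sigma(
    noiseless: np.ndarray, target_rho: float = DEFAULT_REPLICATE_CORRELATION
) -> float:
    """Noise sigma giving the requested replicate-spot correlation.

    For X = I * eps with unit-mean log-normal eps, two replicates of the same
    spot satisfy corr = Var(I) / (Var(I) + E[I^2] (exp(sigma^2) - 1)), hence
    sigma^2 = log(1 + (1/rho - 1) Var(I) / E[I^2]).
    """
    if not 0 < target_rho < 1:
        raise ValueError("target correlation must lie in (0, 1)")
    noiseless = np.asarray(noiseless, dtype=float)
    var = noiseless.var()
    second = np.mean(noiseless**2)
    return float(np.sqrt(np.log1p((1.0 / target_rho - 1.0) * var / second)))


def fragment_length_histogram(
    model: FragmentationModel, n: int, seed: int = 0
) -> np.ndarray:
    """Sampled fragment lengths (Monte-Carlo check of the geometric law)."""
    return sample_fragment_lengths(model, n, np.random.default_rng(seed))
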