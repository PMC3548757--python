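"""Per-chip parameter estimation by derivative-free least squares.

The fit minimizes the squared difference between observed and expected
intensities over the eight synthesis rates (incorporation and retention per
base) and one concentration per target segment, using Powell's direction-set
method.  Rates are optimized on a logit scale and concentrations on a log
scale, so the unconstrained search respects their natural bounds.  Wash
stringency and mean fragment size are discrete experiment-level knobs: the
continuous fit is repeated on a (mu, K_eqW) grid and the grid point with the
highest Pearson correlation wins (ties break toward smaller K_eqW, then
smaller mu).  Restarts jitter the starting point; the model surface is
benign enough that they converge to the same optimum on clean data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, logit

from .design import ChipDesign
from .engine import PredictionEngine
from .fragments import FragmentationModel
from .hybridization import WashModel
from .nn_thermo import NNParameterSet, load_nn_params
from .scanner import ScannerModel, expected_intensity
from .synthesis_errors import SynthesisModel

__all__ = ["FitConfig", "FitResult", "objective", "fit_chip", "nn_one_d_search"]

logger = logging.getLogger(__name__)

_NEUTRAL_RATE = 0.97


@dataclass
class FitConfig:
    """Grids, restarts and optimizer settings for one chip fit."""

    wash_grid: list[float] = field(default_factory=lambda: [0.0, 1e6])
    frag_grid: list[float] = field(default_factory=lambda: [30.0, 50.0])
    n_restarts: int = 2
    seed: int = 0
    tolerance: float = 1e-9
    max_iterations: int = 150
    objective_scale: str = "raw"  # or "log"

    def __post_init__(self) -> None:
        if not self.wash_grid or not self.frag_grid:
            raise ValueError("wash and fragmentation grids must be non-empty")
        if self.n_restarts < 1:
            raise ValueError("need at least one restart")
        if self.objective_scale not in ("raw", "log"):
            raise ValueError("objective_scale must be 'raw' or 'log'")

    @property
    def combos(self) -> list[tuple[float, float]]:
        return [(mu, w) for mu in self.frag_grid for w in self.wash_grid]


@dataclass
class FitResult:
    """Fitted parameters, goodness of fit and per-probe predictions."""

    synthesis: SynthesisModel
    concentrations: dict[str, float]
    mu: float
    keqw: float
    objective: float
    pearson_r: float
    pearson_r_log: float
    predicted: dict[str, float]
    converged: bool
    n_missing_observations: int

    def __post_init__(self) -> None:
        if self.objective < 0:
            raise ValueError("objective must be >= 0")
        for r in (self.pearson_r, self.pearson_r_log):
            if not -1.0 <= r <= 1.0:
                raise ValueError("correlation outside [-1, 1]")


def _observed_vector(design: ChipDesign, observed: dict[str, float]):
    obs = np.array(
        [observed.get(p.probe_id, np.nan) for p in design.probes], dtype=float
    )
    mask = np.isfinite(obs)
    n_missing = int((~mask).sum())
    if n_missing:
        logger.info("objective: skipping %d probes without observations", n_missing)
    if not mask.any():
        raise ValueError("no probe has an observed intensity")
    return obs, mask, n_missing


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    if x.std() == 0 or y.std() == 0:
        return 0.0
    return float(np.corrcoef(x, y)[0, 1])


def objective(
    synthesis: SynthesisModel,
    concentrations: dict[str, float],
    design: ChipDesign,
    observed: dict[str, float],
    frag: FragmentationModel,
    wash: WashModel,
    scanner: ScannerModel,
    nn_params: NNParameterSet | None = None,
    temp_k: float = 315.15,
    na: float = 1.0,
    scale: str = "raw",
    engine: PredictionEngine | None = None,
    combo: int = 0,
) -> float:
    """Sum of squared observed-vs-expected intensity differences.

    Probes without an observation are skipped (with a logged count), never
    imputed.  ``scale="log"`` compares log1p intensities instead.
    """
    if engine is None:
        engine = PredictionEngine(
            design,
            nn_params if nn_params is not None else load_nn_params(),
            temp_k,
            na,
            [(frag.mean_fragment_size_mu, wash.keq_threshold_KeqW)],
        )
        combo = 0
    obs, mask, _ = _observed_vector(design, observed)
    pred = engine.predict_intensity(synthesis, concentrations, scanner, combo)
    if scale == "log":
        return float(np.sum((np.log1p(obs[mask]) - np.log1p(pred[mask])) ** 2))
    return float(np.sum((obs[mask] - pred[mask]) ** 2))


def fit_chip(
    design: ChipDesign,
    observed: dict[str, float],
    config: FitConfig,
    scanner: ScannerModel = ScannerModel(),
    nn_params: NNParameterSet | None = None,
    temp_k: float = 315.15,
    na: float = 1.0,
    engine: PredictionEngine | None = None,
) -> FitResult:
    """Fit synthesis rates and segment concentrations to one chip.

    At each (mu, K_eqW) grid point the Powell search is staged: the
    full-length probability constrains only the *product* S_b * B_b per
    base, so a first Powell pass fits the four products (with an even
    incorporation/retention split) plus the concentrations on a
    well-conditioned 4+n_seg-dimensional surface, and a second pass opens
    the split into the full 8 rates.  ``n_restarts`` seeded jittered starts
    guard against local minima of the weakly identified split directions.
    Returns the grid point with the highest raw Pearson correlation;
    deterministic given ``config.seed``.
    """
    if nn_params is None:
        nn_params = load_nn_params()
    combos = config.combos
    if engine is None:
        engine = PredictionEngine(design, nn_params, temp_k, na, combos)
    obs, mask, n_missing = _observed_vector(design, observed)
    if config.objective_scale == "log":
        obs_cmp = np.log1p(obs[mask])
    else:
        obs_cmp = obs[mask]
    rng = np.random.default_rng(config.seed)
    nseg = len(engine.segment_ids)

    def unpack(z):
        rates = expit(z[:8])
        synth = SynthesisModel.from_vectors(rates[:4], rates[4:])
        concs = dict(zip(engine.segment_ids, np.exp(z[8:])))
        return synth, concs

    def powell(fun, z0, maxiter):
        return minimize(
            fun,
            z0,
            method="Powell",
            options={
                "xtol": config.tolerance,
                "ftol": config.tolerance * 1e-4,
                "maxiter": maxiter,
                "maxfev": 400000,
            },
        )

    scale = float(np.sum(obs_cmp**2))
    best = None  # (key, combo result)
    converged_all = True
    for ci, (mu, keqw) in enumerate(combos):

        def sse(z, _ci=ci):
            synth, concs = unpack(z)
            pred = engine.predict_intensity(synth, concs, scanner, _ci)
            d = obs_cmp - (np.log1p(pred[mask]) if config.objective_scale == "log" else pred[mask])
            return float(np.sum(d * d))

        def sse_product(z, _ci=ci):
            # even-split surrogate: S = B = sqrt(product)
            root = np.sqrt(expit(z[:4]))
            full = np.concatenate([logit(np.clip(root, 1e-12, 1 - 1e-12))] * 2 + [z[4:]])
            return sse(full, _ci)

        # coarse common concentration scale under neutral products
        z_prod0 = np.full(4, logit(_NEUTRAL_RATE**2))
        best_c, best_f = None, np.inf
        for log10c in np.linspace(-24.0, -8.0, 33):
            f = sse_product(np.concatenate([z_prod0, np.full(nseg, log10c * np.log(10))]))
            if f < best_f:
                best_f, best_c = f, log10c * np.log(10)

        combo_best = None
        for ri in range(config.n_restarts):
            zA = np.concatenate([z_prod0, np.full(nseg, best_c)])
            if ri > 0:
                zA = zA + rng.normal(0.0, 0.4, size=zA.shape)
            resA = powell(sse_product, zA, config.max_iterations)
            root = np.sqrt(expit(resA.x[:4]))
            zB = np.concatenate(
                [logit(np.clip(root, 1e-12, 1 - 1e-12))] * 2 + [resA.x[4:]]
            )
            res = None
            for _round in range(3):  # re-running resets Powell's direction set
                res = powell(sse, zB, config.max_iterations)
                improved = res.fun < (1 - 1e-9) * sse(zB)
                zB = res.x
                if not improved or res.fun <= 1e-14 * max(scale, 1.0):
                    break
            if not res.success:
                converged_all = False
                logger.warning(
                    "Powell did not converge (mu=%g, K_eqW=%g, restart %d): %s",
                    mu,
                    keqw,
                    ri,
                    res.message,
                )
            if combo_best is None or res.fun < combo_best.fun:
                combo_best = res
            if combo_best.fun <= 1e-14 * max(scale, 1.0):
                break  # exact reproduction reached; extra restarts are moot
        synth, concs = unpack(combo_best.x)
        pred = engine.predict_intensity(synth, concs, scanner, ci)
        r = _pearson(obs[mask], pred[mask])
        # grid winner: highest correlation; ties toward smaller K_eqW, then mu
        key = (-r, keqw, mu)
        if best is None or key < best[0]:
            best = (key, (mu, keqw, combo_best.fun, synth, concs, pred, r))

    mu, keqw, fun, synth, concs, pred, r = best[1]
    r_log = _pearson(np.log1p(obs[mask]), np.log1p(pred[mask]))
    return FitResult(
        synthesis=synth,
        concentrations=concs,
        mu=mu,
        keqw=keqw,
        objective=float(fun),
        pearson_r=r,
        pearson_r_log=r_log,
        predicted={p.probe_id: float(v) for p, v in zip(design.probes, pred)},
        converged=converged_all,
        n_missing_observations=n_missing,
    )


def nn_one_d_search(
    chips: list[tuple[ChipDesign, dict[str, float]]],
    step_id: str,
    ratio_grid: list[float],
    base_params: dict,
) -> pd.DataFrame:
    """One-dimensional dH search for a single NN step.

    For each ratio, the step's dH is scaled, the K_eq forests are rebuilt
    and the mean (over chips) of each chip's best Pearson correlation across
    the configured wash/fragmentation combinations is recorded, normalized
    by the value at ratio 1.  ``base_params`` supplies the evaluation point:
    synthesis model, concentrations, scanner, NN table, temperature, [Na+],
    and the wash/fragmentation grids.  Returns a DataFrame with columns
    ratio, mean_correlation, normalized.
    """
    if not any(np.isclose(r, 1.0) for r in ratio_grid):
        raise ValueError("ratio grid must include 1.0")
    nn = base_params.get("nn_params") or load_nn_params()
    nn.step(step_id)  # raises ParameterTableError for an unknown step id
    synth = base_params["synthesis"]
    concs = base_params["concentrations"]
    scanner = base_params.get("scanner", ScannerModel())
    temp_k = base_params.get("temperature_k", 315.15)
    na = base_params.get("na_molar", 1.0)
    combos = [
        (mu, w)
        for mu in base_params.get("frag_grid", [50.0])
        for w in base_params.get("wash_grid", [0.0])
    ]

    rows = []
    for ratio in ratio_grid:
        scaled = nn.scaled(step_id, float(ratio))
        engines: dict[int, PredictionEngine] = {}
        corrs = []
        for design, observed in chips:
            eng = engines.get(id(design))
            if eng is None:
                eng = PredictionEngine(design, scaled, temp_k, na, combos)
                engines[id(design)] = eng
            obs, mask, _ = _observed_vector(design, observed)
            best_r = -np.inf
            for ci in range(len(combos)):
                pred = eng.predict_intensity(synth, concs, scanner, ci)
                best_r = max(best_r, _pearson(obs[mask], pred[mask]))
            corrs.append(best_r)
        rows.append({"ratio": float(ratio), "mean_correlation": float(np.mean(corrs))})
    out = pd.DataFrame(rows)
    ref = out.loc[np.isclose(out["ratio"], 1.0), "mean_correlation"].iloc[0]
    out["normalized"] = out["mean_correlation"] / ref
    return out
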