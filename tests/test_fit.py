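"""Objective function, staged Powell fitting, and the 1-D NN search."""

import numpy as np
import pytest
from scipy.optimize import minimize_scalar

from probeforest import (
    ChipDesign,
    FitConfig,
    NoiseModel,
    PredictionEngine,
    ProbeSpot,
    ScannerModel,
    SynthesisModel,
    TargetSegment,
    WashModel,
    cut_probability,
    fit_chip,
    nn_one_d_search,
    objective,
    revcomp,
    simulate_chip,
)
from probeforest.nn_thermo import ParameterTableError

from conftest import TEMP_K, random_dna
from test_engine import reference_intensity


@pytest.fixture(scope="module")
def tiny_chip(nn_params):
    """A 12-spot chip of 8-mers on two short segments, with known truth."""
    rng = np.random.default_rng(17)
    segs = [TargetSegment("s0", random_dna(rng, 22)), TargetSegment("s1", random_dna(rng, 18))]
    probes = []
    for n in range(6):
        seg = segs[n % 2]
        start = int(rng.integers(0, len(seg) - 8))
        window = seg.sequence[start : start + 8]
        probes.append(ProbeSpot(f"p{n}F", revcomp(window), "forward", seg.id))
        probes.append(ProbeSpot(f"p{n}R", window, "reverse", seg.id))
    design = ChipDesign(probes, segs)
    synth = SynthesisModel(
        {"A": 0.98, "C": 0.95, "G": 0.92, "T": 0.96},
        {"A": 0.97, "C": 0.99, "G": 0.90, "T": 0.99},
    )
    concs = {"s0": 3e-7, "s1": 1e-7}
    mu, thr = 6.0, 0.0
    obs = simulate_chip(
        design, synth, concs, cut_probability(mu), WashModel(thr), ScannerModel(),
        NoiseModel("none"), nn_params=nn_params, temp_k=TEMP_K,
    )
    return design, synth, concs, mu, thr, obs


class TestObjective:
    def test_zero_at_generating_parameters(self, tiny_chip, nn_params):
        design, synth, concs, mu, thr, obs = tiny_chip
        sse = objective(
            synth, concs, design, obs, cut_probability(mu), WashModel(thr),
            ScannerModel(), nn_params, TEMP_K,
        )
        assert sse == pytest.approx(0.0, abs=1e-12)

    def test_perturbed_concentration_increases_objective(self, tiny_chip, nn_params):
        design, synth, concs, mu, thr, obs = tiny_chip
        worse = {**concs, "s0": concs["s0"] * 3}
        sse = objective(
            synth, worse, design, obs, cut_probability(mu), WashModel(thr),
            ScannerModel(), nn_params, TEMP_K,
        )
        assert sse > 0

    def test_matches_naive_two_pass_recomputation(self, tiny_chip, nn_params):
        design, synth, concs, mu, thr, obs = tiny_chip
        shifted = {**concs, "s1": concs["s1"] * 0.5}
        sse = objective(
            synth, shifted, design, obs, cut_probability(mu), WashModel(thr),
            ScannerModel(), nn_params, TEMP_K,
        )
        pred = reference_intensity(
            design, design.segments, synth, shifted, cut_probability(mu),
            WashModel(thr), ScannerModel(), nn_params,
        )
        obs_vec = np.array([obs[p.probe_id] for p in design.probes])
        assert sse == pytest.approx(float(np.sum((obs_vec - pred) ** 2)), rel=1e-9)

    def test_missing_observations_skipped_all_missing_error(self, tiny_chip, nn_params):
        design, synth, concs, mu, thr, obs = tiny_chip
        partial = dict(list(obs.items())[:5])
        sse = objective(
            synth, concs, design, partial, cut_probability(mu), WashModel(thr),
            ScannerModel(), nn_params, TEMP_K,
        )
        assert sse == pytest.approx(0.0, abs=1e-12)
        with pytest.raises(ValueError):
            objective(
                synth, concs, design, {}, cut_probability(mu), WashModel(thr),
                ScannerModel(), nn_params, TEMP_K,
            )


class TestFitChip:
    def test_deterministic_given_seed(self, tiny_chip, nn_params):
        design, synth, concs, mu, thr, obs = tiny_chip
        config = FitConfig(wash_grid=[0.0], frag_grid=[6.0], n_restarts=2, seed=3,
                           max_iterations=25)
        engine = PredictionEngine(design, nn_params, TEMP_K, 1.0, config.combos)
        a = fit_chip(design, obs, config, ScannerModel(), nn_params, TEMP_K, engine=engine)
        b = fit_chip(design, obs, config, ScannerModel(), nn_params, TEMP_K, engine=engine)
        assert a.predicted == b.predicted
        assert a.synthesis == b.synthesis
        assert a.concentrations == b.concentrations
        assert (a.mu, a.keqw, a.objective) == (b.mu, b.keqw, b.objective)
        # predicting again at the fitted parameters reproduces the reported
        # predictions and correlation exactly
        repredict = engine.predict_intensity(
            a.synthesis, a.concentrations, ScannerModel(),
            config.combos.index((a.mu, a.keqw)),
        )
        assert repredict == pytest.approx(
            np.array([a.predicted[p.probe_id] for p in design.probes])
        )
        obs_vec = np.array([obs[p.probe_id] for p in design.probes])
        assert np.corrcoef(obs_vec, repredict)[0, 1] == pytest.approx(a.pearson_r)

    def test_concentration_only_recovery_within_one_percent(self, nn_params):
        """Rates pinned at 1, wash off, one segment: C recovered to < 1%."""
        rng = np.random.default_rng(23)
        seg = TargetSegment("s0", random_dna(rng, 26))
        probes = []
        for n in range(5):
            start = int(rng.integers(0, len(seg) - 8))
            probes.append(
                ProbeSpot(f"p{n}", revcomp(seg.sequence[start : start + 8]), "forward", "s0")
            )
        design = ChipDesign(probes, [seg])
        ones = SynthesisModel.uniform()
        true_c = 2.4e-7
        obs = simulate_chip(
            design, ones, {"s0": true_c}, cut_probability(5.0), WashModel(0.0),
            ScannerModel(), NoiseModel("none"), nn_params=nn_params, temp_k=TEMP_K,
        )
        engine = PredictionEngine(design, nn_params, TEMP_K, 1.0, [(5.0, 0.0)])
        obs_vec = np.array([obs[p.probe_id] for p in design.probes])

        def sse(log_c):
            pred = engine.predict_intensity(ones, {"s0": np.exp(log_c)}, ScannerModel(), 0)
            return float(np.sum((obs_vec - pred) ** 2))

        res = minimize_scalar(sse, bounds=(np.log(true_c) - 7, np.log(true_c) + 7),
                              method="bounded", options={"xatol": 1e-12})
        assert np.exp(res.x) == pytest.approx(true_c, rel=0.01)


class TestNNSearch:
    def _base(self, nn_params, synth, concs):
        return {
            "synthesis": synth,
            "concentrations": concs,
            "scanner": ScannerModel(),
            "nn_params": nn_params,
            "temperature_k": TEMP_K,
            "frag_grid": [6.0],
            "wash_grid": [0.0],
        }

    def test_ratio_one_normalizes_to_unity(self, tiny_chip, nn_params):
        design, synth, concs, mu, thr, obs = tiny_chip
        curve = nn_one_d_search(
            [(design, obs)], "AA/TT", [0.8, 1.0, 1.2],
            self._base(nn_params, synth, concs),
        )
        row = curve.loc[np.isclose(curve["ratio"], 1.0)].iloc[0]
        assert row["normalized"] == pytest.approx(1.0)

    def test_grid_must_include_one(self, tiny_chip, nn_params):
        design, synth, concs, mu, thr, obs = tiny_chip
        with pytest.raises(ValueError):
            nn_one_d_search([(design, obs)], "AA/TT", [0.8, 1.2],
                            self._base(nn_params, synth, concs))

    def test_unknown_step_rejected(self, tiny_chip, nn_params):
        design, synth, concs, mu, thr, obs = tiny_chip
        with pytest.raises(ParameterTableError):
            nn_one_d_search([(design, obs)], "XX/YY", [1.0],
                            self._base(nn_params, synth, concs))

    def test_step_absent_from_design_gives_flat_curve(self, nn_params):
        """A/T-only design: scaling a C/G-top step cannot change anything."""
        rng = np.random.default_rng(4)
        seq = "".join(rng.choice(list("AT"), size=20))
        seg = TargetSegment("s0", seq)
        probes = [
            ProbeSpot("p0", revcomp(seq[2:10]), "forward", "s0"),
            ProbeSpot("p1", seq[5:13], "reverse", "s0"),
        ]
        design = ChipDesign(probes, [seg])
        synth = SynthesisModel.uniform(0.95, 0.97)
        concs = {"s0": 1e-7}
        obs = simulate_chip(
            design, synth, concs, cut_probability(6.0), WashModel(0.0),
            ScannerModel(), NoiseModel(sigma=0.3, seed=8), nn_params=nn_params,
            temp_k=TEMP_K,
        )
        curve = nn_one_d_search(
            [(design, obs)], "CG/GC", [0.5, 1.0, 2.0],
            self._base(nn_params, synth, concs),
        )
        assert curve["normalized"].values == pytest.approx([1.0, 1.0, 1.0], abs=1e-12)
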