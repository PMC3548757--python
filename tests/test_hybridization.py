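"""K_eq tables and washed competitive occupancy vs brute-force oracles."""

import numpy as np
import pandas as pd
import pytest

from probeforest import (
    KeqTable,
    TargetSegment,
    WashModel,
    build_keq_table,
    cut_probability,
    fraction_bound,
    revcomp,
)
from probeforest.nn_thermo import encode
from probeforest.hybridization import score_windows

from conftest import TEMP_K, random_dna
from oracles import brute_fraction_bound


def window_count_brute_force(P: int, L: int) -> int:
    """Triple loop over (i, j, k): paired windows of >= 2 bases inside the probe."""
    n = 0
    for j in range(2, min(P, L) + 1):
        n += (P - j + 1) * (L - j + 1)
    return n


class TestBuildKeqTable:
    def test_two_base_probe_contains_full_overlap(self, nn_params):
        seg = TargetSegment("s", "AC")
        table = build_keq_table(revcomp("AC"), [seg], nn_params, TEMP_K, prune=0.0)
        keys = set(
            map(tuple, table.entries[["segment", "strand", "i", "j", "k"]].values)
        )
        assert ("s", "forward", 1, 2, 2) in keys

    def test_window_enumeration_count(self, nn_params):
        """Distinct (segment, strand, i, j, k) keys match the triple loop."""
        seg = TargetSegment("s", "ACGTACGTACGT")
        probe = revcomp(seg.sequence)
        table = build_keq_table(probe, [seg], nn_params, TEMP_K, prune=0.0)
        distinct = table.entries[["segment", "strand", "i", "j", "k"]].drop_duplicates()
        assert len(distinct) == 2 * window_count_brute_force(12, 12)

    def test_all_keq_positive_and_no_duplicates(self, nn_params, rng):
        seg = TargetSegment("s", random_dna(rng, 20))
        table = build_keq_table(random_dna(rng, 8), [seg], nn_params, TEMP_K, prune=0.0)
        assert (table.entries["keq"] > 0).all()
        key = ["segment", "strand", "i", "j", "k", "tail_class"]
        assert not table.entries.duplicated(key).any()

    def test_prune_keeps_strongest_and_zero_is_exhaustive(self, nn_params, rng):
        seg = TargetSegment("s", random_dna(rng, 18))
        probe = revcomp(seg.sequence[3:11])
        full = build_keq_table(probe, [seg], nn_params, TEMP_K, prune=0.0)
        pruned = build_keq_table(probe, [seg], nn_params, TEMP_K, prune=1e-6)
        assert len(pruned.entries) < len(full.entries)
        assert pruned.entries["keq"].max() == full.entries["keq"].max()
        assert (
            pruned.entries["keq"] >= 1e-6 * full.entries["keq"].max()
        ).all()

    def test_left_overhang_flag(self, nn_params, rng):
        seg = TargetSegment("s", random_dna(rng, 16))
        probe = random_dna(rng, 6)
        with_oh = build_keq_table(probe, [seg], nn_params, TEMP_K, prune=0.0)
        without = build_keq_table(
            probe, [seg], nn_params, TEMP_K, prune=0.0, allow_left_overhang=False
        )
        classes = set(without.entries["tail_class"])
        assert "left_open" not in classes and "both_open" not in classes
        assert {"left_open"} <= set(with_oh.entries["tail_class"])

    def test_errors(self, nn_params):
        with pytest.raises(ValueError):
            build_keq_table("ACGT", [], nn_params, TEMP_K)
        with pytest.raises(ValueError):
            build_keq_table("A", [TargetSegment("s", "ACGT")], nn_params, TEMP_K)

    def test_temperature_only_reorders_through_exp(self, nn_params, rng):
        """With all dS = 0, scaling T preserves the dH ordering of entries."""
        from probeforest import NNParameterSet

        params = NNParameterSet(
            {k: (-float(rng.integers(1000, 40000)), 0.0) for k in nn_params.match_steps},
            {k: (-float(rng.integers(100, 5000)), 0.0) for k in nn_params.mismatch_steps},
            {"GC": (500.0, 0.0), "AT": (900.0, 0.0)},
            salt_coeff=0.0,
        )
        seg = TargetSegment("s", random_dna(rng, 14))
        probe = revcomp(seg.sequence[2:10])
        t1 = build_keq_table(probe, [seg], params, 300.0, prune=0.0)
        t2 = build_keq_table(probe, [seg], params, 600.0, prune=0.0)
        assert (
            t1.entries["keq"].rank(method="first").values
            == t2.entries["keq"].rank(method="first").values
        ).all()


def toy_table(ck_entries):
    """Hand-built KeqTable on a fictitious 10-base segment."""
    rows = [
        {
            "segment": "s",
            "strand": "forward",
            "i": 3,
            "j": 2,
            "k": 2 + n,
            "tail_class": "both_cut",
            "keq": k,
        }
        for n, k in enumerate(ck_entries)
    ]
    return KeqTable("probe", pd.DataFrame(rows), {"s": 10}, TEMP_K, 1.0)


class TestFractionBound:
    def test_single_complex_half_occupancy(self):
        """C K_eq = 1 is the Langmuir fixed point alpha = 0.5."""
        frag = cut_probability(2.0)  # p = q = 0.5 -> weight p^2 q = 0.125
        table = toy_table([8.0])  # C K w = 1 with C = 1
        assert fraction_bound(table, frag, {"s": 1.0}) == pytest.approx(0.5)

    def test_wash_above_everything_empties_numerator(self):
        table = toy_table([8.0, 2.0])
        assert (
            fraction_bound(table, cut_probability(2.0), {"s": 1.0}, WashModel(100.0))
            == 0.0
        )

    def test_monotone_in_concentration_without_wash(self, nn_params, rng):
        seg = TargetSegment("s", random_dna(rng, 14))
        table = build_keq_table(random_dna(rng, 6), [seg], nn_params, TEMP_K, prune=0.0)
        frag = cut_probability(5.0)
        alphas = [
            fraction_bound(table, frag, {"s": c}) for c in (1e-20, 1e-16, 1e-12, 1e-8)
        ]
        assert all(a1 < a2 for a1, a2 in zip(alphas, alphas[1:]))
        assert all(0 <= a < 1 for a in alphas)

    def test_wash_never_increases_alpha(self, nn_params, rng):
        seg = TargetSegment("s", random_dna(rng, 16))
        table = build_keq_table(random_dna(rng, 7), [seg], nn_params, TEMP_K, prune=0.0)
        frag = cut_probability(8.0)
        a_off = fraction_bound(table, frag, {"s": 1e-14})
        a_on = fraction_bound(table, frag, {"s": 1e-14}, WashModel(1e10))
        assert a_on <= a_off

    def test_dilution_limit_is_linear(self, nn_params, rng):
        seg = TargetSegment("s", random_dna(rng, 12))
        table = build_keq_table(random_dna(rng, 6), [seg], nn_params, TEMP_K, prune=0.0)
        frag = cut_probability(4.0)
        c = 1e-25
        alpha = fraction_bound(table, frag, {"s": c})
        linear = fraction_bound(table, frag, {"s": 2 * c}) / 2
        assert alpha == pytest.approx(linear, rel=1e-4)

    def test_missing_and_negative_concentrations_rejected(self, nn_params):
        seg = TargetSegment("s", "ACGTACGT")
        table = build_keq_table("ACGT", [seg], nn_params, TEMP_K, prune=0.0)
        with pytest.raises(ValueError):
            fraction_bound(table, cut_probability(3.0), {})
        with pytest.raises(ValueError):
            fraction_bound(table, cut_probability(3.0), {"s": -1.0})

    def test_oracle_equivalence_small_batch(self, nn_params, rng):
        """Collapsed tail classes equal full fragment materialization."""
        for _ in range(12):
            seg = TargetSegment("s", random_dna(rng, int(rng.integers(4, 18))))
            plen = int(rng.integers(2, 9))
            probe = random_dna(rng, plen)
            if plen >= 4 and rng.random() < 0.5:
                m = int(rng.integers(1, plen - 1))
                probe = probe[:m] + "_" + probe[m + 1 :]
            frag = cut_probability(float(rng.choice([1.5, 3.0, 20.0])))
            thr = float(rng.choice([0.0, 1.0, 1e5]))
            concs = {"s": float(rng.choice([1e-6, 1.0]))}
            table = build_keq_table(probe, [seg], nn_params, TEMP_K, prune=0.0)
            a = fraction_bound(table, frag, concs, WashModel(thr))
            b = brute_fraction_bound(
                probe, [seg], concs, frag, thr, nn_params, TEMP_K
            )
            assert a == pytest.approx(b, rel=1e-10, abs=1e-12)


class TestScoreWindows:
    def test_overhanging_target_bases_carry_no_energy(self, nn_params):
        """A fragment dangling past the probe end scores only its paired part."""
        probe = "ACGTAC"
        seg_seq = revcomp(probe) + "GGGG"  # target continues past the probe
        ws = score_windows(encode(probe), encode(seg_seq), nn_params, TEMP_K)
        full = ws.keq[(ws.jp == 6) & (ws.k0 == 0)]
        ws_exact = score_windows(
            encode(probe), encode(revcomp(probe)), nn_params, TEMP_K
        )
        exact = ws_exact.keq[(ws_exact.jp == 6) & (ws_exact.k0 == 0)]
        assert full[0] == pytest.approx(exact[0], rel=1e-12)
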