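"""Decay-chain physics: loading, Bateman solutions, equilibrium, bookkeeping."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from _oracles import ode_activities
from rptdose import (
    DecayDataError,
    bateman_activities,
    cumulated_decays_per_parent_decay,
    equilibrium_ratios,
    load_chain,
)
from rptdose.nuclide_chain import DecayChain, Nuclide, validate_nuclide_records

AC_DAUGHTERS = {"Fr-221", "At-217", "Bi-213", "Po-213", "Tl-209", "Pb-209"}


def make_chain(*specs):
    """Linear/branched test chain from (name, half_life_s, [(daughter, frac), ...])."""
    nucs = [
        Nuclide(name=n, half_life_s=hl, branches=tuple(br),
                energy_MeV={"alpha": 0.0, "electron": 0.0, "photon": 0.0})
        for n, hl, br in specs
    ]
    return DecayChain(root=specs[0][0], nuclides=tuple(nucs))


class TestLoadChain:
    def test_lu177_is_single_radioactive_member(self, lu_chain):
        assert [n.name for n in lu_chain.radioactive_members] == ["Lu-177"]
        assert lu_chain["Hf-177"].stable

    def test_ac225_chain_contains_all_daughters_and_branch(self, ac_chain):
        names = {n.name for n in ac_chain.radioactive_members}
        assert names == {"Ac-225"} | AC_DAUGHTERS
        assert dict(ac_chain["Bi-213"].branches) == pytest.approx(
            {"Po-213": 0.978, "Tl-209": 0.022}
        )
        assert ac_chain["Bi-209"].stable

    def test_unknown_nuclide_raises(self):
        with pytest.raises(DecayDataError, match="unknown nuclide"):
            load_chain("Xx-999")

    @pytest.mark.parametrize(
        "record, message",
        [
            ({"name": "A", "half_life_s": 1.0,
              "branches": [{"daughter": "B", "fraction": 0.5}],
              "energy_MeV": {"alpha": 0, "electron": 0, "photon": 0}}, "sum"),
            ({"name": "A", "half_life_s": -4.0,
              "branches": [{"daughter": "B", "fraction": 1.0}],
              "energy_MeV": {"alpha": 0, "electron": 0, "photon": 0}}, "half-life"),
            ({"name": "A", "half_life_s": 1.0,
              "branches": [{"daughter": "B", "fraction": 1.0}],
              "energy_MeV": {"alpha": -1, "electron": 0, "photon": 0}}, "negative"),
        ],
    )
    def test_invalid_records_rejected_by_name(self, record, message):
        with pytest.raises(DecayDataError, match=message):
            validate_nuclide_records([record])

    def test_cyclic_data_rejected(self):
        with pytest.raises(DecayDataError, match="cyclic"):
            make_chain_cyclic = [
                {"name": "A", "half_life_s": 1.0,
                 "branches": [{"daughter": "B", "fraction": 1.0}],
                 "energy_MeV": {"alpha": 0, "electron": 0, "photon": 0}},
                {"name": "B", "half_life_s": 2.0,
                 "branches": [{"daughter": "A", "fraction": 1.0}],
                 "energy_MeV": {"alpha": 0, "electron": 0, "photon": 0}},
            ]
            import yaml
            from pathlib import Path
            import tempfile
            with tempfile.TemporaryDirectory() as d:
                p = Path(d) / "cyc.yaml"
                p.write_text(yaml.safe_dump({"data_version": "t", "nuclides": make_chain_cyclic}))
                load_chain("A", p)


class TestBateman:
    def test_single_member_identity_and_half_life(self, lu_chain):
        a0 = bateman_activities(lu_chain, 5.0, 0.0)
        assert a0["Lu-177"] == pytest.approx(5.0)
        at = bateman_activities(lu_chain, 5.0, lu_chain.parent.half_life_s)
        assert at["Lu-177"] == pytest.approx(2.5, rel=1e-12)

    def test_two_member_chain_matches_ode_oracle(self):
        # λ1 = 0.1/h, λ2 = 1.0/h, branching 1, evaluated at 5 h
        chain = make_chain(
            ("P", 3600 * math.log(2) / 0.1, [("D", 1.0)]),
            ("D", 3600 * math.log(2) / 1.0, [("S", 1.0)]),
            ("S", math.inf, []),
        )
        t = 5 * 3600.0
        got = bateman_activities(chain, 1.0, t)["D"]
        want = ode_activities(chain, 1.0, [t])["D"][0]
        assert got == pytest.approx(want, rel=1e-8)

    def test_full_ac225_chain_matches_ode_oracle(self, ac_chain):
        times = np.logspace(0.0, np.log10(30 * 86400.0), 20)
        oracle = ode_activities(ac_chain, 1.0, times)
        for k, t in enumerate(times):
            got = bateman_activities(ac_chain, 1.0, t)
            for name, ref in oracle.items():
                if ref[k] > 1e-30:
                    assert got[name] == pytest.approx(ref[k], rel=1e-6), (name, t)

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(t=st.floats(min_value=0.0, max_value=3e6))
    def test_activities_never_negative(self, t):
        chain = load_chain("Ac-225")
        assert all(v >= 0.0 for v in bateman_activities(chain, 1.0, t).values())

    def test_atom_conservation_against_ode(self, ac_chain):
        # atoms decayed from root == atoms banked in stable members, via the
        # ODE system extended with stable bins
        t = 5 * 86400.0
        acts = ode_activities(ac_chain, 1.0, [t])
        lam_root = ac_chain.parent.decay_constant
        n_root0 = 1.0 / lam_root
        decayed_root = n_root0 - acts["Ac-225"][0] / lam_root
        # per-parent-decay bookkeeping: every decayed root atom ends in Bi-209
        # after all daughters decay; at finite t the in-flight atoms are the
        # daughters' current populations
        in_flight = sum(
            acts[n.name][0] / n.decay_constant
            for n in ac_chain.radioactive_members
            if n.name != "Ac-225"
        )
        banked = decayed_root - in_flight
        assert 0.0 <= banked <= decayed_root
        # late time: nearly everything decayed sits in the stable sink
        t_late = 200 * 86400.0
        acts_late = ode_activities(ac_chain, 1.0, [t_late])
        in_flight_late = sum(
            acts_late[n.name][0] / n.decay_constant
            for n in ac_chain.radioactive_members if n.name != "Ac-225"
        )
        decayed_late = n_root0 - acts_late["Ac-225"][0] / lam_root
        assert in_flight_late / decayed_late < 1e-4


class TestEquilibrium:
    def test_single_member_chain_is_trivially_one(self, lu_chain):
        assert equilibrium_ratios(lu_chain) == {"Lu-177": 1.0}

    def test_fast_daughter_limit(self):
        chain = make_chain(
            ("P", 1e9, [("D", 1.0)]), ("D", 1.0, [("S", 1.0)]), ("S", math.inf, [])
        )
        assert equilibrium_ratios(chain)["D"] == pytest.approx(1.0, abs=1e-3)

    def test_ratios_match_bateman_at_late_times(self, ac_chain):
        slowest = max(n.half_life_s for n in ac_chain.radioactive_members if n.name != "Ac-225")
        t = 10 * slowest
        acts = bateman_activities(ac_chain, 1.0, t)
        ratios = equilibrium_ratios(ac_chain)
        for name, ratio in ratios.items():
            assert acts[name] / acts["Ac-225"] == pytest.approx(ratio, rel=0.01), name

    def test_po213_ratio_is_branching_times_lambda_correction(self, ac_chain):
        ratios = equilibrium_ratios(ac_chain)
        lam_root = ac_chain.parent.decay_constant
        correction = 1.0
        for name in ("Fr-221", "At-217", "Bi-213", "Po-213"):
            lam = ac_chain[name].decay_constant
            correction *= lam / (lam - lam_root)
        assert ratios["Po-213"] == pytest.approx(0.978 * correction, rel=1e-9)
        assert 0.978 < ratios["Po-213"] < 0.99  # correction is small but real

    def test_no_equilibrium_for_long_lived_daughter(self):
        chain = make_chain(
            ("P", 1.0, [("D", 1.0)]), ("D", 100.0, [("S", 1.0)]), ("S", math.inf, [])
        )
        with pytest.raises(DecayDataError, match="secular equilibrium"):
            equilibrium_ratios(chain)


class TestCumulatedDecays:
    def test_linear_chain_conserves_decays(self):
        chain = make_chain(
            ("A", 100.0, [("B", 1.0)]), ("B", 10.0, [("C", 1.0)]),
            ("C", 1.0, [("S", 1.0)]), ("S", math.inf, []),
        )
        for mode in ("equilibrium", "bateman"):
            vals = cumulated_decays_per_parent_decay(chain, mode=mode)
            assert all(v == pytest.approx(1.0, rel=1e-9) for v in vals.values())

    def test_branch_point_splits_and_sums_to_one(self, ac_chain):
        vals = cumulated_decays_per_parent_decay(ac_chain)
        assert vals["Po-213"] == pytest.approx(0.978)
        assert vals["Tl-209"] == pytest.approx(0.022)
        assert vals["Po-213"] + vals["Tl-209"] == pytest.approx(1.0)
        assert vals["Pb-209"] == pytest.approx(1.0)  # branches reconverge

    @pytest.mark.parametrize("root", ["Lu-177", "Ac-225"])
    def test_bateman_mode_equals_equilibrium_mode(self, root):
        chain = load_chain(root)
        eq = cumulated_decays_per_parent_decay(chain, "equilibrium")
        bat = cumulated_decays_per_parent_decay(chain, "bateman")
        for name in eq:
            assert bat[name] == pytest.approx(eq[name], rel=1e-6)


def test_chain_energy_is_alpha_dominated_for_ac225(ac_chain, lu_chain):
    ac_e = ac_chain.energy_per_parent_decay_MeV()
    lu_e = lu_chain.energy_per_parent_decay_MeV()
    assert ac_e["alpha"] > 20.0  # several alphas of ~6-8 MeV each
    assert (ac_e["alpha"] + ac_e["electron"]) / (lu_e["alpha"] + lu_e["electron"]) > 50.0
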