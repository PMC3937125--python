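"""Circuit layer: Hill input, parameter rescaling, reaction assembly."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from micffl.circuits import (
    TOPOLOGIES,
    KineticParameters,
    TopologyName,
    build_reaction_system,
    get_topology,
    hill_activation,
    interaction_strength,
    kon_for_strength,
    load_parameters,
    rescale_parameters,
    save_parameters,
    unrescale_parameters,
    with_interaction_strength,
)
from micffl.errors import ConfigurationError


class TestHill:
    @pytest.mark.parametrize(
        "ptf,n,h,k_max,expected",
        [
            (3.0, 1.0, 3.0, 10.0, 5.0),       # half saturation at pTF = h
            (3.0, 4.0, 3.0, 10.0, 5.0),       # independent of n at pTF = h
            (0.0, 2.0, 5.0, 7.0, 0.0),        # no activator, no transcription
        ],
    )
    def test_reference_points(self, ptf, n, h, k_max, expected):
        assert hill_activation(ptf, n, h, k_max) == pytest.approx(expected)

    def test_saturation_limit(self):
        assert hill_activation(1e6 * 2.0, 2.0, 2.0, 1.0) == pytest.approx(
            1.0, abs=1e-12
        )

    @pytest.mark.parametrize("bad", [-1.0, float("nan"), float("inf")])
    def test_domain_errors(self, bad):
        with pytest.raises(ValueError):
            hill_activation(bad, 2.0, 1.0, 1.0)
        with pytest.raises(ValueError):
            hill_activation(1.0, 2.0, bad if bad == bad else -1.0, 1.0)

    @given(
        p=st.floats(0, 1e6), n=st.floats(1, 8), h=st.floats(0.01, 1e3),
        dp=st.floats(0.001, 100),
    )
    def test_monotone_and_bounded(self, p, n, h, dp):
        lo = hill_activation(p, n, h, 3.0)
        hi = hill_activation(p + dp, n, h, 3.0)
        # monotone up to floating-point roundoff at saturation
        assert 0.0 <= lo <= hi + 3.0 * 1e-12
        assert hi < 3.0 + 1e-12


class TestRescaling:
    def test_equal_degradations_become_one(self):
        p = KineticParameters(g_pt=4.0, g_ptf=4.0, g_mtf=4.0, g_mt=4.0,
                              g_mi=4.0, g_ctf=4.0, g_ct=4.0)
        r = rescale_parameters(p)
        assert r.g_pt == r.g_ptf == r.g_mtf == r.g_mt == 1.0

    def test_already_rescaled_is_identity(self, params):
        assert rescale_parameters(params) == params

    @given(scale=st.floats(0.01, 100), k=st.floats(0.1, 50))
    def test_round_trip(self, scale, k):
        p = KineticParameters(g_pt=scale, k_mtf=k)
        r = rescale_parameters(p)
        assert r.g_pt == pytest.approx(1.0)
        back = unrescale_parameters(r, scale)
        for f in ("k_mi", "k_mtf", "g_mt", "k_on_t", "g_pt"):
            assert getattr(back, f) == pytest.approx(getattr(p, f), rel=1e-12)

    def test_zero_degradation_rejected(self, params):
        with pytest.raises(ZeroDivisionError):
            rescale_parameters(params.replace(g_pt=0.0))


class TestParameterValidation:
    def test_negative_rate_rejected(self):
        with pytest.raises(ConfigurationError):
            KineticParameters(k_mtf=-1.0)

    @pytest.mark.parametrize("field,value", [
        ("alpha", 1.5), ("hill_h", 0.0), ("hill_n", 0.5), ("omega", 0.0),
    ])
    def test_bounds(self, field, value):
        with pytest.raises(ConfigurationError):
            KineticParameters(**{field: value})

    def test_strict_topology_mismatch(self, params):
        with pytest.raises(ConfigurationError):
            build_reaction_system(params, "NM1", strict=True)
        ok = params.replace(k_mi=0.0, k_on_tf=0.0, k_on_t=0.0)
        assert build_reaction_system(ok, "NM1", strict=True).n_reactions == 8


class TestReactionSystem:
    def test_nm1_reaction_enumeration(self, params):
        sys = build_reaction_system(params, "NM1")
        # production + decay for each of mTF, pTF, mT, pT
        names = {r.name for r in sys.reactions}
        assert names == {
            "transcribe_mTF", "degrade_mTF", "translate_pTF", "degrade_pTF",
            "transcribe_mT", "degrade_mT", "translate_pT", "degrade_pT",
        }

    def test_recycling_splits_degradation(self, params):
        sys = build_reaction_system(params.replace(alpha=0.3), "MICFFL")
        by_name = {r.name: r for r in sys.reactions}
        for c, g in (("cTF", params.g_ctf), ("cT", params.g_ct)):
            assert by_name[f"recycle_{c}"].rate == pytest.approx(0.3 * g)
            assert by_name[f"degrade_{c}"].rate == pytest.approx(0.7 * g)

    @pytest.mark.parametrize("alpha,n_channels", [(0.0, 1), (1.0, 1), (0.5, 2)])
    def test_degenerate_alpha_single_channel(self, params, alpha, n_channels):
        sys = build_reaction_system(params.replace(alpha=alpha), "MICFFL")
        per_complex = [r for r in sys.reactions if "cTF" in r.name
                       and r.name != "bind_mi_mTF"]
        assert len(per_complex) == n_channels

    def test_flag_removal_is_surgical(self, params):
        """Disabling the miRNA->T link removes exactly its reactions."""
        full = {r.name for r in build_reaction_system(params, "MICFFL").reactions}
        nm2 = {r.name for r in build_reaction_system(params, "NM2").reactions}
        assert full - nm2 == {"bind_mi_mT", "degrade_cT"}

    @given(
        state=st.lists(st.integers(0, 500), min_size=7, max_size=7),
        alpha=st.sampled_from([0.0, 0.5, 1.0]),
    )
    def test_propensities_nonnegative(self, state, alpha):
        p = KineticParameters(alpha=alpha)
        sys = build_reaction_system(p, "MICFFL")
        a = sys.propensities(np.array(state, dtype=float))
        assert np.all(a >= 0.0) and np.all(np.isfinite(a))

    def test_alpha_one_conserves_mirna_stoichiometrically(self, params):
        sys = build_reaction_system(params.replace(alpha=1.0), "MICFFL")
        weights = np.array([
            1 if s in ("mi", "cTF", "cT") else 0 for s in sys.species
        ])
        for r, rxn in enumerate(sys.reactions):
            if "cTF" in rxn.name or "cT" in rxn.name or "bind" in rxn.name:
                assert sys.stoichiometry[r] @ weights == 0, rxn.name

    def test_omega_scaling(self, params):
        """Transcription propensities scale with omega, binding with 1/omega."""
        s1 = build_reaction_system(params, "MICFFL")
        s100 = build_reaction_system(params.replace(omega=100.0), "MICFFL")
        r1 = {r.name: r for r in s1.reactions}
        r100 = {r.name: r for r in s100.reactions}
        assert r100["transcribe_mTF"].rate == pytest.approx(100 * r1["transcribe_mTF"].rate)
        assert r100["bind_mi_mTF"].rate == pytest.approx(r1["bind_mi_mTF"].rate / 100)
        assert r100["degrade_pT"].rate == pytest.approx(r1["degrade_pT"].rate)


class TestTopologies:
    def test_registry_matches_motif_definitions(self):
        t = TOPOLOGIES
        mic = t[TopologyName.MICFFL]
        assert mic.mirna_targets_tf and mic.mirna_targets_t and mic.tf_regulates_t
        assert not mic.independent_mirnas
        nm1 = t[TopologyName.NM1]
        assert nm1.tf_regulates_t and not nm1.has_mirna
        assert t[TopologyName.NM2].mirna_targets_tf and not t[TopologyName.NM2].mirna_targets_t
        assert t[TopologyName.NM3].mirna_targets_t and not t[TopologyName.NM3].mirna_targets_tf
        nm4 = t[TopologyName.NM4]
        assert nm4.mirna_targets_tf and nm4.mirna_targets_t and not nm4.tf_regulates_t
        nm5 = t[TopologyName.NM5]
        assert nm5.independent_mirnas and nm5.tf_regulates_t
        assert nm5.species == ("mi", "mi2", "mTF", "pTF", "mT", "pT", "cTF", "cT")

    def test_get_topology_case_insensitive(self):
        assert get_topology("micffl").name is TopologyName.MICFFL


class TestInteractionStrength:
    def test_increasing_in_kon(self, params):
        f1 = interaction_strength(params)
        f2 = interaction_strength(params.replace(k_on_t=2 * params.k_on_t))
        assert f2 > f1 >= 0

    def test_round_trip(self, params):
        p = with_interaction_strength(params, 7.5)
        assert interaction_strength(p, "t") == pytest.approx(7.5)
        assert interaction_strength(p, "tf") == pytest.approx(7.5)
        assert kon_for_strength(7.5, params.g_ct) == pytest.approx(p.k_on_t)


class TestYaml:
    def test_round_trip(self, tmp_path, params):
        path = tmp_path / "params.yaml"
        save_parameters(path, params.replace(alpha=0.25), get_topology("NM3"))
        loaded, topo = load_parameters(path)
        assert loaded == params.replace(alpha=0.25)
        assert topo.name is TopologyName.NM3

    def test_unknown_key_rejected(self, tmp_path):
        path = tmp_path / "bad.yaml"
        path.write_text("topology: MICFFL\nnot_a_rate: 3\n")
        with pytest.raises(ConfigurationError):
            load_parameters(path)

    def test_missing_topology_rejected(self, tmp_path):
        path = tmp_path / "bad.yaml"
        path.write_text("k_mi: 3\n")
        with pytest.raises(ConfigurationError):
            load_parameters(path)
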