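"""Scenario-level tests on deliberately coarse meshes (seconds per run)."""

import numpy as np
import pytest

from osseodebond.contact_law import ContactLaw
from osseodebond.response import ResponseHistory
from osseodebond.scenarios import (AciConfig, CsiConfig, build_aci, build_csi,
                                   run_csi_test, sweep)


def coarse_csi(**kw):
    base = dict(n_bone_plan=9, n_bone_z=1, n_implant_z=1, du=2e-6,
                n_removal_steps=45)
    base.update(kw)
    return CsiConfig(**base)


@pytest.fixture(scope="module")
def iia_mc_history():
    cfg = coarse_csi(law="mc")
    return cfg, run_csi_test(build_csi(cfg), "IIa")


class TestCsi:
    def test_default_mesh_matches_reference_element_counts(self):
        m = build_csi(CsiConfig())
        assert int((m.fem.mesh.body == "implant").sum()) == 18
        assert int((m.fem.mesh.body == "bone").sum()) == 450
        assert m.pair.master_facets.shape[0] == 9
        assert m.pair.slave_facets.shape[0] == 225

    def test_refined_mesh_scales_structured(self):
        m = build_csi(CsiConfig(refine=2))
        assert int((m.fem.mesh.body == "implant").sum()) == 8 * 18
        assert int((m.fem.mesh.body == "bone").sum()) == 8 * 450

    def test_implant_centered_on_block(self):
        m = build_csi(CsiConfig())
        pts = m.fem.mesh.nodes[np.unique(m.pair.master_facets)]
        np.testing.assert_allclose(pts[:, :2].mean(axis=0), 0.0, atol=1e-12)

    def test_press_lands_on_target_force(self, iia_mc_history):
        cfg, hist = iia_mc_history
        df = hist.to_frame()
        press = df[df.stage == "press"]
        assert press.F_z.iloc[-1] == pytest.approx(-70.0, abs=0.05)

    def test_mode2_compression_peak_and_coulomb_tail(self, iia_mc_history):
        # stick peak ~ mu_ub * N, decaying toward the broken-state mu_b * N
        cfg, hist = iia_mc_history
        rem = hist.to_frame().query("stage == 'removal'")
        assert rem.F_x.max() == pytest.approx(0.44 * 70.0, rel=0.05)
        assert rem.F_x.iloc[-1] == pytest.approx(0.3 * 70.0, rel=0.05)

    def test_phibar_non_increasing_during_removal(self, iia_mc_history):
        cfg, hist = iia_mc_history
        rem = hist.to_frame().query("stage == 'removal'")
        assert np.all(np.diff(rem.phi_bar.to_numpy()) <= 1e-12)

    def test_normal_hold_constant_during_slide(self, iia_mc_history):
        cfg, hist = iia_mc_history
        rem = hist.to_frame().query("stage == 'removal'")
        np.testing.assert_allclose(rem.F_z, -70.0, atol=0.2)

    def test_emc_with_zero_t0_reproduces_mc_curves(self):
        """Law degeneration oracle on the oblique mixed-mode test."""
        kw = dict(preload=-70.0, alpha_deg=45.0, n_removal_steps=25, du=2e-6)
        h_mc = run_csi_test(build_csi(coarse_csi(law="mc", **kw)), "I+IIc")
        h_emc = run_csi_test(build_csi(coarse_csi(law="emc", t0=0.0, **kw)),
                             "I+IIc")
        a = h_mc.to_frame().query("stage == 'removal'")
        b = h_emc.to_frame().query("stage == 'removal'")
        np.testing.assert_allclose(b.F_x.to_numpy(), a.F_x.to_numpy(),
                                   atol=1e-6 * 70)
        np.testing.assert_allclose(b.F_z.to_numpy(), a.F_z.to_numpy(),
                                   atol=1e-6 * 70)

    def test_peaks_non_decreasing_in_phi0(self):
        peaks = []
        for phi0 in (0.0, 0.5, 1.0):
            cfg = coarse_csi(law="mc", phi0=phi0, n_removal_steps=30)
            h = run_csi_test(build_csi(cfg), "IIa")
            peaks.append(h.to_frame().query("stage == 'removal'").F_x.max())
        assert peaks[0] <= peaks[1] <= peaks[2]
        # broken/unbroken friction endpoints bracket the blend
        assert peaks[0] == pytest.approx(0.3 * 70, rel=0.05)
        assert peaks[2] == pytest.approx(0.44 * 70, rel=0.05)

    def test_mode2_symmetry_plus_minus_x(self):
        cfg = coarse_csi(law="mc", n_removal_steps=20)
        h_plus = run_csi_test(build_csi(cfg), "IIa")
        m = build_csi(cfg)
        hist = ResponseHistory()
        m.press_to_force(-70.0, cfg.du * 2, 60, hist)
        m.set_osseointegration(cfg.phi0)
        m.removal(hist, n_steps=20, du=(-cfg.du, 0.0, 0.0), hold_z=-70.0)
        a = h_plus.to_frame().query("stage == 'removal'").F_x.to_numpy()
        b = hist.to_frame().query("stage == 'removal'").F_x.to_numpy()
        np.testing.assert_allclose(b, -a, atol=5e-3 * 70)

    def test_tension_test_requires_emc(self):
        with pytest.raises(ValueError, match="EMC"):
            run_csi_test(build_csi(coarse_csi(law="mc")), "IIb")

    def test_unknown_test_id(self):
        with pytest.raises(ValueError):
            run_csi_test(build_csi(coarse_csi()), "IV")


class TestAci:
    def test_cavity_radius_follows_interference_fit(self):
        cfg = AciConfig(IF=1.0e-3)
        assert cfg.R_b == pytest.approx(25.0e-3)
        m = build_aci(cfg)
        # cavity-surface nodes sit at R_b (up to the rim relief ring)
        cav = np.unique(m.pair.slave_facets)
        r = np.linalg.norm(m.fem.mesh.nodes[cav], axis=1)
        assert np.median(np.round(r, 6)) == pytest.approx(cfg.R_b, rel=1e-9)

    def test_zero_interference_is_conforming(self):
        m = build_aci(AciConfig(IF=0.0))
        ev = m.pair.evaluate(m.fem.mesh.nodes)
        ok = ev.facet_idx >= 0
        assert ok.any()
        assert ev.g_n[ok].min() > -1e-9  # no initial penetration

    def test_bodies_and_driven_set(self):
        m = build_aci(AciConfig())
        assert set(np.unique(m.fem.mesh.body)) == {"bone", "implant", "ancillary"}
        assert m.driven.size > 0

    def test_low_friction_pullout_force_vanishes(self):
        """mu_b below ~0.15 cannot retain the press-fit: pull-out peak ~ 0."""
        cfg = AciConfig(mu_b=0.1, law="mc", n=4, bone_layers=3, n_removal=25,
                        phi0=0.0)
        h = run_aci_removal_cached(cfg, "I")
        rem = h.to_frame().query("stage == 'removal_modeI'")
        assert rem.F_z.max() < 0.01 * abs(cfg.F0)
        assert h.d0 > 0.0
        ins = h.to_frame().query("stage == 'insertion'")
        assert ins.F_z.iloc[-1] == pytest.approx(cfg.F0, abs=1.0)


_aci_cache = {}


def run_aci_removal_cached(cfg, mode):
    from osseodebond.scenarios import run_aci_removal

    key = (repr(cfg), mode)
    if key not in _aci_cache:
        _aci_cache[key] = run_aci_removal(build_aci(cfg), mode)
    return _aci_cache[key]


class TestSweep:
    def test_single_config_sweep_matches_direct_run(self, iia_mc_history, tmp_path):
        cfg, hist = iia_mc_history
        df = sweep([cfg], [cfg.phi0], mode="IIa", cache_dir=tmp_path)
        assert len(df) == 1
        assert df.status.iloc[0] == "ok"
        assert df.F_x_max.iloc[0] == pytest.approx(
            hist.to_frame().query("stage=='removal'").F_x.max(), rel=1e-6)
        # cached rerun gives identical rows without recomputation
        df2 = sweep([cfg], [cfg.phi0], mode="IIa", cache_dir=tmp_path)
        assert df2.F_x_max.iloc[0] == df.F_x_max.iloc[0]

    def test_failures_recorded_not_raised(self):
        bad = coarse_csi(law="mc")  # tension test demands EMC -> failure row
        df = sweep([bad], [1.0], mode="IIb")
        assert df.status.iloc[0].startswith("failed")
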