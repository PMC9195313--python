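"""Phase/amplitude extraction, mean-vector-length PAC with circular-shift
surrogates, and cross-frequency phase-slope directionality."""
import numpy as np
import pytest

from facegamma import coupling as cpl
from facegamma import io_preprocess as iop
from facegamma import simulate as sim
from helpers import make_channels, make_epochs


@pytest.fixture(scope="module")
def coupled_scene():
    """60 face trials with 6 Hz fusiform phase driving 60-90 Hz amygdala
    amplitude at +15 ms lag."""
    spec = sim.CouplingSpec("fusiform", "amygdala", 6.0, (60.0, 90.0),
                            0.8, 15.0)
    cfg = sim.SimConfig(n_per_category=12, regions=("amygdala", "fusiform"),
                        erp_components=(), gamma_effects=(),
                        coupling_specs=(spec,), seed=5)
    ev = sim.schedule_events(cfg)
    rec = sim.synthesize_recording(cfg, ev, "P01", "O")
    return iop.epoch(rec.pick(["AM1_L", "FU1_L"]), ev)


class TestExtractPhaseAmp:
    def test_phase_advances_at_carrier_rate(self):
        fs = 1024.0
        t = np.arange(2662) / fs
        ep = make_epochs(np.sin(2 * np.pi * 8.0 * t)[None, None, :], fs=fs)
        phase, _ = cpl.extract_phase_amp(ep, "AM1_L")
        p8 = np.unwrap(phase[0, 5, :])  # 8 Hz bin
        slope = np.polyfit(np.arange(p8.size) / fs, p8, 1)[0]
        assert slope == pytest.approx(2 * np.pi * 8.0, rel=0.02)

    def test_constant_envelope_carrier_has_low_cv(self):
        fs = 1024.0
        t = np.arange(2662) / fs
        ep = make_epochs(np.sin(2 * np.pi * 80.0 * t)[None, None, :], fs=fs)
        _, amp = cpl.extract_phase_amp(ep, "AM1_L")
        env = amp[0, np.argmin(np.abs(cpl.AMP_FREQS - 80.0)), :]
        assert env.std() / env.mean() < 0.05

    def test_scaling_doubles_amplitude_not_phase(self, rng):
        x = rng.normal(size=(2, 1, 2662))
        ep1, ep2 = make_epochs(x), make_epochs(2.0 * x)
        p1, a1 = cpl.extract_phase_amp(ep1, "AM1_L")
        p2, a2 = cpl.extract_phase_amp(ep2, "AM1_L")
        np.testing.assert_allclose(a2, 2.0 * a1, rtol=1e-9)
        np.testing.assert_allclose(p2, p1, atol=1e-9)

    def test_out_of_grid_frequencies_rejected(self, rng):
        ep = make_epochs(rng.normal(size=(1, 1, 2662)))
        with pytest.raises(ValueError):
            cpl.extract_phase_amp(ep, "AM1_L", phase_freqs=np.array([25.0]))
        with pytest.raises(ValueError):
            cpl.extract_phase_amp(ep, "AM1_L", amp_freqs=np.array([30.0]))


class TestPacComodulogram:
    def test_mi_invariant_to_constant_phase_offset(self, rng):
        phase = rng.uniform(-np.pi, np.pi, size=(12, 3, 500))
        amp = rng.gamma(2.0, 1.0, size=(12, 4, 500))
        a = cpl.pac_comodulogram(phase, amp, 1024.0, n_surrogates=20, seed=0,
                                 phase_freqs=np.arange(3), amp_freqs=np.arange(4))
        b = cpl.pac_comodulogram(phase + 1.234, amp, 1024.0, n_surrogates=20,
                                 seed=0, phase_freqs=np.arange(3),
                                 amp_freqs=np.arange(4))
        np.testing.assert_allclose(a.mi, b.mi, rtol=1e-12)

    def test_constant_amplitude_gives_vanishing_mi(self, rng):
        n = 40000
        phase = rng.uniform(-np.pi, np.pi, size=(1, 1, n))
        amp = np.ones((1, 1, n))
        res = cpl.pac_comodulogram(phase, amp, 1024.0, n_surrogates=20,
                                   seed=0, phase_freqs=np.arange(1),
                                   amp_freqs=np.arange(1))
        assert res.mi[0, 0] < 3.0 / np.sqrt(n)

    def test_detects_injected_coupling_for_faces_only(self, coupled_scene):
        pac = cpl.pac_between(coupled_scene, "FU1_L", "AM1_L",
                              sim.FACE_CATEGORIES, n_surrogates=200, seed=0)
        ip = np.argmin(np.abs(pac.phase_freqs - 6.0))
        ia = np.argmin(np.abs(pac.amp_freqs - 75.0))
        assert pac.z[ia, ip] >= 2.0
        assert pac.direction == "fusiform-phase -> amygdala-amp"
        mos = cpl.pac_between(coupled_scene, "FU1_L", "AM1_L", "mosaic",
                              n_surrogates=200, seed=0)
        assert mos.z[ia, ip] < 2.0

    def test_surrogate_z_calibration_on_white_noise(self, rng):
        phase = rng.uniform(-np.pi, np.pi, size=(30, 10, 768))
        amp = rng.gamma(2.0, 1.0, size=(30, 10, 768))
        res = cpl.pac_comodulogram(phase, amp, 1024.0, n_surrogates=200,
                                   seed=1, phase_freqs=np.arange(10),
                                   amp_freqs=np.arange(10))
        assert abs(res.z.mean()) < 0.2
        assert 0.8 < res.z.std() < 1.2

    def test_few_trials_warns(self, rng):
        phase = rng.uniform(-np.pi, np.pi, size=(4, 1, 2200))
        amp = rng.gamma(2.0, 1.0, size=(4, 1, 2200))
        with pytest.warns(UserWarning, match="10 usable trials"):
            cpl.pac_comodulogram(phase, amp, 1024.0, n_surrogates=10, seed=0,
                                 phase_freqs=np.arange(1),
                                 amp_freqs=np.arange(1))


class TestPhaseSlopeIndex:
    def test_exact_antisymmetry(self, rng):
        x = rng.normal(size=(15, 768))
        y = rng.normal(size=(15, 768))
        a = cpl.phase_slope_index(x, y, 1024.0, 6.0)
        b = cpl.phase_slope_index(y, x, 1024.0, 6.0)
        assert a == pytest.approx(-b, rel=1e-12, abs=1e-15)

    def test_known_lag_gives_positive_psi(self, rng):
        # y is a delayed noisy copy of slow x: x leads -> psi > 0
        fs, n_tr, n_t = 1024.0, 40, 768
        lag = int(0.020 * fs)
        psis = []
        for _ in range(3):
            base = rng.normal(size=(n_tr, n_t + lag))
            from scipy.signal import butter, sosfiltfilt
            sos = butter(2, [4, 9], btype="bandpass", fs=fs, output="sos")
            slow = sosfiltfilt(sos, base, axis=1)
            x = slow[:, lag:]
            y = slow[:, :-lag] + 0.5 * rng.normal(size=(n_tr, n_t))
            psis.append(cpl.phase_slope_index(x, y, fs, 6.0))
        assert np.mean(psis) > 0

    def test_independent_channels_rarely_significant(self, rng):
        x = rng.normal(size=(30, 6, 768))
        y = rng.normal(size=(30, 8, 768))
        res = cpl.psi_map(x, y, 1024.0, phase_freqs=np.arange(5.0, 11.0),
                          amp_freqs=np.arange(50.0, 90.0, 5.0),
                          n_surrogates=150, seed=2)
        assert (np.abs(res.z) < 2.0).mean() >= 0.85

    def test_too_few_segments_rejected(self, rng):
        with pytest.raises(ValueError, match="segments"):
            cpl.phase_slope_index(rng.normal(size=(1, 768)),
                                  rng.normal(size=(1, 768)), 1024.0, 6.0)


class TestRestrictPsiToPac:
    def make_pair(self, rng, z_pac):
        nA, nP = len(cpl.AMP_FREQS), len(cpl.PHASE_FREQS)
        pac = cpl.CouplingMap(mi=np.ones((nA, nP)), z=z_pac,
                              phase_freqs=cpl.PHASE_FREQS.copy(),
                              amp_freqs=cpl.AMP_FREQS.copy())
        psi = cpl.PSIResult(psi=rng.normal(size=(nA, nP)),
                            z=rng.normal(size=(nA, nP)),
                            phase_freqs=cpl.PHASE_FREQS.copy(),
                            amp_freqs=cpl.AMP_FREQS.copy())
        return pac, psi

    def test_empty_mask_blanks_everything(self, rng):
        pac, psi = self.make_pair(rng, np.zeros((len(cpl.AMP_FREQS),
                                                 len(cpl.PHASE_FREQS))))
        out = cpl.restrict_psi_to_pac(psi, pac)
        assert np.isnan(out.z).all()

    def test_full_mask_is_identity(self, rng):
        pac, psi = self.make_pair(rng, np.full((len(cpl.AMP_FREQS),
                                                len(cpl.PHASE_FREQS)), 5.0))
        out = cpl.restrict_psi_to_pac(psi, pac)
        np.testing.assert_array_equal(out.z, psi.z)

    def test_single_pixel_mask(self, rng):
        z = np.zeros((len(cpl.AMP_FREQS), len(cpl.PHASE_FREQS)))
        z[4, 7] = 3.0
        pac, psi = self.make_pair(rng, z)
        out = cpl.restrict_psi_to_pac(psi, pac)
        assert np.isfinite(out.z).sum() == 1
        assert out.z[4, 7] == psi.z[4, 7]

    def test_grid_mismatch_rejected(self, rng):
        pac, psi = self.make_pair(rng, np.zeros((len(cpl.AMP_FREQS),
                                                 len(cpl.PHASE_FREQS))))
        psi.phase_freqs = psi.phase_freqs + 1.0
        with pytest.raises(ValueError, match="grids"):
            cpl.restrict_psi_to_pac(psi, pac)


class TestChooseChannel:
    def test_fewest_rejected_wins_ties_by_order(self, rng):
        chans = make_channels(3)
        ep = make_epochs(rng.normal(size=(10, 3, 256)), channels=chans)
        ep.kept_mask[:3, 0] = False
        ep.kept_mask[:1, 1] = False
        ep.kept_mask[:1, 2] = False
        # AM2 and AM3 tie at one rejection; order breaks the tie
        assert cpl.choose_channel(ep, "amygdala") == "AM2_L"
        ep.kept_mask[:4, 1] = False
        assert cpl.choose_channel(ep, "amygdala") == "AM3_L"

    def test_unknown_region_rejected(self, rng):
        ep = make_epochs(rng.normal(size=(2, 1, 128)))
        with pytest.raises(ValueError):
            cpl.choose_channel(ep, "hippocampus")
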