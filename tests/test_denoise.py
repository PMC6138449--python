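"""Denoising operators and the three pipeline compositions."""

import numpy as np
import pytest

from cpmkit import denoise as dn
from cpmkit.runs import RunTimeSeries

TR = 0.72


def _run(channels, roles=None, fd=None, motion=None, tr=TR):
    t = channels.shape[0]
    return RunTimeSeries(
        subject_id="S0", run_label="REST1_LR", channels=channels,
        channel_roles=roles or ["parcel"] * channels.shape[1],
        motion_params=motion if motion is not None else np.zeros((t, 6)),
        fd=fd if fd is not None else np.zeros(t), tr_s=tr)


class TestZScore:
    def test_definition_and_idempotence(self):
        rng = np.random.default_rng(0)
        r = _run(rng.standard_normal((100, 3)) * 5 + 2)
        z1 = dn.zscore_channels(r)
        assert np.allclose(z1.channels.mean(axis=0), 0, atol=1e-12)
        assert np.allclose(z1.channels.std(axis=0, ddof=1), 1, atol=1e-12)
        z2 = dn.zscore_channels(z1)
        assert np.allclose(z1.channels, z2.channels, atol=1e-12)

    def test_constant_channel_dropped_with_warning(self):
        x = np.random.default_rng(1).standard_normal((50, 2))
        x[:, 1] = 3.0
        with pytest.warns(UserWarning, match="zero-variance"):
            z = dn.zscore_channels(_run(x))
        assert np.all(z.channels[:, 1] == 0)


class TestLegendreDetrend:
    def test_cubic_annihilated(self):
        t = np.linspace(-1, 1, 200)
        x = (2 + 3 * t - t ** 2 + 0.5 * t ** 3)[:, None]
        out = dn.legendre_detrend(_run(x), 3, roles=("parcel",))
        assert np.max(np.abs(out.channels)) < 1e-8

    def test_residual_orthogonal_to_basis(self):
        rng = np.random.default_rng(2)
        r = _run(rng.standard_normal((150, 2)))
        out = dn.legendre_detrend(r, 3, roles=("parcel",))
        basis = dn._legendre_basis(150, 3)
        assert np.max(np.abs(basis.T @ out.channels)) < 1e-8

    def test_low_frequency_sinusoid_barely_attenuated(self):
        # 0.05 Hz over 1200 TRs of 0.72 s is ~43 cycles: far above the
        # polynomial band, so a degree-3 detrend should not touch it
        t = np.arange(1200) * TR
        x = np.sin(2 * np.pi * 0.05 * t)[:, None]
        out = dn.legendre_detrend(_run(x), 3, roles=("parcel",))
        atten = 1 - np.linalg.norm(out.channels) / np.linalg.norm(x)
        assert abs(atten) < 0.01

    def test_roles_respected(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal((80, 2))
        r = _run(x.copy(), roles=["parcel", "WM"])
        out = dn.legendre_detrend(r, 2, roles=("WM",))
        assert np.array_equal(out.channels[:, 0], x[:, 0])
        assert not np.array_equal(out.channels[:, 1], x[:, 1])


class TestRegressNuisance:
    def test_self_regression_gives_zero(self):
        rng = np.random.default_rng(4)
        x = rng.standard_normal((100, 1))
        out = dn.regress_nuisance(_run(x), x)
        assert np.max(np.abs(out.channels)) < 1e-10

    def test_residual_orthogonal_to_design(self):
        rng = np.random.default_rng(5)
        x = rng.standard_normal((100, 3))
        design = rng.standard_normal((100, 4))
        out = dn.regress_nuisance(_run(x), design)
        assert np.max(np.abs(design.T @ out.channels)) < 1e-8

    def test_orthogonal_design_only_demeans(self):
        rng = np.random.default_rng(6)
        x = rng.standard_normal((400, 1))
        x -= x.mean()
        design = rng.standard_normal((400, 1))
        design -= design.mean()
        design -= x * (x.T @ design) / (x.T @ x)  # exactly orthogonal
        out = dn.regress_nuisance(_run(x.copy()), design)
        assert np.allclose(out.channels, x, atol=1e-10)

    def test_collinear_columns_dropped_with_warning(self):
        rng = np.random.default_rng(7)
        x = rng.standard_normal((60, 1))
        d = rng.standard_normal((60, 1))
        with pytest.warns(UserWarning, match="collinear"):
            dn.regress_nuisance(_run(x), np.hstack([d, d]))


class TestExpandMotion:
    def test_column_counts(self):
        m = np.random.default_rng(8).standard_normal((50, 6))
        assert dn.expand_motion(m, "A").shape == (50, 12)
        assert dn.expand_motion(m, "B").shape == (50, 24)

    def test_zero_motion_gives_zero_columns(self):
        assert np.all(dn.expand_motion(np.zeros((30, 6)), "B") == 0)

    def test_derivative_first_row_zero(self):
        m = np.cumsum(np.ones((10, 6)), axis=0)
        e = dn.expand_motion(m, "A")
        assert np.all(e[0, 6:] == 0)
        assert np.allclose(e[1:, 6:12], 1.0)


class TestGaussianLowpass:
    def test_constant_unchanged(self):
        out = dn.gaussian_lowpass(_run(np.full((100, 1), 3.0)), sd_s=TR)
        assert np.allclose(out.channels, 3.0, atol=1e-10)

    def test_white_noise_variance_reduction_matches_kernel_energy(self):
        # oracle: the variance ratio for white noise is the discrete
        # kernel's energy sum, obtained from the impulse response
        from scipy.ndimage import gaussian_filter1d
        impulse = np.zeros(101)
        impulse[50] = 1.0
        kernel = gaussian_filter1d(impulse, sigma=1.0, truncate=4.0)
        expected = float(np.sum(kernel ** 2))
        rng = np.random.default_rng(9)
        x = rng.standard_normal((200000, 1))
        out = dn.gaussian_lowpass(_run(x), sd_s=TR)
        ratio = out.channels.var() / x.var()
        assert ratio == pytest.approx(expected, rel=0.02)

    @pytest.mark.parametrize("f_hz", [0.02, 0.05, 0.1])
    def test_sinusoid_transfer_function(self, f_hz):
        # continuous-time Gaussian transfer: exp(-2 pi^2 f^2 sigma^2)
        t = np.arange(4000) * TR
        x = np.sin(2 * np.pi * f_hz * t)[:, None]
        out = dn.gaussian_lowpass(_run(x), sd_s=TR)
        measured = (np.linalg.norm(out.channels[500:-500])
                    / np.linalg.norm(x[500:-500]))
        expected = np.exp(-2 * np.pi ** 2 * f_hz ** 2 * TR ** 2)
        assert measured == pytest.approx(expected, rel=0.02)


class TestButterBandpass:
    def _sine(self, f_hz, t_n=3000):
        t = np.arange(t_n) * TR
        return np.sin(2 * np.pi * f_hz * t)[:, None]

    def test_passband_frequency_retained(self):
        x = self._sine(0.04)
        out = dn.butter_bandpass(_run(x), 1, 0.01, 0.08)
        ratio = np.linalg.norm(out.channels[300:-300]) / np.linalg.norm(x[300:-300])
        assert ratio >= 0.90

    def test_stopband_frequency_suppressed(self):
        x = self._sine(0.2)
        out = dn.butter_bandpass(_run(x), 1, 0.01, 0.08)
        ratio = np.linalg.norm(out.channels[300:-300]) / np.linalg.norm(x[300:-300])
        assert ratio <= 0.15

    def test_dc_removed(self):
        rng = np.random.default_rng(10)
        x = rng.standard_normal((2000, 1)) + 100.0
        out = dn.butter_bandpass(_run(x), 1, 0.01, 0.08)
        assert abs(out.channels.mean()) < 0.05

    def test_all_censored_rejected(self):
        r = _run(np.random.default_rng(11).standard_normal((100, 1)))
        r.censor_mask[:] = False
        with pytest.raises(ValueError):
            dn.butter_bandpass(r, 1, 0.01, 0.08)


class TestCensorVolumes:
    def test_fd_threshold(self):
        r = _run(np.random.default_rng(12).standard_normal((3, 2)),
                 fd=np.array([0.1, 0.3, 0.1]))
        assert np.array_equal(dn.censor_volumes(r, 0.25),
                              [True, False, True])

    def test_quiet_run_uncensored(self):
        r = _run(np.random.default_rng(13).standard_normal((100, 4)))
        mask = dn.censor_volumes(r, 0.25, dvars_ratio=None)
        assert mask.all()

    def test_spike_censored_by_dvars(self):
        rng = np.random.default_rng(14)
        x = rng.standard_normal((200, 10)) * 0.1
        x[77] += 10.0  # one spike volume
        mask = dn.censor_volumes(_run(x), 0.25, dvars_ratio=1.05)
        assert not mask[77]
        assert mask[0]  # first volume never censored by DVARS


class TestCompCor:
    def test_rank5_fixture_removes_shared_variance(self):
        rng = np.random.default_rng(15)
        latents = rng.standard_normal((500, 5))
        mix = rng.standard_normal((5, 9))
        tissue = latents @ mix  # 9 WM/CSF channels spanning a rank-5 space
        contaminated = latents @ rng.standard_normal(5) \
            + 0.01 * rng.standard_normal(500)
        roles = ["parcel"] + ["WM"] * 6 + ["CSF"] * 3
        channels = np.column_stack([contaminated, tissue])
        r = _run(channels, roles=roles)
        comps = dn.compcor(r, k=5)
        resid = dn.regress_nuisance(r, comps).channels[:, 0]
        removed = 1 - resid.var() / contaminated.var()
        assert removed >= 0.999

    def test_k_zero_gives_empty_design(self):
        r = _run(np.random.default_rng(16).standard_normal((50, 10)),
                 roles=["parcel"] + ["WM"] * 6 + ["CSF"] * 3)
        assert dn.compcor(r, k=0).shape == (50, 0)

    def test_components_orthogonal(self):
        r = _run(np.random.default_rng(17).standard_normal((300, 10)),
                 roles=["parcel"] + ["WM"] * 6 + ["CSF"] * 3)
        c = dn.compcor(r, k=5)
        gram = c.T @ c
        off = gram - np.diag(np.diag(gram))
        assert np.max(np.abs(off)) < 1e-8

    def test_too_few_channels_rejected(self):
        r = _run(np.random.default_rng(18).standard_normal((50, 4)),
                 roles=["parcel", "WM", "WM", "CSF"])
        with pytest.raises(ValueError, match="CompCor"):
            dn.compcor(r, k=5)


class TestPipelines:
    def test_pipeline_a_trace_order(self, demo_run):
        out = dn.denoise(demo_run, dn.DenoiseConfig(pipeline="A"))
        assert out.trace == [
            "zscore",
            "legendre_detrend(deg=3,roles=WM/CSF)",
            "tissue_regression(CSF,WM)",
            "motion_regression(12)",
            "gaussian_lowpass(sd=0.72s)",
            "legendre_detrend(deg=3,roles=parcel)",
            "gsr",
        ]

    def test_pipeline_a_final_state(self, demo_run):
        out = dn.denoise(demo_run, dn.DenoiseConfig(pipeline="A"))
        parcels = out.parcels()
        assert np.max(np.abs(parcels.mean(axis=0))) < 1e-8
        gs = out.channels[:, out.role_idx("global")]
        assert np.max(np.abs(gs.T @ parcels)) < 1e-6

    def test_pipeline_b_spectrum_matches_filter_oracle(self, small_cohort):
        # Oracle: the out-of-band power fraction of the bare zero-phase
        # first-order Butterworth on matched-length white noise.  (A
        # first-order band-pass has a shallow rolloff, so this fraction is
        # substantial; the point is that the pipeline's combined
        # regression must not add out-of-band power beyond it.)
        from scipy.signal import periodogram, sosfiltfilt, butter
        from cpmkit import synth

        def oob_fraction(x):
            f, p = periodogram(x, fs=1 / TR, axis=0)
            pm = p.mean(axis=1) if p.ndim > 1 else p
            return 1 - pm[(f >= 0.01) & (f <= 0.08)].sum() / pm.sum()

        rng = np.random.default_rng(0)
        sos = butter(1, [0.01, 0.08], btype="bandpass", fs=1 / TR,
                     output="sos")
        oracle = oob_fraction(sosfiltfilt(sos,
                                          rng.standard_normal((1200, 100)),
                                          axis=0))
        spec, cohort, truth = small_cohort
        run = synth.generate_run_timeseries(
            cohort, truth, "REST1_LR", n_timepoints=1200, fix_like=True,
            subjects=cohort.subject_ids[:1])[0]
        out = dn.denoise(run, dn.DenoiseConfig(pipeline="B"))
        measured = oob_fraction(out.parcels())
        assert measured == pytest.approx(oracle, abs=0.05)

    def test_censoring_is_mask_not_deletion(self, demo_run, clean_run):
        # pipeline C carries its censor mask to FC; pipeline B absorbs
        # censored volumes into spike regressors and retains all rows
        c_out = dn.denoise(clean_run, dn.DenoiseConfig(pipeline="C"))
        assert c_out.n_timepoints == clean_run.n_timepoints
        assert c_out.censor_mask.dtype == bool
        b_out = dn.denoise(demo_run, dn.DenoiseConfig(pipeline="B"))
        assert b_out.censor_mask.all()

    def test_pipelines_preserve_shape_and_are_deterministic(self, demo_run,
                                                            clean_run):
        for p in ("A", "B", "C"):
            src = clean_run if p == "C" else demo_run
            a = dn.denoise(src, dn.DenoiseConfig(pipeline=p))
            b = dn.denoise(src, dn.DenoiseConfig(pipeline=p))
            assert a.channels.shape == src.channels.shape
            assert np.array_equal(a.channels, b.channels)

    def test_missing_role_rejected_by_name(self):
        r = _run(np.random.default_rng(19).standard_normal((120, 2)),
                 roles=["parcel", "parcel"])
        with pytest.raises(ValueError, match="WM"):
            dn.denoise(r, dn.DenoiseConfig(pipeline="A"))
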