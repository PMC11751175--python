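"""VOR summation, surrogate sweeps, sinusoid fits and null points."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mvstim.cupula import CristaStimulusSet
from mvstim.vor import (
    ETS_NULLS_DEG,
    FE_NULLS_DEG,
    SurrogateCristaModel,
    fe_torsional_amplitude_ratio,
    find_nulls,
    fit_sinusoid,
    normalize_spv,
    phase_lag_deg,
    spv_from_cristae,
    spv_from_cristae_bookkeeping,
    surrogate_stimuli,
    sweep_surrogate,
)


# -- VOR summation -----------------------------------------------------------

def test_supine_unit_pattern_maps_to_left_and_counterclockwise():
    s = CristaStimulusSet(s_LH=-1, s_RH=1, s_LS=1, s_RS=-1, s_LP=1, s_RP=-1)
    r = spv_from_cristae(s)
    assert (r.spv_hor, r.spv_ver, r.spv_tor) == (-2, 0, 4)


def test_zero_stimuli_give_zero_spv():
    r = spv_from_cristae(CristaStimulusSet(0, 0, 0, 0, 0, 0))
    assert (r.spv_hor, r.spv_ver, r.spv_tor) == (0, 0, 0)


def test_negated_stimuli_negate_spv():
    s = CristaStimulusSet(0.3, -1.2, 0.7, 0.1, -0.4, 0.9)
    sm = CristaStimulusSet(*(-v for v in s.as_dict().values()))
    r, rm = spv_from_cristae(s), spv_from_cristae(sm)
    assert np.allclose(rm.components(), -r.components())


def test_signed_reduction_equals_bookkeeping_on_random_inputs():
    """The signed reduction and the literal ex/in bookkeeping agree on 10^4
    random stimulus sets."""
    rng = np.random.default_rng(42)
    draws = rng.normal(size=(10_000, 6)) * rng.choice([1e-4, 1.0, 1e3], size=(10_000, 1))
    for row in draws:
        s = CristaStimulusSet(*row)
        a = spv_from_cristae(s).components()
        b = spv_from_cristae_bookkeeping(s).components()
        # different summation order: allow rounding at the scale of the terms
        assert np.allclose(a, b, rtol=1e-9, atol=1e-12 * np.abs(row).sum())


def test_nonfinite_stimuli_rejected():
    with pytest.raises(ValueError, match="finite"):
        spv_from_cristae(CristaStimulusSet(np.nan, 0, 0, 0, 0, 0))


# -- surrogate sweeps ---------------------------------------------------------

@pytest.fixture(scope="module")
def ets_sweep():
    return sweep_surrogate("ETS")


@pytest.fixture(scope="module")
def fe_sweep():
    return sweep_surrogate("FE")


def test_ets_supine_angle_matches_supine_signs(ets_sweep):
    r0 = next(r for r in ets_sweep if r.angle_deg == 0.0)
    assert r0.spv_hor < 0 and r0.spv_tor > 0 and abs(r0.spv_ver) < 1e-12


def test_ets_crista_nulls_match_configuration():
    for canal, null in ETS_NULLS_DEG.items():
        s = surrogate_stimuli(-null, "ETS")
        assert abs(getattr(s, f"s_L{canal}")) < 1e-12
        s = surrogate_stimuli(+null, "ETS")
        assert abs(getattr(s, f"s_R{canal}")) < 1e-12


def test_ets_horizontal_follows_trig_identity(ets_sweep):
    """sin(th - 12) - sin(th + 12) = -2 cos(th) sin(12): the horizontal SPV of
    the mirrored pair is proportional to -cos(theta)."""
    th = np.radians([r.angle_deg for r in ets_sweep])
    hor = np.array([r.spv_hor for r in ets_sweep])
    expected = -2 * np.cos(th) * np.sin(np.radians(ETS_NULLS_DEG["H"]))
    assert np.allclose(hor, expected, atol=1e-12)


def test_ets_nulls_at_plus_minus_ninety(ets_sweep):
    for comp in ("hor", "tor"):
        nulls = find_nulls(ets_sweep, comp).angles_deg
        assert np.allclose(nulls, [-90.0, 90.0], atol=1e-9)
    assert np.allclose(find_nulls(ets_sweep, "ver").angles_deg, [0.0, 180.0], atol=1e-9)


def test_antiperiodicity(ets_sweep, fe_sweep):
    for recs in (ets_sweep, fe_sweep):
        by_angle = {r.angle_deg: r.components() for r in recs}
        for th in (-135.0, -90.0, -30.0, 0.0):
            assert np.allclose(by_angle[th + 180.0], -by_angle[th], atol=1e-12)


@settings(max_examples=40, deadline=None)
@given(
    ah=st.floats(0.1, 10.0),
    ap=st.floats(0.1, 10.0),
    as_=st.floats(0.1, 10.0),
)
def test_ets_nulls_robust_to_amplitudes(ah, ap, as_):
    """Mirrored amplitudes move amplitudes, never the +/-90 deg nulls."""
    model = SurrogateCristaModel(amplitudes={"H": ah, "P": ap, "S": as_})
    recs = sweep_surrogate("ETS", np.arange(-179.0, 181.0, 3.0), model)
    for comp in ("hor", "tor"):
        nulls = find_nulls(recs, comp).angles_deg
        assert np.allclose(np.abs(nulls), 90.0, atol=1e-9)


def test_fe_horizontal_nulls_match_crista_nulls(fe_sweep):
    nulls = find_nulls(fe_sweep, "hor").angles_deg
    assert np.allclose(nulls, [FE_NULLS_DEG["H"], FE_NULLS_DEG["H"] + 180.0], atol=1e-9)


def test_fe_vertical_is_identically_null(fe_sweep):
    assert find_nulls(fe_sweep, "ver").null_everywhere
    assert max(abs(r.spv_ver) for r in fe_sweep) < 1e-12


def test_fe_supine_signs(fe_sweep):
    r0 = next(r for r in fe_sweep if r.angle_deg == 0.0)
    assert r0.spv_hor < 0 and r0.spv_tor > 0


def test_fe_torsional_null_calibration():
    ratio = fe_torsional_amplitude_ratio(-50.0)
    model = SurrogateCristaModel(amplitudes={"H": 1.0, "S": ratio, "P": 1.0})
    nulls = find_nulls(sweep_surrogate("FE", model=model), "tor").angles_deg
    assert np.allclose(nulls, [-50.0, 130.0], atol=1e-9)


# -- sinusoid fits -------------------------------------------------------------

def test_fit_recovers_exact_sinusoid():
    th = np.arange(-179.0, 181.0, 10.0)
    y = np.sin(np.radians(th - 30.0))
    fit = fit_sinusoid(th, y)
    assert abs(fit.amplitude - 1.0) < 1e-12
    assert abs(fit.phase_deg - 30.0) < 1e-9
    assert abs(fit.adjusted_r2 - 1.0) < 1e-12


def test_fit_with_noise_below_one():
    rng = np.random.default_rng(0)
    th = np.arange(-179.0, 181.0, 5.0)
    y = np.sin(np.radians(th)) + rng.normal(0, 0.1, size=th.size)
    fit = fit_sinusoid(th, y)
    assert fit.adjusted_r2 < 1.0


def test_fit_degenerate_zero_component():
    th = np.arange(-179.0, 181.0, 10.0)
    fit = fit_sinusoid(th, np.zeros_like(th))
    assert fit.degenerate and fit.amplitude == 0.0 and np.isnan(fit.adjusted_r2)


def test_fit_requires_enough_angles():
    with pytest.raises(ValueError, match="4 distinct"):
        fit_sinusoid([0.0, 10.0, 20.0], [0.0, 1.0, 2.0])


def test_vertical_lags_horizontal_by_ninety(ets_sweep):
    angles = [r.angle_deg for r in ets_sweep]
    fh = fit_sinusoid(angles, [r.spv_hor for r in ets_sweep])
    fv = fit_sinusoid(angles, [r.spv_ver for r in ets_sweep])
    assert abs(phase_lag_deg(fh, fv) - 90.0) < 1e-9


def test_analytic_and_bisection_nulls_agree(ets_sweep):
    for comp in ("hor", "tor", "ver"):
        a = find_nulls(ets_sweep, comp, method="fit").angles_deg
        b = find_nulls(ets_sweep, comp, method="bisect").angles_deg
        assert len(a) == len(b)
        assert np.allclose(sorted(a), sorted(b), atol=0.5)


# -- normalization --------------------------------------------------------------

def test_normalization_rule(ets_sweep):
    recs = normalize_spv(list(ets_sweep))
    hor = np.array([r.norm_hor for r in recs])
    tor = np.array([r.norm_tor for r in recs])
    assert np.isclose(np.abs(hor).max(), 1.0)
    assert np.isclose(np.abs(tor).max(), 1.0)
    hpk = np.abs([r.spv_hor for r in recs]).max()
    for r in recs[:10]:
        assert np.isclose(r.norm_ver, r.spv_ver / hpk)


def test_normalize_single_record():
    from mvstim.vor import SPVRecord

    recs = normalize_spv([SPVRecord(-2.0, 0.0, 4.0)])
    assert (recs[0].norm_hor, recs[0].norm_ver, recs[0].norm_tor) == (-1.0, 0.0, 1.0)


def test_normalize_all_zero_set():
    from mvstim.vor import SPVRecord

    recs = normalize_spv([SPVRecord(0.0, 0.0, 0.0), SPVRecord(0.0, 0.0, 0.0)])
    assert all(r.norm_hor == r.norm_ver == r.norm_tor == 0.0 for r in recs)
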