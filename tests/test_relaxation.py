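"""Three-pool Bloch–McConnell SPGR model: limits, conservation, inversion."""

import numpy as np
import pytest
from scipy.linalg import expm

from dcewex import (
    AcquisitionSchedule,
    RelaxationContext,
    TissueParams,
    pool_relaxation_rates,
    signal_to_concentration,
    spgr_signal,
    spgr_signal_3s2x,
    steady_state_vs_transient,
)
from dcewex.kinetics import ConcSeries
from dcewex.relaxation import SignalSeries, _exchange_generator, _propagators

P = TissueParams(ve=0.15, vp=0.03, Fp=0.5, PS=0.05, kio=2.0)
P_FAST = TissueParams(ve=0.15, vp=0.03, Fp=0.5, PS=0.05, kio=1e4)
POST_RATES = np.array([1.5, 2.5, 0.5])  # blood, interstitial, intracellular s^-1


def const_rates(n, triple=POST_RATES):
    return np.tile(triple, (n, 1))


# --- schedule arithmetic ------------------------------------------------


def test_schedule_defaults_and_segment_alignment():
    s = AcquisitionSchedule()
    assert s.total_spokes == 3 * 51360
    assert s.total_time == pytest.approx(616.32)
    assert s.n_frames == 123
    angles, boundary = s.frame_flip_angles()
    # 205.44 s segments on a 5 s frame grid: switches land inside frames 41, 82
    assert list(np.flatnonzero(boundary)) == [41, 82]
    assert angles[0] == 8.0 and angles[50] == 25.0 and angles[-1] == 8.0
    # majority rule: frame 41 spans 205-210 s, mostly past the 205.44 s switch
    assert angles[41] == 25.0


def test_schedule_yaml_round_trip(tmp_path):
    s = AcquisitionSchedule()
    path = tmp_path / "schedule.yaml"
    s.to_yaml(path)
    assert AcquisitionSchedule.from_yaml(path) == s


def test_schedule_rejects_bad_angles():
    with pytest.raises(ValueError):
        AcquisitionSchedule(segments=((0.0, 100),))
    with pytest.raises(ValueError):
        AcquisitionSchedule(segments=((95.0, 100),))


# --- concentration to rates --------------------------------------------


def test_pool_rates_linear_in_concentration():
    t = np.arange(3) * 5.0
    conc = ConcSeries(t=t, Cp=np.array([0.0, 0.5, 0.0]),
                      Ce=np.array([0.0, 0.0, 1.0]), Ct=np.zeros(3))
    ctx = RelaxationContext(r1=3.3, R10=0.5)
    r = pool_relaxation_rates(conc, ctx)
    assert np.allclose(r[0], 0.5)                      # no agent anywhere
    assert r[1, 0] - 0.5 == pytest.approx(3.3 * 0.5)   # blood rises with C_p
    assert r[2, 1] - 0.5 == pytest.approx(3.3 * 1.0)   # interstitium with C_e
    assert np.allclose(r[:, 2], 0.5)                   # cells see no agent
    ctx51 = RelaxationContext(r1=5.1, R10=0.5)
    r51 = pool_relaxation_rates(conc, ctx51)
    assert r51[1, 0] - 0.5 == pytest.approx(5.1 * 0.5)


# --- exchange generator structure --------------------------------------


def test_exchange_generator_conserves_and_fixes_equilibrium():
    X = _exchange_generator(P, k_bo=3.0)
    assert np.abs(X.sum(axis=0)).max() < 1e-12          # ones is a left null vector
    assert np.abs(X @ P.fractions()).max() < 1e-12      # detailed balance
    # thermal equilibrium is a fixed point of the free relaxation at uniform R1
    ctx = RelaxationContext(R10=0.7, M0=100.0)
    E, f = _propagators(P, np.full((1, 3), 0.7), ctx, 0.004)
    Meq = 100.0 * f
    assert np.allclose(E[0] @ (Meq - Meq) + Meq, Meq)


def test_propagator_equals_dense_matrix_exponential():
    ctx = RelaxationContext(R10=0.5, k_bo=3.0)
    rates = const_rates(1)
    E, _ = _propagators(P, rates, ctx, 0.004)
    A = -np.diag(rates[0]) + _exchange_generator(P, ctx.k_bo)
    assert np.max(np.abs(E[0] - expm(A * 0.004))) < 1e-13


# --- signal model limits ------------------------------------------------


def test_identical_pools_reduce_to_single_pool():
    """Exchange between pools with equal R1 is unobservable."""
    s = AcquisitionSchedule()
    ctx = RelaxationContext(R10=0.5, M0=1000.0)
    angles, _ = s.frame_flip_angles()
    sig = spgr_signal_3s2x(P, np.full((s.n_frames, 3), 0.5), s, ctx)
    ref = spgr_signal(0.5, angles, s.tr_s, 1000.0)
    assert np.max(np.abs(sig.S - ref) / ref) < 1e-12


def test_fast_exchange_limit_population_weighted_rate():
    s = AcquisitionSchedule()
    ctx = RelaxationContext(R10=0.5, M0=1000.0, k_bo=1e4)
    angles, _ = s.frame_flip_angles()
    sig = spgr_signal_3s2x(P_FAST, const_rates(s.n_frames), s, ctx)
    rbar = float(P_FAST.fractions() @ POST_RATES)
    ref = spgr_signal(rbar, angles, s.tr_s, 1000.0)
    assert np.max(np.abs(sig.S - ref) / ref) < 1e-3


def test_low_flip_angle_more_exchange_sensitive():
    """|S(k_io) - S(fast limit)| is larger at 8 deg than at 25 deg."""
    s = AcquisitionSchedule()
    ctx = RelaxationContext(R10=0.5, M0=1000.0)
    ctx_fast = ctx.with_(k_bo=1e4)
    n = 4

    def dev(alpha):
        fa = np.full(n, alpha)
        fin = spgr_signal_3s2x(P, const_rates(n), s, ctx, frame_angles=fa)
        inf = spgr_signal_3s2x(P_FAST, const_rates(n), s, ctx_fast, frame_angles=fa)
        return abs(fin.S[0] - inf.S[0]) / inf.S[0]

    assert dev(8.0) > dev(25.0)


def test_signal_monotone_in_kio():
    """With R1_o > R1_i post-contrast, signal varies monotonically with k_io."""
    s = AcquisitionSchedule()
    ctx = RelaxationContext(R10=0.5, M0=1000.0)
    vals = []
    for kio in [0.0, 0.5, 1.0, 2.0, 5.0, 10.0, 30.0, 100.0]:
        p = TissueParams(ve=0.15, vp=0.03, Fp=0.5, PS=0.05, kio=kio)
        sig = spgr_signal_3s2x(p, const_rates(2), s, ctx,
                               frame_angles=np.full(2, 8.0))
        vals.append(sig.S[0])
    diffs = np.diff(vals)
    assert np.all(diffs > 0) or np.all(diffs < 0)


# --- transient vs steady state -----------------------------------------


def test_transient_converges_to_steady_state():
    s = AcquisitionSchedule()
    ctx = RelaxationContext(R10=0.5, M0=1000.0)
    steady, trans, (sig, ang) = steady_state_vs_transient(
        P, const_rates(3), s, ctx)
    # by the last excitation of each frame the geometric map has converged
    assert np.max(np.abs(trans.S - steady.S) / steady.S) < 1e-4
    # immediately after start (from equilibrium) the train is NOT at steady
    # state: the first excitation sees full equilibrium magnetization
    assert sig[0] > steady.S[0]


def test_transient_after_segment_switch():
    """The first excitations at 25 deg differ from that segment's steady state."""
    seg = ((8.0, 2500), (25.0, 2500))
    s = AcquisitionSchedule(segments=seg, frame_s=5.0)
    ctx = RelaxationContext(R10=0.5, M0=1000.0)
    steady, trans, (sig, ang) = steady_state_vs_transient(
        P, const_rates(s.n_frames), s, ctx)
    switch = 2500  # 10 s in at 4 ms TR: first excitation of frame 2
    frame_of_switch = 2
    assert ang[switch] == 25.0
    first = sig[switch]
    assert abs(first - steady.S[frame_of_switch]) / steady.S[frame_of_switch] > 1e-3
    # 200+ excitations later it has converged
    assert abs(sig[switch + 300] - steady.S[frame_of_switch]) \
        / steady.S[frame_of_switch] < 1e-4


# --- signal <-> concentration ------------------------------------------


def test_signal_to_concentration_round_trip():
    s = AcquisitionSchedule()
    ctx = RelaxationContext(r1=3.3, R10=1.0 / 2.0, M0=1000.0)
    angles, boundary = s.frame_flip_angles()
    for C in (0.0, 0.3):
        R1 = 1.0 / 2.0 + 3.3 * C
        S = spgr_signal(R1, angles, s.tr_s, 1000.0)
        ser = SignalSeries(t=s.frame_times, S=S, flip_angle_per_frame=angles,
                           boundary_frame=boundary)
        conc, nclip = signal_to_concentration(ser, 2.0, 1000.0, s, ctx)
        assert nclip == 0
        assert np.max(np.abs(conc - C)) < 1e-8


def test_signal_beyond_spgr_maximum_clipped_and_counted():
    s = AcquisitionSchedule()
    ctx = RelaxationContext(r1=3.3, R10=0.5, M0=1000.0)
    angles, boundary = s.frame_flip_angles()
    S = spgr_signal(0.5, angles, s.tr_s, 1000.0)
    smax = 1000.0 * np.sin(np.deg2rad(angles))
    S_bad = S.copy()
    S_bad[5] = smax[5] * 1.05  # 5% above the invertible maximum
    ser = SignalSeries(t=s.frame_times, S=S_bad, flip_angle_per_frame=angles,
                       boundary_frame=boundary)
    conc, nclip = signal_to_concentration(ser, 2.0, 1000.0, s, ctx)
    assert nclip == 1
    assert np.all(np.isfinite(conc))
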