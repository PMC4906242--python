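"""Trace extraction, normalization, QC, rate fits and summaries."""

import numpy as np
import pytest

from svpop.protocol import StimProtocol
from svpop.segmentation import response_map, segment
from svpop.synthetic import (
    KineticParams,
    RenderParams,
    render_movie,
    simulate_ca_trace,
    simulate_pools,
)
from svpop.synthetic.calcium import CaParams, free_concentration
from svpop.traces import (
    EXCL_DRIFT,
    EXCL_NH4CL,
    KEPT,
    TraceSet,
    ca_summaries,
    endo_rate,
    endo_trace,
    exo_rate,
    extract_traces,
    occlusion,
    ols_slope,
    percent_inhibition,
    pool_plateau,
    qc_filter,
    rate_table,
)


def normal_equations_slope(t, y):
    """Independent OLS oracle: solve the 2x2 normal equations directly."""
    A = np.column_stack([np.ones_like(t), t])
    coef = np.linalg.solve(A.T @ A, A.T @ y)
    return coef[1]


def make_traceset(norm, protocol, qc=None):
    n = norm.shape[0]
    return TraceSet(
        raw=norm.copy(),
        norm=norm,
        f_nh4cl=np.ones(n),
        qc_status=np.full(n, KEPT, dtype=object) if qc is None else qc,
        prep_id="prep0",
        field_id="field0",
        group="ctrl",
        bouton_ids=np.array([f"b{i}" for i in range(n)], dtype=object),
        protocol=protocol,
    )


# ---------------------------------------------------------------- extract --


def test_extract_noiseless_normalized_equals_fluorescent_fraction(
    default_kinetics, default_protocol
):
    pools = simulate_pools(default_kinetics, default_protocol)
    render = RenderParams(image_size=(48, 48), gain=0.0, read_noise_sd=0.0,
                          background_level=0.0, expression_lognorm_sigma=0.0)
    rf = render_movie(pools.f[None, :], render, np.random.default_rng(0), quantize=False)
    rmap = response_map(rf.stack, default_protocol)
    bm = segment(rmap, baseline_floor=1e-6, size_gate=(1, 500))
    assert bm.n_boutons == 1
    ts = extract_traces(rf.stack, bm, default_protocol)
    assert np.abs(ts.norm[0] - pools.f).max() < 1e-6
    post = default_protocol.post_nh4cl_frames()
    assert np.abs(ts.norm[0][post][-5:] - 1.0).max() < 1e-9


def test_extract_normalization_cancels_expression(default_kinetics, default_protocol):
    """5x expression difference: identical normalized traces (zero background)."""
    pools = simulate_pools(default_kinetics, default_protocol)
    render = RenderParams(image_size=(64, 64), gain=0.0, read_noise_sd=0.0,
                          background_level=0.0)
    traces = np.tile(pools.f, (2, 1))
    rf = render_movie(traces, render, np.random.default_rng(1),
                      positions=np.array([[20.0, 20.0], [40.0, 40.0]]),
                      amplitudes=np.array([4000.0, 20000.0]), quantize=False)
    bm = segment(response_map(rf.stack, default_protocol),
                 baseline_floor=1e-6, size_gate=(1, 500))
    assert bm.n_boutons == 2
    ts = extract_traces(rf.stack, bm, default_protocol)
    assert np.abs(ts.norm[0] - ts.norm[1]).max() < 1e-9


def test_extract_nh4cl_invalid_flagged(fast_protocol):
    stack = np.full((fast_protocol.n_frames, 16, 16), 100.0)
    post = fast_protocol.post_nh4cl_frames()
    stack[post] = 50.0  # NH4Cl level below baseline
    from svpop.segmentation import BoutonMap

    labels = np.zeros((16, 16), dtype=int)
    labels[5:8, 5:8] = 1
    bm = BoutonMap(labels=labels, areas=np.array([9]),
                   centroids=np.array([[6.0, 6.0]]), threshold=1.0,
                   min_rel_df=0.05, dilation_radius=1, size_gate=(1, 100))
    ts = extract_traces(stack, bm, fast_protocol)
    assert ts.qc_status[0] == EXCL_NH4CL


def test_extract_requires_enough_nh4cl_frames(fast_protocol):
    stack = np.zeros((fast_protocol.n_frames, 8, 8))
    from svpop.segmentation import BoutonMap

    labels = np.zeros((8, 8), dtype=int)
    labels[2, 2] = 1
    bm = BoutonMap(labels=labels, areas=np.array([1]), centroids=np.array([[2.0, 2.0]]),
                   threshold=1.0, min_rel_df=0.05, dilation_radius=0, size_gate=(1, 10))
    with pytest.raises(ValueError, match="NH4Cl window"):
        extract_traces(stack, bm, fast_protocol, n_norm_frames=50)


# --------------------------------------------------------------------- QC --


def test_qc_keeps_driftfree_traces(default_kinetics, default_protocol):
    pools = simulate_pools(default_kinetics, default_protocol)
    ts = make_traceset(np.tile(pools.f, (10, 1)), default_protocol)
    out = qc_filter(ts)
    assert (out.qc_status == KEPT).all()


def test_qc_excludes_planted_baseline_jump(default_kinetics, default_protocol):
    pools = simulate_pools(default_kinetics, default_protocol)
    t = default_protocol.frame_times()
    drifted = pools.f + np.where(t >= 100.0, 0.15, 0.0)  # +0.15 between trains
    norm = np.vstack([pools.f, drifted])
    out = qc_filter(make_traceset(norm, default_protocol), drift_tol=0.10)
    assert out.qc_status[0] == KEPT
    assert out.qc_status[1] == EXCL_DRIFT


def test_qc_excludes_post_baf_ramp(default_kinetics, default_protocol):
    pools = simulate_pools(default_kinetics, default_protocol)
    t = default_protocol.frame_times()
    baf, t2 = 360.0, 390.0
    ramp = np.clip((t - baf) / (t2 - baf), 0, None) * 0.25
    ramp[t >= t2] = 0.0  # ramp confined to the post-Baf segment
    out = qc_filter(make_traceset(np.vstack([pools.f + ramp]), default_protocol))
    assert out.qc_status[0] == EXCL_DRIFT


def test_qc_sensitivity_and_false_exclusion(default_kinetics, default_protocol):
    """10% planted drifters at 2x tolerance among 1000 noisy traces."""
    rng = np.random.default_rng(42)
    pools = simulate_pools(default_kinetics, default_protocol)
    t = default_protocol.frame_times()
    n = 1000
    drifter = np.zeros(n, dtype=bool)
    drifter[rng.choice(n, 100, replace=False)] = True
    norm = np.tile(pools.f, (n, 1)) + rng.normal(0, 0.01, (n, pools.f.size))
    norm[drifter] += np.where(t >= 100.0, 0.20, 0.0)
    out = qc_filter(make_traceset(norm, default_protocol), drift_tol=0.10)
    excluded = out.qc_status == EXCL_DRIFT
    sensitivity = excluded[drifter].mean()
    false_rate = excluded[~drifter].mean()
    assert sensitivity >= 0.95
    assert false_rate <= 0.05


# ------------------------------------------------------------------- rates --


def test_exo_rate_exact_line(fast_protocol):
    t = fast_protocol.frame_times()
    trace = 0.01 * (t - 96.0)  # 0.02 per frame after train-2 onset
    slope, r2 = exo_rate(trace, fast_protocol)
    assert slope == pytest.approx(0.01, abs=1e-12)
    assert r2 == pytest.approx(1.0)


def test_ols_slope_matches_normal_equations_oracle():
    rng = np.random.default_rng(0)
    for _ in range(20):
        t = np.arange(6) * 2.0
        y = 0.3 + 0.07 * t + rng.normal(0, 0.05, 6)
        slope, _ = ols_slope(t, y)
        assert slope == pytest.approx(normal_equations_slope(t, y), abs=1e-12)


def test_exo_rate_linear_regime_prediction(default_protocol):
    """Small k_exo (depletion < 10% over the fit window)."""
    k = KineticParams(k_exo=0.008, k_endo=0.002)
    pools = simulate_pools(k, default_protocol)
    slope, _ = exo_rate(pools.f, default_protocol)
    assert slope == pytest.approx(k.releasable_fraction * k.k_exo, rel=0.10)


def test_exo_rate_requires_six_frames():
    proto = StimProtocol(frame_interval=2.0, train_onsets=[20.0, 60.0],
                        train_n_aps=[40, 40], train_freq=10.0, baf_time=56.0,
                        nh4cl_time=90.0, total_duration=110.0)
    pools = simulate_pools(KineticParams(), proto)
    with pytest.raises(ValueError, match="frames in train window"):
        exo_rate(pools.f, proto)  # 4 s train = 3 frames


def test_endo_trace_identical_traces_zero(default_kinetics, default_protocol):
    pools = simulate_pools(default_kinetics, default_protocol)
    flat = np.full_like(pools.f, 0.5)
    _, diff = endo_trace(flat, flat, default_protocol)
    assert np.abs(diff).max() == 0.0


def test_endo_decomposition_identity(default_kinetics, default_protocol):
    """first_trace + endo_trace == baf_trace, exactly by construction."""
    pools = simulate_pools(default_kinetics, default_protocol)
    from svpop.traces import _train_segment

    from svpop.traces import _onset_baseline

    t_rel, diff = endo_trace(pools.f, pools.f, default_protocol)
    b1 = _onset_baseline(pools.f, default_protocol, 0)
    b2 = _onset_baseline(pools.f, default_protocol, 1)
    seg1 = _train_segment(pools.f, default_protocol, 0)[: diff.size] - b1
    seg2 = _train_segment(pools.f, default_protocol, 1)[: diff.size] - b2
    assert np.abs(seg1 + diff - seg2).max() < 1e-12


def test_endo_trace_matches_recovered_pool(default_protocol):
    """Noiseless two-train difference equals the quench-adjusted recovered
    (re-acidified) reporter accumulated during the matched first train."""
    k = KineticParams(tau_reacid=0.5)  # fast re-acidification: diff ~ cum endo
    pools = simulate_pools(k, default_protocol)
    t_rel, diff = endo_trace(pools.f, pools.f, default_protocol)
    t = pools.times
    onset1 = default_protocol.onset_frame(0)
    endo_true = pools.endo[onset1 : onset1 + diff.size] - pools.endo[onset1]
    # fast tau makes reacidified ~ cumulative endo within half a frame lag
    assert np.abs(diff - (1 - k.quench_ratio) * endo_true).max() < 0.01


def test_endo_rate_trivial_line(default_protocol):
    diff = np.concatenate([np.zeros(5), 0.01 * np.arange(20)])
    slope, _ = endo_rate(diff, default_protocol, onset_offset_frames=9)
    assert slope == pytest.approx(0.005, abs=1e-12)  # 0.01/frame @ 2 s


def test_endo_rate_zero_when_no_endocytosis(default_protocol):
    k = KineticParams(k_endo=0.0)
    pools = simulate_pools(k, default_protocol)
    _, diff = endo_trace(pools.f, pools.f, default_protocol)
    slope, _ = endo_rate(diff, default_protocol)
    assert abs(slope) < 1e-9


def test_endo_rate_insufficient_frames(default_protocol):
    with pytest.raises(ValueError):
        endo_rate(np.zeros(10), default_protocol, onset_offset_frames=9)


def test_exo_endo_ratio_regime(default_kinetics, default_protocol):
    """Defaults land in the ~3x exo:endo regime."""
    pools = simulate_pools(default_kinetics, default_protocol)
    s, _ = exo_rate(pools.f, default_protocol)
    _, diff = endo_trace(pools.f, pools.f, default_protocol)
    e, _ = endo_rate(diff, default_protocol)
    assert 2.0 < s / e < 4.0


# ---------------------------------------------------------------- plateau --


def test_pool_plateau_noiseless(default_kinetics, depletion_protocol):
    pools = simulate_pools(default_kinetics, depletion_protocol)
    plateau, plateaued = pool_plateau(pools.f, depletion_protocol)
    expected = default_kinetics.releasable_fraction * (1 - default_kinetics.quench_ratio)
    assert plateau == pytest.approx(expected, abs=1e-3)
    assert plateaued


def test_pool_plateau_equal_across_k_exo(depletion_protocol):
    plateaus = []
    for k_exo in (0.05, 0.15):
        pools = simulate_pools(KineticParams(k_exo=k_exo), depletion_protocol)
        plateaus.append(pool_plateau(pools.f, depletion_protocol)[0])
    assert abs(plateaus[0] - plateaus[1]) < 1e-3


def test_pool_plateau_zero_without_exocytosis(depletion_protocol):
    pools = simulate_pools(KineticParams(k_exo=0.0), depletion_protocol)
    plateau, _ = pool_plateau(pools.f, depletion_protocol)
    assert abs(plateau) < 1e-9


def test_pool_plateau_flags_unplateaued(depletion_protocol):
    t = depletion_protocol.frame_times()
    rising = 0.002 * t  # still rising at the end
    _, plateaued = pool_plateau(rising, depletion_protocol)
    assert not plateaued


# ------------------------------------------------------------- rate table --


def test_rate_table_counts_reconcile(default_kinetics, default_protocol):
    pools = simulate_pools(default_kinetics, default_protocol)
    norm = np.tile(pools.f, (4, 1))
    qc = np.array([KEPT, KEPT, EXCL_DRIFT, KEPT], dtype=object)
    rt = rate_table(make_traceset(norm, default_protocol, qc=qc))
    assert len(rt) == 4
    assert rt["exo_rate"].notna().sum() == 3
    assert (rt.loc[rt.qc_status != KEPT, "exo_rate"].isna()).all()


# ------------------------------------------------------------ ca summaries --


@pytest.fixture(scope="module")
def ca_protocol():
    return StimProtocol(train_onsets=[60.0], train_n_aps=[300], baf_time=None,
                        nh4cl_time=None, ionomycin_time=120.0, total_duration=140.0)


def test_ca_summary_step_cdf(ca_protocol):
    f = simulate_ca_trace(CaParams(), ca_protocol)
    raw = np.tile(100.0 + 500.0 * f, (5, 1))
    cs = ca_summaries(raw, ca_protocol)
    assert np.all(np.diff(cs.cdf) >= 0)
    p = cs.peaks[0]
    assert np.allclose(cs.peaks, p)
    assert cs.cdf[cs.grid < p - 1e-9].max(initial=0) == 0.0
    assert cs.cdf[-1] == 1.0
    assert 0 < p < 1


def test_ca_summary_group_scale_orders_peaks(ca_protocol):
    f_hi = simulate_ca_trace(CaParams(group_scale=1.0), ca_protocol)
    f_lo = simulate_ca_trace(CaParams(group_scale=0.6), ca_protocol)
    hi = ca_summaries(100 + 400 * f_hi[None, :], ca_protocol)
    lo = ca_summaries(100 + 400 * f_lo[None, :], ca_protocol)
    assert lo.peaks[0] < hi.peaks[0]
    # the low-scale CDF sits above (stochastically smaller peaks)
    grid = hi.grid
    lo2 = ca_summaries(100 + 400 * f_lo[None, :], ca_protocol, grid=grid)
    assert np.all(lo2.cdf >= hi.cdf - 1e-12)
    assert np.max(lo2.cdf - hi.cdf) > 0


def test_ca_summary_linear_regime_proportional(ca_protocol):
    """kd >> c: normalized peak proportional to influx rate within 2%."""
    peaks = []
    for influx in (1.0, 2.0):
        ca = CaParams(influx_rate=influx, kd=1e4, hill=1.0, f_rest=0.0)
        f = simulate_ca_trace(ca, ca_protocol)
        cs = ca_summaries(10 + 100 * f[None, :], ca_protocol)
        peaks.append(cs.peaks[0])
    assert peaks[1] / peaks[0] == pytest.approx(2.0, rel=0.02)


def test_ca_summary_invalid_ionomycin_excluded(ca_protocol):
    f = simulate_ca_trace(CaParams(), ca_protocol)
    good = 100 + 400 * f
    bad = np.full_like(f, 100.0)
    bad[-5:] = 50.0  # ionomycin below baseline
    cs = ca_summaries(np.vstack([good, bad]), ca_protocol)
    assert not cs.excluded[0]
    assert cs.excluded[1]
    assert np.isnan(cs.peaks[1])


# ------------------------------------------------------- percent inhibition --


def test_percent_inhibition_arithmetic():
    assert percent_inhibition(1.0, 1.0) == 0.0
    assert percent_inhibition(1.0, 0.27) == pytest.approx(73.0)
    assert occlusion(73.0, 10.0) == pytest.approx(63.0)
    with pytest.raises(ValueError):
        percent_inhibition(0.0, 1.0)


def test_percent_inhibition_from_simulated_knockdown(default_protocol):
    """sigma_field = 0: 40% knockdown recovered from estimated rates."""
    from svpop.synthetic import HierarchyDesign, simulate_experiment

    design = HierarchyDesign(n_preps=1, fields_per_prep=4, boutons_per_field=10,
                             sigma_field=0.0, sigma_bouton=0.0,
                             group_effects={"ctrl": 1.0, "kd": 0.6}, seed=5)
    exp = simulate_experiment(design, KineticParams(k_exo=0.01, k_endo=0.003),
                              None, default_protocol)
    rates = {}
    for g in ("ctrl", "kd"):
        fields = [f for f in exp.fields if f.group == g]
        slopes = [exo_rate(pt.f, default_protocol)[0] for f in fields for pt in f.pools]
        rates[g] = np.mean(slopes)
    inh = percent_inhibition(rates["ctrl"], rates["kd"])
    assert inh == pytest.approx(40.0, abs=3.0)
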