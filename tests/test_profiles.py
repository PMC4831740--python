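"""Line-profile operators and gradient-threshold detectors."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ctstain import (
    EdgePair,
    LineProfile,
    NoEdgeError,
    PhantomSpec,
    SliceImage,
    ValidationError,
    detect_sample_edges,
    detect_stain_front,
    extract_line_profile,
    generate_phantom_slice,
    gradient_per_mm,
    neighbourhood_average,
    normalise_cohort,
    smooth_profile,
    to_depth_series,
)
from conftest import profile_of

PX = 0.0075


def make_profile(values, spacing=PX, **meta):
    values = np.asarray(values, dtype=float)
    return LineProfile(
        positions_mm=np.arange(values.size) * spacing, values=values, **meta
    )


# --- extraction ----------------------------------------------------------

def test_extract_constant_and_band_mean():
    img = np.full((40, 25), 5.0)
    sl = SliceImage(pixels=img, pixel_size_mm=PX)
    p = extract_line_profile(sl)
    assert np.allclose(p.values, 5.0)
    assert p.spacing_mm == pytest.approx(PX)

    # rows alternating 0/1 average to 0.5 over a width-10 band
    img = np.tile(np.arange(40)[:, None] % 2, (1, 25)).astype(float)
    sl = SliceImage(pixels=img, pixel_size_mm=PX)
    p = extract_line_profile(sl, width_px=10)
    assert np.allclose(p.values, 0.5)


def test_extract_band_bounds_error():
    sl = SliceImage(pixels=np.zeros((6, 10)), pixel_size_mm=PX)
    with pytest.raises(ValidationError):
        extract_line_profile(sl, row=1, width_px=10)
    with pytest.raises(ValidationError):
        extract_line_profile(sl, width_px=0)


def test_extract_matches_phantom_truth(sat_spec):
    p, sl, truth = profile_of(sat_spec, 2.0)
    # raw (unnormalised) profile along the diameter equals the closed form
    raw = extract_line_profile(sl)
    n = sl.pixels.shape[0]
    c_mm = (n - 1) / 2 * PX
    r = np.abs(raw.positions_mm - c_mm)
    inside = r <= truth.true_radius_mm - PX
    expect = truth.intensity(truth.true_radius_mm - r[inside])
    # averaging across the 10-row band introduces sub-pixel depth error
    assert np.allclose(raw.values[inside], expect, atol=0.01)


# --- normalisation -------------------------------------------------------

def test_normalise_cohort_uses_global_max():
    p1 = make_profile([10, 100.0])
    p2 = make_profile([50, 200.0])
    out = normalise_cohort([p1, p2])
    assert max(v.values.max() for v in out) == 1.0
    assert out[0].values.max() == pytest.approx(0.5)  # global, not per-profile
    assert all(v.normalised for v in out)
    single = normalise_cohort([p2])[0]
    assert np.allclose(single.values, [0.25, 1.0])


def test_normalise_cohort_errors():
    with pytest.raises(ValidationError):
        normalise_cohort([])
    with pytest.raises(ValidationError):
        normalise_cohort([make_profile([0.0, 0.0])])


@settings(derandomize=True, max_examples=25)
@given(
    vals=st.lists(st.floats(0.01, 100.0), min_size=2, max_size=30),
    scale=st.floats(0.001, 1000.0),
)
def test_normalise_cohort_scale_invariant_and_idempotent(vals, scale):
    p = make_profile(vals)
    scaled = make_profile(np.asarray(vals) * scale)
    a = normalise_cohort([p])[0]
    b = normalise_cohort([scaled])[0]
    assert np.allclose(a.values, b.values, rtol=1e-12)
    again = normalise_cohort([a])[0]
    assert np.allclose(a.values, again.values, rtol=1e-12)


# --- smoothing / gradient / neighbourhood vs brute force -----------------

def brute_gaussian(values, sigma):
    radius = int(4 * sigma + 0.5)
    k = np.exp(-0.5 * (np.arange(-radius, radius + 1) / sigma) ** 2)
    k /= k.sum()
    n = len(values)
    out = np.zeros(n)
    for i in range(n):
        for j, w in enumerate(k):
            idx = min(max(i + j - radius, 0), n - 1)  # edge replication
            out[i] += w * values[idx]
    return out


def test_smooth_constant_impulse_and_oracle(rng):
    const = make_profile(np.full(80, 3.3))
    assert np.allclose(smooth_profile(const).values, 3.3)

    imp = np.zeros(101)
    imp[50] = 1.0
    sm = smooth_profile(make_profile(imp)).values
    assert sm.sum() == pytest.approx(1.0, abs=1e-10)

    vals = rng.normal(size=120)
    got = smooth_profile(make_profile(vals), sigma_px=4).values
    assert np.allclose(got, brute_gaussian(vals, 4), atol=1e-10)
    # shorter-than-kernel profile is rejected
    with pytest.raises(ValidationError):
        smooth_profile(make_profile(np.zeros(10)), sigma_px=4)


def test_gradient_ramp_constant_and_oracle(rng):
    ramp = make_profile(np.arange(50) * PX * 2.0)  # slope 2 per mm
    assert np.allclose(gradient_per_mm(ramp), 2.0)
    assert np.allclose(gradient_per_mm(make_profile(np.full(50, 7.0))), 0.0)

    vals = rng.normal(size=64)
    got = gradient_per_mm(make_profile(vals))
    h = PX
    expect = np.empty(64)
    expect[0] = (vals[1] - vals[0]) / h
    expect[-1] = (vals[-1] - vals[-2]) / h
    for i in range(1, 63):
        expect[i] = (vals[i + 1] - vals[i - 1]) / (2 * h)
    assert np.allclose(got, expect, rtol=0, atol=1e-12)


def test_neighbourhood_average_oracle(rng):
    const = make_profile(np.full(60, 2.0))
    assert np.allclose(neighbourhood_average(const).values, 2.0)
    p = make_profile(rng.normal(size=40))
    assert neighbourhood_average(p, window_mm=PX / 2) is p  # identity

    vals = rng.normal(size=90)
    p = make_profile(vals)
    got = neighbourhood_average(p, window_mm=0.1).values
    k = int((0.1 / 2) / PX)
    expect = np.array(
        [vals[max(i - k, 0): i + k + 1].mean() for i in range(90)]
    )
    assert np.allclose(got, expect, atol=1e-12)


# --- edge detection ------------------------------------------------------

def test_flat_profile_raises_no_edge():
    with pytest.raises(NoEdgeError):
        detect_sample_edges(make_profile(np.full(200, 0.4)))


def test_edges_symmetric_on_phantom(sat_spec):
    p, sl, truth = profile_of(sat_spec, 2.0)
    e = detect_sample_edges(p)
    n = sl.pixels.shape[0]
    c_mm = (n - 1) / 2 * PX
    assert abs((c_mm - e.left_mm) - (e.right_mm - c_mm)) <= 2 * PX


@pytest.mark.parametrize("radius", [0.6, 0.9, 1.2])
@pytest.mark.parametrize("width", [0.15, 0.3])
def test_edges_within_4sigma_of_true_boundary(radius, width):
    spec = PhantomSpec(mode="front", radius0_mm=radius, C=radius * 0.8, K=0.5,
                       front_width_mm=width, I_in=0.1, I_out=0.65)
    p, sl, truth = profile_of(spec, 1.0)
    e = detect_sample_edges(p, sigma_px=4)
    n = sl.pixels.shape[0]
    c_mm = (n - 1) / 2 * PX
    # 4 sigma at sigma = 4 px, plus one grid step: the truncated kernel's
    # support ends exactly 16 px inside the boundary
    tol = (4 * 4 + 1) * PX
    assert abs(e.left_mm - (c_mm - truth.true_radius_mm)) <= tol
    assert abs(e.right_mm - (c_mm + truth.true_radius_mm)) <= tol
    # paired-edge invariant: width error bounded by 4 sigma + ramp width
    assert abs(e.width_mm - 2 * truth.true_radius_mm) <= tol + width


def test_detected_width_shrinks_with_radius(sat_spec):
    widths = []
    for s in (0.0, 0.05, 0.10):
        spec = PhantomSpec(**{**sat_spec.__dict__, "shrink_fraction": s})
        p, _, _ = profile_of(spec, 2.0)
        widths.append(detect_sample_edges(p).width_mm)
    assert widths[0] > widths[1] > widths[2]


# --- stain-front detection ----------------------------------------------

def test_no_front_in_saturating_phantom(sat_spec):
    for t in (0.0, 2.0, 4.0):
        p, _, _ = profile_of(sat_spec, t)
        e = detect_sample_edges(p)
        fl = detect_stain_front(p, e, side="left")
        assert not fl.found


def test_front_depth_tracks_truth_and_is_monotone(front_spec):
    prev = -1.0
    for t in (0.0, 1.0, 2.0, 3.0, 4.0):
        p, _, truth = profile_of(front_spec, t)
        e = detect_sample_edges(p)
        w = front_spec.front_width_mm
        for side in ("left", "right"):
            fl = detect_stain_front(p, e, side=side)
            assert fl.found
            # front edge sits at the inner end of the ramp: d + w/2
            assert abs(fl.depth_mm - (truth.true_front_depth_mm + w / 2)) <= w
        assert fl.depth_mm >= prev
        prev = fl.depth_mm


def test_front_beyond_centre_is_capped():
    spec = PhantomSpec(mode="front", radius0_mm=0.9, C=2.0, K=2.0,
                       front_width_mm=0.2, I_in=0.1, I_out=0.65)
    p, _, truth = profile_of(spec, 4.0)  # front would be at 2.0 mm > radius
    e = detect_sample_edges(p)
    fl = detect_stain_front(p, e, side="left")
    if fl.found:
        assert fl.capped
        assert fl.depth_mm <= e.width_mm / 2 + 1e-9


def test_front_invalid_edges():
    p = make_profile(np.linspace(0, 1, 300))
    with pytest.raises(ValidationError):
        detect_stain_front(p, EdgePair(left_mm=-1.0, right_mm=10.0))
    with pytest.raises(ValidationError):
        detect_stain_front(p, EdgePair(left_mm=0.01, right_mm=0.05), side="up")


# --- depth series --------------------------------------------------------

def build_series(spec, days=(0.0, 1.0, 2.0, 3.0, 4.0), **kw):
    """Cohort-normalised depth series plus truth/edge bookkeeping."""
    raw, truths, geom = [], {}, {}
    for t in days:
        sl, truth = generate_phantom_slice(spec, t)
        p = extract_line_profile(sl)
        raw.append(p)
        truths[p.day] = truth
        geom[p.day] = (sl.pixels.shape[0] - 1) / 2 * PX
    scale = max(p.values.max() for p in raw)
    profs = {p.day: p for p in normalise_cohort(raw)}
    edges = {d: detect_sample_edges(p) for d, p in profs.items()}
    return to_depth_series(profs, edges, **kw), truths, edges, geom, scale


def test_depth_series_sides_agree_and_match_truth(sat_spec):
    ds, truths, edges, geom, scale = build_series(sat_spec, max_depth_mm=0.7)
    # symmetric phantom: the two sides agree
    ok = ds.dropna(subset=["intensity_left", "intensity_right"])
    assert np.allclose(ok["intensity_left"], ok["intensity_right"], atol=5e-3)
    # values match the closed form evaluated at the true depth of the
    # sampled point (detected edge sits slightly inside the boundary)
    for day in (1, 4):
        sub = ds[ds["day"] == day].dropna(subset=["intensity"])
        truth, e = truths[day], edges[day]
        delta = e.left_mm - (geom[day] - truth.true_radius_mm)
        expect = truth.intensity(sub["depth_mm"].to_numpy() + delta)
        got = sub["intensity"].to_numpy() * scale
        assert np.allclose(got, expect, atol=0.02)


def test_depth_series_zero_depth_is_edge_intensity(sat_spec):
    ds, truths, edges, geom, scale = build_series(sat_spec, max_depth_mm=0.3)
    row0 = ds[(ds["day"] == 2) & (ds["depth_mm"] == 0.0)].iloc[0]
    assert np.isfinite(row0["intensity"])


def test_depth_series_identity_checks(sat_spec, front_spec):
    p1, _, _ = profile_of(sat_spec, 1.0)
    p2, _, _ = profile_of(front_spec, 1.0)
    e1 = detect_sample_edges(p1)
    e2 = detect_sample_edges(p2)
    with pytest.raises(ValidationError):
        to_depth_series({1: p1, 2: p2}, {1: e1, 2: e2})
    with pytest.raises(ValidationError):
        to_depth_series({1: p1}, {2: e1})


def test_depths_beyond_half_width_are_missing(sat_spec):
    ds, _, edges, _, _ = build_series(sat_spec, max_depth_mm=1.5)
    half = edges[0].width_mm / 2
    deep = ds[ds["depth_mm"] > half + 0.1]
    assert deep["intensity"].isna().all()
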