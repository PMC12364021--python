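"""Inverse method: two-point solve, flank regression, association, demux."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dynaquad import isotopes
from dynaquad.containers import IntensityProfile, ScanRecord, SelectionWindow
from dynaquad.errors import InvalidParameterError, UnsolvableGeometryError
from dynaquad.infer import (
    associate_products,
    demultiplex,
    evaluate_estimates,
    phase,
    profile_fit,
    resolving_power,
    two_point_solve,
)
from dynaquad.transfer import transmission


def triangle_points(true_mz, amp, width, centers):
    """Forward model: noiseless intensities at the given selection centers."""
    return amp * transmission(np.asarray(centers, dtype=float), true_mz, width)


# ---------------------------------------------------------------------------
# two-point solver
# ---------------------------------------------------------------------------


def test_two_point_worked_example():
    est = two_point_solve((200.0, 600.0), (205.0, 400.0), 10.0)
    assert est.mz == pytest.approx(202.0, abs=1e-12)
    assert est.apex_intensity == pytest.approx(1000.0, abs=1e-9)
    assert est.x_low == pytest.approx(197.0)
    assert est.x_high == pytest.approx(207.0)


def test_two_point_symmetry_and_edge_cases():
    # equal intensities at 50 % overlap: precursor at the midpoint
    est = two_point_solve((200.0, 500.0), (205.0, 500.0), 10.0)
    assert est.mz == pytest.approx(202.5)
    # second intensity zero: precursor exactly at the first center
    est = two_point_solve((200.0, 700.0), (205.0, 0.0), 10.0)
    assert est.mz == pytest.approx(200.0)
    assert est.apex_intensity == pytest.approx(700.0)


def test_two_point_order_invariance():
    a = two_point_solve((200.0, 600.0), (205.0, 400.0), 10.0)
    b = two_point_solve((205.0, 400.0), (200.0, 600.0), 10.0)
    assert a.mz == b.mz and a.apex_intensity == b.apex_intensity


def test_two_point_one_sided_branches():
    # both observations on the same flank (x below both centers)
    x, amp, w = 199.0, 1000.0, 10.0
    c1, c2 = 200.5, 202.5
    i1, i2 = (amp * transmission(c, x, w) for c in (c1, c2))
    est = two_point_solve((c1, i1), (c2, i2), w)
    assert est.mz == pytest.approx(x, abs=1e-9)
    assert est.apex_intensity == pytest.approx(amp, rel=1e-9)
    # mirrored: x above both centers
    i1m, i2m = (amp * transmission(c, 203.9, w) for c in (c1, c2))
    est = two_point_solve((c1, i1m), (c2, i2m), w)
    assert est.mz == pytest.approx(203.9, abs=1e-9)


def test_two_point_unsolvable_and_invalid():
    with pytest.raises(UnsolvableGeometryError):
        # equal intensities with near-total overlap force an inconsistent branch
        two_point_solve((200.0, 500.0), (212.0, 500.0), 10.0)
    with pytest.raises(InvalidParameterError):
        two_point_solve((200.0, 1.0), (200.0, 2.0), 10.0)
    with pytest.raises(InvalidParameterError):
        two_point_solve((200.0, 0.0), (205.0, 0.0), 10.0)


@settings(derandomize=True, max_examples=300)
@given(
    x_frac=st.floats(min_value=0.01, max_value=0.99),
    amp=st.floats(min_value=1e-3, max_value=1e9),
    width=st.floats(min_value=0.5, max_value=30.0),
    c1=st.floats(min_value=150.0, max_value=1700.0),
    overlap_frac=st.floats(min_value=0.1, max_value=0.9),
)
def test_two_point_round_trip_property(x_frac, amp, width, c1, overlap_frac):
    """Forward-simulate then invert: exact recovery when x lies between centers."""
    c2 = c1 + width * (1 - overlap_frac)
    x = c1 + x_frac * (c2 - c1)
    i1, i2 = (float(amp * transmission(c, x, width)) for c in (c1, c2))
    if i1 == 0 or i2 == 0:
        # precursor outside one window: a silent scan only brackets an edge,
        # so exact recovery is not defined in that regime
        return
    est = two_point_solve((c1, i1), (c2, i2), width)
    assert est.mz == pytest.approx(x, abs=1e-9 * max(1.0, abs(x)))
    assert est.apex_intensity == pytest.approx(amp, rel=1e-9)


# ---------------------------------------------------------------------------
# phase
# ---------------------------------------------------------------------------


def test_phase_anchor_values():
    # centers equidistant from the precursor: 0 degrees
    assert phase(199.57, 204.57, 202.07) == 0.0
    # first center on the precursor: +180; second center: -180
    assert phase(202.07, 207.07, 202.07) == 180.0
    assert phase(197.07, 202.07, 202.07) == -180.0
    # linear in between
    assert phase(200.0, 205.0, 201.25) == pytest.approx(90.0)


# ---------------------------------------------------------------------------
# profile fit
# ---------------------------------------------------------------------------


def test_profile_fit_recovers_triangle_exactly():
    true_mz, amp, width = 202.07, 1234.5, 8.0
    centers = np.round(np.arange(196.07, 208.075, 0.1), 5)
    prof = IntensityProfile(
        mz=500.0, centers=centers,
        intensities=triangle_points(true_mz, amp, width, centers), width=width,
    )
    est = profile_fit(prof)
    assert est.method == "profile_fit"
    assert est.mz == pytest.approx(true_mz, abs=1e-9)
    assert est.apex_intensity == pytest.approx(amp, rel=1e-9)
    # x-intercepts span exactly the starting window width
    assert est.intercept_span == pytest.approx(width, abs=1e-9)
    assert est.x_low == pytest.approx(true_mz - width / 2, abs=1e-9)


def test_profile_fit_matches_two_point_on_flank_pairs():
    true_mz, amp, width = 500.37, 800.0, 10.0
    centers = np.arange(true_mz - 6.0, true_mz + 6.01, 0.25)
    ints = triangle_points(true_mz, amp, width, centers)
    dense = profile_fit(IntensityProfile(mz=1.0, centers=centers, intensities=ints, width=width))
    # any straddling pair gives the same answer
    pair = two_point_solve((centers[10], ints[10]), (centers[-10], ints[-10]), width)
    assert dense.mz == pytest.approx(pair.mz, abs=1e-9)
    assert dense.apex_intensity == pytest.approx(pair.apex_intensity, rel=1e-9)


def test_profile_fit_two_point_fallback_with_adjacent_zero():
    """A precursor exactly on a selection center is pinned by its silent neighbours."""
    width = 10.0
    centers = np.array([495.0, 500.0, 505.0])
    ints = np.array([0.0, 750.0, 0.0])
    est = profile_fit(IntensityProfile(mz=1.0, centers=centers, intensities=ints, width=width))
    assert est.method == "two_point_fallback"
    assert est.mz == pytest.approx(500.0, abs=1e-9)
    assert est.apex_intensity == pytest.approx(750.0)


def test_profile_fit_scale_invariance():
    true_mz, width = 321.4, 10.0
    centers = np.arange(316.0, 327.0, 0.5)
    ints = triangle_points(true_mz, 100.0, width, centers)
    e1 = profile_fit(IntensityProfile(mz=1.0, centers=centers, intensities=ints, width=width))
    e2 = profile_fit(
        IntensityProfile(mz=1.0, centers=centers, intensities=ints * 5417.0, width=width)
    )
    assert e1.mz == pytest.approx(e2.mz, abs=1e-12)
    assert e2.apex_intensity == pytest.approx(5417.0 * e1.apex_intensity, rel=1e-12)


def test_profile_fit_composite_isotopolog_profile_gives_weighted_mean():
    """Flank-only sampling of a composite profile extrapolates to the
    contribution-weighted mean m/z (sum-of-lines algebra)."""
    pep = isotopes.AveraginePeptide(length=20, charge=2)
    width = 10.0
    from dynaquad.isotopes import SUPPORT_FRACTION, _composite_weights

    weights, mzs = _composite_weights(pep, 3, 0.011)
    keep = mzs - pep.mz <= SUPPORT_FRACTION * width
    weights, mzs = weights[keep], mzs[keep]
    left = np.linspace(mzs[-1] - width / 2 + 0.05, mzs[0] - 0.05, 15)
    right = np.linspace(mzs[-1] + 0.05, mzs[0] + width / 2 - 0.05, 15)
    centers = np.concatenate([left, right])
    ints = np.array([float(np.sum(weights * transmission(mzs, c, width))) for c in centers])
    est = profile_fit(IntensityProfile(mz=1.0, centers=centers, intensities=ints, width=width))
    expected = float(np.sum(weights * mzs) / weights.sum())
    assert est.mz == pytest.approx(expected, abs=1e-9)
    assert est.mz - pep.mz == pytest.approx(isotopes.mass_residual(pep, 3, width), abs=1e-9)


def test_intercept_span_robust_to_noise(rng):
    """With 1 % RMS noise and dense flanks the span stays within 2 % of w."""
    true_mz, amp, width = 202.07, 1000.0, 8.0
    centers = np.arange(196.27, 207.88, 0.1)
    ints = triangle_points(true_mz, amp, width, centers)
    spans = []
    for _ in range(25):
        noisy = ints * rng.lognormal(mean=0.0, sigma=0.01, size=ints.shape)
        est = profile_fit(
            IntensityProfile(mz=1.0, centers=centers, intensities=noisy, width=width)
        )
        spans.append(est.intercept_span)
    assert np.max(np.abs(np.array(spans) - width)) < 0.02 * width


# ---------------------------------------------------------------------------
# association and demultiplexing
# ---------------------------------------------------------------------------


def make_scan(idx, center, width, it, peaks):
    mzs = np.array([p[0] for p in peaks])
    ints = np.array([p[1] for p in peaks])
    return ScanRecord(
        scan_index=idx,
        window=SelectionWindow(center=center, start_width=width, accumulation_time=it),
        accumulation_time=it,
        mzs=mzs,
        intensities=ints,
    )


def test_associate_products_merges_within_tolerance():
    scans = [
        make_scan(0, 500.0, 10.0, 10.0, [(300.0000, 100.0), (400.0, 50.0)]),
        make_scan(1, 505.0, 10.0, 20.0, [(300.0030, 80.0), (400.04, 10.0)]),
    ]
    profiles = associate_products(scans, ppm_tol=25.0, pad_zeros=False)
    # 300.000 vs 300.003 is 10 ppm: merged; 400.00 vs 400.04 is 100 ppm: not merged
    assert len(profiles) == 1
    prof = profiles[0]
    assert prof.n_points == 2
    # flux normalisation by each scan's actual accumulation time
    np.testing.assert_allclose(prof.intensities, [100.0 / 10.0, 80.0 / 20.0])


def test_associate_products_rejects_mixed_widths():
    scans = [
        make_scan(0, 500.0, 10.0, 10.0, [(300.0, 1.0)]),
        make_scan(1, 505.0, 8.0, 10.0, [(300.0, 1.0)]),
    ]
    with pytest.raises(InvalidParameterError):
        associate_products(scans)


def test_associate_products_pads_adjacent_zero_points():
    scans = [
        make_scan(0, 495.0, 10.0, 10.0, []),
        make_scan(1, 500.0, 10.0, 10.0, [(300.0, 100.0)]),
        make_scan(2, 505.0, 10.0, 10.0, []),
    ]
    profiles = associate_products(scans)
    assert len(profiles) == 1
    np.testing.assert_allclose(profiles[0].centers, [495.0, 500.0, 505.0])
    np.testing.assert_allclose(profiles[0].intensities, [0.0, 10.0, 0.0])


def test_demultiplex_separates_two_close_precursors():
    """Two precursors 1 Th apart resolve into two clean pseudo-spectra."""
    from dynaquad.containers import NoiseModel
    from dynaquad.simulate import simulate_dia_cycle, two_peptide_infusion

    precursors = two_peptide_infusion()
    scans = simulate_dia_cycle(
        precursors, (480.0, 520.0), width=10.0, overlap=5.0,
        noise=NoiseModel(rms=0.01), seed=7,
    )
    result = demultiplex(scans, width=10.0)
    assert len(result.pseudo_spectra) == 2
    truth = {round(p.mz, 6): {round(f.mz, 4) for f in p.products} for p in precursors}
    for ps in result.pseudo_spectra:
        true_mz = min(truth, key=lambda t: abs(t - ps.precursor_mz))
        assert abs(ps.precursor_mz - true_mz) <= 0.3
        assert {round(m, 4) for m in ps.product_mzs} == truth[true_mz]


def test_demultiplex_single_precursor_single_cluster():
    from dynaquad.simulate import simulate_dia_cycle, two_peptide_infusion

    precursors = two_peptide_infusion()[:1]
    scans = simulate_dia_cycle(precursors, (480.0, 520.0), width=10.0, overlap=5.0, seed=3)
    result = demultiplex(scans)
    assert len(result.pseudo_spectra) == 1
    assert len(result.pseudo_spectra[0].product_mzs) == len(precursors[0].products)


def test_mass_range_ladder_deviation_table():
    """Synthetic 20-species ladder, 150-1750 Th, 10 Th windows with 5 Th
    overlap, no dissociation: calculated precursor m/z matches the observed
    spectrum m/z for every feature across the mass range."""
    from dynaquad.containers import NoiseModel
    from dynaquad.simulate import flexmix_ladder, simulate_dia_cycle

    ladder = flexmix_ladder(n_species=20, seed=1)
    scans = simulate_dia_cycle(
        ladder, (150.0, 1750.0), width=10.0, overlap=5.0,
        noise=NoiseModel(rms=0.01), seed=9,
    )
    result = demultiplex(scans, width=10.0)
    assert len(result.pseudo_spectra) == 20
    estimates = [e for ps in result.pseudo_spectra for e in ps.estimates]
    df = evaluate_estimates(estimates, [p.mz for p in ladder], width=10.0)
    assert df.attrs["summary"]["n"] == 20
    assert df.attrs["summary"]["max_abs_delta_mz"] < 0.1
    assert {"estimated_mz", "true_mz", "delta_mz", "apex_intensity"} <= set(df.columns)


def test_evaluate_estimates_report():
    ests = [
        two_point_solve((200.0, 600.0), (205.0, 400.0), 10.0),  # x = 202.0
        two_point_solve((300.0, 500.0), (305.0, 500.0), 10.0),  # x = 302.5
    ]
    df = evaluate_estimates(ests, [202.1, 302.5], width=10.0)
    assert df.attrs["summary"]["n"] == 2
    assert df.attrs["summary"]["max_abs_delta_mz"] == pytest.approx(0.1, abs=1e-9)
    assert df["span_dev"].abs().max() == pytest.approx(0.0, abs=1e-9)


def test_resolving_power():
    assert resolving_power(10.0, 0.3) == 33
    assert resolving_power(4.0, 0.8) == 5
    assert resolving_power(7.0, 7.0) == 1
    with pytest.raises(InvalidParameterError):
        resolving_power(10.0, 0.0)
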