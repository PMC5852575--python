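import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rnaocclusion import (
    AnnotationError,
    DomainError,
    Ensemble,
    OverlapSeries,
    Selection,
    UsageError,
    compare_distributions,
    ensemble_overlap,
    frame_overlap,
    make_variant_pair,
    overlap_distribution,
    sphere_pair_overlap,
)

from conftest import make_peptide, random_rotation


def mc_sphere_overlap(r1, r2, d, n_samples, rng):
    """Monte-Carlo integration oracle for the two-sphere intersection.

    Samples uniformly in a tight bounding box of the intersection region
    (the lens slab for partial overlap, the smaller sphere's box under
    containment) and scales the hit fraction by the box volume."""
    if d >= r1 + r2:
        return 0.0
    c1 = np.zeros(3)
    c2 = np.array([d, 0.0, 0.0])
    if d <= abs(r1 - r2):
        rmin, centre = (r1, c1) if r1 < r2 else (r2, c2)
        lo = centre - rmin
        hi = centre + rmin
    else:
        x_lo, x_hi = d - r2, r1
        # max radial extent of the lens: the lower envelope of the two
        # circle profiles peaks at x=0, x=d or at the crossing plane
        def radial(x):
            f1 = np.sqrt(max(r1 * r1 - x * x, 0.0))
            f2 = np.sqrt(max(r2 * r2 - (d - x) ** 2, 0.0))
            return min(f1, f2)
        xc = (d * d + r1 * r1 - r2 * r2) / (2 * d)
        a = max(radial(x) for x in (0.0, d, xc) if x_lo <= x <= x_hi)
        lo = np.array([x_lo, -a, -a])
        hi = np.array([x_hi, a, a])
    box_vol = np.prod(hi - lo)
    hits = 0
    chunk = 2_000_000
    remaining = n_samples
    while remaining > 0:
        m = min(chunk, remaining)
        pts = rng.random((m, 3)) * (hi - lo) + lo
        in1 = np.sum((pts - c1) ** 2, axis=1) <= r1 * r1
        in2 = np.sum((pts - c2) ** 2, axis=1) <= r2 * r2
        hits += int(np.count_nonzero(in1 & in2))
        remaining -= m
    return box_vol * hits / n_samples


def brute_force_overlap(p, pr, r, rr):
    total = 0.0
    for i in range(len(p)):
        for j in range(len(r)):
            total += sphere_pair_overlap(pr[i], rr[j], float(np.linalg.norm(p[i] - r[j])))
    return total


def random_system(rng, n_p=50, n_r=30):
    p = rng.uniform(-8, 8, size=(n_p, 3))
    r = rng.uniform(-8, 8, size=(n_r, 3))
    pr = rng.uniform(1.2, 2.0, size=n_p)
    rr = rng.uniform(1.2, 2.0, size=n_r)
    return p, pr, r, rr


class TestSpherePairOverlap:
    def test_disjoint_spheres_give_zero(self):
        assert sphere_pair_overlap(1.70, 1.52, 5.0) == 0.0

    def test_contained_sphere_gives_smaller_sphere_volume(self):
        assert sphere_pair_overlap(2.0, 1.0, 0.5) == pytest.approx(4 * np.pi / 3)

    def test_unit_spheres_at_unit_distance(self):
        # lens closed form: π(r1+r2−d)²(d²+2d(r1+r2)−3(r1−r2)²)/(12d) = 5π/12
        assert sphere_pair_overlap(1.0, 1.0, 1.0) == pytest.approx(5 * np.pi / 12)

    def test_matches_monte_carlo_on_random_triples(self):
        rng = np.random.default_rng(99)
        for _ in range(10):
            r1, r2 = rng.uniform(0.8, 2.5, size=2)
            d = rng.uniform(0.0, r1 + r2 + 0.5)
            exact = sphere_pair_overlap(r1, r2, d)
            approx = mc_sphere_overlap(r1, r2, d, 1_000_000, rng)
            if exact == 0.0:
                assert approx == 0.0
            else:
                assert approx == pytest.approx(exact, rel=0.01)

    def test_nonpositive_radius_rejected(self):
        with pytest.raises(DomainError):
            sphere_pair_overlap(0.0, 1.0, 1.0)
        with pytest.raises(DomainError):
            sphere_pair_overlap(1.0, 1.0, -0.1)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(r1=st.floats(0.6, 2.9), r2=st.floats(0.6, 2.9),
           d=st.floats(0.0, 6.0))
    def test_bounds_and_symmetry(self, r1, r2, d):
        v = sphere_pair_overlap(r1, r2, d)
        vmin = 4 / 3 * np.pi * min(r1, r2) ** 3
        assert 0.0 <= v <= vmin + 1e-9
        assert v == pytest.approx(sphere_pair_overlap(r2, r1, d), abs=1e-12)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(r1=st.floats(0.6, 2.9), r2=st.floats(0.6, 2.9))
    def test_monotonically_nonincreasing_in_distance(self, r1, r2):
        ds = np.linspace(0, r1 + r2 + 0.5, 40)
        vols = [sphere_pair_overlap(r1, r2, d) for d in ds]
        assert all(a >= b - 1e-12 for a, b in zip(vols, vols[1:]))


class TestFrameOverlap:
    def test_distant_clusters_give_zero(self, rng):
        p, pr, r, rr = random_system(rng)
        assert frame_overlap(p + 100.0, pr, r, rr) == 0.0

    def test_coincident_equal_radius_atoms(self):
        v = frame_overlap(np.zeros((1, 3)), np.array([1.5]),
                          np.zeros((1, 3)), np.array([1.5]))
        assert v == pytest.approx(4 / 3 * np.pi * 1.5 ** 3)

    def test_matches_brute_force_on_seeded_system(self, rng):
        p, pr, r, rr = random_system(rng)
        assert frame_overlap(p, pr, r, rr) == pytest.approx(
            brute_force_overlap(p, pr, r, rr), abs=1e-9)

    def test_rigid_invariance_under_joint_transform(self, rng):
        p, pr, r, rr = random_system(rng)
        v0 = frame_overlap(p, pr, r, rr)
        rot = random_rotation(rng)
        shift = rng.normal(size=3) * 30
        v1 = frame_overlap(p @ rot.T + shift, pr, r @ rot.T + shift, rr)
        assert v1 == pytest.approx(v0, rel=1e-9)

    def test_monotone_as_rna_translates_away(self, rng):
        # RNA starts on the +axis side of the protein, so every pair
        # distance grows with the translation and overlap cannot increase
        p, pr, r, rr = random_system(rng)
        axis = np.array([1.0, 0.3, -0.2])
        axis /= np.linalg.norm(axis)
        r = r + (np.max(p @ axis) - np.min(r @ axis)) * axis
        vols = [frame_overlap(p, pr, r + step * axis, rr)
                for step in np.linspace(0, 40, 20)]
        assert vols[0] > 0
        assert all(a >= b - 1e-9 for a, b in zip(vols, vols[1:]))

    def test_upper_bound_by_protein_sphere_volumes(self, rng):
        p, pr, r, rr = random_system(rng, n_p=20, n_r=20)
        v = frame_overlap(p, pr, r, rr)
        assert v <= np.sum(4 / 3 * np.pi * pr ** 3) * len(r) + 1e-9

    def test_missing_radius_rejected(self):
        with pytest.raises(AnnotationError):
            frame_overlap(np.zeros((1, 3)), np.array([np.nan]),
                          np.zeros((1, 3)), np.array([1.5]))


class TestEnsembleOverlap:
    def test_static_ensemble_gives_constant_series(self, rng):
        ens_a, _, rna = make_variant_pair()
        topo = ens_a.topology
        static = Ensemble(topo, np.repeat(topo.coords[None], 4, axis=0),
                          fitted=True)
        series = ensemble_overlap(static, rna, rna_sel=Selection(chains={"R"}))
        assert len(series) == 4
        assert np.ptp(series.volumes) == 0.0

    def test_far_translated_ensemble_all_zero(self):
        ens_a, _, rna = make_variant_pair()
        far = Ensemble(ens_a.topology, ens_a.frames + 100.0, fitted=True)
        series = ensemble_overlap(far, rna)
        assert np.all(series.volumes == 0.0)

    def test_unfitted_ensemble_without_fit_selection_rejected(self):
        ens_a, _, rna = make_variant_pair()
        assert not ens_a.fitted
        with pytest.raises(UsageError):
            ensemble_overlap(ens_a, rna)

    def test_series_mean_matches_per_frame_recomputation(self):
        from rnaocclusion import RadiusTable, assign_radii
        ens_a, _, rna = make_variant_pair()
        ens = Ensemble(ens_a.topology, ens_a.frames, fitted=True)
        series = ensemble_overlap(ens, rna)
        annot_p = assign_radii(ens.topology, RadiusTable.bondi())
        annot_r = assign_radii(rna, RadiusTable.bondi())
        oracle = np.array([
            brute_force_overlap(ens.frames[f], annot_p.radii,
                                annot_r.coords, annot_r.radii)
            for f in range(ens.n_frames)
        ])
        assert np.abs(series.volumes - oracle).max() < 1e-9


class TestDistribution:
    def test_constant_series_single_occupied_bin_integrates_to_one(self):
        series = OverlapSeries([f"f{i}" for i in range(5)], np.full(5, 3.0))
        dist = overlap_distribution(series)
        widths = np.diff(dist.bin_edges)
        assert np.count_nonzero(dist.density) == 1
        assert np.sum(dist.density * widths) == pytest.approx(1.0, abs=1e-9)

    def test_any_series_integrates_to_one(self, rng):
        v = rng.gamma(2.0, 5.0, size=500)
        dist = overlap_distribution(v)
        assert np.sum(dist.density * np.diff(dist.bin_edges)) == pytest.approx(
            1.0, abs=1e-9)

    def test_uniform_samples_recover_flat_density(self):
        rng = np.random.default_rng(5)
        v = rng.random(10_000)
        dist = overlap_distribution(v, binning=np.linspace(0, 1, 11))
        assert np.all(np.abs(dist.density - 1.0) < 0.05)


class TestCompare:
    def test_identical_series_no_direction(self, rng):
        v = rng.gamma(2.0, 5.0, size=100)
        report = compare_distributions(v, v.copy())
        assert report.direction == "none"
        assert report.median_diff == 0.0
        assert report.p_value > 0.9

    def test_constant_shift_recovered_exactly(self, rng):
        v = rng.gamma(2.0, 5.0, size=100)
        report = compare_distributions(v, v + 10.0)
        assert report.mean_diff == pytest.approx(10.0)
        assert report.median_diff == pytest.approx(10.0)
        assert report.direction == "b_higher"

    def test_builtin_variant_effect_detected(self):
        from rnaocclusion import VariantPairSpec, make_reference_complex, fit_ensemble
        spec = VariantPairSpec(seed=42, n_frames=200)
        ens_a, ens_b, rna = make_variant_pair(spec)
        ref = make_reference_complex(spec)
        sel = Selection(chains={"A"}, res_range=(406, 465), atom_names={"CA"})
        fa, _ = fit_ensemble(ens_a, ref, sel)
        fb, _ = fit_ensemble(ens_b, ref, sel)
        sa = ensemble_overlap(fa, ref)
        sb = ensemble_overlap(fb, ref)
        report = compare_distributions(sa, sb)
        assert report.direction == "b_higher"
        assert report.p_value < 0.01
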