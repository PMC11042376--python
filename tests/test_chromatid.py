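"""Tests of the coarse-grained 3D chromatid builders."""

import numpy as np
import pytest

from mitofold.chromatid import (
    ChromatidParams, CohesiveLinkSet, Conformation, apply_helical_scaffold,
    build_bottlebrush, build_chromatid, build_nested_bottlebrush,
    build_periodic_random_walk, build_sister_pair, cross_section_profile,
    realized_volume_density, segments_from_loops,
)
from mitofold.synthetic import exponential_loop_array, make_cohesive_links

GENOME = 50e6


@pytest.fixture(scope="module")
def loops_400():
    return exponential_loop_array(GENOME, 400e3, seed=1)


@pytest.fixture(scope="module")
def helix_conf(loops_400, ):
    params = ChromatidParams()  # condensin II defaults
    return build_chromatid(loops_400, params, GENOME, seed=1)


class TestParams:
    def test_pitch_consistency(self):
        p = ChromatidParams(turn_mb=17.0, linear_density_mb_um=42.5)
        assert p.pitch_nm == pytest.approx(400.0)

    def test_winding_number(self):
        p = ChromatidParams(turn_mb=17.0)
        assert p.winding_number(100e6) == pytest.approx(100 / 17, rel=1e-6)

    def test_volume_density_sanity_band(self):
        with pytest.raises(ValueError):
            ChromatidParams(volume_density_mb_um3=500.0)

    def test_invalid_mode_rejected(self):
        with pytest.raises(ValueError):
            ChromatidParams(helix_mode="flat")


class TestSegments:
    def test_gaps_become_linker_segments(self):
        loops = np.array([[0, 4e5], [6e5, 1e6]])
        segs = segments_from_loops(loops, 1.5e6)
        assert [s[2] for s in segs] == [True, False, True, False]

    def test_overlapping_loops_rejected(self):
        with pytest.raises(ValueError):
            segments_from_loops(np.array([[0, 5e5], [4e5, 8e5]]), 1e6)


class TestBottlebrush:
    def test_genomic_ordering_preserved(self, helix_conf):
        assert np.all(np.diff(helix_conf.genomic_bp) > 0)

    def test_beads_confined_to_cylinder(self, helix_conf):
        params = helix_conf.meta["params"]
        R = params.cylinder_radius_nm(GENOME)
        r = np.hypot(helix_conf.xyz[:, 0], helix_conf.xyz[:, 1])
        assert np.quantile(r, 0.999) <= R * 1.01

    def test_volume_density_within_15_percent(self, loops_400):
        for mode_kw in (
            dict(),  # condensin II cylinder defaults
            dict(loop_bp=100e3, gap_nm=20.0, turn_mb=None,
                 volume_density_mb_um3=77.0,
                 helix_mode="periodic_random_walk", end_to_end_um=2.0),
        ):
            params = ChromatidParams(**mode_kw)
            loops = exponential_loop_array(GENOME, params.loop_bp, seed=2)
            conf = build_chromatid(loops, params, GENOME, seed=2)
            rho = realized_volume_density(conf)
            assert rho == pytest.approx(params.volume_density_mb_um3, rel=0.15)

    def test_scaffold_confined_inside_half_radius(self, helix_conf):
        params = helix_conf.meta["params"]
        R = params.cylinder_radius_nm(GENOME)
        anchors = helix_conf.select("loop_anchor")
        r = np.hypot(anchors[:, 0], anchors[:, 1])
        # scaffold radius (rms radial position of anchors) < 0.5 chromatid radius
        assert np.sqrt(np.mean(r ** 2)) < 0.5 * R * 1.15

    def test_zero_loops_reduces_to_bare_fiber(self):
        params = ChromatidParams()
        conf = build_bottlebrush(np.empty((0, 2)), params, 5e6, seed=3)
        assert conf.n_beads > 100
        assert not conf.annotations["loop_interior"].any()

    def test_oversized_gap_rejected(self):
        params = ChromatidParams(gap_nm=5000.0)
        with pytest.raises(ValueError):
            build_bottlebrush(np.array([[0, 4e5]]), params, 5e6, seed=0)


class TestHelicalScaffold:
    def test_winding_number_realized(self, helix_conf):
        params = helix_conf.meta["params"]
        anchors = helix_conf.select("loop_anchor")
        phi = np.unwrap(np.arctan2(anchors[:, 1], anchors[:, 0]))
        turns = (phi[-1] - phi[0]) / (2 * np.pi)
        expected = GENOME / 1e6 / params.turn_mb
        assert turns == pytest.approx(expected, rel=0.25)

    def test_ends_near_opposite_caps(self, helix_conf):
        params = helix_conf.meta["params"]
        Lz = params.axis_length_nm(GENOME)
        assert helix_conf.xyz[0, 2] < 0.25 * Lz
        assert helix_conf.xyz[-1, 2] > 0.75 * Lz

    def test_infinite_turn_length_gives_straight_backbone(self, loops_400):
        params = ChromatidParams(turn_mb=None)
        conf = build_chromatid(loops_400, params, GENOME, seed=1)
        anchors = conf.select("loop_anchor")
        phi = np.unwrap(np.arctan2(anchors[:, 1], anchors[:, 0]))
        assert abs(phi[-1] - phi[0]) / (2 * np.pi) < 2.0

    def test_single_turn_warns(self):
        params = ChromatidParams(turn_mb=17.0)
        loops = exponential_loop_array(10e6, 400e3, seed=4)
        conf = build_bottlebrush(loops, params, 10e6, seed=4)
        with pytest.warns(UserWarning, match="fewer than one turn"):
            apply_helical_scaffold(conf, params)


class TestPeriodicRandomWalk:
    def test_end_to_end_imposed(self):
        params = ChromatidParams(loop_bp=100e3, gap_nm=20.0, turn_mb=None,
                                 volume_density_mb_um3=77.0,
                                 helix_mode="periodic_random_walk",
                                 end_to_end_um=2.0)
        loops = exponential_loop_array(GENOME, 100e3, seed=5)
        conf = build_periodic_random_walk(loops, params, GENOME, seed=5)
        anchors = conf.select("loop_anchor")
        # the imposed quantity is the axial (stretch-direction) extension;
        # free transverse wander adds to the full 3D distance
        assert anchors[-1, 2] - anchors[0, 2] == pytest.approx(2000.0, rel=0.1)
        e2e = np.linalg.norm(anchors[-1] - anchors[0])
        assert e2e >= 2000.0 * 0.9

    def test_backbone_msd_linear_over_2_to_8_mb(self):
        params = ChromatidParams(loop_bp=100e3, gap_nm=20.0, turn_mb=None,
                                 volume_density_mb_um3=77.0,
                                 helix_mode="periodic_random_walk",
                                 end_to_end_um=4.0)
        msds = {s: [] for s in (2e6, 4e6, 8e6)}
        for seed in range(6):
            loops = exponential_loop_array(100e6, 100e3, seed=seed)
            conf = build_periodic_random_walk(loops, params, 100e6, seed=seed)
            anchors = conf.select("loop_anchor")
            g = conf.genomic_bp[conf.annotations["loop_anchor"].astype(bool)]
            for s in msds:
                k = int(round(s / np.median(np.diff(g))))
                d = anchors[k:] - anchors[:-k]
                msds[s].append(np.mean(np.sum(d ** 2, axis=1)))
        m2, m4, m8 = (np.mean(msds[s]) for s in (2e6, 4e6, 8e6))
        # diffusive: MSD doubles when s doubles (within tolerance)
        assert m4 / m2 == pytest.approx(2.0, rel=0.4)
        assert m8 / m4 == pytest.approx(2.0, rel=0.4)

    def test_excessive_end_to_end_rejected(self):
        params = ChromatidParams(helix_mode="periodic_random_walk",
                                 end_to_end_um=100.0, gap_nm=20.0)
        loops = exponential_loop_array(10e6, 100e3, seed=0)
        with pytest.raises(ValueError, match="end-to-end"):
            build_periodic_random_walk(loops, params, 10e6, seed=0)


@pytest.fixture(scope="module")
def setup():
    params = ChromatidParams(turn_mb=None)
    links = make_cohesive_links(GENOME / 1e6, links_per_mb=1.0, seed=4)
    return params, links


class TestSisterPair:
    def _build(self, mode, params, links, seed):
        l1 = exponential_loop_array(GENOME, 400e3, seed=seed + 100)
        l2 = exponential_loop_array(GENOME, 400e3, seed=seed + 200)
        return build_sister_pair(l1, l2, links, mode, params, GENOME, seed)

    def test_bypass_separates_axes_stall_merges_them(self, setup):
        params, links = setup
        seps = {"bypass": [], "stall": []}
        for mode in seps:
            for seed in range(3):
                pair = self._build(mode, params, links, seed)
                anc = pair.annotations["loop_anchor"].astype(bool)
                x0 = pair.xyz[anc & (pair.chromatid_id == 0), 0].mean()
                x1 = pair.xyz[anc & (pair.chromatid_id == 1), 0].mean()
                seps[mode].append(abs(x1 - x0))
        assert min(seps["bypass"]) > max(seps["stall"])

    def test_bypass_cohesin_sits_between_condensin_axes(self, setup):
        params, links = setup
        pair = self._build("bypass", params, links, 1)
        anc = pair.annotations["loop_anchor"].astype(bool)
        coh = pair.annotations["cohesive_cohesin"].astype(bool)
        x0 = pair.xyz[anc & (pair.chromatid_id == 0), 0].mean()
        x1 = pair.xyz[anc & (pair.chromatid_id == 1), 0].mean()
        mid = (x0 + x1) / 2
        coh_x = pair.xyz[coh, 0].mean()
        assert abs(coh_x - mid) < 0.25 * abs(x1 - x0)

    def test_zero_links_gives_independent_chromatids(self, setup):
        params, _ = setup
        pair = self._build("bypass", params, CohesiveLinkSet(np.array([])), 2)
        assert not pair.annotations["cohesive_cohesin"].any()
        assert len(np.unique(pair.chromatid_id)) == 2

    def test_links_outside_range_rejected(self, setup):
        params, _ = setup
        bad = CohesiveLinkSet(np.array([GENOME * 2]))
        with pytest.raises(ValueError, match="outside"):
            self._build("bypass", params, bad, 0)

    def test_stall_mode_truncates_loops_at_links(self, setup):
        params, links = setup
        pair = self._build("stall", params, links, 3)
        loops = pair.meta["params"]  # params round-trip only
        # link positions coincide with loop anchors in stall mode
        coh = pair.annotations["cohesive_cohesin"].astype(bool)
        anc = pair.annotations["loop_anchor"].astype(bool)
        assert (coh & anc).sum() / coh.sum() > 0.9


class TestCrossSection:
    def test_uniform_cylinder_matches_projected_density_oracle(self):
        # beads uniform in a cylinder: the transverse profile is the
        # analytic half-chord projection 2*sqrt(R^2-x^2)/(pi R^2)
        rng = np.random.default_rng(0)
        R, n = 500.0, 60_000
        r = R * np.sqrt(rng.random(n))
        phi = rng.uniform(0, 2 * np.pi, n)
        xyz = np.column_stack([r * np.cos(phi), r * np.sin(phi),
                               rng.uniform(0, 4000, n)])
        conf = Conformation(
            genomic_bp=np.arange(n, dtype=float), xyz=xyz, bead_bp=1000,
            annotations={"loop_anchor": np.ones(n, dtype=bool)})
        prof = cross_section_profile(conf, markers=("dna",),
                                     axis_direction=np.array([0, 0, 1.0]))
        x = prof["dna"]["bins_nm"]
        dens = prof["dna"]["density"]
        inside = np.abs(x) < 0.95 * R
        expected = 2 * np.sqrt(R ** 2 - x[inside] ** 2) / (np.pi * R ** 2)
        resid = dens[inside] - expected
        assert np.sqrt(np.mean(resid ** 2)) < 0.10 * expected.max()

    def test_condensin_profile_narrower_than_dna(self, helix_conf):
        prof = cross_section_profile(helix_conf,
                                     markers=("dna", "loop_anchor"),
                                     axis_direction=np.array([0, 0, 1.0]))
        assert prof["loop_anchor"]["fwhm_nm"] < prof["dna"]["fwhm_nm"]

    def test_few_beads_warns(self):
        rng = np.random.default_rng(1)
        n = 60
        conf = Conformation(
            genomic_bp=np.arange(n, dtype=float),
            xyz=rng.standard_normal((n, 3)) * 100, bead_bp=1000,
            annotations={"loop_anchor": np.ones(n, dtype=bool)})
        with pytest.warns(UserWarning, match="fewer than 100"):
            cross_section_profile(conf, markers=("dna",))


class TestNestedBuilder:
    def test_nested_conformation_orders_and_counts(self):
        p_out = ChromatidParams()
        p_in = ChromatidParams(loop_bp=100e3, gap_nm=20.0,
                               volume_density_mb_um3=77.0, turn_mb=None)
        outer = exponential_loop_array(20e6, 400e3, seed=1)
        rng = np.random.default_rng(2)
        inner = []
        for a, b in outer:
            cuts = np.arange(a, b, 100e3)
            inner += [(c, min(c + 100e3, b)) for c in cuts]
        conf = build_nested_bottlebrush(outer, np.array(inner), p_out, p_in,
                                        20e6, seed=3)
        assert np.all(np.diff(conf.genomic_bp) > 0)
        assert conf.annotations["loop_anchor"].sum() >= len(inner)
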