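"""Fibril layout, zone and band-detection tests."""

import pytest

from collagen_gpo import fibril
from collagen_gpo.conservation import ConservationProfile
from collagen_gpo.errors import ParameterError, RangeError
from collagen_gpo.fibril import (
    BindingSiteAnnotation,
    build_layout,
    chain_symmetry,
    detect_bands,
    detect_chain_bands,
    gpo_axial_profile,
    site_flanks,
    zone_of,
)
from conftest import band_interval_oracle


def profile_from_sites(sites, n_triplets, chain_id="alpha1"):
    """Profile with the given 1-based triplet indices conserved."""
    return ConservationProfile(
        chain_id=chain_id,
        triplet_index=tuple(range(1, n_triplets + 1)),
        helix_pos=tuple(3 * s + 1 for s in range(n_triplets)),
        p_gpo=tuple(1.0 if s + 1 in sites else 0.0 for s in range(n_triplets)),
    )


class TestLayout:
    def test_axial_arithmetic(self):
        layout = build_layout(1014, 1014)
        assert layout.axial(3, 0, 1) == 468  # (3-1) * 234
        assert layout.axial(1, 1, 1) == layout.axial(1, 0, 1) + 1  # one-residue stagger
        assert layout.axial(1, 0, 10) == 9

    def test_short_d5_period(self):
        # 1014-residue helix: molecule 5 starts at 936, D5 spans only 78
        layout = build_layout(1014, 1014)
        start, _ = layout.molecule_span(5)
        assert start == 936
        assert 1014 - 4 * 234 == 78 < 234

    def test_parameter_errors(self):
        with pytest.raises(ParameterError):
            build_layout(1014, 1014, d_period=0)
        with pytest.raises(ParameterError):
            build_layout(1014, 1014, n_molecules=0)
        with pytest.raises(ParameterError):
            build_layout(1014, 900)  # chains differ by more than a triplet


class TestZones:
    def test_overlap_iff_all_molecules_cover(self):
        layout = build_layout(1014, 1014)
        # positions covered by all 5 molecules start where molecule 5 starts
        assert layout.coverage(936) == 5
        assert zone_of(936, layout) == "overlap"
        assert layout.coverage(930) == 4
        assert zone_of(930, layout) == "hole"

    def test_out_of_span_raises(self):
        layout = build_layout(1014, 1014)
        with pytest.raises(RangeError):
            zone_of(-1, layout)
        with pytest.raises(RangeError):
            zone_of(10**6, layout)

    def test_full_profile_matches_brute_force_coverage(self):
        layout = build_layout(60, 60, d_period=12, n_molecules=3)
        start, end = layout.span
        n_overlap = n_hole = 0
        for pos in range(start, end):
            covered = sum(
                1
                for m in range(1, 4)
                if layout.molecule_span(m)[0] <= pos < layout.molecule_span(m)[1]
            )
            expected = "overlap" if covered == 3 else "hole"
            assert zone_of(pos, layout) == expected
            n_overlap += expected == "overlap"
            n_hole += expected == "hole"
        assert n_overlap + n_hole == end - start  # zones partition the span

    def test_exact_multiple_length_is_all_overlap_in_central_period(self):
        # helix_length = 2 * d_period: central D period fully tiled
        layout = build_layout(48, 48, d_period=24, n_molecules=5)
        central = range(4 * 24, 48 + 0 * 24)  # covered by molecule 5 onward
        for pos in central:
            assert zone_of(pos, layout) == "overlap"


class TestAxialProfile:
    def test_single_site_counts(self):
        # one conserved site carried by the two alpha1 chains of each molecule
        profile = profile_from_sites({2}, 10)
        layout = build_layout(30, 30, d_period=10, n_molecules=2)
        axial = gpo_axial_profile(layout, {"alpha1": profile})
        total = sum(b.gpo_count for b in axial.bins)
        assert total == 3 * 2 * 2  # 3 residues x 2 molecules x 2 chains

    def test_empty_profile_gives_zeros(self):
        profile = profile_from_sites(set(), 10)
        layout = build_layout(30, 30, d_period=10)
        axial = gpo_axial_profile(layout, {"alpha1": profile, "alpha2": profile})
        assert all(b.gpo_count == 0 for b in axial.bins)

    def test_all_gpo_chain_is_uniform_inside_molecule_1(self):
        profile = profile_from_sites(set(range(1, 11)), 10)
        layout = build_layout(30, 30, d_period=30, n_molecules=1, stagger=0)
        axial = gpo_axial_profile(layout, {"alpha1": profile}, bin_width=3)
        inside = [b.gpo_count for b in axial.bins]
        assert len(set(inside)) == 1  # every triplet bin identical


class TestBands:
    def layout_and_profile(self, sites, n_triplets=40):
        profile = profile_from_sites(sites, n_triplets)
        layout = build_layout(
            3 * n_triplets, 3 * n_triplets, d_period=3 * n_triplets, n_molecules=1, stagger=0
        )
        axial = gpo_axial_profile(layout, {"alpha1": profile})
        return axial

    def test_one_dense_run_one_band(self):
        axial = self.layout_and_profile({5, 6, 7})
        bands = detect_bands(axial)
        assert len(bands) == 1
        assert bands[0].size == len(axial.placements)

    def test_two_runs_separated_beyond_window_give_two_bands(self):
        axial = self.layout_and_profile({5, 6, 20, 21})
        bands = detect_bands(axial, window_w=9, min_count=4)
        assert len(bands) == 2

    def test_uniform_zero_profile_has_no_bands(self):
        axial = self.layout_and_profile(set())
        assert detect_bands(axial) == []

    @pytest.mark.parametrize("sites", [{3, 4}, {1, 2, 3, 10, 11}, {6, 9, 12}, {2, 12, 22, 23}])
    def test_band_intervals_match_brute_force_oracle(self, sites):
        axial = self.layout_and_profile(sites)
        bands = detect_bands(axial, window_w=9, min_count=4)
        oracle = band_interval_oracle(axial.counts_by_position(), 9, 4)
        assert [(b.start, b.end) for b in bands] == oracle

    def test_translation_invariance(self):
        sites = {4, 5, 15, 16}
        a1 = self.layout_and_profile(sites)
        a2 = self.layout_and_profile({s + 2 for s in sites})  # +2 triplets = +6 residues
        b1 = detect_bands(a1)
        b2 = detect_bands(a2)
        assert [(b.start + 6, b.end + 6) for b in b1] == [(b.start, b.end) for b in b2]

    def test_each_placement_in_at_most_one_band(self):
        axial = self.layout_and_profile({1, 2, 3, 4, 12, 13, 30, 31})
        bands = detect_bands(axial)
        seen = []
        for band in bands:
            seen.extend(id(p) for p in band.members)
        assert len(seen) == len(set(seen))


class TestSiteFlanks:
    def make_bands(self):
        profile = profile_from_sites({43, 44}, 60)  # Gly positions 127, 130
        return detect_chain_bands(profile)

    def test_n_terminal_side_and_distance(self):
        bands = self.make_bands()
        centroid = bands[0].centroid
        site = BindingSiteAnnotation("integrin", "alpha1", 100, 111)
        out = site_flanks(site, bands)
        assert out.side == "N-terminal"
        assert out.distance == pytest.approx(centroid - 110)

    def test_overlapping_site(self):
        bands = self.make_bands()
        site = BindingSiteAnnotation("ddr", "alpha1", 125, 132)
        out = site_flanks(site, bands)
        assert out.side == "overlapping"
        assert out.distance == 0.0

    def test_nearest_band_matches_exhaustive_oracle(self):
        profile = profile_from_sites({5, 6, 43, 44}, 60)
        bands = detect_chain_bands(profile)
        assert len(bands) == 2
        site = BindingSiteAnnotation("vwf", "alpha1", 60, 70)
        out = site_flanks(site, bands)
        dists = []
        for band in bands:
            c = band.centroid
            d = 0.0 if site.start < band.end and band.start < site.end else min(
                abs(site.start - c), abs(site.end - 1 - c)
            )
            dists.append(d)
        assert out.distance == min(dists)

    def test_no_bands_flagged(self):
        site = BindingSiteAnnotation("integrin", "alpha1", 10, 20)
        out = site_flanks(site, [])
        assert out.side == "no-band"
        assert out.distance is None


class TestChainSymmetry:
    def test_classes(self):
        a1 = profile_from_sites({1, 2}, 5, "alpha1")
        a2 = profile_from_sites({1, 3}, 5, "alpha2")
        assert chain_symmetry(1, a1, a2) == "all-chain"
        assert chain_symmetry(2, a1, a2) == "alpha1-only"
        assert chain_symmetry(3, a1, a2) == "alpha2-only"
        assert chain_symmetry(4, a1, a2) == "none"

    def test_out_of_range_locus(self):
        a1 = profile_from_sites({1}, 5, "alpha1")
        a2 = profile_from_sites({1}, 5, "alpha2")
        with pytest.raises(RangeError):
            chain_symmetry(99, a1, a2)

    def test_zone_tabulation_matches_enumeration(self):
        a1 = profile_from_sites({1, 5, 10, 20, 30}, 40, "alpha1")
        a2 = profile_from_sites({1, 10, 25}, 40, "alpha2")
        layout = build_layout(120, 120, d_period=50, n_molecules=5)
        table = fibril.symmetry_by_zone(layout, a1, a2)
        mid = 3
        expected = {}
        for t in range(1, 41):
            cls = chain_symmetry(t, a1, a2)
            if cls == "none":
                continue
            axial = layout.axial(mid, 0, 3 * (t - 1) + 1)
            z = zone_of(axial, layout)
            expected[(z, cls)] = expected.get((z, cls), 0) + 1
        got = {(r.zone, r.symmetry): r.n_loci for r in table.itertuples()}
        assert got == expected


def test_ascii_map_shape_and_marks():
    profile = profile_from_sites({1, 2}, 10)
    layout = build_layout(30, 30, d_period=15, n_molecules=3)
    axial = gpo_axial_profile(layout, {"alpha1": profile})
    rows = fibril.ascii_map(axial)
    assert len(rows) == 3
    assert len(set(len(r) for r in rows)) == 1
    assert "O" in rows[0] and "O" in rows[2]
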