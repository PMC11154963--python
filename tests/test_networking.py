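"""Shift-aware spectral similarity and molecular network construction."""

import networkx as nx
import numpy as np
import pytest

from wwscreen.io_formats import Spectrum
from wwscreen.networking import (
    build_network,
    clusters,
    modified_cosine,
    parent_link_fraction,
)

from conftest import tiny_ms2


def rand_pair(rng, max_peaks=6):
    """Random spectrum pair with a mix of direct and shifted coincidences."""
    def spec(name, precursor):
        n = int(rng.integers(1, max_peaks + 1))
        mzs = sorted({round(float(rng.uniform(50, 200)), 2) for _ in range(n)})
        peaks = [(m, float(rng.uniform(0.1, 1.0))) for m in mzs]
        return Spectrum(identifier=name, precursor_mz=precursor, peaks=peaks)

    pa = round(float(rng.uniform(200, 400)), 2)
    shift = round(float(rng.uniform(-30, 30)), 2)
    a = spec("a", pa)
    b = spec("b", pa - shift)
    # overlay some of a's peaks into b, directly or shifted
    extra = []
    for mz, inten in a.peaks:
        r = rng.random()
        if r < 0.3:
            extra.append((mz, float(rng.uniform(0.1, 1.0))))
        elif r < 0.6 and 50 < mz - shift < 200:
            extra.append((round(mz - shift, 2), float(rng.uniform(0.1, 1.0))))
    merged = list({p[0]: p for p in b.peaks + extra}.values())[: max_peaks]
    b = Spectrum(identifier="b", precursor_mz=b.precursor_mz, peaks=merged)
    return a, b


class TestModifiedCosine:
    def test_self_similarity(self):
        sp = tiny_ms2("a", 242.1, peaks=[(100.0, 1.0), (150.0, 2.0), (180.0, 0.5)])
        sim, matched = modified_cosine(sp, sp)
        assert sim == pytest.approx(1.0, abs=1e-9)
        assert matched == 3

    def test_disjoint_spectra(self):
        a = tiny_ms2("a", 300.0, peaks=[(100.0, 1.0)])
        b = tiny_ms2("b", 300.0, peaks=[(200.0, 1.0)])
        assert modified_cosine(a, b) == (0.0, 0)

    def test_direct_plus_shifted_match(self):
        # one direct pair and one pair shifted by the precursor difference
        a = Spectrum("a", precursor_mz=241.110,
                     peaks=[(100.0, 1.0), (150.0, 1.0)])
        b = Spectrum("b", precursor_mz=257.105,
                     peaks=[(100.0, 1.0), (165.995, 1.0)])
        sim, matched = modified_cosine(a, b)
        assert sim == pytest.approx(1.0, abs=1e-9)
        assert matched == 2

    def test_empty_peaks_rejected(self):
        a = tiny_ms2("a", 300.0)
        b = Spectrum("b", precursor_mz=300.0, peaks=[])
        with pytest.raises(ValueError):
            modified_cosine(a, b)

    def test_symmetry(self):
        rng = np.random.default_rng(21)
        for _ in range(50):
            a, b = rand_pair(rng)
            assert modified_cosine(a, b) == modified_cosine(b, a)

    def test_similarity_bounded(self):
        rng = np.random.default_rng(22)
        for _ in range(200):
            a, b = rand_pair(rng, max_peaks=10)
            sim, _ = modified_cosine(a, b)
            assert 0.0 <= sim <= 1.0 + 1e-9

    def test_exact_equals_brute_force(self):
        """The default assignment reproduces full-enumeration optima."""
        rng = np.random.default_rng(23)
        for _ in range(300):
            a, b = rand_pair(rng, max_peaks=6)
            sim_x, m_x = modified_cosine(a, b, method="exact")
            sim_b, m_b = modified_cosine(a, b, method="brute")
            assert sim_x == pytest.approx(sim_b, abs=1e-12)
            assert m_x == m_b

    def test_greedy_never_exceeds_exact(self):
        rng = np.random.default_rng(24)
        for _ in range(100):
            a, b = rand_pair(rng)
            sim_g, _ = modified_cosine(a, b, method="greedy")
            sim_x, _ = modified_cosine(a, b, method="exact")
            assert sim_g <= sim_x + 1e-12

    def test_agrees_with_matchms_on_unambiguous_pair(self):
        """Cross-check against the community implementation on a pair with
        a unique assignment."""
        matchms = pytest.importorskip("matchms")
        from matchms.similarity import ModifiedCosine

        a = Spectrum("a", precursor_mz=300.0,
                     peaks=[(100.0, 5.0), (150.0, 2.0), (210.0, 7.0)])
        b = Spectrum("b", precursor_mz=316.0,
                     peaks=[(100.0, 4.0), (166.0, 2.5), (226.0, 6.0)])
        sim, matched = modified_cosine(a, b, intensity_power=1.0)
        sa = matchms.Spectrum(
            mz=np.array(a.mz), intensities=np.array(a.intensity),
            metadata={"precursor_mz": a.precursor_mz},
        )
        sb = matchms.Spectrum(
            mz=np.array(b.mz), intensities=np.array(b.intensity),
            metadata={"precursor_mz": b.precursor_mz},
        )
        ref = ModifiedCosine(tolerance=0.01).pair(sa, sb)
        assert sim == pytest.approx(float(ref["score"]), abs=1e-6)
        assert matched == int(ref["matches"])


class TestBuildNetwork:
    def test_identical_spectra_form_single_cluster(self):
        peaks = [(100.0, 1.0), (120.0, 2.0), (140.0, 1.5), (160.0, 1.0)]
        spectra = [tiny_ms2(f"s{i}", 300.0, peaks=list(peaks)) for i in range(3)]
        graph = build_network(spectra)
        assert len(clusters(graph)[0]) == 3

    def test_thresholds_above_everything_gives_singletons(self):
        peaks = [(100.0, 1.0), (120.0, 2.0), (140.0, 1.5), (160.0, 1.0)]
        spectra = [tiny_ms2(f"s{i}", 300.0, peaks=list(peaks)) for i in range(4)]
        graph = build_network(spectra, min_similarity=1.1)
        assert graph.number_of_edges() == 0
        assert len(clusters(graph)) == 4

    def test_min_two_spectra_required(self):
        with pytest.raises(ValueError):
            build_network([tiny_ms2("only", 300.0)])

    def test_planted_family_clusters(self, demo_dataset):
        """A planted parent with two metabolites sharing direct and shifted
        fragments clusters together at the default thresholds."""
        gt = demo_dataset.ground_truth
        src = gt.ms2_sources
        by_name = {src[sp.identifier]: sp for sp in demo_dataset.spectra}
        comp = gt.compounds
        families = []
        for parent in comp[comp.kind == "parent"].itertuples():
            mets = comp[
                (comp.parent_name == parent.name) & comp.ms2_emitted
            ]["name"].tolist()
            if parent.ms2_emitted and len(mets) >= 2:
                families.append([parent.name] + mets[:2])
        assert families, "generator should emit at least one full family"
        name_set = families[0]
        graph = build_network([by_name[n] for n in name_set])
        assert len(clusters(graph)[0]) == 3


class TestParentLinkFraction:
    def _fixture_graph(self):
        g = nx.Graph()
        g.add_nodes_from(["P", "m1", "m2", "m3", "m4"])
        g.add_edge("P", "m1")  # direct parent link
        g.add_edge("m1", "m2")  # sibling link
        g.add_edge("P", "m3")
        return g

    def test_three_of_four_linked(self):
        g = self._fixture_graph()
        parent_map = {"P": "P", "m1": "P", "m2": "P", "m3": "P", "m4": "P"}
        frac = parent_link_fraction(g, ["m1", "m2", "m3", "m4"], parent_map)
        assert frac == 0.75

    def test_all_linked(self):
        g = self._fixture_graph()
        g.add_edge("P", "m4")
        parent_map = {n: "P" for n in g.nodes}
        assert parent_link_fraction(g, ["m1", "m2", "m3", "m4"], parent_map) == 1.0

    def test_edgeless_graph(self):
        g = nx.Graph()
        g.add_nodes_from(["P", "m1"])
        assert parent_link_fraction(g, ["m1"], {"P": "P", "m1": "P"}) == 0.0

    def test_empty_confirmed_set_undefined(self):
        assert parent_link_fraction(nx.Graph(), [], {}) is None
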