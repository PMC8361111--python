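import itertools

import numpy as np
import pytest
from hypothesis import given

from flavoscreen import (
    FragmentPeak,
    NetworkConfig,
    Spectrum,
    build_network,
    export_graph,
    import_graph,
    spectral_similarity,
)

from conftest import spectra


def spectrum(frags, sid="s", precursor=500.0, charge=1):
    return Spectrum(
        id=sid,
        precursor_mz=precursor,
        charge=charge,
        fragments=tuple(FragmentPeak(mz, i) for mz, i in frags),
    )


def brute_force_cosine(a, b, cfg):
    """Exhaustive optimal one-to-one assignment cosine (oracle for <= 5 peaks)."""
    wa = [(f.mz, f.intensity**cfg.intensity_weighting) for f in a.fragments]
    wb = [(f.mz, f.intensity**cfg.intensity_weighting) for f in b.fragments]
    if not wa or not wb:
        return 0.0
    na = np.sqrt(sum(w * w for _, w in wa))
    nb = np.sqrt(sum(w * w for _, w in wb))
    best = 0.0
    idx_b = range(len(wb))
    for k in range(0, min(len(wa), len(wb)) + 1):
        for subset_a in itertools.combinations(range(len(wa)), k):
            for perm_b in itertools.permutations(idx_b, k):
                score = 0.0
                ok = True
                for i, j in zip(subset_a, perm_b):
                    if abs(wa[i][0] - wb[j][0]) > cfg.bin_tolerance:
                        ok = False
                        break
                    score += wa[i][1] * wb[j][1]
                if ok:
                    best = max(best, score)
    return best / (na * nb)


def random_spectrum(rng, n_peaks, mz_grid):
    """Peaks on a coarse m/z grid (spacing >> tolerance) so matching is unambiguous."""
    mzs = rng.choice(mz_grid, size=n_peaks, replace=False)
    frags = [(float(m) + rng.uniform(-0.004, 0.004), float(rng.uniform(1e3, 1e6)))
             for m in mzs]
    return spectrum(frags, sid=f"r{rng.integers(1e9)}")


class TestSpectralSimilarity:
    def test_identical_spectra_score_one(self):
        s = spectrum([(287.05, 5000), (449.11, 4000), (611.16, 3000)])
        assert spectral_similarity(s, s) == pytest.approx(1.0)

    def test_disjoint_spectra_score_zero(self):
        a = spectrum([(100.0, 5000)])
        b = spectrum([(200.0, 5000)])
        assert spectral_similarity(a, b) == 0.0

    def test_empty_spectrum_scores_zero(self):
        a = spectrum([(100.0, 5000)])
        assert spectral_similarity(a, spectrum([])) == 0.0

    @given(spectra(max_fragments=6), spectra(max_fragments=6))
    def test_symmetric_and_bounded(self, a, b):
        cfg = NetworkConfig()
        sab = spectral_similarity(a, b, cfg)
        assert 0.0 <= sab <= 1.0
        assert sab == pytest.approx(spectral_similarity(b, a, cfg), abs=1e-12)

    def test_matches_brute_force_assignment_oracle(self):
        cfg = NetworkConfig()
        rng = np.random.default_rng(11)
        grid = np.arange(100.0, 900.0, 1.0)
        for _ in range(40):
            a = random_spectrum(rng, int(rng.integers(1, 6)), grid)
            b = random_spectrum(rng, int(rng.integers(1, 6)), grid)
            assert spectral_similarity(a, b, cfg) == pytest.approx(
                brute_force_cosine(a, b, cfg), abs=1e-9
            )

    def test_matches_independent_cosine_implementation(self):
        """Cross-check against matchms CosineGreedy at unit intensity power."""
        matchms = pytest.importorskip("matchms")
        from matchms.similarity import CosineGreedy

        cfg = NetworkConfig(intensity_weighting=1.0)
        rng = np.random.default_rng(12)
        grid = np.arange(100.0, 900.0, 1.0)
        kernel = CosineGreedy(tolerance=cfg.bin_tolerance)
        for _ in range(20):
            a = random_spectrum(rng, int(rng.integers(2, 8)), grid)
            b = random_spectrum(rng, int(rng.integers(2, 8)), grid)
            ms = [
                matchms.Spectrum(
                    mz=s.mz_array, intensities=s.intensity_array,
                    metadata={"precursor_mz": s.precursor_mz},
                )
                for s in (a, b)
            ]
            expected = float(kernel.pair(*ms)["score"])
            assert spectral_similarity(a, b, cfg) == pytest.approx(expected, abs=1e-6)

    def test_modified_cosine_links_shifted_spectra(self):
        a = spectrum([(280.00, 5000), (350.00, 4000)], precursor=773.21)
        b = spectrum([(280.00 + 162.05, 5000), (350.00 + 162.05, 4000)],
                     precursor=773.21 + 162.05)
        plain = spectral_similarity(a, b)
        shifted = spectral_similarity(a, b, NetworkConfig(modified_cosine=True))
        assert plain == 0.0 and shifted == pytest.approx(1.0)


class TestBuildNetwork:
    def test_two_identical_spectra_one_edge(self):
        a = spectrum([(287.05, 5000), (449.11, 4000)], sid="a")
        b = spectrum([(287.05, 5000), (449.11, 4000)], sid="b")
        net = build_network([a, b])
        assert net.n_nodes == 2 and net.n_edges == 1 and net.isolated == []

    def test_disjoint_spectra_stay_isolated(self):
        a = spectrum([(100.0, 5000)], sid="a")
        b = spectrum([(200.0, 5000)], sid="b")
        net = build_network([a, b])
        assert net.n_nodes == 0 and sorted(net.isolated) == ["a", "b"]

    def _planted_clusters(self):
        rng = np.random.default_rng(13)
        spectra_list = []
        for c, base in enumerate((100.0, 400.0, 700.0)):
            motif = [(base + 10 * i, 5000.0) for i in range(5)]
            for k in range(4):
                jittered = [(mz, inten * rng.uniform(0.8, 1.2)) for mz, inten in motif]
                spectra_list.append(spectrum(jittered, sid=f"c{c}_{k}"))
        return spectra_list

    def test_planted_partition_recovered(self):
        import networkx as nx

        net = build_network(self._planted_clusters(), NetworkConfig(similarity_cutoff=0.7))
        comps = list(nx.connected_components(net.graph))
        assert len(comps) == 3
        for comp in comps:
            assert len({i.split("_")[0] for i in comp}) == 1

    def test_order_invariance(self):
        spectra_list = self._planted_clusters()
        net1 = build_network(spectra_list)
        net2 = build_network(list(reversed(spectra_list)))
        edges = lambda n: {
            (u, v, round(d["similarity"], 9)) for u, v, d in n.graph.edges(data=True)
        }
        assert edges(net1) == edges(net2)

    def test_raising_cutoff_monotone(self):
        spectra_list = self._planted_clusters()
        lo = build_network(spectra_list, NetworkConfig(similarity_cutoff=0.5))
        hi = build_network(spectra_list, NetworkConfig(similarity_cutoff=0.9))
        assert hi.n_nodes <= lo.n_nodes and hi.n_edges <= lo.n_edges

    def test_node_attributes_attached(self):
        a = spectrum([(287.05, 5000)], sid="a")
        b = spectrum([(287.05, 5000)], sid="b", charge=2)
        net = build_network(
            [a, b], NetworkConfig(), node_attrs={"a": {"prediction": "in-house"}}
        )
        assert net.graph.nodes["a"]["prediction"] == "in-house"
        assert net.graph.nodes["b"]["charge"] == 2


class TestGraphExport:
    def test_roundtrip(self, tmp_path):
        a = spectrum([(287.05, 5000), (449.11, 4000)], sid="a")
        b = spectrum([(287.05, 5000), (449.11, 4000)], sid="b")
        net = build_network([a, b])
        np_, ep = tmp_path / "nodes.tsv", tmp_path / "edges.tsv"
        export_graph(net, np_, ep)
        back = import_graph(np_, ep)
        assert set(back.graph.nodes) == set(net.graph.nodes)
        assert {
            frozenset(e) for e in back.graph.edges
        } == {frozenset(e) for e in net.graph.edges}

    def test_empty_graph_header_only(self, tmp_path):
        net = build_network([])
        np_, ep = tmp_path / "nodes.tsv", tmp_path / "edges.tsv"
        export_graph(net, np_, ep)
        assert np_.read_text().strip() == "id"
        assert ep.read_text().strip() == "source\tedge\tsimilarity".replace("edge", "target")

    def test_single_edge_file_contents(self, tmp_path):
        a = spectrum([(287.05, 5000)], sid="a")
        b = spectrum([(287.05, 5000)], sid="b")
        net = build_network([a, b])
        np_, ep = tmp_path / "n.tsv", tmp_path / "e.tsv"
        export_graph(net, np_, ep)
        lines = ep.read_text().strip().splitlines()
        assert len(lines) == 2 and lines[1].startswith("a\tb\t")
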