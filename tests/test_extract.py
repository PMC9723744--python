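import math

import numpy as np
import pytest

from myconet.extract import (
    ExtractionParams,
    estimate_widths,
    extract_network,
    preprocess,
    prune_and_clean,
    skeleton_to_graph,
    skeletonize_mask,
)
from myconet.synthetic import SynthParams, grow_network, render_image

from conftest import make_net


def ribbon_image(length=60, width=5, pad=15, horizontal=True):
    """Uniform dark frame with one bright ribbon."""
    img = np.zeros((length + 2 * pad, length + 2 * pad), dtype=np.uint8)
    mid = pad + length // 2
    if horizontal:
        img[mid - width // 2: mid + (width + 1) // 2, pad:pad + length] = 220
    else:
        img[pad:pad + length, mid - width // 2: mid + (width + 1) // 2] = 220
    return img


class TestPreprocess:
    def test_rendered_edge_recovered(self):
        """Mask covers >= 95% of the ground-truth foreground of a clean render."""
        net = make_net({0: (10.0, 20.0), 1: (90.0, 25.0)}, [(0, 1, 80.2, 6.0)])
        r = render_image(net, pixel_size=1.0, blur_sigma=0.0, noise_sd=0.0)
        truth = r.image > 127
        mask = preprocess(r.image, ExtractionParams(pixel_size=1.0))
        assert (mask & truth).sum() >= 0.95 * truth.sum()

    def test_invert_flag_symmetry(self):
        img = ribbon_image()
        mask = preprocess(img, ExtractionParams(pixel_size=1.0))
        mask_inv = preprocess(255 - img, ExtractionParams(pixel_size=1.0, invert=True))
        assert np.array_equal(mask, mask_inv)

    def test_pure_noise_mostly_rejected(self):
        rng = np.random.default_rng(0)
        img = rng.normal(0.5, 0.1, (300, 300))
        mask = preprocess(img, ExtractionParams(pixel_size=1.0))
        assert mask.mean() < 0.05

    def test_constant_image_rejected(self):
        with pytest.raises(ValueError):
            preprocess(np.full((50, 50), 7.0), ExtractionParams(pixel_size=1.0))


class TestSkeletonize:
    def test_ribbon_thins_to_line(self):
        """5 px ribbon -> a single 1 px line; thinning erodes each end by
        about half the ribbon width."""
        mask = ribbon_image() > 127
        skel = skeletonize_mask(mask)
        rows, cols = np.nonzero(skel)
        assert len(np.unique(rows)) <= 2          # essentially one horizontal line
        assert abs((cols.max() - cols.min() + 1) - 60) <= 6

    def test_skeleton_subset_of_mask(self):
        net = grow_network(SynthParams(seed=4, n_steps=15))
        r = render_image(net, pixel_size=1.0, blur_sigma=0.0)
        mask = preprocess(r.image, ExtractionParams(pixel_size=1.0))
        skel = skeletonize_mask(mask)
        assert not (skel & ~mask).any()

    def test_plus_sign_single_junction_cluster(self):
        img = np.maximum(ribbon_image(horizontal=True), ribbon_image(horizontal=False))
        skel = skeletonize_mask(img > 127)
        from scipy import ndimage as ndi

        nbr = ndi.convolve(skel.astype(np.uint8), np.ones((3, 3), np.uint8),
                           mode="constant") - 1
        nbr[~skel] = 0
        _, n_clusters = ndi.label(skel & (nbr >= 3), structure=np.ones((3, 3)))
        assert n_clusters == 1

    def test_disk_degenerates(self):
        rr, cc = np.mgrid[0:60, 0:60]
        mask = (rr - 30) ** 2 + (cc - 30) ** 2 < 15 ** 2
        assert skeletonize_mask(mask).sum() <= 10

    def test_empty_mask(self):
        assert skeletonize_mask(np.zeros((10, 10), bool)).sum() == 0


class TestSkeletonToGraph:
    def test_straight_line(self):
        skel = np.zeros((20, 60), bool)
        skel[10, 5:55] = True
        net = skeleton_to_graph(skel, ExtractionParams(pixel_size=2.0))
        assert net.n_nodes == 2 and net.n_edges == 1
        e = next(iter(net.edges.values()))
        assert e.length == pytest.approx(49 * 2.0, abs=2 * 2.0)

    def test_plus_sign(self):
        skel = np.zeros((41, 41), bool)
        skel[20, 5:36] = True
        skel[5:36, 20] = True
        net = skeleton_to_graph(skel, ExtractionParams(pixel_size=1.0))
        kinds = sorted(n.kind for n in net.nodes.values())
        assert kinds.count("tip") == 4
        assert kinds.count("junction") == 1
        assert net.n_edges == 4

    def test_y_shape(self):
        skel = np.zeros((40, 40), bool)
        skel[5:21, 20] = True                       # stem
        for i in range(12):                         # two diagonal arms
            skel[20 + i, 20 - i] = True
            skel[20 + i, 20 + i] = True
        net = skeleton_to_graph(skel, ExtractionParams(pixel_size=1.0))
        junctions = [n for n in net.nodes.values() if n.kind == "junction"]
        assert len(junctions) == 1
        assert net.measured_degree(junctions[0].id) == 3
        assert sum(1 for n in net.nodes.values() if n.kind == "tip") == 3


class TestWidths:
    def test_five_pixel_ribbon(self):
        mask = ribbon_image(width=5) > 127
        skel = skeletonize_mask(mask)
        net = skeleton_to_graph(skel, ExtractionParams(pixel_size=1.0))
        estimate_widths(net, mask, 1.0)
        e = next(iter(net.edges.values()))
        assert e.width == pytest.approx(5.0, abs=1.0)

    def test_parallel_ribbons_ordered(self):
        img = np.zeros((60, 100), dtype=np.uint8)
        img[15:18, 10:90] = 220        # width 3
        img[40:49, 10:90] = 220        # width 9
        mask = img > 127
        skel = skeletonize_mask(mask)
        net = skeleton_to_graph(skel, ExtractionParams(pixel_size=1.0))
        estimate_widths(net, mask, 1.0)
        widths = sorted(e.width for e in net.edges.values())
        assert widths[0] < widths[1]
        assert widths[0] == pytest.approx(3.0, abs=1.0)
        assert widths[1] == pytest.approx(9.0, abs=1.0)

    def test_intensity_rescaling_irrelevant(self):
        """Widths depend only on the mask, not the raw intensities."""
        img = ribbon_image()
        p = ExtractionParams(pixel_size=1.0)
        m1 = preprocess(img, p)
        m2 = preprocess((img.astype(float) * 0.3), p)
        assert np.array_equal(m1, m2)


class TestPrune:
    def test_short_spur_removed_and_path_merged(self):
        """Y with one 2 px spur: prune, then the through-path merges to one edge."""
        net = make_net({0: (0.0, 0.0), 1: (10.0, 0.0), 2: (20.0, 0.0), 3: (10.0, 2.0)},
                       [(0, 1, 10.0, 2.0), (1, 2, 10.0, 2.0), (1, 3, 2.0, 1.0)])
        out = prune_and_clean(net, ExtractionParams(pixel_size=1.0, min_spur_length=5.0))
        assert out.n_edges == 1
        e = next(iter(out.edges.values()))
        assert e.length == pytest.approx(20.0)
        assert e.width == pytest.approx(2.0)

    def test_no_spurs_identity(self):
        net = make_net({0: (0.0, 0.0), 1: (10.0, 0.0), 2: (20.0, 5.0)},
                       [(0, 1, 10.0, 2.0), (1, 2, 11.2, 2.0)])
        before = sorted((e.length, e.width) for e in net.edges.values())
        out = prune_and_clean(net.copy(), ExtractionParams(pixel_size=1.0,
                                                           min_spur_length=5.0))
        # the degree-2 chain is dissolved, but total geometry is conserved
        assert sum(e.length for e in out.edges.values()) == pytest.approx(
            sum(l for l, _ in before))

    def test_pruning_never_disconnects_root_component(self):
        for s in range(5):
            net = grow_network(SynthParams(seed=s, n_steps=20))
            prune_and_clean(net, ExtractionParams(pixel_size=1.0, min_spur_length=3.0))
            assert net.is_connected()


class TestRoundTrip:
    @pytest.mark.parametrize("seed", [0, 1])
    def test_render_extract_fidelity(self, seed):
        """Noise-free synthetic colony: length within 5%, widths within 10%."""
        net = grow_network(SynthParams(seed=seed, n_steps=30))
        r = render_image(net, pixel_size=1.0, blur_sigma=1.0, noise_sd=0.0)
        cx, cy = -r.origin[0], -r.origin[1]
        ext = extract_network(r.image, ExtractionParams(pixel_size=1.0),
                              inoculum_center=(cx, cy), inoculum_radius=24.0)
        assert ext.total_length() == pytest.approx(net.total_length(), rel=0.05)

        def wmean(n):
            es = list(n.measured_edges())
            total = sum(e.length for e in es)
            return sum(e.width * e.length for e in es) / total

        assert wmean(ext) == pytest.approx(wmean(net), rel=0.10)
        assert ext.root_id is not None

    def test_deterministic(self):
        net = grow_network(SynthParams(seed=3, n_steps=15))
        r = render_image(net, pixel_size=1.0, blur_sigma=1.0, noise_sd=0.0)
        nets = [extract_network(r.image, ExtractionParams(pixel_size=1.0))
                for _ in range(2)]
        sig = [sorted((round(e.length, 9), round(e.width, 9)) for e in n.edges.values())
               for n in nets]
        assert sig[0] == sig[1]

    def test_arc_length_at_least_chord(self):
        net = grow_network(SynthParams(seed=6, n_steps=15))
        r = render_image(net, pixel_size=1.0, blur_sigma=0.0)
        ext = extract_network(r.image, ExtractionParams(pixel_size=1.0))
        for e in ext.measured_edges():
            chord = math.dist(ext.nodes[e.u].xy, ext.nodes[e.v].xy)
            assert e.length >= chord - 1e-9
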