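import math

import numpy as np
import pytest

from mitomorph.image_io import read_metrics_table, write_metrics_table
from mitomorph.metrics import (
    EXTENSIVE_FIELDS,
    INTENSIVE_FIELDS,
    PipelineConfig,
    analyze_batch,
    analyze_field_segmented,
    analyze_image,
    compute_metrics,
    normalize_metrics,
    skeletonize_image,
)
from mitomorph.skelgraph import Branch, Component, SkeletonGraph


def make_graph(rod_lengths=(), network_branches=(), punctates=0):
    """Assemble a SkeletonGraph directly from class/length descriptions."""
    comps, cid = [], 0
    for _ in range(punctates):
        cid += 1
        comps.append(Component(cid, 1, 0, 0,
                               [Branch(cid, -1, -1, 0.0, 1)], "punctate"))
    for L in rod_lengths:
        cid += 1
        comps.append(Component(cid, int(L) + 1, 2, 0,
                               [Branch(cid, -1, -2, float(L), int(L) - 1)], "rod"))
    for branches in network_branches:
        cid += 1
        blist = [Branch(cid, 1, 2, float(b), int(b)) for b in branches]
        comps.append(Component(cid, int(sum(branches)) + 1, 2, 1, blist, "network"))
    return SkeletonGraph(components=comps)


class TestComputeMetrics:
    def test_hand_computed_reference_case(self):
        """2 rods (7, 9) + 1 network with branches (4, 5, 6): every derived
        parameter from its definitional formula."""
        g = make_graph(rod_lengths=(7, 9), network_branches=((4, 5, 6),))
        m = compute_metrics(g, unit_id="case")
        assert m.rod_count == 2 and m.network_count == 1 and m.punctate_count == 0
        assert m.mean_rod_length == pytest.approx(8.0)
        assert m.total_network_branch_count == 3
        assert m.mean_network_branch_count == pytest.approx(3.0)
        assert m.mean_network_branch_length == pytest.approx(5.0)
        assert m.mean_network_length == pytest.approx(15.0)
        assert m.all_branch_count == 5
        assert m.mean_length_all_branches == pytest.approx(31 / 5)
        assert m.mean_network_and_rod_length == pytest.approx((15 + 16) / 3)
        assert m.punctate_pct == pytest.approx(0.0)
        assert m.rod_pct == pytest.approx(200 / 3)
        assert m.network_pct == pytest.approx(100 / 3)

    def test_empty_skeleton_all_counts_zero_all_means_missing(self):
        m = compute_metrics(make_graph())
        assert m.skeleton_area == 0
        assert m.punctate_count == m.rod_count == m.network_count == 0
        for f in ("punctate_pct", "rod_pct", "network_pct", "mean_rod_length",
                  "mean_network_branch_count", "mean_network_branch_length",
                  "mean_network_length", "mean_length_all_branches",
                  "mean_network_and_rod_length"):
            assert getattr(m, f) is None

    def test_single_punctate_percentages(self):
        m = compute_metrics(make_graph(punctates=1))
        assert m.punctate_pct == pytest.approx(100.0)
        assert m.rod_pct == pytest.approx(0.0)
        assert m.network_pct == pytest.approx(0.0)
        assert m.mean_rod_length is None          # no rods: missing, not 0

    def test_percentages_sum_to_100(self):
        m = compute_metrics(make_graph(rod_lengths=(5,), punctates=3,
                                       network_branches=((4, 4, 4),)))
        assert m.punctate_pct + m.rod_pct + m.network_pct == pytest.approx(100, abs=1e-9)

    def test_length_weighted_percentages_option(self):
        g = make_graph(rod_lengths=(10,), network_branches=((5, 5),))
        m = compute_metrics(g, percent_basis="length")
        assert m.rod_pct == pytest.approx(50.0)
        assert m.network_pct == pytest.approx(50.0)

    def test_pixel_size_scales_lengths_and_areas(self):
        g = make_graph(rod_lengths=(10,))
        m = compute_metrics(g, pixel_size=0.5)
        assert m.rod_length == pytest.approx(5.0)
        assert m.skeleton_area == pytest.approx(11 * 0.25)


class TestNormalization:
    def _metrics(self):
        return compute_metrics(
            make_graph(rod_lengths=(7, 9), network_branches=((4, 5, 6),),
                       punctates=10)
        )

    def test_unit_normalizer_is_identity_on_values(self):
        m = self._metrics()
        n = normalize_metrics(m, "cell_area", 1.0)
        for f in EXTENSIVE_FIELDS + INTENSIVE_FIELDS:
            assert getattr(n, f) == getattr(m, f)
        assert n.normalizer_kind == "cell_area"

    def test_extensive_fields_divide_intensive_unchanged(self):
        m = self._metrics()
        n = normalize_metrics(m, "nuclei_count", 2.0)
        assert n.punctate_count == pytest.approx(m.punctate_count / 2)
        assert n.rod_count == pytest.approx(m.rod_count / 2)
        assert n.skeleton_area == pytest.approx(m.skeleton_area / 2)
        for f in INTENSIVE_FIELDS:
            assert getattr(n, f) == getattr(m, f)

    def test_round_trip_recovers_raw_values(self):
        m = self._metrics()
        n = normalize_metrics(m, "cell_area", 137.5)
        for f in EXTENSIVE_FIELDS:
            assert getattr(n, f) * 137.5 == pytest.approx(getattr(m, f), abs=1e-12)

    def test_nonpositive_normalizer_rejected(self):
        with pytest.raises(ValueError):
            normalize_metrics(self._metrics(), "cell_area", 0.0)
        with pytest.raises(ValueError):
            normalize_metrics(self._metrics(), "bogus", 2.0)


class TestPipeline:
    def test_scene_metrics_match_ground_truth_counts(self, small_scene):
        spec, img, truth = small_scene
        m = analyze_image(img)
        assert m.punctate_count == truth.n_punctates
        assert m.rod_count == truth.n_rods
        assert m.network_count == truth.n_networks

    def test_definitional_identities_on_pipeline_output(self, small_scene):
        _, img, _ = small_scene
        m = analyze_image(img)
        assert m.mean_network_branch_count * m.network_count == pytest.approx(
            m.total_network_branch_count)
        assert m.mean_network_branch_length * m.total_network_branch_count == (
            pytest.approx(m.network_length))
        assert m.punctate_pct + m.rod_pct + m.network_pct == pytest.approx(100, abs=1e-9)


class TestBatch:
    def test_aggregate_batch_one_record_per_field(self, tmp_path):
        from mitomorph.image_io import write_image
        from mitomorph.synth import SceneSpec, generate_scene

        for i in range(3):
            img, _ = generate_scene(SceneSpec(rng_seed=40 + i, n_punctates=5,
                                              n_rods=5, n_networks=1))
            write_image(img, tmp_path / f"f{i}.tif")
        records = analyze_batch(tmp_path, mode="aggregate")
        assert len(records) == 3
        assert all(r.normalizer_kind == "none" for r in records)
        out = tmp_path / "table.csv"
        write_metrics_table(records, out)
        assert len(read_metrics_table(out)) == 3

    def test_aggregate_batch_normalizes_by_companion_nuclei(self, tmp_path,
                                                            multicell_scene):
        from mitomorph.image_io import write_image

        mito, nuclei, truth = multicell_scene
        write_image(mito, tmp_path / "field.tif")
        write_image(nuclei, tmp_path / "field_nuclei.tif")
        (rec,) = analyze_batch(tmp_path, mode="aggregate")
        assert rec.normalizer_kind == "nuclei_count"
        assert rec.normalizer_value == truth.nuclei_count

    def test_segmented_batch_one_record_per_cell(self, tmp_path, multicell_scene):
        from mitomorph.image_io import write_image

        mito, _, truth = multicell_scene
        write_image(mito, tmp_path / "field.tif")
        records = analyze_batch(tmp_path, mode="segmented")
        assert len(records) == int(truth.cell_labels.max())
        assert all(r.normalizer_kind == "cell_area" for r in records)
        assert len({r.unit_id for r in records}) == len(records)

    def test_unreadable_file_skipped_with_warning(self, tmp_path, caplog):
        (tmp_path / "junk.tif").write_bytes(b"not a tiff")
        assert analyze_batch(tmp_path, mode="aggregate") == []

    def test_empty_directory_warns_and_returns_empty(self, tmp_path):
        assert analyze_batch(tmp_path, mode="aggregate") == []
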