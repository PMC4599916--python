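"""Mask construction and per-object measurement against fixture ground truth."""

import numpy as np
import pytest
from scipy.spatial import cKDTree

from conftest import circle_pixel_oracle
from nucshift.exceptions import InputError
from nucshift.segment import (
    SegmentationParams,
    measure_intensities,
    remove_objects_overlapping,
    segment_cytoplasm,
    segment_hsc,
    segment_nuclei,
)
from nucshift.synthesize import (
    GroundTruthCell,
    IntensityComponent,
    PopulationSpec,
    generate_cell_table,
    render_tissue_image,
)


def spec20(noise_sd=0.0, seed=11, n_hsc=0):
    return PopulationSpec(
        n_cells=20,
        n_hsc=n_hsc,
        components=(IntensityComponent(1.0, 0.4, 0.05, 0.3, 0.05),),
        noise_sd=noise_sd,
        seed=seed,
        frame=(256, 256),
    )


@pytest.fixture(scope="module")
def clean_scene():
    spec = spec20()
    table = generate_cell_table(spec)
    return spec, table, render_tissue_image(table, spec)


def test_blank_image_yields_zero_objects():
    mask = segment_nuclei(np.zeros((64, 64)))
    assert mask.n_objects == 0
    assert mask.labels.max() == 0


def test_nucleus_count_and_area_match_oracle(clean_scene):
    spec, table, img = clean_scene
    nuclei = segment_nuclei(img.channels["dapi"])
    assert nuclei.n_objects == 20
    expected = set()
    for row in table.itertuples(index=False):
        expected |= circle_pixel_oracle(spec.frame, (row.y, row.x), row.nucleus_radius)
    assert int((nuclei.labels > 0).sum()) == len(expected)


def test_single_cell_cytoplasm_is_disk_minus_nucleus_within_one_pixel():
    spec = spec20()
    cell = GroundTruthCell(
        cell_id=0, center=(100.0, 100.0), nucleus_radius=5.0, cell_radius=10.0,
        true_nuclear_intensity=0.5, true_cytoplasmic_intensity=0.3,
    )
    img = render_tissue_image([cell], spec)
    nuclei = segment_nuclei(img.channels["dapi"])
    cyto = segment_cytoplasm(img.channels["phalloidin"], img.channels["dapi"], nuclei)
    assert cyto.n_objects == 1
    got = set(zip(*map(list, np.nonzero(cyto.labels == 1))))
    expected = circle_pixel_oracle(spec.frame, (100, 100), 10.0) - circle_pixel_oracle(
        spec.frame, (100, 100), 5.0
    )
    # disagreement confined to the outermost 1-pixel boundary band
    for r, c in got ^ expected:
        d = np.hypot(r - 100.0, c - 100.0)
        assert 10.0 - 1.0 <= d <= 10.0 + 1.0


def test_empty_nuclei_give_empty_cytoplasm():
    blank = np.zeros((64, 64))
    nuclei = segment_nuclei(blank)
    cyto = segment_cytoplasm(blank, blank, nuclei)
    assert cyto.n_objects == 0


def test_adjacent_cells_have_disjoint_compartments(clean_scene):
    _, _, img = clean_scene
    nuclei = segment_nuclei(img.channels["dapi"])
    cyto = segment_cytoplasm(img.channels["phalloidin"], img.channels["dapi"], nuclei)
    assert cyto.n_objects == nuclei.n_objects
    overlap = (nuclei.labels > 0) & (cyto.labels > 0)
    assert not overlap.any()  # nucleus ∩ cytoplasm = ∅ for every cell
    # determinism: identical inputs, identical masks
    again = segment_cytoplasm(img.channels["phalloidin"], img.channels["dapi"], nuclei)
    assert np.array_equal(cyto.labels, again.labels)


def test_dimension_mismatch_rejected():
    nuclei = segment_nuclei(np.zeros((64, 64)))
    with pytest.raises(InputError):
        segment_cytoplasm(np.zeros((32, 32)), np.zeros((64, 64)), nuclei)


def test_manual_roi_triangle_rasterization():
    from shapely.geometry import Point, Polygon

    tri = np.array([[10.0, 10.0], [40.0, 12.0], [25.0, 45.0]])
    mask = segment_hsc(np.zeros((64, 64)), manual_rois=[tri])
    assert mask.n_objects == 1
    got = set(zip(*map(list, np.nonzero(mask.labels == 1))))
    poly = Polygon([(r, c) for r, c in tri])
    inner = poly.buffer(-1.0)
    outer = poly.buffer(+1.0)
    for r in range(64):
        for c in range(64):
            p = Point(r, c)
            if inner.contains(p):
                assert (r, c) in got
            if not outer.contains(p):
                assert (r, c) not in got


def test_self_intersecting_roi_rejected():
    bowtie = np.array([[0.0, 0.0], [10.0, 10.0], [0.0, 10.0], [10.0, 0.0]])
    with pytest.raises(InputError, match="self-intersecting"):
        segment_hsc(np.zeros((32, 32)), manual_rois=[bowtie])


def test_blank_gfap_without_rois_yields_zero_objects():
    assert segment_hsc(np.zeros((64, 64))).n_objects == 0


def test_five_gfap_ellipses_found():
    spec = spec20(n_hsc=5, seed=3)
    table = generate_cell_table(spec)
    img = render_tissue_image(table, spec)
    assert segment_hsc(img.channels["gfap"]).n_objects == 5


def test_constant_target_measures_constant(clean_scene):
    _, _, img = clean_scene
    nuclei = segment_nuclei(img.channels["dapi"])
    cyto = segment_cytoplasm(img.channels["phalloidin"], img.channels["dapi"], nuclei)
    meas = measure_intensities(np.full((256, 256), 0.37), nuclei, cyto)
    assert len(meas) == 20
    assert np.allclose(meas["i_nuclear"], 0.37, rtol=1e-12)
    assert np.allclose(meas["i_cytoplasmic"], 0.37, rtol=1e-12)


def test_empty_masks_give_empty_table():
    blank = np.zeros((64, 64))
    nuclei = segment_nuclei(blank)
    cyto = segment_cytoplasm(blank, blank, nuclei)
    meas = measure_intensities(blank, nuclei, cyto)
    assert len(meas) == 0
    assert list(meas.columns)[:3] == ["image_id", "cell_id", "cell_type"]


def test_noise_free_measurement_recovers_ground_truth(clean_scene):
    spec, table, img = clean_scene
    nuclei = segment_nuclei(img.channels["dapi"])
    cyto = segment_cytoplasm(img.channels["phalloidin"], img.channels["dapi"], nuclei)
    meas = measure_intensities(img.channels["nfkb"], nuclei, cyto)
    assert len(meas) == 20
    tree = cKDTree(table[["y", "x"]].to_numpy())
    d, idx = tree.query(meas[["y", "x"]].to_numpy())
    assert d.max() < 2.0
    truth_n = table["true_i_nuclear"].to_numpy()[idx]
    truth_c = table["true_i_cytoplasmic"].to_numpy()[idx]
    assert np.all(np.abs(meas["i_nuclear"] - truth_n) / truth_n <= 0.02)
    assert np.all(np.abs(meas["i_cytoplasmic"] - truth_c) / truth_c <= 0.02)


def test_count_recovery_with_noise():
    spec = spec20(noise_sd=0.05, seed=29)
    table = generate_cell_table(spec)
    img = render_tissue_image(table, spec)
    n = segment_nuclei(img.channels["dapi"]).n_objects
    assert 19 <= n <= 21  # within 5% of the 20 rendered nuclei


def test_remove_objects_overlapping_hsc_footprints():
    spec = spec20(n_hsc=5, seed=3)
    table = generate_cell_table(spec)
    img = render_tissue_image(table, spec)
    nuclei = segment_nuclei(img.channels["dapi"])
    hsc = segment_hsc(img.channels["gfap"])
    kept = remove_objects_overlapping(nuclei, hsc)
    assert kept.n_objects == 20  # HSC nuclear footprints removed, hepatocytes kept
    assert kept.labels.max() == kept.n_objects


def test_fixed_threshold_mode_and_border_exclusion():
    img = np.zeros((64, 64))
    img[0:6, 10:16] = 0.9  # touches the border
    img[30:36, 30:36] = 0.9
    params = SegmentationParams(threshold_method="fixed", fixed_threshold=0.5, min_area=4)
    assert segment_nuclei(img, params).n_objects == 2
    params_b = SegmentationParams(
        threshold_method="fixed", fixed_threshold=0.5, min_area=4, exclude_border=True
    )
    assert segment_nuclei(img, params_b).n_objects == 1
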