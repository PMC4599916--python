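"""Ground-truth generator and tissue renderer contracts."""

import numpy as np
import pandas as pd
import pytest

from conftest import circle_pixel_oracle
from nucshift.exceptions import ConfigurationError, GeometryError
from nucshift.synthesize import (
    GroundTruthCell,
    IntensityComponent,
    PopulationSpec,
    generate_cell_table,
    place_landmarks,
    render_tissue_image,
)


def constant_spec(**kw):
    base = dict(
        n_cells=30,
        components=(IntensityComponent(1.0, 0.5, 0.0, 0.5, 0.0),),
        noise_sd=0.0,
        seed=7,
        frame=(256, 256),
    )
    base.update(kw)
    return PopulationSpec(**base)


def test_degenerate_noise_free_spec_yields_constant_intensities():
    t = generate_cell_table(constant_spec())
    assert len(t) == 30
    assert (t["i_nuclear"] == 0.5).all()
    assert (t["i_cytoplasmic"] == 0.5).all()


def test_mixture_proportions_match_binomial_oracle():
    spec = PopulationSpec(
        n_cells=2000,
        n_images=10,
        frame=(512, 512),
        components=(
            IntensityComponent(0.5, 0.2, 0.02, 0.3, 0.02),
            IntensityComponent(0.5, 0.5, 0.02, 0.6, 0.02),  # >= 5 sd away in both axes
        ),
        seed=21,
    )
    t = generate_cell_table(spec)
    frac = (t["component"] == 0).mean()
    assert abs(frac - 0.5) <= 0.03  # within 3% (binomial sd at n=2000 is ~1.1%)


def test_same_seed_is_bit_identical():
    spec = constant_spec(n_cells=40, n_hsc=4)
    t1, t2 = generate_cell_table(spec), generate_cell_table(spec)
    pd.testing.assert_frame_equal(t1, t2)
    assert t1.to_csv(index=False) == t2.to_csv(index=False)


def test_invalid_mixture_weights_rejected():
    with pytest.raises(ConfigurationError):
        PopulationSpec(components=(IntensityComponent(0.7, 0.2, 0.1, 0.3, 0.1),))
    with pytest.raises(ConfigurationError):
        PopulationSpec(n_cells=0)


def test_disjoint_layout_has_no_overlaps():
    t = generate_cell_table(constant_spec(n_cells=60, n_hsc=6))
    pts = t[["y", "x"]].to_numpy()
    radii = t["cell_radius"].to_numpy()
    d = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))
    sep = radii[:, None] + radii[None, :]
    off = ~np.eye(len(t), dtype=bool)
    assert (d[off] >= sep[off]).all()


def test_render_single_cell_noise_free_contract():
    spec = constant_spec(n_cells=1)
    cell = GroundTruthCell(
        cell_id=0, center=(64.0, 80.0), nucleus_radius=5.0, cell_radius=10.0,
        true_nuclear_intensity=0.41, true_cytoplasmic_intensity=0.23,
    )
    img = render_tissue_image([cell], spec)
    nfkb = img.channels["nfkb"]
    rr, cc = np.indices(spec.frame)
    d2 = (rr - 64.0) ** 2 + (cc - 80.0) ** 2
    nucleus = d2 <= 5.0**2
    annulus = (d2 > 5.0**2) & (d2 <= 10.0**2)
    assert nfkb[nucleus].mean() == pytest.approx(0.41, rel=1e-12)
    assert nfkb[annulus].mean() == pytest.approx(0.23, rel=1e-12)
    assert img.channels["gfap"].sum() == 0.0


def test_render_empty_scene_is_all_zero():
    img = render_tissue_image([], constant_spec())
    for arr in img.channels.values():
        assert arr.sum() == 0.0


def test_dapi_foreground_matches_rasterization_oracle():
    spec = constant_spec(n_cells=20)
    t = generate_cell_table(spec)
    img = render_tissue_image(t, spec)
    expected = set()
    for row in t.itertuples(index=False):
        expected |= circle_pixel_oracle(spec.frame, (row.y, row.x), row.nucleus_radius)
    fg = img.channels["dapi"] > 0
    assert fg.sum() == len(expected)
    got = set(zip(*map(list, np.nonzero(fg))))
    assert got == expected


def test_gfap_confined_to_hsc_footprints():
    spec = constant_spec(n_cells=5, n_hsc=6)
    t = generate_cell_table(spec)
    img = render_tissue_image(t, spec)
    gfap = img.channels["gfap"]
    assert (gfap > 0).sum() > 0
    hsc = t[t.cell_type == "hsc"]
    pts = np.column_stack(np.nonzero(gfap > 0)).astype(float)
    centers = hsc[["y", "x"]].to_numpy()
    major = hsc["cell_radius"].to_numpy()
    dmin = np.sqrt(((pts[:, None] - centers[None]) ** 2).sum(-1)).min(axis=1)
    assert (dmin <= major.max() + 1).all()


def test_cell_outside_frame_is_a_geometry_error():
    cell = GroundTruthCell(
        cell_id=0, center=(5.0, 5.0), nucleus_radius=5.0, cell_radius=10.0,
        true_nuclear_intensity=0.5, true_cytoplasmic_intensity=0.5,
    )
    with pytest.raises(GeometryError):
        render_tissue_image([cell], constant_spec())


def test_place_landmarks_types_determinism_and_separation():
    lms = place_landmarks((512, 512), n_portal=1, n_central=1, seed=3)
    assert sorted(lm.landmark_type for lm in lms) == ["central", "portal"]
    again = place_landmarks((512, 512), n_portal=1, n_central=1, seed=3)
    assert [(lm.y, lm.x) for lm in lms] == [(lm.y, lm.x) for lm in again]
    many = place_landmarks((512, 512), n_portal=2, n_central=2, zone_radius=80,
                           min_separation=100, seed=5)
    for i in range(len(many)):
        for j in range(i + 1, len(many)):
            d = np.hypot(many[i].y - many[j].y, many[i].x - many[j].x)
            assert d >= 100
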