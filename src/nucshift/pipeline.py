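"""End-to-end orchestration: simulate/ingest → segment → quantify → zonate → analyze.

A single config drives every stage. The run is fully deterministic under the
configured seed (per-group and per-image random streams are spawned from
it), and every output file carries the config hash in a header line or
sidecar so reruns are attributable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .exceptions import ConfigurationError, InputError, PipelineError
from .normalize import IntensityNormalizer
from .quantify import GeometryParams, add_nuclear_fraction
from .segment import (
    SegmentationParams,
    measure_intensities,
    remove_objects_overlapping,
    segment_cytoplasm,
    segment_hsc,
    segment_nuclei,
)
from .stats import exceedance_probability, kde2d, permutation_test, rank_test
from .synthesize import (
    FractionComponent,
    HscComponent,
    IntensityComponent,
    LandmarkSpec,
    PopulationSpec,
    generate_dataset,
    read_landmarks,
    render_tissue_image,
    save_multiplex,
    write_landmarks,
)
from .zonation import zonal_split

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "RunReport", "run_pipeline", "negative_control_check"]


def _component_from_dict(d: dict):
    d = dict(d)
    if "nf_mean" in d:
        return FractionComponent(**d)
    return IntensityComponent(**d)


def _spec_from_dict(group: str, d: dict) -> PopulationSpec:
    d = dict(d)
    if "components" in d:
        d["components"] = tuple(_component_from_dict(c) for c in d["components"])
    if "hsc_components" in d:
        d["hsc_components"] = tuple(HscComponent(**c) for c in d["hsc_components"])
    if "landmarks" in d and d["landmarks"] is not None:
        d["landmarks"] = LandmarkSpec(**d["landmarks"])
    if "frame" in d:
        d["frame"] = tuple(d["frame"])
    return PopulationSpec(group=group, **d)


@dataclass
class RunConfig:
    """Everything a pipeline run needs; see ``RunConfig.from_yaml``."""

    outdir: Path
    seed: int = 0
    groups: dict = field(default_factory=dict)  # group name -> PopulationSpec
    comparison: tuple | None = None  # (reference group, treatment group)
    geometry: GeometryParams = field(default_factory=GeometryParams)
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    n_permutations: int = 10000
    statistic: str = "mean_diff"
    table_only: bool = False  # skip rendering/segmentation, use ground-truth intensities
    save_images: bool = False
    image_format: str = "tiff"
    make_figures: bool = False
    input_table: Path | None = None  # ingest a pre-measured CellMeasurement CSV
    landmarks_file: Path | None = None
    negative_control_threshold: float | None = None

    def __post_init__(self):
        self.outdir = Path(self.outdir)
        for attr in ("input_table", "landmarks_file"):
            p = getattr(self, attr)
            if p is not None:
                p = Path(p)
                setattr(self, attr, p)
                if not p.exists():
                    raise ConfigurationError(f"{attr} does not exist: {p}")
        if not self.groups and self.input_table is None:
            raise ConfigurationError("config needs either simulated groups or an input table")
        if self.comparison is None and len(self.groups) >= 2:
            self.comparison = tuple(list(self.groups)[:2])

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs: dict = {}
        kwargs["outdir"] = raw.get("outdir", "nucshift-run")
        kwargs["seed"] = int(raw.get("seed", 0))
        kwargs["groups"] = {
            name: _spec_from_dict(name, spec) for name, spec in (raw.get("groups") or {}).items()
        }
        if raw.get("comparison"):
            kwargs["comparison"] = tuple(raw["comparison"])
        if "geometry" in raw:
            kwargs["geometry"] = GeometryParams(**raw["geometry"])
        if "segmentation" in raw:
            kwargs["segmentation"] = SegmentationParams(**raw["segmentation"])
        perm = raw.get("permutations") or {}
        kwargs["n_permutations"] = int(perm.get("iterations", 10000))
        kwargs["statistic"] = perm.get("statistic", "mean_diff")
        pipe = raw.get("pipeline") or {}
        for key in ("table_only", "save_images", "make_figures"):
            if key in pipe:
                kwargs[key] = bool(pipe[key])
        if "image_format" in pipe:
            kwargs["image_format"] = pipe["image_format"]
        inputs = raw.get("inputs") or {}
        if inputs.get("table"):
            kwargs["input_table"] = inputs["table"]
        if inputs.get("landmarks"):
            kwargs["landmarks_file"] = inputs["landmarks"]
        if "negative_control_threshold" in raw:
            kwargs["negative_control_threshold"] = raw["negative_control_threshold"]
        kwargs.update(overrides)
        return cls(**kwargs)

    def config_hash(self) -> str:
        """Hash of the scientific configuration (output location excluded)."""
        payload = dataclasses.asdict(self)
        payload.pop("outdir", None)
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


@dataclass
class RunReport:
    config_hash: str
    seed: int
    outdir: Path
    counts: dict
    results: dict
    files: dict


def negative_control_check(measurements: pd.DataFrame, threshold: float = 0.05) -> bool:
    """Pass when the upper quartile of all measured intensities is strictly below threshold.

    Mirrors the no-primary-antibody control: residual signal must be
    negligible. A distribution sitting exactly at the threshold fails
    (strict inequality).
    """
    vals = measurements[["i_nuclear", "i_cytoplasmic", "i_wholecell"]].to_numpy(dtype=float).ravel()
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise InputError("no intensity values to check")
    return bool(np.percentile(vals, 75) < threshold)


def _measure_rendered(spec: PopulationSpec, dataset, seg: SegmentationParams, rng_seq,
                      save_dir=None, image_format="tiff"):
    """Render each image of a condition, segment it, and measure intensities."""
    frames = []
    for image_id, sub in dataset.table.groupby("image_id", sort=True):
        child = np.random.default_rng(rng_seq.spawn(1)[0])
        image = render_tissue_image(sub, spec, rng=child)
        if save_dir is not None:
            save_multiplex(image, save_dir, image_id, fmt=image_format)
        nuclei = segment_nuclei(image.channels["dapi"], seg)
        hsc = None
        if (sub["cell_type"] == "hsc").any():
            hsc = segment_hsc(image.channels["gfap"], seg)
            nuclei = remove_objects_overlapping(nuclei, hsc)
        cyto = segment_cytoplasm(image.channels["phalloidin"], image.channels["dapi"], nuclei, seg)
        meas = measure_intensities(image.channels["nfkb"], nuclei, cyto, hsc, image_id=image_id)
        meas["group"] = spec.group
        lms = dataset.landmarks.get(image_id) or []
        if lms:
            meas, _ = zonal_split(meas, lms)
        else:
            meas["zone"] = "midzonal"
        frames.append(meas)
    return pd.concat(frames, ignore_index=True)


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute every stage and write measurement CSVs, result JSON and provenance."""
    chash = config.config_hash()
    outdir = config.outdir
    outdir.mkdir(parents=True, exist_ok=True)
    counts: dict = {}
    results: dict = {"config_hash": chash, "seed": config.seed}
    files: dict = {}
    root = np.random.SeedSequence(config.seed)

    # --- simulate / ingest -------------------------------------------------
    stage = "simulate"
    try:
        tables = []
        if config.input_table is not None:
            df = pd.read_csv(config.input_table, comment="#")
            if config.landmarks_file is not None:
                lms = read_landmarks(config.landmarks_file)
                df, _ = zonal_split(df, lms)
            tables.append(df)
        group_seqs = root.spawn(max(len(config.groups), 1))
        for seq, (name, spec) in zip(group_seqs, config.groups.items()):
            seed = int(seq.generate_state(1)[0] % (2**31))
            spec = replace(spec, seed=seed, group=name)
            dataset = generate_dataset(spec)
            for image_id, lms in dataset.landmarks.items():
                if lms:
                    write_landmarks(lms, outdir / f"landmarks_{image_id}.csv")
            if config.table_only:
                tables.append(dataset.table)
            else:
                stage = "segment"
                save_dir = outdir / "images" if config.save_images else None
                tables.append(
                    _measure_rendered(spec, dataset, config.segmentation, seq,
                                      save_dir=save_dir, image_format=config.image_format)
                )
                stage = "simulate"
        measurements = pd.concat(tables, ignore_index=True)
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001 - rewrap with stage context
        raise PipelineError(stage, str(exc)) from exc

    counts["cells_total"] = int(len(measurements))
    for g, sub in measurements.groupby("group"):
        counts[f"cells_{g}"] = int(len(sub))
        logger.info("group %s: %d cells", g, len(sub))

    # --- quantify ----------------------------------------------------------
    try:
        if config.negative_control_threshold is not None:
            results["negative_control_pass"] = negative_control_check(
                measurements, config.negative_control_threshold
            )
        norm = IntensityNormalizer().fit(measurements)
        measurements = norm.transform(measurements)
        measurements = add_nuclear_fraction(measurements, config.geometry)
        factors = norm.factors_
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("quantify", str(exc)) from exc

    if "zone" in measurements.columns:
        zc = measurements.groupby(["group", "zone"]).size()
        counts["zones"] = {f"{g}/{z}": int(v) for (g, z), v in zc.items()}

    # --- analyze -----------------------------------------------------------
    try:
        if config.comparison is not None:
            ref, trt = config.comparison
            hep = measurements[measurements["cell_type"] == "hepatocyte"]
            nf_ref = hep.loc[hep["group"] == ref, "nuclear_fraction"].dropna().to_numpy()
            nf_trt = hep.loc[hep["group"] == trt, "nuclear_fraction"].dropna().to_numpy()
            if nf_ref.size and nf_trt.size:
                seed = int(root.spawn(1)[0].generate_state(1)[0] % (2**31))
                perm = permutation_test(
                    nf_ref, nf_trt, n_iterations=config.n_permutations,
                    seed=seed, statistic=config.statistic,
                )
                results["comparison"] = {"reference": ref, "treatment": trt}
                results["mean_nuclear_fraction"] = {
                    ref: float(nf_ref.mean()), trt: float(nf_trt.mean()),
                }
                results["nuclear_fraction_shift"] = float(nf_trt.mean() - nf_ref.mean())
                results["permutation"] = {
                    "observed": perm.observed, "p_value": perm.p_value,
                    "iterations": perm.n_iterations, "mode": perm.mode,
                }
                results["rank_test_p"] = rank_test(nf_ref, nf_trt)
            kde_modes = {}
            for g, sub in hep.groupby("group"):
                if len(sub) >= 10:
                    surf = kde2d(sub["i_nuclear"].to_numpy(), sub["i_cytoplasmic"].to_numpy())
                    kde_modes[g] = int(surf.modes.shape[0])
            if kde_modes:
                results["kde_modes"] = kde_modes
            hsc = measurements[measurements["cell_type"] == "hsc"]
            if config.comparison is not None and len(hsc):
                w_ref = hsc.loc[hsc["group"] == ref, "i_wholecell"].dropna().to_numpy()
                w_trt = hsc.loc[hsc["group"] == trt, "i_wholecell"].dropna().to_numpy()
                if w_ref.size and w_trt.size:
                    results["hsc_exceedance"] = exceedance_probability(w_trt, w_ref)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("analyze", str(exc)) from exc

    # --- report ------------------------------------------------------------
    try:
        header = f"# config_hash={chash} seed={config.seed}\n"
        meas_path = outdir / "measurements.csv"
        with open(meas_path, "w") as fh:
            fh.write(header)
            measurements.to_csv(fh, index=False)
        fac_path = outdir / "factors.csv"
        with open(fac_path, "w") as fh:
            fh.write(header)
            factors.to_csv(fh, index=False)
        results["counts"] = counts
        res_path = outdir / "results.json"
        res_path.write_text(json.dumps(results, indent=2, sort_keys=True))
        prov = {
            "config_hash": chash,
            "seed": config.seed,
            "nucshift_version": __version__,
            "versions": _library_versions(),
        }
        prov_path = outdir / "provenance.json"
        prov_path.write_text(json.dumps(prov, indent=2, sort_keys=True))
        files = {"measurements": meas_path, "factors": fac_path,
                 "results": res_path, "provenance": prov_path}
        if config.make_figures:
            files["figures"] = _make_figures(measurements, outdir, chash)
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("report", str(exc)) from exc

    return RunReport(config_hash=chash, seed=config.seed, outdir=outdir,
                     counts=counts, results=results, files=files)


def _library_versions() -> dict:
    import numpy
    import pandas
    import scipy
    import skimage

    return {
        "numpy": numpy.__version__,
        "scipy": scipy.__version__,
        "pandas": pandas.__version__,
        "scikit-image": skimage.__version__,
    }


def _make_figures(measurements: pd.DataFrame, outdir: Path, chash: str):
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    from .stats import ecdf as _ecdf

    figdir = outdir / "figures"
    figdir.mkdir(exist_ok=True)
    hep = measurements[measurements["cell_type"] == "hepatocyte"]
    paths = []

    fig, ax = plt.subplots(figsize=(5, 4))
    for g, sub in hep.groupby("group"):
        nf = sub["nuclear_fraction"].dropna().to_numpy()
        if nf.size:
            f = _ecdf(nf)
            xs = np.sort(nf)
            ax.step(xs, f(xs), where="post", label=g)
    ax.set_xlabel("nuclear fraction")
    ax.set_ylabel("cumulative fraction of cells")
    ax.legend(fontsize=8)
    fig.tight_layout()
    p = figdir / "ecdf_nuclear_fraction.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    paths.append(p)

    for g, sub in hep.groupby("group"):
        if len(sub) < 10:
            continue
        surf = kde2d(sub["i_nuclear"].to_numpy(), sub["i_cytoplasmic"].to_numpy())
        fig, ax = plt.subplots(figsize=(4.5, 4))
        ax.contourf(surf.x, surf.y, surf.density.T, levels=12)
        ax.set_xlabel("nuclear intensity")
        ax.set_ylabel("cytoplasmic intensity")
        ax.set_title(g, fontsize=9)
        fig.tight_layout()
        p = figdir / f"kde_{g}.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        paths.append(p)
    (figdir / "provenance.txt").write_text(f"config_hash={chash}\n")
    return paths
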