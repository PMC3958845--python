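"""End-to-end orchestration: sections in, stratification tables out.

``measure_section`` runs the per-image quantification chain (threshold →
noise reduction → optional 1-megapixel reduction → segmentation →
dual-channel autofluorescence removal → congruency-based artifact rejection
→ biovolume fractions).  ``run_pipeline`` applies it to a whole manifest of
sections and writes object tables, depth and shell profiles, geometry and
regression summaries plus a run log to an output directory, deterministically
for a given config.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .geometry import measure_compartment, measure_thickness
from .imaging import (
    AMX_CHANNEL,
    AOB_CHANNEL,
    REFERENCE_CHANNEL,
    BinaryMask,
    SectionImage,
    downscale_mask,
    noise_reduce,
    read_section,
    threshold_fixed,
    write_section,
)
from .objects import (
    ArtifactParams,
    areal_density,
    biovolume_fraction,
    object_table,
    reject_artifacts,
    remove_autofluorescent,
    score_congruency,
    segment,
)
from .slicer import (
    SlicerParams,
    aggregate_shell_profiles,
    profiles_to_frame,
    shell_biovolume_profile,
    wall_distance_shells,
)
from .stats import DepthProfile, fit_depth_regression

__all__ = [
    "PipelineConfig",
    "PipelineError",
    "SectionMeasurement",
    "measure_section",
    "measure_stack",
    "run_pipeline",
    "io_roundtrip",
]

PROBE_NAMES = {AOB_CHANNEL: "aob", AMX_CHANNEL: "amx"}


class PipelineError(RuntimeError):
    """A pipeline stage failed; message names the stage and section."""


@dataclass
class PipelineConfig:
    """Run configuration: input manifest, parameters, output directory."""

    sections: list[dict]  # each: {"path": ..., "depth_um": ...}
    out_dir: str
    reference_channel: str = REFERENCE_CHANNEL
    specific_channels: tuple[str, str] = (AOB_CHANNEL, AMX_CHANNEL)
    cutoffs: dict[str, int] | int = 30
    artifact_params: ArtifactParams = field(default_factory=ArtifactParams)
    slicer_params: SlicerParams = field(default_factory=SlicerParams)
    overlap_rule: float = 0.50
    min_nonzero_neighbors: int = 1
    downscale_mp: float = 1.0
    regression_windows: dict[str, tuple[float, float] | None] = field(
        default_factory=lambda: {"aob": None, "amx": (180.0, 400.0)}
    )
    alpha: float = 0.05
    compartment_reference_side_um: float | None = None
    seed: int = 0

    def cutoff_for(self, channel: str) -> int:
        if isinstance(self.cutoffs, dict):
            return int(self.cutoffs.get(channel, 30))
        return int(self.cutoffs)

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "artifact_params" in raw:
            raw["artifact_params"] = ArtifactParams(**raw["artifact_params"])
        if "slicer_params" in raw:
            raw["slicer_params"] = SlicerParams(**raw["slicer_params"])
        if "regression_windows" in raw:
            raw["regression_windows"] = {
                k: tuple(v) if v is not None else None
                for k, v in raw["regression_windows"].items()
            }
        if "specific_channels" in raw:
            raw["specific_channels"] = tuple(raw["specific_channels"])
        missing = [
            s["path"] for s in raw.get("sections", []) if not os.path.exists(s["path"])
        ]
        if missing:
            raise FileNotFoundError(f"manifest references missing files: {missing}")
        return cls(**raw)


@dataclass
class SectionMeasurement:
    """Quantification results for one section."""

    depth_um: float
    masks: dict[str, BinaryMask]
    kept_objects: dict[str, list]
    removed_objects: list
    fractions: dict[str, float]
    areal_density: float
    qc_pass: dict[str, bool]
    compartment_mask: BinaryMask


def _compartment_footprint(reference: BinaryMask) -> tuple[BinaryMask, object]:
    """Wall-to-wall compartment region: the filled minimal bounding rectangle."""
    from skimage import draw as _draw

    geom = measure_compartment(reference)
    quad = geom.corners_px
    rr, cc = _draw.polygon(quad[:, 0], quad[:, 1], shape=reference.data.shape)
    mask = np.zeros(reference.data.shape, dtype=bool)
    mask[rr, cc] = True
    mask |= reference.data  # rasterized rectangle must cover all signal
    return BinaryMask(mask, reference.pixel_size_um, provenance="compartment"), geom


def measure_section(
    image: SectionImage,
    cutoff: int | dict[str, int] = 30,
    reference_channel: str = REFERENCE_CHANNEL,
    specific_channels: tuple[str, ...] = (AOB_CHANNEL, AMX_CHANNEL),
    artifact_params: ArtifactParams | None = None,
    overlap_rule: float = 0.50,
    min_nonzero_neighbors: int = 1,
    downscale_mp: float = 1.0,
) -> SectionMeasurement:
    """Quantify one section: masks, objects, biovolume fractions, QC flags."""
    artifact_params = artifact_params or ArtifactParams()

    def _cut(ch: str) -> int:
        return cutoff[ch] if isinstance(cutoff, dict) else cutoff

    masks = {}
    for name in (reference_channel, *specific_channels):
        m = threshold_fixed(
            image.channel(name), _cut(name), pixel_size_um=image.pixel_size_um
        )
        m = noise_reduce(m, min_nonzero_neighbors)
        m = downscale_mask(m, downscale_mp)
        masks[name] = m

    reference = masks[reference_channel]
    objs = {
        name: score_congruency(segment(masks[name], channel=name), reference)
        for name in specific_channels
    }
    removed = []
    if len(specific_channels) == 2:
        a, b = specific_channels
        objs[a], objs[b], removed = remove_autofluorescent(
            objs[a], objs[b], overlap_rule
        )
    kept = {}
    qc = {}
    fractions = {}
    comp_mask, _ = _compartment_footprint(reference)
    for name in specific_channels:
        kept[name], qc[name] = reject_artifacts(objs[name], reference, artifact_params)
        fractions[PROBE_NAMES.get(name, name)] = biovolume_fraction(kept[name], reference)
    dens = areal_density(reference, comp_mask.area_um2)
    return SectionMeasurement(
        depth_um=image.depth_um,
        masks=masks,
        kept_objects=kept,
        removed_objects=removed,
        fractions=fractions,
        areal_density=dens,
        qc_pass=qc,
        compartment_mask=comp_mask,
    )


def measure_stack(images: list[SectionImage], cutoff: int | dict = 30, **kw) -> pd.DataFrame:
    """Per-section biovolume fractions and areal density for a whole stack."""
    rows = []
    for img in images:
        m = measure_section(img, cutoff=cutoff, **kw)
        row = {"depth_um": m.depth_um, "areal_density": m.areal_density}
        row.update(m.fractions)
        rows.append(row)
    return pd.DataFrame(rows)


_CSV_HEADER = f"# fishstrat v{__version__} schema=1\n"


def _write_csv(frame: pd.DataFrame, path: str) -> None:
    with open(path, "w") as fh:
        fh.write(_CSV_HEADER)
        frame.to_csv(fh, index=False)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full quantification over a section manifest.

    Writes per-section object tables, the depth profile, per-shell profiles
    and their cross-section aggregate, geometry/thickness tables, regression
    summaries and a run log to ``config.out_dir``.  Returns the result
    bundle as a dict of DataFrames / results.  Any stage failure raises
    :class:`PipelineError` naming the stage and section.
    """
    os.makedirs(config.out_dir, exist_ok=True)
    object_rows = []
    profile_rows = []
    geometry_rows = []
    shell_profiles = []
    applied_thresholds = []

    for entry in config.sections:
        sid = entry.get("section", entry["path"])
        try:
            image = read_section(entry["path"])
        except Exception as e:  # noqa: BLE001
            raise PipelineError(f"stage=read section={sid}: {e}") from e
        if "depth_um" in entry and entry["depth_um"] is not None:
            image.depth_um = float(entry["depth_um"])
        try:
            m = measure_section(
                image,
                cutoff=config.cutoffs,
                reference_channel=config.reference_channel,
                specific_channels=config.specific_channels,
                artifact_params=config.artifact_params,
                overlap_rule=config.overlap_rule,
                min_nonzero_neighbors=config.min_nonzero_neighbors,
                downscale_mp=config.downscale_mp,
            )
        except Exception as e:  # noqa: BLE001
            raise PipelineError(f"stage=measure section={sid}: {e}") from e
        for name in config.specific_channels:
            applied_thresholds.append(
                {"section": sid, "channel": name, "cutoff": config.cutoff_for(name)}
            )
            tab = object_table(m.kept_objects[name])
            tab.insert(0, "section", sid)
            object_rows.append(tab)
        row = {
            "section": sid,
            "depth_um": m.depth_um,
            "areal_density": m.areal_density,
            **m.fractions,
            **{f"qc_{PROBE_NAMES.get(k, k)}": v for k, v in m.qc_pass.items()},
        }
        profile_rows.append(row)

        try:
            geom = measure_compartment(
                m.masks[config.reference_channel], depth_um=m.depth_um
            )
            thick = measure_thickness(
                m.masks[config.reference_channel], geometry=geom
            )
            grow = {
                "section": sid,
                "depth_um": m.depth_um,
                "mean_side_um": geom.mean_side_um,
                "area_um2": geom.area_um2,
                "side_thickness_mean_um": thick.side_mean_um,
                "corner_thickness_mean_um": thick.corner_mean_um,
            }
            if config.compartment_reference_side_um:
                grow["linear_shrinkage_ratio"] = (
                    geom.mean_side_um / config.compartment_reference_side_um
                )
                grow["area_shrinkage_ratio"] = (
                    geom.area_um2 / config.compartment_reference_side_um**2
                )
            geometry_rows.append(grow)
        except Exception as e:  # noqa: BLE001
            raise PipelineError(f"stage=geometry section={sid}: {e}") from e

        try:
            shells = wall_distance_shells(m.compartment_mask, config.slicer_params)
            profs = shell_biovolume_profile(
                shells,
                {
                    PROBE_NAMES.get(n, n): m.kept_objects[n]
                    for n in config.specific_channels
                },
                m.masks[config.reference_channel],
                config.slicer_params,
            )
            shell_profiles.append(profs)
        except Exception as e:  # noqa: BLE001
            raise PipelineError(f"stage=slicer section={sid}: {e}") from e

    profile = pd.DataFrame(profile_rows)
    objects = (
        pd.concat(object_rows, ignore_index=True) if object_rows else pd.DataFrame()
    )
    geometry = pd.DataFrame(geometry_rows)
    shell_long = profiles_to_frame(shell_profiles)
    shell_agg = aggregate_shell_profiles(shell_long)

    regression_rows = []
    regressions = {}
    for probe, window in config.regression_windows.items():
        col = probe if probe in profile.columns else None
        if col is None:
            continue
        try:
            res = fit_depth_regression(
                DepthProfile(
                    probe,
                    profile["depth_um"].to_numpy(),
                    profile[col].to_numpy(),
                ),
                window=window,
                alpha=config.alpha,
            )
        except ValueError as e:
            raise PipelineError(f"stage=stats probe={probe}: {e}") from e
        regressions[probe] = res
        regression_rows.append(
            {
                "probe": probe,
                "window_lo_um": res.window_um[0],
                "window_hi_um": res.window_um[1],
                "slope_per_um": res.slope,
                "intercept": res.intercept,
                "r_squared": res.r_squared,
                "n": res.n,
                "p_value": res.p_value,
                "alpha": res.alpha,
                "significant": res.significant,
            }
        )
    regression = pd.DataFrame(regression_rows)

    _write_csv(profile, os.path.join(config.out_dir, "depth_profile.csv"))
    _write_csv(objects, os.path.join(config.out_dir, "objects.csv"))
    _write_csv(geometry, os.path.join(config.out_dir, "geometry.csv"))
    _write_csv(shell_long, os.path.join(config.out_dir, "shell_profile.csv"))
    _write_csv(shell_agg, os.path.join(config.out_dir, "shell_aggregate.csv"))
    _write_csv(regression, os.path.join(config.out_dir, "regressions.csv"))
    log = {
        "version": __version__,
        "seed": config.seed,
        "n_sections": len(config.sections),
        "cutoffs": applied_thresholds,
        "artifact_params": asdict(config.artifact_params),
        "slicer_params": asdict(config.slicer_params),
        "alpha": config.alpha,
    }
    with open(os.path.join(config.out_dir, "run_log.json"), "w") as fh:
        json.dump(log, fh, indent=2, sort_keys=True)

    return {
        "depth_profile": profile,
        "objects": objects,
        "geometry": geometry,
        "shell_profile": shell_long,
        "shell_aggregate": shell_agg,
        "regression": regression,
        "regressions": regressions,
    }


def io_roundtrip(image: SectionImage, directory: str) -> SectionImage:
    """Write a section to ``directory`` and read it back (bit-identical)."""
    path = os.path.join(directory, "roundtrip.tif")
    write_section(image, path)
    return read_section(path)
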