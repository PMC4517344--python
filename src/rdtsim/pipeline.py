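"""End-to-end pipeline driver.

For every sampled phantom and fragment depth: generate the tooth, place the
fragment, carve the staging platform and the ultrasonic trough, measure the
3D minimum remaining dentin thickness; find the parallax angle separating
the mesiobuccal and palatal roots; render the paralleling (0°) and angled
projections and take the 2D rectangle measurements; then run the agreement
statistics.  Both fragment depths run as paired conditions on the same
phantom, so each tooth serves as its own control.

Fully deterministic for a fixed configuration seed; all artifacts can be
written to an output directory as CSV/JSON.
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

from .instrument import Fragment, _Polyline, place_fragment
from .measure2d import RDTRecord, min_rdt_2d
from .phantom import (
    DEFAULT_VARIATION,
    PhantomParams,
    default_params,
    generate_phantom,
    sample_population,
)
from .projection import (
    NoSeparationError,
    Projection2D,
    find_parallax_angle,
    project_point,
    render_drr,
)
from .removal import (
    GG4_DIAMETER_MM,
    TroughSpec,
    access_rectangle,
    carve_staging_platform,
    carve_trough,
    trough_z_span,
)
from .stats import (
    coefficient_of_variation,
    dunnett_vs_control,
    icc,
    two_way_anova,
)
from .thickness3d import distance_to_exterior_um, min_rdt_3d
from .volume import BACKGROUND, ToothVolume

logger = logging.getLogger("rdtsim")


@dataclass
class RunConfig:
    """Configuration of a population run."""

    n_phantoms: int = 36
    seed: int = 1
    voxel_size_um: float = 60.0
    depths_mm: tuple = (3.0, 5.0)
    tip_diameter_mm: float = 0.25
    taper: float = 0.06
    fragment_length_mm: float = 3.0
    ultrasonic_tip_diameter_mm: float = 0.40
    trough_depth_mm: float = 1.5
    platform_diameter_mm: float = GG4_DIAMETER_MM
    parallax_step_deg: float = 0.5
    parallax_max_deg: float = 60.0
    threshold_fraction: float = 0.05
    base_params: PhantomParams | None = None
    variation: dict | None = None
    out_dir: str | None = None

    def resolved_base(self) -> PhantomParams:
        if self.base_params is not None:
            return self.base_params
        return default_params(self.voxel_size_um)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["depths_mm"] = list(self.depths_mm)
        if self.base_params is not None:
            d["base_params"] = self.base_params.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if d.get("base_params") is not None:
            d["base_params"] = PhantomParams.from_dict(d["base_params"])
        if "depths_mm" in d:
            d["depths_mm"] = tuple(d["depths_mm"])
        return cls(**d)

    def config_hash(self) -> str:
        d = self.to_dict()
        d.pop("out_dir", None)  # hash identifies the scientific conditions
        payload = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class PipelineResult:
    records: pd.DataFrame  # tidy: phantom_id, method, depth_mm, side, angle, rdt
    anova: object
    dunnett: dict  # depth -> comparisons DataFrame
    icc_table: pd.DataFrame
    angles: pd.DataFrame
    summary: dict
    failed: list = field(default_factory=list)


def isolate_structure(volume: ToothVolume, tag: str, margin_vox: int = 4) -> ToothVolume:
    """Crop a volume to one named structure, blanking everything else.

    Used to read the mesiobuccal root outline the way an observer traces it
    on the film, free of the palatal-root shadow.
    """
    mask = volume.structures[tag]
    idx = np.nonzero(mask)
    lo = [max(0, int(i.min()) - margin_vox) for i in idx]
    hi = [min(n, int(i.max()) + 1 + margin_vox) for i, n in zip(idx, mask.shape)]
    sl = tuple(slice(a, b) for a, b in zip(lo, hi))
    labels = np.where(mask[sl], volume.labels[sl], BACKGROUND)
    origin = tuple(
        o + a * volume.voxel_size_um for o, a in zip(volume.origin_um, lo)
    )
    return ToothVolume(
        labels=labels,
        voxel_size_um=volume.voxel_size_um,
        origin_um=origin,
        structures={tag: mask[sl].copy()},
        centerline_um=None if volume.centerline_um is None else volume.centerline_um.copy(),
    )


def _measure_phantom(
    config: RunConfig, params: PhantomParams, phantom_id: str, seed: int
) -> tuple[list[RDTRecord], dict]:
    vol = generate_phantom(params, seed=seed)
    try:
        par = find_parallax_angle(
            vol,
            "mb_root",
            "palatal_root",
            step_deg=config.parallax_step_deg,
            max_angle_deg=config.parallax_max_deg,
        )
        angle, separated = par.angle_deg, True
    except NoSeparationError as err:
        angle, separated = err.result.min_overlap_angle_deg, False
        logger.warning("%s: no full silhouette separation; using %.1f deg", phantom_id, angle)

    dist = distance_to_exterior_um(vol)  # exterior surface is carve-invariant
    mb = isolate_structure(vol, "mb_root")
    orifice = vol.centerline_um[0]
    cl = _Polyline(vol.centerline_um)

    records: list[RDTRecord] = []
    for depth in config.depths_mm:
        frag = Fragment(
            tip_diameter_mm=config.tip_diameter_mm,
            taper=config.taper,
            length_mm=config.fragment_length_mm,
            depth_below_orifice_mm=depth,
        )
        spec = TroughSpec.for_fragment(
            frag,
            ultrasonic_tip_diameter_mm=config.ultrasonic_tip_diameter_mm,
            trough_depth_mm=config.trough_depth_mm,
        )
        carved = carve_trough(
            carve_staging_platform(
                place_fragment(vol, frag), frag, config.platform_diameter_mm
            ),
            frag,
            spec,
        )
        roi = trough_z_span(carved, frag, spec)
        rdt3d, _ = min_rdt_3d(carved, roi=roi, distance_um=dist)
        records.append(
            RDTRecord(value_um=rdt3d, method="3D", depth_group_mm=depth, phantom_id=phantom_id)
        )

        mb_frag = place_fragment(mb, frag)
        rect = access_rectangle(frag, spec)
        # rectangle centred on the projected access-corridor axis (canal
        # axis at the fragment's coronal end), top edge at orifice level
        corridor_pt = cl.point_at_s(depth * 1000.0)
        for method, ang in (("Pa", 0.0), ("An", angle)):
            proj = render_drr(mb_frag, ang, attenuation=params.attenuation)
            ax, _ = project_point(mb_frag, corridor_pt, ang)
            rect_a = replace(rect, anchor_um=(ax, float(orifice[2])))
            for side in ("distal", "mesial"):
                records.append(
                    min_rdt_2d(
                        proj,
                        rect_a,
                        side=side,
                        threshold_fraction=config.threshold_fraction,
                        method=method,
                        depth_group_mm=depth,
                        phantom_id=phantom_id,
                    )
                )
    angle_row = {"phantom_id": phantom_id, "angle_deg": angle, "separated": separated}
    return records, angle_row


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Run the full virtual-removal study on a seeded phantom population."""
    logger.info(
        "pipeline start: n=%d seed=%d voxel=%g um config=%s",
        config.n_phantoms,
        config.seed,
        config.voxel_size_um,
        config.config_hash(),
    )
    base = config.resolved_base()
    population = sample_population(
        config.n_phantoms, base, variation=config.variation, seed=config.seed
    )
    all_records: list[dict] = []
    angle_rows: list[dict] = []
    failed: list[dict] = []
    for i, params in enumerate(population):
        pid = f"P{i:03d}"
        try:
            recs, angle_row = _measure_phantom(config, params, pid, seed=config.seed + i)
        except Exception as err:  # a failed phantom is recorded, not dropped
            logger.error("%s failed: %s", pid, err)
            failed.append({"phantom_id": pid, "error": str(err)})
            continue
        angle_rows.append(angle_row)
        for r in recs:
            all_records.append(
                {
                    "phantom_id": r.phantom_id,
                    "method": r.method,
                    "depth_mm": r.depth_group_mm,
                    "side": r.side,
                    "angle_deg": "" if r.angle_deg is None else r.angle_deg,
                    "rdt_um": r.value_um,
                }
            )
    columns = ["phantom_id", "method", "depth_mm", "side", "angle_deg", "rdt_um"]
    records = pd.DataFrame(all_records, columns=columns)
    angles = pd.DataFrame(angle_rows, columns=["phantom_id", "angle_deg", "separated"])
    result = _analyse(config, records, angles, failed)
    if config.out_dir is not None:
        _write_outputs(config, result)
    return result


def _analyse(config, records: pd.DataFrame, angles: pd.DataFrame, failed) -> PipelineResult:
    distal = records[records["side"] == "distal"].copy()
    summary: dict = {
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "n_phantoms": config.n_phantoms,
        "n_failed": len(failed),
        "voxel_size_um": config.voxel_size_um,
    }
    anova = None
    dunnett: dict = {}
    icc_rows: list[dict] = []
    if len(distal) > 0 and distal["phantom_id"].nunique() >= 2:
        anova = two_way_anova(distal)
        group = distal.groupby(["method", "depth_mm"])["rdt_um"]
        summary["mean_rdt_um"] = {
            f"{m}_{d:g}mm": float(v) for (m, d), v in group.mean().items()
        }
        summary["sd_rdt_um"] = {
            f"{m}_{d:g}mm": float(v) for (m, d), v in group.std(ddof=1).items()
        }
        for depth in config.depths_mm:
            sub = distal[distal["depth_mm"] == depth]
            dunnett[depth] = dunnett_vs_control(sub)
            wide = sub.pivot(index="phantom_id", columns="method", values="rdt_um")
            for other in ("Pa", "An"):
                for model in ("consistency", "absolute"):
                    res = icc(wide[["3D", other]].to_numpy(), model_tag=model)
                    icc_rows.append(
                        {
                            "depth_mm": depth,
                            "pair": f"{other}-3D",
                            "model": model,
                            "icc": res.icc_value,
                            "n_subjects": res.n_subjects,
                        }
                    )
            summary.setdefault("cv_3d", {})[f"{depth:g}mm"] = coefficient_of_variation(
                wide["3D"].to_numpy()
            )
    icc_table = pd.DataFrame(icc_rows)
    if len(angles) > 0:
        summary["parallax_angle_deg"] = {
            "mean": float(angles["angle_deg"].mean()),
            "sd": float(angles["angle_deg"].std(ddof=1)) if len(angles) > 1 else 0.0,
            "n_separated": int(angles["separated"].sum()),
        }
    if icc_rows:
        summary["icc_consistency"] = {
            f"{r['pair']}_{r['depth_mm']:g}mm": r["icc"]
            for r in icc_rows
            if r["model"] == "consistency"
        }
    return PipelineResult(
        records=records,
        anova=anova,
        dunnett=dunnett,
        icc_table=icc_table,
        angles=angles,
        summary=summary,
        failed=failed,
    )


def _write_outputs(config: RunConfig, result: PipelineResult) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.records.to_csv(out / "records.csv", index=False)
    result.angles.to_csv(out / "angles.csv", index=False)
    result.icc_table.to_csv(out / "icc.csv", index=False)
    if result.anova is not None:
        result.anova.table.to_csv(out / "anova.csv")
    for depth, df in result.dunnett.items():
        df.to_csv(out / f"dunnett_{depth:g}mm.csv", index=False)
    (out / "summary.json").write_text(
        json.dumps(result.summary, sort_keys=True, indent=2)
    )
    logger.info("outputs written to %s", out)
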