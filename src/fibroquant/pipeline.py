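"""End-to-end orchestration: simulate -> project -> measure -> compare.

Stages communicate through tidy CSVs on disk so every intermediate is
inspectable; a JSON manifest records the configuration hash, per-stage row
counts, warnings and a checksum for every output file.  Re-running with the
same configuration and seed reproduces identical files.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .anisotropy import measure_anisotropy
from .ccp import DEFAULT_CCP_THRESHOLD, ccp
from .images import Micrograph, RegionMask
from .mechanics import strain_report
from .morphometry import measure_region, project_max
from .stats import compare_groups, summarise_box
from .synthim import StudyConfig, StudyRecord, generate_study, write_study

__all__ = ["RunConfig", "RunManifest", "measure_study", "compare_study", "run"]

log = logging.getLogger("fibroquant")

METRICS = ("cell_area_um2", "cell_eccentricity", "nucleus_area_um2",
           "anisotropy", "ccp")


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Either ``study`` (simulate mode) or ``design_csv`` + ``image_dir``
    (measure-existing mode) must be provided.
    """

    output_dir: str | Path
    seed: int = 0
    study: StudyConfig | None = None
    design_csv: str | Path | None = None
    image_dir: str | Path | None = None
    metrics: tuple[str, ...] = METRICS
    ccp_threshold: float = DEFAULT_CCP_THRESHOLD
    write_images: bool = False

    def __post_init__(self) -> None:
        if self.study is None and (self.design_csv is None or self.image_dir is None):
            raise ValueError("provide either a StudyConfig or design_csv + image_dir")


@dataclass
class RunManifest:
    config_hash: str
    version: str
    seed: int
    stage_rows: dict[str, int] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)
    outputs: dict[str, str] = field(default_factory=dict)  # path -> sha256

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, sort_keys=True))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _config_hash(config: RunConfig) -> str:
    def default(o):
        if hasattr(o, "__dataclass_fields__"):
            return asdict(o)
        if isinstance(o, Path):
            return str(o)
        if isinstance(o, (np.integer, np.floating)):
            return o.item()
        return str(o)

    def stringify_keys(obj):
        if isinstance(obj, dict):
            return {str(k): stringify_keys(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [stringify_keys(v) for v in obj]
        return obj

    blob = json.dumps(stringify_keys(asdict(config)), default=default, sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def measure_record(
    rec: StudyRecord, ccp_threshold: float = DEFAULT_CCP_THRESHOLD
) -> dict[str, float]:
    """All per-image metrics for one generated record."""
    cell_img = project_max(rec.cell_image)
    nuc_img = project_max(rec.nucleus_image)
    cell_morph = measure_region(rec.cell_mask, cell_img.pixel_size)
    nuc_morph = measure_region(rec.nucleus_mask, nuc_img.pixel_size)
    aniso = measure_anisotropy(cell_img, rec.cell_mask)
    chromatin = ccp(nuc_img, rec.nucleus_mask, ccp_threshold)
    return {
        "cell_area_um2": cell_morph.area_um2,
        "cell_area_px": cell_morph.area_px,
        "cell_eccentricity": cell_morph.eccentricity,
        "nucleus_area_um2": nuc_morph.area_um2,
        "nucleus_area_px": nuc_morph.area_px,
        "anisotropy": aniso.value,
        "orientation_rad": aniso.mean_orientation,
        "ccp": chromatin.value,
        "ccp_edge_pixels": chromatin.edge_pixels,
    }


def measure_study(
    records: list[StudyRecord], ccp_threshold: float = DEFAULT_CCP_THRESHOLD
) -> pd.DataFrame:
    """Tidy long-format measurement table for a generated study.

    One row per (image, metric): columns image_id, group, timepoint, well,
    plate, metric, value.
    """
    rows = []
    for rec in records:
        vals = measure_record(rec, ccp_threshold)
        for metric in METRICS:
            rows.append(
                {
                    "image_id": rec.image_id,
                    "group": rec.group,
                    "timepoint": rec.timepoint,
                    "well": rec.well,
                    "plate": rec.plate,
                    "metric": metric,
                    "value": vals[metric],
                }
            )
    return pd.DataFrame(rows)


def _measure_from_disk(
    design: pd.DataFrame,
    image_dir: Path,
    ccp_threshold: float,
    pixel_size: float = 0.1,
) -> tuple[pd.DataFrame, list[str]]:
    """Measure-existing mode: load image/mask pairs named by the design CSV."""
    rows, warns = [], []
    for _, drow in design.iterrows():
        iid = drow["image_id"]
        try:
            cell_img = Micrograph.from_tiff(
                image_dir / f"{iid}_cell.tif", pixel_size, "cytoskeleton"
            )
            cell_mask = RegionMask.from_tiff(image_dir / f"{iid}_cell_mask.tif")
            nuc_img = Micrograph.from_tiff(
                image_dir / f"{iid}_nucleus.tif", pixel_size, "nucleus"
            )
            nuc_mask = RegionMask.from_tiff(image_dir / f"{iid}_nucleus_mask.tif")
        except (FileNotFoundError, ValueError) as exc:
            msg = f"{iid}: skipped ({exc})"
            warns.append(msg)
            log.warning(msg)
            continue
        rec = StudyRecord(
            image_id=iid, group=drow["group"], timepoint=drow["timepoint"],
            well=drow.get("well", ""), plate=drow.get("plate", ""),
            cell_image=cell_img, cell_mask=cell_mask,
            nucleus_image=nuc_img, nucleus_mask=nuc_mask,
            cell_truth=None, nucleus_truth=None,
        )
        vals = measure_record(rec, ccp_threshold)
        for metric in METRICS:
            rows.append(
                {
                    "image_id": iid, "group": rec.group, "timepoint": rec.timepoint,
                    "well": rec.well, "plate": rec.plate,
                    "metric": metric, "value": vals[metric],
                }
            )
    return pd.DataFrame(rows), warns


def compare_study(measurements: pd.DataFrame) -> pd.DataFrame:
    """Gated comparisons for every (metric, timepoint) family.

    Returns a tidy table with one row per pairwise comparison, carrying the
    family's gate and omnibus result alongside.
    """
    rows = []
    for (metric, tp), fam in measurements.groupby(["metric", "timepoint"], sort=False):
        if fam["group"].nunique() < 2:
            log.warning("family (%s, %s): fewer than 2 groups, skipped", metric, tp)
            continue
        res = compare_groups(fam, metric_name=metric, timepoint=tp)
        for pc in res.pairwise:
            rows.append(
                {
                    "metric": metric, "timepoint": tp, "gate": res.gate,
                    "omnibus_stat": res.omnibus_stat, "omnibus_p": res.omnibus_p,
                    "group_a": pc.group_a, "group_b": pc.group_b,
                    "p": pc.p, "significant": pc.significant, "stars": pc.stars,
                }
            )
    return pd.DataFrame(rows)


def run(config: RunConfig) -> RunManifest:
    """Execute the full pipeline and write all stage outputs plus a manifest.

    Outputs under ``config.output_dir``: ``design.csv``, ``truth.csv``
    (simulate mode), ``measurements.csv``, ``comparisons.csv``,
    ``box_summaries.csv``, ``report.json`` and ``manifest.json``.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        config_hash=_config_hash(config), version=__version__, seed=config.seed
    )

    if config.study is not None:
        log.info("simulate stage: seed=%d", config.seed)
        records, design, truth = generate_study(config.study, config.seed)
        design.to_csv(out / "design.csv", index=False)
        truth.to_csv(out / "truth.csv", index=False)
        if config.write_images:
            write_study(records, design, truth, out)
        measurements = measure_study(records, config.ccp_threshold)
    else:
        design = pd.read_csv(config.design_csv)
        design.to_csv(out / "design.csv", index=False)
        measurements, warns = _measure_from_disk(
            design, Path(config.image_dir), config.ccp_threshold
        )
        manifest.warnings.extend(warns)
    manifest.stage_rows["design"] = len(design)
    manifest.stage_rows["measurements"] = len(measurements)
    measurements.to_csv(out / "measurements.csv", index=False)

    comparisons = compare_study(measurements)
    comparisons.to_csv(out / "comparisons.csv", index=False)
    manifest.stage_rows["comparisons"] = len(comparisons)

    box_rows = []
    for (metric, tp), fam in measurements.groupby(["metric", "timepoint"], sort=False):
        for b in summarise_box(fam):
            box_rows.append({"metric": metric, "timepoint": tp, **asdict(b)})
    boxes = pd.DataFrame(box_rows)
    boxes["outliers"] = boxes["outliers"].map(lambda t: ";".join(map(str, t)))
    boxes.to_csv(out / "box_summaries.csv", index=False)

    # Header report: the loading bands the experiment emulates.
    report = {
        "physiological": strain_report(27.0, 0.0162, 0.0016, 1e6, 7e6),
        "pathological": strain_report(60.0, 0.0162, 0.0016, 1e6, 7e6),
        "n_images": len(design),
        "n_comparison_families": int(
            measurements.groupby(["metric", "timepoint"]).ngroups
        ),
    }
    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))

    for p in sorted(out.glob("*.csv")) + [out / "report.json"]:
        manifest.outputs[p.name] = _sha256(p)
    manifest.to_json(out / "manifest.json")
    return manifest
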