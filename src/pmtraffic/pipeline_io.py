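"""Plate layout, filename schema, and end-to-end pipeline orchestration.

`run_pipeline` wires the two-pipeline design together: illumination
profiles are estimated across the plate per channel, subtracted from each
field, cells are segmented and measured, the three QC levels are applied,
and conditions are scored against the negative control. Every input image
is either processed or listed in the skipped-files table with a reason,
and a rerun with identical inputs and configuration is bit-identical.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage as ndi

from . import __version__
from .config import PipelineConfig
from .core import CHANNEL_ROLES, NUCLEI, TOTAL, FieldImage
from .errors import FilenameParseError, LayoutError
from .image_correction import (
    IlluminationProfile,
    apply_correction,
    background_robust_sd,
    estimate_illumination,
    residual_background,
)
from .quality_control import (
    CellQCThresholds,
    PlateQCResult,
    adaptive_focus_gate,
    assess_image,
    assess_plate_transfection,
    expression_gate_from_background,
    flag_cells,
    focus_score,
)
from .screen_scoring import READOUTS, image_summary, score_screen
from .segmentation import measure_cells, segment_cells, segment_nuclei

WELL_PATTERN = re.compile(r"^[A-Z]{1,2}\d{2}$")
_PLACEHOLDER = re.compile(r"\{(\w+)(?::[^}]*)?\}")
_GROUP_PATTERNS = {
    "well": r"(?P<well>[A-Z]{1,2}\d{2})",
    "field": r"(?P<field>\d+)",
    "channel": r"(?P<channel>[A-Za-z0-9]+)",
}


@dataclass
class FilenameSchema:
    """Configurable filename grammar mapping names to (well, field, channel role).

    ``parse(format(x)) == x`` for every valid identity triple.
    """

    template: str = "{well}_f{field:02d}_ch{channel}.tif"
    channel_map: dict[str, str] = dc_field(
        default_factory=lambda: {"1": "nuclei", "2": "total", "3": "surface"}
    )

    def __post_init__(self) -> None:
        pattern = ""
        last = 0
        for match in _PLACEHOLDER.finditer(self.template):
            name = match.group(1)
            if name not in _GROUP_PATTERNS:
                raise FilenameParseError(f"unknown template field {name!r}")
            pattern += re.escape(self.template[last : match.start()]) + _GROUP_PATTERNS[name]
            last = match.end()
        pattern += re.escape(self.template[last:])
        self._regex = re.compile("^" + pattern + "$")
        self._role_to_token = {role: token for token, role in self.channel_map.items()}

    def format(self, well: str, field: int, channel_role: str) -> str:
        token = self._role_to_token[channel_role]
        return self.template.format(well=well, field=field, channel=token)

    def parse(self, name: str) -> tuple[str, int, str]:
        match = self._regex.match(name)
        if match is None:
            raise FilenameParseError(f"{name!r} does not match template {self.template!r}")
        token = match.group("channel")
        if token not in self.channel_map:
            raise FilenameParseError(f"{name!r}: unknown channel token {token!r}")
        return match.group("well"), int(match.group("field")), self.channel_map[token]


@dataclass
class PlateLayout:
    """Well-to-treatment mapping with control roles."""

    plate_id: str
    table: pd.DataFrame  # columns: well, condition, class, control_role

    def __post_init__(self) -> None:
        required = {"well", "condition", "class", "control_role"}
        missing = required - set(self.table.columns)
        if missing:
            raise LayoutError(
                f"layout is missing columns {sorted(missing)}; expected schema: "
                "well, condition, class, control_role"
            )
        duplicated = self.table["well"][self.table["well"].duplicated()]
        if not duplicated.empty:
            raise LayoutError(f"duplicate well id(s): {sorted(duplicated.unique())}")
        bad_wells = [w for w in self.table["well"] if not WELL_PATTERN.match(str(w))]
        if bad_wells:
            raise LayoutError(f"well ids must follow A01..P24 convention; bad: {bad_wells[:5]}")
        if not (self.table["control_role"] == "negative").any():
            raise LayoutError(
                "layout has no negative-control well; deviation scores are impossible"
            )

    def condition_of(self, well: str) -> str:
        rows = self.table.loc[self.table["well"] == well, "condition"]
        if rows.empty:
            raise LayoutError(f"well {well!r} not present in layout")
        return str(rows.iloc[0])

    @property
    def negative_condition(self) -> str:
        names = sorted(
            self.table.loc[self.table["control_role"] == "negative", "condition"].unique()
        )
        return names[0]

    @property
    def transfection_control_wells(self) -> list[str]:
        mask = self.table["control_role"] == "transfection_control"
        return sorted(self.table.loc[mask, "well"].astype(str))


def load_layout(path: str | Path, plate_id: str = "") -> PlateLayout:
    """Read and validate a layout CSV (columns: well, condition, class, control_role)."""
    table = pd.read_csv(path, keep_default_na=False)  # "NA"-like names stay strings
    return PlateLayout(plate_id=plate_id or Path(path).stem, table=table)


def parse_filename(name: str, schema: FilenameSchema) -> tuple[str, int, str]:
    return schema.parse(name)


@dataclass
class PipelineResult:
    """End-to-end result bundle; ``write`` persists every table as text."""

    cells: pd.DataFrame
    images: pd.DataFrame
    conditions: pd.DataFrame
    hits: pd.DataFrame
    plate_qc: PlateQCResult | None
    skipped: pd.DataFrame
    profiles: dict[str, IlluminationProfile]
    report: str
    manifest: dict

    @property
    def plate_rejected(self) -> bool:
        return self.plate_qc is not None and not self.plate_qc.accepted

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.cells.to_csv(outdir / "cells.csv", index=False)
        self.images.to_csv(outdir / "images.csv", index=False)
        self.conditions.to_csv(outdir / "conditions.csv", index=False)
        self.hits.to_csv(outdir / "hits.csv", index=False)
        self.skipped.to_csv(outdir / "skipped_files.csv", index=False)
        if self.plate_qc is not None:
            pd.DataFrame([vars(self.plate_qc)]).to_csv(outdir / "plate_qc.csv", index=False)
        profile_dir = outdir / "illumination_profiles"
        profile_dir.mkdir(exist_ok=True)
        for role, profile in self.profiles.items():
            profile.save(profile_dir / f"illumination_{role}.tif")
        (outdir / "report.txt").write_text(self.report)
        (outdir / "manifest.json").write_text(json.dumps(self.manifest, indent=2, sort_keys=True))


def _collect_fields(
    image_dir: Path, schema: FilenameSchema, layout: PlateLayout
) -> tuple[dict[tuple[str, int], dict[str, Path]], list[dict]]:
    """Group image files by (well, field); unparseable files are reported, not fatal."""
    groups: dict[tuple[str, int], dict[str, Path]] = {}
    skipped: list[dict] = []
    layout_wells = set(layout.table["well"].astype(str))
    for path in sorted(image_dir.iterdir()):
        if not path.is_file() or path.suffix.lower() not in (".tif", ".tiff"):
            continue
        try:
            well, field, role = schema.parse(path.name)
        except FilenameParseError as exc:
            skipped.append({"file": path.name, "reason": str(exc)})
            continue
        if well not in layout_wells:
            skipped.append({"file": path.name, "reason": f"well {well} not in layout"})
            continue
        groups.setdefault((well, field), {})[role] = path
    complete: dict[tuple[str, int], dict[str, Path]] = {}
    for key, channels in sorted(groups.items()):
        missing = [role for role in CHANNEL_ROLES if role not in channels]
        if missing:
            for role, path in channels.items():
                skipped.append(
                    {"file": path.name, "reason": f"field missing channel(s) {missing}"}
                )
        else:
            complete[key] = channels
    return complete, skipped


def _load_phenotype_flags(image_dir: Path, layout: PlateLayout) -> list[bool] | None:
    """Per-control-image phenotype flags: ground truth in simulation, an
    annotation CSV (well, field, phenotype) on real data."""
    path = image_dir / "phenotype_flags.csv"
    control_wells = set(layout.transfection_control_wells)
    if not path.exists() or not control_wells:
        return None
    table = pd.read_csv(path)
    table = table[table["well"].astype(str).isin(control_wells)]
    if table.empty:
        return None
    return [bool(v) for v in table.sort_values(["well", "field"])["phenotype"]]


def run_pipeline(
    image_dir: str | Path,
    layout: PlateLayout,
    config: PipelineConfig | None = None,
    outdir: str | Path | None = None,
) -> PipelineResult:
    """Run the full analysis on a directory of per-channel TIFF fields."""
    config = config or PipelineConfig()
    image_dir = Path(image_dir)
    schema = FilenameSchema(template=config.filename_template, channel_map=config.channel_map)
    fields, skipped_rows = _collect_fields(image_dir, schema, layout)
    if not fields:
        raise LayoutError(f"no complete multichannel fields found in {image_dir}")

    # acquisition pre-check: wells with fewer fields than the configured minimum
    fields_per_well: dict[str, int] = {}
    for well, _ in fields:
        fields_per_well[well] = fields_per_well.get(well, 0) + 1
    underacquired = sorted(
        w for w, n in fields_per_well.items() if n < config.min_fields_per_replicate
    )

    raw: dict[tuple[str, int], FieldImage] = {
        (well, field): FieldImage(
            well=well,
            field=field,
            channels={role: tifffile.imread(path) for role, path in channels.items()},
            bit_depth=config.bit_depth,
        )
        for (well, field), channels in sorted(fields.items())
    }

    # pipeline 1: per-channel illumination correction functions for the plate
    keys = sorted(raw)
    if len(keys) > config.illumination_max_images:
        idx = np.linspace(0, len(keys) - 1, config.illumination_max_images).astype(int)
        sample_keys = [keys[i] for i in idx]
    else:
        sample_keys = keys
    profiles = {
        role: estimate_illumination(
            [raw[k].channels[role] for k in sample_keys],
            smoothing_scale=config.smoothing_scale,
            channel_role=role,
        )
        for role in CHANNEL_ROLES
    }

    # plate-level transfection QC gates everything downstream
    plate_qc = None
    phenotype_flags = _load_phenotype_flags(image_dir, layout)
    if phenotype_flags is not None:
        plate_qc = assess_plate_transfection(
            phenotype_flags,
            plate_id=layout.plate_id,
            max_failure_fraction=config.plate_max_failure_fraction,
        )

    skipped = pd.DataFrame(skipped_rows, columns=["file", "reason"])
    manifest = {
        "pmtraffic_version": __version__,
        "config_hash": config.content_hash(),
        "n_fields": len(raw),
        "n_skipped_files": len(skipped),
        "underacquired_wells": underacquired,
        "negative_control": layout.negative_condition,
    }

    if plate_qc is not None and not plate_qc.accepted:
        report = _render_report(layout, None, None, None, plate_qc, underacquired)
        result = PipelineResult(
            cells=pd.DataFrame(),
            images=pd.DataFrame(),
            conditions=pd.DataFrame(),
            hits=pd.DataFrame(),
            plate_qc=plate_qc,
            skipped=skipped,
            profiles=profiles,
            report=report,
            manifest=manifest,
        )
        if outdir is not None:
            result.write(outdir)
        return result

    # pipeline 2: correction, segmentation, integration, cell/image QC
    cell_rows: list[dict] = []
    image_rows: list[dict] = []
    summaries = []
    for (well, field), image in sorted(raw.items()):
        condition = layout.condition_of(well)
        corrected = {
            role: apply_correction(image.channels[role], profiles[role], channel_role=role)
            for role in CHANNEL_ROLES
        }
        nuclei = segment_nuclei(
            corrected[NUCLEI],
            min_area=config.nucleus_min_area,
            max_area=config.nucleus_max_area,
            peak_min_distance=config.nucleus_peak_min_distance,
        )
        cells = segment_cells(corrected[TOTAL], nuclei, config.cell_threshold_policy)
        records = measure_cells(
            cells,
            nuclei,
            corrected,
            image.channels,
            bit_depth=config.bit_depth,
            well=well,
            field=field,
        )
        # dilate so cell fringes do not contaminate the background estimate
        cell_mask = ndi.binary_dilation(cells.raster > 0, iterations=2)
        try:
            res_bg = residual_background(corrected[TOTAL], cell_mask)
            robust_sd = background_robust_sd(corrected[TOTAL], cell_mask)
        except Exception:
            res_bg, robust_sd = float("nan"), 0.0
        thresholds = CellQCThresholds(
            min_total_expression=expression_gate_from_background(
                robust_sd, k=config.expression_gate_k
            ),
            max_saturated_fraction=config.max_saturated_fraction,
            area_range=config.cell_area_range,
            min_form_factor=config.min_form_factor,
        )
        records = flag_cells(records, thresholds)
        summary = image_summary(records, well=well, field=field, condition=condition)
        n_pass = sum(r.passes_qc for r in records)
        image_rows.append(
            {
                "well": well,
                "field": field,
                "condition": condition,
                "focus_score": focus_score(corrected[NUCLEI]),
                "residual_background": res_bg,
                "n_cells": len(records),
                "n_cells_pass": n_pass,
            }
        )
        if summary is not None:
            summaries.append(summary)
        for r in records:
            row = {
                "well": r.well,
                "field": r.field,
                "condition": condition,
                "cell": r.cell,
                "nucleus_row": r.nucleus_row,
                "nucleus_col": r.nucleus_col,
                "area": r.area,
                "form_factor": r.form_factor,
                "nucleus_area": r.nucleus_area,
                "integrated_total": r.integrated_total,
                "integrated_surface": r.integrated_surface,
                "integrated_nuclei": r.integrated_nuclei,
                "mean_total": r.mean_total,
                "qc_flags": ";".join(sorted(r.qc_flags)),
                "pass": r.passes_qc,
            }
            for role in CHANNEL_ROLES:
                row[f"saturated_{role}"] = r.saturated_pixel_count[role]
            cell_rows.append(row)

    images_df = pd.DataFrame(image_rows)
    gate = adaptive_focus_gate(
        images_df["focus_score"].to_numpy(), mad_multiplier=config.focus_mad_multiplier
    )
    statuses = []
    for row in image_rows:
        qc = assess_image(
            row["well"],
            row["field"],
            row["focus_score"],
            row["residual_background"],
            row["n_cells_pass"],
            focus_gate=gate,
            background_gate=config.max_residual_background,
            min_cells=config.min_cells_per_image,
        )
        statuses.append(qc.status)
    images_df["qc_status"] = statuses
    status_by_key = {
        (row["well"], row["field"]): status for row, status in zip(image_rows, statuses)
    }
    for summary in summaries:
        summary.qc_status = status_by_key[(summary.well, summary.field)]
    images_df = images_df.merge(
        pd.DataFrame(
            [
                {
                    "well": s.well,
                    "field": s.field,
                    "median_traffic_efficiency": s.median_traffic_efficiency,
                    "median_total": s.median_total,
                    "median_surface": s.median_surface,
                }
                for s in summaries
            ],
            columns=[
                "well",
                "field",
                "median_traffic_efficiency",
                "median_total",
                "median_surface",
            ],
        ),
        on=["well", "field"],
        how="left",
    )

    condition_summaries, hits, excluded = score_screen(
        summaries,
        negative_control=layout.negative_condition,
        k=config.sem_multiplier_k,
        aggregation=config.aggregation,
        welch=config.welch,
    )
    conditions_df = pd.DataFrame(
        [
            {
                "condition": s.condition,
                "n_images": s.n_images,
                **{f"mean_{r}": s.mean[r] for r in READOUTS},
                **{f"sem_{r}": s.sem[r] for r in READOUTS},
            }
            for s in condition_summaries
        ]
    ).sort_values("condition", ignore_index=True)
    hits_df = pd.DataFrame(
        [
            {
                "condition": h.condition,
                "readout": h.readout,
                "deviation_score": h.deviation_score,
                "classification": h.classification,
                "p_value": h.p_value,
                "negative_control": h.negative_control_ref,
                "sem_multiplier": h.sem_multiplier,
            }
            for h in hits
        ]
    )

    manifest["focus_gate"] = gate
    manifest["excluded_conditions"] = excluded
    report = _render_report(layout, images_df, conditions_df, hits_df, plate_qc, underacquired)
    result = PipelineResult(
        cells=pd.DataFrame(cell_rows),
        images=images_df,
        conditions=conditions_df,
        hits=hits_df,
        plate_qc=plate_qc,
        skipped=skipped,
        profiles=profiles,
        report=report,
        manifest=manifest,
    )
    if outdir is not None:
        result.write(outdir)
    return result


def _render_report(
    layout: PlateLayout,
    images: pd.DataFrame | None,
    conditions: pd.DataFrame | None,
    hits: pd.DataFrame | None,
    plate_qc: PlateQCResult | None,
    underacquired: list[str],
) -> str:
    lines = [f"Screen report — plate {layout.plate_id}", "=" * 40]
    if plate_qc is not None:
        verdict = "ACCEPTED" if plate_qc.accepted else "REJECTED"
        lines.append(
            f"Plate transfection QC: {verdict} "
            f"({plate_qc.n_phenotype_positive}/{plate_qc.n_control_images} control images "
            f"phenotype-positive; failure fraction {plate_qc.failure_fraction:.2f})"
        )
        if not plate_qc.accepted:
            lines.append(
                "Plate rejected: transfection phenotype missing in more than 75% of "
                "control images. Scoring was skipped."
            )
            return "\n".join(lines) + "\n"
    else:
        lines.append("Plate transfection QC: skipped (no transfection-control flags)")
    if underacquired:
        lines.append(
            f"Warning: wells below the minimum fields-per-replicate requirement: "
            f"{', '.join(underacquired)}"
        )
    if images is not None:
        n_pass = int((images["qc_status"] == "pass").sum())
        lines.append(f"Images passing QC: {n_pass}/{len(images)}")
    if conditions is not None:
        lines.append(f"Conditions summarized: {len(conditions)}")
    if hits is not None and not hits.empty:
        called = hits[hits["classification"] != "neutral"]
        lines.append(f"Non-neutral calls: {len(called)}")
        for _, h in called.iterrows():
            lines.append(
                f"  {h['condition']} [{h['readout']}]: {h['classification']} "
                f"(score {h['deviation_score']:.2f}, p {h['p_value']:.3g})"
            )
    return "\n".join(lines) + "\n"
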