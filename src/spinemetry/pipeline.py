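"""End-to-end validity analyses on a dataset (synthetic or user-supplied).

Three report shapes are produced:

* **concurrent** — agreement between the IMU chain and the optical chain for
  the nine region x plane measures plus the composite index (ICC(2,1) with
  CI, Pearson r, RMSE, Bland-Altman bias and limits of agreement, SEM, MDC);
* **discriminant** — patient-vs-control group summaries and unpaired t-tests
  per measure;
* **construct** — Pearson correlation matrices of the IMU measures against
  conventional metrology and against clinical outcome variables, with
  significance stars.

Reports are plain tables with deterministic formatting so a (config, seed)
pair maps to byte-identical output files.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import agreement as ag
from .errors import DataError, InvalidParameterError
from .imu_kinematics import (
    absolute_sagittal_angle,
    aggregate_repetitions,
    relative_angle_series,
    repetition_windows,
    rom_by_repetition,
    zero_to_reference,
)
from .metrology import (
    IndexConfig,
    compute_composite_index,
    default_kinematic_index_config,
)
from .mocap_kinematics import SegmentDef, projected_segment_angle_series
from .motion_sim import Dataset
from .resample import ResampleSpec, upsample_linear
from .series import PLANES, Plane, Region

logger = logging.getLogger(__name__)

__all__ = [
    "ReportTable",
    "MEASURES",
    "extract_rom_table",
    "compute_index_scores",
    "measure_matrix",
    "run_concurrent",
    "run_discriminant",
    "run_construct",
    "write_report",
    "read_report",
]

#: the nine reported region x plane measures, in table order
MEASURES: tuple[tuple[Region, Plane], ...] = tuple(
    (region, plane)
    for region in (Region.CERVICAL, Region.L1_ABSOLUTE, Region.LUMBAR)
    for plane in PLANES
)

#: conventional metrology outcome columns (construct-validity anchors)
METROLOGY_COLUMNS = (
    "lateral_flexion_cm",
    "tragus_to_wall_cm",
    "schober_cm",
    "intermalleolar_cm",
    "cervical_rotation_deg",
)

#: clinical outcome columns
OUTCOME_COLUMNS = ("BASDAI", "ASDAS", "BASFI", "ASAS_HI", "BAS_G", "mSASSS")

#: composite-index component -> (region, plane) source measure.  "lumbar
#: flexion" uses the lumbar-region (not trunk) angle; "lateral flexion" uses
#: the trunk (L1-absolute) frontal angle, matching its shoulder+hip origin.
INDEX_COMPONENT_SOURCES: dict[str, tuple[Region, Plane]] = {
    "cervical_flexion": (Region.CERVICAL, Plane.SAGITTAL),
    "cervical_rotation": (Region.CERVICAL, Plane.AXIAL),
    "lumbar_flexion": (Region.LUMBAR, Plane.SAGITTAL),
    "lateral_flexion": (Region.L1_ABSOLUTE, Plane.FRONTAL),
    "lumbar_rotation": (Region.LUMBAR, Plane.AXIAL),
}


def measure_label(region: Region, plane: Plane) -> str:
    return f"{region.value}_{plane.value}"


@dataclass
class ReportTable:
    """One analysis result: a tidy table plus formatting metadata."""

    kind: str
    table: pd.DataFrame
    meta: dict = field(default_factory=dict)


# --------------------------------------------------------------------------- #
# ROM extraction
# --------------------------------------------------------------------------- #

def _protocol_windows(protocol: dict):
    keys = ("lead_in", "cycle_duration", "rest_duration", "n_reps")
    if not all(k in protocol for k in keys):
        return None
    return repetition_windows(
        protocol["lead_in"],
        protocol["cycle_duration"],
        protocol["rest_duration"],
        int(protocol["n_reps"]),
    )


def extract_rom_table(
    ds: Dataset,
    chain: str = "imu",
    rule: str = "max",
    resample: ResampleSpec = ResampleSpec(),
) -> pd.DataFrame:
    """Per-subject, per-measure peak-to-peak ROM for one processing chain.

    ``chain="imu"`` runs reference zeroing → per-plane sensor subtraction
    (plus the absolute trunk angle from the upper lumbar sensor) → 100 Hz
    upsampling → per-repetition ROM aggregation.  ``chain="mocap"`` runs the
    projected marker-segment chain through the same resampling/aggregation.
    Returns columns subject_id, region, plane, rom_deg, rule.
    """
    if chain not in ("imu", "mocap"):
        raise InvalidParameterError("chain must be 'imu' or 'mocap'")
    windows = _protocol_windows(ds.protocol)
    ref_window = float(ds.protocol.get("lead_in", 1.0))
    rows = []
    if chain == "imu":
        for (sid, region, plane), (upper, lower) in sorted(ds.imu.items()):
            upper_z = zero_to_reference(upper, ref_window)
            lower_z = zero_to_reference(lower, ref_window)
            rel = relative_angle_series(upper_z, lower_z, plane, region)
            series_list = [(region, rel)]
            if region is Region.LUMBAR:
                series_list.append(
                    (Region.L1_ABSOLUTE, absolute_sagittal_angle(upper_z, plane))
                )
            for out_region, series in series_list:
                hi = upsample_linear(series, resample)
                result = aggregate_repetitions(
                    rom_by_repetition(hi, windows), rule, out_region, plane
                )
                rows.append(
                    {
                        "subject_id": sid,
                        "region": out_region.value,
                        "plane": plane.value,
                        "rom_deg": result.rom,
                        "rule": result.aggregation_rule,
                    }
                )
    else:
        for (sid, region, plane), (a, b) in sorted(ds.mocap.items()):
            seg = SegmentDef(a.marker_id, b.marker_id, plane, region)
            series = projected_segment_angle_series(a, b, seg, ref_window)
            hi = upsample_linear(series, resample)
            result = aggregate_repetitions(
                rom_by_repetition(hi, windows), rule, region, plane
            )
            rows.append(
                {
                    "subject_id": sid,
                    "region": region.value,
                    "plane": plane.value,
                    "rom_deg": result.rom,
                    "rule": result.aggregation_rule,
                }
            )
    logger.info("extracted %d ROM values via %s chain (rule=%s)", len(rows), chain, rule)
    return pd.DataFrame(rows, columns=["subject_id", "region", "plane", "rom_deg", "rule"])


def _truth_as_rom_table(ds: Dataset, rule: str) -> pd.DataFrame:
    if ds.truth is None:
        raise DataError("dataset has neither recordings nor ground-truth ROMs")
    df = ds.truth.rename(columns={"rom_true_deg": "rom_deg"}).copy()
    df["rule"] = rule
    return df[["subject_id", "region", "plane", "rom_deg", "rule"]]


def compute_index_scores(
    rom_table: pd.DataFrame,
    config: IndexConfig | None = None,
    index_name: str = "IUCOASMI",
) -> pd.DataFrame:
    """Composite 0-10 index per subject from a ROM table.

    Subjects missing any of the five component measures are skipped.
    """
    config = config if config is not None else default_kinematic_index_config()
    rows = []
    for sid, g in rom_table.groupby("subject_id", sort=True):
        lookup = {(r, p): v for r, p, v in zip(g["region"], g["plane"], g["rom_deg"])}
        try:
            components = {
                name: lookup[(region.value, plane.value)]
                for name, (region, plane) in INDEX_COMPONENT_SOURCES.items()
            }
        except KeyError:
            continue
        score = compute_composite_index(components, config, index_name)
        rows.append(
            {
                "subject_id": sid,
                "index": index_name,
                "score": score.score,
                **{f"component_{k}": v for k, v in score.components.items()},
            }
        )
    return pd.DataFrame(rows)


def measure_matrix(
    ds: Dataset,
    rule: str = "max",
    index_config: IndexConfig | None = None,
) -> pd.DataFrame:
    """Wide per-subject matrix: group, nine IMU measures, composite, outcomes.

    Datasets generated without signal rendering fall back to the ground-truth
    ROM table (the measured and true values coincide by construction there).
    """
    if ds.imu:
        rom = extract_rom_table(ds, "imu", rule)
    else:
        rom = _truth_as_rom_table(ds, rule)
    wide = rom.pivot_table(
        index="subject_id", columns=["region", "plane"], values="rom_deg"
    )
    wide.columns = [f"{r}_{p}" for r, p in wide.columns]
    scores = compute_index_scores(rom, index_config, "IUCOASMI")
    if len(scores):
        wide = wide.join(scores.set_index("subject_id")["score"].rename("IUCOASMI"))
    out = ds.subjects.set_index("subject_id").join(wide)
    if ds.outcomes is not None:
        extra = ds.outcomes.set_index("subject_id").drop(columns=["group"], errors="ignore")
        out = out.join(extra)
    return out.reset_index()


# --------------------------------------------------------------------------- #
# validity analyses
# --------------------------------------------------------------------------- #

def run_concurrent(
    ds: Dataset,
    rule: str = "max",
    index_config: IndexConfig | None = None,
    sd_pooled: float | None = None,
) -> ReportTable:
    """Agreement panel between the IMU and optical chains, one row per measure.

    Subjects lacking an optical recording are skipped (with a warning); the
    analysis errors out below 3 usable subjects.  The last row compares the
    composite index computed from each chain.
    """
    if not ds.imu or not ds.mocap:
        raise DataError("concurrent validity requires both IMU and optical recordings")
    imu = extract_rom_table(ds, "imu", rule)
    moc = extract_rom_table(ds, "mocap", rule)
    imu_subjects = set(imu["subject_id"])
    moc_subjects = set(moc["subject_id"])
    skipped = sorted(imu_subjects - moc_subjects)
    if skipped:
        logger.warning("skipping %d subjects without optical recordings: %s",
                       len(skipped), ", ".join(skipped))
    rows = []
    for region, plane in MEASURES:
        a = imu[(imu["region"] == region.value) & (imu["plane"] == plane.value)]
        b = moc[(moc["region"] == region.value) & (moc["plane"] == plane.value)]
        merged = a.merge(b, on="subject_id", suffixes=("_imu", "_moc"))
        if len(merged) < 3:
            raise DataError(
                f"fewer than 3 usable subjects for {measure_label(region, plane)}"
            )
        rep = ag.agreement_report(
            merged["rom_deg_imu"], merged["rom_deg_moc"],
            measure=measure_label(region, plane), units="deg", sd_pooled=sd_pooled,
        )
        rows.append(_report_row(rep))
    s_imu = compute_index_scores(imu, index_config, "IUCOASMI").set_index("subject_id")
    s_moc = compute_index_scores(moc, index_config, "UCOASMI").set_index("subject_id")
    common = s_imu.index.intersection(s_moc.index)
    if len(common) >= 3:
        rep = ag.agreement_report(
            s_imu.loc[common, "score"], s_moc.loc[common, "score"],
            measure="composite_index", units="0-10", sd_pooled=sd_pooled,
        )
        rows.append(_report_row(rep))
    table = pd.DataFrame(rows)
    logger.info("concurrent validity: %d measures, n=%d", len(table), int(table["n"].min()))
    return ReportTable("concurrent", table, {"rule": rule})


def _report_row(rep: ag.AgreementReport) -> dict:
    return {
        "measure": rep.measure,
        "units": rep.units,
        "n": rep.n,
        "icc": rep.icc,
        "icc_ci_lower": rep.icc_ci_95[0],
        "icc_ci_upper": rep.icc_ci_95[1],
        "icc_strength": ag.classify_strength(min(max(rep.icc, -1.0), 1.0), "icc"),
        "r": rep.r,
        "rmse": rep.rmse,
        "bias": rep.bias,
        "loa_lower": rep.loa_lower,
        "loa_upper": rep.loa_upper,
        "sem": rep.sem,
        "mdc": rep.mdc,
    }


def _stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def run_discriminant(
    ds: Dataset,
    variant: str = "pooled",
    rule: str = "max",
    include_outcomes: bool = True,
    index_config: IndexConfig | None = None,
) -> ReportTable:
    """Group comparison (patients vs. controls) per measure.

    Reports each group's mean (SD) and range together with the unpaired
    t-test (pooled Student by default, Welch on request).
    """
    matrix = measure_matrix(ds, rule, index_config)
    groups = sorted(matrix["group"].unique())
    if len(groups) != 2:
        raise DataError(f"discriminant validity requires exactly 2 groups, got {groups}")
    g1, g2 = groups
    measure_cols = [measure_label(r, p) for r, p in MEASURES]
    if "IUCOASMI" in matrix.columns:
        measure_cols.append("IUCOASMI")
    if include_outcomes:
        measure_cols += [c for c in METROLOGY_COLUMNS if c in matrix.columns]
    rows = []
    for col in measure_cols:
        sub = matrix[["group", col]].dropna()
        va = sub.loc[sub["group"] == g1, col].to_numpy()
        vb = sub.loc[sub["group"] == g2, col].to_numpy()
        if va.size < 2 or vb.size < 2:
            continue
        res = ag.ttest_unpaired(va, vb, variant)
        rows.append(
            {
                "measure": col,
                f"{g1}_n": va.size,
                f"{g1}_mean": va.mean(),
                f"{g1}_sd": va.std(ddof=1),
                f"{g1}_min": va.min(),
                f"{g1}_max": va.max(),
                f"{g2}_n": vb.size,
                f"{g2}_mean": vb.mean(),
                f"{g2}_sd": vb.std(ddof=1),
                f"{g2}_min": vb.min(),
                f"{g2}_max": vb.max(),
                "t": res.t,
                "df": res.df,
                "p": res.p,
                "p_display": ag.format_p(res.p),
                "significant": _stars(res.p),
            }
        )
    table = pd.DataFrame(rows)
    logger.info("discriminant validity: %d measures (%s vs %s, %s t-test)",
                len(table), g1, g2, variant)
    return ReportTable("discriminant", table, {"variant": variant, "rule": rule})


def run_construct(
    ds: Dataset,
    groups: tuple[str, ...] = ("axSpA",),
    rule: str = "max",
    index_config: IndexConfig | None = None,
) -> ReportTable:
    """Correlations of IMU measures with metrology and outcome anchors.

    One row per (measure, anchor) pair, tagged with its block (``metrology``
    or ``outcomes``); anchors with zero variance are reported as undefined.
    """
    matrix = measure_matrix(ds, rule, index_config)
    if groups:
        matrix = matrix[matrix["group"].isin(groups)]
    measure_cols = [measure_label(r, p) for r, p in MEASURES]
    if "IUCOASMI" in matrix.columns:
        measure_cols.append("IUCOASMI")
    blocks = [
        ("metrology", [c for c in METROLOGY_COLUMNS if c in matrix.columns]),
        ("outcomes", [c for c in OUTCOME_COLUMNS if c in matrix.columns]),
    ]
    rows = []
    for block, anchors in blocks:
        for anchor in anchors:
            for col in measure_cols:
                sub = matrix[[col, anchor]].dropna()
                if len(sub) < 3:
                    continue
                try:
                    r, p = ag.pearson_test(sub[col], sub[anchor])
                except ag.UndefinedStatisticError:
                    logger.warning("constant column: %s vs %s undefined", col, anchor)
                    rows.append(
                        {"block": block, "measure": col, "anchor": anchor,
                         "n": len(sub), "r": np.nan, "p": np.nan,
                         "p_display": "undefined", "significant": ""}
                    )
                    continue
                rows.append(
                    {
                        "block": block,
                        "measure": col,
                        "anchor": anchor,
                        "n": len(sub),
                        "r": r,
                        "p": p,
                        "p_display": ag.format_p(p),
                        "significant": _stars(p),
                    }
                )
    table = pd.DataFrame(rows)
    logger.info("construct validity: %d correlations in groups %s", len(table), list(groups))
    return ReportTable("construct", table, {"groups": list(groups), "rule": rule})


# --------------------------------------------------------------------------- #
# report persistence
# --------------------------------------------------------------------------- #

#: display decimals per column family (angles/cm 1, ICC/r 3, scores 2)
_ONE_DECIMAL = (
    "rmse", "bias", "loa_lower", "loa_upper", "sem", "mdc",
    "_mean", "_sd", "_min", "_max",
)
_THREE_DECIMAL = ("icc", "icc_ci_lower", "icc_ci_upper", "r", "t", "df")


def _format_cell(col: str, value):
    if isinstance(value, float):
        if col == "p":
            return ag.format_p(value)
        if col in _THREE_DECIMAL:
            return f"{value:.3f}"
        if col in _ONE_DECIMAL or any(col.endswith(s) for s in _ONE_DECIMAL):
            return f"{value:.1f}"
        return f"{value:.6g}"
    return value


def write_report(report: ReportTable, path: str | Path, format: str = "csv") -> Path:
    """Persist a report deterministically (fixed decimals, sorted JSON keys)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if format == "csv":
        formatted = report.table.copy()
        for col in formatted.columns:
            formatted[col] = [_format_cell(col, v) for v in formatted[col]]
        formatted.to_csv(path, index=False)
    elif format == "json":
        payload = {
            "kind": report.kind,
            "meta": report.meta,
            "columns": list(report.table.columns),
            "rows": json.loads(report.table.to_json(orient="records", double_precision=10)),
        }
        path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    else:
        raise InvalidParameterError("format must be 'csv' or 'json'")
    return path


def read_report(path: str | Path) -> ReportTable:
    """Load a JSON report written by :func:`write_report`."""
    payload = json.loads(Path(path).read_text())
    table = pd.DataFrame(payload["rows"])
    if "columns" in payload and len(table):
        table = table[payload["columns"]]
    return ReportTable(payload["kind"], table, payload.get("meta", {}))
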