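"""Plate CSV and report readers/writers.

Plate files are long-format CSV, one row per well::

    well,role,group_id,concentration,od450
    A1,blank,blank,,0.10
    A4,standard,std_20,20.0,1.05

``concentration`` is the Gal-BSA-equivalent concentration of the pre-mix
lysate in µg/mL, present only for ``role=standard``.  Lines starting
with ``#`` are comments.  Wells follow the row-major A1–H12 convention.

JSON is the canonical machine report; CSV and text renderings are
projections of it.  All numeric output uses a period decimal separator
regardless of locale.
"""

from __future__ import annotations

import csv
import json
import re
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .core import (
    CalibrationFit,
    ConfigurationError,
    GalQuantError,
    PlateReadout,
    PlateWell,
    QCReport,
    ROLES,
    SampleResult,
    format_count,
    format_percent,
)

__all__ = [
    "read_plate_csv",
    "write_plate_csv",
    "read_calibration_json",
    "write_calibration_json",
    "write_report",
]

_WELL_RE = re.compile(r"^([A-H])(\d{1,2})$")
_PLATE_COLUMNS = ["well", "role", "group_id", "concentration", "od450"]


def _parse_well_id(well: str) -> tuple[str, int]:
    m = _WELL_RE.match(str(well).strip().upper())
    if not m:
        raise ConfigurationError(f"malformed well id {well!r} (expected e.g. 'A1')")
    return m.group(1), int(m.group(2))


def read_plate_csv(path: str | Path) -> PlateReadout:
    """Read a long-format plate CSV into a validated :class:`PlateReadout`."""
    path = Path(path)
    df = pd.read_csv(path, comment="#", dtype=str, skip_blank_lines=True)
    missing = [c for c in _PLATE_COLUMNS if c not in df.columns]
    if missing:
        raise ConfigurationError(
            f"{path.name}: missing column(s) {missing}; expected {_PLATE_COLUMNS}"
        )
    wells: list[PlateWell] = []
    for i, rec in enumerate(df.to_dict("records"), start=2):  # header is line 1
        row, col = _parse_well_id(rec["well"])
        role = str(rec["role"]).strip()
        if role not in ROLES:
            raise ConfigurationError(
                f"{path.name} row {i}: unknown role {role!r}; "
                f"allowed: {sorted(ROLES)}"
            )
        raw_conc = rec.get("concentration")
        conc = None
        if raw_conc is not None and str(raw_conc).strip() not in ("", "nan"):
            conc = float(raw_conc)
        try:
            od = float(rec["od450"])
            wells.append(
                PlateWell(
                    row=row,
                    column=col,
                    role=role,
                    od450=od,
                    group_id=str(rec.get("group_id") or "").strip(),
                    concentration=conc,
                )
            )
        except GalQuantError as exc:
            raise ConfigurationError(f"{path.name} row {i}: {exc}") from exc
        except ValueError as exc:
            raise ConfigurationError(
                f"{path.name} row {i}: bad numeric value ({exc})"
            ) from exc
    return PlateReadout(wells=wells, plate_id=path.stem)


def write_plate_csv(plate: PlateReadout, path: str | Path) -> Path:
    """Write a plate in the dialect :func:`read_plate_csv` reads.
    Round-trips the data model exactly (up to float text precision)."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        fh.write("# galquant plate CSV; concentration = pre-mix lysate µg/mL "
                 "Gal-BSA equivalent (standards only)\n")
        writer = csv.writer(fh)
        writer.writerow(_PLATE_COLUMNS)
        for w in plate.wells:
            writer.writerow(
                [
                    w.well_id,
                    w.role,
                    w.group_id,
                    "" if w.concentration is None else repr(w.concentration),
                    repr(w.od450),
                ]
            )
    return path


# ---------------------------------------------------------------------------
# Calibration JSON
# ---------------------------------------------------------------------------


def write_calibration_json(fit: CalibrationFit, path: str | Path) -> Path:
    path = Path(path)
    payload = {
        "A": fit.A,
        "t": fit.t,
        "y0": fit.y0,
        "residual_ss": fit.residual_ss,
        "converged": fit.converged,
        "x_min": fit.x_min,
        "x_max": fit.x_max,
        "ldl": fit.ldl,
        "ldl_anchored": fit.ldl_anchored,
        "n_points": fit.n_points,
    }
    path.write_text(json.dumps(payload, indent=2) + "\n")
    return path


def read_calibration_json(path: str | Path) -> CalibrationFit:
    data = json.loads(Path(path).read_text())
    return CalibrationFit(
        A=data["A"],
        t=data["t"],
        y0=data["y0"],
        residual_ss=data.get("residual_ss", float("nan")),
        converged=data["converged"],
        x_min=data["x_min"],
        x_max=data["x_max"],
        ldl=data.get("ldl"),
        ldl_anchored=data.get("ldl_anchored", True),
        n_points=data.get("n_points", 0),
    )


# ---------------------------------------------------------------------------
# Reports
# ---------------------------------------------------------------------------


def _gate_to_dict(gate) -> dict | None:
    if gate is None:
        return None
    return {
        "passed": gate.passed,
        "p_value": gate.p_value,
        "statistic": gate.statistic,
        **gate.details,
    }


def _sample_to_dict(res: SampleResult, fit: CalibrationFit | None) -> dict:
    d: dict = {
        "sample_id": res.sample_id,
        "n_replicates": res.n_replicates,
        "inhibition_mean_percent": res.inhibition_mean,
        "inhibition_sd_percent": res.inhibition_sd,
        "dilution_factor": res.dilution_factor,
        "censoring": res.censoring,
    }
    if res.censoring == "quantified":
        d["concentration_ug_per_ml"] = res.concentration
        d["epitope_count"] = res.quantity.count
        d["epitope_count_display"] = format_count(res.quantity.count)
        d["basis"] = res.quantity.basis
        d["galbsa_equivalent_mass_g"] = res.quantity.galbsa_equivalent_mass
    elif res.censoring == "below_ldl":
        d["concentration_ug_per_ml"] = None
        ldl = fit.ldl if fit is not None else None
        d["display"] = f"< LDL ({ldl:g} µg/mL)" if ldl is not None else "< LDL"
    else:
        d["concentration_ug_per_ml"] = None
        d["display"] = "above calibrated range"
    return d


def _report_payload(
    results: Sequence[SampleResult],
    qc: QCReport | None,
    fit: CalibrationFit | None,
) -> dict:
    payload: dict = {"samples": [_sample_to_dict(r, fit) for r in results]}
    if fit is not None:
        payload["calibration"] = {
            "A": fit.A,
            "t": fit.t,
            "y0": fit.y0,
            "residual_ss": fit.residual_ss,
            "converged": fit.converged,
            "x_min": fit.x_min,
            "x_max": fit.x_max,
            "ldl": fit.ldl,
        }
    if qc is not None:
        rep = qc.repeatability
        payload["qc"] = {
            "negative_gate": _gate_to_dict(qc.negative_gate),
            "positive_gate": _gate_to_dict(qc.positive_gate),
            "repeatability": rep,
        }
    return payload


def _render_text(payload: dict) -> str:
    lines: list[str] = []
    if "calibration" in payload:
        cal = payload["calibration"]
        lines.append("Calibration  Y = A*exp(-x/t) + y0")
        lines.append(
            f"  A={cal['A']:.4g}  t={cal['t']:.4g} ug/mL  y0={cal['y0']:.4g}  "
            f"residual SS={cal['residual_ss']:.4g}"
        )
        ldl = cal["ldl"]
        lines.append(
            f"  range [{cal['x_min']:g}, {cal['x_max']:g}] ug/mL"
            + (f"  LDL={ldl:g} ug/mL" if ldl is not None else "")
        )
    if payload.get("samples"):
        lines.append("Samples")
        for s in payload["samples"]:
            inh = format_percent(s["inhibition_mean_percent"])
            sd = s["inhibition_sd_percent"]
            sd_txt = format_percent(sd) if sd is not None else "NA"
            if s["censoring"] == "quantified":
                body = (
                    f"{s['epitope_count_display']} epitopes ({s['basis']}), "
                    f"{s['concentration_ug_per_ml']:.4g} ug/mL"
                )
            else:
                body = s.get("display", s["censoring"])
            lines.append(
                f"  {s['sample_id']}: inhibition {inh}% (SD {sd_txt}), {body}"
            )
    if payload.get("qc"):
        lines.append("QC")
        neg = payload["qc"]["negative_gate"]
        if neg:
            lines.append(
                f"  negative specificity: {'PASS' if neg['passed'] else 'FAIL'}"
                + (f" (p={neg['p_value']:.3f})" if neg["p_value"] is not None else "")
            )
        pos = payload["qc"]["positive_gate"]
        if pos:
            lines.append(
                f"  positive accuracy: {'PASS' if pos['passed'] else 'FAIL'} "
                f"(deviation {pos['deviation_percent']:.2f}% of certified)"
            )
        rep = payload["qc"]["repeatability"]
        if rep:
            for k, v in rep.items():
                if v is not None:
                    lines.append(f"  {k} CV: {format_percent(v['cv_percent'])}%")
    return "\n".join(lines) + "\n"


def write_report(
    results: Sequence[SampleResult],
    qc: QCReport | None,
    path: str | Path,
    format: str = "json",
    fit: CalibrationFit | None = None,
) -> Path:
    """Write a quantification/QC report.  ``format`` is json (canonical),
    csv (sample table only) or text (human-readable)."""
    path = Path(path)
    qc_payload = qc
    if qc is not None and qc.repeatability is not None:
        rep = {
            k: (v if v is None or isinstance(v, dict) else {
                "mean": v.mean, "sd": v.sd, "cv_percent": v.cv_percent, "n": v.n
            })
            for k, v in qc.repeatability.items()
        }
        qc_payload = QCReport(
            negative_gate=qc.negative_gate, positive_gate=qc.positive_gate,
            repeatability=rep,
        )
    payload = _report_payload(results, qc_payload, fit)
    if format == "json":
        path.write_text(json.dumps(payload, indent=2) + "\n")
    elif format == "csv":
        pd.DataFrame(payload["samples"]).to_csv(path, index=False)
    elif format == "text":
        path.write_text(_render_text(payload))
    else:
        raise ConfigurationError(f"unknown report format {format!r}")
    return path
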