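"""NONMEM-style longitudinal dataset reader/writer.

Column dialect (CSV): ``ID, TIME, AMT, RATE, EVID, DVID, DV, MDV, BLQ, AGE,
WT, SCR, CLCR`` with optional ``ALB`` (albumin, g/L) and ``TBIL`` (total
bilirubin, µmol/L).  Dose rows carry ``EVID=1, MDV=1, AMT>0, RATE>0``
(infusion duration = AMT/RATE); observation rows carry ``EVID=0`` with
``DVID`` 1 for unbound serum and 2 for periprostatic tissue.  Times are
hours from the start of the first infusion.  ``CLCR`` is optional: it is
recomputed by Cockcroft–Gault from AGE/WT/SCR when absent, and a warning is
emitted when a supplied value disagrees with the formula by more than 5%.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .pkmodel import (
    SERUM,
    TISSUE,
    DoseEvent,
    Observation,
    SubjectCovariates,
    SubjectRecord,
    cockcroft_gault,
)

__all__ = ["read_dataset", "write_dataset", "DatasetError"]

_COLUMNS = ["ID", "TIME", "AMT", "RATE", "EVID", "DVID", "DV", "MDV", "BLQ", "AGE", "WT", "SCR", "CLCR"]
_OPTIONAL = ["ALB", "TBIL"]
_DVID_TO_CHANNEL = {1: SERUM, 2: TISSUE}
_CHANNEL_TO_DVID = {SERUM: 1, TISSUE: 2}


class DatasetError(ValueError):
    """Raised when a dataset file violates the dialect; lists offending rows."""


def read_dataset(path) -> list[SubjectRecord]:
    """Read and validate a NONMEM-style CSV into subject records."""
    df = pd.read_csv(path)
    missing = [c for c in _COLUMNS if c not in df.columns and c != "CLCR"]
    if missing:
        raise DatasetError(f"{path}: missing required columns {missing}")

    errors: list[str] = []
    subjects: list[SubjectRecord] = []
    for sid, grp in df.groupby("ID", sort=False):
        lines = grp.index + 2  # header + 1-based
        times = grp["TIME"].to_numpy(dtype=float)
        if np.any(times < 0):
            errors.append(f"ID {sid}: negative TIME (line {lines[times < 0][0]})")
        if not np.all(np.diff(times) >= 0):
            bad = lines[1:][np.diff(times) < 0]
            errors.append(f"ID {sid}: TIME not sorted (line {bad[0]})")

        first = grp.iloc[0]
        try:
            extra = {}
            if "ALB" in grp.columns and np.isfinite(first.get("ALB", np.nan)):
                extra["albumin"] = float(first["ALB"])
            if "TBIL" in grp.columns and np.isfinite(first.get("TBIL", np.nan)):
                extra["bilirubin"] = float(first["TBIL"])
            clcr = None
            if "CLCR" in grp.columns and np.isfinite(first.get("CLCR", np.nan)):
                clcr = float(first["CLCR"])
                derived = cockcroft_gault(float(first["AGE"]), float(first["WT"]), float(first["SCR"]))
                if abs(clcr - derived) / derived > 0.05:
                    warnings.warn(
                        f"ID {sid}: supplied CLCR {clcr:.1f} differs from Cockcroft–Gault "
                        f"{derived:.1f} by more than 5%",
                        RuntimeWarning,
                        stacklevel=2,
                    )
            cov = SubjectCovariates(
                age=float(first["AGE"]),
                weight=float(first["WT"]),
                serum_creatinine=float(first["SCR"]),
                clcr=clcr,
                **extra,
            )
        except (ValueError, KeyError) as exc:
            errors.append(f"ID {sid}: invalid covariates ({exc})")
            continue

        doses: list[DoseEvent] = []
        observations: list[Observation] = []
        n_tissue = 0
        for line, (_, row) in zip(lines, grp.iterrows()):
            if int(row["EVID"]) == 1:
                if not (row["AMT"] > 0 and row["RATE"] > 0 and int(row["MDV"]) == 1):
                    errors.append(f"ID {sid}: invalid dose row (line {line})")
                    continue
                doses.append(
                    DoseEvent(float(row["TIME"]), float(row["AMT"]), float(row["AMT"] / row["RATE"]))
                )
            else:
                if row["DV"] < 0:
                    errors.append(f"ID {sid}: negative DV (line {line})")
                    continue
                dvid = int(row["DVID"])
                if dvid not in _DVID_TO_CHANNEL:
                    errors.append(f"ID {sid}: unknown DVID {dvid} (line {line})")
                    continue
                if dvid == 2:
                    n_tissue += 1
                    if n_tissue > 1:
                        errors.append(f"ID {sid}: more than one tissue (DVID=2) row (line {line})")
                        continue
                observations.append(
                    Observation(
                        float(row["TIME"]),
                        float(row["DV"]),
                        _DVID_TO_CHANNEL[dvid],
                        below_lloq=bool(int(row["BLQ"])),
                    )
                )
        if errors:
            continue
        subjects.append(SubjectRecord(int(sid), cov, doses, observations))
    if errors:
        raise DatasetError("dataset validation failed:\n  " + "\n  ".join(errors))
    return subjects


def write_dataset(subjects, path) -> pd.DataFrame:
    """Write subject records to the CSV dialect; returns the frame written."""
    subjects = list(subjects.subjects) if hasattr(subjects, "subjects") else list(subjects)
    rows = []
    for s in subjects:
        c = s.covariates
        base = {
            "ID": s.subject_id, "AGE": c.age, "WT": c.weight, "SCR": c.serum_creatinine,
            "CLCR": c.clcr, "ALB": c.albumin, "TBIL": c.bilirubin,
        }
        events = [
            {**base, "TIME": d.start_time, "AMT": d.amount, "RATE": d.amount / d.infusion_duration,
             "EVID": 1, "DVID": 0, "DV": 0.0, "MDV": 1, "BLQ": 0, "_ord": 0}
            for d in s.doses
        ] + [
            {**base, "TIME": o.time, "AMT": 0.0, "RATE": 0.0, "EVID": 0,
             "DVID": _CHANNEL_TO_DVID[o.channel], "DV": o.value, "MDV": 0,
             "BLQ": int(o.below_lloq), "_ord": 1}
            for o in s.observations
        ]
        events.sort(key=lambda r: (r["TIME"], r["_ord"], r["DVID"]))
        rows.extend(events)
    df = pd.DataFrame(rows, columns=_COLUMNS + _OPTIONAL + ["_ord"]).drop(columns="_ord")
    df.to_csv(path, index=False, float_format="%.17g")
    return df
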