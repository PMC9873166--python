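"""CSV and configuration I/O for clinical-format series and parameter sets.

The on-disk data format is a two-file CSV pair mirroring how anemia
treatment records are kept: an Hb file (``time_days, hb_g_dl``) and an ESA
file (``time_days, dose``) holding non-zero administrations only.  A
``date`` column with ISO-8601 dates may replace ``time_days``; dates are
converted to day offsets from the earliest record across both files.
Configuration files are flat YAML key-value mappings using the published
parameter symbol names; unknown keys are rejected.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .metrics import ClinicalSeries
from .model import PatientParams, TreatmentParams, params_from_dict, params_to_dict

__all__ = [
    "read_series",
    "write_series",
    "read_config",
    "write_config",
    "RunManifest",
    "write_manifest",
]


def _load_channel(path, value_col: str, kind: str):
    """Read one CSV channel, returning (times_in_days, values, line_numbers)."""
    path = Path(path)
    df = pd.read_csv(path)
    lines = np.arange(2, len(df) + 2)  # header is line 1
    if "time_days" in df.columns:
        t = pd.to_numeric(df["time_days"], errors="coerce").to_numpy(dtype=float)
    elif "date" in df.columns:
        dates = pd.to_datetime(df["date"], errors="coerce", format="ISO8601")
        if dates.isna().any():
            bad = lines[dates.isna().to_numpy()]
            raise ValueError(f"{path}: malformed date on line(s) {bad.tolist()}")
        t = (dates - dates.min()).dt.total_seconds().to_numpy() / 86400.0
    else:
        raise ValueError(f"{path}: need a 'time_days' or 'date' column")
    if value_col not in df.columns:
        raise ValueError(f"{path}: missing required column '{value_col}'")
    v = pd.to_numeric(df[value_col], errors="coerce").to_numpy(dtype=float)

    errors = []
    bad = ~np.isfinite(t) | ~np.isfinite(v)
    for ln in lines[bad]:
        errors.append(f"{path}: malformed row on line {ln}")
    tc, vc, lc = t[~bad], v[~bad], lines[~bad]
    order = np.diff(tc) <= 0
    for ln in lc[1:][order]:
        errors.append(f"{path}: {kind} times not strictly increasing at line {ln}")
    nonpos = vc <= 0
    for ln in lc[nonpos]:
        if kind == "Hb":
            errors.append(f"{path}: non-positive Hb value on line {ln}")
        else:
            errors.append(
                f"{path}: non-positive dose on line {ln} "
                "(zero doses are implicit and must not be recorded)"
            )
    if errors:
        raise ValueError("; ".join(errors))
    return t, v


def read_series(hb_csv, esa_csv, patient_id=None) -> ClinicalSeries:
    """Load and validate a clinical-format (Hb, ESA) CSV pair.

    Both files may carry either ``time_days`` or ISO-8601 ``date`` columns;
    with dates, day offsets are measured from the earliest record of the
    pair.  Validation failures report the offending line numbers.
    """
    hb_df = pd.read_csv(hb_csv, nrows=1)
    esa_df = pd.read_csv(esa_csv, nrows=1)
    use_dates = "date" in hb_df.columns or "date" in esa_df.columns

    hb_t, hb_v = _load_channel(hb_csv, "hb_g_dl", "Hb")
    esa_t, esa_v = _load_channel(esa_csv, "dose", "ESA")
    if use_dates:
        # re-anchor both channels to the earliest date of the pair
        def first_date(path):
            df = pd.read_csv(path)
            return pd.to_datetime(df["date"], format="ISO8601").min() \
                if "date" in df.columns else None

        starts = [d for d in (first_date(hb_csv), first_date(esa_csv)) if d is not None]
        origin = min(starts)
        for path, t in ((hb_csv, hb_t), (esa_csv, esa_t)):
            d0 = first_date(path)
            if d0 is not None:
                t += (d0 - origin).total_seconds() / 86400.0
    return ClinicalSeries(hb_times=hb_t, hb_values=hb_v,
                          esa_times=esa_t, esa_doses=esa_v,
                          patient_id=patient_id)


def write_series(series: ClinicalSeries, hb_csv, esa_csv) -> None:
    """Write a series as the clinical-format CSV pair (UTF-8, '.' decimal)."""
    pd.DataFrame({"time_days": series.hb_times, "hb_g_dl": series.hb_values}) \
        .to_csv(hb_csv, index=False)
    pd.DataFrame({"time_days": series.esa_times, "dose": series.esa_doses}) \
        .to_csv(esa_csv, index=False)


def read_config(path) -> tuple[PatientParams, TreatmentParams]:
    """Parameter sets from a flat YAML key-value file (unknown keys error)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a flat key-value mapping")
    return params_from_dict(cfg)


def write_config(path, patient: PatientParams, treatment: TreatmentParams) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(params_to_dict(patient, treatment), fh,
                       default_flow_style=False, sort_keys=True)


@dataclass
class RunManifest:
    """Everything needed to re-run a command bit-identically."""

    command: str
    parameters: dict
    seed: object
    package_version: str
    extras: dict = field(default_factory=dict)
    created: str | None = None


def write_manifest(path, command: str, patient: PatientParams,
                   treatment: TreatmentParams, seed, created: str | None = None,
                   **extras) -> RunManifest:
    from . import __version__

    man = RunManifest(command=command,
                      parameters=params_to_dict(patient, treatment),
                      seed=int(seed) if isinstance(seed, (int, np.integer)) else str(seed),
                      package_version=__version__, extras=extras, created=created)
    with open(path, "w") as fh:
        json.dump(asdict(man), fh, indent=2, sort_keys=True)
        fh.write("\n")
    return man
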