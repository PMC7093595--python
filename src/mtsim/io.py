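"""Event-record dataset I/O (NONMEM-convention CSV dialect).

One row per event.  Columns: ID, TIME (day), EVID (0 observation / 1 dose),
AMT (mg, dose rows only), DV (ANC G/L, observation rows only), MDV
(missing-DV flag), CRP (mg/L, observation rows; empty when not measured) and
BSA (m2, constant within ID).  Times are days from each patient's
maintenance-therapy start.  Floats are written with 6 significant digits and
rows in (ID, TIME, EVID) order, so write -> read -> write is byte-stable.
"""

from __future__ import annotations

import hashlib
import json
from typing import Sequence

import numpy as np
import pandas as pd

from .cohort import PatientRecord
from .pkpd import DoseSchedule

__all__ = ["COLUMNS", "read_cohort", "write_cohort", "write_manifest",
           "CohortFormatError"]

COLUMNS = ["ID", "TIME", "EVID", "AMT", "DV", "MDV", "CRP", "BSA"]


class CohortFormatError(ValueError):
    """Schema or consistency violation in an event-record file."""


def _fmt(x) -> str:
    if x is None or (isinstance(x, float) and np.isnan(x)):
        return ""
    return f"{x:.6g}"


def write_cohort(records: Sequence[PatientRecord], path) -> None:
    """Write records in the canonical event-record dialect."""
    lines = [",".join(COLUMNS)]
    for rec in records:
        rows = []
        for t, a in zip(rec.doses.times, rec.doses.amounts):
            rows.append((t, 1, a, np.nan, 1, np.nan))
        for t, y, c in zip(rec.obs_times, rec.anc, rec.crp):
            rows.append((t, 0, np.nan, y, 0, c))
        rows.sort(key=lambda r: (r[0], r[1]))
        for t, evid, amt, dv, mdv, crp in rows:
            lines.append(",".join([
                rec.id, _fmt(t), str(evid), _fmt(amt) if evid == 1 else "",
                _fmt(dv) if evid == 0 else "", str(mdv),
                _fmt(crp) if evid == 0 else "", _fmt(rec.bsa)]))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_cohort(path) -> list:
    """Read an event-record CSV into validated :class:`PatientRecord`s.

    Violations are reported with the offending column and 1-based row
    number (header = row 1).
    """
    df = pd.read_csv(path, dtype={"ID": str}, keep_default_na=True)
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise CohortFormatError(f"missing columns: {missing}")
    df = df[COLUMNS]
    records = []
    for pid, grp in df.groupby("ID", sort=True):
        rows = grp.index.to_numpy() + 2  # 1-based file rows incl. header
        t = grp["TIME"].to_numpy(dtype=float)
        if np.any(np.isnan(t)):
            raise CohortFormatError(f"ID {pid}: missing TIME at row "
                                    f"{rows[np.isnan(t)][0]}")
        if np.any(np.diff(t) < 0):
            bad = rows[1:][np.diff(t) < 0][0]
            raise CohortFormatError(f"ID {pid}: TIME not nondecreasing at row {bad}")
        evid = grp["EVID"].to_numpy()
        if not np.isin(evid, (0, 1)).all():
            bad = rows[~np.isin(evid, (0, 1))][0]
            raise CohortFormatError(f"ID {pid}: EVID must be 0 or 1 at row {bad}")
        bsa = grp["BSA"].to_numpy(dtype=float)
        if np.any(np.isnan(bsa)) or not np.allclose(bsa, bsa[0]):
            raise CohortFormatError(f"ID {pid}: BSA must be present and "
                                    f"constant within ID")
        is_dose = evid == 1
        amt = grp["AMT"].to_numpy(dtype=float)
        dv = grp["DV"].to_numpy(dtype=float)
        mdv = grp["MDV"].to_numpy(dtype=float)
        if np.any(np.isnan(amt[is_dose])):
            bad = rows[is_dose][np.isnan(amt[is_dose])][0]
            raise CohortFormatError(f"ID {pid}: dose row without AMT at row {bad}")
        if np.any(~np.isnan(amt[~is_dose])):
            bad = rows[~is_dose][~np.isnan(amt[~is_dose])][0]
            raise CohortFormatError(f"ID {pid}: AMT on observation row {bad}")
        obs = ~is_dose & (mdv == 0)
        if np.any(np.isnan(dv[obs])):
            bad = rows[obs][np.isnan(dv[obs])][0]
            raise CohortFormatError(f"ID {pid}: observation without DV at row {bad}")
        records.append(PatientRecord(
            id=str(pid), bsa=float(bsa[0]),
            doses=DoseSchedule(t[is_dose], amt[is_dose]),
            obs_times=t[obs], anc=dv[obs],
            crp=grp["CRP"].to_numpy(dtype=float)[obs]))
    return records


def write_manifest(path, seed, config=None, extra=None) -> None:
    """Reproducibility manifest: seed, package version and a hash of the
    generating configuration."""
    from . import __version__

    cfg = {} if config is None else {
        k: (list(v) if isinstance(v, tuple) else v)
        for k, v in vars(config).items()}
    payload = {
        "seed": int(seed),
        "mtsim_version": __version__,
        "config": cfg,
        "config_sha256": hashlib.sha256(
            json.dumps(cfg, sort_keys=True).encode()).hexdigest(),
    }
    if extra:
        payload.update(extra)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
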