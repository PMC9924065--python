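"""Dataset dialect (event-record CSV) and run configuration.

The on-disk format follows the pharmacometric event-record convention: one
comma-separated row per dose event or observation, missing values as ".".

Columns
-------
ID       subject identifier
TIME     decimal hours from the first CPG2 dose (HD-MTX infusions in phase-2
         files therefore carry negative times)
EVID     0 = observation, 1 = dose
AMT      dose amount (U for CPG2, umol for MTX); "." on observation rows
DUR      infusion duration (h); 0 = bolus
CMT      1 = CPG2, 2 = MTX central, 3 = MTX peripheral
DV       observed concentration (mg/L CPG2, umol/L MTX); "." on dose rows
MDV      missing-DV flag (1 on dose rows)
BLQ      below-LLOQ flag
NOM      nominal schedule label of an observation ("." when absent)
WT HT BSA AGE SCR   covariates, repeated on every row of a subject

Within a subject rows are sorted by time, observations before doses at equal
times (an observation at a dose instant reads the pre-dose state).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .models import Covariates, DoseEvent
from .records import Observation, SubjectRecord

__all__ = ["COLUMNS", "write_dataset", "read_dataset", "RunConfig",
           "require_covariates"]

COLUMNS = ["ID", "TIME", "EVID", "AMT", "DUR", "CMT", "DV", "MDV", "BLQ",
           "NOM", "WT", "HT", "BSA", "AGE", "SCR"]

_CMT_OF = {("CPG2", "central"): 1, ("MTX", "central"): 2, ("MTX", "peripheral"): 3}
_ANALYTE_OF = {1: ("CPG2", "central"), 2: ("MTX", "central"), 3: ("MTX", "peripheral")}
MISSING = "."


def _fmt(x) -> str:
    return MISSING if x is None else repr(float(x)) if isinstance(x, float) else str(x)


def write_dataset(records: list[SubjectRecord], path) -> None:
    """Write subject records to the event-record CSV dialect (lossless
    round trip with :func:`read_dataset` up to simulator-only truth)."""
    lines = [",".join(COLUMNS)]
    for rec in records:
        cov = rec.covariates
        cov_cells = [_fmt(cov.body_weight), _fmt(cov.height), _fmt(cov.bsa),
                     _fmt(cov.age), _fmt(cov.serum_creatinine)]
        rows = []
        for o in rec.observations:
            cmt = _CMT_OF[(o.analyte, "central")]
            rows.append((o.time, 0, [rec.id, _fmt(o.time), "0", MISSING, "0",
                                     str(cmt), _fmt(o.value), "0",
                                     "1" if o.below_lloq else "0",
                                     o.nominal or MISSING] + cov_cells))
        for d in rec.doses:
            cmt = _CMT_OF[(d.analyte, d.compartment)]
            rows.append((d.time, 1, [rec.id, _fmt(d.time), "1", _fmt(d.amount),
                                     _fmt(d.infusion_duration), str(cmt),
                                     MISSING, "1", "0", MISSING] + cov_cells))
        rows.sort(key=lambda r: (r[0], r[1]))
        lines.extend(",".join(cells) for _t, _e, cells in rows)
    Path(path).write_text("\n".join(lines) + "\n")


class DatasetError(ValueError):
    pass


def _parse(value: str, line_no: int, col: str, required: bool = True):
    if value == MISSING or value == "":
        if required:
            raise DatasetError(f"line {line_no}: missing required value in {col}")
        return None
    try:
        return float(value)
    except ValueError:
        raise DatasetError(f"line {line_no}: cannot parse {col}={value!r}") from None


def read_dataset(path) -> list[SubjectRecord]:
    """Read the event-record CSV dialect back into subject records."""
    text = Path(path).read_text().splitlines()
    if not text:
        raise DatasetError("empty file")
    header = text[0].split(",")
    if header != COLUMNS:
        raise DatasetError(f"bad header: expected {COLUMNS}, got {header}")
    col = {c: i for i, c in enumerate(COLUMNS)}

    subjects: dict[str, dict] = {}
    order: list[str] = []
    for line_no, line in enumerate(text[1:], start=2):
        if not line.strip():
            continue
        cells = line.split(",")
        if len(cells) != len(COLUMNS):
            raise DatasetError(f"line {line_no}: expected {len(COLUMNS)} fields, "
                               f"got {len(cells)}")
        sid = cells[col["ID"]]
        t = _parse(cells[col["TIME"]], line_no, "TIME")
        evid = int(_parse(cells[col["EVID"]], line_no, "EVID"))
        cmt = int(_parse(cells[col["CMT"]], line_no, "CMT"))
        if cmt not in _ANALYTE_OF:
            raise DatasetError(f"line {line_no}: unknown CMT {cmt}")
        analyte, compartment = _ANALYTE_OF[cmt]
        if sid not in subjects:
            wt = _parse(cells[col["WT"]], line_no, "WT")
            ht = _parse(cells[col["HT"]], line_no, "HT")
            subjects[sid] = {
                "cov": Covariates(
                    body_weight=wt, height=ht,
                    bsa=_parse(cells[col["BSA"]], line_no, "BSA", required=False),
                    age=_parse(cells[col["AGE"]], line_no, "AGE", required=False),
                    serum_creatinine=_parse(cells[col["SCR"]], line_no, "SCR",
                                            required=False)),
                "doses": [], "obs": [], "last_t": -np.inf}
            order.append(sid)
        sub = subjects[sid]
        if t < sub["last_t"]:
            raise DatasetError(f"line {line_no}: decreasing time within subject {sid}")
        sub["last_t"] = t
        if evid == 1:
            amt = _parse(cells[col["AMT"]], line_no, "AMT")
            dur = _parse(cells[col["DUR"]], line_no, "DUR")
            sub["doses"].append(DoseEvent(time=t, amount=amt,
                                          infusion_duration=dur,
                                          analyte=analyte,
                                          compartment=compartment))
        elif evid == 0:
            dv = _parse(cells[col["DV"]], line_no, "DV")
            blq = int(_parse(cells[col["BLQ"]], line_no, "BLQ"))
            nom = cells[col["NOM"]]
            sub["obs"].append(Observation(
                time=t, analyte=analyte, value=dv, below_lloq=bool(blq),
                nominal=None if nom == MISSING else nom))
        else:
            raise DatasetError(f"line {line_no}: unknown EVID {evid}")

    return [SubjectRecord(id=sid, covariates=subjects[sid]["cov"],
                          doses=subjects[sid]["doses"],
                          observations=subjects[sid]["obs"])
            for sid in order]


def require_covariates(records: list[SubjectRecord], names: list[str]) -> None:
    """Raise naming the first covariate a model needs but a record lacks."""
    for rec in records:
        for n in names:
            if getattr(rec.covariates, n, None) is None:
                raise DatasetError(
                    f"subject {rec.id}: required covariate column "
                    f"{n.upper()[:3] if n != 'serum_creatinine' else 'SCR'} "
                    f"({n}) is missing")


@dataclass
class RunConfig:
    """Validated run configuration for the pipeline commands."""

    seed: int = 0
    phase: int = 2
    n_subjects: int = 15
    cpg2_units_per_mg: float = 1000.0
    solver_rtol: float = 1e-8
    solver_atol: float = 1e-10
    n_boot: int = 1000
    n_sim: int = 1000
    output_dir: str = "out"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    def snapshot(self, out_dir) -> Path:
        """Write the config snapshot (seed + settings + versions) an artifact
        directory needs to be regenerated."""
        import scipy
        from . import __version__
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        payload = {"config": self.to_dict(), "config_hash": self.config_hash(),
                   "versions": {"cpg2mtx": __version__,
                                "numpy": np.__version__,
                                "scipy": scipy.__version__,
                                "pandas": pd.__version__}}
        path = out / "run_config.json"
        path.write_text(json.dumps(payload, indent=2) + "\n")
        return path
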