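"""Reading, writing, assembling and checking concentration-time datasets.

The on-disk format is the comma-separated dialect used for factor-VIII/IX
population-PK modeling: one row per event, with the required columns CID,
OCC, TIMEH, AMT, RATE, DV, AGE, BW, EVID, DOSE, PREDOSE, MDV5, BASELINE,
BLQ, MDV3 and the optional covariates HT, VWF, RACE, BTYPE, HCT.

Each subject's records follow a fixed layout per dose occasion:

1. a pre-dose record at the time origin (TIMEH = 0 for the first occasion)
   carrying PREDOSE (measured pre-dose level, or -1) and BASELINE (measured
   endogenous level, or the assumed 0.005 IU/mL when unmeasured);
2. a dose record whose TIMEH is the infusion duration in hours (truncated to
   4 decimals) and whose RATE equals AMT/TIMEH;
3. observation records (EVID=0, MDV5=MDV3=0) and below-LOQ records (EVID=3,
   MDV5=1, MDV3=0, BLQ = the LOQ in IU/L), ordered by time.

Concentrations are IU/L internally; clinically quoted values in IU/mL are
converted by a factor of 1000 at the API boundary.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field, fields, replace
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .structural import DoseRegimen, Infusion, InitialState

__all__ = [
    "EventRecord",
    "SubjectData",
    "PKDataset",
    "ValidationFlag",
    "DatasetFormatError",
    "DatasetParseError",
    "read_dataset",
    "write_dataset",
    "assemble_subject",
    "validate_dataset",
    "apply_resolutions",
    "DEFAULT_BASELINE_IU_ML",
    "DEFAULT_LOQ_IU_ML",
    "iu_ml_to_iul",
    "truncate4",
]

# unmeasured endogenous level: assume 0.5% of normal factor activity
DEFAULT_BASELINE_IU_ML = 0.005
# coagulation-assay limit of quantification
DEFAULT_LOQ_IU_ML = 0.01

REQUIRED_COLUMNS = (
    "CID", "OCC", "TIMEH", "AMT", "RATE", "DV", "AGE", "BW", "EVID",
    "DOSE", "PREDOSE", "MDV5", "BASELINE", "BLQ", "MDV3",
)
OPTIONAL_COLUMNS = ("HT", "VWF", "RACE", "BTYPE", "HCT")

BTYPE_CODES = (1, 2, 3, 4)  # A, B, AB, O


def iu_ml_to_iul(x: float) -> float:
    return x * 1000.0


def truncate4(hours: float) -> float:
    """Truncate (not round) hours to 4 decimal places: 10 min -> 0.1666."""
    return math.floor(hours * 1e4 + 1e-9) / 1e4


class DatasetFormatError(ValueError):
    pass


class DatasetParseError(ValueError):
    pass


@dataclass
class EventRecord:
    cid: int
    occ: int
    timeh: float
    amt: float
    rate: float
    dv: float
    age: float
    bw: float
    evid: int
    dose: float
    predose: float
    mdv5: int
    baseline: float
    blq: float
    mdv3: int
    ht: float | None = None
    vwf: float | None = None
    race: int | None = None
    btype: int | None = None
    hct: float | None = None

    def __post_init__(self) -> None:
        if self.evid not in (0, 1, 3):
            raise DatasetParseError(f"unexpected EVID code {self.evid}")

    @property
    def is_observation(self) -> bool:
        return self.evid == 0 and self.mdv5 == 0

    @property
    def is_blq(self) -> bool:
        return self.evid == 3

    @property
    def is_dose(self) -> bool:
        return self.amt > 0


@dataclass
class SubjectData:
    """All records for one subject, in dataset order."""

    records: list[EventRecord]

    def __post_init__(self) -> None:
        if not self.records:
            raise ValueError("subject must have at least one record")
        cids = {r.cid for r in self.records}
        if len(cids) != 1:
            raise ValueError("all records of a subject must share the CID")

    @property
    def cid(self) -> int:
        return self.records[0].cid

    @property
    def baseline_iul(self) -> float:
        b = self.records[0].baseline
        return b if b > 0 else iu_ml_to_iul(DEFAULT_BASELINE_IU_ML)

    @property
    def predose_iul(self) -> float | None:
        p = self.records[0].predose
        return p if p >= 0 else None

    @property
    def residual_iul(self) -> float:
        p = self.predose_iul
        return max(p - self.baseline_iul, 0.0) if p is not None else 0.0

    def initial_state(self) -> InitialState:
        return InitialState(baseline_iul=self.baseline_iul, residual_iul=self.residual_iul)

    def regimen(self) -> DoseRegimen:
        """Dose regimen from the dose records, one per occasion.

        Within an occasion the infusion starts at the occasion's first-record
        time and lasts until the dose record's TIMEH.
        """
        infusions = []
        occ_start: dict[int, float] = {}
        for r in self.records:
            occ_start.setdefault(r.occ, r.timeh)
            if r.is_dose:
                start = occ_start[r.occ]
                infusions.append(Infusion(start, r.timeh - start, r.amt))
        return DoseRegimen(infusions)

    def observations(self) -> list[EventRecord]:
        return [r for r in self.records if r.is_observation or r.is_blq]

    def covariates(self) -> dict[str, float]:
        r = self.records[0]
        cov = {"AGE": r.age, "BW": r.bw}
        for name in ("ht", "vwf", "race", "btype", "hct"):
            v = getattr(r, name)
            if v is not None and not (isinstance(v, float) and math.isnan(v)):
                cov[name.upper()] = v
        return cov


@dataclass
class PKDataset:
    subjects: list[SubjectData]
    provenance: str = ""

    def __post_init__(self) -> None:
        cids = [s.cid for s in self.subjects]
        if len(set(cids)) != len(cids):
            raise ValueError("duplicate CID across subjects")
        for s in self.subjects:
            if not any(r.is_dose for r in s.records):
                raise ValueError(f"subject {s.cid} has no dose record")
            if not s.observations():
                raise ValueError(f"subject {s.cid} has no observation or BLQ record")

    def __len__(self) -> int:
        return len(self.subjects)

    def subject(self, cid: int) -> SubjectData:
        for s in self.subjects:
            if s.cid == cid:
                return s
        raise KeyError(cid)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        use_optional = {
            c: any(getattr(r, c.lower()) is not None for s in self.subjects for r in s.records)
            for c in OPTIONAL_COLUMNS
        }
        for s in self.subjects:
            for r in s.records:
                row = {c: getattr(r, c.lower()) for c in REQUIRED_COLUMNS}
                for c in OPTIONAL_COLUMNS:
                    if use_optional[c]:
                        v = getattr(r, c.lower())
                        row[c] = -1 if v is None else v
                rows.append(row)
        return pd.DataFrame(rows)


def _records_from_frame(df: pd.DataFrame, provenance: str) -> PKDataset:
    present_optional = [c for c in OPTIONAL_COLUMNS if c in df.columns]
    subjects: list[SubjectData] = []
    for cid, grp in df.groupby("CID", sort=False):
        recs = []
        for _, row in grp.iterrows():
            kwargs = {c.lower(): float(row[c]) for c in REQUIRED_COLUMNS}
            for c in ("CID", "OCC", "EVID", "MDV5", "MDV3"):
                kwargs[c.lower()] = int(kwargs[c.lower()])
            for c in present_optional:
                v = row[c]
                if pd.isna(v) or v == -1:
                    kwargs[c.lower()] = None
                elif c in ("RACE", "BTYPE"):
                    kwargs[c.lower()] = int(v)
                else:
                    kwargs[c.lower()] = float(v)
            recs.append(EventRecord(**kwargs))
        subjects.append(SubjectData(recs))
    return PKDataset(subjects, provenance=provenance)


def read_dataset(source, provenance: str = "") -> PKDataset:
    """Read a dataset from a CSV path, file object or literal CSV text."""
    if isinstance(source, str) and "\n" in source:
        buf = io.StringIO(source)
    else:
        buf = source
    df = pd.read_csv(buf, na_values=["."], skipinitialspace=True,
                     float_precision="round_trip")
    df.columns = [c.strip().upper() for c in df.columns]
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise DatasetFormatError(f"missing required column(s): {', '.join(missing)}")
    for c in REQUIRED_COLUMNS:
        coerced = pd.to_numeric(df[c], errors="coerce")
        bad = coerced.isna() & df[c].notna()
        if bad.any():
            row = int(bad.idxmax()) + 2  # 1-based, after header
            raise DatasetParseError(f"non-numeric value in column {c} at file row {row}")
        df[c] = coerced
    bad_evid = ~df["EVID"].isin([0, 1, 3])
    if bad_evid.any():
        raise DatasetParseError(
            f"unexpected EVID code {int(df.loc[bad_evid.idxmax(), 'EVID'])}"
        )
    return _records_from_frame(df, provenance)


def write_dataset(ds: PKDataset, path=None) -> str:
    """Write to CSV; returns the CSV text (and writes to ``path`` if given).

    Floats are written with shortest round-trip precision so read(write(ds))
    reproduces every numeric field exactly."""
    text = ds.to_frame().to_csv(index=False, float_format=lambda x: repr(float(x)))
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def assemble_subject(
    dose: Mapping[str, float],
    observations: Sequence[Mapping[str, float]],
    demographics: Mapping[str, float],
    baseline_measured: float | None = None,
    predose_measured: float | None = None,
    loq_iul: float = iu_ml_to_iul(DEFAULT_LOQ_IU_ML),
    cid: int = 1,
    occ: int = 1,
) -> SubjectData:
    """Assemble one subject's record block from raw inputs.

    ``dose`` needs ``amount_iu`` and ``duration_h``; each observation needs
    ``time_h`` and ``conc_iul``.  Unmeasured baseline defaults to
    0.005 IU/mL (5 IU/L); concentrations below ``loq_iul`` become BLQ rows.
    """
    amount = float(dose["amount_iu"])
    duration = float(dose["duration_h"])
    if duration <= 0:
        raise ValueError("invalid dose: duration_h must be positive")
    if amount < 0:
        raise ValueError("invalid dose: amount_iu must be non-negative")
    age = float(demographics["age"])
    bw = float(demographics["bw"])
    optional = {
        k: demographics.get(k) for k in ("ht", "vwf", "race", "btype", "hct")
    }
    baseline = (
        float(baseline_measured)
        if baseline_measured is not None
        else iu_ml_to_iul(DEFAULT_BASELINE_IU_ML)
    )
    predose = float(predose_measured) if predose_measured is not None else -1.0
    timeh_dose = truncate4(duration)
    base_kwargs = dict(cid=cid, occ=occ, age=age, bw=bw, **optional)
    records = [
        EventRecord(
            timeh=0.0, amt=0.0, rate=0.0, dv=0.0, evid=0, dose=0.0,
            predose=predose, mdv5=1, baseline=baseline, blq=0.0, mdv3=1,
            **base_kwargs,
        ),
        EventRecord(
            timeh=timeh_dose, amt=amount, rate=amount / timeh_dose, dv=0.0,
            evid=1, dose=amount / bw, predose=-1.0, mdv5=1, baseline=-1.0,
            blq=0.0, mdv3=1, **base_kwargs,
        ),
    ]
    obs = sorted(observations, key=lambda o: float(o["time_h"]))
    for o in obs:
        t = float(o["time_h"])
        c = float(o["conc_iul"])
        if t < 0:
            raise ValueError("observation before time 0")
        if c < loq_iul:
            records.append(EventRecord(
                timeh=t, amt=0.0, rate=0.0, dv=loq_iul, evid=3, dose=0.0,
                predose=-1.0, mdv5=1, baseline=-1.0, blq=loq_iul, mdv3=0,
                **base_kwargs,
            ))
        else:
            records.append(EventRecord(
                timeh=t, amt=0.0, rate=0.0, dv=c, evid=0, dose=0.0,
                predose=-1.0, mdv5=0, baseline=-1.0, blq=0.0, mdv3=0,
                **base_kwargs,
            ))
    return SubjectData(records)


FlagCategory = Literal[
    "rising-concentration", "missing-value", "covariate-outlier",
    "unexpected-category", "duplicate-record",
]


@dataclass
class ValidationFlag:
    cid: int
    row_index: int          # index into the subject's record list
    category: FlagCategory
    message: str
    resolution: Literal["unresolved", "corrected", "excluded"] = "unresolved"
    replacement: EventRecord | None = None


DEFAULT_COVARIATE_BOUNDS = {
    "AGE": (0.0, 120.0),
    "BW": (2.0, 300.0),
    "HT": (40.0, 230.0),
    "VWF": (5.0, 500.0),
    "HCT": (10.0, 70.0),
}


def validate_dataset(
    ds: PKDataset,
    covariate_bounds: Mapping[str, tuple[float, float]] | None = None,
    categorical_codes: Mapping[str, Iterable[int]] | None = None,
    rising_rel_tol: float = 0.0,
) -> list[ValidationFlag]:
    """Screen a dataset for likely errors; the dataset itself is unchanged.

    Flags: post-dose concentrations rising versus the previous valid
    observation in the same occasion, missing required values, continuous
    covariates outside plausible bounds, unexpected categorical codes, and
    duplicate records within a subject.

    ``rising_rel_tol`` relaxes the rising-concentration rule: a rise is
    flagged when it exceeds the previous observation by more than this
    relative fraction.  The default 0 flags every rise, as suited to data
    expected to decline monotonically; when the assay CV is known, a value
    near ``4*sqrt(2)*CV`` keeps noise-level fluctuations between closely
    spaced samples from being flagged.
    """
    bounds = dict(DEFAULT_COVARIATE_BOUNDS)
    if covariate_bounds:
        bounds.update({k.upper(): tuple(v) for k, v in covariate_bounds.items()})
    codes = {"BTYPE": set(BTYPE_CODES), "RACE": set(range(1, 100))}
    if categorical_codes:
        codes.update({k.upper(): set(v) for k, v in categorical_codes.items()})

    flags: list[ValidationFlag] = []
    numeric_fields = [f.name for f in fields(EventRecord) if f.name not in
                      ("ht", "vwf", "race", "btype", "hct")]
    for s in ds.subjects:
        # rising concentration after end of infusion, within one occasion
        infusion_end: dict[int, float] = {}
        for r in s.records:
            if r.is_dose:
                infusion_end[r.occ] = max(infusion_end.get(r.occ, 0.0), r.timeh)
        prev: dict[int, tuple[int, float]] = {}
        for i, r in enumerate(s.records):
            if r.is_observation and r.timeh >= infusion_end.get(r.occ, 0.0):
                if r.occ in prev and r.dv > prev[r.occ][1] * (1.0 + rising_rel_tol):
                    flags.append(ValidationFlag(
                        s.cid, i, "rising-concentration",
                        f"concentration {r.dv} at t={r.timeh} h exceeds previous "
                        f"observation {prev[r.occ][1]}",
                    ))
                prev[r.occ] = (i, r.dv)
        # missing values
        for i, r in enumerate(s.records):
            for name in numeric_fields:
                v = getattr(r, name)
                if v is None or (isinstance(v, float) and math.isnan(v)):
                    flags.append(ValidationFlag(
                        s.cid, i, "missing-value", f"missing value in {name.upper()}"
                    ))
        # covariate bounds and categorical codes (checked on every row)
        for i, r in enumerate(s.records):
            for name, (lo, hi) in bounds.items():
                v = getattr(r, name.lower(), None)
                if v is not None and not (isinstance(v, float) and math.isnan(v)) \
                        and not (lo <= v <= hi):
                    flags.append(ValidationFlag(
                        s.cid, i, "covariate-outlier",
                        f"{name}={v} outside plausible range ({lo}, {hi})",
                    ))
            for name, okset in codes.items():
                v = getattr(r, name.lower(), None)
                if v is not None and v not in okset:
                    flags.append(ValidationFlag(
                        s.cid, i, "unexpected-category",
                        f"{name}={v} not in declared code set",
                    ))
        # duplicates: identical records within the subject
        seen: dict[tuple, int] = {}
        for i, r in enumerate(s.records):
            key = tuple(getattr(r, f.name) for f in fields(EventRecord))
            if key in seen:
                flags.append(ValidationFlag(
                    s.cid, i, "duplicate-record",
                    f"identical to record {seen[key]} of subject {s.cid}",
                ))
            else:
                seen[key] = i
    return flags


@dataclass
class AuditEntry:
    cid: int
    row_index: int
    action: str
    detail: str


def apply_resolutions(
    ds: PKDataset, flags: Sequence[ValidationFlag]
) -> tuple[PKDataset, list[AuditEntry]]:
    """Apply documented corrections/exclusions; refuses unresolved flags.

    Excluded rows are removed; a subject left without any observation is
    dropped entirely (with an audit entry).  Returns the new dataset and the
    audit log.  Flagged rows are never silently kept.
    """
    unresolved = [f for f in flags if f.resolution == "unresolved"]
    if unresolved:
        raise ValueError(
            f"{len(unresolved)} unresolved flag(s); every flag must be corrected or excluded"
        )
    audit: list[AuditEntry] = []
    by_subject: dict[int, dict[int, ValidationFlag]] = {}
    for f in flags:
        by_subject.setdefault(f.cid, {})[f.row_index] = f
    new_subjects = []
    for s in ds.subjects:
        fl = by_subject.get(s.cid, {})
        recs = []
        for i, r in enumerate(s.records):
            f = fl.get(i)
            if f is None:
                recs.append(r)
            elif f.resolution == "corrected":
                new_r = f.replacement if f.replacement is not None else r
                recs.append(new_r)
                audit.append(AuditEntry(s.cid, i, "corrected", f.message))
            else:
                audit.append(AuditEntry(s.cid, i, "excluded", f.message))
        sub = SubjectData(recs) if recs else None
        if sub is None or not sub.observations() or not any(r.is_dose for r in recs):
            audit.append(AuditEntry(
                s.cid, -1, "subject-dropped",
                "no valid observation or dose record remains after exclusions",
            ))
        else:
            new_subjects.append(sub)
    return PKDataset(new_subjects, provenance=ds.provenance), audit
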