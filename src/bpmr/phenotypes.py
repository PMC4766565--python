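"""Derivation of analysis-ready phenotypes from raw clinical measurements.

Implements the clinical protocol of the SEED (Singapore Epidemiology of Eye
Diseases) examinations: blood pressure is measured twice five minutes apart,
with a third reading taken when the first two disagree by more than
10 mmHg systolic or 5 mmHg diastolic, and the subject's BP is the mean of
the two closest readings; mean arterial pressure is SBP/3 + 2·DBP/3; retinal
vascular caliber summaries (CRAE, CRVE) are computed from the six largest
arteriolar/venular widths with the revised Knudtson-Parr-Hubbard iterative
pairing formula; hypertension and diabetes status are derived from
diagnosis, medication and casual glucose.

Scalar functions validate their inputs and are the reference semantics;
:func:`derive_participant_table` applies the same rules vectorised over a
cohort table.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "BpReadingSet",
    "VesselWidthSet",
    "ParticipantRecord",
    "needs_third_reading",
    "combine_bp_readings",
    "mean_arterial_pressure",
    "knudtson_caliber",
    "classify_hypertension",
    "classify_diabetes",
    "body_mass_index",
    "derive_participant_table",
    "pooled_percentage",
    "KNUDTSON_ARTERIOLE",
    "KNUDTSON_VENULE",
    "SBP_REPEAT_THRESHOLD",
    "DBP_REPEAT_THRESHOLD",
    "DIABETES_GLUCOSE_MMOL",
]

# Protocol constants. The repeat-reading thresholds are in mmHg; the Knudtson
# branching constants are the revised values for arterioles and venules; the
# casual-glucose diabetes cut-off is inclusive.
SBP_REPEAT_THRESHOLD = 10.0
DBP_REPEAT_THRESHOLD = 5.0
KNUDTSON_ARTERIOLE = 0.88
KNUDTSON_VENULE = 0.95
DIABETES_GLUCOSE_MMOL = 11.1


@dataclass(frozen=True)
class BpReadingSet:
    """Two or three (SBP, DBP) reading pairs in mmHg."""

    readings: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        if not 2 <= len(self.readings) <= 3:
            raise ValueError(
                f"BpReadingSet requires 2 or 3 readings, got {len(self.readings)}"
            )
        for i, (sbp, dbp) in enumerate(self.readings):
            if not (sbp > dbp > 0):
                raise ValueError(
                    f"reading {i + 1}: need sbp > dbp > 0, got ({sbp}, {dbp})"
                )


@dataclass(frozen=True)
class VesselWidthSet:
    """Exactly six positive vessel widths (μm) of one vessel type."""

    widths: tuple[float, ...]
    vessel_type: str  # "arteriole" | "venule"

    def __post_init__(self) -> None:
        if len(self.widths) != 6:
            raise ValueError(f"need exactly six widths, got {len(self.widths)}")
        if any(w <= 0 for w in self.widths):
            raise ValueError("all widths must be positive")
        if self.vessel_type not in ("arteriole", "venule"):
            raise ValueError(f"unknown vessel_type {self.vessel_type!r}")


@dataclass
class ParticipantRecord:
    """One subject's phenotypes, covariates and derived flags."""

    id: str
    stratum: str
    age: float
    gender: int  # 1 = male
    sbp: float | None = None
    dbp: float | None = None
    map: float | None = None
    crae: float | None = None
    crve: float | None = None
    height: float | None = None  # cm
    weight: float | None = None  # kg
    bmi: float | None = None
    total_cholesterol: float | None = None  # mmol/L
    glucose: float | None = None  # mmol/L
    creatinine: float | None = None  # mg/dl
    hypertension_dx: bool = False
    htn_medication: bool = False
    diabetes_dx: bool = False
    dm_medication: bool = False
    smoking: bool = False
    alcohol: bool = False
    household_income: str | None = None
    presence_of_hypertension: bool | None = None
    presence_of_diabetes: bool | None = None
    extras: dict = field(default_factory=dict)

    @classmethod
    def from_row(cls, row: pd.Series) -> "ParticipantRecord":
        known = {f for f in cls.__dataclass_fields__ if f != "extras"}
        kwargs = {k: row[k] for k in known if k in row.index}
        kwargs.setdefault("id", str(row.get("participant_id", "")))
        extras = {k: row[k] for k in row.index if k not in known and k != "participant_id"}
        return cls(extras=extras, **kwargs)


def needs_third_reading(
    r1: Sequence[float],
    r2: Sequence[float],
    *,
    sbp_threshold: float = SBP_REPEAT_THRESHOLD,
    dbp_threshold: float = DBP_REPEAT_THRESHOLD,
    rule: str = "or",
) -> bool:
    """Whether the repeat-reading protocol asks for a third BP measurement.

    Default ``rule="or"``: a third reading is triggered when the systolic
    difference exceeds ``sbp_threshold`` OR the diastolic difference exceeds
    ``dbp_threshold`` (both strict). ``rule="and"`` requires both, for
    sensitivity to the alternative literal protocol reading.
    """
    ds = abs(r1[0] - r2[0]) > sbp_threshold
    dd = abs(r1[1] - r2[1]) > dbp_threshold
    if rule == "or":
        return ds or dd
    if rule == "and":
        return ds and dd
    raise ValueError(f"rule must be 'or' or 'and', got {rule!r}")


_PAIRS = ((0, 1), (0, 2), (1, 2))


def combine_bp_readings(
    readings: BpReadingSet | Sequence[Sequence[float]],
) -> tuple[float, float]:
    """Combine 2-3 BP readings into a single (SBP, DBP) pair.

    With two readings, the component-wise mean. With three, the mean of the
    two closest readings, closeness being |ΔSBP| + |ΔDBP|; ties go to the
    earliest pair in reading order.
    """
    if isinstance(readings, BpReadingSet):
        r = readings.readings
    else:
        r = tuple(tuple(map(float, x)) for x in readings)
        BpReadingSet(r)  # validate
    if len(r) == 2:
        return ((r[0][0] + r[1][0]) / 2.0, (r[0][1] + r[1][1]) / 2.0)
    dists = [abs(r[i][0] - r[j][0]) + abs(r[i][1] - r[j][1]) for i, j in _PAIRS]
    i, j = _PAIRS[int(np.argmin(dists))]
    return ((r[i][0] + r[j][0]) / 2.0, (r[i][1] + r[j][1]) / 2.0)


def mean_arterial_pressure(sbp, dbp):
    """MAP = SBP/3 + 2·DBP/3 (mmHg). Accepts scalars or arrays."""
    sbp = np.asarray(sbp, dtype=float)
    dbp = np.asarray(dbp, dtype=float)
    valid = ~(np.isnan(sbp) | np.isnan(dbp))
    if np.any((dbp[valid] > sbp[valid]) | (dbp[valid] <= 0)):
        raise ValueError("require sbp >= dbp > 0")
    out = sbp / 3.0 + 2.0 * dbp / 3.0
    return float(out) if out.ndim == 0 else out


def _knudtson_chain(widths: np.ndarray, k: float) -> np.ndarray:
    """Iterative pairwise combination of six widths, vectorised over rows.

    Sort descending, pair largest with smallest (combined = k·√(wa²+wb²)),
    6→3; with three values combine largest+smallest and carry the middle,
    3→2; combine the final pair, 2→1.
    """
    w = np.sort(np.asarray(widths, dtype=float), axis=1)[:, ::-1]
    c = k * np.sqrt(w[:, :3] ** 2 + w[:, 5:2:-1] ** 2)  # (0,5),(1,4),(2,3)
    s = np.sort(c, axis=1)[:, ::-1]
    d = k * np.sqrt(s[:, 0] ** 2 + s[:, 2] ** 2)  # carry s[:,1]
    return k * np.sqrt(d**2 + s[:, 1] ** 2)


def knudtson_caliber(
    widths: VesselWidthSet | Sequence[float],
    vessel_type: str | None = None,
    *,
    constant: float | None = None,
) -> float:
    """Summarise the six largest vessel widths as CRAE or CRVE (μm).

    Revised Knudtson branching constants: 0.88 for arterioles, 0.95 for
    venules; ``constant`` overrides for sensitivity analysis. The result is
    invariant to the input order and homogeneous of degree one in the widths.
    """
    if isinstance(widths, VesselWidthSet):
        vset = widths
    else:
        if vessel_type is None:
            raise ValueError("vessel_type required when passing raw widths")
        vset = VesselWidthSet(tuple(float(w) for w in widths), vessel_type)
    if constant is None:
        constant = (
            KNUDTSON_ARTERIOLE if vset.vessel_type == "arteriole" else KNUDTSON_VENULE
        )
    return float(_knudtson_chain(np.array([vset.widths]), constant)[0])


def classify_hypertension(hypertension_dx: bool, htn_medication: bool) -> bool:
    """Hypertension: prior diagnosis or anti-hypertensive medication."""
    return bool(hypertension_dx) or bool(htn_medication)


def classify_diabetes(
    diabetes_dx: bool,
    dm_medication: bool,
    glucose: float | None,
    *,
    glucose_threshold: float = DIABETES_GLUCOSE_MMOL,
) -> bool | None:
    """Diabetes: diagnosis, medication, or casual glucose ≥ 11.1 mmol/L.

    The glucose cut-off is inclusive. A missing glucose with both flags
    false is indeterminate and returns ``None`` (flagged missing), never a
    hard ``False``.
    """
    if diabetes_dx or dm_medication:
        return True
    if glucose is None or (isinstance(glucose, float) and np.isnan(glucose)):
        return None
    return float(glucose) >= glucose_threshold


def body_mass_index(height_cm: float, weight_kg: float) -> float:
    """BMI = weight / height² (kg/m²)."""
    if height_cm <= 0 or weight_kg <= 0:
        raise ValueError("height and weight must be positive")
    h = height_cm / 100.0
    return weight_kg / (h * h)


def pooled_percentage(counts: Iterable[float], total: float, ndigits: int = 1) -> float:
    """Pooled prevalence (%) from per-stratum counts and a pooled n."""
    c = float(np.sum(np.fromiter((float(x) for x in counts), dtype=float)))
    if total <= 0:
        raise ValueError("total must be positive")
    return round(100.0 * c / float(total), ndigits)


ART_WIDTH_COLUMNS = [f"art_w{i}" for i in range(1, 7)]
VEN_WIDTH_COLUMNS = [f"ven_w{i}" for i in range(1, 7)]


def _combine_readings_vec(df: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    s = df[["sbp1", "sbp2", "sbp3"]].to_numpy(dtype=float)
    d = df[["dbp1", "dbp2", "dbp3"]].to_numpy(dtype=float)
    has3 = ~np.isnan(s[:, 2])
    mean2_s = (s[:, 0] + s[:, 1]) / 2.0
    mean2_d = (d[:, 0] + d[:, 1]) / 2.0
    dist = np.stack(
        [np.abs(s[:, i] - s[:, j]) + np.abs(d[:, i] - d[:, j]) for i, j in _PAIRS],
        axis=1,
    )
    # argmin over NaN-free rows only; argmin keeps the earliest pair on ties
    best = np.zeros(len(df), dtype=int)
    if has3.any():
        best[has3] = np.argmin(dist[has3], axis=1)
    ii = np.array([p[0] for p in _PAIRS])[best]
    jj = np.array([p[1] for p in _PAIRS])[best]
    rows = np.arange(len(df))
    sbp = np.where(has3, (s[rows, ii] + s[rows, jj]) / 2.0, mean2_s)
    dbp = np.where(has3, (d[rows, ii] + d[rows, jj]) / 2.0, mean2_d)
    return sbp, dbp


def derive_participant_table(
    raw: pd.DataFrame,
    *,
    arteriole_constant: float = KNUDTSON_ARTERIOLE,
    venule_constant: float = KNUDTSON_VENULE,
    glucose_threshold: float = DIABETES_GLUCOSE_MMOL,
) -> pd.DataFrame:
    """Apply the full derivation protocol to a raw cohort table.

    Expects reading columns ``sbp1,dbp1,sbp2,dbp2,sbp3,dbp3`` (third reading
    NaN when not taken), width columns ``art_w1..6`` / ``ven_w1..6``, and the
    covariate columns of the phenotype dictionary. Adds ``sbp, dbp, map,
    crae, crve, bmi, presence_of_hypertension, presence_of_diabetes``.
    Columns already present are left untouched (pre-derived inputs win).
    """
    out = raw.copy()
    if "sbp" not in out.columns and "sbp1" in out.columns:
        out["sbp"], out["dbp"] = _combine_readings_vec(out)
    if "map" not in out.columns:
        out["map"] = mean_arterial_pressure(out["sbp"], out["dbp"])
    if "crae" not in out.columns and set(ART_WIDTH_COLUMNS) <= set(out.columns):
        out["crae"] = _knudtson_chain(
            out[ART_WIDTH_COLUMNS].to_numpy(dtype=float), arteriole_constant
        )
    if "crve" not in out.columns and set(VEN_WIDTH_COLUMNS) <= set(out.columns):
        out["crve"] = _knudtson_chain(
            out[VEN_WIDTH_COLUMNS].to_numpy(dtype=float), venule_constant
        )
    if "bmi" not in out.columns and {"height", "weight"} <= set(out.columns):
        h = out["height"].to_numpy(dtype=float) / 100.0
        out["bmi"] = out["weight"].to_numpy(dtype=float) / (h * h)
    if "presence_of_hypertension" not in out.columns:
        out["presence_of_hypertension"] = out["hypertension_dx"].astype(bool) | out[
            "htn_medication"
        ].astype(bool)
    if "presence_of_diabetes" not in out.columns:
        flags = out["diabetes_dx"].astype(bool) | out["dm_medication"].astype(bool)
        glu = out["glucose"].astype(float) if "glucose" in out.columns else pd.Series(
            np.nan, index=out.index
        )
        pod = pd.array(flags | (glu >= glucose_threshold), dtype="boolean")
        pod[(~flags) & glu.isna().to_numpy()] = pd.NA
        out["presence_of_diabetes"] = pod
    return out
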