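"""Reading, validation and recoding of per-participant risk assessments.

Seven injection-risk behaviors feed the mixture models: relative frequency
of sharing syringes, cookers, cotton filters and rinse water; frequency of
using a new sterile syringe to divide drugs; frequency of cleaning needles
with bleach; and the number of syringe-sharing partners.  The frequency
items are asked on a 7-point Likert scale from 1 = "always" to 7 = "never"
with "about half the time" at the midpoint.  The two "safe" behaviors
(new-syringe-to-divide, bleach cleaning) are reverse-scored so that higher
always means riskier, and every item is collapsed to three ordered
categories:

* 0 — never
* 1 — less than half the time
* 2 — half the time or more (the midpoint belongs to this category)

The partner count is collapsed to none / one / more than one.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
import pandas as pd

from ._utils import MISSING

WAVES = ("baseline", "m3", "m6")
ARMS = ("control", "pei", "none")
SEXES = ("male", "female")
RACES = ("white", "black", "hispanic", "other")
SITES = ("baltimore", "chicago", "los_angeles", "new_york", "seattle")

#: raw CSV columns holding the six Likert frequency items, in model order
LIKERT_COLUMNS = (
    "share_syringe",
    "share_cooker",
    "share_cotton",
    "share_water",
    "new_syringe_divide",
    "bleach_clean",
)
PARTNER_COLUMN = "n_sharing_partners"

#: short indicator names, same order as the columns above plus partners
ITEM_NAMES = ("syringe", "cooker", "cotton", "water", "divide", "bleach", "partners")

#: items whose raw scale measures *safe* behavior and is reverse-scored
REVERSED_ITEMS = frozenset({"divide", "bleach"})

COVARIATE_COLUMNS = ("sex", "age", "race", "site", "homeless")

COHORT_COLUMNS = (
    ("participant_id", "wave", "arm")
    + LIKERT_COLUMNS
    + (PARTNER_COLUMN,)
    + COVARIATE_COLUMNS
    + ("randomized", "returned_6m")
)


@dataclass
class RawAssessment:
    """One participant-wave record as read from the cohort CSV."""

    participant_id: str
    wave: str
    arm: str
    likert_items: tuple  # six ints in 1..7, or None when missing
    n_sharing_partners: int | None
    sex: str
    age: float
    race: str
    site: str
    homeless: bool
    randomized: bool
    returned_6m: bool


@dataclass
class IndicatorMatrix:
    """N x 7 matrix of 3-category ordinal risk indicators.

    ``values`` holds codes in {0, 1, 2} with ``MISSING`` (-1) for
    unobserved entries.  Rows are aligned with ``participant_id``; all rows
    belong to the wave recorded in ``wave``.
    """

    values: np.ndarray
    participant_id: np.ndarray
    wave: str
    item_names: tuple = ITEM_NAMES
    reversed_items: frozenset = field(default=REVERSED_ITEMS)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int64)
        ok = (self.values == MISSING) | ((self.values >= 0) & (self.values <= 2))
        if not ok.all():
            raise ValueError("indicator entries must be 0/1/2 or the missing sentinel")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=list(self.item_names))
        df.insert(0, "wave", self.wave)
        df.insert(0, "participant_id", self.participant_id)
        return df


def recode_item(raw: int, reversed_: bool = False) -> int:
    """Collapse a 7-point frequency response to the 3-category risk code.

    ``raw`` runs 1 = "always" ... 7 = "never".  Reverse-scored (safe
    behavior) items are flipped first (raw -> 8 - raw) so that higher means
    riskier, then: 7 -> 0 (never), 5-6 -> 1 (less than half the time),
    1-4 -> 2 (half the time or more; the midpoint 4 carries the "half the
    time" label and belongs to the upper category).
    """
    raw = int(raw)
    if not 1 <= raw <= 7:
        raise ValueError(f"Likert response must be in 1..7, got {raw}")
    if reversed_:
        raw = 8 - raw
    if raw == 7:
        return 0
    if raw >= 5:
        return 1
    return 2


def recode_partners(n: int) -> int:
    """Collapse a syringe-sharing partner count to none / one / more than one."""
    n = int(n)
    if n < 0:
        raise ValueError(f"partner count must be non-negative, got {n}")
    return min(n, 2)


def _recode_likert_column(col: pd.Series, reversed_: bool, name: str) -> np.ndarray:
    vals = pd.to_numeric(col, errors="coerce").to_numpy(dtype=float)
    out = np.full(vals.shape, MISSING, dtype=np.int64)
    obs = ~np.isnan(vals)
    raw = vals[obs]
    if ((raw < 1) | (raw > 7) | (raw != np.round(raw))).any():
        bad = np.flatnonzero(obs)[np.flatnonzero((raw < 1) | (raw > 7) | (raw != np.round(raw)))[0]]
        raise ValueError(f"item {name!r}: out-of-range Likert value at row {bad}")
    r = raw.astype(np.int64)
    if reversed_:
        r = 8 - r
    coded = np.where(r == 7, 0, np.where(r >= 5, 1, 2))
    out[obs] = coded
    return out


def _recode_partner_column(col: pd.Series) -> np.ndarray:
    vals = pd.to_numeric(col, errors="coerce").to_numpy(dtype=float)
    out = np.full(vals.shape, MISSING, dtype=np.int64)
    obs = ~np.isnan(vals)
    raw = vals[obs]
    if (raw < 0).any():
        bad = np.flatnonzero(obs)[int(np.argmax(raw < 0))]
        raise ValueError(f"item {PARTNER_COLUMN!r}: negative count at row {bad}")
    out[obs] = np.minimum(raw, 2).astype(np.int64)
    return out


def build_indicators(records: pd.DataFrame, wave: str) -> IndicatorMatrix:
    """Recode the raw items of one wave into an :class:`IndicatorMatrix`."""
    if wave not in WAVES:
        raise ValueError(f"unknown wave {wave!r}")
    sub = records.loc[records["wave"] == wave]
    cols = []
    for name, col in zip(ITEM_NAMES[:6], LIKERT_COLUMNS):
        cols.append(_recode_likert_column(sub[col], name in REVERSED_ITEMS, col))
    cols.append(_recode_partner_column(sub[PARTNER_COLUMN]))
    values = np.column_stack(cols)
    return IndicatorMatrix(values=values,
                           participant_id=sub["participant_id"].to_numpy(),
                           wave=wave)


def read_cohort(path) -> pd.DataFrame:
    """Read and validate a cohort CSV of raw assessments.

    Missing values are encoded as empty fields.  Unknown columns are
    preserved (and ignored downstream).  Raises ``ValueError`` naming the
    offending CSV line on malformed rows or duplicate (participant, wave)
    keys.
    """
    df = pd.read_csv(path, dtype={"participant_id": str})
    missing_cols = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"cohort file missing required columns: {missing_cols}")
    # +2: header line and 1-based numbering
    lineno = df.index.to_numpy() + 2

    def _bad(mask: np.ndarray, msg: str) -> None:
        if np.asarray(mask).any():
            first = int(lineno[np.asarray(mask)][0])
            raise ValueError(f"line {first}: {msg}")

    _bad(~df["wave"].isin(WAVES), f"wave must be one of {WAVES}")
    _bad(~df["arm"].isin(ARMS), f"arm must be one of {ARMS}")
    dup = df.duplicated(subset=["participant_id", "wave"], keep=False)
    _bad(dup, "duplicate (participant_id, wave)")
    for col in LIKERT_COLUMNS:
        vals = pd.to_numeric(df[col], errors="coerce")
        _bad(df[col].notna() & vals.isna(), f"non-numeric value in {col}")
        _bad(vals.notna() & ~vals.isin(range(1, 8)), f"{col} outside 1..7")
    partners = pd.to_numeric(df[PARTNER_COLUMN], errors="coerce")
    _bad(partners.notna() & (partners < 0), "negative partner count")
    age = pd.to_numeric(df["age"], errors="coerce")
    _bad(age.notna() & ((age < 15) | (age > 30)), "age outside 15..30")
    rand = df["randomized"].astype(bool)
    _bad((df["arm"] == "none") & rand, "randomized participants must have a trial arm")
    _bad((df["arm"] != "none") & ~rand, "non-randomized participants must have arm='none'")
    return df


def write_cohort(records: pd.DataFrame, path) -> None:
    records.to_csv(path, index=False)


def iter_assessments(records: pd.DataFrame) -> Iterator[RawAssessment]:
    """Yield one :class:`RawAssessment` per validated cohort row."""
    for row in records.itertuples(index=False):
        likert = tuple(
            None if pd.isna(getattr(row, c)) else int(getattr(row, c))
            for c in LIKERT_COLUMNS
        )
        partners = getattr(row, PARTNER_COLUMN)
        yield RawAssessment(
            participant_id=row.participant_id,
            wave=row.wave,
            arm=row.arm,
            likert_items=likert,
            n_sharing_partners=None if pd.isna(partners) else int(partners),
            sex=row.sex,
            age=float(row.age),
            race=row.race,
            site=row.site,
            homeless=bool(row.homeless),
            randomized=bool(row.randomized),
            returned_6m=bool(row.returned_6m),
        )


def write_indicators(matrix: IndicatorMatrix, path) -> None:
    """Write an indicator matrix to CSV; missing entries become empty fields."""
    df = matrix.to_frame()
    for name in matrix.item_names:
        df[name] = df[name].astype("object")
        df.loc[df[name] == MISSING, name] = ""
    df.to_csv(path, index=False)


def read_indicators(path) -> IndicatorMatrix:
    df = pd.read_csv(path, dtype={"participant_id": str})
    wave_vals = df["wave"].unique()
    if len(wave_vals) != 1:
        raise ValueError("indicator file must contain a single wave")
    values = np.full((len(df), len(ITEM_NAMES)), MISSING, dtype=np.int64)
    for j, name in enumerate(ITEM_NAMES):
        col = pd.to_numeric(df[name], errors="coerce")
        obs = col.notna().to_numpy()
        values[obs, j] = col.to_numpy(dtype=float)[obs].astype(np.int64)
    return IndicatorMatrix(values=values,
                           participant_id=df["participant_id"].to_numpy(),
                           wave=str(wave_vals[0]))
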