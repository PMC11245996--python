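"""Domain containers and tabular IO for Likert rating data.

The pipeline's universal input is a long-format table of beauty (and
optionally typicality) ratings: one row per participant x image x session,
on a 1-7 Likert scale.  This module validates that structure, summarizes
it per image, bins it into per-image histograms, and round-trips it
through CSV.

Conventions fixed here and relied on everywhere downstream:

* sample statistics use the n-1 denominator (the "dispersion of 1, 3, 5
  is 2" convention of the estimation-task instructions);
* an image rated by a single participant has an *undefined* SD, reported
  as missing rather than zero;
* ratings are strict integers in [1, 7], while self-reported estimates
  (estimated mean / SD) may be any real number.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

LIKERT_MIN = 1
LIKERT_MAX = 7
#: bin centres of the standard 7-point scale
LIKERT_BINS = tuple(range(LIKERT_MIN, LIKERT_MAX + 1))

CONDITIONS = ("disputed", "undisputed", "foil")

#: canonical column order of a ratings CSV
RATING_COLUMNS = ("participant_id", "image_id", "session",
                  "beauty", "typicality", "condition")


class SchemaError(ValueError):
    """A required column is missing or the file layout is unusable."""


class ValidationError(ValueError):
    """Rows violate the rating-table invariants; message names the rows."""


def sample_sd(values: Sequence[float]) -> float:
    """Sample standard deviation with the n-1 denominator.

    Returns NaN for fewer than two values: a single observation carries
    no spread information, and silently reporting 0 would conflate
    "no information" with "perfect consensus".
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        return float("nan")
    return float(np.std(arr, ddof=1))


@dataclass(frozen=True)
class RatingTable:
    """Validated long-format rating records.

    Wraps a DataFrame with columns ``participant_id``, ``image_id``,
    ``session`` (1 or 2), ``beauty`` (int 1-7), ``typicality``
    (int 1-7 or missing), ``condition`` (disputed/undisputed/foil or
    missing).  (participant, image, session) triples are unique, and
    every session-2 record has a session-1 counterpart.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        object.__setattr__(self, "frame", _validate_frame(self.frame))

    # -- accessors ---------------------------------------------------------
    def __len__(self) -> int:
        return len(self.frame)

    @property
    def image_ids(self) -> list[str]:
        return sorted(self.frame["image_id"].unique())

    @property
    def participant_ids(self) -> list[str]:
        return sorted(self.frame["participant_id"].unique())

    def session(self, session: int) -> pd.DataFrame:
        return self.frame[self.frame["session"] == session]

    def ratings_matrix(self, session: int = 1, images: Sequence[str] | None = None,
                       complete_only: bool = False) -> pd.DataFrame:
        """Participant x image matrix of beauty ratings for one session.

        With ``complete_only`` participants missing any requested image
        are dropped.
        """
        sub = self.session(session)
        if images is not None:
            missing = set(images) - set(sub["image_id"])
            if missing:
                raise KeyError(f"unknown image_id(s) in session {session}: {sorted(missing)}")
            sub = sub[sub["image_id"].isin(images)]
        mat = sub.pivot(index="participant_id", columns="image_id", values="beauty")
        if images is not None:
            mat = mat[list(images)]
        if complete_only:
            mat = mat.dropna(axis=0, how="any")
        return mat

    def equals(self, other: "RatingTable") -> bool:
        a = self.frame.sort_values(list(RATING_COLUMNS[:3])).reset_index(drop=True)
        b = other.frame.sort_values(list(RATING_COLUMNS[:3])).reset_index(drop=True)
        return a.equals(b)


def _validate_frame(frame: pd.DataFrame) -> pd.DataFrame:
    required = {"participant_id", "image_id", "session", "beauty"}
    missing = required - set(frame.columns)
    if missing:
        raise SchemaError(f"missing required column(s): {sorted(missing)}")
    frame = frame.copy()
    if "typicality" not in frame.columns:
        frame["typicality"] = pd.NA
    if "condition" not in frame.columns:
        frame["condition"] = pd.NA
    frame = frame[list(RATING_COLUMNS)]
    frame["participant_id"] = frame["participant_id"].astype(str)
    frame["image_id"] = frame["image_id"].astype(str)

    bad_rows: list[str] = []
    converted: dict[str, pd.Series] = {}
    for col in ("session", "beauty", "typicality"):
        vals = pd.to_numeric(frame[col], errors="coerce")
        nonint = vals.notna() & (vals != np.floor(vals))
        if col == "session":
            out = vals.isna() | ~vals.isin([1, 2])
        elif col == "beauty":
            out = vals.isna() | (vals < LIKERT_MIN) | (vals > LIKERT_MAX)
        else:
            out = frame[col].notna() & (vals.isna() | (vals < LIKERT_MIN) | (vals > LIKERT_MAX))
        for idx in frame.index[nonint | out]:
            bad_rows.append(f"row {idx}: {col}={frame.at[idx, col]!r}")
        converted[col] = vals
    cond_bad = frame["condition"].notna() & ~frame["condition"].isin(CONDITIONS)
    for idx in frame.index[cond_bad]:
        bad_rows.append(f"row {idx}: condition={frame.at[idx, 'condition']!r}")
    if bad_rows:
        raise ValidationError("invalid rating rows: " + "; ".join(bad_rows[:20]))
    for col, vals in converted.items():
        frame[col] = vals.astype("Int64")

    dup = frame.duplicated(subset=["participant_id", "image_id", "session"])
    if dup.any():
        raise ValidationError(
            f"duplicate (participant, image, session) triples at rows {list(frame.index[dup])[:20]}")

    s1 = set(map(tuple, frame.loc[frame["session"] == 1, ["participant_id", "image_id"]].values))
    s2 = set(map(tuple, frame.loc[frame["session"] == 2, ["participant_id", "image_id"]].values))
    orphans = s2 - s1
    if orphans:
        raise ValidationError(
            f"session-2 records without a session-1 counterpart: {sorted(orphans)[:20]}")
    return frame.reset_index(drop=True)


@dataclass(frozen=True)
class ImageSummary:
    """Per-image across-participant summary (mean/SD beauty, mean typicality)."""

    image_id: str
    beauty_mean: float
    beauty_sd: float  # NaN when n_raters < 2
    typicality_mean: float  # NaN when no typicality ratings
    n_raters: int


@dataclass(frozen=True)
class RatingHistogram:
    """Counts of ratings over the Likert bins 1..7 for one image."""

    counts: tuple[int, ...]
    bins: tuple[int, ...] = LIKERT_BINS
    image_id: str | None = None

    def __post_init__(self) -> None:
        if len(self.counts) != len(self.bins):
            raise ValueError("counts and bins must have equal length")
        if any(c < 0 for c in self.counts):
            raise ValueError("counts must be nonnegative")
        object.__setattr__(self, "counts", tuple(int(c) for c in self.counts))

    @property
    def n_total(self) -> int:
        return int(sum(self.counts))

    @property
    def n_bins(self) -> int:
        return len(self.bins)

    def as_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        return np.asarray(self.bins, float), np.asarray(self.counts, float)


@dataclass(frozen=True)
class NumberSet:
    """One of the control-task number sets (values in [1,7])."""

    set_id: str
    values: tuple[float, ...]

    def __post_init__(self) -> None:
        if any(not (LIKERT_MIN <= v <= LIKERT_MAX) for v in self.values):
            raise ValueError(f"{self.set_id}: values must lie in [1, 7]")
        object.__setattr__(self, "values", tuple(float(v) for v in self.values))

    @property
    def set_size(self) -> int:
        return len(self.values)

    @property
    def mean(self) -> float:
        return float(np.mean(self.values))

    @property
    def sd(self) -> float:
        return sample_sd(self.values)


@dataclass(frozen=True)
class EstimationRecord:
    """One participant's estimated vs. actual mean/SD for one target.

    ``excluded`` marks the outlier rule: estimated means at or above the
    configured threshold (default 18) are dropped from accuracy analyses.
    """

    participant_id: str
    target_kind: str  # "quartet" | "number_set"
    target_id: str
    estimated_mean: float
    estimated_sd: float
    actual_mean: float
    actual_sd: float
    excluded: bool = False

    def __post_init__(self) -> None:
        if self.target_kind not in ("quartet", "number_set"):
            raise ValueError(f"unknown target_kind {self.target_kind!r}")


OUTLIER_ESTIMATED_MEAN = 18.0


def apply_exclusion_rule(records: Iterable[EstimationRecord],
                         threshold: float = OUTLIER_ESTIMATED_MEAN) -> list[EstimationRecord]:
    """Flag records whose estimated mean is at or above ``threshold``."""
    return [dataclasses.replace(r, excluded=bool(r.estimated_mean >= threshold))
            for r in records]


# --------------------------------------------------------------------------
# IO
# --------------------------------------------------------------------------

def read_ratings(path: str | Path,
                 schema: Mapping[str, str] | None = None) -> RatingTable:
    """Read a long-format ratings CSV into a validated :class:`RatingTable`.

    ``schema`` optionally maps canonical column names to the file's
    column names, e.g. ``{"participant_id": "subject"}``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = pd.read_csv(path, dtype={0: str})
    if schema:
        rename = {file_col: canon for canon, file_col in schema.items()}
        absent = [c for c in schema.values() if c not in raw.columns]
        if absent:
            raise SchemaError(f"{path}: schema names absent column(s) {absent}")
        raw = raw.rename(columns=rename)
    return RatingTable(raw)


def write_ratings(table: RatingTable, path: str | Path) -> None:
    frame = table.frame.sort_values(["participant_id", "image_id", "session"])
    frame.to_csv(path, index=False)


def read_number_sets(path: str | Path) -> list[NumberSet]:
    """Read number sets from CSV with columns set_id, values (semicolon-joined)."""
    frame = pd.read_csv(path, dtype=str)
    if not {"set_id", "values"} <= set(frame.columns):
        raise SchemaError(f"{path}: need columns set_id, values")
    return [NumberSet(row.set_id, tuple(float(v) for v in row.values.split(";")))
            for row in frame.itertuples(index=False)]


def write_number_sets(sets: Sequence[NumberSet], path: str | Path) -> None:
    pd.DataFrame({"set_id": [s.set_id for s in sets],
                  "values": [";".join(repr(v) for v in s.values) for s in sets]}
                 ).to_csv(path, index=False)


ESTIMATION_COLUMNS = ("participant_id", "target_kind", "target_id",
                      "estimated_mean", "estimated_sd", "actual_mean", "actual_sd")


def read_estimations(path: str | Path) -> list[EstimationRecord]:
    frame = pd.read_csv(path, dtype={"participant_id": str, "target_id": str})
    missing = set(ESTIMATION_COLUMNS) - set(frame.columns)
    if missing:
        raise SchemaError(f"{path}: missing column(s) {sorted(missing)}")
    return [EstimationRecord(str(r.participant_id), r.target_kind, str(r.target_id),
                             float(r.estimated_mean), float(r.estimated_sd),
                             float(r.actual_mean), float(r.actual_sd))
            for r in frame.itertuples(index=False)]


def write_estimations(records: Sequence[EstimationRecord], path: str | Path) -> None:
    pd.DataFrame([{c: getattr(r, c) for c in ESTIMATION_COLUMNS} for r in records]
                 ).to_csv(path, index=False)


def summaries_to_frame(summaries: Sequence[ImageSummary]) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(s) for s in summaries])


# --------------------------------------------------------------------------
# summaries and histograms
# --------------------------------------------------------------------------

def summarize_images(table: RatingTable, session: int = 1) -> list[ImageSummary]:
    """Across-participant mean and sample SD of beauty plus mean typicality.

    SD uses the n-1 denominator; an image with a single rater reports a
    missing (NaN) SD.
    """
    sub = table.session(session)
    if sub.empty:
        raise ValueError(f"no records for session {session}")
    out = []
    for image_id, grp in sub.groupby("image_id", sort=True):
        beauty = grp["beauty"].astype(float).to_numpy()
        typ = grp["typicality"].dropna().astype(float).to_numpy()
        out.append(ImageSummary(
            image_id=str(image_id),
            beauty_mean=float(beauty.mean()),
            beauty_sd=sample_sd(beauty),
            typicality_mean=float(typ.mean()) if typ.size else float("nan"),
            n_raters=len(grp),
        ))
    return out


def histogram(table: RatingTable, image_id: str, session: int = 1) -> RatingHistogram:
    """Counts of beauty ratings over bins 1..7 for one image and session."""
    sub = table.session(session)
    grp = sub[sub["image_id"] == image_id]
    if grp.empty:
        raise KeyError(f"no ratings for image {image_id!r} in session {session}")
    counts = np.bincount(grp["beauty"].astype(int), minlength=LIKERT_MAX + 1)[LIKERT_MIN:]
    return RatingHistogram(counts=tuple(int(c) for c in counts), image_id=image_id)
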