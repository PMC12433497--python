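"""Domain types, validation and delimited-file I/O for feeding-trial records.

A trial dataset bundles three tables:

* ``birds.csv`` — one row per hen with period-aggregated performance
  (daily feed consumed, daily fresh manure weight, body weight, eggs);
* ``assays.csv`` — one manure-chemistry record per hen, with the air-dry
  recovery and analyte contents expressed on the air-dried-sample basis;
* ``feed.csv`` — a single diet-composition row on the as-fed basis.

All masses are grams, all contents g/kg. Validation is eager: malformed
rows are rejected with their row numbers so lab data problems surface at
load time, not as NaNs three stages later.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FeedComposition",
    "BirdRecord",
    "ManureAssay",
    "TrialDataset",
    "TrialValidationError",
    "read_trial",
    "write_trial",
    "aggregate_daily",
    "BIRD_COLUMNS",
    "ASSAY_COLUMNS",
    "FEED_COLUMNS",
]

BIRD_COLUMNS = [
    "bird_id",
    "line",
    "dfc",
    "dmw",
    "dbw",
    "eggs_laid",
    "mean_egg_weight",
    "expected_eggs",
    "period_days",
]
ASSAY_COLUMNS = [
    "bird_id",
    "adm",
    "dm_ad",
    "ash_ad",
    "nitrogen_ad",
    "fat_ad",
    "uric_acid_ad",
]
FEED_COLUMNS = ["dm", "nitrogen", "fat", "ash", "sugar"]


class TrialValidationError(ValueError):
    """Raised when trial inputs violate the documented schema or invariants."""


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise TrialValidationError(msg)


@dataclass(frozen=True)
class FeedComposition:
    """Diet nutrient contents on the as-fed basis (g/kg feed).

    ``sugar`` is carried for completeness but plays no role in the
    digestibility coefficients; it may be absent (``None``).
    """

    dm: float
    nitrogen: float
    fat: float
    ash: float
    sugar: float | None = None

    def __post_init__(self) -> None:
        for name in ("dm", "nitrogen", "fat", "ash"):
            v = getattr(self, name)
            _require(np.isfinite(v) and v >= 0, f"feed {name} must be finite and >= 0, got {v}")
        _require(self.dm <= 1000, f"feed dm must be <= 1000 g/kg, got {self.dm}")
        _require(
            self.nitrogen + self.fat + self.ash <= self.dm,
            "feed nitrogen + fat + ash exceeds dry matter content",
        )
        if self.sugar is not None:
            _require(self.sugar >= 0, f"feed sugar must be >= 0, got {self.sugar}")


@dataclass(frozen=True)
class BirdRecord:
    """One hen's period-aggregated trial record.

    dfc/dmw are daily means in g/day; dbw is the mean body weight in g.
    ``expected_eggs`` is the laying-percentage denominator (the egg
    collection window, default 8 days) while ``period_days`` is the
    feed-recording window used for FCR (default 7 days) — the two windows
    deliberately differ because day-0 eggs can roll into the collection.
    """

    bird_id: str
    line: str
    dfc: float
    dmw: float
    dbw: float
    eggs_laid: int
    mean_egg_weight: float | None = None
    expected_eggs: int = 8
    period_days: int = 7

    def __post_init__(self) -> None:
        _require(bool(str(self.bird_id)), "bird_id must be non-empty")
        _require(self.dfc > 0, f"bird {self.bird_id}: dfc must be > 0, got {self.dfc}")
        _require(self.dmw >= 0, f"bird {self.bird_id}: dmw must be >= 0, got {self.dmw}")
        _require(self.dbw > 0, f"bird {self.bird_id}: dbw must be > 0, got {self.dbw}")
        _require(self.eggs_laid >= 0, f"bird {self.bird_id}: eggs_laid must be >= 0")
        _require(self.expected_eggs > 0, f"bird {self.bird_id}: expected_eggs must be > 0")
        _require(self.period_days > 0, f"bird {self.bird_id}: period_days must be > 0")
        _require(
            self.eggs_laid <= self.expected_eggs,
            f"bird {self.bird_id}: eggs_laid ({self.eggs_laid}) exceeds expected_eggs "
            f"({self.expected_eggs})",
        )
        if self.eggs_laid > 0:
            _require(
                self.mean_egg_weight is not None and self.mean_egg_weight > 0,
                f"bird {self.bird_id}: mean_egg_weight must be > 0 when eggs were laid",
            )


@dataclass(frozen=True)
class ManureAssay:
    """Manure-chemistry record for one bird.

    ``adm`` is the air-dry recovery: grams of air-dried manure obtained per
    kg of fresh manure. All ``*_ad`` contents are on the air-dried-sample
    basis (g/kg air-dried sample); conversion to the dry-matter basis is
    done downstream via ``dm_ad``.
    """

    bird_id: str
    adm: float
    dm_ad: float
    ash_ad: float
    nitrogen_ad: float
    fat_ad: float
    uric_acid_ad: float

    def __post_init__(self) -> None:
        _require(0 <= self.adm <= 1000, f"assay {self.bird_id}: adm must be in [0, 1000] g/kg")
        _require(
            0 < self.dm_ad <= 1000, f"assay {self.bird_id}: dm_ad must be in (0, 1000] g/kg"
        )
        for name in ("ash_ad", "nitrogen_ad", "fat_ad", "uric_acid_ad"):
            v = getattr(self, name)
            _require(
                0 <= v <= self.dm_ad,
                f"assay {self.bird_id}: {name} = {v} outside [0, dm_ad = {self.dm_ad}]",
            )


@dataclass
class TrialDataset:
    """A validated trial: bird records, their manure assays and the diet."""

    birds: list[BirdRecord]
    assays: dict[str, ManureAssay]
    feed: FeedComposition

    def __post_init__(self) -> None:
        ids = [b.bird_id for b in self.birds]
        dupes = {i for i in ids if ids.count(i) > 1}
        _require(not dupes, f"duplicate bird_id(s): {sorted(dupes)}")
        orphans = sorted(set(self.assays) - set(ids))
        _require(not orphans, f"assay(s) reference unknown bird_id(s): {orphans}")

    def __len__(self) -> int:
        return len(self.birds)

    def bird(self, bird_id: str) -> BirdRecord:
        for b in self.birds:
            if b.bird_id == bird_id:
                return b
        raise KeyError(bird_id)

    def birds_frame(self) -> pd.DataFrame:
        return pd.DataFrame([_record_to_row(b, BIRD_COLUMNS) for b in self.birds])

    def assays_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [_record_to_row(self.assays[b.bird_id], ASSAY_COLUMNS) for b in self.birds
             if b.bird_id in self.assays],
            columns=ASSAY_COLUMNS,
        )


def _record_to_row(rec, columns: Sequence[str]) -> dict:
    return {c: getattr(rec, c) for c in columns}


# ---------------------------------------------------------------------------
# CSV I/O


def _check_columns(df: pd.DataFrame, expected: Sequence[str], what: str) -> None:
    unknown = [c for c in df.columns if c not in expected]
    missing = [c for c in expected if c not in df.columns and c != "sugar"]
    if unknown:
        raise TrialValidationError(f"{what}: unknown column(s) {unknown}")
    if missing:
        raise TrialValidationError(f"{what}: missing column(s) {missing}")


def _collect_rows(df: pd.DataFrame, builder, what: str) -> list:
    out, errors = [], []
    for i, row in df.iterrows():
        try:
            out.append(builder(row))
        except (TrialValidationError, ValueError, TypeError) as exc:
            errors.append(f"{what} row {i + 2}: {exc}")  # +2: header + 1-based
    if errors:
        raise TrialValidationError("; ".join(errors))
    return out


def read_trial(
    path_records: str | Path,
    path_assays: str | Path,
    path_feed: str | Path,
) -> TrialDataset:
    """Read and validate the three trial CSV files into a :class:`TrialDataset`.

    Raises :class:`TrialValidationError` naming the offending rows for any
    schema or invariant violation, including assays whose bird_id has no
    matching bird record.
    """
    for p in (path_records, path_assays, path_feed):
        if not Path(p).exists():
            raise FileNotFoundError(p)
    birds_df = pd.read_csv(
        path_records, dtype={"bird_id": str, "line": str}, float_precision="round_trip"
    )
    assays_df = pd.read_csv(path_assays, dtype={"bird_id": str}, float_precision="round_trip")
    feed_df = pd.read_csv(path_feed, float_precision="round_trip")
    _check_columns(birds_df, BIRD_COLUMNS, "birds")
    _check_columns(assays_df, ASSAY_COLUMNS, "assays")
    _check_columns(feed_df, FEED_COLUMNS, "feed")
    if len(feed_df) != 1:
        raise TrialValidationError(f"feed file must have exactly one row, got {len(feed_df)}")

    def build_bird(row) -> BirdRecord:
        mew = row.get("mean_egg_weight")
        return BirdRecord(
            bird_id=str(row["bird_id"]),
            line=str(row["line"]),
            dfc=float(row["dfc"]),
            dmw=float(row["dmw"]),
            dbw=float(row["dbw"]),
            eggs_laid=int(row["eggs_laid"]),
            mean_egg_weight=None if pd.isna(mew) else float(mew),
            expected_eggs=int(row.get("expected_eggs", 8)),
            period_days=int(row.get("period_days", 7)),
        )

    def build_assay(row) -> ManureAssay:
        return ManureAssay(
            bird_id=str(row["bird_id"]),
            adm=float(row["adm"]),
            dm_ad=float(row["dm_ad"]),
            ash_ad=float(row["ash_ad"]),
            nitrogen_ad=float(row["nitrogen_ad"]),
            fat_ad=float(row["fat_ad"]),
            uric_acid_ad=float(row["uric_acid_ad"]),
        )

    birds = _collect_rows(birds_df, build_bird, "birds")
    assays = _collect_rows(assays_df, build_assay, "assays")
    frow = feed_df.iloc[0]
    sugar = frow.get("sugar")
    feed = FeedComposition(
        dm=float(frow["dm"]),
        nitrogen=float(frow["nitrogen"]),
        fat=float(frow["fat"]),
        ash=float(frow["ash"]),
        sugar=None if sugar is None or pd.isna(sugar) else float(sugar),
    )
    return TrialDataset(birds=birds, assays={a.bird_id: a for a in assays}, feed=feed)


def write_trial(dataset: TrialDataset, out_dir: str | Path) -> dict[str, Path]:
    """Write ``birds.csv``, ``assays.csv`` and ``feed.csv`` under *out_dir*.

    Output is full precision so ``read_trial(**write_trial(d))`` reproduces
    the dataset field-for-field. Returns the written paths keyed by table.
    """
    if not dataset.birds:
        raise TrialValidationError("dataset has no birds; nothing to write")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "path_records": out / "birds.csv",
        "path_assays": out / "assays.csv",
        "path_feed": out / "feed.csv",
    }
    # %.17g keeps float round-trips exact
    dataset.birds_frame().to_csv(paths["path_records"], index=False, float_format="%.17g")
    dataset.assays_frame().to_csv(paths["path_assays"], index=False, float_format="%.17g")
    pd.DataFrame([_record_to_row(dataset.feed, FEED_COLUMNS)]).to_csv(
        paths["path_feed"], index=False, float_format="%.17g"
    )
    return paths


# ---------------------------------------------------------------------------
# Daily-row aggregation

MANURE_SAMPLING_DAYS = 3.5  # fresh-manure collection window: 7 subsamples over 3.5 days


def aggregate_daily(
    raw_daily_rows: pd.DataFrame | Iterable[Mapping],
    *,
    bird_id: str,
    line: str,
    manure_span_days: float = MANURE_SAMPLING_DAYS,
    feed_days: int | None = None,
    expected_eggs: int = 8,
    period_days: int = 7,
) -> BirdRecord:
    """Collapse one bird's raw daily rows into a :class:`BirdRecord`.

    Expected columns (all optional per row, aggregated where present):
    ``feed_consumed`` (g per weighing interval), ``manure_weight`` (g per
    subsample), ``body_weight`` (g), ``eggs`` (count laid that day),
    ``egg_weight`` (g, mean for that day's eggs).

    * dfc — mean of the feed-consumption entries; ``feed_days`` overrides
      the divisor when the averaging window differs from the number of
      weighings recorded.
    * dmw — total fresh manure divided by ``manure_span_days`` (the
      collection window, 3.5 days by default), making it a g/day rate
      commensurate with dfc.
    * dbw — mean of the body-weight measurements.

    The result is order-invariant in the input rows.
    """
    df = pd.DataFrame(raw_daily_rows)
    if df.empty:
        raise TrialValidationError(f"bird {bird_id}: no daily rows")
    for col in ("feed_consumed", "manure_weight", "body_weight"):
        if col in df.columns and (df[col].dropna() < 0).any():
            raise TrialValidationError(f"bird {bird_id}: negative {col}")

    feed = df["feed_consumed"].dropna() if "feed_consumed" in df.columns else pd.Series(dtype=float)
    if feed.empty:
        raise TrialValidationError(f"bird {bird_id}: no feed-weighing rows")
    dfc = feed.sum() / (feed_days if feed_days is not None else len(feed))

    manure = df["manure_weight"].dropna() if "manure_weight" in df.columns else pd.Series(dtype=float)
    dmw = manure.sum() / manure_span_days

    bw = df["body_weight"].dropna() if "body_weight" in df.columns else pd.Series(dtype=float)
    if bw.empty:
        raise TrialValidationError(f"bird {bird_id}: no body-weight rows")
    dbw = bw.mean()

    eggs = df["eggs"].dropna() if "eggs" in df.columns else pd.Series(dtype=float)
    eggs_laid = int(eggs.sum())
    mew = None
    if eggs_laid > 0:
        ew = df["egg_weight"].dropna() if "egg_weight" in df.columns else pd.Series(dtype=float)
        if ew.empty:
            raise TrialValidationError(f"bird {bird_id}: eggs laid but no egg weights")
        # weight rows are per laying day; weight each day's mean by its egg count
        w = df.loc[ew.index, "eggs"].fillna(0) if "eggs" in df.columns else pd.Series(1, index=ew.index)
        mew = float((ew * w).sum() / w.sum()) if w.sum() > 0 else float(ew.mean())
    return BirdRecord(
        bird_id=bird_id,
        line=line,
        dfc=float(dfc),
        dmw=float(dmw),
        dbw=float(dbw),
        eggs_laid=eggs_laid,
        mean_egg_weight=mew,
        expected_eggs=expected_eggs,
        period_days=period_days,
    )
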