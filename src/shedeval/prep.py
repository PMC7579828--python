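"""Phenotype preparation: filters, age classes, and contemporary groups.

Hair shedding scores (1-5 visual appraisal, 1 = fully shed) arrive with the
covariates that define management context.  This module applies the record
filters, classifies ages into BIF-style yearly windows, imputes missing
calving seasons, builds 7-day score groups, and assembles the six-part
contemporary group key (farm x year x calving season x fescue status x age
group x score group), dropping groups that are too small or invariant.

Age windows run from (n*365)-90 to ((n+1)*365)-90 days, lower bound
inclusive, upper exclusive; records younger than 275 days (the n=1 lower
bound) are removed rather than classified.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: Minimum age in days for a record to be usable; equals the n=1 window floor.
MIN_AGE_DAYS = 275

#: Default month -> calving season map (configurable).
DEFAULT_SEASON_OF_MONTH = {m: ("spring" if m <= 6 else "fall") for m in range(1, 13)}

#: Contemporary groups smaller than this are dropped.
MIN_CG_SIZE = 5

_BIF_EDGES = [(1, "yearling"), (2, "2"), (3, "3"), (4, "4"), (5, "5-9"),
              (10, "10"), (11, "11"), (12, "12"), (13, "13+")]


@dataclass(frozen=True)
class AgeClass:
    age_days: int
    class_n: int
    four_class: str  # "1", "2", "3", "other"
    bif_class: str


def assign_age_class(age_days: int) -> AgeClass | None:
    """Classify an age in days into its yearly window.

    Returns ``None`` for ages below the 275-day floor (the record should be
    flagged for removal, not raised on).
    """
    if age_days < MIN_AGE_DAYS:
        return None
    # lower-inclusive, upper-exclusive: (n*365)-90 <= age < ((n+1)*365)-90
    n = (age_days + 90) // 365
    four = str(n) if n <= 3 else "other"
    if n <= 4:
        bif = {1: "yearling", 2: "2", 3: "3", 4: "4"}[n]
    elif n <= 9:
        bif = "5-9"
    elif n <= 12:
        bif = str(n)
    else:
        bif = "13+"
    return AgeClass(int(age_days), int(n), four, bif)


def validate_records(records: pd.DataFrame, pedigree_meta: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the sex / age-floor / age-mismatch record filters.

    Parameters
    ----------
    records : DataFrame
        Must have ``animal_id``, ``age_days``; optionally ``sex``,
        ``breeder_reported_age`` (years).
    pedigree_meta : DataFrame
        Indexed by or containing ``animal_id`` with registered ``sex``.

    Returns
    -------
    (kept, removal_log)
        Every input record lands in exactly one of the two frames; the log
        carries a ``reason`` code per row.
    """
    rec = records.reset_index(drop=True).copy()
    meta = pedigree_meta.set_index("animal_id") if "animal_id" in pedigree_meta else pedigree_meta
    reasons = pd.Series("", index=rec.index, dtype=object)

    if "sex" in rec.columns and "sex" in meta.columns:
        ped_sex = rec["animal_id"].map(meta["sex"])
        mismatch = ped_sex.notna() & rec["sex"].notna() & (ped_sex != rec["sex"])
        reasons[mismatch & (reasons == "")] = "sex mismatch"
    ped_sex = rec["animal_id"].map(meta["sex"]) if "sex" in meta.columns else rec.get("sex")
    if ped_sex is not None:
        male = ped_sex.fillna(rec.get("sex", pd.Series(index=rec.index, dtype=object))) == "M"
        reasons[male & (reasons == "")] = "sex"

    young = rec["age_days"] < MIN_AGE_DAYS
    reasons[young & (reasons == "")] = "age < 275d"

    if "breeder_reported_age" in rec.columns:
        calc = rec["age_days"].map(
            lambda d: assign_age_class(d).class_n if d >= MIN_AGE_DAYS else np.nan
        )
        rep = pd.to_numeric(rec["breeder_reported_age"], errors="coerce")
        mism = (rep - calc).abs() > 2
        reasons[mism.fillna(False) & (reasons == "")] = "age mismatch > 2y"

    dropped = reasons != ""
    log = rec[dropped].assign(reason=reasons[dropped])
    return rec[~dropped].reset_index(drop=True), log.reset_index(drop=True)


def average_same_day_scores(records: pd.DataFrame) -> pd.DataFrame:
    """Collapse multiple scores on the same animal and day to their mean."""
    keys = ["animal_id", "date"]
    others = [c for c in records.columns if c not in keys + ["score"]]
    agg = {"score": "mean", **{c: "first" for c in others}}
    out = records.groupby(keys, as_index=False, sort=False).agg(agg)
    return out[records.columns.tolist()]


def impute_calving_season(
    records: pd.DataFrame,
    calving_history: pd.DataFrame | None = None,
    season_of_month: dict[int, str] | None = None,
) -> pd.DataFrame:
    """Fill missing calving seasons.

    Uses the most recent natural-birth calving date prior to the score date;
    when none exists, the animal's own birth date.  ``calving_history`` has
    columns ``animal_id``, ``calving_date`` (natural births only).
    """
    som = season_of_month or DEFAULT_SEASON_OF_MONTH
    rec = records.copy()
    missing = rec["calving_season"].isna() | (rec["calving_season"] == "")
    if not missing.any():
        return rec
    hist: dict[str, np.ndarray] = {}
    if calving_history is not None and len(calving_history):
        ch = calving_history.copy()
        ch["calving_date"] = pd.to_datetime(ch["calving_date"])
        hist = {
            a: np.sort(g["calving_date"].to_numpy())
            for a, g in ch.groupby("animal_id")
        }
    score_dates = pd.to_datetime(rec["date"])
    birth_dates = pd.to_datetime(rec["birth_date"]) if "birth_date" in rec else None
    for i in rec.index[missing]:
        animal = rec.at[i, "animal_id"]
        basis = None
        dates = hist.get(animal)
        if dates is not None:
            prior = dates[dates <= np.datetime64(score_dates[i])]
            if len(prior):
                basis = pd.Timestamp(prior[-1])
        if basis is None and birth_dates is not None:
            basis = birth_dates[i]
        if basis is not None and not pd.isna(basis):
            rec.at[i, "calving_season"] = som[basis.month]
    return rec


def build_score_groups(dates: pd.Series) -> pd.Series:
    """Greedy 7-day sliding-window score groups within one farm-year.

    Sort distinct dates ascending; open a window at the earliest unassigned
    date; every date within 6 days of the window start joins the group.
    Deterministic and near-optimal when scoring days cluster.
    """
    d = pd.to_datetime(dates)
    uniq = np.sort(d.unique())
    label_of = {}
    group = 0
    i = 0
    while i < len(uniq):
        start = uniq[i]
        group += 1
        while i < len(uniq) and (uniq[i] - start) <= np.timedelta64(6, "D"):
            label_of[uniq[i]] = f"sg{group}"
            i += 1
    return d.map(label_of)


CG_KEY = ["farm_id", "year", "calving_season", "fescue_status", "age_group", "score_group"]


def assemble_contemporary_groups(
    records: pd.DataFrame,
    min_size: int = MIN_CG_SIZE,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Build the six-part contemporary-group key and apply the group filters.

    Requires resolved covariate columns (``farm_id``, ``year``,
    ``calving_season``, ``fescue_status``, ``age_group``, ``score_group``).
    Groups with fewer than ``min_size`` records or zero score variance are
    dropped; their records go to the removal log.
    """
    rec = records.copy()
    rec["cg_id"] = rec[CG_KEY].astype(str).agg("/".join, axis=1)
    sizes = rec.groupby("cg_id")["score"].transform("size")
    variation = rec.groupby("cg_id")["score"].transform(lambda s: s.nunique() > 1)
    small = sizes < min_size
    flat = ~variation
    reasons = pd.Series("", index=rec.index, dtype=object)
    reasons[small] = "cg size < 5"
    reasons[flat & ~small] = "cg no variation"
    dropped = reasons != ""
    log = rec[dropped].assign(reason=reasons[dropped])
    return rec[~dropped].reset_index(drop=True), log.reset_index(drop=True)


def prepare_records(
    records: pd.DataFrame,
    pedigree_meta: pd.DataFrame,
    calving_history: pd.DataFrame | None = None,
    location_fescue_default: dict[str, str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full preparation: filters -> averaging -> imputation -> CG assembly.

    Idempotent: running the output back through changes nothing.  Returns
    (prepared records with ``cg_id``, removal log).
    """
    rec = records.copy()
    if location_fescue_default:
        missing = rec["fescue_status"].isna() | (rec["fescue_status"] == "")
        rec.loc[missing, "fescue_status"] = rec.loc[missing, "farm_id"].map(
            location_fescue_default
        )
    kept, log1 = validate_records(rec, pedigree_meta)
    kept = average_same_day_scores(kept)
    kept = impute_calving_season(kept, calving_history)
    if "year" not in kept.columns:
        kept["year"] = pd.to_datetime(kept["date"]).dt.year
    kept["age_group"] = kept["age_days"].map(lambda d: assign_age_class(d).four_class)
    if "score_group" not in kept.columns:
        kept["score_group"] = ""
    for (_, _), idx in kept.groupby(["farm_id", "year"]).groups.items():
        kept.loc[idx, "score_group"] = build_score_groups(kept.loc[idx, "date"]).values
    kept, log2 = assemble_contemporary_groups(kept)
    log = pd.concat([log1, log2], ignore_index=True)
    return kept, log
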