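"""August brood-survey aggregation: encounter rates and demographic indices.

Pointing-dog surveys record, per sampling block, the hours searched, the
number of females seen without a brood, and the chick count of every brood
encountered.  Blocks are pooled within a species-year (ratio of sums, not
mean of ratios) before computing:

* breeding success   = chicks per female,
* brood frequency    = proportion of females with >= 1 chick,
* brood size         = chicks per brood (undefined without broods),

so that ``breeding_success = brood_frequency * brood_size`` holds exactly
whenever at least one brood was seen.  "Females" counts both lone and
brooded hens; August surveys cannot separate failed breeders from
non-breeders.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

SURVEY_COLUMNS = ("year", "species", "block", "hours",
                  "females_no_brood", "brood_chicks")


@dataclass(frozen=True)
class DemographicIndex:
    """Annual demographic indices for one species, with their sample sizes."""

    year: int
    species: str
    n_females: int
    n_broods: int
    n_chicks: int
    breeding_success: float
    brood_frequency: float
    brood_size: float  # NaN when no broods were observed


def parse_brood_chicks(cell) -> list[int]:
    """Decode the semicolon-separated brood list of one survey record."""
    if cell is None or (isinstance(cell, float) and np.isnan(cell)):
        return []
    text = str(cell).strip()
    if not text:
        return []
    chicks = [int(tok) for tok in text.split(";")]
    if any(c < 1 for c in chicks):
        raise ValueError("every brood must contain at least one chick")
    return chicks


def load_survey(path) -> pd.DataFrame:
    """Read a survey CSV (`year,species,block,hours,females_no_brood,brood_chicks`)."""
    df = pd.read_csv(path, keep_default_na=False,
                     dtype={"brood_chicks": str})
    df["year"] = df["year"].astype(int)
    df["hours"] = df["hours"].astype(float)
    df["females_no_brood"] = df["females_no_brood"].astype(int)
    return validate_survey(df)


def validate_survey(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in SURVEY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"survey frame lacks columns: {missing}")
    if (df["hours"].to_numpy(dtype=float) <= 0).any():
        raise ValueError("sampling_hours must be > 0")
    if (df["females_no_brood"].to_numpy(dtype=float) < 0).any():
        raise ValueError("counts must be non-negative")
    df["brood_chicks"].map(parse_brood_chicks)  # raises on malformed cells
    return df


def encounter_rate(records: pd.DataFrame) -> float:
    """Birds per 10 hours of sampling, pooled over the given records.

    Birds = lone females + brooded hens + their chicks + any ``other_birds``
    column present.  Effort is pooled before dividing, so splitting a
    block's effort into sub-records cannot change the rate.
    """
    hours = float(records["hours"].sum())
    if hours <= 0:
        raise ValueError("total sampling hours must be > 0")
    birds = int(records["females_no_brood"].sum())
    for cell in records["brood_chicks"]:
        chicks = parse_brood_chicks(cell)
        birds += len(chicks) + sum(chicks)
    if "other_birds" in records.columns:
        birds += int(records["other_birds"].sum())
    return 10.0 * birds / hours


def demographic_indices(year: int, species: str, females_without_brood: int,
                        broods: list[int]) -> DemographicIndex:
    """The three demographic indices from pooled species-year counts."""
    if females_without_brood < 0:
        raise ValueError("counts must be non-negative")
    if any(b < 1 for b in broods):
        raise ValueError("every brood must contain at least one chick")
    n_broods = len(broods)
    n_chicks = int(sum(broods))
    n_females = females_without_brood + n_broods
    if n_females < 1:
        raise ValueError("no females observed")
    return DemographicIndex(
        year=year, species=species,
        n_females=n_females, n_broods=n_broods, n_chicks=n_chicks,
        breeding_success=n_chicks / n_females,
        brood_frequency=n_broods / n_females,
        brood_size=n_chicks / n_broods if n_broods else float("nan"))


def annual_table(records: pd.DataFrame) -> pd.DataFrame:
    """One row of demographic indices per species-year, blocks pooled.

    Years inside each species' observed span with no female observations are
    emitted with NaN indices so downstream regressions see them as missing.
    """
    validate_survey(records)
    rows = []
    for species, sub in records.groupby("species"):
        span = range(int(sub["year"].min()), int(sub["year"].max()) + 1)
        by_year = dict(tuple(sub.groupby("year")))
        for year in span:
            grp = by_year.get(year)
            broods: list[int] = []
            lone = 0
            if grp is not None:
                lone = int(grp["females_no_brood"].sum())
                for cell in grp["brood_chicks"]:
                    broods.extend(parse_brood_chicks(cell))
            if grp is None or lone + len(broods) == 0:
                rows.append({"year": year, "species": species,
                             "breeding_success": np.nan,
                             "brood_frequency": np.nan, "brood_size": np.nan,
                             "n_females": 0, "n_broods": 0, "n_chicks": 0})
                continue
            idx = demographic_indices(year, species, lone, broods)
            rows.append({"year": idx.year, "species": idx.species,
                         "breeding_success": idx.breeding_success,
                         "brood_frequency": idx.brood_frequency,
                         "brood_size": idx.brood_size,
                         "n_females": idx.n_females,
                         "n_broods": idx.n_broods,
                         "n_chicks": idx.n_chicks})
    out = pd.DataFrame(rows).sort_values(["species", "year"])
    return out.reset_index(drop=True)
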