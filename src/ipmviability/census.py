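"""Census table I/O, survival-record correction, and life-cycle state labelling.

Long-term plant censuses record, for every tagged individual in every year,
whether it was found alive, its rosette diameter, and its fruit count.  Two
patterns in such records need special handling before demographic modelling:

* **Reincarnation** — a plant that is dormant belowground is scored dead,
  then reappears.  Interior "deaths" flanked by live observations are
  corrected to live records, and dormancy is scored as a derived variable by
  comparing the raw and corrected survival strings.
* **Bolters** — plants reproducing from the terminal bud are alive but have
  no measurable basal rosette (diameter 0 or missing).

Every plant-year is classified into exactly one of NORMAL, BOLTER, DORMANT,
DEAD or PRE_RECRUIT.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import CensusValidationError, ConfigurationError

# discrete life-cycle states
NORMAL = "normal"
BOLTER = "bolter"
DORMANT = "dormant"
DEAD = "dead"
PRE_RECRUIT = "pre_recruit"

LIVE_STATES = (NORMAL, BOLTER, DORMANT)

CANONICAL_COLUMNS = (
    "population",
    "transect",
    "quadrat",
    "plant_id",
    "year",
    "diameter_mm",
    "survival",
    "fruits",
)

_KEY = ["population", "transect", "quadrat", "plant_id", "year"]


def default_dialect() -> dict:
    """Identity column mapping plus common missing-value codes."""
    return {
        "columns": {c: c for c in CANONICAL_COLUMNS},
        "na_values": ["", "NA", "na", "NaN", "nan", "."],
    }


# ---------------------------------------------------------------------------
# survival-string algebra
# ---------------------------------------------------------------------------

def _check_binary(s: str) -> None:
    if not isinstance(s, str) or len(s) == 0:
        raise CensusValidationError("survival history must be a non-empty string")
    bad = set(s) - {"0", "1"}
    if bad:
        raise CensusValidationError(
            f"survival history contains non-binary characters: {sorted(bad)!r}"
        )


def correct_reincarnation(raw_survival: str) -> str:
    """Flip interior deaths flanked by live observations to live records.

    Every '0' strictly between the first and the last '1' becomes '1';
    leading zeros (pre-recruitment) and trailing zeros (post-death) are
    untouched.  Idempotent.

    >>> correct_reincarnation("00011101")
    '00011111'
    """
    _check_binary(raw_survival)
    first = raw_survival.find("1")
    if first == -1:
        return raw_survival
    last = raw_survival.rfind("1")
    return raw_survival[:first] + "1" * (last - first + 1) + raw_survival[last + 1:]


def score_dormancy(raw_survival: str, corrected_survival: str) -> str:
    """Flag string with '1' exactly where corrected=1 and raw=0.

    Dormancy is a derived variable: the census scored the plant dead but the
    corrected record shows it was alive belowground.
    """
    _check_binary(raw_survival)
    _check_binary(corrected_survival)
    if len(raw_survival) != len(corrected_survival):
        raise CensusValidationError(
            "raw and corrected survival strings differ in length "
            f"({len(raw_survival)} vs {len(corrected_survival)})"
        )
    return "".join(
        "1" if c == "1" and r == "0" else "0"
        for r, c in zip(raw_survival, corrected_survival)
    )


def _size_missing(diameter_mm) -> bool:
    # diameter 0 and missing both mean "no measurable rosette"
    if diameter_mm is None:
        return True
    try:
        v = float(diameter_mm)
    except (TypeError, ValueError):
        return True
    return math.isnan(v) or v == 0.0


def classify_state(alive: int, diameter_mm, dormant_flag: int) -> str:
    """Classify one plant-year into a discrete life-cycle state.

    Dormancy takes precedence by definition; an alive plant with no
    measurable rosette is a bolter; otherwise alive plants are normal.
    """
    if dormant_flag:
        if not alive:
            raise CensusValidationError("dormant_flag=1 requires alive=1")
        return DORMANT
    if alive:
        return BOLTER if _size_missing(diameter_mm) else NORMAL
    return DEAD


# ---------------------------------------------------------------------------
# records I/O
# ---------------------------------------------------------------------------

def validate_records(df: pd.DataFrame) -> None:
    """Check structural invariants of a canonical census table."""
    missing = [c for c in CANONICAL_COLUMNS if c not in df.columns]
    if missing:
        raise ConfigurationError(f"census table lacks canonical columns: {missing}")
    dup = df.duplicated(subset=_KEY)
    if dup.any():
        rows = df.index[dup].tolist()[:10]
        raise CensusValidationError(
            f"duplicated (population, transect, quadrat, plant_id, year) keys at rows {rows}"
        )
    for col in ("diameter_mm", "fruits"):
        neg = df.index[df[col].to_numpy(dtype=float) < 0].tolist()
        if neg:
            raise CensusValidationError(f"negative {col} at rows {neg[:10]}")
    surv = df["survival"].dropna()
    bad = surv[~surv.isin([0, 1, 0.0, 1.0])]
    if len(bad):
        raise CensusValidationError(
            f"survival must be 0/1; offending rows {bad.index.tolist()[:10]}"
        )


def read_census(path, dialect: dict | None = None) -> pd.DataFrame:
    """Read a long-format census CSV into the canonical column layout.

    Parameters
    ----------
    path : path-like
        CSV file with a header row.
    dialect : dict, optional
        ``{"columns": {canonical: actual}, "na_values": [...]}``; unmapped
        canonical columns or unresolvable actual columns raise
        :class:`ConfigurationError`.
    """
    d = default_dialect()
    if dialect:
        d["columns"].update(dialect.get("columns", {}))
        if "na_values" in dialect:
            d["na_values"] = list(dialect["na_values"])
    colmap = d["columns"]
    unmapped = [c for c in CANONICAL_COLUMNS if c not in colmap]
    if unmapped:
        raise ConfigurationError(f"dialect does not map canonical columns {unmapped}")

    df = pd.read_csv(path, na_values=d["na_values"], keep_default_na=True)
    absent = [src for src in colmap.values() if src not in df.columns]
    if absent:
        raise ConfigurationError(
            f"columns {absent} not present in {path}; available: {list(df.columns)}"
        )
    df = df[[colmap[c] for c in CANONICAL_COLUMNS]]
    df.columns = list(CANONICAL_COLUMNS)

    if df["year"].isna().any():
        raise CensusValidationError("year column contains missing values")
    df["year"] = df["year"].astype(int)
    for col in ("diameter_mm", "survival", "fruits"):
        df[col] = pd.to_numeric(df[col], errors="raise")
    validate_records(df)
    return df.sort_values(_KEY).reset_index(drop=True)


def write_census(df: pd.DataFrame, path) -> None:
    """Write a canonical census table; missing values become empty fields."""
    df.to_csv(path, index=False, na_rep="")


# ---------------------------------------------------------------------------
# individual histories
# ---------------------------------------------------------------------------

@dataclass
class IndividualHistory:
    """One plant's per-year record with derived state labels."""

    population: str
    transect: str
    quadrat: str
    plant_id: str
    years: tuple
    raw_survival: str
    corrected_survival: str
    dormant_flags: str
    states: tuple
    sizes: np.ndarray     # diameter (mm); NaN when absent or sizeless
    fruits: np.ndarray    # NaN when unrecorded

    @property
    def ever_alive(self) -> bool:
        return "1" in self.corrected_survival

    @property
    def recruitment_year(self):
        """First census year observed alive, or None for all-zero records."""
        i = self.corrected_survival.find("1")
        return None if i == -1 else self.years[i]

    @property
    def is_reincarnate(self) -> bool:
        return "1" in self.dormant_flags

    @property
    def ever_bolter(self) -> bool:
        return BOLTER in self.states

    def n_dormant_years(self) -> int:
        return self.dormant_flags.count("1")


def build_histories(df: pd.DataFrame, require_consecutive: bool = True) -> list[IndividualHistory]:
    """Reconstruct per-plant histories from a canonical census table.

    Years absent for a plant (within the global census span) are treated as
    "not found" (survival 0), which is what the reincarnation correction then
    repairs when the plant is seen alive later.

    The correction itself is applied as a vectorized running-maximum trick —
    a year is corrected-alive iff some live observation exists both at/before
    and at/after it — which is exactly :func:`correct_reincarnation` applied
    row-wise (property-tested against it).
    """
    validate_records(df)
    years = np.sort(df["year"].unique())
    if len(years) == 0:
        return []
    if require_consecutive and not np.all(np.diff(years) == 1):
        raise CensusValidationError(
            f"census years are not consecutive: {years.tolist()}"
        )
    n_years = len(years)
    year_pos = pd.Series(np.arange(n_years), index=years)

    keys = pd.MultiIndex.from_frame(
        df[["population", "transect", "quadrat", "plant_id"]].astype(str))
    plant_codes, plant_keys = pd.factorize(keys, sort=True)
    n_plants = len(plant_keys)
    yi = year_pos.loc[df["year"]].to_numpy()

    alive_col = df["survival"].fillna(0).astype(int).to_numpy()
    diam_col = df["diameter_mm"].to_numpy(dtype=float)
    fruit_col = df["fruits"].to_numpy(dtype=float)
    dead_with_size = (alive_col == 0) & np.isfinite(diam_col) & (diam_col > 0)
    if dead_with_size.any():
        rows = df.index[dead_with_size].tolist()[:10]
        raise CensusValidationError(
            f"diameter recorded for plants scored dead at rows {rows}"
        )

    raw = np.zeros((n_plants, n_years), dtype=np.int8)
    sizes = np.full((n_plants, n_years), np.nan)
    fruits = np.full((n_plants, n_years), np.nan)
    raw[plant_codes, yi] = alive_col
    has_size = (alive_col == 1) & np.isfinite(diam_col) & (diam_col > 0)
    sizes[plant_codes[has_size], yi[has_size]] = diam_col[has_size]
    has_fruit = (alive_col == 1) & np.isfinite(fruit_col)
    fruits[plant_codes[has_fruit], yi[has_fruit]] = fruit_col[has_fruit]

    seen_before = np.maximum.accumulate(raw, axis=1)
    seen_after = np.maximum.accumulate(raw[:, ::-1], axis=1)[:, ::-1]
    corrected = (seen_before & seen_after).astype(np.int8)
    flags = ((corrected == 1) & (raw == 0)).astype(np.int8)

    sizeless = ~np.isfinite(sizes)
    states_m = np.full((n_plants, n_years), PRE_RECRUIT, dtype=object)
    states_m[(corrected == 0) & (seen_before == 1)] = DEAD
    states_m[(corrected == 1) & ~sizeless] = NORMAL
    states_m[(corrected == 1) & sizeless] = BOLTER
    states_m[flags == 1] = DORMANT

    year_tuple = tuple(int(y) for y in years)
    digits = np.char.mod("%d", raw)
    histories = []
    for p in range(n_plants):
        pop, tr, q, pid = plant_keys[p]
        raw_s = "".join(digits[p])
        corr_s = "".join("1" if c else "0" for c in corrected[p])
        flag_s = "".join("1" if c else "0" for c in flags[p])
        histories.append(
            IndividualHistory(
                population=pop, transect=tr, quadrat=q, plant_id=pid,
                years=year_tuple, raw_survival=raw_s,
                corrected_survival=corr_s, dormant_flags=flag_s,
                states=tuple(states_m[p]), sizes=sizes[p], fruits=fruits[p],
            )
        )
    return histories


@dataclass
class CohortSummary:
    """Counts the data-correction step reports for a set of histories."""

    total_plants: int
    n_reincarnates: int
    n_bolters: int
    alive_by_year: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "total_plants": self.total_plants,
            "n_reincarnates": self.n_reincarnates,
            "n_bolters": self.n_bolters,
            "alive_by_year": {str(k): v for k, v in self.alive_by_year.items()},
        }


def summarize_cohort(histories: list[IndividualHistory]) -> CohortSummary:
    """Total plants, plants with ≥1 dormant year, plants with ≥1 bolter year."""
    if not histories:
        return CohortSummary(0, 0, 0, {})
    years = histories[0].years
    alive = {y: 0 for y in years}
    reinc = bolt = 0
    for h in histories:
        reinc += h.is_reincarnate
        bolt += h.ever_bolter
        for y, c in zip(h.years, h.corrected_survival):
            alive[y] += c == "1"
    return CohortSummary(len(histories), reinc, bolt, alive)


@dataclass
class PopulationCensus:
    """Histories of one population together with its sampling effort."""

    population: str
    n_quadrats: int
    histories: list[IndividualHistory]

    def __post_init__(self):
        if self.n_quadrats < 1:
            raise CensusValidationError("n_quadrats must be >= 1")

    @property
    def annual_counts(self) -> dict:
        return summarize_cohort(self.histories).alive_by_year

    def annual_densities(self) -> dict:
        return {
            y: density_from_counts(c, self.n_quadrats)
            for y, c in self.annual_counts.items()
        }


def density_from_counts(count: float, n_quadrats: int) -> float:
    """Individuals per m² given a count over ``n_quadrats`` 1 m² quadrats."""
    if count < 0:
        raise CensusValidationError("count must be nonnegative")
    if n_quadrats < 1:
        raise CensusValidationError("n_quadrats must be >= 1")
    return count / n_quadrats


def corrected_table(histories: list[IndividualHistory]) -> pd.DataFrame:
    """Long-format table after correction, with state and dormancy columns."""
    rows = []
    for h in histories:
        for i, y in enumerate(h.years):
            if h.states[i] == PRE_RECRUIT:
                continue
            rows.append({
                "population": h.population, "transect": h.transect,
                "quadrat": h.quadrat, "plant_id": h.plant_id, "year": y,
                "diameter_mm": h.sizes[i],
                "survival": int(h.corrected_survival[i]),
                "raw_survival": int(h.raw_survival[i]),
                "dormant": int(h.dormant_flags[i]),
                "state": h.states[i],
                "fruits": h.fruits[i],
            })
    return pd.DataFrame(rows)
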