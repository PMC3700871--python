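"""Core data model and CSV I/O for carcass-search mortality studies.

Two tables drive everything downstream:

* a *night table* with one row per turbine-night (carcasses found,
  acoustic bat activity, nightly median wind speed, whether the plot was
  searched that morning), and
* a *detection table* with one row per turbine holding the search effort
  and the detection-process parameters: fall-in proportion ``a`` (share of
  kills landing inside the searched plot), daily carcass persistence
  probability ``s``, searcher efficiency ``f`` and the composite carcass
  detection probability ``p``, each with a 95% confidence interval where
  estimated.

The detection table of the 30-turbine German study that motivated this
package, together with its per-year aggregates and the published
regression coefficients, is bundled as fixtures (``load_example_*``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence, Union

import pandas as pd

__all__ = [
    "FormatError",
    "ValidationError",
    "NightRecord",
    "TurbineDetection",
    "Dataset",
    "read_detection_table",
    "write_detection_table",
    "read_night_table",
    "write_night_table",
    "summarize_dataset",
    "load_example_detection_table",
    "load_example_year_summary",
    "load_example_coefficients",
]

#: Column order of the on-disk detection table.
DETECTION_COLUMNS = [
    "turbine", "year", "C", "T", "a",
    "s", "s_lwr", "s_upr", "f", "f_lwr", "f_upr", "p", "p_lwr", "p_upr",
]

#: Column order of the on-disk night table.
NIGHT_COLUMNS = ["turbine", "night", "count", "activity", "wind", "searched"]


class FormatError(ValueError):
    """The file does not have the documented structure (missing columns etc.)."""


class ValidationError(ValueError):
    """The file parses but a value violates a domain invariant."""


@dataclass(frozen=True)
class NightRecord:
    """One turbine-night.

    ``night_index`` is 1-based and labels the 24-h interval ending at the
    morning search.  ``carcass_count`` is the number of carcasses found at
    that search; on nights without a search it must be 0 (nothing was
    looked for) and the row only carries covariates.
    """

    turbine_id: str
    night_index: int
    carcass_count: int
    activity: int
    wind: float
    searched: bool = True

    def __post_init__(self) -> None:
        if self.night_index < 1:
            raise ValidationError(
                f"turbine {self.turbine_id}: night_index must be >= 1, "
                f"got {self.night_index}")
        if self.carcass_count < 0 or self.activity < 0:
            raise ValidationError(
                f"turbine {self.turbine_id} night {self.night_index}: "
                "counts must be non-negative")
        if not math.isfinite(self.wind) or self.wind < 0:
            raise ValidationError(
                f"turbine {self.turbine_id} night {self.night_index}: "
                f"wind must be a non-negative real, got {self.wind}")
        if not self.searched and self.carcass_count != 0:
            raise ValidationError(
                f"turbine {self.turbine_id} night {self.night_index}: "
                "carcass_count must be 0 on unsearched nights")


def _check_prob(value: float, name: str, turbine: object) -> None:
    if not 0.0 <= value <= 1.0:
        raise ValidationError(
            f"turbine {turbine}: {name}={value} outside [0, 1]")


@dataclass(frozen=True)
class TurbineDetection:
    """Per-turbine search effort and detection parameters with uncertainty.

    ``total_found`` is the carcass total over the ``n_searches`` searches.
    The fall-in proportion is treated as known without error; persistence,
    efficiency and the composite detection probability carry 95% CIs.
    """

    turbine_id: str
    year: int
    total_found: int
    n_searches: int
    fall_in: float
    persistence_mean: float
    persistence_ci: tuple[float, float]
    efficiency_mean: float
    efficiency_ci: tuple[float, float]
    detection_mean: float
    detection_ci: tuple[float, float]

    def __post_init__(self) -> None:
        if self.total_found < 0:
            raise ValidationError(
                f"turbine {self.turbine_id}: total_found must be >= 0")
        if self.n_searches < 1:
            raise ValidationError(
                f"turbine {self.turbine_id}: n_searches must be >= 1")
        _check_prob(self.fall_in, "a", self.turbine_id)
        for name, mean, ci in [
            ("s", self.persistence_mean, self.persistence_ci),
            ("f", self.efficiency_mean, self.efficiency_ci),
            ("p", self.detection_mean, self.detection_ci),
        ]:
            _check_prob(mean, name, self.turbine_id)
            _check_prob(ci[0], f"{name}_lwr", self.turbine_id)
            _check_prob(ci[1], f"{name}_upr", self.turbine_id)
            if ci[0] > ci[1]:
                raise ValidationError(
                    f"turbine {self.turbine_id}: {name} CI lower > upper")
        # Published tables occasionally show a point estimate outside its
        # own CI (a typesetting artefact); rows are accepted and only the
        # CI *width* is consumed downstream (see the priors module).


@dataclass
class Dataset:
    """A night table together with the detection table it refers to."""

    nights: list[NightRecord] = field(default_factory=list)
    detections: dict[str, TurbineDetection] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = {r.turbine_id for r in self.nights} - set(self.detections)
        if missing:
            raise ValidationError(
                "turbines present in night table but missing from the "
                f"detection table: {sorted(missing)}")

    def turbine_ids(self) -> list[str]:
        """Turbines in night-table order (detection-table order if no nights)."""
        if self.nights:
            seen: dict[str, None] = {}
            for r in self.nights:
                seen.setdefault(r.turbine_id, None)
            return list(seen)
        return list(self.detections)

    def nights_for(self, turbine_id: str) -> list[NightRecord]:
        return [r for r in self.nights if r.turbine_id == turbine_id]


# ---------------------------------------------------------------------------
# Detection table I/O


def _detection_from_row(row: Mapping, rownum: int) -> TurbineDetection:
    try:
        return TurbineDetection(
            turbine_id=str(row["turbine"]),
            year=int(row["year"]),
            total_found=int(row["C"]),
            n_searches=int(row["T"]),
            fall_in=float(row["a"]),
            persistence_mean=float(row["s"]),
            persistence_ci=(float(row["s_lwr"]), float(row["s_upr"])),
            efficiency_mean=float(row["f"]),
            efficiency_ci=(float(row["f_lwr"]), float(row["f_upr"])),
            detection_mean=float(row["p"]),
            detection_ci=(float(row["p_lwr"]), float(row["p_upr"])),
        )
    except (TypeError, ValueError) as exc:
        if isinstance(exc, ValidationError):
            raise ValidationError(f"row {rownum}: {exc}") from None
        raise ValidationError(f"row {rownum}: {exc}") from exc


def read_detection_table(path: Union[str, Path]) -> list[TurbineDetection]:
    """Read a per-turbine detection-parameter CSV.

    Raises :class:`FormatError` for an empty file or missing columns and
    :class:`ValidationError` (with the 1-based data row number) for values
    violating domain invariants.
    """
    try:
        df = pd.read_csv(path, comment="#", float_precision="round_trip")
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: empty file") from None
    missing = [c for c in DETECTION_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    # note: row dicts keep per-column dtypes (iterrows would upcast)
    return [_detection_from_row(row, i + 1)
            for i, row in enumerate(df.to_dict("records"))]


def write_detection_table(
    records: Iterable[TurbineDetection], path: Union[str, Path]
) -> None:
    rows = []
    for r in records:
        rows.append({
            "turbine": r.turbine_id, "year": r.year, "C": r.total_found,
            "T": r.n_searches, "a": r.fall_in,
            "s": r.persistence_mean, "s_lwr": r.persistence_ci[0],
            "s_upr": r.persistence_ci[1],
            "f": r.efficiency_mean, "f_lwr": r.efficiency_ci[0],
            "f_upr": r.efficiency_ci[1],
            "p": r.detection_mean, "p_lwr": r.detection_ci[0],
            "p_upr": r.detection_ci[1],
        })
    pd.DataFrame(rows, columns=DETECTION_COLUMNS).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Night table I/O


def read_night_table(path: Union[str, Path]) -> list[NightRecord]:
    """Read a per-turbine-night CSV, returning records sorted by
    (turbine, night) with consecutive 1-based night indices enforced."""
    try:
        df = pd.read_csv(path, comment="#", float_precision="round_trip")
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: empty file") from None
    missing = [c for c in NIGHT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")

    records = []
    for i, row in enumerate(df.to_dict("records")):
        try:
            records.append(NightRecord(
                turbine_id=str(row["turbine"]),
                night_index=int(row["night"]),
                carcass_count=int(row["count"]),
                activity=int(row["activity"]),
                wind=float(row["wind"]),
                searched=_parse_bool(row["searched"]),
            ))
        except (TypeError, ValueError) as exc:
            raise ValidationError(f"row {i + 1}: {exc}") from None
    records.sort(key=lambda r: (r.turbine_id, r.night_index))
    _check_consecutive(records)
    return records


def _parse_bool(value: object) -> bool:
    if isinstance(value, bool):
        return value
    text = str(value).strip().lower()
    if text in {"true", "1", "yes"}:
        return True
    if text in {"false", "0", "no"}:
        return False
    raise ValueError(f"cannot parse boolean from {value!r}")


def _check_consecutive(records: Sequence[NightRecord]) -> None:
    expected: dict[str, int] = {}
    for r in records:
        want = expected.get(r.turbine_id, 1)
        if r.night_index != want:
            raise ValidationError(
                f"turbine {r.turbine_id}: night indices must be consecutive "
                f"from 1; expected {want}, got {r.night_index}")
        expected[r.turbine_id] = want + 1


def write_night_table(records: Iterable[NightRecord], path: Union[str, Path]) -> None:
    rows = [{
        "turbine": r.turbine_id, "night": r.night_index,
        "count": r.carcass_count, "activity": r.activity,
        "wind": repr(r.wind), "searched": r.searched,
    } for r in records]
    pd.DataFrame(rows, columns=NIGHT_COLUMNS).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Summaries and bundled fixtures


def summarize_dataset(
    data: Union[Dataset, Iterable[TurbineDetection]]
) -> pd.DataFrame:
    """Per-year study aggregates: turbines, turbine-nights (search effort),
    carcass totals, and the unweighted mean composite detection probability.
    """
    detections: Iterable[TurbineDetection]
    detections = data.detections.values() if isinstance(data, Dataset) else data
    detections = list(detections)
    if not detections:
        raise ValidationError("empty dataset")
    df = pd.DataFrame({
        "year": [d.year for d in detections],
        "C": [d.total_found for d in detections],
        "T": [d.n_searches for d in detections],
        "p": [d.detection_mean for d in detections],
    })
    out = df.groupby("year").agg(
        n_turbines=("C", "size"),
        total_carcasses=("C", "sum"),
        turbine_nights=("T", "sum"),
        mean_detection=("p", "mean"),
    ).reset_index()
    return out


def _fixture(name: str):
    return resources.files("windmort.data").joinpath(name)


def load_example_detection_table() -> list[TurbineDetection]:
    """The bundled 30-turbine detection table (12 turbines 2007, 18 in 2008)."""
    with resources.as_file(_fixture("table2_detection.csv")) as path:
        return read_detection_table(path)


def load_example_year_summary() -> pd.DataFrame:
    """Published per-year aggregates, including the wind mean/SD used for
    back-transforming standardized wind coefficients."""
    with resources.as_file(_fixture("table1_summary.csv")) as path:
        return pd.read_csv(path)


def load_example_coefficients() -> pd.DataFrame:
    """Published posterior-mean regression coefficients per year and
    observation-model variant, with mortality totals for comparison."""
    with resources.as_file(_fixture("table4_coefficients.csv")) as path:
        return pd.read_csv(path)
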