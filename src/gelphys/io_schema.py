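"""Validated tabular I/O and the shared domain records used by every stage.

All quantities carry fixed units throughout the package: masses in mg,
volumes in mL, swelling/release time in hours, degradation time in days,
temperature in °C, molar mass in g·mol⁻¹, concentrations in µg/mL,
fluorescence in arbitrary units (a.u.), lengths in Å.  No function performs
implicit unit conversion.

Files are comma-separated text with a dot decimal separator and a single
header row.  Missing values are not permitted: an aliquot that was not taken
is an omitted row, never a blank cell.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

__all__ = [
    "SchemaError",
    "GravimetricSeries",
    "GpcSeries",
    "SolGelMasses",
    "ReleaseExperiment",
    "PlateReadings",
    "CalibrationPoint",
    "StructureRecord",
    "SCHEMAS",
    "load_table",
    "write_table",
]


class SchemaError(ValueError):
    """A table does not conform to its declared schema.

    Carries the offending row number (1-based, counting data rows) when the
    problem is attributable to a single row.
    """

    def __init__(self, message: str, row: int | None = None):
        self.row = row
        if row is not None:
            message = f"row {row}: {message}"
        super().__init__(message)


# ---------------------------------------------------------------------------
# domain records


@dataclass
class GravimetricSeries:
    """One sample's dry mass plus timed wet masses at one temperature.

    ``observations`` is an ordered list of ``(t_hours, wet_mass_mg)`` pairs
    with strictly increasing times.
    """

    sample_id: str
    crosslinker_label: str
    temperature_c: float
    m0_mg: float
    observations: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.m0_mg <= 0:
            raise SchemaError(f"dry mass must be positive, got {self.m0_mg}")
        if not self.observations:
            raise SchemaError(f"series {self.sample_id!r} has no observations")
        times = [t for t, _ in self.observations]
        for i in range(1, len(times)):
            if times[i] <= times[i - 1]:
                raise SchemaError(
                    f"times must be strictly increasing, got {times[i]} after "
                    f"{times[i - 1]}",
                    row=i + 1,
                )
        if times[0] < 0:
            raise SchemaError(f"negative time {times[0]}", row=1)
        for i, (_, mt) in enumerate(self.observations):
            if mt <= 0:
                raise SchemaError(f"wet mass must be positive, got {mt}", row=i + 1)


@dataclass
class GpcSeries:
    """Number-average molar mass Mn (g·mol⁻¹) versus storage time in days.

    A day-0 entry is required so retention can be normalised.
    """

    polymer_label: str
    observations: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.observations:
            raise SchemaError(f"series {self.polymer_label!r} has no observations")
        days = [d for d, _ in self.observations]
        if days[0] != 0:
            raise SchemaError(
                f"series {self.polymer_label!r} must start at day 0, got {days[0]}"
            )
        for i in range(1, len(days)):
            if days[i] <= days[i - 1]:
                raise SchemaError(
                    f"days must be strictly increasing, got {days[i]} after "
                    f"{days[i - 1]}",
                    row=i + 1,
                )
        for i, (_, mn) in enumerate(self.observations):
            if mn <= 0:
                raise SchemaError(f"Mn must be positive, got {mn}", row=i + 1)


@dataclass
class SolGelMasses:
    """Pre-reaction precursor dry mass W0 and washed-and-dried gel mass W1 (mg)."""

    sample_id: str
    w0_mg: float
    w1_mg: float

    def __post_init__(self) -> None:
        if self.w0_mg <= 0:
            raise SchemaError(f"W0 must be positive, got {self.w0_mg}")
        if not 0 <= self.w1_mg <= self.w0_mg:
            raise SchemaError(
                f"W1 must satisfy 0 <= W1 <= W0, got W1={self.w1_mg}, W0={self.w0_mg}"
            )


@dataclass
class ReleaseExperiment:
    """Aliquot fluorescence series plus the volumes needed for correction.

    ``volume_ml`` is the release-medium volume V, ``aliquot_ml`` the sampled
    (and replaced) volume v, ``loaded_mass_ug`` the solute mass initially in
    the gel.  ``observations`` is ``(t_hours, intensity_au)`` with strictly
    increasing times.
    """

    sample_id: str
    volume_ml: float
    aliquot_ml: float
    loaded_mass_ug: float
    observations: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.volume_ml <= 0:
            raise SchemaError(f"medium volume must be positive, got {self.volume_ml}")
        if not 0 <= self.aliquot_ml < self.volume_ml:
            raise SchemaError(
                f"aliquot volume must satisfy 0 <= v < V, got v={self.aliquot_ml}, "
                f"V={self.volume_ml}"
            )
        if self.loaded_mass_ug <= 0:
            raise SchemaError(
                f"loaded mass must be positive, got {self.loaded_mass_ug}"
            )
        if not self.observations:
            raise SchemaError(f"experiment {self.sample_id!r} has no observations")
        times = [t for t, _ in self.observations]
        for i in range(1, len(times)):
            if times[i] <= times[i - 1]:
                raise SchemaError(
                    f"times must be strictly increasing, got {times[i]} after "
                    f"{times[i - 1]}",
                    row=i + 1,
                )


@dataclass
class PlateReadings:
    """Raw plate-reader intensities for one viability assay.

    Replicate control wells are averaged upstream; here each control is one
    number.  The negative control (untreated cells) defines 100% viability,
    the blank (no cells) defines the background.
    """

    f_blank: float
    f_negative: float
    f_positive: float
    f_samples: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.f_negative <= self.f_blank:
            raise SchemaError(
                f"negative control ({self.f_negative}) must exceed blank "
                f"({self.f_blank})"
            )


@dataclass
class CalibrationPoint:
    """One (concentration, intensity) pair of a fluorescence standard series."""

    conc_ug_ml: float
    intensity_au: float

    def __post_init__(self) -> None:
        if self.conc_ug_ml < 0:
            raise SchemaError(f"concentration must be >= 0, got {self.conc_ug_ml}")


@dataclass
class StructureRecord:
    """Derived network descriptors for one formulation, for tabular export."""

    sample_id: str
    q: float
    v2s: float
    mc_g_mol: float
    n_links: float
    r0_angstrom: float
    xi_angstrom: float


# ---------------------------------------------------------------------------
# schema registry

# column order defines the on-disk layout; dtype str marks id columns
_SCHEMA_COLUMNS: dict[str, list[tuple[str, type]]] = {
    "swelling": [
        ("sample_id", str),
        ("crosslinker_label", str),
        ("temperature_c", float),
        ("m0_mg", float),
        ("t_h", float),
        ("mt_mg", float),
    ],
    "gpc": [("polymer_label", str), ("day", float), ("mn_g_mol", float)],
    "solgel": [("sample_id", str), ("w0_mg", float), ("w1_mg", float)],
    "calibration": [("conc_ug_ml", float), ("intensity_au", float)],
    "release": [
        ("sample_id", str),
        ("volume_ml", float),
        ("aliquot_ml", float),
        ("loaded_mass_ug", float),
        ("t_h", float),
        ("intensity_au", float),
    ],
    "plate": [("well", str), ("role", str), ("intensity_au", float)],
    "structure": [
        ("sample_id", str),
        ("q", float),
        ("v2s", float),
        ("mc_g_mol", float),
        ("n_links", float),
        ("r0_angstrom", float),
        ("xi_angstrom", float),
    ],
}

SCHEMAS = tuple(_SCHEMA_COLUMNS)


def _read_checked(path: str | Path, schema_name: str) -> pd.DataFrame:
    path = Path(path)
    if schema_name not in _SCHEMA_COLUMNS:
        raise ValueError(f"unknown schema {schema_name!r}; expected one of {SCHEMAS}")
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    expected = [c for c, _ in _SCHEMA_COLUMNS[schema_name]]
    missing = [c for c in expected if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{path.name}: missing column(s) {', '.join(missing)} for schema "
            f"{schema_name!r}"
        )
    out = pd.DataFrame(index=df.index)
    for col, typ in _SCHEMA_COLUMNS[schema_name]:
        if typ is str:
            out[col] = df[col]
            continue
        vals = []
        for i, cell in enumerate(df[col]):
            try:
                vals.append(float(cell))
            except ValueError:
                raise SchemaError(
                    f"non-numeric value {cell!r} in column {col!r}", row=i + 1
                ) from None
        out[col] = vals
    return out


def _group_constant(df: pd.DataFrame, key: str, col: str, label: str):
    vals = df[col].unique()
    if len(vals) > 1:
        raise SchemaError(f"{label} {key!r}: column {col!r} not constant within group")
    return vals[0]


def load_table(path: str | Path, schema_name: str):
    """Read and validate one CSV table, returning typed records.

    Parameters
    ----------
    path:
        CSV file with a single header row.
    schema_name:
        One of ``swelling, gpc, solgel, calibration, release, plate,
        structure``.

    Returns
    -------
    list of domain records (``plate`` returns a single :class:`PlateReadings`).
    Row order within each series is preserved; violations raise
    :class:`SchemaError` naming the offending row.
    """
    df = _read_checked(path, schema_name)
    if df.empty:
        raise SchemaError(f"{Path(path).name}: no data rows")

    if schema_name == "swelling":
        series = []
        for sid, g in df.groupby("sample_id", sort=False):
            series.append(
                GravimetricSeries(
                    sample_id=sid,
                    crosslinker_label=_group_constant(
                        g, sid, "crosslinker_label", "sample"
                    ),
                    temperature_c=_group_constant(g, sid, "temperature_c", "sample"),
                    m0_mg=_group_constant(g, sid, "m0_mg", "sample"),
                    observations=list(zip(g["t_h"], g["mt_mg"])),
                )
            )
        return series
    if schema_name == "gpc":
        return [
            GpcSeries(polymer_label=lab, observations=list(zip(g["day"], g["mn_g_mol"])))
            for lab, g in df.groupby("polymer_label", sort=False)
        ]
    if schema_name == "solgel":
        return [
            SolGelMasses(sample_id=r.sample_id, w0_mg=r.w0_mg, w1_mg=r.w1_mg)
            for r in df.itertuples(index=False)
        ]
    if schema_name == "calibration":
        return [
            CalibrationPoint(conc_ug_ml=r.conc_ug_ml, intensity_au=r.intensity_au)
            for r in df.itertuples(index=False)
        ]
    if schema_name == "release":
        out = []
        for sid, g in df.groupby("sample_id", sort=False):
            out.append(
                ReleaseExperiment(
                    sample_id=sid,
                    volume_ml=_group_constant(g, sid, "volume_ml", "experiment"),
                    aliquot_ml=_group_constant(g, sid, "aliquot_ml", "experiment"),
                    loaded_mass_ug=_group_constant(
                        g, sid, "loaded_mass_ug", "experiment"
                    ),
                    observations=list(zip(g["t_h"], g["intensity_au"])),
                )
            )
        return out
    if schema_name == "plate":
        roles = {"blank": [], "negative": [], "positive": [], "sample": []}
        for i, r in enumerate(df.itertuples(index=False)):
            if r.role not in roles:
                raise SchemaError(
                    f"unknown role {r.role!r}; expected one of {sorted(roles)}",
                    row=i + 1,
                )
            roles[r.role].append(r.intensity_au)
        for need in ("blank", "negative", "positive"):
            if not roles[need]:
                raise SchemaError(f"plate table lacks a {need!r} control well")
        mean = lambda xs: sum(xs) / len(xs)  # noqa: E731 - replicate wells average
        return PlateReadings(
            f_blank=mean(roles["blank"]),
            f_negative=mean(roles["negative"]),
            f_positive=mean(roles["positive"]),
            f_samples=roles["sample"],
        )
    if schema_name == "structure":
        return [
            StructureRecord(**{f.name: getattr(r, f.name) for f in
                               dataclasses.fields(StructureRecord)})
            for r in df.itertuples(index=False)
        ]
    raise AssertionError(schema_name)


def _records_to_frame(records: Sequence, schema_name: str) -> pd.DataFrame:
    rows: list[dict] = []
    if schema_name == "swelling":
        for s in records:
            for t, mt in s.observations:
                rows.append(
                    dict(
                        sample_id=s.sample_id,
                        crosslinker_label=s.crosslinker_label,
                        temperature_c=s.temperature_c,
                        m0_mg=s.m0_mg,
                        t_h=t,
                        mt_mg=mt,
                    )
                )
    elif schema_name == "gpc":
        for s in records:
            for day, mn in s.observations:
                rows.append(dict(polymer_label=s.polymer_label, day=day, mn_g_mol=mn))
    elif schema_name == "release":
        for s in records:
            for t, inten in s.observations:
                rows.append(
                    dict(
                        sample_id=s.sample_id,
                        volume_ml=s.volume_ml,
                        aliquot_ml=s.aliquot_ml,
                        loaded_mass_ug=s.loaded_mass_ug,
                        t_h=t,
                        intensity_au=inten,
                    )
                )
    elif schema_name in ("solgel", "calibration", "structure"):
        rows = [dataclasses.asdict(r) for r in records]
    elif schema_name == "plate":
        (p,) = records
        rows.append(dict(well="B1", role="blank", intensity_au=p.f_blank))
        rows.append(dict(well="N1", role="negative", intensity_au=p.f_negative))
        rows.append(dict(well="P1", role="positive", intensity_au=p.f_positive))
        for i, v in enumerate(p.f_samples, start=1):
            rows.append(dict(well=f"S{i}", role="sample", intensity_au=v))
    else:
        raise ValueError(f"unknown schema {schema_name!r}")
    return pd.DataFrame(rows, columns=[c for c, _ in _SCHEMA_COLUMNS[schema_name]])


_RECORD_SCHEMA = {
    GravimetricSeries: "swelling",
    GpcSeries: "gpc",
    SolGelMasses: "solgel",
    CalibrationPoint: "calibration",
    ReleaseExperiment: "release",
    PlateReadings: "plate",
    StructureRecord: "structure",
}


def write_table(records, path: str | Path, schema_name: str | None = None) -> None:
    """Write records back to CSV so that ``load_table`` round-trips exactly.

    The schema is inferred from the record type when not given.  Floats are
    written with ``repr`` precision, so numeric round-trips are bit-exact.
    """
    if isinstance(records, PlateReadings):
        records = [records]
    records = list(records)
    if not records:
        raise ValueError("cannot write an empty record collection")
    if schema_name is None:
        try:
            schema_name = _RECORD_SCHEMA[type(records[0])]
        except KeyError:
            raise TypeError(
                f"no schema registered for record type {type(records[0]).__name__}"
            ) from None
    df = _records_to_frame(records, schema_name)
    df.to_csv(path, index=False)
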