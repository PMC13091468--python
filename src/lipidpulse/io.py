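"""Tabular I/O and run configuration.

Canonical tabular dialect: tab-separated, UTF-8, ``.`` decimal.  Measurement
tables have columns ``cell_id, observable_id, time, measurement, noise_sd``
(one row per observable per cell); a PEtab-style column naming variant is
available for interoperability with that ecosystem.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path

import pandas as pd
import yaml

from .expansion import ExpandedModel
from .population import CellCohort, MeasurementSet

__all__ = [
    "read_measurements",
    "write_measurements",
    "read_ground_truth",
    "RunConfig",
]

MEASUREMENT_COLUMNS = ("cell_id", "observable_id", "time", "measurement", "noise_sd")
PETAB_ALIASES = {
    "cell_id": "simulationConditionId",
    "observable_id": "observableId",
    "time": "time",
    "measurement": "measurement",
    "noise_sd": "noiseParameters",
}


class MeasurementFormatError(ValueError):
    pass


def write_measurements(
    cohort_or_frame: CellCohort | pd.DataFrame, path: str | Path, petab_names: bool = False
) -> None:
    """Write a cohort's measurement table as TSV."""
    if isinstance(cohort_or_frame, CellCohort):
        df = cohort_or_frame.measurement_frame()
    else:
        df = cohort_or_frame.loc[:, list(MEASUREMENT_COLUMNS)]
    if petab_names:
        df = df.rename(columns=PETAB_ALIASES)
    df.to_csv(path, sep="\t", index=False)


def read_measurements(
    path: str | Path, model: ExpandedModel | None = None
) -> dict[str, MeasurementSet]:
    """Read a measurement TSV into per-cell measurement sets.

    Accepts canonical or PEtab-style column names.  When ``model`` is
    given, observable ids are validated against its observable list.
    """
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    reverse = {v: k for k, v in PETAB_ALIASES.items()}
    df = df.rename(columns=reverse)
    missing = [c for c in MEASUREMENT_COLUMNS if c not in df.columns]
    if missing:
        raise MeasurementFormatError(f"{path}: missing column(s) {', '.join(missing)}")
    for col in ("time", "measurement", "noise_sd"):
        parsed = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[parsed.isna() & df[col].notna()]
        if len(bad):
            # +2: header line and 1-based numbering
            raise MeasurementFormatError(
                f"{path}: non-numeric value in column {col!r} at line {bad[0] + 2}"
            )
        df[col] = parsed
    if model is not None:
        known = set(model.observable_ids)
        unknown = sorted(set(df["observable_id"]) - known)
        if unknown:
            raise MeasurementFormatError(
                f"{path}: unknown observable id(s): {', '.join(unknown[:5])}"
            )
    out: dict[str, MeasurementSet] = {}
    for cid, grp in df.groupby("cell_id", sort=False):
        out[str(cid)] = MeasurementSet(
            tuple(grp["observable_id"]),
            grp["measurement"].to_numpy(dtype=float),
            grp["noise_sd"].to_numpy(dtype=float),
            float(grp["time"].iloc[0]) if len(grp) else 0.0,
        )
    return out


def read_ground_truth(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if "cell_id" not in df.columns:
        raise MeasurementFormatError(f"{path}: missing column 'cell_id'")
    return df


@dataclass
class RunConfig:
    """Serializable configuration of a full pipeline run.

    Every stochastic step has its own explicit seed so that any stage can be
    re-run in isolation and byte-identically.
    """

    network: str = "pinned"
    n_labels: int = 3
    t_meas: float = 10.0
    switch_times: list[float] | None = None
    log10_sd: float = 0.1
    noise_cv: float = 0.1
    bounds_log10: tuple[float, float] = (-4.0, 2.0)
    n_starts: int = 1000
    n_cells: int = 10
    seed_population: int = 1
    seed_noise: int = 2
    seed_optimization: int = 3
    sim_rtol: float = 1e-8
    sim_atol: float = 1e-12
    output_dir: str = "results"

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["bounds_log10"] = list(self.bounds_log10)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False), encoding="utf-8")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
        if "bounds_log10" in data:
            data["bounds_log10"] = tuple(data["bounds_log10"])
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {', '.join(sorted(unknown))}")
        return cls(**data)
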