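"""Feature-table and report I/O.

The canonical in-memory container is :class:`FeatureTable`: one row per
patient, continuous gait features in named columns (units embedded in the
names, e.g. ``"Lower Limb - Cadence R (steps/min)"``), and a measured walking
distance in meters as the regression target.

CSV dialect: comma-separated, header row, UTF-8, ``.`` decimal separator.
The empty string and ``NA`` are the recognized missing markers; any other
non-numeric feature cell is a data error.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, DataError

MISSING_MARKERS = ("", "NA")


@dataclass
class FeatureTable:
    """Patients x gait features plus the measured walking distance.

    Parameters
    ----------
    features : pandas.DataFrame
        Continuous feature matrix; missing cells are NaN. Column names must
        be unique; column order is preserved across read/write round-trips.
    target : pandas.Series
        Measured 2-minute-walk distance in meters, aligned with ``features``.
        Where present, values must be strictly positive.
    patient_id : pandas.Index
        Unique opaque identifier per row.
    """

    features: pd.DataFrame
    target: pd.Series
    patient_id: pd.Index

    def __post_init__(self) -> None:
        if not isinstance(self.patient_id, pd.Index):
            self.patient_id = pd.Index(self.patient_id)
        if len(self.features) != len(self.target) or len(self.features) != len(self.patient_id):
            raise DataError("features, target and patient_id must have equal length")
        if self.patient_id.has_duplicates:
            dups = self.patient_id[self.patient_id.duplicated()].unique().tolist()
            raise DataError(f"duplicate patient identifiers: {dups[:5]}")
        if self.features.columns.has_duplicates:
            raise DataError("duplicate feature column names")
        observed = self.target.dropna()
        if (observed <= 0).any():
            bad = observed.index[observed <= 0][0]
            raise DataError(f"non-positive measured distance at row {bad!r}")

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    @property
    def n_patients(self) -> int:
        return len(self.features)

    @property
    def feature_names(self) -> list[str]:
        return list(self.features.columns)

    def take(self, positions: np.ndarray) -> "FeatureTable":
        """Row subset by integer positions (order preserved as given)."""
        return FeatureTable(
            features=self.features.iloc[positions].reset_index(drop=True),
            target=self.target.iloc[positions].reset_index(drop=True),
            patient_id=self.patient_id[positions],
        )

    def to_frame(self, target_column: str = "distance_m", id_column: str = "patient_id") -> pd.DataFrame:
        frame = self.features.copy()
        frame.insert(0, id_column, self.patient_id)
        frame[target_column] = self.target.values
        return frame

    def __eq__(self, other: object) -> bool:  # content equality, used by round-trip tests
        if not isinstance(other, FeatureTable):
            return NotImplemented
        return (
            self.features.equals(other.features)
            and self.target.equals(other.target)
            and self.patient_id.equals(other.patient_id)
        )


def read_feature_table(
    path: str | Path,
    target_column: str,
    id_column: str | None = None,
    feature_columns: list[str] | None = None,
) -> FeatureTable:
    """Read a CSV feature table.

    All columns except the identifier and the target become features unless
    ``feature_columns`` restricts the selection explicitly. When ``id_column``
    is None the 0-based row index becomes the patient identifier.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"feature table not found: {path}")
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    if target_column not in raw.columns:
        raise ConfigurationError(
            f"target column {target_column!r} absent from {path.name}; columns: {list(raw.columns)[:8]}..."
        )
    if id_column is not None:
        if id_column not in raw.columns:
            raise ConfigurationError(f"id column {id_column!r} absent from {path.name}")
        vals = raw[id_column]
        numeric = pd.to_numeric(vals, errors="coerce")
        if not numeric.isna().any():  # integer ids survive the round trip as integers
            if (numeric % 1 == 0).all():
                numeric = numeric.astype(int)
            ids = pd.Index(numeric.values, name=id_column)
        else:
            ids = pd.Index(vals.values, name=id_column)
    else:
        ids = pd.RangeIndex(len(raw))

    drop = {target_column} | ({id_column} if id_column else set())
    if feature_columns is not None:
        missing = [c for c in feature_columns if c not in raw.columns]
        if missing:
            raise ConfigurationError(f"requested feature columns absent: {missing}")
        feat_names = list(feature_columns)
    else:
        feat_names = [c for c in raw.columns if c not in drop]

    features = pd.DataFrame(index=raw.index)
    for col in feat_names:
        features[col] = _numeric_column(raw, col)
    target = _numeric_column(raw, target_column).rename(target_column)
    return FeatureTable(features=features, target=target, patient_id=ids)


def _numeric_column(raw: pd.DataFrame, col: str) -> pd.Series:
    cleaned = raw[col].str.strip().replace(list(MISSING_MARKERS), np.nan)
    probe = pd.to_numeric(cleaned, errors="coerce")  # lossy, only to locate bad cells
    bad = probe.isna() & cleaned.notna()
    if bad.any():
        row = int(np.flatnonzero(bad.values)[0])
        raise DataError(
            f"non-numeric value {raw[col].iloc[row]!r} in column {col!r}, row {row}"
        )
    return cleaned.astype(float)  # correctly rounded parse, round-trip exact


def write_feature_table(table: FeatureTable, path: str | Path,
                        target_column: str = "distance_m", id_column: str = "patient_id") -> None:
    """Write a table as CSV with the package's dialect (NaN -> empty cell).

    Floats are written with 17 significant digits so the round trip is exact.
    """
    table.to_frame(target_column, id_column).to_csv(path, index=False, float_format="%.17g")


# --------------------------------------------------------------------------
# Benchmark report persistence


def write_report(report, path: str | Path) -> None:
    """Serialize a benchmark report to a directory.

    Writes ``report.json`` (the complete numeric content; floats round-trip
    bit-identically through repr) plus CSV views of the learning-rate curves,
    shape grids, final comparison and the winner's prediction pairs for
    external plotting. A report covering only part of the staged benchmark is
    written with ``"partial": true``.
    """
    if not getattr(report, "stages", None):
        raise ConfigurationError("cannot write a report with no finished stages")
    path = Path(path)
    try:
        path.mkdir(parents=True, exist_ok=True)
    except OSError as exc:  # unwritable location
        raise OSError(f"cannot create report directory {path}: {exc}") from exc

    payload = report.to_dict()
    (path / "report.json").write_text(json.dumps(payload, indent=1))

    stages = payload["stages"]
    if "lr_sweep" in stages:
        rows = [
            {"algorithm": alg, "learning_rate": lr, "msearr": m, "sd": s, "n_failed": f}
            for alg, recs in stages["lr_sweep"]["records"].items()
            for lr, m, s, f in recs
        ]
        pd.DataFrame(rows).to_csv(path / "lr_curves.csv", index=False)
    if "shape_grid" in stages:
        rows = [
            {"algorithm": alg, "spread": sp, "depth": dp, "msearr": m, "sd": s, "n_failed": f}
            for alg, recs in stages["shape_grid"]["records"].items()
            for sp, dp, m, s, f in recs
        ]
        pd.DataFrame(rows).to_csv(path / "shape_grids.csv", index=False)
    if "compare" in stages:
        rows = [
            {"algorithm": alg, **rec} for alg, rec in stages["compare"]["records"].items()
        ]
        pd.DataFrame(rows).to_csv(path / "comparison.csv", index=False)
        pairs = payload.get("winner", {}).get("prediction_pairs")
        if pairs:
            pd.DataFrame(pairs, columns=["measured_m", "predicted_m"]).to_csv(
                path / "winner_predictions.csv", index=False
            )
    rsw = payload.get("reverse_weight_table")
    if rsw:
        pd.DataFrame(rsw, columns=["feature", "reverse_weight"]).to_csv(
            path / "reverse_weights.csv", index=False
        )


def read_report(path: str | Path):
    """Read back a report written by :func:`write_report` (exact content)."""
    from .benchmark import BenchmarkReport

    payload = json.loads((Path(path) / "report.json").read_text())
    return BenchmarkReport.from_dict(payload)
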