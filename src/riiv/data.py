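"""Reading, validation, transformation and design encoding of assay data.

Long-format repeated-measures data — one row per behavioural assay —
are read from CSV, validated against the trait's invariants (counts are
non-negative integers, mass is positive), transformed to the modelling
scale (log then Z for the response; Z for mass and temperature; week
centred on the middle burst), and encoded into dense index maps for the
individual and individual-by-burst random effects.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import (
    ConfigurationError,
    DataValidationError,
    DegenerateDataError,
)

#: canonical column names, in storage order
COLUMNS = (
    "individual_id",
    "week",
    "batch",
    "mass",
    "temperature",
    "am_pm",
    "activity",
)


@dataclass
class Dataset:
    """Validated long-format observations.

    Attributes
    ----------
    df : pandas.DataFrame
        One row per assay with the canonical columns
        ``individual_id, week, batch, mass, temperature, am_pm, activity``.
    n_dropped : int
        Rows removed because a required field was missing.
    levels : dict
        Recorded categorical levels (individual ids, week labels).
    """

    df: pd.DataFrame
    n_dropped: int = 0
    levels: dict = field(default_factory=dict)

    def __len__(self) -> int:  # pragma: no cover - trivial
        return len(self.df)


@dataclass
class TransformConfig:
    """Options controlling the response and covariate transformations.

    log_mode : ``"log1p"`` (default) or ``"log"``.  Counts of line
        crossings can be zero, which ``log`` cannot handle; ``log1p``
        is therefore the default, with strict ``log`` available for
        data known to be positive.
    sd_ddof : delta degrees of freedom for the Z-standardising SD
        (1 = sample SD, the default; 0 = population SD).
    week_centre : the week label subtracted from the week covariate.
        ``None`` centres on the second distinct week (the middle burst
        in a three-burst design).
    """

    log_mode: str = "log1p"
    sd_ddof: int = 1
    week_centre: float | None = None

    def __post_init__(self) -> None:
        if self.log_mode not in ("log1p", "log"):
            raise ConfigurationError(
                f"log_mode must be 'log1p' or 'log', got {self.log_mode!r}"
            )
        if self.sd_ddof not in (0, 1):
            raise ConfigurationError("sd_ddof must be 0 or 1")


@dataclass
class IndexMaps:
    """Dense observation-to-group index maps.

    ``j_index[i]`` is the individual (0-based) of observation *i*;
    ``k_index[i]`` its individual-by-burst cell.  ``cell_to_id[k]``
    gives the individual owning cell *k*, so the nesting is explicit.
    """

    j_index: np.ndarray
    k_index: np.ndarray
    n_id: int
    n_cell: int
    id_labels: list
    cell_labels: list
    cell_to_id: np.ndarray


@dataclass
class PreparedData:
    """Model-ready arrays plus the record needed to undo the transform."""

    y: np.ndarray                 # transformed response, shape (n,)
    x_mean: np.ndarray            # (n, 5): batch, z-mass, c-week, z-temp, am_pm
    x_resid: np.ndarray           # (n, 2): z-mass, c-week
    indices: IndexMaps
    transform_record: dict

    @property
    def n_obs(self) -> int:
        return self.y.shape[0]

    @property
    def j_index(self) -> np.ndarray:
        return self.indices.j_index

    @property
    def k_index(self) -> np.ndarray:
        return self.indices.k_index

    @property
    def n_id(self) -> int:
        return self.indices.n_id

    @property
    def n_cell(self) -> int:
        return self.indices.n_cell

    # -- serialization ---------------------------------------------------
    def to_npz(self, path) -> None:
        """Write a single-archive bundle (versioned) for reproducibility."""
        np.savez(
            path,
            y=self.y,
            x_mean=self.x_mean,
            x_resid=self.x_resid,
            j_index=self.indices.j_index,
            k_index=self.indices.k_index,
            cell_to_id=self.indices.cell_to_id,
            id_labels=np.asarray(self.indices.id_labels, dtype=str),
            cell_labels=np.asarray(
                ["{}|{}".format(*c) for c in self.indices.cell_labels], dtype=str
            ),
            transform_record=np.frombuffer(
                json.dumps(self.transform_record).encode(), dtype=np.uint8
            ),
            format_version=np.array([1]),
        )

    @classmethod
    def from_npz(cls, path) -> "PreparedData":
        with np.load(path, allow_pickle=False) as z:
            record = json.loads(bytes(z["transform_record"]).decode())
            cell_labels = [tuple(s.split("|")) for s in z["cell_labels"]]
            idx = IndexMaps(
                j_index=z["j_index"],
                k_index=z["k_index"],
                n_id=int(z["j_index"].max()) + 1,
                n_cell=int(z["k_index"].max()) + 1,
                id_labels=list(z["id_labels"]),
                cell_labels=cell_labels,
                cell_to_id=z["cell_to_id"],
            )
            return cls(
                y=z["y"],
                x_mean=z["x_mean"],
                x_resid=z["x_resid"],
                indices=idx,
                transform_record=record,
            )


# ---------------------------------------------------------------------------
# loading
# ---------------------------------------------------------------------------

def load_long_csv(
    path, column_map: Mapping[str, str] | None = None
) -> Dataset:
    """Read and validate long-format assay data from a CSV file.

    Parameters
    ----------
    path : path or file-like
        CSV with a header row, one row per assay.
    column_map : optional mapping
        ``{canonical_name: csv_name}`` for files whose headers differ
        from the canonical names.

    Rows missing any required field are dropped and counted.  Invalid
    values (negative or non-integer activity, non-positive mass) raise
    :class:`~riiv.errors.DataValidationError` naming the offending row.
    """
    raw = pd.read_csv(path)
    column_map = dict(column_map or {})
    rename = {}
    for canon in COLUMNS:
        src = column_map.get(canon, canon)
        if src not in raw.columns:
            raise ConfigurationError(
                f"required column {src!r} (for {canon!r}) not found; "
                f"available: {list(raw.columns)}"
            )
        rename[src] = canon
    df = raw.rename(columns=rename)[list(COLUMNS)]

    n_before = len(df)
    df = df.dropna(subset=list(COLUMNS)).reset_index(drop=True)
    n_dropped = n_before - len(df)

    for col in ("activity", "mass", "temperature", "week", "batch", "am_pm"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise DataValidationError(
                f"non-numeric value {df[col].iloc[row]!r} in column "
                f"{col!r} at row {row}"
            )
        df[col] = coerced

    act = df["activity"].to_numpy()
    if (act < 0).any():
        row = int(np.flatnonzero(act < 0)[0])
        raise DataValidationError(f"negative activity count at row {row}")
    if not np.allclose(act, np.round(act)):
        row = int(np.flatnonzero(~np.isclose(act, np.round(act)))[0])
        raise DataValidationError(f"non-integer activity count at row {row}")
    if (df["mass"].to_numpy() <= 0).any():
        row = int(np.flatnonzero(df["mass"].to_numpy() <= 0)[0])
        raise DataValidationError(f"non-positive mass at row {row}")
    for col in ("batch", "am_pm"):
        vals = set(df[col].unique())
        if not vals <= {0, 1}:
            raise DataValidationError(
                f"column {col!r} must be coded 0/1; found {sorted(vals)}"
            )

    df["individual_id"] = df["individual_id"].astype(str)
    levels = {
        "individual_id": sorted(df["individual_id"].unique()),
        "week": sorted(df["week"].unique()),
    }
    return Dataset(df=df, n_dropped=n_dropped, levels=levels)


# ---------------------------------------------------------------------------
# design indices
# ---------------------------------------------------------------------------

def build_indices(data: Dataset | pd.DataFrame) -> IndexMaps:
    """Encode individual and individual-by-burst factors as dense indices.

    Indices are 0-based, consecutive, and assigned in order of first
    appearance, so identical input yields identical maps.  The number of
    cells equals the number of distinct (individual, week) pairs — at
    most ``n_id * n_burst`` but smaller when some individuals miss a
    burst.
    """
    df = data.df if isinstance(data, Dataset) else data
    j_codes, id_labels = pd.factorize(df["individual_id"], sort=False)
    cell_key = list(zip(df["individual_id"], df["week"]))
    k_codes, cell_labels = pd.factorize(pd.Series(cell_key), sort=False)
    cell_to_id = np.empty(len(cell_labels), dtype=np.int64)
    label_to_j = {lab: j for j, lab in enumerate(id_labels)}
    for k, (ident, _week) in enumerate(cell_labels):
        cell_to_id[k] = label_to_j[ident]
    return IndexMaps(
        j_index=np.asarray(j_codes, dtype=np.int64),
        k_index=np.asarray(k_codes, dtype=np.int64),
        n_id=len(id_labels),
        n_cell=len(cell_labels),
        id_labels=list(id_labels),
        cell_labels=list(cell_labels),
        cell_to_id=cell_to_id,
    )


# ---------------------------------------------------------------------------
# transformation
# ---------------------------------------------------------------------------

def _zscore(x: np.ndarray, ddof: int, name: str):
    mean = float(np.mean(x))
    sd = float(np.std(x, ddof=ddof))
    if sd == 0 or not np.isfinite(sd):
        raise DegenerateDataError(
            f"column {name!r} has zero variance; cannot Z-standardize"
        )
    return (x - mean) / sd, mean, sd


def transform(
    data: Dataset, config: TransformConfig | None = None
) -> PreparedData:
    """Transform a validated dataset to the modelling scale.

    The response is log- then Z-transformed; mass and temperature are
    Z-transformed; week is centred so the middle burst sits at zero.
    The means and SDs used are stored in ``transform_record`` so
    predictions can be mapped back to the count scale.
    """
    config = config or TransformConfig()
    df = data.df

    act = df["activity"].to_numpy(dtype=float)
    if config.log_mode == "log":
        if (act <= 0).any():
            raise DegenerateDataError(
                "activity contains zeros; log(x) is undefined — use "
                "log_mode='log1p'"
            )
        log_act = np.log(act)
    else:
        log_act = np.log1p(act)
    y, y_mean, y_sd = _zscore(log_act, config.sd_ddof, "log-activity")

    z_mass, mass_mean, mass_sd = _zscore(
        df["mass"].to_numpy(dtype=float), config.sd_ddof, "mass"
    )
    z_temp, temp_mean, temp_sd = _zscore(
        df["temperature"].to_numpy(dtype=float), config.sd_ddof, "temperature"
    )

    weeks = df["week"].to_numpy(dtype=float)
    if config.week_centre is None:
        distinct = np.unique(weeks)
        centre = float(distinct[1]) if len(distinct) >= 2 else float(distinct[0])
    else:
        centre = float(config.week_centre)
    c_week = weeks - centre

    x_mean = np.column_stack(
        [df["batch"].to_numpy(float), z_mass, c_week, z_temp,
         df["am_pm"].to_numpy(float)]
    )
    x_resid = np.column_stack([z_mass, c_week])

    record = {
        "log_mode": config.log_mode,
        "sd_ddof": config.sd_ddof,
        "y_log_mean": y_mean,
        "y_log_sd": y_sd,
        "mass_mean": mass_mean,
        "mass_sd": mass_sd,
        "temp_mean": temp_mean,
        "temp_sd": temp_sd,
        "week_centre": centre,
    }
    return PreparedData(
        y=y,
        x_mean=x_mean,
        x_resid=x_resid,
        indices=build_indices(data),
        transform_record=record,
    )


def inverse_transform_y(y: np.ndarray, transform_record: dict) -> np.ndarray:
    """Map transformed responses back to the activity-count scale."""
    log_act = np.asarray(y) * transform_record["y_log_sd"] + transform_record[
        "y_log_mean"
    ]
    if transform_record["log_mode"] == "log":
        return np.exp(log_act)
    return np.expm1(log_act)


def prepare_latent(df: pd.DataFrame, y_column: str = "y_latent",
                   sd_ddof: int = 1) -> PreparedData:
    """Build :class:`PreparedData` from a simulated latent-scale response.

    The response column is taken as already on the Z-log scale (no
    re-standardisation, so generating parameters keep their meaning);
    mass and temperature are Z-transformed and week centred exactly as
    in :func:`transform`.
    """
    z_mass, mass_mean, mass_sd = _zscore(
        df["mass"].to_numpy(dtype=float), sd_ddof, "mass"
    )
    z_temp, temp_mean, temp_sd = _zscore(
        df["temperature"].to_numpy(dtype=float), sd_ddof, "temperature"
    )
    weeks = df["week"].to_numpy(dtype=float)
    distinct = np.unique(weeks)
    centre = float(distinct[1]) if len(distinct) >= 2 else float(distinct[0])
    c_week = weeks - centre
    x_mean = np.column_stack(
        [df["batch"].to_numpy(float), z_mass, c_week, z_temp,
         df["am_pm"].to_numpy(float)]
    )
    x_resid = np.column_stack([z_mass, c_week])
    record = {
        "log_mode": "latent",
        "sd_ddof": sd_ddof,
        "y_log_mean": 0.0,
        "y_log_sd": 1.0,
        "mass_mean": mass_mean,
        "mass_sd": mass_sd,
        "temp_mean": temp_mean,
        "temp_sd": temp_sd,
        "week_centre": centre,
    }
    return PreparedData(
        y=df[y_column].to_numpy(dtype=float),
        x_mean=x_mean,
        x_resid=x_resid,
        indices=build_indices(df),
        transform_record=record,
    )
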