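"""Tabular I/O, spectral containers, and run-configuration contracts.

The package moves three kinds of tables through its pipeline:

* :class:`SpectraTable` — leaf (or plot) reflectance factors on the fixed
  350–2500 nm, 1-nm instrument grid (2151 bands);
* trait tables — samples × traits numeric matrices (metabolite
  intensities, fiber traits, vegetation indices), missing values allowed;
* metabolite annotation — platform / class / subclass / InChIKey records;
  only metabolites carrying an InChIKey are admitted to analysis.

On disk everything is plain CSV.  The canonical spectral layout is *wide*
(first column ``sample_id``, then integer-named wavelength columns); a
tidy *long* layout (``sample_id, wavelength_nm, reflectance``) is accepted
as an alternate dialect.  Missing values are written as ``NA`` and read
from either ``NA`` or empty cells.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
import warnings
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "WAVELENGTH_GRID",
    "SpectraTable",
    "read_spectra",
    "write_spectra",
    "read_traits",
    "write_traits",
    "read_annotation",
    "filter_annotated",
    "average_replicate_spectra",
    "RunConfig",
    "load_run_config",
    "config_hash",
    "get_logger",
]

#: The fixed instrument grid: 2151 one-nanometre bands from 350 to 2500 nm.
WAVELENGTH_GRID = np.arange(350, 2501, dtype=int)

_REFLECTANCE_HI = 1.5  # calibration artifacts can push reflectance slightly >1


class GridError(ValueError):
    """Raised when a spectral file does not cover the canonical grid."""


@dataclasses.dataclass
class SpectraTable:
    """Samples × 2151 reflectance factors on the canonical wavelength grid.

    ``data`` is a DataFrame indexed by ``sample_id`` (opaque strings) whose
    columns are the integer wavelengths 350..2500.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        cols = np.asarray(self.data.columns, dtype=int)
        if cols.shape != WAVELENGTH_GRID.shape or not np.array_equal(cols, WAVELENGTH_GRID):
            missing = np.setdiff1d(WAVELENGTH_GRID, cols)
            extra = np.setdiff1d(cols, WAVELENGTH_GRID)
            raise GridError(
                f"wavelength grid must be 350..2500 nm step 1; "
                f"missing bands {missing[:5].tolist()}"
                + ("..." if missing.size > 5 else "")
                + (f", unexpected bands {extra[:5].tolist()}" if extra.size else "")
            )
        self.data.columns = pd.Index(WAVELENGTH_GRID)
        self.data.index = self.data.index.astype(str)
        self.data = self.data.sort_index()
        values = self.data.to_numpy(dtype=float)
        if not np.isfinite(values).all():
            raise ValueError("reflectance values must be finite")
        if (values < 0).any() or (values > _REFLECTANCE_HI).any():
            warnings.warn(
                "reflectance outside [0, 1.5]: possible calibration artifact",
                stacklevel=2,
            )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def n_samples(self) -> int:
        return len(self.data)

    def band(self, wavelength_nm: int) -> pd.Series:
        """Reflectance of every sample at one exact nanometre band."""
        return self.data[int(wavelength_nm)]

    def to_array(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)


def read_spectra(path: str | Path, dialect: str = "wide-csv") -> SpectraTable:
    """Read a reflectance table in the wide or long CSV dialect.

    Wide: first column sample_id, remaining columns integer wavelengths.
    Long: columns (sample_id, wavelength_nm, reflectance).
    """
    path = Path(path)
    if dialect == "wide-csv":
        frame = pd.read_csv(path, index_col=0, na_values=["NA"])
        try:
            frame.columns = frame.columns.astype(int)
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path}: non-integer wavelength column: {exc}") from None
    elif dialect == "long-csv":
        long = pd.read_csv(path, na_values=["NA"])
        required = {"sample_id", "wavelength_nm", "reflectance"}
        if not required.issubset(long.columns):
            raise ValueError(f"{path}: long dialect needs columns {sorted(required)}")
        frame = long.pivot(index="sample_id", columns="wavelength_nm", values="reflectance")
        frame.columns = frame.columns.astype(int)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    bad = frame.columns[frame.isna().any(axis=0)]
    if len(bad):
        nan_loc = frame.isna().stack()
        row, col = nan_loc[nan_loc].index[0]
        raise ValueError(f"{path}: non-numeric or missing reflectance at sample {row!r}, band {col}")
    return SpectraTable(frame)


def write_spectra(table: SpectraTable, path: str | Path, dialect: str = "wide-csv") -> None:
    path = Path(path)
    if dialect == "wide-csv":
        out = table.data.copy()
        out.index.name = "sample_id"
        out.to_csv(path, na_rep="NA", float_format="%.8g")
    elif dialect == "long-csv":
        long = table.data.stack().rename("reflectance").reset_index()
        long.columns = ["sample_id", "wavelength_nm", "reflectance"]
        long.to_csv(path, index=False, na_rep="NA", float_format="%.8g")
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def read_traits(path: str | Path) -> pd.DataFrame:
    """Read a samples × traits table (wide CSV, first column sample_id)."""
    frame = pd.read_csv(path, index_col=0, na_values=["NA"])
    frame.index = frame.index.astype(str)
    values = frame.to_numpy(dtype=float)
    if np.isinf(values).any():
        raise ValueError(f"{path}: non-finite trait values")
    return frame


def write_traits(frame: pd.DataFrame, path: str | Path) -> None:
    out = frame.copy()
    out.index.name = "sample_id"
    out.to_csv(path, na_rep="NA", float_format="%.10g")


def read_annotation(path: str | Path) -> pd.DataFrame:
    """Read metabolite annotation (trait_id, platform, main_class, subclass, inchikey)."""
    ann = pd.read_csv(path, na_values=["NA"], dtype=str)
    required = {"trait_id", "platform", "main_class", "subclass", "inchikey"}
    if not required.issubset(ann.columns):
        raise ValueError(f"{path}: annotation needs columns {sorted(required)}")
    return ann


def filter_annotated(annotation: pd.DataFrame) -> pd.DataFrame:
    """Admit only metabolites carrying a non-empty InChIKey.

    Compounds without a chemical-structure identifier never enter the
    statistical analysis.
    """
    key = annotation["inchikey"].fillna("").str.strip()
    return annotation.loc[key != ""].reset_index(drop=True)


def average_replicate_spectra(
    leaf_spectra: SpectraTable, grouping: Mapping[str, str]
) -> SpectraTable:
    """Average per-leaf spectra to plot level.

    Five leaves are measured per plot in the field protocol; the plot
    spectrum is the band-wise arithmetic mean of its member leaves.
    ``grouping`` maps each leaf sample_id to its plot id.
    """
    missing = [s for s in leaf_spectra.sample_ids if s not in grouping]
    if missing:
        raise ValueError(f"leaf samples without a plot assignment: {missing[:5]}")
    groups = pd.Series({s: grouping[s] for s in leaf_spectra.sample_ids})
    if groups.empty:
        raise ValueError("empty spectra table")
    averaged = leaf_spectra.data.groupby(groups).mean()
    averaged.index = averaged.index.astype(str)
    return SpectraTable(averaged)


# --------------------------------------------------------------------------
# Run configuration


@dataclasses.dataclass
class RunConfig:
    """Pipeline-wide knobs, all defaulted to the study's analysis settings."""

    seed: int = 1
    years: tuple[int, ...] = (2018, 2019)
    fc_lo: float = 0.5       # fold-change decrease threshold (WL/WW)
    fc_hi: float = 2.0       # fold-change increase threshold
    fdr: float = 0.05        # Benjamini–Hochberg level
    max_factors: int = 12    # PLSR factor search 0..12
    folds: int = 4           # CV groups for the prediction models
    knn_k: int = 10          # neighbours for metabolite imputation
    outlier_alpha: float = 0.05
    lrt_alpha: float = 0.05
    q2_accurate: float = 0.5  # "accurately predicted" threshold

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["years"] = list(self.years)
        return d


def load_run_config(path: str | Path) -> RunConfig:
    """Load a YAML run configuration with a strict schema (unknown keys error)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a mapping")
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
    if "years" in raw:
        raw["years"] = tuple(raw["years"])
    return RunConfig(**raw)


def config_hash(config: RunConfig) -> str:
    """Stable short hash of the run configuration, for logs and manifests."""
    payload = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def get_logger(name: str = "leafmet", level: int = logging.INFO) -> logging.Logger:
    """Line-oriented logger with ISO-8601 timestamps."""
    logger = logging.getLogger(name)
    if not logger.handlers:
        handler = logging.StreamHandler(sys.stderr)
        handler.setFormatter(
            logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s",
                              datefmt="%Y-%m-%dT%H:%M:%S")
        )
        logger.addHandler(handler)
    logger.setLevel(level)
    return logger
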