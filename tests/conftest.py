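import numpy as np
import pandas as pd
import pytest

from leafmet.io_formats import WAVELENGTH_GRID, SpectraTable


def make_spectra(values: dict[str, float | dict[int, float]],
                 default: float = 0.5) -> SpectraTable:
    """SpectraTable from per-sample flat values or {band: reflectance} overrides."""
    rows = {}
    for sid, spec in values.items():
        arr = np.full(WAVELENGTH_GRID.size, default, dtype=float)
        if isinstance(spec, dict):
            for band, val in spec.items():
                arr[band - 350] = val
        else:
            arr[:] = spec
        rows[sid] = arr
    frame = pd.DataFrame(rows).T
    frame.columns = WAVELENGTH_GRID
    return SpectraTable(frame)


def balanced_design(n_genotypes: int, n_reps: int, treatments=("WW", "WL")):
    """Fully crossed genotype × treatment × rep design (one obs per combo)."""
    rows = []
    i = 0
    for t in treatments:
        for k in range(n_reps):
            for g in range(n_genotypes):
                i += 1
                rows.append({"genotype": f"G{g + 1:02d}", "treatment": t,
                             "rep": f"R{k + 1}", "block": "B1", "column": "C1"})
    return pd.DataFrame(rows, index=[f"P{j:03d}" for j in range(1, i + 1)])


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_balanced_design():
    return balanced_design(6, 3)
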