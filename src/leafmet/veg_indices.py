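"""Reflectance-based vegetation indices at exact nanometre bands.

Four leaf-level indices, each a proxy for a physiological state:

* NDVI  = (R820 − R670)/(R820 + R670)  — general plant health;
* PRI   = (R531 − R570)/(R531 + R570) and sPRI = (PRI + 1)/2 —
  photosynthetic radiation-use efficiency, scaled to avoid negatives;
* CRI — carotenoid content.  Default ``ratio`` mode computes R550/R510,
  the algebraic value of the reciprocal-quotient expression (and the one
  consistent with typical leaf values of ≈2.0–2.4); the
  ``reciprocal-difference`` mode computes the literature form
  1/R510 − 1/R550 (≈7–15 on typical leaves);
* WI and WI/NDVI — leaf water content.  Default ``ratio`` mode uses
  WI = R900/R970 (WI/NDVI then lands near 1.2–1.3 on green leaves);
  the ``difference`` mode uses (R900 − R970)/NDVI, which is not
  scale-free and roughly two orders of magnitude smaller.

Higher WI/NDVI indicates lower leaf water content.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .io_formats import SpectraTable

__all__ = ["REQUIRED_BANDS", "compute_vis"]

REQUIRED_BANDS = (510, 531, 550, 570, 670, 820, 900, 970)


def _safe_div(num: pd.Series, den: pd.Series, name: str) -> pd.Series:
    out = num / den.replace(0.0, np.nan)
    if den.eq(0.0).any():
        warnings.warn(f"{name}: zero denominator for "
                      f"{list(den.index[den == 0])[:5]}; value set missing",
                      stacklevel=3)
    return out


def compute_vis(spectra: SpectraTable, cri_mode: str = "ratio",
                wi_mode: str = "ratio") -> pd.DataFrame:
    """Compute NDVI, PRI, sPRI, CRI, WI and WI/NDVI per sample.

    Returns a DataFrame indexed by sample_id with a ``mode`` provenance
    column recording the CRI/WI conventions used.
    """
    if cri_mode not in ("ratio", "reciprocal-difference"):
        raise ValueError(f"unknown cri_mode {cri_mode!r}")
    if wi_mode not in ("ratio", "difference"):
        raise ValueError(f"unknown wi_mode {wi_mode!r}")

    R = {b: spectra.band(b) for b in REQUIRED_BANDS}
    ndvi = _safe_div(R[820] - R[670], R[820] + R[670], "NDVI")
    pri = _safe_div(R[531] - R[570], R[531] + R[570], "PRI")
    spri = (pri + 1.0) / 2.0
    if cri_mode == "ratio":
        cri = _safe_div(R[550], R[510], "CRI")
    else:
        cri = _safe_div(pd.Series(1.0, index=R[510].index), R[510], "CRI") \
            - _safe_div(pd.Series(1.0, index=R[550].index), R[550], "CRI")
    if wi_mode == "ratio":
        wi = _safe_div(R[900], R[970], "WI")
    else:
        wi = R[900] - R[970]
    wi_ndvi = _safe_div(wi, ndvi, "WI/NDVI")

    out = pd.DataFrame({
        "NDVI": ndvi, "PRI": pri, "sPRI": spri, "CRI": cri,
        "WI": wi, "WI_over_NDVI": wi_ndvi,
    })
    out["mode"] = f"cri={cri_mode};wi={wi_mode}"
    out.index.name = "sample_id"
    return out
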