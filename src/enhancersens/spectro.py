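"""Closed-form biophysics utilities for peptide secondary structure.

Helicity from far-UV circular dichroism uses the linear single-wavelength
estimate %H = ([theta]_222 - 3000) / (-36000 - 3000) * 100 on the mean
residue ellipticity at 222 nm ([theta] in deg cm^2 dmol^-1): fully coil
peptides sit near +3000 and fully helical ones near -36000.

NMR Calpha secondary chemical shifts (SCS = observed - random coil, ppm)
flag transient helix as any maximal run of at least ``min_run`` consecutive
residues with positive SCS. The random-coil reference set is a required
input table, not a bundled constant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

log = logging.getLogger("enhancersens")

_COIL_THETA = 3000.0
_HELIX_THETA = -36000.0


@dataclass
class Helicity:
    theta_222: float
    raw_percent: float
    percent: float  # clipped to [0, 100]


def helicity_from_cd(spectrum: pd.DataFrame) -> Helicity:
    """Percent helix from a CD spectrum (columns wavelength, ellipticity).

    [theta]_222 is interpolated linearly when 222 nm is absent but bracketed;
    outside the measured range is an error. Both the raw and the [0,100]-
    clipped percentage are reported.
    """
    wl = spectrum["wavelength"].to_numpy(dtype=float)
    el = spectrum["ellipticity"].to_numpy(dtype=float)
    order = np.argsort(wl)
    wl, el = wl[order], el[order]
    if np.any(np.diff(wl) <= 0):
        raise ValueError("wavelengths must be strictly increasing")
    if not (wl[0] <= 222.0 <= wl[-1]):
        raise ValueError("222 nm outside the measured range")
    theta = float(np.interp(222.0, wl, el))
    raw = (theta - _COIL_THETA) / (_HELIX_THETA - _COIL_THETA) * 100.0
    return Helicity(theta_222=theta, raw_percent=raw, percent=float(np.clip(raw, 0.0, 100.0)))


def secondary_shifts(table: pd.DataFrame) -> pd.DataFrame:
    """Per-residue Calpha SCS = observed - random coil.

    ``table`` columns: residue (index), aa, observed, reference. Residues
    with a missing reference are excluded with a log message.
    """
    df = table.copy()
    missing = df["reference"].isna() | df["observed"].isna()
    if missing.any():
        log.warning("excluding %d residues without a reference shift", int(missing.sum()))
        df = df[~missing]
    for col in ("observed", "reference"):
        vals = df[col].to_numpy(dtype=float)
        if np.any((vals <= 0) | (vals >= 80)):
            raise ValueError(f"{col} shifts must lie in (0, 80) ppm")
    df = df.assign(scs=df["observed"].astype(float) - df["reference"].astype(float))
    return df.reset_index(drop=True)


def call_transient_helix(scs: pd.DataFrame, min_run: int = 4) -> list[tuple[int, int]]:
    """Maximal runs of >= min_run consecutive residues with SCS > 0.

    Returns inclusive (first_residue, last_residue) ranges. Residue numbers
    must be contiguous within a run for it to count as consecutive.
    """
    df = scs.sort_values("residue")
    res = df["residue"].to_numpy(dtype=int)
    pos = df["scs"].to_numpy(dtype=float) > 0
    calls: list[tuple[int, int]] = []
    start = None
    prev = None
    for r, p in zip(res, pos):
        contiguous = prev is not None and r == prev + 1
        if start is not None and (not p or not contiguous):
            if prev - start + 1 >= min_run:
                calls.append((start, prev))
            start = None
        if p and start is None:
            start = r
        prev = r
    if start is not None and prev - start + 1 >= min_run:
        calls.append((start, prev))
    return calls
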