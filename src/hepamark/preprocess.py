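"""Spectral bucketing and variable scaling.

Spectra are integrated into half-open 0.01 ppm buckets from 0.5 to 10
ppm; buckets intersecting the solvent exclusion windows (water 4.5-5.1
ppm, methanol 3.2-3.35 ppm) are dropped entirely. Each sample's bucket
row is then normalized by its own whole-spectrum integral over the
retained buckets, and variables are Pareto-scaled (center, divide by the
square root of the standard deviation) before multivariate modeling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid

__all__ = [
    "DEFAULT_EXCLUSIONS",
    "BucketTable",
    "ParetoScaling",
    "bucket_edges",
    "bucket_spectrum",
    "bucket_spectra",
    "normalize_buckets",
    "pareto_scale",
]

#: Solvent suppression windows (ppm): residual water and methanol.
DEFAULT_EXCLUSIONS: tuple[tuple[float, float], ...] = ((4.5, 5.1), (3.2, 3.35))


@dataclass
class BucketTable:
    """Samples x buckets matrix; columns are bucket left edges in ppm.

    ``state`` is one of ``raw`` (integrals), ``normalized`` (rows sum to
    1 over retained buckets) or ``pareto``.
    """

    values: pd.DataFrame
    state: str = "raw"
    width: float = 0.01

    def __post_init__(self) -> None:
        if self.state not in ("raw", "normalized", "pareto"):
            raise ValueError(f"unknown state {self.state!r}")

    @property
    def buckets(self) -> np.ndarray:
        return self.values.columns.to_numpy(dtype=float)

    @property
    def samples(self) -> list[str]:
        return [str(i) for i in self.values.index]

    def to_csv(self, path: str | Path) -> None:
        out = self.values.copy()
        out.columns = [f"{b:.2f}" for b in self.buckets]
        out.to_csv(path, index_label="sample_id")

    @classmethod
    def from_csv(cls, path: str | Path, state: str = "raw", width: float = 0.01):
        df = pd.read_csv(path, index_col="sample_id")
        df.columns = df.columns.astype(float)
        return cls(values=df, state=state, width=width)


def bucket_edges(
    lo: float = 0.5,
    hi: float = 10.0,
    width: float = 0.01,
    exclusions: Sequence[tuple[float, float]] = DEFAULT_EXCLUSIONS,
) -> np.ndarray:
    """Left edges of the retained buckets.

    Buckets are half-open ``[edge, edge + width)``; any bucket whose
    interior intersects an exclusion window is dropped entirely
    (conservative treatment of partial overlaps).
    """
    n = int(round((hi - lo) / width))
    edges = np.round(lo + width * np.arange(n), 6)
    keep = np.ones(n, dtype=bool)
    for a, b in exclusions:
        keep &= ~((edges < b - 1e-9) & (edges + width > a + 1e-9))
    return edges[keep]


def bucket_spectrum(
    spectrum,
    lo: float = 0.5,
    hi: float = 10.0,
    width: float = 0.01,
    exclusions: Sequence[tuple[float, float]] = DEFAULT_EXCLUSIONS,
) -> pd.Series:
    """Integrate one spectrum into raw bucket values.

    The raw value of bucket ``[a, a+width)`` is the trapezoidal integral
    of the intensity over that interval, evaluated from the cumulative
    trapezoid of the sampled spectrum (linear interpolation at bucket
    edges). The grid must cover ``[lo, hi]``.
    """
    ppm = spectrum.ppm
    if ppm[0] > lo + 1e-12 or ppm[-1] < hi - 1e-12:
        uncovered = []
        if ppm[0] > lo + 1e-12:
            uncovered.append((lo, float(ppm[0])))
        if ppm[-1] < hi - 1e-12:
            uncovered.append((float(ppm[-1]), hi))
        raise ValueError(f"spectrum grid does not cover [{lo}, {hi}]: missing {uncovered}")

    cum = np.concatenate([[0.0], cumulative_trapezoid(spectrum.intensity, ppm)])
    edges = bucket_edges(lo, hi, width, exclusions)
    left = np.interp(edges, ppm, cum)
    right = np.interp(edges + width, ppm, cum)
    return pd.Series(right - left, index=edges, name=spectrum.sample_id or None)


def bucket_spectra(
    spectra,
    lo: float = 0.5,
    hi: float = 10.0,
    width: float = 0.01,
    exclusions: Sequence[tuple[float, float]] = DEFAULT_EXCLUSIONS,
) -> BucketTable:
    """Bucket a list of spectra into one raw BucketTable."""
    rows = {}
    for s in spectra:
        rows[s.sample_id] = bucket_spectrum(s, lo, hi, width, exclusions)
    df = pd.DataFrame(rows).T
    df.index.name = "sample_id"
    return BucketTable(values=df, state="raw", width=width)


def normalize_buckets(table: BucketTable) -> BucketTable:
    """Divide each row by its own total over retained buckets.

    Samples with non-positive totals cannot be normalized; they are
    dropped with a warning (degenerate spectra). Normalizing an already
    normalized table is a no-op (idempotent).
    """
    if table.state == "pareto":
        raise ValueError("cannot normalize a pareto-scaled table")
    totals = table.values.sum(axis=1)
    bad = totals <= 0
    values = table.values
    if bad.any():
        warnings.warn(
            f"excluding {int(bad.sum())} sample(s) with non-positive spectrum "
            f"integral: {list(values.index[bad])}",
            stacklevel=2,
        )
        values = values.loc[~bad]
        totals = totals.loc[~bad]
    return BucketTable(values=values.div(totals, axis=0), state="normalized", width=table.width)


@dataclass
class ParetoScaling:
    """Pareto-scaled matrix with the factors needed to invert it."""

    scaled: pd.DataFrame
    center: pd.Series
    scale: pd.Series
    zero_variance: pd.Series  # bool per column

    def inverse(self, scaled: pd.DataFrame | None = None) -> pd.DataFrame:
        x = self.scaled if scaled is None else scaled
        out = x.mul(self.scale, axis=1).add(self.center, axis=1)
        # Zero-variance columns were mapped to 0 with scale 0; restore center.
        return out


def pareto_scale(matrix: pd.DataFrame | np.ndarray) -> ParetoScaling:
    """Center each column and divide by the square root of its sample
    standard deviation (ddof=1).

    Zero-variance columns are scaled to all-zeros and flagged rather than
    producing NaNs.
    """
    df = pd.DataFrame(matrix).copy()
    if len(df) < 2:
        raise ValueError("pareto scaling needs at least 2 rows")
    center = df.mean(axis=0)
    sd = df.std(axis=0, ddof=1)
    zero_var = sd <= 0
    scale = np.sqrt(sd)
    scale[zero_var] = 0.0
    safe = scale.replace(0.0, np.nan)
    scaled = df.sub(center, axis=1).div(safe, axis=1).fillna(0.0)
    return ParetoScaling(scaled=scaled, center=center, scale=scale, zero_variance=zero_var)
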