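"""The metabolite method: template unmixing of whole spectra.

Each library metabolite is rendered noiselessly, bucketed on the common
grid, and L1-normalized into a template column. A sample's normalized
bucket row is decomposed by non-negative least squares against the
template matrix; estimates below a detection floor count as absent.
Metabolites present in at least half of the samples at one overfeeding
day are retained, Pareto-scaled, and qualified by one-component PLS1
VIP > 1 together with BH-corrected per-metabolite regressions.

The unmixing is a deliberately simple fingerprint-deconvolution scheme:
templates are not locally realigned, so chemical-shift jitter beyond
about one bucket width degrades recovery.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from hepamark.bucket_method import _regression_pvalues, bh_adjust
from hepamark.chemometrics import fit_pls1
from hepamark.preprocess import DEFAULT_EXCLUSIONS, BucketTable, bucket_spectrum, pareto_scale
from hepamark.synthetic import FingerprintLibrary, render_spectrum

__all__ = [
    "build_templates",
    "unmix_spectrum",
    "unmix_study",
    "presence_filter",
    "qualify_metabolite_biomarkers",
]


def build_templates(
    library: FingerprintLibrary,
    lo: float = 0.5,
    hi: float = 10.0,
    width: float = 0.01,
    exclusions=DEFAULT_EXCLUSIONS,
    grid_step: float = 0.001,
    linewidth: float = 0.002,
) -> pd.DataFrame:
    """Buckets x metabolites template matrix.

    One noiseless, jitter-free rendered spectrum per metabolite at unit
    concentration, bucketed exactly as the samples, then L1-normalized.
    Metabolites whose peaks all fall in excluded regions produce an
    all-zero column and are dropped with a warning.
    """
    if not library.metabolites:
        raise ValueError("empty fingerprint library")
    cols = {}
    dropped = []
    for name in library.metabolites:
        spec = render_spectrum(
            {name: 1.0},
            library,
            grid_step=grid_step,
            linewidth=linewidth,
            shift_jitter_sd=0.0,
            noise_sd=0.0,
            seed=0,
        )
        raw = bucket_spectrum(spec, lo, hi, width, exclusions)
        total = raw.sum()
        # analytic area of the unit-concentration render; a metabolite whose
        # peaks all sit in excluded regions leaves only far Lorentzian tail
        expected = sum(p.n_protons for p in library.peaks_for(name))
        if total <= 0.05 * expected:
            dropped.append(name)
            continue
        cols[name] = raw / total
    if dropped:
        warnings.warn(f"dropped template(s) with no retained signal: {dropped}", stacklevel=2)
    return pd.DataFrame(cols)


def unmix_spectrum(
    bucket_row: pd.Series,
    templates: pd.DataFrame,
    detection_floor: float = 1e-6,
) -> pd.Series:
    """Non-negative least-squares unmixing of one bucket row.

    Solves ``argmin_{c >= 0} ||b - T c||^2``; coefficients below
    ``detection_floor`` times the row's total intensity are set to
    exactly 0 and count as "absent" for the presence filter.
    """
    if len(bucket_row) != len(templates):
        raise ValueError("bucket row and templates are on different bucket sets")
    if not np.array_equal(
        np.asarray(bucket_row.index, dtype=float),
        np.asarray(templates.index, dtype=float),
    ):
        raise ValueError("bucket labels of row and templates differ")
    b = bucket_row.to_numpy(dtype=float)
    c, _ = nnls(templates.to_numpy(dtype=float), b)
    floor = detection_floor * max(b.sum(), 0.0)
    c[c < floor] = 0.0
    return pd.Series(c, index=templates.columns, name=bucket_row.name)


def unmix_study(
    table: BucketTable,
    templates: pd.DataFrame,
    detection_floor: float = 1e-6,
) -> pd.DataFrame:
    """Unmix every sample of a bucket table into a concentration matrix."""
    rows = [
        unmix_spectrum(row, templates, detection_floor)
        for _, row in table.values.iterrows()
    ]
    conc = pd.DataFrame(rows)
    conc.index = table.values.index
    return conc


def presence_filter(
    conc: pd.DataFrame,
    pheno: pd.DataFrame,
    min_frac: float = 0.5,
) -> list[str]:
    """Retain metabolites present (> 0) in at least ``min_frac`` of the
    samples of at least one overfeeding day."""
    day = pheno.set_index("sample_id").loc[conc.index, "day"]
    retained = []
    for m in conc.columns:
        present = conc[m] > 0
        frac_by_day = present.groupby(day).mean()
        if (frac_by_day >= min_frac).any():
            retained.append(m)
    return retained


def qualify_metabolite_biomarkers(
    conc: pd.DataFrame,
    y,
    trait: str = "",
    vip_thresh: float = 1.0,
    bh_thresh: float = 0.05,
) -> pd.DataFrame:
    """PLS1-VIP plus BH qualification of a retained concentration table.

    The table is Pareto-scaled and fitted against the trait with one
    latent variable; per metabolite the trait is regressed on the
    concentration and the p-values BH-adjusted across retained
    metabolites. A biomarker needs both VIP above ``vip_thresh`` and a
    BH p-value below ``bh_thresh``.
    """
    if conc.shape[1] < 3:
        raise ValueError("need at least 3 retained metabolites")
    y = np.asarray(y, dtype=float)
    scaled = pareto_scale(conc).scaled
    model = fit_pls1(scaled, y)
    _, p, _ = _regression_pvalues(conc.to_numpy(dtype=float), y)
    bh = bh_adjust(p)

    yc = y - y.mean()
    M = conc.to_numpy(dtype=float)
    xc = M - M.mean(axis=0)
    denom = np.sqrt((xc**2).sum(axis=0)) * np.sqrt((yc**2).sum())
    corr = np.where(denom > 0, (xc * yc[:, None]).sum(axis=0) / np.maximum(denom, 1e-300), 0.0)
    r2 = corr**2

    qualified = (model.vip > vip_thresh) & (bh < bh_thresh)
    return pd.DataFrame(
        {
            "metabolite": conc.columns,
            "trait": trait,
            "method": "metabolite",
            "vip": model.vip,
            "bh_p": bh,
            "r2": r2,
            "corr_with_trait": corr,
            "qualified": qualified,
        }
    ).reset_index(drop=True)
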