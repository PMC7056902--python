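"""Marker screening for genomic prediction.

Two screens are implemented, both computed on a reference (training) subset
of individuals with missing genotypes ignored:

* the homozygote-contrast statistic (pre-marker-selection, PMS):
  ``d = |mean(yc | dosage 0) - mean(yc | dosage 2)|``, normalised to
  ``d' = d / max(d)`` over markers with both homozygote classes present;
  markers with ``d'`` strictly above a cutoff are retained;
* single-marker GWAS: OLS of yc on dosage with intercept, two-sided p-value
  from a t reference with n-2 degrees of freedom; markers with p strictly
  below an alpha threshold are retained.

Heterozygotes carry no information for the PMS contrast; a marker whose
reference subset lacks one (or both) homozygote classes is ineligible and
can never be selected.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .data import MISSING, GenotypeMatrix

_TINY = 1e-12


@dataclass
class SelectionConfig:
    """How to preselect markers: method PMS/GWAS/ALL and its cutoff.

    ``cutoff`` is the d' threshold for PMS (default 0.05) or the p-value
    threshold for GWAS (default 0.01); ALL ignores it.
    """

    method: str = "PMS"
    cutoff: float = 0.05

    def __post_init__(self) -> None:
        self.method = self.method.upper()
        if self.method not in ("PMS", "GWAS", "ALL"):
            raise ValueError(f"unknown selection method: {self.method}")
        if self.method != "ALL" and not (0 < self.cutoff <= 1):
            raise ValueError("cutoff must lie in (0, 1]")

    @classmethod
    def default_for(cls, method: str) -> "SelectionConfig":
        m = method.upper()
        return cls(m, {"PMS": 0.05, "GWAS": 0.01, "ALL": 1.0}[m])


def _align(g: GenotypeMatrix, yc: pd.DataFrame, reference_ids) -> tuple[np.ndarray, np.ndarray]:
    """Dosage submatrix and yc vector for the reference subset, in a fixed order."""
    ref = list(reference_ids)
    have = set(g.individual_ids)
    yc_map = dict(zip(yc["id"], yc["yc"]))
    missing = [i for i in ref if i not in have or i not in yc_map]
    if missing:
        raise ValueError(f"reference ids lack genotype or phenotype: {missing[:5]}")
    pos = {s: i for i, s in enumerate(g.individual_ids)}
    idx = np.array([pos[i] for i in ref], dtype=int)
    y = np.array([yc_map[i] for i in ref], dtype=float)
    return g.dosages[idx, :], y


# ---------------------------------------------------------------------------
# PMS homozygote contrast


def _pms_stats(dos: np.ndarray, y: np.ndarray):
    """Per-marker homozygote counts and phenotype sums (missing excluded)."""
    hom0 = dos == 0
    hom2 = dos == 2
    return (
        hom0.sum(axis=0),
        y @ hom0,
        hom2.sum(axis=0),
        y @ hom2,
    )


def _pms_d(cnt0, sum0, cnt2, sum2):
    """d and eligibility from homozygote sufficient statistics."""
    eligible = (cnt0 >= 1) & (cnt2 >= 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.abs(sum0 / cnt0 - sum2 / cnt2)
    d = np.where(eligible, d, np.nan)
    return d, eligible


def _normalize_d(d: np.ndarray, eligible: np.ndarray) -> np.ndarray:
    if not eligible.any():
        raise ValueError("no marker has both homozygote classes in the reference set")
    dmax = np.nanmax(d)
    if dmax <= _TINY:
        warnings.warn("max homozygote contrast is 0; all d' set to 0", stacklevel=2)
        return np.where(eligible, 0.0, np.nan)
    return d / dmax

def pms_scores(
    g: GenotypeMatrix, yc: pd.DataFrame, reference_ids=None
) -> pd.DataFrame:
    """Homozygote-contrast scores per marker on a reference subset.

    Returns a DataFrame with columns marker_id, n_hom1, n_hom2, d, d_prime,
    eligible.  d' is d divided by the maximum d over eligible markers of
    this reference subset, so max(d') = 1 whenever any eligible contrast is
    positive.
    """
    if reference_ids is None:
        reference_ids = yc["id"]
    dos, y = _align(g, yc, reference_ids)
    cnt0, sum0, cnt2, sum2 = _pms_stats(dos, y)
    d, eligible = _pms_d(cnt0, sum0, cnt2, sum2)
    d_prime = _normalize_d(d, eligible)
    return pd.DataFrame(
        {
            "marker_id": g.marker_ids,
            "n_hom1": cnt0,
            "n_hom2": cnt2,
            "d": d,
            "d_prime": d_prime,
            "eligible": eligible,
        }
    )


def select_pms(scores: pd.DataFrame, cutoff: float = 0.05) -> np.ndarray:
    """Marker ids of eligible markers with d' strictly greater than ``cutoff``."""
    keep = scores["eligible"] & (scores["d_prime"] > cutoff)
    sel = scores.loc[keep, "marker_id"].to_numpy()
    if sel.size == 0:
        warnings.warn("PMS selection is empty", stacklevel=2)
    return sel


# ---------------------------------------------------------------------------
# Single-marker GWAS


def _gwas_stats(dos: np.ndarray, y: np.ndarray):
    """Sufficient statistics per marker for OLS of y on dosage, missing dropped."""
    obs = dos != MISSING
    x = np.where(obs, dos, 0).astype(float)
    n = obs.sum(axis=0)
    sx = x.sum(axis=0)
    sxx = (x * x).sum(axis=0)
    sy = y @ obs
    syy = (y * y) @ obs
    sxy = y @ x
    return n, sx, sxx, sy, syy, sxy


def _gwas_tests(n, sx, sxx, sy, syy, sxy):
    """slope, SE, t, p, residual variance from sufficient statistics."""
    with np.errstate(invalid="ignore", divide="ignore"):
        sxx_c = sxx - sx * sx / n
        sxy_c = sxy - sx * sy / n
        syy_c = syy - sy * sy / n
    testable = (n >= 3) & (sxx_c > _TINY * np.maximum(sxx, 1.0))
    with np.errstate(invalid="ignore", divide="ignore"):
        slope = sxy_c / sxx_c
        rss = np.maximum(syy_c - slope * sxy_c, 0.0)
        sigma2 = rss / (n - 2)
        se = np.sqrt(sigma2 / sxx_c)
        t = slope / se
        # se = 0 at an exact fit: the slope is then infinitely significant
        t = np.where(se > 0, t, np.inf * np.sign(slope))
        p = 2.0 * sps.t.sf(np.abs(t), np.maximum(n - 2, 1))
    bad = ~testable
    for a in (slope, se, t, p, sigma2):
        a[bad] = np.nan
    return slope, se, t, p, sigma2, testable


def gwas_scan(
    g: GenotypeMatrix, yc: pd.DataFrame, reference_ids=None
) -> pd.DataFrame:
    """Single-marker regression of corrected phenotype on dosage.

    Returns marker_id, slope, slope_se, t_stat, p_value, residual_variance,
    testable.  Markers with zero dosage variance in the reference subset
    (after dropping missing genotypes) or fewer than 3 observations are
    flagged untestable.
    """
    if reference_ids is None:
        reference_ids = yc["id"]
    dos, y = _align(g, yc, reference_ids)
    slope, se, t, p, sigma2, testable = _gwas_tests(*_gwas_stats(dos, y))
    return pd.DataFrame(
        {
            "marker_id": g.marker_ids,
            "slope": slope,
            "slope_se": se,
            "t_stat": t,
            "p_value": p,
            "residual_variance": sigma2,
            "testable": testable,
        }
    )


def select_gwas(result: pd.DataFrame, alpha: float = 0.01) -> np.ndarray:
    """Marker ids of testable markers with p strictly below ``alpha``."""
    keep = result["testable"] & (result["p_value"] < alpha)
    return result.loc[keep, "marker_id"].to_numpy()


def preselect_markers(
    g: GenotypeMatrix,
    yc: pd.DataFrame,
    reference_ids,
    config: SelectionConfig,
) -> np.ndarray:
    """Apply the configured screen and return the selected marker ids."""
    if config.method == "ALL":
        return g.marker_ids.copy()
    if config.method == "PMS":
        return select_pms(pms_scores(g, yc, reference_ids), config.cutoff)
    return select_gwas(gwas_scan(g, yc, reference_ids), config.cutoff)
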