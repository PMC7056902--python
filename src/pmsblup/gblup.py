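"""Genomic BLUP with a VanRaden relationship matrix and exact 1-D REML.

The model is the standard single-random-effect animal model

    y = 1 mu + g + e,   g ~ N(0, G sigma_g^2),   e ~ N(0, I sigma_e^2),

with G = M M' / sum_i 2 p_i (1 - p_i) built from centered allele dosages
(column i of M holds 0-2p_i, 1-2p_i or 2-2p_i; missing genotypes are 0
after centering, i.e. the expected score).  Because there is a single
genomic variance plus a residual, the restricted likelihood can be profiled
down to one dimension: after an eigendecomposition of the phenotyped block
of G, the REML criterion is an explicit function of the heritability
h2 = sigma_g^2 / (sigma_g^2 + sigma_e^2), maximised by Brent search.  This
makes refitting cheap enough to repeat inside leave-one-out
cross-validation.

The module follows the statsmodels convention: :class:`GBLUP` is the model
(data + design), :meth:`GBLUP.fit` runs REML and returns a
:class:`GBLUPResults` carrying variance components, their uncertainty,
breeding values for every individual in G, and a ``summary()`` table.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve, eigh
from scipy.optimize import minimize_scalar

from .data import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)

_H2_LO = 1e-6
_H2_HI = 1.0 - 1e-6


@dataclass
class CenteredMarkerMatrix:
    """Allele-frequency-centered dosage matrix M and its VanRaden denominator."""

    values: np.ndarray  # n x m, centered; 0 where the genotype was missing
    freqs: np.ndarray  # allele2 frequency per retained marker, in (0, 1)
    denominator: float  # sum over markers of 2 p (1 - p)
    individual_ids: list
    marker_ids: np.ndarray


@dataclass
class GenomicRelationshipMatrix:
    """VanRaden genomic relationship matrix G = MM'/sum 2p(1-p)."""

    values: np.ndarray
    individual_ids: list
    marker_ids: np.ndarray
    denominator: float
    jitter: float = 0.0

    def __post_init__(self) -> None:
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("G must be symmetric")

    def submatrix(self, ids) -> np.ndarray:
        pos = {s: i for i, s in enumerate(self.individual_ids)}
        idx = np.array([pos[i] for i in ids], dtype=int)
        return self.values[np.ix_(idx, idx)]

    def to_tsv(self, path) -> None:
        pd.DataFrame(
            self.values, index=self.individual_ids, columns=self.individual_ids
        ).to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path) -> "GenomicRelationshipMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        vals = df.to_numpy(dtype=float)
        vals = 0.5 * (vals + vals.T)  # text round-trip symmetrization
        return cls(vals, [str(i) for i in df.index], np.array([]), np.nan)


@dataclass
class VarianceComponents:
    """REML variance components for the single-genomic-effect model."""

    sigma_g2: float
    sigma_e2: float
    h2: float
    se_h2: float
    loglik: float
    boundary: bool = False

    def __post_init__(self) -> None:
        if self.sigma_g2 < 0 or self.sigma_e2 < 0:
            raise ValueError("variance components must be non-negative")


@dataclass
class GblupFit:
    """Intercept and genomic breeding values from a GBLUP solve."""

    mu: float
    gebv: pd.Series  # indexed by individual id, covers every individual in G
    trained_on: list


def center_matrix(g: GenotypeMatrix, marker_subset=None) -> CenteredMarkerMatrix:
    """Center dosages by twice the observed allele frequency.

    Frequencies are computed from the non-missing genotypes of *all*
    individuals in ``g``.  Monomorphic markers (p = 0 or 1) contribute
    nothing to relationships and are dropped with a warning; missing
    genotypes are set to the expected score, i.e. 0 after centering.
    """
    if marker_subset is not None:
        g = g.subset_markers(marker_subset)
    if g.n_markers == 0:
        raise ValueError("empty marker subset")
    dos = g.dosages
    obs = dos != MISSING
    n_obs = obs.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(obs, dos, 0).sum(axis=0) / (2.0 * n_obs)
    poly = (n_obs > 0) & (p > 0.0) & (p < 1.0)
    if not poly.any():
        raise ValueError("all markers are monomorphic; VanRaden denominator is 0")
    if not poly.all():
        warnings.warn(
            f"dropping {int((~poly).sum())} monomorphic/uncalled markers from M",
            stacklevel=2,
        )
    p = p[poly]
    M = np.where(obs[:, poly], dos[:, poly], 2.0 * p) - 2.0 * p
    return CenteredMarkerMatrix(
        values=M,
        freqs=p,
        denominator=float(np.sum(2.0 * p * (1.0 - p))),
        individual_ids=list(g.individual_ids),
        marker_ids=g.marker_ids[poly],
    )


def build_grm(c: CenteredMarkerMatrix, jitter: float = 0.0) -> GenomicRelationshipMatrix:
    """G = MM' / sum 2p(1-p), optionally with a small diagonal addition."""
    if c.denominator <= 0:
        raise ValueError("VanRaden denominator must be positive")
    if jitter < 0:
        raise ValueError("jitter must be non-negative")
    G = (c.values @ c.values.T) / c.denominator
    G = 0.5 * (G + G.T)
    if jitter > 0:
        G = G + jitter * np.eye(G.shape[0])
        logger.info("applied diagonal jitter %.2e to G", jitter)
    return GenomicRelationshipMatrix(
        G, c.individual_ids, c.marker_ids, c.denominator, jitter
    )


def grm_from_genotypes(
    g: GenotypeMatrix, marker_subset=None, jitter: float = 0.0
) -> GenomicRelationshipMatrix:
    """Convenience: center and build G in one call."""
    return build_grm(center_matrix(g, marker_subset), jitter)


# ---------------------------------------------------------------------------
# REML internals: everything is a function of h2 after one eigendecomposition


class _Profile:
    """Profiled restricted log-likelihood of h2 for y = 1 mu + g + e."""

    def __init__(self, G_tt: np.ndarray, y: np.ndarray):
        self.n = len(y)
        self.d, U = eigh(G_tt)
        self.yt = U.T @ y
        self.xt = U.T @ np.ones(self.n)
        self.U = U

    def _weights(self, h2: float) -> np.ndarray:
        # eigenvalues of K = h2 G + (1 - h2) I; tiny floor guards G with
        # slightly negative numerical eigenvalues at h2 near 1
        return np.maximum(h2 * self.d + (1.0 - h2), 1e-12)

    def components(self, h2: float):
        """(mu, sigma_p2, rss, k) at a given heritability."""
        k = self._weights(h2)
        w = 1.0 / k
        xwx = np.sum(w * self.xt**2)
        xwy = np.sum(w * self.xt * self.yt)
        mu = xwy / xwx
        rss = np.sum(w * (self.yt - mu * self.xt) ** 2)
        sigma_p2 = rss / (self.n - 1)
        return mu, sigma_p2, rss, k, xwx

    def loglik(self, h2: float) -> float:
        _, sigma_p2, _, k, xwx = self.components(h2)
        n1 = self.n - 1
        return -0.5 * (
            n1 * np.log(sigma_p2)
            + np.sum(np.log(k))
            + np.log(xwx)
            + n1 * (1.0 + np.log(2.0 * np.pi))
        )


def _loglik_curvature(profile: _Profile, h2: float, step: float = 1e-4) -> float:
    """Central second difference of the profiled restricted log-likelihood."""
    h = min(step, (h2 - _H2_LO) / 2, (_H2_HI - h2) / 2)
    if h <= 0:
        return -np.inf
    f0 = profile.loglik(h2)
    return (profile.loglik(h2 + h) - 2 * f0 + profile.loglik(h2 - h)) / h**2


def _align_phenotypes(grm: GenomicRelationshipMatrix, yc: pd.DataFrame, ids) -> tuple[list, np.ndarray]:
    yc_map = dict(zip(yc["id"], yc["yc"]))
    ids = [i for i in (ids if ids is not None else grm.individual_ids) if i in yc_map]
    absent = [i for i in ids if i not in set(grm.individual_ids)]
    if absent:
        raise ValueError(f"ids missing from G: {absent[:5]}")
    return ids, np.array([yc_map[i] for i in ids], dtype=float)


def reml_fit(
    grm: GenomicRelationshipMatrix,
    yc: pd.DataFrame,
    ids=None,
    h2_tol: float = 1e-8,
) -> VarianceComponents:
    """Estimate sigma_g2 and sigma_e2 by REML.

    Maximizes the restricted likelihood over h2 in [1e-6, 1-1e-6] by Brent
    search on the 1-D profile obtained from an eigendecomposition of the
    phenotyped block of G.  The standard error of h2 comes from the inverse
    observed information (numerical curvature) of the profile; estimates
    within 1e-5 of a bound, or components below 1e-8 x var(y), are flagged
    as boundary solutions.
    """
    ids, y = _align_phenotypes(grm, yc, ids)
    if len(ids) < 3:
        raise ValueError("need at least 3 phenotyped individuals for REML")
    profile = _Profile(grm.submatrix(ids), y)
    opt = minimize_scalar(
        lambda h2: -profile.loglik(h2),
        bounds=(_H2_LO, _H2_HI),
        method="bounded",
        options={"xatol": h2_tol},
    )
    if not opt.success:
        raise RuntimeError(f"REML optimization did not converge: {opt.message}")
    h2 = float(opt.x)
    _, sigma_p2, _, _, _ = profile.components(h2)
    curv = _loglik_curvature(profile, h2)
    se_h2 = float(1.0 / np.sqrt(-curv)) if curv < 0 else np.nan
    sigma_g2 = h2 * sigma_p2
    sigma_e2 = (1.0 - h2) * sigma_p2
    floor = 1e-8 * np.var(y)
    boundary = (
        h2 < _H2_LO + 1e-5
        or h2 > _H2_HI - 1e-5
        or sigma_g2 < floor
        or sigma_e2 < floor
    )
    return VarianceComponents(
        sigma_g2=float(sigma_g2),
        sigma_e2=float(sigma_e2),
        h2=h2,
        se_h2=se_h2,
        loglik=float(profile.loglik(h2)),
        boundary=bool(boundary),
    )


def gblup_predict(
    grm: GenomicRelationshipMatrix,
    yc: pd.DataFrame,
    vc: VarianceComponents,
    train_ids=None,
) -> GblupFit:
    """Solve the mixed-model equations for every individual in G.

    The intercept is the GLS estimate on the training block with
    V = G_tt sigma_g2 + I sigma_e2, and

        ghat = sigma_g2 * G[:, t] V^{-1} (y_t - 1 mu),

    so individuals without phenotypes (or outside ``train_ids``) still
    receive breeding values through their genomic relationships.
    """
    train_ids, y = _align_phenotypes(grm, yc, train_ids)
    nt = len(train_ids)
    V = vc.sigma_g2 * grm.submatrix(train_ids) + vc.sigma_e2 * np.eye(nt)
    ones = np.ones(nt)
    try:
        cf = cho_factor(V)
    except np.linalg.LinAlgError:
        logger.warning("V not positive definite; retrying with 1e-6 jitter")
        cf = cho_factor(V + 1e-6 * np.eye(nt))
    Vinv_y = cho_solve(cf, y)
    Vinv_1 = cho_solve(cf, ones)
    mu = float(ones @ Vinv_y / (ones @ Vinv_1))
    alpha = cho_solve(cf, y - mu)
    pos = {s: i for i, s in enumerate(grm.individual_ids)}
    tidx = np.array([pos[i] for i in train_ids], dtype=int)
    gebv = vc.sigma_g2 * (grm.values[:, tidx] @ alpha)
    return GblupFit(
        mu=mu,
        gebv=pd.Series(gebv, index=grm.individual_ids, name="gebv"),
        trained_on=train_ids,
    )


def heritability(vc: VarianceComponents) -> float:
    """Narrow-sense heritability sigma_g2 / (sigma_g2 + sigma_e2)."""
    tot = vc.sigma_g2 + vc.sigma_e2
    if tot <= 0:
        raise ValueError("both variance components are zero")
    return vc.sigma_g2 / tot


# ---------------------------------------------------------------------------
# Model / Results surface


class GBLUP:
    """Genomic BLUP model: corrected phenotypes plus a relationship matrix.

    Parameters
    ----------
    yc : pandas.DataFrame
        Corrected phenotypes with columns ``id`` and ``yc``.
    grm : GenomicRelationshipMatrix
        VanRaden G over all individuals to be predicted.
    train_ids : sequence of str, optional
        Individuals whose phenotypes enter the fit; defaults to every
        phenotyped individual present in G.  Everyone in G is predicted.

    Examples
    --------
    >>> model = GBLUP.from_genotypes(genotypes, yc)       # doctest: +SKIP
    >>> res = model.fit()                                  # doctest: +SKIP
    >>> res.h2, res.gebv.head()                            # doctest: +SKIP
    """

    def __init__(self, yc: pd.DataFrame, grm: GenomicRelationshipMatrix, train_ids=None):
        self.grm = grm
        self.yc = yc
        self.train_ids, self._y = _align_phenotypes(grm, yc, train_ids)

    @classmethod
    def from_genotypes(
        cls, g: GenotypeMatrix, yc: pd.DataFrame, marker_subset=None, train_ids=None
    ) -> "GBLUP":
        return cls(yc, grm_from_genotypes(g, marker_subset), train_ids)

    def fit(self, h2_tol: float = 1e-8) -> "GBLUPResults":
        vc = reml_fit(self.grm, self.yc, self.train_ids, h2_tol=h2_tol)
        blup = gblup_predict(self.grm, self.yc, vc, self.train_ids)
        return GBLUPResults(self, vc, blup)


class GBLUPResults:
    """REML estimates, breeding values and diagnostics from a GBLUP fit."""

    def __init__(self, model: GBLUP, vc: VarianceComponents, blup: GblupFit):
        self.model = model
        self.vc = vc
        self.mu = blup.mu
        self.gebv = blup.gebv
        self.trained_on = blup.trained_on

    @property
    def sigma_g2(self) -> float:
        return self.vc.sigma_g2

    @property
    def sigma_e2(self) -> float:
        return self.vc.sigma_e2

    @property
    def h2(self) -> float:
        return self.vc.h2

    @property
    def se_h2(self) -> float:
        return self.vc.se_h2

    @property
    def loglik(self) -> float:
        return self.vc.loglik

    def summary(self) -> str:
        lines = [
            "GBLUP / REML results",
            "--------------------",
            f"individuals in G:      {len(self.model.grm.individual_ids)}",
            f"phenotyped (training): {len(self.trained_on)}",
            f"markers in G:          {len(self.model.grm.marker_ids)}",
            f"intercept mu:          {self.mu:.6g}",
            f"sigma_g^2:             {self.sigma_g2:.6g}",
            f"sigma_e^2:             {self.sigma_e2:.6g}",
            f"h^2:                   {self.h2:.4f} +/- {self.se_h2:.4f}",
            f"restricted loglik:     {self.loglik:.6g}",
        ]
        if self.vc.boundary:
            lines.append("note: boundary estimate (a component is at its floor)")
        return "\n".join(lines)

    def to_frame(self) -> pd.DataFrame:
        """One-row report of the variance components and fit diagnostics."""
        return pd.DataFrame(
            {
                "sigma_g2": [self.sigma_g2],
                "sigma_e2": [self.sigma_e2],
                "h2": [self.h2],
                "se_h2": [self.se_h2],
                "loglik": [self.loglik],
                "n": [len(self.trained_on)],
                "m_used": [len(self.model.grm.marker_ids)],
            }
        )
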