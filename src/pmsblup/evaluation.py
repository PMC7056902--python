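"""Leave-one-out cross-validation, accuracy/unbiasedness metrics and
bootstrapped scenario comparison.

Each fold withholds one phenotyped individual, re-runs marker preselection
on the remaining n-1 (the withheld bird's phenotype never enters screening),
rebuilds the VanRaden G on the selected markers over all individuals,
re-estimates variance components by REML on the training phenotypes and
predicts the withheld breeding value.  Accuracy is the single pooled Pearson
correlation between the n out-of-fold GEBVs and the corrected phenotypes;
unbiasedness is the slope of yc regressed on GEBV (1 = unbiased).  Scenario
pairs are compared with a bootstrapped paired t-test: individuals are
resampled jointly, both accuracies recomputed per replicate, and a paired t
applied to the replicate differences.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .data import MISSING, GenotypeMatrix
from .gblup import _Profile
from .preselect import (
    SelectionConfig,
    _gwas_stats,
    _gwas_tests,
    _pms_d,
    _pms_stats,
)

_TINY = 1e-12


@dataclass
class LooCvConfig:
    """Configuration of a leave-one-out cross-validation run."""

    selection: SelectionConfig = field(default_factory=SelectionConfig)
    bootstrap_reps: int = 1000
    seed: int = 0
    refit_variance_per_fold: bool = True
    on_empty_selection: str = "abort"  # or "skip"

    def __post_init__(self) -> None:
        if self.bootstrap_reps < 100:
            raise ValueError("bootstrap_reps must be at least 100")
        if self.on_empty_selection not in ("abort", "skip"):
            raise ValueError("on_empty_selection must be 'abort' or 'skip'")


@dataclass
class LooCvResult:
    """Pooled out-of-fold predictions and their summary metrics."""

    gebv_oof: pd.Series  # indexed by individual id
    yc: pd.Series
    accuracy: float
    accuracy_se: float
    bias_slope: float
    bias_slope_se: float
    per_fold_markers: np.ndarray
    failed_folds: list
    config: LooCvConfig

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "individual_id": self.gebv_oof.index,
                "yc": self.yc.to_numpy(),
                "gebv_oof": self.gebv_oof.to_numpy(),
                "n_markers_selected": self.per_fold_markers,
            }
        )

    def summary_row(self, scenario: str = "") -> pd.DataFrame:
        return pd.DataFrame(
            {
                "scenario": [scenario or self.config.selection.method],
                "accuracy": [self.accuracy],
                "accuracy_se": [self.accuracy_se],
                "bias_slope": [self.bias_slope],
                "bias_slope_se": [self.bias_slope_se],
                "seed": [self.config.seed],
            }
        )


@dataclass
class ScenarioComparison:
    """Bootstrapped paired t-test between two prediction scenarios."""

    accuracy_a: float
    accuracy_b: float
    accuracy_a_se: float
    accuracy_b_se: float
    t_stat: float
    p_value: float
    n_boot: int
    seed: int


# ---------------------------------------------------------------------------
# Metrics


def accuracy(gebv_oof, yc) -> float:
    """Pooled Pearson correlation between predictions and corrected phenotypes."""
    g = np.asarray(gebv_oof, dtype=float)
    y = np.asarray(yc, dtype=float)
    if len(g) < 3:
        raise ValueError("need at least 3 pairs for a correlation")
    if np.std(g) <= _TINY or np.std(y) <= _TINY:
        warnings.warn("constant input; accuracy undefined", stacklevel=2)
        return np.nan
    return float(np.corrcoef(g, y)[0, 1])


def unbiasedness(gebv_oof, yc) -> tuple[float, float]:
    """OLS slope (and SE) of yc on GEBV, with intercept; 1 means unbiased."""
    g = np.asarray(gebv_oof, dtype=float)
    y = np.asarray(yc, dtype=float)
    n = len(g)
    vg = np.var(g)
    if vg <= _TINY:
        warnings.warn("zero-variance GEBV; slope undefined", stacklevel=2)
        return np.nan, np.nan
    slope = float(np.cov(g, y, ddof=1)[0, 1] / np.var(g, ddof=1))
    resid = y - y.mean() - slope * (g - g.mean())
    if n > 2:
        se = float(np.sqrt(resid @ resid / (n - 2) / ((n - 1) * np.var(g, ddof=1))))
    else:
        se = np.nan
    return slope, se


def _boot_correlations(a, b, y, n_boot: int, rng) -> tuple[np.ndarray, np.ndarray]:
    """Joint bootstrap of two prediction-vs-phenotype correlations."""
    n = len(y)
    ra = np.empty(n_boot)
    rb = np.empty(n_boot)
    for i in range(n_boot):
        idx = rng.integers(0, n, n)
        ys = y[idx]
        with np.errstate(invalid="ignore", divide="ignore"):
            ra[i] = _corr(a[idx], ys)
            rb[i] = _corr(b[idx], ys)
    return ra, rb


def _corr(x, y) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    den = np.sqrt((xc @ xc) * (yc @ yc))
    return (xc @ yc) / den if den > 0 else np.nan


def compare_scenarios(
    gebv_a, gebv_b, yc, n_boot: int = 1000, seed: int = 0
) -> ScenarioComparison:
    """Bootstrapped paired t-test on the accuracy difference of two scenarios.

    Individuals are resampled with replacement (jointly for both scenarios);
    both accuracies are recomputed on each of ``n_boot`` replicates and a
    paired t-test with n_boot - 1 degrees of freedom is applied to the
    replicate differences.  If every difference is exactly zero, t = 0 and
    p = 1 by convention.  The bootstrap SE of each accuracy is the standard
    deviation of its resampled values.
    """
    a = np.asarray(gebv_a, dtype=float)
    b = np.asarray(gebv_b, dtype=float)
    y = np.asarray(yc, dtype=float)
    if not (len(a) == len(b) == len(y)):
        raise ValueError("scenario GEBVs and yc must align to the same individuals")
    rng = np.random.default_rng(seed)
    ra, rb = _boot_correlations(a, b, y, n_boot, rng)
    diffs = ra - rb
    diffs = diffs[~np.isnan(diffs)]
    if len(diffs) == 0 or np.all(diffs == 0.0):
        t, p = 0.0, 1.0
    else:
        sd = diffs.std(ddof=1)
        if sd <= 0:
            t, p = (0.0, 1.0) if diffs.mean() == 0 else (np.inf, 0.0)
        else:
            t = diffs.mean() / (sd / np.sqrt(len(diffs)))
            p = float(2.0 * sps.t.sf(abs(t), len(diffs) - 1))
    return ScenarioComparison(
        accuracy_a=accuracy(a, y),
        accuracy_b=accuracy(b, y),
        accuracy_a_se=float(np.nanstd(ra, ddof=1)),
        accuracy_b_se=float(np.nanstd(rb, ddof=1)),
        t_stat=float(t),
        p_value=float(p),
        n_boot=n_boot,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Leave-one-out cross-validation


def _centered_all_markers(dos: np.ndarray):
    """Centered dosage matrix over every marker (monomorphic columns are 0).

    Returns (M, weights) where weights[i] = 2 p_i (1 - p_i); the VanRaden
    denominator of any marker subset is the sum of its weights.
    """
    obs = dos != MISSING
    n_obs = obs.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n_obs > 0, np.where(obs, dos, 0).sum(axis=0) / (2.0 * n_obs), 0.0)
    M = np.where(obs, dos, 2.0 * p) - 2.0 * p
    M[:, (p <= 0) | (p >= 1)] = 0.0
    w = 2.0 * p * (1.0 - p)
    w[(p <= 0) | (p >= 1)] = 0.0
    return M, w


def _fold_selection_masks(dos, y, cfg: SelectionConfig):
    """Yield (fold index, selected-marker boolean mask) per left-out individual.

    Selection statistics are computed from sufficient statistics over all n
    reference individuals, downdated by the left-out bird — algebraically
    identical to rescreening on the n-1 remaining ones.
    """
    n, m = dos.shape
    if cfg.method == "ALL":
        mask = np.ones(m, dtype=bool)
        for k in range(n):
            yield k, mask
        return
    if cfg.method == "PMS":
        cnt0, sum0, cnt2, sum2 = _pms_stats(dos, y)
        for k in range(n):
            h0 = dos[k] == 0
            h2m = dos[k] == 2
            d, elig = _pms_d(
                cnt0 - h0, sum0 - y[k] * h0, cnt2 - h2m, sum2 - y[k] * h2m
            )
            if not elig.any():
                yield k, np.zeros(m, dtype=bool)
                continue
            dmax = np.nanmax(d)
            if dmax <= _TINY:
                yield k, np.zeros(m, dtype=bool)
                continue
            yield k, elig & (d / dmax > cfg.cutoff)
        return
    # GWAS
    nn, sx, sxx, sy, syy, sxy = _gwas_stats(dos, y)
    for k in range(n):
        o = (dos[k] != MISSING).astype(float)
        xk = np.where(dos[k] != MISSING, dos[k], 0).astype(float)
        _, _, _, p, _, testable = _gwas_tests(
            nn - o,
            sx - xk,
            sxx - xk * xk,
            sy - y[k] * o,
            syy - y[k] * y[k] * o,
            sxy - y[k] * xk,
        )
        with np.errstate(invalid="ignore"):
            yield k, testable & (p < cfg.cutoff)


def loo_cv(g: GenotypeMatrix, yc: pd.DataFrame, config: LooCvConfig) -> LooCvResult:
    """Leave-one-out cross-validation with per-fold marker reselection.

    For each phenotyped individual k: markers are preselected on the other
    n-1 individuals, G is rebuilt on the selected subset over all n,
    variance components are re-estimated on the n-1 training phenotypes
    (unless ``refit_variance_per_fold`` is off) and k's GEBV is predicted
    with its phenotype withheld.  Metrics are pooled over all folds.
    """
    ids = [i for i in g.individual_ids if i in set(yc["id"])]
    if len(ids) < 10:
        raise ValueError("need at least 10 phenotyped, genotyped individuals")
    gsub = g.subset_individuals(ids)
    ymap = dict(zip(yc["id"], yc["yc"]))
    y = np.array([ymap[i] for i in ids], dtype=float)
    n = len(ids)
    dos = gsub.dosages
    M, wts = _centered_all_markers(dos)

    fixed_vc = None
    if not config.refit_variance_per_fold:
        from .gblup import GBLUP
        from .preselect import preselect_markers

        sel_full = preselect_markers(gsub, yc, ids, config.selection)
        fixed_vc = GBLUP.from_genotypes(gsub, yc, marker_subset=sel_full).fit().vc

    gebv = np.full(n, np.nan)
    n_markers = np.zeros(n, dtype=int)
    failed = []
    train_all = np.arange(n)
    for k, sel in _fold_selection_masks(dos, y, config.selection):
        den = wts[sel].sum()
        n_markers[k] = int(sel.sum())
        if n_markers[k] == 0 or den <= 0:
            failed.append(ids[k])
            if config.on_empty_selection == "abort":
                raise RuntimeError(
                    f"fold {ids[k]}: empty or monomorphic marker selection "
                    f"({n_markers[k]} markers, denominator {den:.3g})"
                )
            continue
        # choose the cheaper of building from the selected or the complement
        if sel.sum() <= (~sel).sum():
            Ms = M[:, sel]
            Gf = (Ms @ Ms.T) / den
        else:
            Mc = M[:, ~sel]
            Gf = ((M @ M.T) - (Mc @ Mc.T)) / den
        tr = train_all[train_all != k]
        prof = _Profile(Gf[np.ix_(tr, tr)], y[tr])
        if fixed_vc is None:
            from scipy.optimize import minimize_scalar

            opt = minimize_scalar(
                lambda h2: -prof.loglik(h2),
                bounds=(1e-6, 1 - 1e-6),
                method="bounded",
                options={"xatol": 1e-8},
            )
            h2 = float(opt.x)
        else:
            h2 = fixed_vc.h2
        mu, sigma_p2, _, kvals, _ = prof.components(h2)
        # alpha = V^{-1}(y_t - mu) via the fold eigendecomposition
        r = prof.U.T @ (y[tr] - mu)
        alpha = prof.U @ (r / kvals) / sigma_p2
        gebv[k] = h2 * sigma_p2 * (Gf[k, tr] @ alpha)

    ok = ~np.isnan(gebv)
    acc = accuracy(gebv[ok], y[ok])
    slope, slope_se = unbiasedness(gebv[ok], y[ok])
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]).generate_state(1)[0])
    ra, _ = _boot_correlations(gebv[ok], gebv[ok], y[ok], config.bootstrap_reps, rng)
    return LooCvResult(
        gebv_oof=pd.Series(gebv, index=ids, name="gebv_oof"),
        yc=pd.Series(y, index=ids, name="yc"),
        accuracy=acc,
        accuracy_se=float(np.nanstd(ra, ddof=1)),
        bias_slope=slope,
        bias_slope_se=slope_se,
        per_fold_markers=n_markers,
        failed_folds=failed,
        config=config,
    )
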