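"""Bootstrap backward-elimination on line-origin-coded genotypes (Model 2).

Candidate markers from forward selection are recoded by the line of
origin of their alleles: +1 for homozygotes of the allele that is major
in the high-weight-selected (HWS) founders, -1 for homozygotes of the
LWS-founder-major allele, 0 for heterozygotes.  A positive fitted
allele-substitution effect therefore means the HWS-major allele
increases weight; a negative sign flags transgression (or collinearity
among tightly linked markers).

Backward elimination starts from the full model (sex + generation + all
candidate markers), repeatedly applies an adaptive FDR criterion to the
marker p-values and drops the single worst failing marker until all
survivors pass at the chosen FDR level (default 20%).  Running the
elimination inside a bootstrap over individuals yields, per marker, the
resample model inclusion probability (RMIP); markers with RMIP above a
threshold (default 0.46, strict inequality) enter the final model, whose
joint fit supplies the reported effects alongside Benjamini-Hochberg
adjusted p-values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ailfm.io_formats import GenotypeMatrix, PhenotypeTable
from ailfm.association import build_design


class BootstrapError(RuntimeError):
    """Too many inestimable bootstrap resamples."""


@dataclass
class EliminationConfig:
    fdr_q: float = 0.20
    n_bootstrap: int = 1000
    rmip_threshold: float = 0.46
    seed: int = 0
    adaptive: bool = True  # two-stage adaptive BH; False = plain BH

    def __post_init__(self) -> None:
        if not 0 < self.fdr_q < 1:
            raise ValueError("fdr_q must be in (0, 1)")
        if self.n_bootstrap < 1:
            raise ValueError("n_bootstrap must be >= 1")
        if not 0 <= self.rmip_threshold <= 1:
            raise ValueError("rmip_threshold must be in [0, 1]")


@dataclass
class ModelFit:
    """Joint OLS fit of Model 2 on a marker subset."""

    marker_ids: list[str]
    effects: np.ndarray
    se: np.ndarray
    p_values: np.ndarray
    n_used: int
    intercept: float
    covariate_effects: np.ndarray


@dataclass
class FinalModelReport:
    """Reported final model: a +/- SE per marker with BH-adjusted p."""

    table: pd.DataFrame  # marker, a, se, p, bh_adjusted_p
    intercept: float
    n_used: int
    fdr_q: float

    @property
    def empty(self) -> bool:
        return len(self.table) == 0


# ---------------------------------------------------------------------------
# line-origin coding
# ---------------------------------------------------------------------------


def code_line_origin(
    geno: GenotypeMatrix,
    candidates: list[str],
    founder_freqs: pd.DataFrame,
) -> pd.DataFrame:
    """Recode dosages into the -1/0/+1 line-origin scale.

    ``founder_freqs`` needs columns ``marker, p_hws, p_lws`` giving the
    reference-allele frequency in each founder line.  When both lines
    share the same major allele the coding falls back to +1 for the
    HWS-major homozygote and -1 for the opposite homozygote, with a
    warning — the scheme presumes divergent majors.
    """
    freqs = founder_freqs.set_index("marker")
    out = {}
    for mid in candidates:
        if mid not in freqs.index:
            raise ValueError(f"no founder frequencies for marker {mid!r}")
        p_hws, p_lws = float(freqs.at[mid, "p_hws"]), float(freqs.at[mid, "p_lws"])
        if np.isnan(p_hws) or np.isnan(p_lws):
            raise ValueError(f"founder frequencies missing for {mid!r}")
        hws_major_ref = p_hws >= 0.5
        lws_major_ref = p_lws >= 0.5
        if hws_major_ref == lws_major_ref:
            warnings.warn(
                f"marker {mid}: HWS and LWS founders share the same major "
                "allele; coding relative to the HWS-major allele",
                stacklevel=2,
            )
        d = geno.dosages[mid].astype(float)
        # dosage counts reference alleles; +1 = homozygous HWS-major
        out[mid] = d - 1.0 if hws_major_ref else 1.0 - d
    return pd.DataFrame(out, index=geno.dosages.index)


# ---------------------------------------------------------------------------
# adaptive FDR criterion
# ---------------------------------------------------------------------------


def benjamini_hochberg(
    p_values: np.ndarray, q: float, m_total: int | None = None
) -> np.ndarray:
    """BH step-up rejection mask.

    ``m_total`` fixes the multiplicity the thresholds are computed
    against (defaults to ``len(p_values)``).  During backward
    elimination it stays anchored at the original candidate count: the
    multiplicity being corrected is the number of markers tested, not
    the number still in the shrinking model — otherwise the last
    survivor (the minimum of all candidate p-values) would only need
    p <= q and the procedure would not control the FDR.
    """
    p = np.asarray(p_values, dtype=float)
    m = len(p)
    if m == 0:
        return np.zeros(0, dtype=bool)
    if m_total is None:
        m_total = m
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    thresholds = q * np.arange(1, m + 1) / m_total
    passing = np.flatnonzero(ranked <= thresholds)
    out = np.zeros(m, dtype=bool)
    if len(passing):
        out[order[: passing[-1] + 1]] = True
    return out


def adaptive_fdr_criterion(
    p_values: np.ndarray,
    q: float,
    adaptive: bool = True,
    m_total: int | None = None,
) -> np.ndarray:
    """Two-stage adaptive BH pass/fail mask.

    Stage 1 runs BH at q' = q / (1 + q) to estimate the number of true
    nulls m0 = m_total - r1; stage 2 re-runs BH at level
    q * m_total / m0.  Since m_total / m0 >= 1 the procedure rejects at
    least as much as plain BH at q while keeping the FDR at q under
    independence.  ``adaptive=False`` gives plain BH at q; ``m_total``
    anchors the multiplicity (see ``benjamini_hochberg``).
    """
    p = np.asarray(p_values, dtype=float)
    if len(p) == 0:
        return np.zeros(0, dtype=bool)
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    if m_total is None:
        m_total = len(p)
    if not adaptive:
        return benjamini_hochberg(p, q, m_total)
    stage1 = benjamini_hochberg(p, q / (1.0 + q), m_total)
    r1 = int(stage1.sum())
    if r1 == 0:
        return benjamini_hochberg(p, q, m_total)
    m0 = m_total - r1
    if m0 <= 0:
        return np.ones(len(p), dtype=bool)
    return benjamini_hochberg(p, min(q * m_total / m0, 1.0), m_total)


# ---------------------------------------------------------------------------
# Model 2 fitting
# ---------------------------------------------------------------------------


def _fit_model2(
    y: np.ndarray, X: np.ndarray, codes: np.ndarray, marker_ids: list[str]
) -> ModelFit | None:
    """Joint OLS of y on covariates + line-origin codes.

    Complete-case on the union of the marker columns.  Returns None when
    the model is inestimable (insufficient rows or rank-deficient).
    """
    mask = ~np.isnan(codes).any(axis=1) & ~np.isnan(y)
    n = int(mask.sum())
    k = X.shape[1] + codes.shape[1]
    if n <= k:
        return None
    M = np.column_stack([X[mask], codes[mask]])
    if np.linalg.matrix_rank(M) < M.shape[1]:
        return None
    yy = y[mask]
    beta, _, _, _ = np.linalg.lstsq(M, yy, rcond=None)
    resid = yy - M @ beta
    df = n - M.shape[1]
    sigma2 = float(resid @ resid) / df
    cov = sigma2 * np.linalg.inv(M.T @ M)
    se = np.sqrt(np.diag(cov))
    t = beta / se
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.maximum(p, np.finfo(float).tiny)
    nc = X.shape[1]
    return ModelFit(
        marker_ids=list(marker_ids),
        effects=beta[nc:],
        se=se[nc:],
        p_values=p[nc:],
        n_used=n,
        intercept=float(beta[0]),
        covariate_effects=beta[1:nc],
    )


def _drop_collinear(
    y: np.ndarray, X: np.ndarray, lom: pd.DataFrame
) -> pd.DataFrame:
    """Drop members of perfectly collinear marker groups before
    elimination proper (largest marginal p first), logging a warning."""
    current = lom
    while True:
        codes = current.to_numpy(dtype=float)
        mask = ~np.isnan(codes).any(axis=1) & ~np.isnan(y)
        M = np.column_stack([X[mask], codes[mask]])
        if (
            M.shape[0] > M.shape[1]
            and np.linalg.matrix_rank(M) == M.shape[1]
        ):
            return current
        if current.shape[1] == 0:
            return current
        # find the column whose removal recovers the most rank, breaking
        # ties toward the weakest marginal association
        marginal_p = []
        for mid in current.columns:
            z = current[mid].to_numpy(dtype=float)
            zm = ~np.isnan(z) & ~np.isnan(y)
            fitmask = zm
            Xi = np.column_stack([X[fitmask], z[fitmask]])
            try:
                b, _, _, _ = np.linalg.lstsq(Xi, y[fitmask], rcond=None)
                r = y[fitmask] - Xi @ b
                dfi = fitmask.sum() - Xi.shape[1]
                s2 = float(r @ r) / dfi
                cov = s2 * np.linalg.inv(Xi.T @ Xi)
                ti = b[-1] / np.sqrt(cov[-1, -1])
                marginal_p.append(2.0 * stats.t.sf(abs(ti), dfi))
            except np.linalg.LinAlgError:
                marginal_p.append(1.0)
        worst = current.columns[int(np.argmax(marginal_p))]
        warnings.warn(
            f"dropping {worst}: collinear in the full Model 2 design",
            stacklevel=2,
        )
        current = current.drop(columns=[worst])


def backward_eliminate(
    y: np.ndarray,
    X: np.ndarray,
    lom: pd.DataFrame,
    fdr_q: float = 0.20,
    adaptive: bool = True,
) -> tuple[list[str], ModelFit | None]:
    """FDR-terminated backward elimination.

    Fit Model 2 on the current marker set; if every marker passes the
    adaptive FDR criterion at ``fdr_q`` stop, otherwise drop the single
    largest-p failing marker and refit.  Returns the retained marker ids
    and their joint fit (None when nothing is retained).
    """
    current = _drop_collinear(y, X, lom)
    m_total = current.shape[1]  # multiplicity anchor for the criterion
    while current.shape[1] > 0:
        fit = _fit_model2(
            y, X, current.to_numpy(dtype=float), list(current.columns)
        )
        if fit is None:
            # inestimable despite the collinearity sweep: drop blindly
            current = current.iloc[:, :-1]
            continue
        passed = adaptive_fdr_criterion(
            fit.p_values, fdr_q, adaptive, m_total=m_total
        )
        if passed.all():
            return list(current.columns), fit
        failing = np.flatnonzero(~passed)
        worst = failing[int(np.argmax(fit.p_values[failing]))]
        current = current.drop(columns=[current.columns[worst]])
    return [], None


# ---------------------------------------------------------------------------
# bootstrap RMIP
# ---------------------------------------------------------------------------


@dataclass
class RMIPTable:
    table: pd.DataFrame  # marker, rmip, included
    n_bootstrap: int
    threshold: float
    n_redrawn: int = 0

    def included_markers(self) -> list[str]:
        return self.table.loc[self.table["included"], "marker"].tolist()


def bootstrap_rmip(
    y: np.ndarray,
    X: np.ndarray,
    lom: pd.DataFrame,
    cfg: EliminationConfig,
    stratify: np.ndarray | None = None,
) -> RMIPTable:
    """Resample model inclusion probabilities.

    Individuals are resampled with replacement to the original n (or
    within strata when ``stratify`` labels are given), backward
    elimination runs on each resample, and a marker's RMIP is the
    fraction of resamples whose final model contains it.  Inclusion in
    the final model requires RMIP strictly greater than the threshold.
    A resample with an inestimable full model is redrawn; more than 10%
    redraws is an error.
    """
    rng = np.random.default_rng(cfg.seed)
    n = len(y)
    counts = {mid: 0 for mid in lom.columns}
    n_redrawn = 0
    max_redraws = max(1, int(0.10 * cfg.n_bootstrap))
    if stratify is not None:
        strata = [np.flatnonzero(stratify == s) for s in pd.unique(stratify)]

    b = 0
    while b < cfg.n_bootstrap:
        if stratify is None:
            idx = rng.integers(0, n, size=n)
        else:
            idx = np.concatenate(
                [s[rng.integers(0, len(s), size=len(s))] for s in strata]
            )
        sub = lom.iloc[idx]
        fitcheck = _fit_model2(
            y[idx], X[idx], sub.to_numpy(dtype=float), list(sub.columns)
        )
        if fitcheck is None:
            n_redrawn += 1
            if n_redrawn > max_redraws:
                raise BootstrapError(
                    f"more than {max_redraws} inestimable bootstrap "
                    "resamples; candidate model too rich for the data"
                )
            continue
        retained, _ = backward_eliminate(
            y[idx], X[idx], sub, cfg.fdr_q, cfg.adaptive
        )
        for mid in retained:
            counts[mid] += 1
        b += 1
    rmip = pd.DataFrame(
        {
            "marker": list(lom.columns),
            "rmip": [counts[mid] / cfg.n_bootstrap for mid in lom.columns],
        }
    )
    rmip["included"] = rmip["rmip"] > cfg.rmip_threshold
    return RMIPTable(rmip, cfg.n_bootstrap, cfg.rmip_threshold, n_redrawn)


def fit_final_model(
    y: np.ndarray,
    X: np.ndarray,
    lom: pd.DataFrame,
    included: list[str],
    fdr_q: float = 0.20,
) -> FinalModelReport:
    """Joint Model 2 fit of the RMIP-included markers.

    Effects and p-values come from the model including all listed loci;
    BH-adjusted p-values across those markers confirm the FDR level of
    the reported model.
    """
    if not included:
        return FinalModelReport(
            pd.DataFrame(
                columns=["marker", "a", "se", "p", "bh_adjusted_p"]
            ),
            np.nan,
            0,
            fdr_q,
        )
    sub = lom[included]
    fit = _fit_model2(y, X, sub.to_numpy(dtype=float), included)
    if fit is None:
        raise ValueError("final model inestimable on the included markers")
    _, bh_p, _, _ = multipletests(fit.p_values, alpha=fdr_q, method="fdr_bh")
    table = pd.DataFrame(
        {
            "marker": included,
            "a": fit.effects,
            "se": fit.se,
            "p": fit.p_values,
            "bh_adjusted_p": bh_p,
        }
    )
    return FinalModelReport(table, fit.intercept, fit.n_used, fdr_q)


def design_for(
    pheno: PhenotypeTable,
) -> tuple[np.ndarray, np.ndarray, list[str], np.ndarray]:
    """(y, X, ids, generation labels) for the phenotyped individuals."""
    y, X, ids = build_design(pheno)
    gen = (
        pheno.phenotyped().set_index("id").loc[ids, "generation"].to_numpy()
    )
    return y, X, ids, gen
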