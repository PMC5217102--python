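"""Single-marker association and forward selection.

Model 1 regresses 56-day body weight on a focal marker dosage with sex
(2 levels) and generation (7 levels, F2-F8) as categorical covariates:

    y = mu + beta_sex,generation X + beta_genotype z + e,   e ~ N(0, s2)

The reference cell is an F2 female, so the intercept estimates the F2
female mean.  The per-marker test is the OLS Wald t-test of
beta_genotype = 0 — with ~1348 phenotyped individuals and a quantitative
trait this is asymptotically equivalent to the score test used in
GWAS toolkits, and exactly reproducible.

Forward selection scans all markers of a QTL region, adds the most
significant marker (nominal p < 0.05) as a covariate, and repeats until
no marker remains significant; candidates with minor-allele frequency
<= 0.10 among phenotyped individuals are then dropped before the
multi-locus stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ailfm.io_formats import GenotypeMatrix, MarkerMap, PhenotypeTable

_RANK_TOL = 1e-8


class DesignError(ValueError):
    """Rank-deficient covariate design."""


@dataclass(frozen=True)
class AssociationResult:
    """Per-marker Model 1 fit: effect in grams per reference-allele copy."""

    marker_id: str
    beta: float
    se: float
    p_value: float
    n_used: int
    testable: bool = True
    note: str = ""

    @classmethod
    def untestable(cls, marker_id: str, n: int, note: str) -> "AssociationResult":
        return cls(marker_id, np.nan, np.nan, np.nan, n, False, note)


@dataclass
class CandidateSet:
    """Forward-selection output: markers in selection order."""

    region: str
    marker_ids: list[str] = field(default_factory=list)
    p_at_selection: list[float] = field(default_factory=list)
    maf: list[float] = field(default_factory=list)
    dropped_low_maf: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.marker_ids)


def build_design(pheno: PhenotypeTable) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Response vector and covariate matrix for phenotyped individuals.

    Returns (y, X, ids) where X holds an intercept plus treatment-coded
    sex and generation indicators with F2 female as the reference cell.
    """
    tab = pheno.phenotyped()
    y = tab["bw56"].to_numpy(dtype=float)
    cols = [np.ones(len(tab))]
    cols.append((tab["sex"] == "M").to_numpy(dtype=float))
    gens = [g for g in ("F3", "F4", "F5", "F6", "F7", "F8")
            if (tab["generation"] == g).any()]
    for g in gens:
        cols.append((tab["generation"] == g).to_numpy(dtype=float))
    X = np.column_stack(cols)
    r = np.linalg.matrix_rank(X)
    if r < X.shape[1]:
        names = ["intercept", "sex[M]"] + [f"generation[{g}]" for g in gens]
        raise DesignError(f"collinear covariate design among {names}")
    return y, X, tab["id"].tolist()


def _wald_last_column(
    X: np.ndarray, z: np.ndarray, y: np.ndarray
) -> tuple[float, float, float]:
    """OLS effect, SE and two-sided p for z after adjusting for X.

    Frisch-Waugh-Lovell: residualize z and y on X, then the slope of the
    simple regression of the residuals equals the multiple-regression
    coefficient of z.  Exact, not approximate.
    """
    Q, _ = np.linalg.qr(X)
    z_r = z - Q @ (Q.T @ z)
    y_r = y - Q @ (Q.T @ y)
    szz = float(z_r @ z_r)
    if szz <= _RANK_TOL * len(z):
        return np.nan, np.nan, np.nan
    beta = float(z_r @ y_r) / szz
    df = len(y) - X.shape[1] - 1
    if df <= 0:
        return np.nan, np.nan, np.nan
    rss = float(y_r @ y_r) - beta * float(z_r @ y_r)
    sigma2 = max(rss, 0.0) / df
    se = float(np.sqrt(sigma2 / szz))
    if se == 0.0:
        return beta, 0.0, 0.0
    t = beta / se
    p = 2.0 * stats.t.sf(abs(t), df)
    # a p-value of exactly zero would break downstream FDR bookkeeping
    return beta, se, max(float(p), np.finfo(float).tiny)


def fit_model1(
    pheno: PhenotypeTable,
    geno: GenotypeMatrix,
    marker_id: str,
    conditioning: list[str] | None = None,
) -> AssociationResult:
    """Fit Model 1 for one focal marker.

    Complete-case on (y, z, conditioning dosages).  Monomorphic or
    collinear focal markers return a structured untestable result.
    """
    conditioning = list(conditioning or [])
    y, X, ids = build_design(pheno)
    z = geno.dosages.reindex(index=ids)[marker_id].to_numpy(dtype=float)
    cond = (
        geno.dosages.reindex(index=ids)[conditioning].to_numpy(dtype=float)
        if conditioning
        else np.empty((len(ids), 0))
    )
    mask = ~np.isnan(z) & ~np.isnan(cond).any(axis=1) & ~np.isnan(y)
    n = int(mask.sum())
    if n == 0 or len(np.unique(z[mask])) < 2:
        return AssociationResult.untestable(marker_id, n, "monomorphic")
    Xc = np.column_stack([X[mask], cond[mask]])
    if np.linalg.matrix_rank(Xc) < Xc.shape[1]:
        bad = [m for m in conditioning
               if np.linalg.matrix_rank(
                   np.column_stack([X[mask],
                                    geno.dosages.reindex(index=ids)[m]
                                    .to_numpy(dtype=float)[mask]])
               ) < X.shape[1] + 1]
        raise DesignError(
            f"conditioning markers collinear with covariates: {bad or conditioning}"
        )
    beta, se, p = _wald_last_column(Xc, z[mask], y[mask])
    if np.isnan(beta):
        return AssociationResult.untestable(
            marker_id, n, "collinear with conditioning set"
        )
    return AssociationResult(marker_id, beta, se, p, n)


def scan_region(
    pheno: PhenotypeTable,
    geno: GenotypeMatrix,
    mmap: MarkerMap,
    region: str,
    conditioning: list[str] | None = None,
) -> pd.DataFrame:
    """Model 1 for every marker of a region, in map order.

    Untestable markers (monomorphic, or members of the conditioning set)
    are carried through with ``testable=False``.
    """
    conditioning = list(conditioning or [])
    marker_ids = mmap.region_marker_ids(region)
    y, X, ids = build_design(pheno)
    dos = geno.dosages.reindex(index=ids)
    cond = (
        dos[conditioning].to_numpy(dtype=float)
        if conditioning
        else np.empty((len(ids), 0))
    )
    base_mask = ~np.isnan(y) & ~np.isnan(cond).any(axis=1)
    Xc_full = np.column_stack([X[base_mask], cond[base_mask]])
    rows = []
    cache: dict[bytes, np.ndarray] = {}
    pos = mmap.table.set_index("marker")["pos_bp"]
    for mid in marker_ids:
        z = dos[mid].to_numpy(dtype=float)
        if mid in conditioning:
            rows.append(
                AssociationResult.untestable(mid, 0, "in conditioning set")
            )
            continue
        mask = base_mask & ~np.isnan(z)
        n = int(mask.sum())
        if n == 0 or len(np.unique(z[mask])) < 2:
            rows.append(AssociationResult.untestable(mid, n, "monomorphic"))
            continue
        if (mask == base_mask).all():
            Xc = Xc_full
        else:
            key = mask.tobytes()
            Xc = cache.setdefault(
                key, np.column_stack([X[mask], cond[mask]])
            )
        beta, se, p = _wald_last_column(Xc, z[mask], y[mask])
        if np.isnan(beta):
            rows.append(
                AssociationResult.untestable(mid, n, "collinear")
            )
        else:
            rows.append(AssociationResult(mid, beta, se, p, n))
    out = pd.DataFrame(
        {
            "marker": [r.marker_id for r in rows],
            "pos_bp": [int(pos[r.marker_id]) for r in rows],
            "beta": [r.beta for r in rows],
            "se": [r.se for r in rows],
            "p": [r.p_value for r in rows],
            "n": [r.n_used for r in rows],
            "testable": [r.testable for r in rows],
        }
    )
    return out


def allele_frequency(dosages: np.ndarray) -> float:
    """Frequency of the reference (counted) allele: sum(d) / (2 n)."""
    d = np.asarray(dosages, dtype=float)
    d = d[~np.isnan(d)]
    if len(d) == 0:
        raise ValueError("no non-missing dosage calls")
    return float(d.sum() / (2.0 * len(d)))


def minor_allele_frequency(dosages: np.ndarray) -> float:
    p = allele_frequency(dosages)
    return min(p, 1.0 - p)


def forward_select(
    pheno: PhenotypeTable,
    geno: GenotypeMatrix,
    mmap: MarkerMap,
    region: str,
    alpha: float = 0.05,
    maf_threshold: float = 0.10,
    min_call_rate: float = 0.0,
) -> CandidateSet:
    """Iterative conditional scan of one region.

    Each round adds the minimum-p marker if p < alpha (ties broken by
    smallest genomic coordinate), conditioning subsequent scans on all
    selected markers; the MAF filter (computed among phenotyped
    individuals) is applied after the selection pass completes.

    ``min_call_rate`` keeps sparsely called markers (an artefact of
    conservative imputation) from being selected: they are still
    scanned, but a selected marker becomes a conditioning covariate and
    a sparse one would shrink every later round's complete-case sample.
    """
    selected: list[str] = []
    pvals: list[float] = []
    region_ids = mmap.region_marker_ids(region)
    n_region = len(region_ids)
    _, _, pheno_ids = build_design(pheno)
    callable_ids = set(region_ids)
    if min_call_rate > 0:
        cr = geno.dosages.reindex(index=pheno_ids, columns=region_ids).notna().mean()
        callable_ids = set(cr[cr >= min_call_rate].index)
    while len(selected) < n_region:
        scan = scan_region(pheno, geno, mmap, region, conditioning=selected)
        ok = scan[scan["testable"] & scan["p"].notna()
                  & scan["marker"].isin(callable_ids)]
        if ok.empty:
            break
        best_p = ok["p"].min()
        if not best_p < alpha:
            break
        best = ok[ok["p"] == best_p].sort_values("pos_bp").iloc[0]
        selected.append(str(best["marker"]))
        pvals.append(float(best_p))

    _, _, ids = build_design(pheno)
    dos = geno.dosages.reindex(index=ids)
    out = CandidateSet(region)
    for mid, p in zip(selected, pvals):
        maf = minor_allele_frequency(dos[mid].to_numpy(dtype=float))
        if maf > maf_threshold:
            out.marker_ids.append(mid)
            out.p_at_selection.append(p)
            out.maf.append(maf)
        else:
            out.dropped_low_maf.append(mid)
    return out
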