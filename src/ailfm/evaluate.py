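"""Truth-comparison metrics for simulated datasets.

These helpers compare phasing, painting and imputation output against
the simulator's ground-truth haplotypes.  Founder haplotype orientation
is arbitrary per chromosome (there is no paternal/maternal labelling for
founders), so founder phase and hap-level painting are scored under the
better of the two orientations per individual and chromosome;
non-founders are scored against the true paternal/maternal order
directly.
"""

from __future__ import annotations

import numpy as np

from ailfm.imputation import (
    ImputedGenotypes,
    PhasedBackbone,
    SegmentPainting,
    _chrom_slices,
)
from ailfm.io_formats import GenotypeMatrix, PedigreeTable
from ailfm.synthetic_data import TrueHaplotypes


def _truth_backbone(
    truth: TrueHaplotypes, marker_ids: list[str]
) -> np.ndarray:
    cols = [truth.marker_ids.index(m) for m in marker_ids]
    return truth.alleles[:, :, cols].astype(float)


def backbone_phase_accuracy(
    phased: PhasedBackbone, truth: TrueHaplotypes, ped: PedigreeTable
) -> dict[str, float]:
    """Site-level phasing quality against simulator truth.

    Returns the fraction of genotype sites resolved, the accuracy among
    resolved sites, and their product — the fraction of all backbone
    sites that are both resolved and correctly phased.
    """
    T = _truth_backbone(truth, phased.marker_ids)
    T = T[[truth.ids.index(i) for i in phased.ids]]
    H = phased.alleles
    founders = set(ped.founder_ids)
    slices = _chrom_slices(phased.chroms)
    n_sites = n_resolved = n_correct = 0
    for i, iid in enumerate(phased.ids):
        res = ~np.isnan(H[i]).any(axis=0)
        n_sites += H.shape[2]
        n_resolved += int(res.sum())
        for sl in slices:
            r = res[sl]
            if not r.any():
                continue
            direct = int(
                ((H[i, 0, sl][r] == T[i, 0, sl][r])
                 & (H[i, 1, sl][r] == T[i, 1, sl][r])).sum()
            )
            if iid in founders:
                flipped = int(
                    ((H[i, 0, sl][r] == T[i, 1, sl][r])
                     & (H[i, 1, sl][r] == T[i, 0, sl][r])).sum()
                )
                n_correct += max(direct, flipped)
            else:
                n_correct += direct
    return {
        "resolved_rate": n_resolved / n_sites,
        "accuracy_resolved": n_correct / n_resolved if n_resolved else np.nan,
        "accuracy_overall": n_correct / n_sites,
    }


def painting_accuracy(
    painting: SegmentPainting, truth: TrueHaplotypes, ped: PedigreeTable
) -> dict[str, float]:
    """Founder-of-origin agreement with truth outside uncertainty gaps.

    Agreement is scored at the founder-individual level (``origin // 2``)
    because the phased orientation of a founder's two haplotypes is
    arbitrary; per-position founder identity is what dense imputation
    consumes together with the matching phased founder panel.
    """
    cols = [truth.marker_ids.index(m) for m in painting.marker_ids]
    order = [truth.ids.index(i) for i in painting.ids]
    t_origin = truth.origin[np.ix_(order, [0, 1], cols)]
    p_origin = painting.origin
    covered = p_origin >= 0
    agree = covered & (p_origin // 2 == t_origin // 2)
    return {
        "coverage": float(covered.mean()),
        "agreement_outside_gaps": float(agree.sum() / covered.sum())
        if covered.any()
        else np.nan,
    }


def imputation_metrics(
    imputed: ImputedGenotypes,
    truth: TrueHaplotypes,
    observed: GenotypeMatrix,
) -> dict[str, float]:
    """Error rate of resolved imputed dosages, call rate, and a check
    that observed calls were passed through unaltered."""
    truth_dos = truth.dosages().reindex(
        index=imputed.genotypes.individual_ids,
        columns=imputed.genotypes.marker_ids,
    )
    out = imputed.genotypes.dosages
    prov = imputed.provenance
    obs = observed.dosages.reindex(index=out.index, columns=out.columns)

    obs_mask = obs.notna().to_numpy()
    preserved = bool(
        (out.to_numpy()[obs_mask] == obs.to_numpy()[obs_mask]).all()
    )
    imp_mask = (prov == ImputedGenotypes.IMPUTED).to_numpy()
    n_imputed = int(imp_mask.sum())
    errors = (
        int((out.to_numpy()[imp_mask] != truth_dos.to_numpy()[imp_mask]).sum())
        if n_imputed
        else 0
    )
    missing_before = (~obs_mask).sum()
    return {
        "observed_preserved": preserved,
        "n_imputed": n_imputed,
        "imputed_error_rate": errors / n_imputed if n_imputed else np.nan,
        "call_rate_missing": n_imputed / missing_before
        if missing_before
        else np.nan,
    }
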