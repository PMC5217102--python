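"""Pedigree-based phasing of the sparse backbone and dense-marker imputation.

The published analysis used pedigree-aware phasing/imputation software
whose internal algorithm is not documented; this module provides its own
deterministic Mendelian/IBD method with conservative missingness:

1. ``phase_backbone`` — homozygotes self-phase; heterozygotes resolve by
   Mendelian constraints against parent genotypes, then by linkage
   (copying from the transmitting parent's haplotype inside inferred IBD
   segments), iterated to a fixed point.  Founders are phased from the
   alleles they transmit to their offspring.
2. ``paint_founder_segments`` — each non-founder haplotype is matched
   against the transmitting parent's two haplotypes over runs of
   informative backbone sites; runs compose recursively down the
   pedigree into founder-haplotype labels.  Crossovers are localized to
   the interval between flanking informative sites, which becomes an
   uncertainty gap.
3. ``impute_dense`` — dense markers inside painted intervals copy the
   allele of the labelled founder haplotype; markers in gaps, painted to
   founders without dense genotypes, or sitting on an arbitrarily phased
   founder heterozygote are left missing rather than guessed.

Observed genotypes are never altered, and anything unresolved degrades
to missing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ailfm.io_formats import GenotypeMatrix, MarkerMap, PedigreeTable


class MendelianError(ValueError):
    """Offspring genotype impossible given its parents' genotypes."""


@dataclass
class PhasedBackbone:
    """Phased backbone haplotypes.

    ``alleles[i, h, j]`` is 0/1 or NaN (unresolved).  For non-founders
    h = 0 is the paternal, h = 1 the maternal haplotype; founder
    orientation is arbitrary per chromosome.  A site is resolved when
    both haplotype alleles are known.
    """

    ids: list[str]
    marker_ids: list[str]
    chroms: np.ndarray
    alleles: np.ndarray  # (n, 2, mb) float

    @property
    def resolved(self) -> np.ndarray:
        return ~np.isnan(self.alleles).any(axis=1)

    def index_of(self, individual_id: str) -> int:
        return self.ids.index(individual_id)


@dataclass
class SegmentPainting:
    """Founder-of-origin labels per backbone position.

    ``origin[i, h, j]`` holds the founder haplotype id
    (2 * founder_index + founder_hap) or -1 for an uncertainty gap.
    """

    ids: list[str]
    marker_ids: list[str]
    chroms: np.ndarray
    origin: np.ndarray  # (n, 2, mb) int32
    founder_ids: list[str]

    def intervals(
        self, individual_id: str, hap: int
    ) -> list[tuple[int, int, int]]:
        """Half-open (start, end, founder_hap_id) runs, gaps omitted."""
        row = self.origin[self.ids.index(individual_id), hap]
        out = []
        start = 0
        for j in range(1, len(row) + 1):
            if j == len(row) or row[j] != row[start] or (
                self.chroms[j] != self.chroms[start] if j < len(row) else False
            ):
                if row[start] >= 0:
                    out.append((start, j, int(row[start])))
                start = j
        return out


@dataclass
class FounderDenseHaplotypes:
    """Phased dense haplotypes for the dense-genotyped founders.

    ``uncertain[f, j]`` marks heterozygous sites whose phase was
    randomized (under a recorded seed) rather than resolved.
    """

    founder_ids: list[str]
    marker_ids: list[str]
    alleles: np.ndarray    # (nf, 2, md) float
    uncertain: np.ndarray  # (nf, md) bool
    seed: int | None = None


@dataclass
class ImputedGenotypes:
    """All-marker genotype matrix with per-call provenance.

    Provenance codes: 0 observed, 1 imputed, 2 unresolved-missing.
    """

    genotypes: GenotypeMatrix
    provenance: pd.DataFrame

    OBSERVED, IMPUTED, UNRESOLVED = 0, 1, 2


# ---------------------------------------------------------------------------
# shared helpers
# ---------------------------------------------------------------------------


def _chrom_slices(chroms: np.ndarray) -> list[slice]:
    slices = []
    start = 0
    for j in range(1, len(chroms) + 1):
        if j == len(chroms) or chroms[j] != chroms[start]:
            slices.append(slice(start, j))
            start = j
    return slices


def _interpolate_runs(info_idx: np.ndarray, info_val: np.ndarray, m: int) -> np.ndarray:
    """Fill positions between informative sites.

    A position takes the shared value of its flanking informative sites;
    positions whose flanks disagree (a crossover lies between them) stay
    -1.  Ends extend outward from the first/last informative site.
    """
    out = np.full(m, -1, dtype=np.int8)
    if len(info_idx) == 0:
        return out
    pos = np.arange(m)
    ri = np.searchsorted(info_idx, pos, side="left")
    li = ri - 1
    lv = np.where(li >= 0, info_val[np.clip(li, 0, None)], -9)
    rv = np.where(ri < len(info_idx), info_val[np.clip(ri, None, len(info_idx) - 1)], -9)
    lv = np.where(lv == -9, rv, lv)
    rv = np.where(rv == -9, lv, rv)
    out[:] = np.where(lv == rv, lv, -1)
    return out


def _match_gamete(
    child_hap: np.ndarray, parent_haps: np.ndarray, slices: list[slice]
) -> np.ndarray:
    """Assign each position of a transmitted gamete to a parent haplotype.

    Informative sites are those where both parent haplotypes are known
    and differ and the child's gamete allele is known.  An informative
    site that disagrees with both its informative neighbours is treated
    as a phase error rather than a double crossover and is ignored.
    Returns 0/1 assignments with -1 uncertainty gaps, per chromosome.
    """
    m = len(child_hap)
    assign = np.full(m, -1, dtype=np.int8)
    p0, p1 = parent_haps[0], parent_haps[1]
    informative = (
        ~np.isnan(p0) & ~np.isnan(p1) & (p0 != p1) & ~np.isnan(child_hap)
    )
    choice = (child_hap == p1).astype(np.int8)
    for sl in slices:
        idx = np.flatnonzero(informative[sl])
        val = choice[sl][idx]
        singletons = np.empty(0, dtype=np.int64)
        if len(idx) >= 2:
            agree_prev = np.concatenate(([False], val[1:] == val[:-1]))
            agree_next = np.concatenate((val[:-1] == val[1:], [False]))
            keep = agree_prev | agree_next
            if keep.any():
                singletons = idx[~keep]
                idx, val = idx[keep], val[keep]
        block = _interpolate_runs(idx, val, sl.stop - sl.start)
        # a site disagreeing with both neighbours is either a phase error
        # or a very short true segment; neither supports painting it
        block[singletons] = -1
        # extension past the outermost informative sites is unchecked by a
        # flanking site; require a terminal run of >= 2 agreeing sites
        if len(idx) >= 2:
            if val[0] != val[1]:
                block[: idx[0]] = -1
            if val[-1] != val[-2]:
                block[idx[-1] + 1:] = -1
        assign[sl] = block
    return assign


def check_mendelian(
    child: np.ndarray, sire: np.ndarray, dam: np.ndarray
) -> np.ndarray:
    """Boolean mask of markers where the trio is inconsistent."""
    def lo_hi(d):
        lo = np.where(np.isnan(d), 0.0, np.where(d == 2.0, 1.0, 0.0))
        hi = np.where(np.isnan(d), 1.0, np.where(d == 0.0, 0.0, 1.0))
        return lo, hi

    s_lo, s_hi = lo_hi(sire)
    d_lo, d_hi = lo_hi(dam)
    lo, hi = s_lo + d_lo, s_hi + d_hi
    return ~np.isnan(child) & ((child < lo) | (child > hi))


# ---------------------------------------------------------------------------
# backbone phasing
# ---------------------------------------------------------------------------


def phase_backbone(
    geno: GenotypeMatrix,
    ped: PedigreeTable,
    mmap: MarkerMap,
    mode: str = "error",
    n_rounds: int = 3,
) -> PhasedBackbone:
    """Deterministic rule-based phasing of the backbone markers.

    ``mode='error'`` raises on a Mendelian violation (simulation mode);
    ``mode='mask'`` sets the violating child call missing and continues
    (real data contain genotyping errors).
    """
    if mode not in ("error", "mask"):
        raise ValueError(f"unknown mode {mode!r}")
    backbone = mmap.table.loc[
        mmap.table["source"].isin(["backbone", "both"]), ["marker", "chrom"]
    ]
    marker_ids = backbone["marker"].tolist()
    chroms = backbone["chrom"].to_numpy()
    slices = _chrom_slices(chroms)
    ids = ped.ids
    index = {iid: k for k, iid in enumerate(ids)}
    D = (
        geno.dosages.reindex(index=ids, columns=marker_ids)
        .to_numpy(dtype=float)
        .copy()
    )
    n, mb = D.shape
    H = np.full((n, 2, mb), np.nan)

    parent_rows = np.full((n, 2), -1, dtype=np.int64)
    for row in ped.table.itertuples():
        if row.generation != "F0":
            i = index[row.id]
            parent_rows[i, 0] = index[str(row.sire)]
            parent_rows[i, 1] = index[str(row.dam)]
    non_founders = np.flatnonzero(parent_rows[:, 0] >= 0)

    # Mendelian screen
    for i in non_founders:
        s, d = parent_rows[i]
        viol = check_mendelian(D[i], D[s], D[d])
        if viol.any():
            if mode == "error":
                j = int(np.flatnonzero(viol)[0])
                raise MendelianError(
                    f"Mendelian violation at marker {marker_ids[j]}: "
                    f"child {ids[i]} (dosage {D[i, j]:.0f}) with sire "
                    f"{ids[s]} ({D[s, j]:.0f}) and dam {ids[d]} ({D[d, j]:.0f})"
                )
            D[i, viol] = np.nan

    # homozygotes self-phase
    hom = np.isin(D, (0.0, 2.0))
    hom_val = np.where(hom, D / 2.0, np.nan)
    H[:, 0, :] = hom_val
    H[:, 1, :] = hom_val

    # trio rules for heterozygotes: a homozygous parent pins one gamete
    for i in non_founders:
        het = D[i] == 1.0
        if not het.any():
            continue
        s, d = parent_rows[i]
        for h, p in ((0, s), (1, d)):
            forced = het & np.isin(D[p], (0.0, 2.0)) & np.isnan(H[i, h])
            H[i, h, forced] = D[p, forced] / 2.0
            H[i, 1 - h, forced] = 1.0 - H[i, h, forced]

    # children grouped by transmitting parent, for founder/parent phasing
    children_of: dict[int, list[tuple[int, int]]] = {}
    for i in non_founders:
        for h in (0, 1):
            children_of.setdefault(parent_rows[i, h], []).append((int(i), h))

    gen_rank = {
        iid: int(g[1:])
        for iid, g in zip(ped.table["id"], ped.table["generation"])
    }
    nf_sorted = sorted(non_founders, key=lambda i: gen_rank[ids[i]])

    for _ in range(n_rounds):
        # phase parents (founders first, then any het parent) from the
        # alleles they demonstrably transmitted
        for p in sorted(children_of, key=lambda i: gen_rank[ids[i]]):
            _phase_by_transmission(H, D, int(p), children_of[p], slices)
        # linkage fill: copy unresolved heterozygote alleles from the
        # transmitting parent's haplotype inside matched IBD runs
        for i in nf_sorted:
            unres = (D[i] == 1.0) & np.isnan(H[i, 0])
            if not unres.any():
                continue
            for h in (0, 1):
                p = parent_rows[i, h]
                assign = _match_gamete(H[i, h], H[p], slices)
                todo = unres & (assign >= 0)
                src = H[p, assign[todo], np.flatnonzero(todo)] if todo.any() else None
                if src is None:
                    continue
                known = ~np.isnan(src)
                sites = np.flatnonzero(todo)[known]
                H[i, h, sites] = src[known]
                H[i, 1 - h, sites] = 1.0 - src[known]
                unres = (D[i] == 1.0) & np.isnan(H[i, 0])

    return PhasedBackbone(list(ids), marker_ids, chroms, H)


def _phase_by_transmission(
    H: np.ndarray,
    D: np.ndarray,
    p: int,
    gametes: list[tuple[int, int]],
    slices: list[slice],
) -> None:
    """Phase parent ``p``'s heterozygous sites from transmitted alleles.

    Greedy left-to-right pass per chromosome: each transmitted gamete is
    tracked as currently copying parent haplotype 0 or 1; at each
    heterozygous site the known transmitted alleles vote on the phase,
    dissenting gametes (recombinations) are reassigned, and ties leave
    the site unresolved.
    """
    het_all = np.flatnonzero((D[p] == 1.0) & np.isnan(H[p, 0]))
    if len(het_all) == 0:
        return
    if not gametes:
        return
    T = np.stack([H[c, h] for c, h in gametes])
    for sl in slices:
        hets = het_all[(het_all >= sl.start) & (het_all < sl.stop)]
        if len(hets) == 0:
            continue
        # already-phased het sites anchor gamete assignments on re-entry
        phased_hets = np.flatnonzero(
            (D[p] == 1.0) & ~np.isnan(H[p, 0])
        )
        phased_hets = phased_hets[
            (phased_hets >= sl.start) & (phased_hets < sl.stop)
        ]
        sites = np.union1d(hets, phased_hets)
        # an arbitrary orientation may only be seeded when nothing in this
        # chromosome block is phased yet; otherwise orientation must flow
        # from existing anchors (alternating sweep directions reach sites
        # on either side of the first anchor)
        may_seed = len(phased_hets) == 0
        for sweep in range(4):
            ordered = sites if sweep % 2 == 0 else sites[::-1]
            assign = np.full(len(gametes), -1, dtype=np.int8)
            progress = False
            for s in ordered:
                known = np.flatnonzero(~np.isnan(T[:, s]))
                if len(known) == 0:
                    continue
                if np.isnan(H[p, 0, s]):
                    voters = known[assign[known] >= 0]
                    if len(voters):
                        # vote for "haplotype 0 carries allele 1"
                        votes = np.where(
                            assign[voters] == 0,
                            T[voters, s],
                            1.0 - T[voters, s],
                        )
                        score = votes.sum() - len(votes) / 2.0
                        if score == 0:
                            continue  # tie: leave unresolved
                        phi = 1.0 if score > 0 else 0.0
                    elif may_seed:
                        # orientation anchor: defines which haplotype is "0"
                        phi = T[known[0], s]
                        may_seed = False
                    else:
                        continue  # defer until orientation reaches this site
                    H[p, 0, s] = phi
                    H[p, 1, s] = 1.0 - phi
                    progress = True
                else:
                    phi = H[p, 0, s]
                assign[known] = np.where(T[known, s] == phi, 0, 1)
            if not progress and sweep > 0:
                break


# ---------------------------------------------------------------------------
# segment painting
# ---------------------------------------------------------------------------


def paint_founder_segments(
    phased: PhasedBackbone, ped: PedigreeTable, mmap: MarkerMap
) -> SegmentPainting:
    """Label every haplotype position with its founder haplotype of origin.

    Recursive descent from the founders: a child gamete is matched to the
    transmitting parent's haplotypes over informative backbone runs, and
    the parent's own founder labels compose through the match.  Unmatched
    runs and positions whose parent label is itself a gap stay gaps.
    """
    ids = phased.ids
    index = {iid: k for k, iid in enumerate(ids)}
    slices = _chrom_slices(phased.chroms)
    n, _, mb = phased.alleles.shape
    origin = np.full((n, 2, mb), -1, dtype=np.int32)
    founder_ids = ped.founder_ids
    f0_index = {iid: k for k, iid in enumerate(founder_ids)}

    order = sorted(
        ped.table.itertuples(), key=lambda r: int(r.generation[1:])
    )
    for row in order:
        i = index[row.id]
        if row.generation == "F0":
            k = f0_index[row.id]
            origin[i, 0, :] = 2 * k
            origin[i, 1, :] = 2 * k + 1
            continue
        for h, parent in enumerate((row.sire, row.dam)):
            p = index[str(parent)]
            assign = _match_gamete(
                phased.alleles[i, h], phased.alleles[p], slices
            )
            ok = assign >= 0
            src = origin[p, assign[ok], np.flatnonzero(ok)]
            dest = np.flatnonzero(ok)
            origin[i, h, dest] = src
            # autozygous parent stretches carry no informative sites, but
            # when both parental haplotypes share one founder label the
            # transmitted label is that label regardless of the match
            amb = (assign < 0) & (origin[p, 0] == origin[p, 1]) & (
                origin[p, 0] >= 0
            )
            origin[i, h, amb] = origin[p, 0, amb]
    return SegmentPainting(
        list(ids), list(phased.marker_ids), phased.chroms, origin, founder_ids
    )


# ---------------------------------------------------------------------------
# founder dense phasing
# ---------------------------------------------------------------------------


def phase_founder_dense(
    founder_geno: GenotypeMatrix,
    ped: PedigreeTable,
    mmap: MarkerMap,
    painting: SegmentPainting,
    offspring_geno: GenotypeMatrix | None = None,
    seed: int = 0,
) -> FounderDenseHaplotypes:
    """Phase the dense-genotyped founders' heterozygous sites.

    Homozygotes phase trivially.  A heterozygote resolves when some
    offspring has an observed dense genotype at the marker that pins the
    transmitted allele, and the offspring's painting attributes that
    gamete to one of the founder's haplotypes (orienting the dense
    phase relative to the phased backbone).  Remaining heterozygotes are
    randomized under ``seed`` and flagged ``uncertain``; conservative
    downstream use drops them rather than trusting the coin flip.
    """
    dense = mmap.table[mmap.table["source"] == "dense"]
    dense_ids = dense["marker"].tolist()
    founders = founder_geno.individual_ids
    Df = founder_geno.dosages.reindex(columns=dense_ids).to_numpy(dtype=float)
    nf, md = Df.shape
    alleles = np.full((nf, 2, md), np.nan)
    hom = np.isin(Df, (0.0, 2.0))
    alleles[:, 0, :] = np.where(hom, Df / 2.0, np.nan)
    alleles[:, 1, :] = np.where(hom, Df / 2.0, np.nan)
    uncertain = np.zeros((nf, md), dtype=bool)

    dense_origin = _origin_at_dense(painting, mmap)
    f0_index = {iid: k for k, iid in enumerate(painting.founder_ids)}
    paint_row = {iid: k for k, iid in enumerate(painting.ids)}

    if offspring_geno is not None:
        parents = ped.parents_of()
        off_dos = offspring_geno.dosages.reindex(columns=dense_ids)
        for fi, fid in enumerate(founders):
            kids = [
                (o, 0 if parents[o][0] == fid else 1)
                for o in offspring_geno.individual_ids
                if fid in parents.get(o, ())
            ]
            if not kids:
                continue
            het_sites = np.flatnonzero(Df[fi] == 1.0)
            f0k = f0_index[fid]
            for o, h in kids:
                row = off_dos.loc[o].to_numpy(dtype=float)
                orig = dense_origin[paint_row[o], h]
                for j in het_sites:
                    if np.isnan(row[j]) or row[j] == 1.0:
                        continue
                    if orig[j] // 2 != f0k:
                        continue
                    fh = int(orig[j] % 2)
                    transmitted = row[j] / 2.0
                    if np.isnan(alleles[fi, fh, j]):
                        alleles[fi, fh, j] = transmitted
                        alleles[fi, 1 - fh, j] = 1.0 - transmitted
                    elif alleles[fi, fh, j] != transmitted:
                        uncertain[fi, j] = True  # conflicting evidence

    rng = np.random.default_rng(seed)
    for fi in range(nf):
        todo = np.flatnonzero((Df[fi] == 1.0) & np.isnan(alleles[fi, 0]))
        if len(todo):
            coin = rng.integers(0, 2, size=len(todo)).astype(float)
            alleles[fi, 0, todo] = coin
            alleles[fi, 1, todo] = 1.0 - coin
            uncertain[fi, todo] = True
    return FounderDenseHaplotypes(
        list(founders), dense_ids, alleles, uncertain, seed
    )


def _origin_at_dense(painting: SegmentPainting, mmap: MarkerMap) -> np.ndarray:
    """Founder-of-origin labels at dense-marker positions.

    A dense marker takes the label shared by its flanking backbone
    markers on the same chromosome; disagreeing flanks (a crossover may
    lie between them) yield a gap.
    """
    tab = mmap.table
    is_backbone = tab["source"].isin(["backbone", "both"]).to_numpy()
    dense_idx = np.flatnonzero(~is_backbone)
    backbone_idx = np.flatnonzero(is_backbone)
    chrom = tab["chrom"].to_numpy()
    n = painting.origin.shape[0]
    out = np.full((n, 2, len(dense_idx)), -1, dtype=np.int32)

    bpos_in_chrom: dict[str, np.ndarray] = {}
    for c in pd.unique(chrom):
        bpos_in_chrom[c] = backbone_idx[chrom[backbone_idx] == c]
    # backbone column position within painting arrays
    bb_col = {int(j): k for k, j in enumerate(backbone_idx)}

    for dj, j in enumerate(dense_idx):
        bb = bpos_in_chrom[chrom[j]]
        ri = np.searchsorted(bb, j)
        li = ri - 1
        left = bb_col[int(bb[li])] if li >= 0 else None
        right = bb_col[int(bb[ri])] if ri < len(bb) else None
        if left is None and right is None:
            continue
        if left is None:
            out[:, :, dj] = painting.origin[:, :, right]
        elif right is None:
            out[:, :, dj] = painting.origin[:, :, left]
        else:
            lo = painting.origin[:, :, left]
            ro = painting.origin[:, :, right]
            out[:, :, dj] = np.where((lo == ro), lo, -1)
    return out


# ---------------------------------------------------------------------------
# dense imputation
# ---------------------------------------------------------------------------


def impute_dense(
    painting: SegmentPainting,
    founder_dense: FounderDenseHaplotypes,
    mmap: MarkerMap,
    observed: GenotypeMatrix,
    include_uncertain_phase: bool = False,
) -> ImputedGenotypes:
    """Copy dense alleles from painted founder haplotypes.

    A homolog's allele resolves when its painting labels a founder that
    has dense genotypes and the founder's phase at the site is not an
    arbitrary coin flip (unless ``include_uncertain_phase``).  The dosage
    is the sum over the two homologs where both resolve, else missing.
    Observed calls are passed through untouched.
    """
    known_founders = set(painting.founder_ids)
    for fid in founder_dense.founder_ids:
        if fid not in known_founders:
            raise ValueError(f"painting references unknown founder {fid!r}")

    tab = mmap.table
    dense_cols = tab.loc[tab["source"] == "dense", "marker"].tolist()
    dense_origin = _origin_at_dense(painting, mmap)  # (n, 2, md)
    n, _, md = dense_origin.shape

    # founder hap id -> row in the dense founder panel (-1 when absent)
    f0_index = {iid: k for k, iid in enumerate(painting.founder_ids)}
    dense_row = np.full(len(painting.founder_ids), -1, dtype=np.int64)
    for k, fid in enumerate(founder_dense.founder_ids):
        dense_row[f0_index[fid]] = k

    hap_alleles = np.full((n, 2, md), np.nan)
    col_idx = np.broadcast_to(np.arange(md), (n, 2, md))
    valid = dense_origin >= 0
    frow = np.where(valid, dense_row[dense_origin // 2 * valid], -1)
    fhap = np.where(valid, dense_origin % 2, 0)
    usable = valid & (frow >= 0)
    src = founder_dense.alleles[
        frow[usable], fhap[usable], col_idx[usable]
    ]
    if not include_uncertain_phase:
        flip = founder_dense.uncertain[frow[usable], col_idx[usable]]
        src = np.where(flip, np.nan, src)
    hap_alleles[usable] = src

    dosage = hap_alleles.sum(axis=1)  # NaN propagates when a homolog is NaN

    imput = pd.DataFrame(
        dosage, index=pd.Index(painting.ids, name="id"), columns=dense_cols
    )
    full = observed.dosages.reindex(
        index=painting.ids, columns=tab["marker"].tolist()
    )
    prov = pd.DataFrame(
        ImputedGenotypes.UNRESOLVED,
        index=full.index,
        columns=full.columns,
        dtype=np.int8,
    )
    prov[full.notna()] = ImputedGenotypes.OBSERVED
    fill = imput.reindex(index=full.index)
    fill_mask = full[dense_cols].isna() & fill.notna()
    prov.loc[:, dense_cols] = prov[dense_cols].where(
        ~fill_mask, ImputedGenotypes.IMPUTED
    )
    out = full.copy()
    out.loc[:, dense_cols] = out[dense_cols].where(~fill_mask, fill)
    return ImputedGenotypes(
        GenotypeMatrix(out, observed.ref_alleles), prov
    )


# ---------------------------------------------------------------------------
# convenience: the full imputation stage
# ---------------------------------------------------------------------------


def impute_pipeline(
    observed: GenotypeMatrix,
    ped: PedigreeTable,
    mmap: MarkerMap,
    dense_founder_ids: list[str],
    seed: int = 0,
    mode: str = "error",
) -> tuple[ImputedGenotypes, PhasedBackbone, SegmentPainting]:
    """phase -> paint -> phase founder dense -> impute, in one call."""
    phased = phase_backbone(observed, ped, mmap, mode=mode)
    painting = paint_founder_segments(phased, ped, mmap)
    founder_geno = observed.subset(individuals=dense_founder_ids)
    founder_dense = phase_founder_dense(
        founder_geno, ped, mmap, painting, offspring_geno=None, seed=seed
    )
    imputed = impute_dense(painting, founder_dense, mmap, observed)
    return imputed, phased, painting
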