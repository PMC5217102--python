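"""Simulated advanced intercross line (AIL) datasets.

Generates populations with the statistical structure the fine-mapping
analysis assumes: two divergently selected founder lines with
line-specific allele frequencies, a nine-generation paired-mating
pedigree (F0-F8), recombination under the Haldane map function, an
additive phenotype model for 56-day body weight, and the two-tier
genotyping design (a sparse backbone genotyped in everyone, dense
markers genotyped in a founder subset only).

Divergence between the founder lines is imposed directly on founder
allele frequencies rather than by simulating the forty generations of
selection that preceded the intercross: the analysis only ever consumes
founder genotypes.  With probability ``f_fixed`` a marker is fixed for
alternative alleles across the lines (emulating completed selective
sweeps); otherwise each line's frequency is an independent Beta draw,
producing markers that still segregate within lines.

All randomness flows from a single master seed through named substreams
(founders, pedigree, meiosis, noise, masking), so identical
configurations reproduce bit-identical datasets and stages can be
re-run independently.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ailfm.io_formats import (
    GenotypeMatrix,
    MarkerMap,
    PedigreeTable,
    PhenotypeTable,
)
from ailfm import published

_SUBSTREAMS = ("founders", "pedigree", "meiosis", "noise", "masking")


@dataclass(frozen=True)
class RegionSpec:
    """One simulated QTL region: genome span and marker counts."""

    name: str
    chromosome: str
    start_bp: int
    end_bp: int
    n_backbone: int
    n_dense: int


def default_regions() -> tuple[RegionSpec, ...]:
    """The nine fine-mapped Virginia AIL regions at their real marker
    counts (281 backbone + 6607 dense markers overall)."""
    tab = published.qtl_region_table()
    return tuple(
        RegionSpec(
            r.region,
            r.chrom,
            int(r.start_bp),
            int(r.end_bp),
            int(r.n_backbone),
            int(r.n_dense),
        )
        for r in tab.itertuples()
    )


@dataclass
class SimulationConfig:
    """Study-design parameters for a simulated AIL.

    Defaults follow the Virginia body-weight AIL: 29 + 30 founders, nine
    generations totalling ~1536 birds with ~90 breeders (45 pairs) per
    generation, phenotypes in F2-F8 only, backbone markers genotyped in
    everyone and dense markers in 40 of the 59 founders.  Phenotypes (grams) follow
    ``mu + sex + generation + sum_k a_k (dosage_k - 1) + N(0, sigma_e^2)``
    with the intercept representing the F2 female mean.
    """

    seed: int = 0
    n_hws: int = 29
    n_lws: int = 30
    n_per_generation: int = 185
    n_breeding_pairs: int | None = 45
    n_generations: int = 9
    regions: tuple[RegionSpec, ...] = field(default_factory=default_regions)
    f_fixed: float = 0.2
    beta_shape: tuple[float, float] = (0.8, 0.8)
    qtl_spec: tuple[tuple[str, float], ...] = ()
    mu: float = 800.0
    sex_effect: float = 150.0
    generation_effects: tuple[float, ...] = (0, 0, 0, 0, 0, 0, -120.0)
    sigma_e: float = 80.0
    cm_per_mb: float = 3.0
    dense_founder_fraction: float = 40 / 59

    def __post_init__(self) -> None:
        for name in ("n_hws", "n_lws", "n_per_generation", "n_generations"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if len(self.generation_effects) != 7:
            raise ValueError(
                "generation_effects needs one value per phenotyped "
                "generation (F2-F8)"
            )
        if self.sigma_e <= 0:
            raise ValueError("sigma_e must be positive")
        if not self.regions:
            raise ValueError("at least one region is required")
        for reg in self.regions:
            if reg.n_backbone + reg.n_dense <= 0:
                raise ValueError(f"region {reg.name} has zero markers")
        for _, a in self.qtl_spec:
            if not np.isfinite(a):
                raise ValueError("QTL effects must be finite")

    def rng(self, stream: str) -> np.random.Generator:
        """Named substream of the master seed."""
        idx = _SUBSTREAMS.index(stream)
        ss = np.random.SeedSequence(self.seed, spawn_key=(idx,))
        return np.random.default_rng(ss)


@dataclass
class TrueHaplotypes:
    """Ground-truth phased haplotypes with founder-of-origin labels.

    ``alleles[i, h, j]`` is the reference-allele count (0/1) of haplotype
    h of individual i at marker j; for non-founders h = 0 is the paternal
    and h = 1 the maternal haplotype.  ``origin`` carries the founder
    haplotype id (2 * founder_index + h0) each position descends from.
    """

    ids: list[str]
    marker_ids: list[str]
    alleles: np.ndarray  # (n, 2, m) int8
    origin: np.ndarray   # (n, 2, m) int32
    founder_ids: list[str]

    def index_of(self, individual_id: str) -> int:
        return self.ids.index(individual_id)

    def dosages(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.alleles.sum(axis=1, dtype=np.int16),
            index=pd.Index(self.ids, name="id"),
            columns=self.marker_ids,
        )

    def founder_of_origin(self, founder_lines: dict[str, str]) -> np.ndarray:
        """Line label array (n, 2, m) mapping origins to HWS/LWS."""
        lines = np.array(
            [founder_lines[f] for f in self.founder_ids], dtype=object
        )
        return lines[self.origin // 2]


@dataclass
class SimulatedAIL:
    """Full bundle a simulation produces: map, pedigree, truth, data."""

    config: SimulationConfig
    marker_map: MarkerMap
    pedigree: PedigreeTable
    haplotypes: TrueHaplotypes
    phenotypes: PhenotypeTable
    observed: GenotypeMatrix
    dense_founder_ids: list[str]
    founder_freqs: pd.DataFrame  # marker, p_hws, p_lws of the ref allele
    qtl_effects: dict[str, float]


# ---------------------------------------------------------------------------
# founders
# ---------------------------------------------------------------------------


def build_marker_map(cfg: SimulationConfig) -> MarkerMap:
    """Evenly spaced backbone markers with dense markers interleaved."""
    rows = []
    bounds = {}
    for reg in cfg.regions:
        n_total = reg.n_backbone + reg.n_dense
        bounds[reg.name] = (reg.chromosome, reg.start_bp, reg.end_bp)
        positions = np.rint(
            np.linspace(reg.start_bp, reg.end_bp, n_total)
        ).astype(np.int64)
        if len(np.unique(positions)) < n_total:
            positions = np.arange(reg.start_bp, reg.start_bp + n_total)
        backbone_idx = set(
            np.rint(np.linspace(0, n_total - 1, reg.n_backbone)).astype(int)
        ) if reg.n_backbone else set()
        for k in range(n_total):
            rows.append(
                {
                    "marker": f"{reg.name}_m{k:05d}",
                    "chrom": reg.chromosome,
                    "pos_bp": int(positions[k]),
                    "region": reg.name,
                    "source": "backbone" if k in backbone_idx else "dense",
                }
            )
    return MarkerMap(pd.DataFrame(rows), bounds)


def draw_divergent_frequencies(
    cfg: SimulationConfig, n_markers: int, rng: np.random.Generator
) -> pd.DataFrame:
    """Per-marker reference-allele frequencies in the two founder lines."""
    fixed = rng.random(n_markers) < cfg.f_fixed
    which = rng.random(n_markers) < 0.5
    a, b = cfg.beta_shape
    p_hws = rng.beta(a, b, size=n_markers)
    p_lws = rng.beta(a, b, size=n_markers)
    p_hws[fixed] = np.where(which[fixed], 1.0, 0.0)
    p_lws[fixed] = np.where(which[fixed], 0.0, 1.0)
    return pd.DataFrame({"p_hws": p_hws, "p_lws": p_lws})


def simulate_founder_lines(
    cfg: SimulationConfig,
) -> tuple[MarkerMap, TrueHaplotypes, PedigreeTable, pd.DataFrame]:
    """Marker map, founder haplotypes and F0 pedigree.

    Founder haplotypes are drawn independently per line at the
    line-specific frequencies from the divergence model.
    """
    rng = cfg.rng("founders")
    mmap = build_marker_map(cfg)
    m = len(mmap)
    freqs = draw_divergent_frequencies(cfg, m, rng)
    freqs.insert(0, "marker", mmap.marker_ids)

    ids, sexes, lines = [], [], []
    for line, n in (("HWS", cfg.n_hws), ("LWS", cfg.n_lws)):
        for k in range(n):
            ids.append(f"{line}{k + 1:03d}")
            sexes.append("M" if k % 2 == 0 else "F")
            lines.append(line)
    ped = PedigreeTable(
        pd.DataFrame(
            {
                "id": ids,
                "sire": [None] * len(ids),
                "dam": [None] * len(ids),
                "sex": sexes,
                "generation": ["F0"] * len(ids),
                "line": lines,
            }
        )
    )
    n = len(ids)
    p = np.where(
        np.array(lines)[:, None] == "HWS",
        freqs["p_hws"].to_numpy()[None, :],
        freqs["p_lws"].to_numpy()[None, :],
    )
    alleles = (rng.random((n, 2, m)) < p[:, None, :]).astype(np.int8)
    origin = np.empty((n, 2, m), dtype=np.int32)
    for i in range(n):
        origin[i, 0, :] = 2 * i
        origin[i, 1, :] = 2 * i + 1
    haps = TrueHaplotypes(ids, mmap.marker_ids, alleles, origin, list(ids))
    return mmap, haps, ped, freqs


# ---------------------------------------------------------------------------
# pedigree
# ---------------------------------------------------------------------------


def _pair(
    males: list[str],
    females: list[str],
    parents: dict[str, tuple[str | None, str | None]],
    rng: np.random.Generator,
) -> list[tuple[str, str]]:
    """Monogamous random pairing avoiding full-sib matings."""
    if not males or not females:
        raise ValueError("too few individuals of one sex to pair")

    def full_sibs(a: str, b: str) -> bool:
        pa, pb = parents.get(a, (None, None)), parents.get(b, (None, None))
        return pa == pb and pa != (None, None)

    for _ in range(100):  # rejection sampling over shuffles
        ms = list(males)
        fs = list(females)
        rng.shuffle(ms)
        rng.shuffle(fs)
        pairs = []
        ok = True
        for sire in ms[: min(len(ms), len(fs))]:
            pick = next((f for f in fs if not full_sibs(sire, f)), None)
            if pick is None:
                ok = False
                break
            fs.remove(pick)
            pairs.append((sire, pick))
        if ok and pairs:
            return pairs
    # tiny cohorts (e.g. a two-bird chain) can leave only full-sib pairs;
    # pair anyway rather than dead-end the pedigree
    warnings.warn(
        "no sib-avoiding pairing exists; allowing full-sib pairs",
        stacklevel=2,
    )
    ms, fs = list(males), list(females)
    rng.shuffle(ms)
    rng.shuffle(fs)
    return list(zip(ms, fs))


def simulate_pedigree(cfg: SimulationConfig, f0: PedigreeTable) -> PedigreeTable:
    """Nine-generation paired-mating pedigree.

    F1 comes from reciprocal HWS x LWS pairings; later generations pair
    males and females of the previous generation at random (no full-sib
    pairs), each pair contributing an equal expected number of offspring.
    """
    rng = cfg.rng("pedigree")
    rows = f0.table.copy().to_dict("records")
    parents = f0.parents_of()
    f0_lines = f0.line_of()
    prev = f0.table

    for g in range(1, cfg.n_generations):
        gen = f"F{g}"
        if g == 1:
            hws_m = [r.id for r in prev.itertuples() if f0_lines.get(r.id) == "HWS" and r.sex == "M"]
            hws_f = [r.id for r in prev.itertuples() if f0_lines.get(r.id) == "HWS" and r.sex == "F"]
            lws_m = [r.id for r in prev.itertuples() if f0_lines.get(r.id) == "LWS" and r.sex == "M"]
            lws_f = [r.id for r in prev.itertuples() if f0_lines.get(r.id) == "LWS" and r.sex == "F"]
            pairs = _pair(hws_m, lws_f, parents, rng) + _pair(
                lws_m, hws_f, parents, rng
            )
        else:
            males = [r.id for r in prev.itertuples() if r.sex == "M"]
            females = [r.id for r in prev.itertuples() if r.sex == "F"]
            pairs = _pair(males, females, parents, rng)
            if cfg.n_breeding_pairs is not None:
                pairs = pairs[: cfg.n_breeding_pairs]
        counts = rng.multinomial(
            cfg.n_per_generation, np.full(len(pairs), 1.0 / len(pairs))
        )
        new_rows = []
        k = 0
        for (sire, dam), c in zip(pairs, counts):
            for _ in range(int(c)):
                k += 1
                cid = f"{gen}_{k:04d}"
                sex = "M" if rng.random() < 0.5 else "F"
                new_rows.append(
                    {
                        "id": cid,
                        "sire": sire,
                        "dam": dam,
                        "sex": sex,
                        "generation": gen,
                        "line": None,
                    }
                )
                parents[cid] = (sire, dam)
        # paired mating needs both sexes downstream; reroll the last sex if
        # a generation came out single-sexed (only possible at tiny sizes)
        if new_rows and len({r["sex"] for r in new_rows}) == 1:
            new_rows[-1]["sex"] = "F" if new_rows[-1]["sex"] == "M" else "M"
        rows.extend(new_rows)
        prev = pd.DataFrame(new_rows)
    return PedigreeTable(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# meiosis
# ---------------------------------------------------------------------------


def recombination_fractions(mmap: MarkerMap, cm_per_mb: float) -> np.ndarray:
    """Per-interval switch probabilities under the Haldane map function.

    Entry j is the probability that marker j derives from the opposite
    parental haplotype relative to marker j-1; the first marker of each
    chromosome gets 0.5 (independent restart).
    """
    tab = mmap.table
    chrom = tab["chrom"].to_numpy()
    pos = tab["pos_bp"].to_numpy(dtype=float)
    r = np.empty(len(tab))
    r[0] = 0.5
    d_cm = cm_per_mb * np.diff(pos) / 1e6
    r[1:] = 0.5 * (1.0 - np.exp(-2.0 * d_cm / 100.0))
    r[1:][chrom[1:] != chrom[:-1]] = 0.5
    return r


def _meiose(
    alleles: np.ndarray,
    origin: np.ndarray,
    rec: np.ndarray,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """One gamete: recombinant mosaic of a parent's two haplotypes."""
    switches = rng.random(len(rec)) < rec
    hap = np.cumsum(switches) % 2
    idx = np.arange(len(rec))
    return alleles[hap, idx], origin[hap, idx]


def gene_drop(
    ped: PedigreeTable,
    f0_haps: TrueHaplotypes,
    mmap: MarkerMap,
    cfg: SimulationConfig,
) -> TrueHaplotypes:
    """Drop founder haplotypes through the pedigree with recombination.

    Crossovers follow the Haldane model (no interference) at
    ``cfg.cm_per_mb`` on the physical map; founder-of-origin labels
    propagate through the recombinant mosaics.
    """
    if not mmap.is_ordered:
        raise ValueError("marker map must be ordered before gene dropping")
    rng = cfg.rng("meiosis")
    rec = recombination_fractions(mmap, cfg.cm_per_mb)
    ids = ped.ids
    n, m = len(ids), len(mmap)
    alleles = np.zeros((n, 2, m), dtype=np.int8)
    origin = np.zeros((n, 2, m), dtype=np.int32)
    index = {iid: k for k, iid in enumerate(ids)}
    f0_index = {iid: k for k, iid in enumerate(f0_haps.ids)}
    for row in ped.table.itertuples():
        i = index[row.id]
        if row.generation == "F0":
            k = f0_index[row.id]
            alleles[i] = f0_haps.alleles[k]
            origin[i] = f0_haps.origin[k]
        else:
            for h, parent in enumerate((row.sire, row.dam)):
                j = index[str(parent)]
                alleles[i, h], origin[i, h] = _meiose(
                    alleles[j], origin[j], rec, rng
                )
    return TrueHaplotypes(
        list(ids), mmap.marker_ids, alleles, origin, list(f0_haps.founder_ids)
    )


# ---------------------------------------------------------------------------
# phenotypes and observation model
# ---------------------------------------------------------------------------


def simulate_phenotypes(
    haps: TrueHaplotypes, ped: PedigreeTable, cfg: SimulationConfig
) -> PhenotypeTable:
    """Additive BW56 phenotypes (grams) for generations F2-F8."""
    rng = cfg.rng("noise")
    marker_pos = {mid: j for j, mid in enumerate(haps.marker_ids)}
    for mid, _ in cfg.qtl_spec:
        if mid not in marker_pos:
            raise ValueError(f"QTL marker {mid!r} not in the marker map")
    gen_effect = {
        f"F{i + 2}": e for i, e in enumerate(cfg.generation_effects)
    }
    index = {iid: k for k, iid in enumerate(haps.ids)}
    rows = []
    for row in ped.table.itertuples():
        if row.generation not in gen_effect:
            rows.append(
                {
                    "id": row.id,
                    "bw56": np.nan,
                    "sex": row.sex,
                    "generation": row.generation,
                }
            )
            continue
        i = index[row.id]
        y = cfg.mu
        y += cfg.sex_effect if row.sex == "M" else 0.0
        y += gen_effect[row.generation]
        for mid, a in cfg.qtl_spec:
            dos = int(haps.alleles[i, :, marker_pos[mid]].sum())
            y += a * (dos - 1)
        y += rng.normal(0.0, cfg.sigma_e)
        rows.append(
            {
                "id": row.id,
                "bw56": y,
                "sex": row.sex,
                "generation": row.generation,
            }
        )
    return PhenotypeTable(pd.DataFrame(rows))


def mask_genotypes(
    haps: TrueHaplotypes,
    mmap: MarkerMap,
    ped: PedigreeTable,
    cfg: SimulationConfig,
) -> tuple[GenotypeMatrix, list[str]]:
    """Apply the two-tier observation design to true genotypes.

    Backbone markers are observed in all individuals; dense markers only
    in a random ``dense_founder_fraction`` of founders.  Returns the
    observed matrix and the dense-genotyped founder ids.
    """
    rng = cfg.rng("masking")
    founders = ped.founder_ids
    n_dense = int(np.rint(cfg.dense_founder_fraction * len(founders)))
    dense_founders = sorted(
        rng.choice(founders, size=n_dense, replace=False).tolist()
    )
    dos = haps.dosages().astype(float)
    dense_cols = mmap.table.loc[
        mmap.table["source"] == "dense", "marker"
    ].tolist()
    hidden_rows = [i for i in haps.ids if i not in set(dense_founders)]
    dos.loc[hidden_rows, dense_cols] = np.nan
    return GenotypeMatrix(dos), dense_founders


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------


def simulate_ail(cfg: SimulationConfig) -> SimulatedAIL:
    """Run the full generator: founders -> pedigree -> meiosis ->
    phenotypes -> observation masking."""
    mmap, f0_haps, f0_ped, freqs = simulate_founder_lines(cfg)
    ped = simulate_pedigree(cfg, f0_ped)
    haps = gene_drop(ped, f0_haps, mmap, cfg)
    pheno = simulate_phenotypes(haps, ped, cfg)
    observed, dense_founders = mask_genotypes(haps, mmap, ped, cfg)
    return SimulatedAIL(
        config=cfg,
        marker_map=mmap,
        pedigree=ped,
        haplotypes=haps,
        phenotypes=pheno,
        observed=observed,
        dense_founder_ids=dense_founders,
        founder_freqs=freqs,
        qtl_effects=dict(cfg.qtl_spec),
    )


def qtl_spec_like_reported(
    mmap: MarkerMap, effects: pd.DataFrame | None = None
) -> tuple[tuple[str, float], ...]:
    """Place the reported final-model effects on a simulated map.

    Each reported (region, position, effect) is mapped to the nearest
    simulated marker in the same region, giving a planted architecture
    that mirrors the published multi-locus model.
    """
    if effects is None:
        effects = published.final_model_table()
    spec = []
    for row in effects.itertuples():
        sub = mmap.table[mmap.table["region"] == row.region]
        if sub.empty:
            continue
        j = (sub["pos_bp"] - row.pos_bp).abs().idxmin()
        spec.append((str(mmap.table.loc[j, "marker"]), float(row.a)))
    return tuple(spec)
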