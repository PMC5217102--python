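"""Tabular input/output, marker ordering and cross-platform genotype QC.

Canonical on-disk dialect: headered TSV (UTF-8) with ``NA`` for missing
values.  CSV input is accepted with delimiter auto-detection.  Genotypes
are dosage-coded (0/1/2 copies of a designated per-marker reference
allele).  Coordinates are 1-based inclusive base-pair positions; the
genome build is metadata only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

MISSING = "NA"

GENERATIONS = tuple(f"F{i}" for i in range(9))
PHENOTYPED_GENERATIONS = tuple(f"F{i}" for i in range(2, 9))
LINES = ("HWS", "LWS")


class FormatError(ValueError):
    """Malformed or inconsistent tabular input."""


class PedigreeError(FormatError):
    """Referential or structural problem in a pedigree table."""


class MarkerMapError(FormatError):
    """Invalid marker map (duplicates, unordered positions, bad regions)."""


# ---------------------------------------------------------------------------
# domain containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Marker:
    """A single marker: id, chromosome label, 1-based position, QTL region
    label (or None) and genotyping source (backbone / dense / both)."""

    marker_id: str
    chromosome: str
    position_bp: int
    qtl_region: str | None = None
    source: str = "backbone"

    def __post_init__(self) -> None:
        if self.position_bp < 1:
            raise MarkerMapError(
                f"marker {self.marker_id}: position_bp must be >= 1, "
                f"got {self.position_bp}"
            )
        if self.source not in ("backbone", "dense", "both"):
            raise MarkerMapError(
                f"marker {self.marker_id}: unknown source {self.source!r}"
            )


class MarkerMap:
    """Ordered marker metadata with optional per-region bounds.

    Parameters
    ----------
    table
        DataFrame with columns ``marker, chrom, pos_bp, region, source``.
        ``region`` may contain missing values for markers outside any QTL.
    region_bounds
        Optional mapping ``region -> (chrom, start_bp, end_bp)``.  When
        absent, bounds default to the min/max marker position per region.
    """

    COLUMNS = ("marker", "chrom", "pos_bp", "region", "source")

    def __init__(
        self,
        table: pd.DataFrame,
        region_bounds: dict[str, tuple[str, int, int]] | None = None,
    ) -> None:
        missing_cols = [c for c in self.COLUMNS if c not in table.columns]
        if missing_cols:
            raise MarkerMapError(f"marker map missing columns: {missing_cols}")
        tab = table.loc[:, list(self.COLUMNS)].copy().reset_index(drop=True)
        tab["marker"] = tab["marker"].astype(str)
        tab["chrom"] = tab["chrom"].astype(str)
        tab["pos_bp"] = tab["pos_bp"].astype(np.int64)
        if (tab["pos_bp"] < 1).any():
            bad = tab.loc[tab["pos_bp"] < 1, "marker"].iloc[0]
            raise MarkerMapError(f"marker {bad}: position_bp must be >= 1")
        dup = tab["marker"].duplicated()
        if dup.any():
            raise MarkerMapError(
                f"duplicate marker id: {tab.loc[dup, 'marker'].iloc[0]}"
            )
        bad_src = ~tab["source"].isin(["backbone", "dense", "both"])
        if bad_src.any():
            raise MarkerMapError(
                f"unknown source for marker {tab.loc[bad_src, 'marker'].iloc[0]}"
            )
        self.table = tab
        if region_bounds is None:
            region_bounds = {}
            for region, grp in tab.dropna(subset=["region"]).groupby("region"):
                region_bounds[str(region)] = (
                    str(grp["chrom"].iloc[0]),
                    int(grp["pos_bp"].min()),
                    int(grp["pos_bp"].max()),
                )
        self.region_bounds = dict(region_bounds)
        self._validate_regions()

    def _validate_regions(self) -> None:
        for region, (chrom, start, end) in self.region_bounds.items():
            if end < start:
                raise MarkerMapError(
                    f"region {region}: end_bp {end} < start_bp {start}"
                )
            sub = self.table[self.table["region"] == region]
            outside = sub[
                (sub["chrom"] != chrom)
                | (sub["pos_bp"] < start)
                | (sub["pos_bp"] > end)
            ]
            if len(outside):
                raise MarkerMapError(
                    f"marker {outside['marker'].iloc[0]} lies outside the "
                    f"bounds of its region {region}"
                )

    # -- basic accessors ---------------------------------------------------

    def __len__(self) -> int:
        return len(self.table)

    @property
    def marker_ids(self) -> list[str]:
        return self.table["marker"].tolist()

    @property
    def regions(self) -> list[str]:
        seen: list[str] = []
        for r in self.table["region"].dropna():
            if r not in seen:
                seen.append(r)
        return seen

    @property
    def is_ordered(self) -> bool:
        tab = self.table
        for _, grp in tab.groupby("chrom", sort=False):
            if not grp["pos_bp"].is_monotonic_increasing:
                return False
            if grp["pos_bp"].duplicated().any():
                return False
        return True

    def region_marker_ids(self, region: str) -> list[str]:
        ids = self.table.loc[self.table["region"] == region, "marker"].tolist()
        if not ids:
            raise MarkerMapError(f"region {region!r} has no markers")
        return ids

    def source_mask(self, *sources: str) -> np.ndarray:
        return self.table["source"].isin(sources).to_numpy()

    def markers(self) -> list[Marker]:
        return [
            Marker(
                row.marker,
                row.chrom,
                int(row.pos_bp),
                None if pd.isna(row.region) else row.region,
                row.source,
            )
            for row in self.table.itertuples()
        ]


class PedigreeTable:
    """Pedigree records: id, sire, dam, sex, generation, founder line.

    Founders (generation F0) have no parents and a founder line; every
    non-founder has both parents present in the table, each from a strictly
    earlier generation (which also rules out cycles).
    """

    COLUMNS = ("id", "sire", "dam", "sex", "generation", "line")

    def __init__(self, table: pd.DataFrame) -> None:
        missing_cols = [c for c in self.COLUMNS if c not in table.columns]
        if missing_cols:
            raise PedigreeError(f"pedigree missing columns: {missing_cols}")
        tab = table.loc[:, list(self.COLUMNS)].copy().reset_index(drop=True)
        tab = tab.where(pd.notna(tab), np.nan)  # None and NaN coincide
        tab["id"] = tab["id"].astype(str)
        if tab["id"].duplicated().any():
            dup = tab.loc[tab["id"].duplicated(), "id"].iloc[0]
            raise PedigreeError(f"duplicate individual id: {dup}")
        bad_sex = ~tab["sex"].isin(["F", "M"])
        if bad_sex.any():
            raise PedigreeError(
                f"invalid sex for id {tab.loc[bad_sex, 'id'].iloc[0]}"
            )
        bad_gen = ~tab["generation"].isin(GENERATIONS)
        if bad_gen.any():
            raise PedigreeError(
                f"invalid generation for id {tab.loc[bad_gen, 'id'].iloc[0]}"
            )
        self.table = tab
        self._validate_structure()

    def _validate_structure(self) -> None:
        tab = self.table
        gen_rank = {g: i for i, g in enumerate(GENERATIONS)}
        rank = {r.id: gen_rank[r.generation] for r in tab.itertuples()}
        for row in tab.itertuples():
            is_founder = row.generation == "F0"
            sire = None if pd.isna(row.sire) else str(row.sire)
            dam = None if pd.isna(row.dam) else str(row.dam)
            if is_founder:
                if sire is not None or dam is not None:
                    raise PedigreeError(f"founder {row.id} has parents listed")
                if row.line not in LINES:
                    raise PedigreeError(
                        f"founder {row.id} lacks a founder line (HWS/LWS)"
                    )
            else:
                for label, parent in (("sire", sire), ("dam", dam)):
                    if parent is None:
                        raise PedigreeError(
                            f"non-founder {row.id} is missing its {label}"
                        )
                    if parent not in rank:
                        raise PedigreeError(
                            f"{label} {parent!r} of individual {row.id} "
                            "is not in the pedigree"
                        )
                    if rank[parent] >= gen_rank[row.generation]:
                        raise PedigreeError(
                            f"{label} {parent} of {row.id} does not belong "
                            "to an earlier generation"
                        )

    def __len__(self) -> int:
        return len(self.table)

    @property
    def ids(self) -> list[str]:
        return self.table["id"].tolist()

    @property
    def founder_ids(self) -> list[str]:
        return self.table.loc[self.table["generation"] == "F0", "id"].tolist()

    def line_of(self) -> dict[str, str]:
        """Founder line per founder id."""
        return {
            r.id: r.line
            for r in self.table.itertuples()
            if r.generation == "F0"
        }

    def parents_of(self) -> dict[str, tuple[str | None, str | None]]:
        out: dict[str, tuple[str | None, str | None]] = {}
        for r in self.table.itertuples():
            sire = None if pd.isna(r.sire) else str(r.sire)
            dam = None if pd.isna(r.dam) else str(r.dam)
            out[r.id] = (sire, dam)
        return out


class GenotypeMatrix:
    """Individuals x markers dosage matrix with missingness.

    Dosage counts copies of the per-marker reference allele; values are
    0, 1, 2 or NaN.  ``ref_alleles`` labels the counted allele per marker.
    """

    def __init__(
        self,
        dosages: pd.DataFrame,
        ref_alleles: pd.Series | None = None,
    ) -> None:
        dos = dosages.astype(float)
        vals = dos.to_numpy()
        ok = np.isnan(vals) | np.isin(vals, (0.0, 1.0, 2.0))
        if not ok.all():
            i, j = np.argwhere(~ok)[0]
            raise FormatError(
                f"invalid dosage {vals[i, j]!r} for individual "
                f"{dos.index[i]!r} at marker {dos.columns[j]!r}"
            )
        dos.index = dos.index.astype(str)
        dos.columns = dos.columns.astype(str)
        self.dosages = dos
        if ref_alleles is None:
            ref_alleles = pd.Series("A1", index=dos.columns)
        self.ref_alleles = ref_alleles.reindex(dos.columns).fillna("A1")

    def __len__(self) -> int:
        return len(self.dosages)

    @property
    def individual_ids(self) -> list[str]:
        return self.dosages.index.tolist()

    @property
    def marker_ids(self) -> list[str]:
        return self.dosages.columns.tolist()

    def column(self, marker_id: str) -> np.ndarray:
        return self.dosages[marker_id].to_numpy(dtype=float)

    def subset(self, individuals=None, markers=None) -> "GenotypeMatrix":
        dos = self.dosages
        if individuals is not None:
            dos = dos.loc[list(individuals)]
        if markers is not None:
            dos = dos.loc[:, list(markers)]
        return GenotypeMatrix(dos, self.ref_alleles)


class PhenotypeTable:
    """Per-individual 56-day body weight (grams) with sex and generation
    echoed from the pedigree.  Only generations F2-F8 carry phenotypes."""

    COLUMNS = ("id", "bw56", "sex", "generation")

    def __init__(self, table: pd.DataFrame) -> None:
        missing_cols = [c for c in self.COLUMNS if c not in table.columns]
        if missing_cols:
            raise FormatError(f"phenotype table missing columns: {missing_cols}")
        tab = table.loc[:, list(self.COLUMNS)].copy().reset_index(drop=True)
        tab["id"] = tab["id"].astype(str)
        tab["bw56"] = tab["bw56"].astype(float)
        has_pheno = tab["bw56"].notna()
        bad = has_pheno & ~tab["generation"].isin(PHENOTYPED_GENERATIONS)
        if bad.any():
            raise FormatError(
                f"individual {tab.loc[bad, 'id'].iloc[0]} has a phenotype "
                "but is outside generations F2-F8"
            )
        if (tab.loc[has_pheno, "bw56"] <= 0).any():
            bad_id = tab.loc[has_pheno & (tab["bw56"] <= 0), "id"].iloc[0]
            raise FormatError(f"non-positive body weight for id {bad_id}")
        self.table = tab

    def __len__(self) -> int:
        return len(self.table)

    def phenotyped(self) -> pd.DataFrame:
        return self.table[self.table["bw56"].notna()].reset_index(drop=True)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def _read_table(path) -> pd.DataFrame:
    return pd.read_csv(
        path, sep=None, engine="python", na_values=[MISSING], dtype=str
    )


def _write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, na_rep=MISSING)


def read_pedigree(path) -> PedigreeTable:
    """Read a pedigree TSV/CSV with header id,sire,dam,sex,generation,line."""
    return PedigreeTable(_read_table(path))


def write_pedigree(ped: PedigreeTable, path) -> None:
    _write_table(ped.table, path)


def read_marker_map(path) -> MarkerMap:
    df = _read_table(path)
    df["pos_bp"] = df["pos_bp"].astype(np.int64)
    return MarkerMap(df)


def write_marker_map(mmap: MarkerMap, path) -> None:
    _write_table(mmap.table, path)


def read_genotypes(path, mmap: MarkerMap, ped: PedigreeTable) -> GenotypeMatrix:
    """Read a genotype TSV (rows: individuals, columns: markers).

    Markers present in the file but absent from the map (and vice versa)
    are reported via a warning; unknown individuals are an error.
    """
    df = _read_table(path)
    if df.columns[0] != "id":
        raise FormatError("genotype file must have 'id' as its first column")
    df = df.set_index("id")
    unknown_ind = set(df.index) - set(ped.ids)
    if unknown_ind:
        raise FormatError(
            f"genotype file contains unknown individual {sorted(unknown_ind)[0]!r}"
        )
    file_markers = set(df.columns)
    map_markers = set(mmap.marker_ids)
    only_file = sorted(file_markers - map_markers)
    only_map = sorted(map_markers - file_markers)
    if only_file or only_map:
        warnings.warn(
            f"genotype/map mismatch: {len(only_file)} markers only in file, "
            f"{len(only_map)} only in map",
            stacklevel=2,
        )
    keep = [m for m in mmap.marker_ids if m in file_markers]
    sub = df.loc[:, keep]
    arr = sub.to_numpy()
    for j, col in enumerate(sub.columns):
        for i, v in enumerate(arr[:, j]):
            if pd.isna(v):
                continue
            if str(v) not in ("0", "1", "2", "0.0", "1.0", "2.0"):
                raise FormatError(
                    f"invalid dosage {v!r} for individual {sub.index[i]!r} "
                    f"at marker {col!r}"
                )
    return GenotypeMatrix(sub.astype(float))


def write_genotypes(geno: GenotypeMatrix, path) -> None:
    out = geno.dosages.copy()
    # integer-like dosages are written without a decimal point
    out = out.map(lambda v: "" if pd.isna(v) else str(int(v)))
    out = out.replace("", np.nan)
    out.insert(0, "id", out.index)
    _write_table(out.reset_index(drop=True), path)


def read_phenotypes(path) -> PhenotypeTable:
    df = _read_table(path)
    return PhenotypeTable(df)


def write_phenotypes(pheno: PhenotypeTable, path) -> None:
    _write_table(pheno.table, path)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def order_markers(mmap: MarkerMap) -> MarkerMap:
    """Stable sort by (chromosome, position_bp).

    Two markers at an identical (chromosome, position) are an error:
    downstream phasing and imputation assume a strict physical order.
    """
    tab = mmap.table.sort_values(
        ["chrom", "pos_bp"], kind="stable"
    ).reset_index(drop=True)
    dup = tab.duplicated(subset=["chrom", "pos_bp"])
    if dup.any():
        row = tab.loc[dup].iloc[0]
        raise MarkerMapError(
            f"duplicate position {row['chrom']}:{row['pos_bp']} "
            f"(marker {row['marker']})"
        )
    return MarkerMap(tab, mmap.region_bounds)


def concordance_qc(
    pairs: pd.DataFrame, max_discordant_fraction: float = 0.0
) -> tuple[list[str], list[str]]:
    """Cross-platform genotype concordance QC.

    ``pairs`` has columns ``marker, individual, dosage_a, dosage_b``: the
    two platforms' dosage calls for the same (individual, marker).  A
    marker is removed when its fraction of discordant non-missing pairs
    exceeds ``max_discordant_fraction`` (default 0: a single discordant
    call removes the marker).  Returns (kept, removed) marker-id lists.
    """
    if len(pairs) == 0:
        return [], []
    df = pairs.copy()
    a = df["dosage_a"].astype(float)
    b = df["dosage_b"].astype(float)
    df["_both"] = a.notna() & b.notna()
    df["_disc"] = df["_both"] & (a != b)
    kept, removed = [], []
    for marker, grp in df.groupby("marker", sort=False):
        n_both = int(grp["_both"].sum())
        n_disc = int(grp["_disc"].sum())
        frac = n_disc / n_both if n_both else 0.0
        (removed if frac > max_discordant_fraction else kept).append(str(marker))
    return kept, removed


def summarize_marker_counts(mmap: MarkerMap) -> pd.DataFrame:
    """Per-QTL-region marker accounting.

    Returns one row per region with the region span (1-based inclusive,
    ``size_bp = end - start + 1``), backbone/dense/total marker counts and
    the marker density per Mb rounded to the nearest integer.
    """
    if not mmap.is_ordered:
        raise MarkerMapError("marker map must be ordered; call order_markers")
    rows = []
    for region in mmap.regions:
        chrom, start, end = mmap.region_bounds[region]
        size = end - start + 1
        if size <= 1 and start == end:
            raise MarkerMapError(f"region {region} has zero span")
        sub = mmap.table[mmap.table["region"] == region]
        n_backbone = int(sub["source"].isin(["backbone", "both"]).sum())
        n_dense = int((sub["source"] == "dense").sum())
        n_total = n_backbone + n_dense
        density = int(np.rint(n_total / (size / 1e6)))
        rows.append(
            {
                "region": region,
                "chrom": chrom,
                "start_bp": start,
                "end_bp": end,
                "size_bp": size,
                "n_backbone": n_backbone,
                "n_dense": n_dense,
                "n_total": n_total,
                "density_per_mb": density,
            }
        )
    return pd.DataFrame(rows)
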