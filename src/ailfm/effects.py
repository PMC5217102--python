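"""Founder-line allele-frequency differentials and QTL contributions.

Under a purely additive model, a set of n associated markers in a QTL is
expected to contribute

    sum_i 2 * a_i * |p_i(HWS) - p_i(LWS)|

grams to the difference between the founder lines, where a_i is the
allele-substitution effect of marker i under line-origin coding and
p_i(HWS), p_i(LWS) are the frequencies of the major-AIL allele in the
high- and low-weight founder lines.  A marker fixed for alternative
alleles contributes two substitution effects; a marker at equal
frequencies in both lines contributes nothing.  The absolute value
applies to the frequency differential only: a negative (transgressive)
effect subtracts from the contribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ailfm.io_formats import GenotypeMatrix, PedigreeTable


@dataclass(frozen=True)
class MarkerEffectRecord:
    """One retained marker: signed effect (grams) and founder frequencies."""

    marker_id: str
    qtl_region: str
    a: float
    se: float | None = None
    p_hws: float | None = None
    p_lws: float | None = None
    delta_af: float | None = None

    def frequency_differential(self) -> float:
        if self.delta_af is not None:
            d = float(self.delta_af)
        elif self.p_hws is not None and self.p_lws is not None:
            d = abs(float(self.p_hws) - float(self.p_lws))
        else:
            raise ValueError(
                f"marker {self.marker_id}: neither delta_af nor founder "
                "frequencies are available"
            )
        if not 0.0 <= d <= 1.0:
            raise ValueError(
                f"marker {self.marker_id}: delta_af {d} outside [0, 1]"
            )
        return d


@dataclass(frozen=True)
class QTLContribution:
    """A region's expected contribution to the founder-line difference."""

    qtl_region: str
    contribution_g: float          # unrounded signed sum
    contribution_rounded_g: int    # nearest gram, as reported
    n_markers: int
    f2_effect_g: float | None = None

    @property
    def percent_of_f2(self) -> float | None:
        if self.f2_effect_g is None:
            return None
        return percent_of_f2(self.contribution_g, self.f2_effect_g)


def founder_delta_af(
    founder_geno: GenotypeMatrix, ped: PedigreeTable
) -> pd.DataFrame:
    """Major-AIL-allele frequencies per founder line and their differential.

    The major AIL allele at each marker is the majority allele over all
    genotyped founders; frequencies of that allele are then computed per
    line.  A line with no genotyped founder at a marker yields a missing
    differential.
    """
    lines = ped.line_of()
    founders = [i for i in founder_geno.individual_ids if i in lines]
    dos = founder_geno.dosages.loc[founders]
    hws = dos.loc[[i for i in founders if lines[i] == "HWS"]]
    lws = dos.loc[[i for i in founders if lines[i] == "LWS"]]

    def _freq(block: pd.DataFrame) -> pd.Series:
        n = block.notna().sum(axis=0)
        s = block.sum(axis=0, skipna=True)
        with np.errstate(invalid="ignore"):
            return s / (2.0 * n.where(n > 0))

    p_ref_all = _freq(dos)
    # frequency of the majority allele over all founders
    major_is_ref = p_ref_all >= 0.5
    p_hws_ref, p_lws_ref = _freq(hws), _freq(lws)
    p_hws = p_hws_ref.where(major_is_ref, 1.0 - p_hws_ref)
    p_lws = p_lws_ref.where(major_is_ref, 1.0 - p_lws_ref)
    out = pd.DataFrame(
        {
            "marker": dos.columns,
            "major_is_ref": major_is_ref.to_numpy(),
            "p_hws": p_hws.to_numpy(dtype=float),
            "p_lws": p_lws.to_numpy(dtype=float),
        }
    )
    out["delta_af"] = (out["p_hws"] - out["p_lws"]).abs()
    return out


def qtl_contribution(
    records: list[MarkerEffectRecord], f2_effect_g: float | None = None
) -> QTLContribution:
    """Signed sum of 2*a*|dAF| over one region's retained markers."""
    if not records:
        return QTLContribution("", 0.0, 0, 0, f2_effect_g)
    regions = {r.qtl_region for r in records}
    if len(regions) != 1:
        raise ValueError(f"records span multiple regions: {sorted(regions)}")
    total = float(
        sum(2.0 * r.a * r.frequency_differential() for r in records)
    )
    return QTLContribution(
        qtl_region=records[0].qtl_region,
        contribution_g=total,
        contribution_rounded_g=int(np.rint(total)),
        n_markers=len(records),
        f2_effect_g=f2_effect_g,
    )


def records_from_table(table: pd.DataFrame) -> list[MarkerEffectRecord]:
    """Build effect records from a final-model table.

    Expects columns ``region, marker, a`` plus either ``delta_af`` or both
    ``p_hws`` and ``p_lws`` (``se`` optional).
    """
    records = []
    for row in table.itertuples():
        records.append(
            MarkerEffectRecord(
                marker_id=str(row.marker),
                qtl_region=str(row.region),
                a=float(row.a),
                se=float(row.se) if hasattr(row, "se") else None,
                p_hws=float(row.p_hws) if hasattr(row, "p_hws") else None,
                p_lws=float(row.p_lws) if hasattr(row, "p_lws") else None,
                delta_af=float(row.delta_af)
                if hasattr(row, "delta_af")
                else None,
            )
        )
    return records


def contributions_by_region(
    table: pd.DataFrame, f2_effects: dict[str, float] | None = None
) -> list[QTLContribution]:
    """Per-region contributions from a final-model table, in table order."""
    f2_effects = f2_effects or {}
    out = []
    for region in table["region"].drop_duplicates():
        recs = records_from_table(table[table["region"] == region])
        out.append(qtl_contribution(recs, f2_effects.get(region)))
    return out


def total_contribution(
    contributions: list[QTLContribution],
) -> tuple[int, float]:
    """Grand total over regions.

    The headline figure sums the per-region values after rounding each to
    the nearest gram (matching how per-region results are reported); the
    unrounded sum is returned alongside.
    """
    rounded = int(sum(c.contribution_rounded_g for c in contributions))
    raw = float(sum(c.contribution_g for c in contributions))
    return rounded, raw


def percent_of_f2(contribution_g: float, f2_effect_g: float) -> float:
    """Contribution as a percentage of an externally estimated F2 effect."""
    if not f2_effect_g > 0:
        raise ValueError(f"f2_effect_g must be positive, got {f2_effect_g}")
    return 100.0 * contribution_g / f2_effect_g
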