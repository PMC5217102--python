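"""Reported results for the nine body-weight QTL in the Virginia AIL.

Two small reference tables from the published fine-mapping of juvenile
body weight (BW56) in the Virginia high/low-weight chicken advanced
intercross:

* the nine QTL regions with their genome spans (galGal3, 1-based bp) and
  the counts of backbone markers (genotyped in the whole pedigree) and
  dense SNP-chip markers (genotyped in 40 of the 59 founders, imputed
  elsewhere);
* the 31 markers retained in the final multi-locus model, with their
  founder-line allele-frequency differences (dAF), allele-substitution
  effects a +/- SE (grams, line-origin coding) and per-marker p-values.

These tables serve as fixed inputs for the contribution arithmetic and as
realistic templates for the synthetic-data generator; the package never
treats them as outputs of its own computations.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ailfm.io_formats import MarkerMap

# region, chromosome, start_bp, end_bp, n_backbone (whole-pedigree markers),
# n_dense (founder SNP-chip markers), reported F2 QTL effect in grams where
# available (comparison constant supplied by earlier F2 line-cross studies).
_REGIONS = [
    ("Growth1", "GGA1", 169_634_954, 181_087_961, 26, 504, 49.0),
    ("Growth2", "GGA2", 47_929_675, 65_460_002, 33, 667, np.nan),
    ("Growth3", "GGA2", 124_333_151, 133_581_122, 19, 395, np.nan),
    ("Growth4", "GGA3", 24_029_841, 68_029_533, 57, 1885, np.nan),
    ("Growth6", "GGA4", 1_354_213, 13_511_203, 23, 514, 92.0),
    ("Growth7", "GGA4", 85_459_943, 88_832_107, 14, 141, 66.0),
    ("Growth8", "GGA5", 33_696_791, 39_052_438, 5, 221, np.nan),
    ("Growth9", "GGA7", 10_916_819, 35_491_706, 76, 1397, 86.0),
    ("Growth12", "GGA20", 7_109_709, 13_899_993, 28, 883, np.nan),
]

# region, marker, position_bp, imputed flag, dAF, a (g), SE (g), p
_FINAL_MODEL = [
    ("Growth1", "rs13968052", 170_637_618, True, 0.28, 16.3, 6.6, 1.3e-2),
    ("Growth1", "rs14916997", 173_709_608, False, 0.71, 19.3, 5.5, 4.8e-4),
    ("Growth2", "rs14185295", 56_720_515, False, 0.32, 13.2, 6.2, 3.3e-2),
    ("Growth2", "rs14185836", 57_198_629, True, 0.16, -12.1, 6.2, 5.4e-2),
    ("Growth2", "rs14196021", 65_460_002, False, 0.32, 14.0, 5.9, 1.7e-2),
    ("Growth3", "rs16120360", 126_000_254, False, 0.36, 12.6, 5.8, 3.0e-2),
    ("Growth4", "rs14328509", 26_215_175, False, 0.53, 19.8, 5.4, 2.3e-4),
    ("Growth4", "rs314044798", 33_743_569, True, 0.46, -21.9, 6.1, 3.8e-4),
    ("Growth4", "rs316425755", 37_287_334, True, 0.12, 27.8, 6.9, 5.7e-5),
    ("Growth4", "rs15468467", 39_139_081, True, 0.23, 27.0, 7.3, 2.1e-4),
    ("Growth4", "rs316384373", 47_729_342, True, 0.30, -13.1, 6.8, 5.5e-2),
    ("Growth4", "rs14363139", 57_624_596, True, 0.64, 18.2, 4.1, 2.9e-4),
    ("Growth6", "rs14419462", 2_392_397, True, 0.30, 19.7, 7.6, 1.0e-2),
    ("Growth6", "rs14428120", 10_914_312, True, 0.77, -14.5, 5.8, 1.3e-2),
    ("Growth6", "rs15500313", 13_511_203, False, 0.78, 17.7, 6.0, 3.4e-3),
    ("Growth7", "rs14499758", 86_755_267, False, 0.32, 18.1, 6.3, 3.9e-3),
    ("Growth7", "rs15639000", 88_325_118, False, 0.06, 13.4, 5.4, 1.3e-2),
    ("Growth8", "rs14530756", 33_713_055, True, 0.46, -13.5, 5.3, 1.1e-2),
    ("Growth8", "rs16487762", 34_772_650, True, 0.53, 15.0, 6.8, 2.7e-2),
    ("Growth8", "rs16487933", 35_299_978, True, 0.40, -18.6, 6.0, 1.8e-3),
    ("Growth8", "rs13585490", 36_291_277, False, 0.15, 14.1, 5.3, 7.3e-3),
    ("Growth8", "rs315605733", 38_774_986, True, 0.23, 23.3, 7.3, 1.4e-3),
    ("Growth8", "rs314075508", 38_867_279, True, 0.37, 16.4, 5.5, 3.0e-3),
    ("Growth9", "rs14611566", 18_544_622, True, 0.00, -20.1, 5.1, 9.4e-5),
    ("Growth9", "rs16596357", 23_959_214, True, 0.17, 18.9, 5.6, 7.7e-4),
    ("Growth9", "rs10727581", 29_631_963, True, 0.32, 15.9, 6.1, 9.0e-3),
    ("Growth9", "rs317586448", 32_262_733, True, 0.33, -13.2, 5.0, 8.7e-3),
    ("Growth12", "rs14277526", 9_302_754, True, 0.34, 21.8, 6.8, 1.4e-3),
    ("Growth12", "rs14278292", 10_165_171, True, 0.37, -14.7, 6.5, 2.4e-2),
    ("Growth12", "rs16172598", 10_667_729, True, 0.56, 14.3, 5.1, 5.1e-3),
    ("Growth12", "rs16176151", 13_427_530, True, 0.13, 8.5, 5.2, 1.0e-1),
]


def qtl_region_table() -> pd.DataFrame:
    """The nine fine-mapped QTL regions and their marker accounting."""
    return pd.DataFrame(
        _REGIONS,
        columns=[
            "region",
            "chrom",
            "start_bp",
            "end_bp",
            "n_backbone",
            "n_dense",
            "f2_effect_g",
        ],
    )


def final_model_table() -> pd.DataFrame:
    """The 31 markers in the reported final multi-locus model."""
    return pd.DataFrame(
        _FINAL_MODEL,
        columns=[
            "region",
            "marker",
            "pos_bp",
            "imputed",
            "delta_af",
            "a",
            "se",
            "p",
        ],
    )


def region_table_to_marker_map(regions: pd.DataFrame | None = None) -> MarkerMap:
    """Expand a region accounting table into a concrete MarkerMap.

    Places ``n_backbone`` backbone and ``n_dense`` dense markers at
    deterministic, distinct positions inside each region's bounds so the
    per-region counts, spans and densities of the input table are exactly
    represented.  Useful for marker-accounting summaries and as a template
    for simulations.
    """
    if regions is None:
        regions = qtl_region_table()
    rows = []
    bounds: dict[str, tuple[str, int, int]] = {}
    for r in regions.itertuples():
        n_total = int(r.n_backbone) + int(r.n_dense)
        bounds[r.region] = (r.chrom, int(r.start_bp), int(r.end_bp))
        positions = np.linspace(r.start_bp, r.end_bp, n_total)
        positions = np.unique(np.rint(positions).astype(np.int64))
        if len(positions) < n_total:  # collisions after rounding
            positions = np.arange(r.start_bp, r.start_bp + n_total)
        # every (n_backbone)-th slot is a backbone marker, evenly interleaved
        backbone_idx = set(
            np.rint(np.linspace(0, n_total - 1, int(r.n_backbone))).astype(int)
        )
        for k, pos in enumerate(positions[:n_total]):
            source = "backbone" if k in backbone_idx else "dense"
            rows.append(
                {
                    "marker": f"{r.region}_m{k:05d}",
                    "chrom": r.chrom,
                    "pos_bp": int(pos),
                    "region": r.region,
                    "source": source,
                }
            )
    return MarkerMap(pd.DataFrame(rows), bounds)
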