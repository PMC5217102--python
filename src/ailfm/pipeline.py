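"""End-to-end orchestration: simulate/load -> impute -> forward-select ->
bootstrap backward-eliminate -> effect report.

Each stage writes plain TSV outputs plus a JSON manifest recording
parameters, derived seeds, input hashes, package version and wall time,
so a run can be audited and resumed.  Candidates from all regions enter
one joint multi-locus model, mirroring the experiment-wide reporting of
independent signals.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

import ailfm
from ailfm import effects as eff
from ailfm import io_formats as io
from ailfm.association import forward_select
from ailfm.imputation import impute_pipeline
from ailfm.multilocus import (
    EliminationConfig,
    bootstrap_rmip,
    code_line_origin,
    design_for,
    fit_final_model,
)
from ailfm.synthetic_data import SimulationConfig, simulate_ail


class ValidationError(ValueError):
    """Cross-file inconsistency in pipeline inputs."""


@dataclass
class RunConfig:
    """Parameters of one pipeline run.

    Either ``simulation`` is set (the generator provides the inputs) or
    the four input paths are.  Per-stage seeds are derived from
    ``seed`` so stages are independently reproducible.
    """

    out_dir: str
    simulation: SimulationConfig | None = None
    genotypes: str | None = None
    pedigree: str | None = None
    marker_map: str | None = None
    phenotypes: str | None = None
    dense_founders: str | None = None  # one id per line
    regions: list[str] | None = None
    alpha: float = 0.05
    maf_threshold: float = 0.10
    min_call_rate: float = 0.5  # candidate filter before the joint model
    fdr_q: float = 0.20
    n_bootstrap: int = 1000
    rmip_threshold: float = 0.46
    seed: int = 0
    f2_effects: dict[str, float] = field(default_factory=dict)

    def stage_seed(self, stage: str) -> int:
        h = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return int.from_bytes(h[:4], "big") % (2**31)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def validate_inputs(
    ped: io.PedigreeTable,
    mmap: io.MarkerMap,
    geno: io.GenotypeMatrix,
    pheno: io.PhenotypeTable,
) -> list[str]:
    """Cross-file consistency report; empty list means consistent."""
    issues: list[str] = []
    ped_ids = set(ped.ids)
    for iid in geno.individual_ids:
        if iid not in ped_ids:
            issues.append(f"genotyped individual {iid} not in pedigree")
    for iid in pheno.table["id"]:
        if iid not in ped_ids:
            issues.append(f"phenotyped individual {iid} not in pedigree")
    map_markers = set(mmap.marker_ids)
    for mid in geno.marker_ids:
        if mid not in map_markers:
            issues.append(f"genotyped marker {mid} not in marker map")
    if not mmap.is_ordered:
        issues.append("marker map is not ordered by (chromosome, position)")
    ped_rows = ped.table.set_index("id")
    ph = pheno.table.set_index("id")
    for iid in ph.index:
        if iid in ped_rows.index:
            if ph.at[iid, "sex"] != ped_rows.at[iid, "sex"]:
                issues.append(f"sex mismatch for {iid}")
            if ph.at[iid, "generation"] != ped_rows.at[iid, "generation"]:
                issues.append(f"generation mismatch for {iid}")
    return issues


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute all stages, returning the manifest dictionary."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": ailfm.__version__,
        "seed": cfg.seed,
        "parameters": {
            "alpha": cfg.alpha,
            "maf_threshold": cfg.maf_threshold,
            "fdr_q": cfg.fdr_q,
            "n_bootstrap": cfg.n_bootstrap,
            "rmip_threshold": cfg.rmip_threshold,
        },
        "stages": [],
    }

    def stage(name: str):
        rec = {"stage": name, "seed": cfg.stage_seed(name), "t0": time.time()}
        manifest["stages"].append(rec)
        return rec

    def done(rec: dict, **extra) -> None:
        rec["wall_s"] = round(time.time() - rec.pop("t0"), 3)
        rec["status"] = "ok"
        rec.update(extra)
        _write_manifest(manifest, out)

    try:
        # ---- inputs ------------------------------------------------------
        if cfg.simulation is not None:
            rec = stage("simulate")
            sim = simulate_ail(cfg.simulation)
            ped, mmap = sim.pedigree, sim.marker_map
            geno, pheno = sim.observed, sim.phenotypes
            dense_founders = sim.dense_founder_ids
            io.write_pedigree(ped, out / "pedigree.tsv")
            io.write_marker_map(mmap, out / "markers.tsv")
            io.write_genotypes(geno, out / "genotypes.tsv")
            io.write_phenotypes(pheno, out / "phenotypes.tsv")
            (out / "dense_founders.txt").write_text(
                "\n".join(dense_founders) + "\n"
            )
            _write_truth(sim, out)
            done(rec, n_individuals=len(ped), n_markers=len(mmap))
        else:
            rec = stage("load")
            ped = io.read_pedigree(cfg.pedigree)
            mmap = io.order_markers(io.read_marker_map(cfg.marker_map))
            geno = io.read_genotypes(cfg.genotypes, mmap, ped)
            pheno = io.read_phenotypes(cfg.phenotypes)
            dense_founders = (
                Path(cfg.dense_founders).read_text().split()
                if cfg.dense_founders
                else []
            )
            issues = validate_inputs(ped, mmap, geno, pheno)
            if issues:
                raise ValidationError("; ".join(issues))
            done(
                rec,
                inputs={
                    k: _sha256(Path(p))
                    for k, p in [
                        ("pedigree", cfg.pedigree),
                        ("markers", cfg.marker_map),
                        ("genotypes", cfg.genotypes),
                        ("phenotypes", cfg.phenotypes),
                    ]
                },
            )

        # ---- imputation --------------------------------------------------
        rec = stage("impute")
        imputed, phased, painting = impute_pipeline(
            geno, ped, mmap, dense_founders, seed=cfg.stage_seed("impute")
        )
        io.write_genotypes(imputed.genotypes, out / "imputed.tsv")
        imputed.provenance.to_csv(out / "provenance.tsv", sep="\t")
        done(
            rec,
            n_imputed=int(
                (imputed.provenance == 1).to_numpy().sum()
            ),
        )

        # ---- forward selection -------------------------------------------
        rec = stage("forward")
        regions = cfg.regions or mmap.regions
        pheno_ids = pheno.phenotyped()["id"].tolist()
        call_rate = (
            imputed.genotypes.dosages.reindex(index=pheno_ids)
            .notna()
            .mean(axis=0)
        )
        candidates: list[str] = []
        cand_rows = []
        for region in regions:
            cs = forward_select(
                pheno,
                imputed.genotypes,
                mmap,
                region,
                alpha=cfg.alpha,
                maf_threshold=cfg.maf_threshold,
                min_call_rate=cfg.min_call_rate,
            )
            for mid, p, maf in zip(cs.marker_ids, cs.p_at_selection, cs.maf):
                # conservative imputation leaves some dense markers sparse;
                # the joint model needs overlapping calls, so sparsely
                # called candidates stay out of the multi-locus stage
                kept = call_rate[mid] >= cfg.min_call_rate
                cand_rows.append(
                    {
                        "region": region,
                        "marker": mid,
                        "p": p,
                        "maf": maf,
                        "call_rate": float(call_rate[mid]),
                        "kept": bool(kept),
                    }
                )
                if kept:
                    candidates.append(mid)
        cand_tab = pd.DataFrame(
            cand_rows,
            columns=["region", "marker", "p", "maf", "call_rate", "kept"],
        )
        cand_tab.to_csv(out / "candidates.tsv", sep="\t", index=False)
        done(
            rec,
            n_candidates=len(candidates),
            n_dropped_sparse=int(len(cand_rows) - len(candidates)),
        )

        # ---- multi-locus selection ---------------------------------------
        rec = stage("select")
        y, X, ids, _ = design_for(pheno)
        founder_geno = geno.subset(
            individuals=[i for i in ped.founder_ids if i in geno.individual_ids]
        )
        daf = eff.founder_delta_af(founder_geno, ped)
        # code_line_origin wants reference-allele frequencies per line
        ref_freqs = _ref_allele_freqs(founder_geno, ped)
        if candidates:
            lom = code_line_origin(
                geno_subset(imputed.genotypes, ids), candidates, ref_freqs
            )
            ecfg = EliminationConfig(
                fdr_q=cfg.fdr_q,
                n_bootstrap=cfg.n_bootstrap,
                rmip_threshold=cfg.rmip_threshold,
                seed=cfg.stage_seed("select"),
            )
            rmip = bootstrap_rmip(y, X, lom, ecfg)
            rmip.table.to_csv(out / "rmip.tsv", sep="\t", index=False)
            final = fit_final_model(
                y, X, lom, rmip.included_markers(), fdr_q=cfg.fdr_q
            )
        else:
            final = fit_final_model(y, X, pd.DataFrame(index=ids), [], cfg.fdr_q)
            pd.DataFrame(columns=["marker", "rmip", "included"]).to_csv(
                out / "rmip.tsv", sep="\t", index=False
            )
        done(rec, n_included=len(final.table))

        # ---- effect report -----------------------------------------------
        rec = stage("report")
        region_of = mmap.table.set_index("marker")["region"]
        pos_of = mmap.table.set_index("marker")["pos_bp"]
        ft = final.table.copy()
        if len(ft):
            ft["region"] = [region_of[m] for m in ft["marker"]]
            ft["pos_bp"] = [int(pos_of[m]) for m in ft["marker"]]
            ft = ft.merge(daf[["marker", "delta_af"]], on="marker", how="left")
        else:
            ft = pd.DataFrame(
                columns=[
                    "marker", "a", "se", "p", "bh_adjusted_p",
                    "region", "pos_bp", "delta_af",
                ]
            )
        ft = ft[
            ["region", "marker", "pos_bp", "delta_af", "a", "se", "p",
             "bh_adjusted_p"]
        ]
        ft.to_csv(out / "final_model.tsv", sep="\t", index=False)
        contribs = eff.contributions_by_region(ft, cfg.f2_effects) if len(ft) else []
        total_rounded, total_raw = eff.total_contribution(contribs)
        rows = [
            {
                "region": c.qtl_region,
                "n_markers": c.n_markers,
                "contribution_g": c.contribution_g,
                "contribution_rounded_g": c.contribution_rounded_g,
                "percent_of_f2": c.percent_of_f2,
            }
            for c in contribs
        ]
        rep = pd.DataFrame(
            rows,
            columns=[
                "region", "n_markers", "contribution_g",
                "contribution_rounded_g", "percent_of_f2",
            ],
        )
        rep.to_csv(out / "contributions.tsv", sep="\t", index=False)
        done(
            rec,
            total_contribution_g=total_rounded,
            total_contribution_unrounded_g=total_raw,
        )
    except Exception as exc:  # record the failure point, then re-raise
        manifest["stages"][-1]["status"] = "failed"
        manifest["stages"][-1]["error"] = str(exc)
        manifest["stages"][-1].pop("t0", None)
        _write_manifest(manifest, out)
        raise
    return manifest


def geno_subset(geno: io.GenotypeMatrix, ids: list[str]) -> io.GenotypeMatrix:
    return geno.subset(individuals=[i for i in ids if i in set(geno.individual_ids)])


def _ref_allele_freqs(
    founder_geno: io.GenotypeMatrix, ped: io.PedigreeTable
) -> pd.DataFrame:
    """Reference-allele frequency per founder line (code_line_origin input)."""
    lines = ped.line_of()
    dos = founder_geno.dosages
    rows = {}
    for line in ("HWS", "LWS"):
        sub = dos.loc[[i for i in dos.index if lines.get(i) == line]]
        n = sub.notna().sum(axis=0)
        with np.errstate(invalid="ignore"):
            rows[line] = sub.sum(axis=0, skipna=True) / (2.0 * n.where(n > 0))
    return pd.DataFrame(
        {
            "marker": dos.columns,
            "p_hws": rows["HWS"].to_numpy(dtype=float),
            "p_lws": rows["LWS"].to_numpy(dtype=float),
        }
    )


def _write_truth(sim, out: Path) -> None:
    """Truth bundle for evaluation: true dosages and planted effects."""
    truth_dir = out / "truth"
    truth_dir.mkdir(exist_ok=True)
    sim.haplotypes.dosages().to_csv(truth_dir / "true_dosages.tsv", sep="\t")
    pd.DataFrame(
        [{"marker": m, "a": a} for m, a in sim.qtl_effects.items()]
    ).to_csv(truth_dir / "true_effects.tsv", sep="\t", index=False)
    sim.founder_freqs.to_csv(
        truth_dir / "founder_frequencies.tsv", sep="\t", index=False
    )


def _write_manifest(manifest: dict, out: Path) -> None:
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
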