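"""End-to-end orchestration: QC -> dedup -> prune -> diversity -> structure
-> LD -> GWAS -> peaks, from one declarative config, with a run manifest.

Every stage writes plain-text outputs under the run directory and records
a sha256 checksum, wall time and the seeds it used in ``manifest.json``.
Re-running with the same config and seeds reproduces identical checksums
for deterministic stages; stages whose outputs already match the manifest
are skipped (resume semantics).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import assoc, diversity, ld, qc, structure
from .io import GenotypeMatrix, read_plink, write_plink
from .simulate import (
    DuplicateSpec,
    SimulationConfig,
    plant_duplicates,
    plant_pigment_loci,
    simulate_pigment_phenotypes,
)

log = logging.getLogger("coredivkit")

DEFAULT_CONFIG = {
    "site_max_missing": 0.95,
    "sample_max_missing": 0.50,
    "sample_max_het": 0.20,
    "dedup_cut_height": 500,
    "prune_window": 50,
    "prune_step": 10,
    "prune_r2": 0.20,
    "prune_maf": 0.01,
    "prune_missing": 0.05,
    "k_min": 1,
    "k_max": 10,
    "k_replicates": 10,
    "assign_threshold": 0.70,
    "ld_max_distance": 10_000_000,
    "ld_bin_width": 500,
    "gwas_min_maf": 0.01,
    "gwas_max_missing": 0.05,
    "alpha": 0.05,
    "peak_r2": 0.20,
    "peak_gap": 1_000_000,
    "coreset_targets": [0.90, 0.95],
    "coreset_iterations": 1000,
    "seed": 0,
}


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


class RunManifest:
    def __init__(self, path: Path):
        self.path = path
        self.data = {"stages": {}, "config": None}
        if path.exists():
            self.data = json.loads(path.read_text())

    def stage_done(self, name: str, outputs: list[Path]) -> bool:
        rec = self.data["stages"].get(name)
        if not rec:
            return False
        for f in outputs:
            if not f.exists() or rec["checksums"].get(f.name) != _sha256(f):
                return False
        return True

    def record(self, name: str, outputs: list[Path], seconds: float, **extra):
        self.data["stages"][name] = {
            "checksums": {f.name: _sha256(f) for f in outputs},
            "wall_time_s": round(seconds, 3),
            **extra,
        }
        self.path.write_text(json.dumps(self.data, indent=2, default=str))


def run_full_analysis(config: dict, out_dir, genotypes: GenotypeMatrix | None = None) -> RunManifest:
    """Run the full pipeline; see DEFAULT_CONFIG for tunables.

    ``config`` may point at a PLINK triple (``plink_prefix``) or request a
    simulated cohort (``simulate`` sub-dict of SimulationConfig fields).
    """
    cfg = {**DEFAULT_CONFIG, **config}
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(out / "manifest.json")
    manifest.data["config"] = cfg
    rng = np.random.default_rng(cfg["seed"])
    seeds = {k: int(rng.integers(2**31 - 1)) for k in
             ("simulate", "duplicates", "pigment", "dedup", "admixture", "coreset")}

    def stage(name, outputs, fn):
        outputs = [out / o for o in outputs]
        if manifest.stage_done(name, outputs):
            log.info("stage %s: up to date, skipped", name)
            return None
        t0 = time.perf_counter()
        extra = fn(outputs) or {}
        manifest.record(name, outputs, time.perf_counter() - t0, **extra)
        log.info("stage %s: done in %.2fs", name, time.perf_counter() - t0)
        return extra

    # ---- input -----------------------------------------------------------
    if genotypes is not None:
        g = genotypes
        truth = None
    elif "plink_prefix" in cfg:
        g = read_plink(cfg["plink_prefix"])
        truth = None
    else:
        sim = SimulationConfig(**cfg.get("simulate", {}))
        from .simulate import simulate_structured_genotypes

        g, true_q = simulate_structured_genotypes(sim, seed=seeds["simulate"])
        # pigment loci go in before duplicate copies so copies inherit them
        g, pig_truth = plant_pigment_loci(g, sim.pigment_spec, seed=seeds["pigment"])
        g, dup_truth = plant_duplicates(g, sim.duplicate_spec, seed=seeds["duplicates"])
        truth = {"true_q": true_q, "duplicates": dup_truth, "pigment": pig_truth}

        def _write_sim(outputs):
            write_plink(g, out / "simulated")
            pd.DataFrame(true_q).to_csv(out / "true_q.tsv", sep="\t", index=False)
            return {"seed": seeds["simulate"]}

        stage("simulate", ["simulated.bed", "simulated.bim", "simulated.fam", "true_q.tsv"], _write_sim)

    # ---- QC --------------------------------------------------------------
    g1, rep_sites = qc.filter_sites_by_missingness(g, cfg["site_max_missing"])
    g2, rep_samples = qc.filter_samples(g1, cfg["sample_max_missing"], cfg["sample_max_het"])
    log.info("qc: removed %d sites, %d samples", rep_sites.n_sites_removed, rep_samples.n_samples_removed)

    dmat = qc.pairwise_hamming(g2)
    clustering = qc.cluster_near_identical(
        dmat, g2.samples["id"].tolist(), cut_height=cfg["dedup_cut_height"], seed=seeds["dedup"]
    )
    g3 = qc.drop_duplicates(g2, clustering)

    def _write_qc(outputs):
        report = {
            "n_sites_removed": rep_sites.n_sites_removed,
            "n_samples_removed": rep_samples.n_samples_removed,
            "n_duplicate_clusters": len(clustering.clusters),
            "n_samples_final": g3.n_samples,
            "dedup_seed": seeds["dedup"],
        }
        (out / "qc_report.json").write_text(json.dumps(report, indent=2))
        return {}

    stage("qc", ["qc_report.json"], _write_qc)

    pruned_ids = qc.ld_prune(
        g3, cfg["prune_window"], cfg["prune_step"], cfg["prune_r2"],
        cfg["prune_maf"], cfg["prune_missing"],
    )
    g_pruned = g3.subset_variant_ids(pruned_ids)
    stage("prune", ["pruned_ids.txt"], lambda o: (o[0].write_text("\n".join(pruned_ids) + "\n"), {})[1])

    # ---- diversity -------------------------------------------------------
    def _write_div(outputs):
        grouping = dict(zip(g3.samples["id"], g3.samples.get("region", pd.Series(["all"] * g3.n_samples))))
        summaries = diversity.diversity_summary(g3, grouping)
        rows = [
            {
                "group": s.group,
                "n_samples": s.n_samples,
                "n_segregating": s.n_segregating,
                "he": s.he,
                "median_maf_segregating": s.median_maf_segregating,
            }
            for s in summaries
        ]
        pd.DataFrame(rows).to_csv(outputs[0], sep="\t", index=False)
        return {}

    stage("diversity", ["diversity_summary.tsv"], _write_div)

    # ---- structure -------------------------------------------------------
    def _write_structure(outputs):
        runs = structure.run_replicated_admixture(
            g_pruned, cfg["k_min"], cfg["k_max"], cfg["k_replicates"],
            seed=seeds["admixture"],
        )
        logliks = {k: [m.loglik for m in models] for k, models in runs.items()}
        table = structure.evanno_best_k(logliks)
        best_k = table.attrs["best_k"]
        best_model = max(runs[best_k], key=lambda m: m.loglik)
        assignment = structure.assign_clusters(best_model, cfg["assign_threshold"])
        table.to_csv(outputs[0], sep="\t", index=False)
        pd.DataFrame(best_model.Q).to_csv(outputs[1], sep="\t", index=False)
        pd.DataFrame({"id": g_pruned.samples["id"], "cluster": assignment}).to_csv(
            outputs[2], sep="\t", index=False
        )
        coords, var_frac = structure.pca_genotypes(g_pruned, n_components=min(10, g_pruned.n_samples - 1))
        pca = pd.DataFrame(coords, columns=[f"PC{i+1}" for i in range(coords.shape[1])])
        pca.insert(0, "id", g_pruned.samples["id"])
        pca.to_csv(outputs[3], sep="\t", index=False)
        extra = {"best_k": int(best_k), "admixture_seed": seeds["admixture"],
                 "pca_variance_fractions": [float(v) for v in var_frac]}
        groups = [np.flatnonzero(assignment == c) for c in sorted(set(assignment[assignment >= 0]))]
        if len(groups) >= 2 and all(len(gr) >= 2 for gr in groups[:2]):
            extra["fst"] = structure.hudson_fst(g_pruned, groups[0], groups[1])
        return extra

    st_extra = stage(
        "structure",
        ["evanno.tsv", "q_best.tsv", "assignments.tsv", "pca.tsv"],
        _write_structure,
    )

    # ---- LD --------------------------------------------------------------
    def _write_ld(outputs):
        pairs = ld.pairwise_r2_within(g3, cfg["ld_max_distance"])
        profile = ld.ld_decay_profile(pairs, cfg["ld_bin_width"])
        d20, dbg = ld.decay_distances(profile)
        profile.bins.to_csv(outputs[0], sep="\t", index=False)
        summary = {
            "background": profile.background,
            "distance_to_r2_020_bp": d20,
            "distance_to_background_bp": dbg,
        }
        outputs[1].write_text(json.dumps(summary, indent=2))
        return {}

    stage("ld", ["ld_bins.tsv", "ld_summary.json"], _write_ld)

    # ---- GWAS on pigment phenotypes (simulated runs only) ---------------
    if truth is not None:
        def _write_gwas(outputs):
            sim = SimulationConfig(**cfg.get("simulate", {}))
            pheno = simulate_pigment_phenotypes(g, sim.pigment_spec, truth["pigment"])
            kin = assoc.centered_kinship(g3)
            id_pos = {s: i for i, s in enumerate(g3.samples["id"])}
            all_peaks = []
            scans = []
            for trait in pheno.traits("qualitative"):
                y = np.full(g3.n_samples, np.nan)
                for s, v in pheno.data[trait].items():
                    if s in id_pos:
                        y[id_pos[s]] = v
                if np.nansum(y) < 5 or np.nansum(y) > len(y) - 5:
                    continue
                scan = assoc.lmm_scan(
                    g3, y, kinship=kin, trait=trait,
                    min_maf=cfg["gwas_min_maf"], max_missing=cfg["gwas_max_missing"],
                )
                res = scan.results.copy()
                res.insert(0, "trait", trait)
                scans.append(res)
                for p in assoc.call_peaks(scan, g3, cfg["peak_r2"], cfg["peak_gap"]):
                    all_peaks.append(
                        {"trait": trait, "chrom": p.chrom, "start": p.start,
                         "end": p.end, "n_snps": len(p.member_ids),
                         "tag_snp": p.tag_snp, "tag_p": p.tag_p}
                    )
            pd.concat(scans, ignore_index=True).to_csv(outputs[0], sep="\t", index=False)
            pd.DataFrame(all_peaks).to_csv(outputs[1], sep="\t", index=False)
            return {"n_traits_scanned": len(scans)}

        stage("gwas", ["gwas_results.tsv", "gwas_peaks.tsv"], _write_gwas)

    return manifest
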