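"""End-to-end orchestration: simulate/read -> preprocess -> deconvolve -> SVA
-> network -> association -> enrichment -> PTRS, with a machine-readable run
manifest and deterministic per-stage seeding.

The stage order mirrors the analysis flow the package implements: cell-type
mixtures and hidden technical factors are characterized before the network is
built, the network is built on covariate/SV-adjusted expression, and the
association and risk-score stages carry the protected covariates plus the
surrogate variables in their regression designs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import association as assoc
from . import deconvolution as deconv
from . import enrichment as enrich_mod
from . import expression as eio
from . import network as net
from . import ptrs as ptrs_mod
from . import sva as sva_mod
from . import synthetic as synth

log = logging.getLogger("coexpheno")

STAGES = (
    "simulate",
    "preprocess",
    "deconvolve",
    "sva",
    "network",
    "associate",
    "enrich",
    "ptrs",
)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def stage_seed(seed: int, stage: str) -> int:
    """Fan a single run seed out to a per-stage seed (fixed counter scheme)."""
    idx = STAGES.index(stage)
    return int(np.random.SeedSequence(seed).generate_state(len(STAGES))[idx] % 2**31)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def load_config(path: str | Path) -> dict[str, Any]:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    cfg.setdefault("seed", 0)
    cfg.setdefault("stages", list(STAGES))
    return cfg


def run_pipeline(config: dict[str, Any], outdir: str | Path | None = None) -> Path:
    """Execute the enabled stages in order; returns the run directory.

    Outputs per stage are TSV/CSV; ``manifest.json`` records the seed,
    parameters, input checksums and stage outputs, and ``summary.txt`` gives a
    human-readable recap.  A stage failure aborts the run with the stage name;
    partial outputs are retained next to a ``FAILED`` marker.
    """
    outdir = Path(outdir or config.get("outdir", "coexpheno_run"))
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    stages = config.get("stages", list(STAGES))
    manifest: dict[str, Any] = {
        "seed": seed,
        "stages": list(stages),
        "parameters": {k: v for k, v in config.items() if k not in ("stages",)},
        "inputs": {},
        "outputs": {},
    }
    summary: list[str] = []
    state: dict[str, Any] = {}

    def emit(stage: str, name: str, path: Path) -> None:
        manifest["outputs"].setdefault(stage, {})[name] = {
            "path": str(path),
            "sha256": _sha256(path),
        }

    try:
        if "simulate" in stages:
            sim_cfg = synth.SimulationConfig(
                **{**config.get("simulate", {}), "seed": stage_seed(seed, "simulate")}
            )
            cohort = synth.generate_cohort(sim_cfg)
            eio.write_counts(cohort.counts, outdir / "counts.tsv")
            cohort.phenotypes.to_csv(outdir / "phenotypes.csv", index_label="sample_id")
            truth = {
                "modules": cohort.truth_modules.tolist(),
                "factors": cohort.truth_factors.tolist(),
                "proportions": cohort.truth_proportions.tolist(),
                "batch": cohort.truth_batch.tolist(),
                "config": asdict(sim_cfg)
                | {"phenotype_effects": {k: list(map(list, v)) for k, v in sim_cfg.phenotype_effects.items()}},
            }
            (outdir / "truth.json").write_text(json.dumps(truth))
            for name in ("counts.tsv", "phenotypes.csv", "truth.json"):
                emit("simulate", name, outdir / name)
            state["counts"] = cohort.counts
            state["pheno"] = cohort.phenotypes
            summary.append(
                f"simulate: {cohort.counts.n_genes} genes x {cohort.counts.n_samples} samples"
            )
        else:
            inputs = config.get("inputs", {})
            counts_path = Path(inputs["counts"])
            state["counts"] = eio.read_counts(counts_path, format=inputs.get("format", "tsv"))
            state["pheno"] = pd.read_csv(inputs["phenotypes"], index_col="sample_id")
            manifest["inputs"]["counts"] = _sha256(counts_path)
            manifest["inputs"]["phenotypes"] = _sha256(Path(inputs["phenotypes"]))

        covariate_names = list(config.get("covariates", sva_mod.PROTECTED_COVARIATES))
        cov = state["pheno"][covariate_names].to_numpy(dtype=float)

        if "preprocess" in stages:
            p = config.get("preprocess", {})
            filtered = eio.filter_low_abundance(
                state["counts"], p.get("min_cpm", 1.0), p.get("min_fraction", 0.5)
            )
            normalized = eio.cpm_normalize(filtered)
            eio.write_counts(normalized, outdir / "normalized.tsv")
            emit("preprocess", "normalized.tsv", outdir / "normalized.tsv")
            state["normalized"] = normalized
            summary.append(
                f"preprocess: {filtered.n_genes}/{state['counts'].n_genes} genes retained"
            )

        if "deconvolve" in stages and config.get("inputs", {}).get("signature"):
            sig_path = Path(config["inputs"]["signature"])
            signature = eio.read_counts(sig_path, format="tsv")
            manifest["inputs"]["signature"] = _sha256(sig_path)
            props = deconv.estimate_proportions(state["counts"], signature)
            props.to_frame().to_csv(outdir / "proportions.csv", index_label="sample_id")
            emit("deconvolve", "proportions.csv", outdir / "proportions.csv")
            tests = deconv.test_proportion_differences(props, state["pheno"], "group")
            tests.to_frame().to_csv(outdir / "proportion_tests.csv", index=False)
            emit("deconvolve", "proportion_tests.csv", outdir / "proportion_tests.csv")
            summary.append(f"deconvolve: {len(props.celltypes)} cell types estimated")

        svs = None
        if "sva" in stages:
            s = config.get("sva", {})
            k = s.get("k")
            if k is None:
                k = sva_mod.estimate_num_sv(
                    state["normalized"],
                    cov,
                    n_permutations=s.get("n_permutations", 50),
                    seed=stage_seed(seed, "sva"),
                )
            if k > 0:
                svs = sva_mod.estimate_svs(state["normalized"], cov, k=k)
                pd.DataFrame(
                    svs.values,
                    index=state["normalized"].sample_ids,
                    columns=[f"SV{j + 1}" for j in range(svs.k)],
                ).to_csv(outdir / "svs.csv", index_label="sample_id")
                emit("sva", "svs.csv", outdir / "svs.csv")
            summary.append(f"sva: {k} surrogate variable(s)")
        state["svs"] = svs

        if "network" in stages:
            ncfg = config.get("network", {})
            adjusted = sva_mod.residualize_expression(state["normalized"], cov, svs)
            params = net.NetworkParams(
                power=ncfg.get("power") or 6,
                network_type=ncfg.get("network_type", "unsigned"),
                min_module_size=ncfg.get("min_module_size", 30),
                merge_height=ncfg.get("merge_height", 0.15),
            )
            if ncfg.get("power") is None:
                power, sft = net.pick_soft_threshold(adjusted, params=params)
                params.power = power
                sft.to_csv(outdir / "soft_threshold.tsv", sep="\t", index=False)
                emit("network", "soft_threshold.tsv", outdir / "soft_threshold.tsv")
            dissim = net.tom_dissimilarity(net.adjacency(adjusted, params))
            partition = net.detect_modules(dissim, params, expression=adjusted)
            partition.to_frame().to_csv(outdir / "modules.tsv", sep="\t", index=False)
            emit("network", "modules.tsv", outdir / "modules.tsv")
            me = net.module_eigengenes(adjusted, partition)
            me.to_frame().to_csv(outdir / "eigengenes.csv", index_label="sample_id")
            emit("network", "eigengenes.csv", outdir / "eigengenes.csv")
            state["partition"], state["me"] = partition, me
            summary.append(
                f"network: power {params.power}, {partition.n_modules} modules, "
                f"{int((partition.labels == 0).sum())} genes pruned"
            )

        if "associate" in stages:
            acfg = config.get("associate", {})
            table = assoc.associate_modules(
                state["me"],
                state["pheno"],
                covariates=covariate_names,
                svs=svs,
                shift_floor=acfg.get("shift_floor", False),
            )
            table.to_csv(outdir / "associations_modules.tsv", sep="\t", index=False)
            emit("associate", "associations_modules.tsv", outdir / "associations_modules.tsv")
            zmat = table.pivot(index="scale", columns="unit", values="z")
            zmat.to_csv(outdir / "z_matrix.tsv", sep="\t")
            emit("associate", "z_matrix.tsv", outdir / "z_matrix.tsv")
            pairs = assoc.significant_pairs(table)
            gene_table = assoc.associate_genes(
                state["normalized"],
                state["pheno"],
                state["partition"],
                pairs,
                covariates=covariate_names,
                svs=svs,
            )
            gene_table.to_csv(outdir / "associations_genes.tsv", sep="\t", index=False)
            emit("associate", "associations_genes.tsv", outdir / "associations_genes.tsv")
            state["assoc_table"], state["sig_pairs"] = table, pairs
            summary.append(
                f"associate: {len(pairs)} significant scale x module pairs; "
                f"{int((gene_table.fdrp < 0.05).sum()) if len(gene_table) else 0} significant gene tests"
            )

        if "enrich" in stages and config.get("inputs", {}).get("gene_sets"):
            gmt_path = Path(config["inputs"]["gene_sets"])
            collection = enrich_mod.read_gmt(gmt_path)
            manifest["inputs"]["gene_sets"] = _sha256(gmt_path)
            sig_labels = sorted(
                {int(str(u).removeprefix("ME")) for _, u in state.get("sig_pairs", [])}
            )
            table = enrich_mod.enrich_all_modules(
                state["partition"],
                collection,
                state["normalized"].gene_ids,
                labels=sig_labels or None,
            )
            table.to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
            emit("enrich", "enrichment.tsv", outdir / "enrichment.tsv")
            summary.append(f"enrich: {len(table)} module x set tests")

        if "ptrs" in stages:
            pcfg = config.get("ptrs", {})
            mode = pcfg.get("mode", "cv")
            if mode == "cv":
                result = ptrs_mod.crossvalidate_ptrs(
                    state["normalized"],
                    state["pheno"],
                    covariates=covariate_names,
                    scales=pcfg.get("scales", synth.SYNDROME_SCALES),
                    k=pcfg.get("k", 5),
                    thresholds=pcfg.get("thresholds", ptrs_mod.DEFAULT_THRESHOLDS),
                    seed=stage_seed(seed, "ptrs"),
                )
            else:
                tables = [
                    ptrs_mod.TranscriptWeightTable.from_tsv(p) for p in pcfg["weight_tables"]
                ]
                result = ptrs_mod.external_ptrs(
                    state["normalized"],
                    state["pheno"],
                    tables,
                    covariates=covariate_names,
                    thresholds=pcfg.get("thresholds", ptrs_mod.DEFAULT_THRESHOLDS),
                )
            result.table.to_csv(outdir / "ptrs.tsv", sep="\t", index=False)
            result.summary.to_csv(outdir / "ptrs_summary.tsv", sep="\t", index=False)
            emit("ptrs", "ptrs.tsv", outdir / "ptrs.tsv")
            emit("ptrs", "ptrs_summary.tsv", outdir / "ptrs_summary.tsv")
            best = result.summary.loc[result.summary.min_p.idxmin()]
            summary.append(
                f"ptrs ({mode}): best scale {best['scale']} "
                f"max R2 {best['max_r2']:.3f}, min p {best['min_p']:.2g}"
            )
    except Exception as exc:  # noqa: BLE001 - abort with stage context
        (outdir / "FAILED").write_text(f"{type(exc).__name__}: {exc}\n")
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
        if isinstance(exc, StageError):
            raise
        raise StageError(_current_stage(manifest, stages), exc) from exc

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    (outdir / "summary.txt").write_text("\n".join(summary) + "\n")
    for line in summary:
        log.info(line)
    return outdir


def _current_stage(manifest: dict[str, Any], stages: list[str]) -> str:
    done = set(manifest["outputs"])
    for s in stages:
        if s not in done:
            return s
    return stages[-1] if stages else "unknown"
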