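"""End-to-end orchestration.

Each stage communicates with the next only through its documented TSV/CSV
outputs under one run directory (``inputs/`` for the simulated study,
``results/`` for analysis outputs), so any stage can be re-run from files.
A manifest (config hash, seed, per-file checksums) is written last; two runs
with the same config and seed produce identical checksums for every
deterministic stage.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import concordance as conc
from . import enrichment as enr
from . import integrate as integ
from . import io, phenotypes, proteomics, qpcr
from .config import RunConfig
from .simulate import SimulationConfig, simulate_all, write_dataset

logger = logging.getLogger(__name__)

STAGES = ("simulate", "kd_qc", "phenotypes", "proteomics_de", "enrich",
          "concordance", "integrate")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _inp(run_dir: Path) -> Path:
    return Path(run_dir) / "inputs"


def _res(run_dir: Path) -> Path:
    p = Path(run_dir) / "results"
    p.mkdir(parents=True, exist_ok=True)
    return p


# ---------------------------------------------------------------------------
# stages (file -> file)
# ---------------------------------------------------------------------------

def stage_simulate(sim_cfg: SimulationConfig, run_dir: Path) -> list[Path]:
    data = simulate_all(sim_cfg)
    paths = write_dataset(data, _inp(run_dir))
    map_path = _inp(run_dir) / "target_map.tsv"
    pd.DataFrame(sorted(data.truth.target_gene.items()),
                 columns=["target", "gene"]).to_csv(map_path, sep="\t", index=False)
    return [*paths.values(), map_path]


def stage_kd_qc(run_dir: Path) -> list[Path]:
    ct = io.read_ct_table(_inp(run_dir) / "qpcr_ct.tsv")
    out = _res(run_dir) / "knockdown_efficiency.tsv"
    io.write_table(out, qpcr.summarize_knockdown(ct))
    return [out]


def stage_phenotypes(run_cfg: RunConfig, run_dir: Path) -> list[Path]:
    table = io.read_assay_table(_inp(run_dir) / "assay_data.csv")
    effects = phenotypes.analyze_assays(table, run_cfg)
    discord = phenotypes.direction_discordance(effects)
    p1 = _res(run_dir) / "assay_effects.tsv"
    p2 = _res(run_dir) / "assay_direction_discordance.tsv"
    io.write_table(p1, effects, columns=["assay", "dose", "target", "cell_line",
                                         "estimate", "se", "p", "p_adj", "hit",
                                         "n_batches", "method"])
    io.write_table(p2, discord)
    logger.info("phenotypes: %d effects, %d hits", len(effects),
                int(effects["hit"].sum()))
    return [p1, p2]


def stage_proteomics(run_cfg: RunConfig, run_dir: Path) -> list[Path]:
    pm = io.read_protein_matrix(_inp(run_dir) / "protein_matrix.tsv",
                                _inp(run_dir) / "sample_metadata.tsv")
    de, anova, skipped, qc = proteomics.differential_abundance(pm, run_cfg)
    tmap = pd.read_csv(_inp(run_dir) / "target_map.tsv", sep="\t", dtype=str)
    self_eff = proteomics.target_self_effect(de, dict(zip(tmap["target"],
                                                          tmap["gene"])))
    res = _res(run_dir)
    outs = {
        "de.tsv": (de, proteomics.DE_COLUMNS),
        "anova.tsv": (anova, None),
        "de_skipped.tsv": (skipped, None),
        "qc_excluded_samples.tsv": (qc.excluded, None),
        "target_self_effects.tsv": (self_eff, None),
    }
    paths = []
    for name, (df, cols) in outs.items():
        p = res / name
        io.write_table(p, df, columns=cols)
        paths.append(p)
    logger.info("proteomics: %d contrasts, %d significant; %d samples excluded",
                len(de), int(de["significant"].sum()), len(qc.excluded))
    return paths


def _disease_ranking(run_dir: Path) -> pd.Series:
    disease = io.read_disease_effects(_inp(run_dir) / "disease_effects.tsv")
    orthos = io.read_ortholog_map(_inp(run_dir) / "ortholog_map.tsv")
    mouse_to_human, _ = conc.resolve_orthologs(orthos)
    effect = dict(zip(disease["gene"], disease["effect"]))
    rows = {m: effect[h] for m, h in mouse_to_human.items() if h in effect}
    return pd.Series(rows, name="stat").rename_axis("gene")


def stage_enrichment(run_cfg: RunConfig, run_dir: Path) -> list[Path]:
    de = io.read_table(_res(run_dir) / "de.tsv")
    coll = io.read_gmt(_inp(run_dir) / "gene_sets.gmt")
    bdmap = io.read_biodomain_map(_inp(run_dir) / "biodomains.tsv")
    contrasts = sorted(set(zip(de["target"], de["cell_line"])))
    seeds = np.random.SeedSequence(run_cfg.seed).spawn(len(contrasts) + 1)

    ranked_disease = enr.RankedList.from_series(_disease_ranking(run_dir))
    dis_res, dis_skip = enr.enrich_collection(
        ranked_disease, coll, bdmap, run_cfg, np.random.default_rng(seeds[0]))

    kd_parts, skip_parts = [], []
    for i, (target, line) in enumerate(contrasts):
        ranking = enr.ranking_from_de(de, target, line)
        ranked = enr.RankedList.from_series(ranking)
        res, skip = enr.enrich_collection(ranked, coll, bdmap, run_cfg,
                                          np.random.default_rng(seeds[i + 1]))
        res.insert(0, "cell_line", line)
        res.insert(0, "target", target)
        skip.insert(0, "cell_line", line)
        skip.insert(0, "target", target)
        kd_parts.append(res)
        skip_parts.append(skip)
    kd_res = pd.concat(kd_parts, ignore_index=True)
    res_dir = _res(run_dir)
    p1 = res_dir / "knockdown_enrichment.tsv"
    p2 = res_dir / "disease_enrichment.tsv"
    p3 = res_dir / "enrichment_skipped.tsv"
    io.write_table(p1, kd_res)
    io.write_table(p2, dis_res)
    io.write_table(p3, pd.concat(skip_parts + [dis_skip], ignore_index=True))
    logger.info("enrichment: %d knockdown results over %d contrasts",
                len(kd_res), len(contrasts))
    return [p1, p2, p3]


def stage_concordance(run_cfg: RunConfig, run_dir: Path) -> list[Path]:
    res_dir = _res(run_dir)
    kd = io.read_table(res_dir / "knockdown_enrichment.tsv")
    dis = io.read_table(res_dir / "disease_enrichment.tsv")
    bdmap = io.read_biodomain_map(_inp(run_dir) / "biodomains.tsv")
    de = io.read_table(res_dir / "de.tsv")
    disease = io.read_disease_effects(_inp(run_dir) / "disease_effects.tsv")
    orthos = io.read_ortholog_map(_inp(run_dir) / "ortholog_map.tsv")
    coll = io.read_gmt(_inp(run_dir) / "gene_sets.gmt")

    pair_parts = []
    for (target, line), sub in kd.groupby(["target", "cell_line"], sort=True):
        pairs = conc.zero_impute_pairs(sub, dis, bdmap, run_cfg.alpha)
        pairs.insert(0, "cell_line", line)
        pairs.insert(0, "target", target)
        pair_parts.append(pairs)
    pair_table = pd.concat(pair_parts, ignore_index=True)
    kendall = conc.domain_kendall(pair_table, run_cfg.alpha,
                                  run_cfg.min_terms_per_domain)
    quadrants = conc.quadrant_counts(pair_table)
    pearson, ortho_report = conc.domain_protein_pearson(
        de, disease, orthos, coll, bdmap, run_cfg.alpha,
        run_cfg.min_proteins_per_domain)
    paths = []
    for name, df in (("term_pairs.tsv", pair_table),
                     ("domain_kendall.tsv", kendall),
                     ("quadrants.tsv", quadrants),
                     ("domain_pearson.tsv", pearson),
                     ("ortholog_report.tsv", ortho_report)):
        p = res_dir / name
        io.write_table(p, df)
        paths.append(p)
    n_rev = int((kendall["direction"] == "reversal").sum()) if len(kendall) else 0
    logger.info("concordance: %d domain tests, %d reversals", len(kendall), n_rev)
    return paths


def stage_integration(run_cfg: RunConfig, run_dir: Path) -> list[Path]:
    res_dir = _res(run_dir)
    effects = io.read_table(res_dir / "assay_effects.tsv")
    kd = io.read_table(res_dir / "knockdown_enrichment.tsv")
    kendall = io.read_table(res_dir / "domain_kendall.tsv")
    corr = integ.phenotype_nes_correlation(effects, kd, run_cfg)
    rule = integ.TopTierRule.from_config(run_cfg)
    verdicts = integ.call_top_tier(effects, kendall, rule, corr)
    p1 = res_dir / "phenotype_term_corr.tsv"
    p2 = res_dir / "verdicts.tsv"
    io.write_table(p1, corr)
    io.write_table(p2, verdicts)
    logger.info("integration: %d top-tier target(s): %s",
                int(verdicts["top_tier"].sum()),
                ", ".join(verdicts.loc[verdicts["top_tier"], "target"]))
    return [p1, p2]


# ---------------------------------------------------------------------------
# run-all
# ---------------------------------------------------------------------------

def run_all(run_cfg: RunConfig, sim_cfg: SimulationConfig,
            out_dir: str | Path, resume: bool = False) -> dict:
    """Run every stage under ``out_dir`` and write ``manifest.json`` last.

    With ``resume=True`` an existing ``inputs/`` directory is reused instead
    of re-simulating.  On failure a ``FAILED`` marker naming the stage is
    left in the run directory and a :class:`PipelineError` is raised.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    config_doc = yaml.safe_dump({"run": run_cfg.to_dict(),
                                 "simulation": sim_cfg.to_dict()},
                                sort_keys=True)
    (out_dir / "config.yaml").write_text(config_doc)
    stage_outputs: dict[str, list[str]] = {}

    def _run(name: str, fn, *args):
        t0 = time.time()
        try:
            paths = fn(*args)
        except Exception as exc:  # noqa: BLE001 - must name the stage
            (out_dir / "FAILED").write_text(
                f"stage: {name}\nerror: {exc}\n"
                f"completed_stages: {list(stage_outputs)}\n")
            raise PipelineError(name, exc) from exc
        stage_outputs[name] = [str(Path(p).relative_to(out_dir)) for p in paths]
        logger.info("stage %s: %d output(s) in %.1fs", name, len(paths),
                    time.time() - t0)

    marker = out_dir / "FAILED"
    if marker.exists():
        marker.unlink()
    if resume and (_inp(out_dir) / "assay_data.csv").exists():
        stage_outputs["simulate"] = sorted(
            str(p.relative_to(out_dir)) for p in _inp(out_dir).iterdir())
    else:
        _run("simulate", stage_simulate, sim_cfg, out_dir)
    _run("kd_qc", stage_kd_qc, out_dir)
    _run("phenotypes", stage_phenotypes, run_cfg, out_dir)
    _run("proteomics_de", stage_proteomics, run_cfg, out_dir)
    _run("enrich", stage_enrichment, run_cfg, out_dir)
    _run("concordance", stage_concordance, run_cfg, out_dir)
    _run("integrate", stage_integration, run_cfg, out_dir)

    manifest = {
        "config_sha256": hashlib.sha256(config_doc.encode()).hexdigest(),
        "seed": {"run": run_cfg.seed, "simulation": sim_cfg.seed},
        "stages": {
            name: {p: _sha256(out_dir / p) for p in paths}
            for name, paths in stage_outputs.items()
        },
        "created": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                      sort_keys=True))
    return manifest
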