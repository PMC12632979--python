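"""Synthetic screening study with planted ground truth.

Generates every input the pipeline consumes: gene-set annotation with a
domain structure, a disease effect vector, knockdown proteomes, replicate
assay tables with batch structure, qPCR Ct tables, and an ortholog map.

The generative model mirrors the screening design it emulates:

* assay readouts are ``baseline * 2^effect * 2^(batch intercept) * lognormal
  noise`` with batch intercepts ~ Normal(0, batch SD) shared by every
  condition measured in that batch;
* the sensitized cell line amplifies planted assay effects (default 1.5x);
* a planted "reversal" knockdown shifts each gene of its planted domains by
  ``-c * (that gene's disease effect)`` plus gene-level noise — i.e. it
  mirrors the disease signature, which is what gives per-domain *rank*
  correlations their sign;
* every knockdown lowers its own target protein;
* proteome missingness is completely at random by default, with a couple of
  low-quality samples (high dropout) planted for the QC filter to catch.

Default parameters define the reference study: 12 targets (3 with planted
dual evidence, 2 with assay effects only, 7 null), 2 cell lines, 4 assays,
2,000 proteins, 100 terms over 6 domains.  All draws come from one seeded
stream; identical seeds give byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from .config import RunConfig
from .containers import BiodomainMap, GeneSetCollection, ProteinMatrix
from .phenotypes import CONTROL_SIRNA

DEFAULT_DOMAINS = (
    "Immune Response",
    "Mitochondrial Metabolism",
    "Oxidative Stress",
    "Synapse",
    "Lipid Metabolism",
    "Proteostasis",
)


def _default_assay_design() -> dict:
    # (batches, replicates per batch), echoing the screen's published design
    return {"alamarBlue": (3, 3), "MitoTracker": (7, 3),
            "phagocytosis": (3, 4), "NFkB": (3, 5)}


def _default_assay_directions() -> dict:
    return {"alamarBlue": -1.0, "MitoTracker": -1.0,
            "phagocytosis": 1.0, "NFkB": 1.0}


@dataclass
class SimulationConfig:
    """Ground-truth generating parameters; defaults are the reference study."""

    # targets
    n_targets: int = 12
    n_dual_evidence: int = 3
    n_assay_only: int = 2
    n_proteome_only: int = 0

    # cell system
    cell_lines: tuple[str, ...] = ("scramble", "psen2_kd")
    sensitized_line: str = "psen2_kd"
    sensitization: float = 1.5

    # assays (log2 units / raw plate-reader scale)
    assays: tuple[str, ...] = ("alamarBlue", "MitoTracker", "phagocytosis", "NFkB")
    dosed_assay: str = "NFkB"
    doses: tuple[float, ...] = (0.0, 0.1)
    assay_design: dict = field(default_factory=_default_assay_design)
    assay_directions: dict = field(default_factory=_default_assay_directions)
    assay_effect_log2: float = 1.0
    batch_sd: float = 0.25
    residual_sd: float = 0.2
    assay_baseline: float = 1000.0
    lps_response_log2: float = 2.0

    # annotation
    n_proteins: int = 2000
    n_terms: int = 100
    term_size_range: tuple[int, int] = (10, 40)
    domains: tuple[str, ...] = DEFAULT_DOMAINS
    genes_per_domain: int = 200
    multi_domain_fraction: float = 0.0

    # disease signature
    disease_up_domains: tuple[str, ...] = ("Immune Response", "Oxidative Stress")
    disease_down_domains: tuple[str, ...] = ("Mitochondrial Metabolism", "Synapse")
    disease_effect_mean: float = 1.0
    disease_effect_sd: float = 0.5

    # knockdown proteomes (log2 scale)
    reversal_domains: tuple[str, ...] = ("Immune Response", "Mitochondrial Metabolism")
    reversal_strength: float = 0.8
    proteome_effect_sd: float = 0.3
    proteome_noise_sd: float = 0.3
    baseline_mean: float = 20.0
    baseline_sd: float = 1.5
    line_effect_sd: float = 0.3
    knockdown_self_log2fc: float = -1.5
    knockdown_exempt: tuple[str, ...] = ()
    replicates_per_group: int = 5
    dropout_rate: float = 0.10
    intensity_dependent_dropout: bool = False
    n_low_quality_samples: int = 2
    low_quality_dropout: float = 0.75

    # cross-species map
    n_ambiguous_orthologs: int = 10

    # qPCR
    qpcr_knockdown_fraction: float = 0.7
    qpcr_ct_noise_sd: float = 0.15
    qpcr_replicates: int = 3
    qpcr_reference_ct: float = 20.0
    qpcr_gene_ct: float = 25.0

    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_targets", "n_proteins", "n_terms", "replicates_per_group",
                     "qpcr_replicates"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("batch_sd", "residual_sd", "proteome_effect_sd",
                     "proteome_noise_sd", "disease_effect_sd", "qpcr_ct_noise_sd",
                     "baseline_sd", "line_effect_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")
        planted = self.n_dual_evidence + self.n_assay_only + self.n_proteome_only
        if planted > self.n_targets:
            raise ValueError("planted target counts exceed n_targets")
        lo, hi = self.term_size_range
        if not 2 <= lo <= hi:
            raise ValueError("term_size_range must satisfy 2 <= lo <= hi")
        if hi > self.genes_per_domain:
            raise ValueError(
                f"max term size {hi} exceeds genes_per_domain "
                f"{self.genes_per_domain}: infeasible annotation")
        if len(self.domains) * self.genes_per_domain > self.n_proteins:
            raise ValueError("domain gene pools exceed n_proteins")
        unknown = [d for d in (*self.disease_up_domains, *self.disease_down_domains,
                               *self.reversal_domains) if d not in self.domains]
        if unknown:
            raise ValueError(f"domains {unknown!r} not in the declared vocabulary")

    @property
    def targets(self) -> tuple[str, ...]:
        return tuple(f"T{i + 1:02d}" for i in range(self.n_targets))

    @property
    def dual_evidence_targets(self) -> tuple[str, ...]:
        return self.targets[: self.n_dual_evidence]

    @property
    def assay_only_targets(self) -> tuple[str, ...]:
        a = self.n_dual_evidence
        return self.targets[a: a + self.n_assay_only]

    @property
    def proteome_only_targets(self) -> tuple[str, ...]:
        a = self.n_dual_evidence + self.n_assay_only
        return self.targets[a: a + self.n_proteome_only]

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for key, val in d.items():
            if isinstance(val, tuple):
                d[key] = list(val)
        d["term_size_range"] = list(self.term_size_range)
        d["assay_design"] = {k: list(v) for k, v in self.assay_design.items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown simulation-config keys: {sorted(unknown)!r}")
        d = dict(d)
        for f in dataclasses.fields(cls):
            if f.name in d and isinstance(getattr(cls, f.name, None), tuple):
                d[f.name] = tuple(d[f.name])
        for name in ("cell_lines", "assays", "doses", "domains",
                     "disease_up_domains", "disease_down_domains",
                     "reversal_domains", "knockdown_exempt", "term_size_range"):
            if name in d and isinstance(d[name], list):
                d[name] = tuple(d[name])
        if "assay_design" in d:
            d["assay_design"] = {k: tuple(v) for k, v in d["assay_design"].items()}
        return cls(**d)


@dataclass
class SyntheticTruth:
    """Planted ground truth, serializable next to the generated data."""

    assay_effects: pd.DataFrame     # target, cell_line, assay, dose, effect
    reversal_domains: dict          # target -> {domain: -1 (reversed) | +1}
    disease_up_domains: tuple
    disease_down_domains: tuple
    target_gene: dict               # target -> silenced mouse protein
    low_quality_samples: tuple
    dual_evidence_targets: tuple
    assay_only_targets: tuple
    proteome_only_targets: tuple

    def summary_frame(self) -> pd.DataFrame:
        rows = []
        all_targets = sorted(self.target_gene)
        for t in all_targets:
            if t in self.dual_evidence_targets:
                cls = "dual_evidence"
            elif t in self.assay_only_targets:
                cls = "assay_only"
            elif t in self.proteome_only_targets:
                cls = "proteome_only"
            else:
                cls = "null"
            doms = self.reversal_domains.get(t, {})
            rows.append({
                "target": t, "truth_class": cls,
                "gene": self.target_gene[t],
                "reversal_domains": ";".join(
                    f"{d}:{'-' if s < 0 else '+'}" for d, s in sorted(doms.items())),
            })
        return pd.DataFrame(rows, columns=["target", "truth_class", "gene",
                                           "reversal_domains"])


def _mouse_gene(i: int) -> str:
    return f"g{i + 1:04d}"


def _human_gene(i: int) -> str:
    return f"H{i + 1:04d}"


def domain_pools(config: SimulationConfig) -> dict[str, list[str]]:
    """Disjoint per-domain gene pools (first block of the gene universe)."""
    pools = {}
    for di, d in enumerate(config.domains):
        start = di * config.genes_per_domain
        pools[d] = [_mouse_gene(i) for i in range(start, start + config.genes_per_domain)]
    return pools


def generate_annotation(config: SimulationConfig, rng: np.random.Generator):
    """Gene sets + domain map: each term samples genes from one domain pool."""
    pools = domain_pools(config)
    n_dom = len(config.domains)
    counts = [config.n_terms // n_dom + (1 if i < config.n_terms % n_dom else 0)
              for i in range(n_dom)]
    coll = GeneSetCollection()
    entries: dict[str, tuple[str, ...]] = {}
    lo, hi = config.term_size_range
    term_i = 0
    for di, domain in enumerate(config.domains):
        pool = pools[domain]
        for _ in range(counts[di]):
            size = int(rng.integers(lo, hi + 1))
            genes = sorted(rng.choice(pool, size=size, replace=False))
            term_id = f"term{term_i + 1:03d}"
            coll.add(term_id, domain, genes)
            doms = [domain]
            if (config.multi_domain_fraction > 0
                    and rng.random() < config.multi_domain_fraction):
                other = [d for d in config.domains if d != domain]
                doms.append(str(rng.choice(other)))
            entries[term_id] = tuple(doms)
            term_i += 1
    bdmap = BiodomainMap(entries, vocabulary=tuple(config.domains))
    return coll, bdmap


def make_truth(config: SimulationConfig) -> SyntheticTruth:
    """Deterministic planted-truth layout implied by the config."""
    effects = []
    assay_targets = set(config.dual_evidence_targets) | set(config.assay_only_targets)
    for assay in config.assays:
        direction = config.assay_directions.get(assay, 1.0)
        doses = config.doses if assay == config.dosed_assay else (np.nan,)
        for dose in doses:
            for line in config.cell_lines:
                amp = config.sensitization if line == config.sensitized_line else 1.0
                for t in config.targets:
                    eff = (direction * config.assay_effect_log2 * amp
                           if t in assay_targets else 0.0)
                    effects.append({"target": t, "cell_line": line,
                                    "assay": assay, "dose": dose, "effect": eff})
    reversal = {}
    for t in (*config.dual_evidence_targets, *config.proteome_only_targets):
        reversal[t] = {d: -1 for d in config.reversal_domains}
    # silenced proteins live outside the domain pools (background genes)
    bg_start = len(config.domains) * config.genes_per_domain
    if bg_start + config.n_targets > config.n_proteins:
        bg_start = config.n_proteins - config.n_targets
    target_gene = {t: _mouse_gene(bg_start + i)
                   for i, t in enumerate(config.targets)}
    return SyntheticTruth(
        assay_effects=pd.DataFrame(effects),
        reversal_domains=reversal,
        disease_up_domains=tuple(config.disease_up_domains),
        disease_down_domains=tuple(config.disease_down_domains),
        target_gene=target_gene,
        low_quality_samples=(),
        dual_evidence_targets=tuple(config.dual_evidence_targets),
        assay_only_targets=tuple(config.assay_only_targets),
        proteome_only_targets=tuple(config.proteome_only_targets),
    )


def generate_disease_effects(config: SimulationConfig,
                             rng: np.random.Generator) -> pd.DataFrame:
    """Human-id disease effect table: +mean in disease-up domains, -mean in
    disease-down domains, 0-centered elsewhere, plus Normal noise."""
    pools = domain_pools(config)
    mean = np.zeros(config.n_proteins)
    gene_index = {_mouse_gene(i): i for i in range(config.n_proteins)}
    for d in config.disease_up_domains:
        for g in pools[d]:
            mean[gene_index[g]] = config.disease_effect_mean
    for d in config.disease_down_domains:
        for g in pools[d]:
            mean[gene_index[g]] = -config.disease_effect_mean
    effect = mean + rng.normal(0.0, config.disease_effect_sd, config.n_proteins)
    return pd.DataFrame({"gene": [_human_gene(i) for i in range(config.n_proteins)],
                         "effect": effect})


def generate_ortholog_map(config: SimulationConfig,
                          rng: np.random.Generator) -> pd.DataFrame:
    """One-to-one human<->mouse pairs plus a few planted one-to-many pairs."""
    rows = [{"human": _human_gene(i), "mouse": _mouse_gene(i)}
            for i in range(config.n_proteins)]
    bg_start = len(config.domains) * config.genes_per_domain
    n_amb = min(config.n_ambiguous_orthologs,
                max(0, config.n_proteins - bg_start - config.n_targets))
    amb_pool = [_mouse_gene(bg_start + config.n_targets + i) for i in range(n_amb)]
    for i, mouse in enumerate(amb_pool):
        rows.append({"human": f"HAMB{i + 1:02d}", "mouse": mouse})
    return pd.DataFrame(rows, columns=["human", "mouse"])


def mouse_disease_effects(config: SimulationConfig,
                          disease: pd.DataFrame) -> dict[str, float]:
    """Disease effects re-keyed by mouse gene via the canonical 1:1 pairing."""
    human_to_idx = {_human_gene(i): i for i in range(config.n_proteins)}
    out = {}
    for row in disease.itertuples():
        idx = human_to_idx.get(row.gene)
        if idx is not None:
            out[_mouse_gene(idx)] = float(row.effect)
    return out


def generate_knockdown_proteomes(config: SimulationConfig,
                                 disease: pd.DataFrame,
                                 truth: SyntheticTruth,
                                 rng: np.random.Generator) -> ProteinMatrix:
    """Proteins x samples log2 matrix with planted domain reversals."""
    pools = domain_pools(config)
    genes = [_mouse_gene(i) for i in range(config.n_proteins)]
    gene_index = {g: i for i, g in enumerate(genes)}
    d_mouse = mouse_disease_effects(config, disease)
    disease_vec = np.array([d_mouse.get(g, 0.0) for g in genes])

    baseline = rng.normal(config.baseline_mean, config.baseline_sd,
                          config.n_proteins)
    line_offset = rng.normal(0.0, config.line_effect_sd, config.n_proteins)

    groups = [CONTROL_SIRNA, *config.targets]
    # fixed per-target gene shifts (shared across cell lines and replicates)
    shifts = {}
    for t in config.targets:
        s = np.zeros(config.n_proteins)
        doms = truth.reversal_domains.get(t, {})
        for d, sign in doms.items():
            idx = np.array([gene_index[g] for g in pools[d]])
            dev = rng.normal(0.0, config.proteome_effect_sd, idx.size)
            s[idx] = sign * config.reversal_strength * disease_vec[idx] + dev
        gene = truth.target_gene.get(t)
        if gene is not None and t not in config.knockdown_exempt:
            s[gene_index[gene]] += config.knockdown_self_log2fc
        shifts[t] = s

    cols, meta_rows, data = [], [], []
    for line in config.cell_lines:
        loff = line_offset if line == config.sensitized_line else 0.0
        for group in groups:
            shift = shifts.get(group, 0.0)
            for rep in range(config.replicates_per_group):
                sid = f"{line}.{group}.r{rep + 1}"
                noise = rng.normal(0.0, config.proteome_noise_sd,
                                   config.n_proteins)
                data.append(baseline + loff + shift + noise)
                cols.append(sid)
                meta_rows.append({"sample": sid, "target": group,
                                  "cell_line": line, "replicate": str(rep + 1)})
    values = np.column_stack(data)

    # missingness
    n_samples = values.shape[1]
    rates = np.full(n_samples, config.dropout_rate)
    n_lq = min(config.n_low_quality_samples, n_samples)
    lq_idx = rng.choice(n_samples, size=n_lq, replace=False) if n_lq else np.array([], int)
    rates[lq_idx] = config.low_quality_dropout
    if config.intensity_dependent_dropout:
        # lower-intensity proteins are likelier to drop out
        rank = baseline.argsort().argsort() / max(config.n_proteins - 1, 1)
        prob = rates[None, :] * (2.0 * (1.0 - rank))[:, None]
        mask = rng.random(values.shape) < np.clip(prob, 0.0, 1.0)
    else:
        mask = rng.random(values.shape) < rates[None, :]
    values = np.where(mask, np.nan, values)

    truth.low_quality_samples = tuple(cols[i] for i in sorted(lq_idx))
    vdf = pd.DataFrame(values, index=genes, columns=cols)
    meta = pd.DataFrame(meta_rows).set_index("sample")
    return ProteinMatrix(vdf, meta)


def generate_assay_data(config: SimulationConfig, truth: SyntheticTruth,
                        rng: np.random.Generator) -> pd.DataFrame:
    """Replicate-level raw assay readouts with batch intercepts."""
    eff = {(r.target, r.cell_line, r.assay,
            None if pd.isna(r.dose) else float(r.dose)): float(r.effect)
           for r in truth.assay_effects.itertuples()}
    rows = []
    for assay in config.assays:
        batches, reps = config.assay_design.get(assay, (3, 3))
        doses = config.doses if assay == config.dosed_assay else (np.nan,)
        intercepts = rng.normal(0.0, config.batch_sd, batches)
        for b in range(batches):
            batch_id = f"{assay}.b{b + 1}"
            for dose in doses:
                dkey = None if pd.isna(dose) else float(dose)
                lps = (config.lps_response_log2
                       if (dkey is not None and dkey > 0) else 0.0)
                for line in config.cell_lines:
                    for target in (CONTROL_SIRNA, *config.targets):
                        effect = eff.get((target, line, assay, dkey), 0.0)
                        noise = rng.normal(0.0, config.residual_sd, reps)
                        vals = (config.assay_baseline
                                * 2.0 ** (effect + lps + intercepts[b] + noise))
                        for r in range(reps):
                            rows.append({
                                "assay": assay, "target": target,
                                "cell_line": line, "dose": dose,
                                "batch": batch_id, "replicate": f"r{r + 1}",
                                "value": vals[r],
                            })
    return pd.DataFrame(rows, columns=io.ASSAY_COLUMNS)


def generate_qpcr_data(config: SimulationConfig, truth: SyntheticTruth,
                       rng: np.random.Generator) -> pd.DataFrame:
    """Triplicate Ct tables consistent with the configured knockdown."""
    fold = 1.0 - config.qpcr_knockdown_fraction
    ddct = -np.log2(fold)
    rows = []
    for t in sorted(truth.target_gene):
        for condition, shift in (("control", 0.0), ("target", ddct)):
            for rep in range(config.qpcr_replicates):
                rows.append({
                    "gene": t, "condition": condition,
                    "replicate": f"r{rep + 1}",
                    "ct_gene": config.qpcr_gene_ct + shift
                    + rng.normal(0.0, config.qpcr_ct_noise_sd),
                    "ct_reference": config.qpcr_reference_ct
                    + rng.normal(0.0, config.qpcr_ct_noise_sd),
                })
    return pd.DataFrame(rows, columns=io.CT_COLUMNS)


@dataclass
class SyntheticData:
    config: SimulationConfig
    truth: SyntheticTruth
    collection: GeneSetCollection
    bdmap: BiodomainMap
    disease_effects: pd.DataFrame
    ortholog_map: pd.DataFrame
    proteome: ProteinMatrix
    assay_table: pd.DataFrame
    ct_table: pd.DataFrame


def simulate_all(config: SimulationConfig,
                 out_dir: str | Path | None = None) -> SyntheticData:
    """Generate the complete input bundle; optionally write it to ``out_dir``.

    Stage-wise child seeds keep every output byte-identical for a given seed
    regardless of which other stages are consumed.
    """
    children = np.random.SeedSequence(config.seed).spawn(6)
    rngs = [np.random.default_rng(s) for s in children]
    truth = make_truth(config)
    coll, bdmap = generate_annotation(config, rngs[0])
    disease = generate_disease_effects(config, rngs[1])
    orthologs = generate_ortholog_map(config, rngs[2])
    proteome = generate_knockdown_proteomes(config, disease, truth, rngs[3])
    assay = generate_assay_data(config, truth, rngs[4])
    ct = generate_qpcr_data(config, truth, rngs[5])
    data = SyntheticData(config=config, truth=truth, collection=coll,
                         bdmap=bdmap, disease_effects=disease,
                         ortholog_map=orthologs, proteome=proteome,
                         assay_table=assay, ct_table=ct)
    if out_dir is not None:
        write_dataset(data, out_dir)
    return data


def write_dataset(data: SyntheticData, out_dir: str | Path) -> dict[str, Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "gene_sets": out / "gene_sets.gmt",
        "biodomains": out / "biodomains.tsv",
        "protein_matrix": out / "protein_matrix.tsv",
        "sample_metadata": out / "sample_metadata.tsv",
        "assay_table": out / "assay_data.csv",
        "ct_table": out / "qpcr_ct.tsv",
        "disease_effects": out / "disease_effects.tsv",
        "ortholog_map": out / "ortholog_map.tsv",
        "truth_assay_effects": out / "truth_assay_effects.tsv",
        "truth_summary": out / "truth_summary.tsv",
    }
    io.write_gmt(paths["gene_sets"], data.collection)
    io.write_biodomain_map(paths["biodomains"], data.bdmap)
    io.write_protein_matrix(paths["protein_matrix"], paths["sample_metadata"],
                            data.proteome)
    io.write_assay_table(paths["assay_table"], data.assay_table)
    io.write_ct_table(paths["ct_table"], data.ct_table)
    io.write_disease_effects(paths["disease_effects"], data.disease_effects)
    io.write_ortholog_map(paths["ortholog_map"], data.ortholog_map)
    io.write_table(paths["truth_assay_effects"], data.truth.assay_effects)
    io.write_table(paths["truth_summary"], data.truth.summary_frame())
    return paths


def default_run_config(seed: int = 0) -> RunConfig:
    """Run parameters matched to the reference synthetic study's scale.

    The QC threshold keeps the same detected-fraction margin the published
    screen used, rescaled to the 2,000-protein world; the permutation count
    is the test-scale default.
    """
    return RunConfig(n_permutations=999, qc_min_proteins=1600, seed=seed)
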