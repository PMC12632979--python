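"""Run configuration: every analysis threshold lives here, with the
screening study's published values as defaults."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass
class RunConfig:
    """Declarative analysis parameters.

    Defaults mirror the screening study: BH-adjusted p <= 0.05 everywhere,
    samples with fewer than 6,100 quantified proteins excluded, classic
    preranked GSEA with weight 1 and 10..500 set sizes.
    """

    # significance
    alpha: float = 0.05

    # preranked GSEA
    n_permutations: int = 10_000
    gsea_weight: float = 1.0
    min_set_size: int = 10
    max_set_size: int = 500

    # proteomics QC / differential abundance
    qc_min_proteins: int = 6_100
    min_obs_per_group: int = 3
    pool_cell_lines_anova: bool = False

    # concordance
    min_terms_per_domain: int = 5
    min_proteins_per_domain: int = 10

    # integration
    min_integration_obs: int = 10

    # BH families (narrowest defensible reading; see methods note)
    phenotype_bh_family: str = "assay_cell_dose"  # or "assay"
    concordance_bh_family: str = "run"

    # mixed-model inference reference distribution for Wald tests
    wald_reference: str = "normal"  # or "t"

    # top-tier rule
    min_assay_hits: int = 1
    min_reversal_domains: int = 1
    require_reversal_direction: bool = True
    domain_whitelist: tuple[str, ...] | None = None

    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.n_permutations < 99:
            raise ValueError("n_permutations must be >= 99")
        if self.min_set_size < 2:
            raise ValueError("min_set_size must be >= 2")
        if self.max_set_size < self.min_set_size:
            raise ValueError("max_set_size must be >= min_set_size")
        if self.qc_min_proteins < 0:
            raise ValueError("qc_min_proteins must be >= 0")
        if self.phenotype_bh_family not in ("assay_cell_dose", "assay"):
            raise ValueError(f"unknown phenotype_bh_family {self.phenotype_bh_family!r}")
        if self.wald_reference not in ("normal", "t"):
            raise ValueError(f"unknown wald_reference {self.wald_reference!r}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if d["domain_whitelist"] is not None:
            d["domain_whitelist"] = list(d["domain_whitelist"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown run-config keys: {sorted(unknown)!r}")
        d = dict(d)
        if d.get("domain_whitelist") is not None:
            d["domain_whitelist"] = tuple(d["domain_whitelist"])
        return cls(**d)


def load_config(path) -> tuple[RunConfig, dict]:
    """Load a YAML config file.

    Returns ``(RunConfig, simulation_section)`` where the second element is the
    raw ``simulation:`` mapping (empty dict when absent) for
    :func:`targetscreen.simulate.SimulationConfig.from_dict`.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    run = RunConfig.from_dict(raw.get("run", {}))
    return run, raw.get("simulation", {})


def save_config(path, run: RunConfig, simulation: dict | None = None) -> None:
    doc: dict = {"run": run.to_dict()}
    if simulation:
        doc["simulation"] = simulation
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=True))
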