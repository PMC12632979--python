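"""Core in-memory containers shared across pipeline stages.

Gene identifiers are case-sensitive opaque strings throughout; no symbol
normalization is ever applied (cross-species joins go through an explicit
ortholog map instead).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: The TREAT-AD biological domains: a fixed vocabulary of AD-relevant
#: functional areas, each defined by a set of GO terms.
TREAT_AD_BIODOMAINS: tuple[str, ...] = (
    "APP Metabolism",
    "Apoptosis",
    "Autophagy",
    "Cell Cycle",
    "DNA Repair",
    "Endolysosome",
    "Epigenetic",
    "Immune Response",
    "Lipid Metabolism",
    "Metal Binding and Homeostasis",
    "Mitochondrial Metabolism",
    "Myelination",
    "Oxidative Stress",
    "Proteostasis",
    "RNA Spliceosome",
    "Structural Stabilization",
    "Synapse",
    "Tau Homeostasis",
    "Vasculature",
)


@dataclass
class GeneSetCollection:
    """A named collection of gene sets (GMT semantics).

    ``sets`` maps a unique set id to ``(description, genes)`` where ``genes``
    is an ordered tuple of unique gene identifiers.
    """

    sets: dict[str, tuple[str, tuple[str, ...]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for set_id, (_, genes) in self.sets.items():
            if len(genes) == 0:
                raise ValueError(f"gene set {set_id!r} is empty")
            if len(set(genes)) != len(genes):
                raise ValueError(f"gene set {set_id!r} contains duplicate genes")

    def __len__(self) -> int:
        return len(self.sets)

    def __contains__(self, set_id: str) -> bool:
        return set_id in self.sets

    def __iter__(self):
        return iter(self.sets)

    def genes(self, set_id: str) -> tuple[str, ...]:
        return self.sets[set_id][1]

    def description(self, set_id: str) -> str:
        return self.sets[set_id][0]

    def sizes(self) -> dict[str, int]:
        return {sid: len(genes) for sid, (_, genes) in self.sets.items()}

    def add(self, set_id: str, description: str, genes) -> None:
        if set_id in self.sets:
            raise ValueError(f"duplicate gene set id {set_id!r}")
        genes = tuple(genes)
        if len(genes) == 0:
            raise ValueError(f"gene set {set_id!r} is empty")
        if len(set(genes)) != len(genes):
            raise ValueError(f"gene set {set_id!r} contains duplicate genes")
        self.sets[set_id] = (description, genes)


@dataclass
class BiodomainMap:
    """Mapping of gene-set (term) ids onto biological domains.

    A term may belong to more than one domain.  ``vocabulary``, when given,
    is the closed list of admissible domain names.
    """

    entries: dict[str, tuple[str, ...]] = field(default_factory=dict)
    vocabulary: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        for term, domains in self.entries.items():
            if len(domains) == 0:
                raise ValueError(f"term {term!r} maps to no domain")
            if self.vocabulary is not None:
                unknown = [d for d in domains if d not in self.vocabulary]
                if unknown:
                    raise ValueError(
                        f"term {term!r} maps to unknown domain(s) {unknown!r}; "
                        f"declared vocabulary: {list(self.vocabulary)!r}"
                    )

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, term: str) -> bool:
        return term in self.entries

    def domains_of(self, term: str) -> tuple[str, ...]:
        """Domains of ``term``; empty tuple when the term is unmapped."""
        return self.entries.get(term, ())

    def terms_in_domain(self, domain: str) -> tuple[str, ...]:
        return tuple(t for t, ds in self.entries.items() if domain in ds)

    def all_domains(self) -> tuple[str, ...]:
        if self.vocabulary is not None:
            return tuple(self.vocabulary)
        seen: dict[str, None] = {}
        for ds in self.entries.values():
            for d in ds:
                seen.setdefault(d, None)
        return tuple(seen)


class ProteinMatrix:
    """Protein log2 intensities (proteins x samples) with sample metadata.

    ``values`` is a float DataFrame indexed by protein id with sample ids as
    columns; missing intensities are NaN.  ``samples`` is indexed by sample id
    and must cover every column of ``values``; it carries at least ``target``,
    ``cell_line`` and ``replicate``.
    """

    REQUIRED_METADATA = ("target", "cell_line", "replicate")

    def __init__(self, values: pd.DataFrame, samples: pd.DataFrame):
        values = values.astype(float)
        missing = [s for s in values.columns if s not in samples.index]
        if missing:
            raise ValueError(
                f"samples missing from metadata: {sorted(missing)!r}"
            )
        absent_cols = [c for c in self.REQUIRED_METADATA if c not in samples.columns]
        if absent_cols:
            raise ValueError(f"sample metadata lacks columns {absent_cols!r}")
        finite_or_nan = np.isfinite(values.to_numpy()) | np.isnan(values.to_numpy())
        if not finite_or_nan.all():
            raise ValueError("protein intensities must be finite where present")
        self.values = values
        self.samples = samples.loc[list(values.columns)]

    @property
    def n_proteins(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def detected_counts(self) -> pd.Series:
        """Number of quantified (non-missing) proteins per sample."""
        return self.values.notna().sum(axis=0)

    def subset_samples(self, sample_ids) -> "ProteinMatrix":
        sample_ids = list(sample_ids)
        return ProteinMatrix(self.values[sample_ids], self.samples.loc[sample_ids])

    def for_cell_line(self, cell_line: str) -> "ProteinMatrix":
        keep = self.samples.index[self.samples["cell_line"] == cell_line]
        return self.subset_samples(keep)
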