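"""Zero-imputed NES pairing, domain rank correlations, quadrant counts."""

import numpy as np
import pandas as pd
import pytest

from oracles import kendall_tau_b_pairs, pearson_formula
from targetscreen import BiodomainMap
from targetscreen.concordance import (domain_kendall, domain_protein_pearson,
                                      quadrant_counts, resolve_orthologs,
                                      zero_impute_pairs)
from targetscreen.containers import GeneSetCollection


def _results(rows):
    return pd.DataFrame(rows, columns=["set_id", "nes", "p_adj"])


class TestZeroImpute:
    def setup_method(self):
        self.bdmap = BiodomainMap({"t1": ("Immune Response",),
                                   "t2": ("Immune Response",),
                                   "t3": ("Synapse", "Immune Response")})

    def test_significant_one_side_pairs_with_zero(self):
        a = _results([("t1", 2.1, 0.01)])
        b = _results([])
        pairs = zero_impute_pairs(a, b, self.bdmap, 0.05)
        assert len(pairs) == 1
        assert pairs.loc[0, "nes_perturbation"] == 2.1
        assert pairs.loc[0, "nes_disease"] == 0.0

    def test_nonsignificant_both_sides_excluded(self):
        a = _results([("t1", 2.1, 0.50)])
        b = _results([("t1", 1.3, 0.90)])
        pairs = zero_impute_pairs(a, b, self.bdmap, 0.05)
        assert pairs.empty

    def test_multi_domain_term_appears_once_per_domain(self):
        a = _results([("t3", -1.5, 0.01)])
        b = _results([("t3", 1.2, 0.02)])
        pairs = zero_impute_pairs(a, b, self.bdmap, 0.05)
        assert sorted(pairs["biodomain"]) == ["Immune Response", "Synapse"]

    def test_counts_per_domain_match_hand_count(self):
        rng = np.random.default_rng(0)
        terms = [f"t{i}" for i in range(12)]
        domains = ["Immune Response", "Synapse", "Apoptosis"]
        bdmap = BiodomainMap({t: (domains[i % 3],) for i, t in enumerate(terms)})
        a = _results([(t, rng.normal(), 0.01 if i < 7 else 0.5)
                      for i, t in enumerate(terms)])
        b = _results([(t, rng.normal(), 0.01 if i % 2 else 0.5)
                      for i, t in enumerate(terms)])
        pairs = zero_impute_pairs(a, b, bdmap, 0.05)
        # union = terms sig in a (i<7) or sig in b (odd i): hand count
        union = {t for i, t in enumerate(terms) if i < 7 or i % 2}
        assert set(pairs["term"]) == union
        for d in domains:
            expected = sum(1 for i, t in enumerate(terms)
                           if t in union and domains[i % 3] == d)
            assert (pairs["biodomain"] == d).sum() == expected


class TestDomainKendall:
    def _pairs(self, x, y, domain="Immune Response"):
        return pd.DataFrame({"term": [f"t{i}" for i in range(len(x))],
                             "biodomain": domain,
                             "nes_perturbation": x, "nes_disease": y})

    def test_identical_vectors_give_tau_one(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0]
        out = domain_kendall(self._pairs(x, x))
        assert out.loc[0, "tau"] == pytest.approx(1.0)
        assert out.loc[0, "direction"] == "concordant"

    def test_negated_vectors_give_reversal(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0]
        out = domain_kendall(self._pairs(x, [-v for v in x]))
        assert out.loc[0, "tau"] == pytest.approx(-1.0)
        assert out.loc[0, "direction"] == "reversal"

    def test_tau_b_matches_pair_counting_oracle_with_ties(self):
        x = [1.0, 1.0, 2.0, 3.0, 4.0, 5.0]
        y = [0.5, 1.5, 1.5, 2.0, 0.0, 3.0]
        out = domain_kendall(self._pairs(x, y))
        assert out.loc[0, "tau"] == pytest.approx(kendall_tau_b_pairs(x, y),
                                                  abs=1e-12)

    def test_random_instances_match_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            n = int(rng.integers(5, 12))
            x = np.round(rng.normal(0, 1, n), 1)  # rounding induces ties
            y = np.round(rng.normal(0, 1, n), 1)
            if len(np.unique(x)) < 2 or len(np.unique(y)) < 2:
                continue
            out = domain_kendall(self._pairs(x, y))
            assert out.loc[0, "tau"] == pytest.approx(
                kendall_tau_b_pairs(x, y), abs=1e-12)

    def test_degenerate_domain_excluded_from_bh_family(self):
        pairs = pd.concat([
            self._pairs([1, 2, 3, 4, 5], [5, 4, 3, 2, 1], "Immune Response"),
            self._pairs([0, 0, 0, 0, 0], [1, 2, 3, 4, 5], "Synapse"),
        ], ignore_index=True)
        out = domain_kendall(pairs).set_index("biodomain")
        assert not out.loc["Synapse", "tested"]
        assert np.isnan(out.loc["Synapse", "tau"])
        # BH family had a single member: its adjusted p equals its raw p
        assert out.loc["Immune Response", "p_adj"] == pytest.approx(
            out.loc["Immune Response", "p"])

    def test_swapping_sides_preserves_abs_tau(self):
        rng = np.random.default_rng(2)
        x, y = rng.normal(0, 1, 8), rng.normal(0, 1, 8)
        t1 = domain_kendall(self._pairs(x, y)).loc[0, "tau"]
        t2 = domain_kendall(self._pairs(y, x)).loc[0, "tau"]
        assert abs(t1) == pytest.approx(abs(t2), abs=1e-12)


class TestDomainPearson:
    def _setup(self, fc_effect_fn, n=12):
        proteins = [f"g{i}" for i in range(n)]
        coll = GeneSetCollection()
        coll.add("t1", "d", proteins)
        bdmap = BiodomainMap({"t1": ("Immune Response",)})
        rng = np.random.default_rng(3)
        fc = rng.normal(0, 1, n)
        de = pd.DataFrame({"protein": proteins, "cell_line": "scramble",
                           "target": "T01", "log2fc": fc})
        disease = pd.DataFrame({"gene": [p.upper() for p in proteins],
                                "effect": fc_effect_fn(fc)})
        orthos = pd.DataFrame({"human": [p.upper() for p in proteins],
                               "mouse": proteins})
        return de, disease, orthos, coll, bdmap, fc

    def test_proportional_effects_give_r_one(self):
        de, disease, orthos, coll, bdmap, _ = self._setup(lambda fc: 2 * fc)
        out, _ = domain_protein_pearson(de, disease, orthos, coll, bdmap,
                                        min_proteins=10)
        assert out.loc[0, "r"] == pytest.approx(1.0)

    def test_negated_effects_give_r_minus_one(self):
        de, disease, orthos, coll, bdmap, _ = self._setup(lambda fc: -fc)
        out, _ = domain_protein_pearson(de, disease, orthos, coll, bdmap,
                                        min_proteins=10)
        assert out.loc[0, "r"] == pytest.approx(-1.0)

    def test_r_matches_covariance_formula(self):
        rng = np.random.default_rng(4)
        noise = rng.normal(0, 1, 12)
        de, disease, orthos, coll, bdmap, fc = self._setup(
            lambda f: -f + noise)
        out, _ = domain_protein_pearson(de, disease, orthos, coll, bdmap,
                                        min_proteins=8)
        assert out.loc[0, "r"] == pytest.approx(
            pearson_formula(fc, -fc + noise), abs=1e-12)

    def test_ambiguous_orthologs_dropped_and_counted(self):
        de, disease, orthos, coll, bdmap, _ = self._setup(lambda fc: fc)
        # one mouse gene maps to two human ids: both pairs must drop
        orthos = pd.concat([orthos, pd.DataFrame(
            {"human": ["EXTRA"], "mouse": ["g0"]})], ignore_index=True)
        mapping, report = resolve_orthologs(orthos)
        assert "g0" not in mapping
        assert report.loc[0, "dropped_ambiguous_pairs"] == 2
        out, _ = domain_protein_pearson(de, disease, orthos, coll, bdmap,
                                        min_proteins=8)
        assert out.loc[0, "n_proteins"] == 11


class TestQuadrants:
    def test_sign_pattern_counts(self):
        pairs = pd.DataFrame({
            "term": ["t1", "t2", "t3"], "biodomain": "Immune Response",
            "nes_perturbation": [1.0, -1.0, 1.0],
            "nes_disease": [2.0, -2.0, -2.0]})
        out = quadrant_counts(pairs)
        row = out.iloc[0]
        assert (row["up_up"], row["down_down"], row["up_down"],
                row["down_up"]) == (1, 1, 1, 0)

    def test_zeros_counted_one_sided(self):
        pairs = pd.DataFrame({
            "term": ["t1", "t2"], "biodomain": "Synapse",
            "nes_perturbation": [1.0, -1.0], "nes_disease": [0.0, 0.0]})
        out = quadrant_counts(pairs)
        assert out.loc[0, "one_sided"] == 2
        assert out.loc[0, "n_terms"] == 2

    def test_swapping_analyses_transposes_counts(self):
        rng = np.random.default_rng(5)
        pairs = pd.DataFrame({
            "term": [f"t{i}" for i in range(20)],
            "biodomain": "Immune Response",
            "nes_perturbation": rng.normal(0, 1, 20),
            "nes_disease": rng.normal(0, 1, 20)})
        out1 = quadrant_counts(pairs).iloc[0]
        swapped = pairs.rename(columns={"nes_perturbation": "nes_disease",
                                        "nes_disease": "nes_perturbation"})
        out2 = quadrant_counts(swapped).iloc[0]
        assert out1["up_down"] == out2["down_up"]
        assert out1["down_up"] == out2["up_down"]
        assert out1["up_up"] == out2["up_up"]
        assert out1["down_down"] == out2["down_down"]


def test_null_signature_pairs_rarely_called_significant():
    """Zero-imputation never manufactures significant concordance from
    two independent null signatures (false-positive rate <= nominal)."""
    rng = np.random.default_rng(6)
    terms = [f"t{i}" for i in range(40)]
    bdmap = BiodomainMap({t: ("Immune Response" if i < 20 else "Synapse",)
                          for i, t in enumerate(terms)})
    n_tested = n_sig = 0
    for _ in range(200):
        def null_results():
            from scipy.stats import norm
            from targetscreen.stats import bh_adjust
            nes = rng.normal(0, 1, 40)
            p = 2 * norm.sf(np.abs(nes))
            return pd.DataFrame({"set_id": terms, "nes": nes,
                                 "p_adj": bh_adjust(p)})
        pairs = zero_impute_pairs(null_results(), null_results(), bdmap, 0.25)
        out = domain_kendall(pairs, alpha=0.05)
        n_tested += int(out["tested"].sum())
        n_sig += int((out["direction"] != "none").sum())
    if n_tested:
        assert n_sig / n_tested <= 0.05 + 2 * np.sqrt(0.05 * 0.95 / n_tested)
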