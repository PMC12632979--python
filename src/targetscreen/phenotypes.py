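"""Hit calling on cellular assay readouts.

Replicates are first averaged within batch; a per-batch log2 fold change of
each target siRNA against the control siRNA is computed within the same cell
line (and LPS dose, where applicable); the log2FCs are then modeled with
fixed siRNA-by-cell-line effects and a random batch intercept (REML).
Marginal means are tested against zero, adjusted by Benjamini-Hochberg, and
hits are any knockdown with adjusted p <= the configured threshold
(boundary inclusive).

Cell lines are analyzed separately throughout: no contrast ever mixes cell
lines, and the NFkB-type assays are analyzed separately per LPS dose.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .config import RunConfig
from .stats import bh_adjust, wald_p

logger = logging.getLogger(__name__)

CONTROL_SIRNA = "ctrl"

_CELL_SEP = "\x1f"  # joins (target, cell_line) into one factor level


def batch_log2fc(table: pd.DataFrame, control: str = CONTROL_SIRNA) -> pd.DataFrame:
    """Per-batch log2 fold changes of target vs control siRNA.

    One record per (assay, target, cell line, dose, batch):
    ``log2(mean target replicates / mean control replicates)`` computed within
    the same assay, cell line, dose and batch.
    """
    records = []
    strata = table.groupby(["assay", "cell_line", "dose", "batch"],
                           dropna=False, sort=True)
    for (assay, cell_line, dose, batch), sub in strata:
        ctrl = sub.loc[sub["target"] == control, "value"]
        if ctrl.empty:
            raise ValueError(
                f"stratum (assay={assay!r}, cell_line={cell_line!r}, "
                f"dose={dose!r}, batch={batch!r}) has no control rows"
            )
        ctrl_mean = ctrl.mean()
        if ctrl_mean <= 0:
            raise ValueError(
                f"non-positive control mean in stratum (assay={assay!r}, "
                f"cell_line={cell_line!r}, dose={dose!r}, batch={batch!r})"
            )
        for target, tsub in sub[sub["target"] != control].groupby("target", sort=True):
            tmean = tsub["value"].mean()
            if tmean <= 0:
                raise ValueError(
                    f"non-positive mean for target {target!r} in stratum "
                    f"(assay={assay!r}, cell_line={cell_line!r}, dose={dose!r}, "
                    f"batch={batch!r})"
                )
            records.append({
                "assay": assay, "target": target, "cell_line": cell_line,
                "dose": dose, "batch": batch,
                "log2fc": float(np.log2(tmean / ctrl_mean)),
            })
    return pd.DataFrame(records,
                        columns=["assay", "target", "cell_line", "dose",
                                 "batch", "log2fc"])


@dataclass
class LmmFit:
    """A fitted per-assay model of log2 fold changes.

    ``effects`` has one row per siRNA-by-cell-line cell with its estimated
    marginal mean and standard error.  ``method`` is "reml" for the mixed
    model or "ols" when the fit was downgraded (fewer than 2 batches) or the
    batch variance hit the zero boundary (where the mixed model reduces
    exactly to ordinary least squares).
    """

    assay: str
    dose: float
    effects: pd.DataFrame
    batch_var: float
    resid_var: float
    n_batches: int
    resid_df: float
    method: str = "reml"
    dropped_cells: list = field(default_factory=list)


def _ols_fit(endog: np.ndarray, exog: np.ndarray):
    res = sm.OLS(endog, exog).fit()
    return res.params, res.bse, float(res.scale), float(res.df_resid)


def fit_random_intercept_lmm(records: pd.DataFrame, assay: str,
                             dose: float = np.nan) -> LmmFit:
    """Fit log2FC ~ siRNA x cell-line cell means + (1 | batch) by REML.

    With fewer than 2 batches the model is unidentifiable and the fit falls
    back to fixed effects only (logged).  A batch variance estimated at the
    zero boundary is clamped to 0, in which case the fixed effects are
    recomputed by OLS (to which the mixed model then reduces exactly).
    """
    sub = records
    if "assay" in records.columns:
        mask = records["assay"] == assay
        if "dose" in records.columns:
            mask &= (records["dose"] == dose) | (records["dose"].isna()
                                                 & pd.isna(dose))
        sub = records.loc[mask]
    if sub.empty:
        raise ValueError(f"no log2FC records for assay {assay!r}, dose {dose!r}")

    cell = sub["target"].astype(str) + _CELL_SEP + sub["cell_line"].astype(str)
    dummies = pd.get_dummies(cell, dtype=float)
    exog = dummies.to_numpy()
    endog = sub["log2fc"].to_numpy(dtype=float)
    cells = list(dummies.columns)
    n_batches = sub["batch"].nunique()

    method = "reml"
    batch_var = 0.0
    if n_batches < 2:
        logger.warning(
            "assay %r (dose %r): only %d batch(es); downgraded to a "
            "fixed-effects-only fit", assay, dose, n_batches)
        params, bse, resid_var, resid_df = _ols_fit(endog, exog)
        method = "ols"
    else:
        counts = sub.groupby("batch").size()
        identifiable = (counts > 1).any()
        fit = None
        last_exc: Exception | None = None
        for optimizer in ("bfgs", "powell", "cg", "nm"):
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    model = sm.MixedLM(endog, exog,
                                       groups=sub["batch"].to_numpy())
                    cand = model.fit(reml=True, method=optimizer)
                if np.isfinite(cand.fe_params).all():
                    fit = cand
                    if cand.converged:
                        break
            except (np.linalg.LinAlgError, ValueError) as exc:
                last_exc = exc
        if fit is not None:
            batch_var = float(np.asarray(fit.cov_re)[0, 0])
            resid_var = float(fit.scale)
        else:
            logger.warning(
                "assay %r (dose %r): mixed model fit failed (%s); downgraded "
                "to a fixed-effects-only fit", assay, dose, last_exc)
            identifiable = False
            batch_var, resid_var = 0.0, np.nan
        resid_df = float(len(endog) - len(cells))
        if not identifiable:
            # one observation per batch: batch and residual variance are
            # inseparable, so the random intercept cannot be estimated
            logger.warning(
                "assay %r (dose %r): <=1 observation per batch; downgraded to "
                "a fixed-effects-only fit", assay, dose)
            params, bse, resid_var, resid_df = _ols_fit(endog, exog)
            batch_var, method = 0.0, "ols"
        elif batch_var <= 1e-7 * max(resid_var, 1e-12):
            # boundary REML: random intercept vanishes, model == OLS
            batch_var = 0.0
            params, bse, resid_var, resid_df = _ols_fit(endog, exog)
            method = "ols"
        else:
            params = np.asarray(fit.fe_params)
            bse = np.asarray(fit.bse_fe)

    split = [c.split(_CELL_SEP) for c in cells]
    effects = pd.DataFrame({
        "assay": assay, "dose": dose,
        "target": [s[0] for s in split],
        "cell_line": [s[1] for s in split],
        "estimate": np.asarray(params, dtype=float),
        "se": np.asarray(bse, dtype=float),
    })
    if (effects["se"] <= 0).any():
        logger.warning("assay %r: zero standard error on %d cell(s) "
                       "(degenerate zero-variance data)", assay,
                       int((effects["se"] <= 0).sum()))
    return LmmFit(assay=assay, dose=dose, effects=effects,
                  batch_var=batch_var, resid_var=float(resid_var),
                  n_batches=int(n_batches), resid_df=float(resid_df),
                  method=method)


def marginal_mean_tests(fit: LmmFit, config: RunConfig | None = None) -> pd.DataFrame:
    """Two-sided test of each siRNA-by-cell-line marginal mean against 0."""
    config = config or RunConfig()
    out = fit.effects.copy()
    df = fit.resid_df if config.wald_reference == "t" else None
    out["p"] = wald_p(out["estimate"], out["se"], config.wald_reference, df)
    out["n_batches"] = fit.n_batches
    out["method"] = fit.method
    return out


def call_hits(effects: pd.DataFrame, threshold: float = 0.05,
              family_cols=("assay", "cell_line", "dose")) -> pd.DataFrame:
    """BH-adjust within each family and flag hits at adjusted p <= threshold.

    The boundary value is a hit (<=, not <).
    """
    out = effects.copy()
    out["p_adj"] = np.nan
    grouped = out.groupby(list(family_cols), dropna=False, sort=False)
    for _, idx in grouped.groups.items():
        out.loc[idx, "p_adj"] = bh_adjust(out.loc[idx, "p"].to_numpy())
    out["hit"] = out["p_adj"] <= threshold
    return out


def analyze_assays(table: pd.DataFrame, config: RunConfig | None = None,
                   control: str = CONTROL_SIRNA) -> pd.DataFrame:
    """Full chain: batch averaging, log2FC, LMM, marginal tests, BH, hits."""
    config = config or RunConfig()
    fc = batch_log2fc(table, control=control)
    tested = []
    for (assay, dose), _ in fc.groupby(["assay", "dose"], dropna=False, sort=True):
        fit = fit_random_intercept_lmm(fc, assay, dose)
        tested.append(marginal_mean_tests(fit, config))
    effects = pd.concat(tested, ignore_index=True)
    family = (("assay", "cell_line", "dose")
              if config.phenotype_bh_family == "assay_cell_dose" else ("assay",))
    return call_hits(effects, config.alpha, family)


def direction_discordance(effects: pd.DataFrame) -> pd.DataFrame:
    """Targets whose effect direction differs between cell lines.

    Reported under both conventions: ``discordant_point`` uses point-estimate
    signs only; ``discordant_significant`` additionally requires the effect to
    be a hit in both cell lines.
    """
    rows = []
    for (assay, dose, target), sub in effects.groupby(["assay", "dose", "target"],
                                                      dropna=False, sort=True):
        if sub["cell_line"].nunique() < 2:
            continue
        signs = np.sign(sub["estimate"].to_numpy())
        point = bool(len(set(signs[signs != 0])) > 1)
        sig = sub[sub["hit"]] if "hit" in sub.columns else sub.iloc[0:0]
        sig_signs = np.sign(sig["estimate"].to_numpy())
        significant = bool(len(sig) >= 2 and len(set(sig_signs[sig_signs != 0])) > 1)
        rows.append({"assay": assay, "dose": dose, "target": target,
                     "discordant_point": point,
                     "discordant_significant": significant})
    return pd.DataFrame(rows, columns=["assay", "dose", "target",
                                       "discordant_point",
                                       "discordant_significant"])
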