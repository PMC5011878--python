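"""End-to-end trial analysis: simulate (or load) a trait table, fit the
mixed models, and write the statistical result files.

Outputs of :func:`analyze_trial` (all CSV, deterministic formatting):

* ``anova.csv`` — Wald F table per trait and fixed term;
* ``vc.csv`` — variance components per trait (slide term, per-N residuals);
* ``h2.csv`` — per-trait, per-N-level variance components and mean-based
  heritability;
* ``blups.csv`` — genotype BLUPs per trait and stratum;
* ``correlations.csv`` — Pearson correlations of the BLUP matrix;
* ``pca.csv`` — PCA scores and loadings of the BLUP matrix.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd

from .errors import InsufficientDataError
from .experiment import TraitTable, merge_trait_tables
from .split_stats import (
    ModelSpec,
    blup_summaries,
    estimate_heritability,
    fit_mixed,
    is_model_excluded,
)
from .synthetic import TrialTruth, default_trial_truths, simulate_trial

_FLOAT_FMT = "%.12g"


@dataclass
class TrialConfig:
    """Configuration of a simulated split-nitrogen trial."""

    n_genotypes: int = 24
    n_reps: int = 4
    missing_rate: float = 0.1  # random crown-root non-establishment
    traits: Tuple[str, ...] = ("ER_Cr", "IC_Cr", "No_Lat_1st", "Med_Lat_1st")


def simulate_trial_tables(
    config: Optional[TrialConfig] = None,
    seed: int = 0,
) -> Tuple[TraitTable, Dict[str, TrialTruth]]:
    """Simulate the configured traits of one trial, returning data + truths.

    Truth parameters (effects) and data noise are both derived
    deterministically from *seed*.
    """
    config = config or TrialConfig()
    root = np.random.SeedSequence(seed)
    truth_rng, data_rng = [np.random.default_rng(s) for s in root.spawn(2)]
    truths = default_trial_truths(
        n_genotypes=config.n_genotypes, n_reps=config.n_reps, rng=truth_rng
    )
    truths = {t: truths[t] for t in config.traits}
    tables = [
        simulate_trial(truths[t], missing_rate=config.missing_rate, seed=data_rng)
        for t in config.traits
    ]
    return merge_trait_tables(tables), truths


def analyze_trial(table: TraitTable, outdir) -> Dict[str, pd.DataFrame]:
    """Fit every (model-eligible) trait of *table* and write result CSVs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    anova_rows, vc_rows, h2_rows = [], [], []
    blup_cols: Dict[str, pd.Series] = {}

    for trait in table.traits:
        if is_model_excluded(trait):
            continue
        spec = ModelSpec.for_trait(table, trait)
        fit = fit_mixed(table, spec)
        for row in fit.anova.to_dict("records"):
            anova_rows.append({"trait": trait, **row})
        for comp, val in fit.varcomp.items():
            vc_rows.append({"trait": trait, "component": comp, "value": val})

        levels = sorted(table.subset(trait)["n_level"].unique())
        for lvl in levels:
            h = estimate_heritability(table, trait, None if lvl == "none" else lvl)
            h2_rows.append({
                "trait": trait, "n_level": h.n_level,
                "sigma2_g": h.vc.sigma2_g, "sigma2_e": h.vc.sigma2_e,
                "r": h.vc.r, "h2": h.h2,
            })
            name = trait if lvl == "none" else f"{trait}_{lvl}"
            blup_cols[name] = _genotype_blups(table, trait, lvl)

    results = {
        "anova": pd.DataFrame(anova_rows),
        "vc": pd.DataFrame(vc_rows),
        "h2": pd.DataFrame(h2_rows),
    }

    blup_matrix = pd.DataFrame(blup_cols)
    blup_matrix.index.name = "genotype"
    results["blups"] = blup_matrix.reset_index()

    try:
        summary = blup_summaries(blup_matrix)
        results["correlations"] = summary.correlations.reset_index(names="trait")
        loadings = summary.pca_loadings.copy()
        loadings.insert(0, "kind", "loading")
        loadings = loadings.reset_index(names="name")
        scores = summary.pca_scores.copy()
        scores.insert(0, "kind", "score")
        scores = scores.reset_index(names="name")
        evr = pd.DataFrame(
            [["explained_variance_ratio", "meta"]
             + list(summary.explained_variance_ratio)],
            columns=["name", "kind"] + list(summary.pca_loadings.columns),
        )
        results["pca"] = pd.concat([loadings, scores, evr], ignore_index=True)
    except InsufficientDataError:
        results["correlations"] = pd.DataFrame()
        results["pca"] = pd.DataFrame()

    for name, df in results.items():
        df.to_csv(outdir / f"{name}.csv", index=False, float_format=_FLOAT_FMT)
    return results


def _genotype_blups(table: TraitTable, trait: str, n_level: str) -> pd.Series:
    """BLUPs of the random genotype effect from the per-stratum fit."""
    from .reml import reml_fit
    from .split_stats import _dummies, needs_sqrt, transform_trait

    df = table.subset(trait).dropna(subset=["value"])
    if n_level != "none":
        df = df[df["n_level"] == n_level]
    df = df.reset_index(drop=True)
    y = transform_trait(df["value"].to_numpy(), trait) if needs_sqrt(trait) \
        else df["value"].to_numpy(float)
    cols = [np.ones((len(df), 1))]
    r_mat, _ = _dummies(df["replicate"], "R")
    if r_mat.shape[1]:
        cols.append(r_mat)
    if df["side"].nunique() > 1:
        s_mat, _ = _dummies(df["side"], "S")
        cols.append(s_mat)
    X = np.hstack(cols)
    genos = sorted(df["genotype"].unique())
    g_mat = np.column_stack([(df["genotype"] == g).to_numpy(float) for g in genos])
    res = reml_fit(y, X, Z=g_mat, strata=None)
    return pd.Series(res.blup_u, index=genos)


def run_pipeline(
    config: Optional[TrialConfig] = None,
    seed: int = 0,
    outdir="results",
) -> Dict[str, pd.DataFrame]:
    """``simulate trial`` -> ``stats`` in one deterministic call.

    Writes ``traits.csv`` and ``truth.json`` next to the statistics output;
    the whole directory is bit-reproducible for a fixed seed and config.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    table, truths = simulate_trial_tables(config, seed)
    table.to_csv(outdir / "traits.csv")
    truth_doc = {
        t: {
            "mu": tr.mu,
            "n_effects": tr.n_effects,
            "genotype_effects": {k: v.tolist() for k, v in tr.genotype_effects.items()},
            "rep_effects": tr.rep_effects.tolist(),
            "side_effects": tr.side_effects,
            "sigma2_gr": tr.sigma2_gr,
            "sigma2_e": tr.sigma2_e,
        }
        for t, tr in truths.items()
    }
    (outdir / "truth.json").write_text(json.dumps(truth_doc, indent=2, sort_keys=True))
    return analyze_trial(table, outdir)
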