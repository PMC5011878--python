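"""Trial statistics: transformation policy, the genotype x nitrogen mixed
model, heritability, Tukey HSD and BLUP-based diversity summaries.

The full model for a split-root trait measured on genotype *i* under N
level *j* in replicate *k* on paper side *l* is

    y_ijkl = mu + G_i + N_j + GN_ij + R_k + S_l + GR_ik + e_ijkl

with the genotype-by-replicate interaction GR (which identifies individual
slides) random and a separate residual variance per N level.  Whole-plant
shoot traits reduce to genotype and replicate as fixed factors with a
single residual variance.

Root traits are square-root transformed before fitting (they are counts or
right-skewed lengths); shoot traits are analysed untransformed.  No
outliers are removed.  Mean-based heritability per N level is

    H^2 = sigma2_g / (sigma2_g + sigma2_e / r)

with r the number of replications, computed from a per-stratum fit in
which genotype is random.  Negative variance estimates are clamped to
zero, so a trait with no usable genetic signal reports H^2 = 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import InsufficientDataError, SchemaError
from .experiment import TraitTable
from .reml import REMLResult, reml_fit, wald_f

#: Traits (by name prefix) that are square-root transformed before model
#: fitting: right-skewed root lengths, counts and weights.
SQRT_TRAIT_PREFIXES = ("ER_Cr", "IC_Cr", "Med_Lat", "Max_Lat", "No_Lat", "DW_R")

#: Traits excluded from the default mixed-model run because their
#: distributions resist normalisation (computed and exported regardless).
NON_NORMAL_TRAIT_PREFIXES = ("LBrZ", "density_", "start_branching")


def needs_sqrt(trait: str) -> bool:
    return any(trait.startswith(p) for p in SQRT_TRAIT_PREFIXES)


def is_model_excluded(trait: str) -> bool:
    return any(trait.startswith(p) for p in NON_NORMAL_TRAIT_PREFIXES)


def transform_trait(values: Sequence[float], trait: str) -> np.ndarray:
    """Apply the trait's transformation policy (sqrt for root traits).

    Raises ``ValueError`` naming the offending record if a root-trait value
    is negative.
    """
    v = np.asarray(values, dtype=float)
    if not needs_sqrt(trait):
        return v
    neg = np.flatnonzero(v < 0)
    if neg.size:
        raise ValueError(
            f"trait {trait!r}: negative values at record indices {neg.tolist()} "
            "cannot be square-root transformed"
        )
    return np.sqrt(v)


# ---------------------------------------------------------------------------
# Design-matrix construction

def _dummies(series: pd.Series, prefix: str, drop_first: bool = True):
    levels = sorted(map(str, series.astype(str).unique()))
    used = levels[1:] if drop_first else levels
    mat = np.column_stack([(series.astype(str) == lev).to_numpy(float) for lev in used]) \
        if used else np.empty((len(series), 0))
    names = [f"{prefix}[{lev}]" for lev in used]
    return mat, names


def _build_design(df: pd.DataFrame, split_root: bool):
    """Fixed-effect design matrix and term -> column-index map."""
    n = len(df)
    cols = [np.ones((n, 1))]
    names = ["intercept"]
    terms: Dict[str, List[int]] = {}

    def add(term, mat, colnames):
        if mat.shape[1] == 0:
            return
        start = sum(c.shape[1] for c in cols)
        cols.append(mat)
        names.extend(colnames)
        terms[term] = list(range(start, start + mat.shape[1]))

    g_mat, g_names = _dummies(df["genotype"], "G")
    add("genotype", g_mat, g_names)
    if split_root:
        n_mat, n_names = _dummies(df["n_level"], "N")
        add("n_level", n_mat, n_names)
        inter = []
        inter_names = []
        for gi, gn in enumerate(g_names):
            for ni, nn in enumerate(n_names):
                inter.append(g_mat[:, gi] * n_mat[:, ni])
                inter_names.append(f"{gn}:{nn}")
        if inter:
            add("genotype:n_level", np.column_stack(inter), inter_names)
    r_mat, r_names = _dummies(df["replicate"], "R")
    add("replicate", r_mat, r_names)
    if split_root:
        s_mat, s_names = _dummies(df["side"], "S")
        add("side", s_mat, s_names)
    X = np.hstack(cols)
    return X, names, terms


def _gr_indicator(df: pd.DataFrame):
    """Indicator matrix of genotype-by-replicate (slide) combinations."""
    key = df["genotype"].astype(str) + "/" + df["replicate"].astype(str)
    levels = sorted(key.unique())
    Z = np.column_stack([(key == lev).to_numpy(float) for lev in levels])
    return Z, levels


# ---------------------------------------------------------------------------
# Model spec and fit

@dataclass(frozen=True)
class ModelSpec:
    """What to fit for one trait.

    ``split_root=True`` selects the full genotype x nitrogen model with the
    random slide (genotype-by-replicate) term and per-N residual variances;
    ``False`` the reduced genotype + replicate fixed model for per-plant
    shoot traits.
    """

    response: str
    split_root: bool = True
    transform: str = "auto"  # auto: sqrt for root traits, none otherwise
    heterogeneous_residual: bool = True

    def resolved_transform(self) -> str:
        if self.transform != "auto":
            return self.transform
        return "sqrt" if needs_sqrt(self.response) else "none"

    @classmethod
    def for_trait(cls, table: TraitTable, trait: str) -> "ModelSpec":
        sub = table.subset(trait)
        split = bool((sub["n_level"] != "none").any())
        return cls(response=trait, split_root=split,
                   heterogeneous_residual=split)


@dataclass
class ModelFit:
    spec: ModelSpec
    beta: pd.Series
    anova: pd.DataFrame  # term, F, num_df, den_df, p
    varcomp: Dict[str, float]
    gr_blups: Optional[pd.Series]
    genotype_means: pd.Series  # predicted means, transformed scale
    avsed: float  # average SE of a genotype-mean difference
    result: REMLResult
    n_obs: int


def fit_mixed(table: TraitTable, spec: ModelSpec) -> ModelFit:
    """REML fit of the trait model defined by *spec*.

    Missing cells are simply absent rows and are handled by the likelihood;
    nothing is imputed.  Fixed-effect tests are Wald F statistics with
    containment denominator degrees of freedom (terms constant within
    slides are tested against the slide stratum, others against the
    residual stratum).
    """
    df = table.subset(spec.response).dropna(subset=["value"]).reset_index(drop=True)
    if df.empty:
        raise InsufficientDataError(f"no records for trait {spec.response!r}")
    if df["genotype"].nunique() < 2:
        raise InsufficientDataError("need >= 2 genotypes")

    y = transform_trait(df["value"].to_numpy(), spec.response) \
        if spec.resolved_transform() == "sqrt" else df["value"].to_numpy(float)

    X, colnames, terms = _build_design(df, spec.split_root)
    Z, gr_levels = (None, None)
    strata = None
    if spec.split_root:
        Z, gr_levels = _gr_indicator(df)
        if spec.heterogeneous_residual:
            strata = df["n_level"].to_numpy()

    res = reml_fit(y, X, Z=Z, strata=strata)

    # containment denominator dfs
    n, p = res.n_obs, res.rank_x
    if Z is not None:
        q = Z.shape[1]
        rank_xz = np.linalg.matrix_rank(np.hstack([X, Z]))
        den_within = max(n - rank_xz, 1)
        # terms constant within slides are tested against the slide stratum
        slide_rank = 1 + len(terms.get("genotype", [])) + len(terms.get("replicate", []))
        den_between = max(q - slide_rank, 1)
        between_terms = {"genotype", "replicate"}
    else:
        den_within = n - p
        den_between = n - p
        between_terms = set()

    rows = []
    for term, idx in terms.items():
        F, num_df = wald_f(res, idx)
        den = den_between if term in between_terms else den_within
        pval = float(sps.f.sf(F, num_df, den))
        rows.append({"term": term, "F": F, "num_df": num_df, "den_df": den, "p": pval})
    anova = pd.DataFrame(rows)

    # predicted genotype means (equal weight over the other factor levels)
    genotypes = sorted(df["genotype"].unique())
    L_rows = []
    for g in genotypes:
        grid = _prediction_grid(df, g, spec.split_root)
        Xg, _, _ = _build_design_like(grid, df, spec.split_root)
        L_rows.append(Xg.mean(axis=0))
    L = np.vstack(L_rows)
    means = L @ res.beta
    cov_means = L @ res.cov_beta @ L.T
    n_g = len(genotypes)
    seds = []
    for i in range(n_g):
        for j in range(i + 1, n_g):
            seds.append(np.sqrt(cov_means[i, i] + cov_means[j, j] - 2 * cov_means[i, j]))
    avsed = float(np.mean(seds)) if seds else float("nan")

    varcomp: Dict[str, float] = {}
    if res.sigma2_u is not None:
        varcomp["GR"] = res.sigma2_u
    for lab, s in res.sigma2_e.items():
        varcomp[f"residual_{lab}" if lab != "all" else "residual"] = s

    gr_blups = None
    if res.blup_u is not None:
        gr_blups = pd.Series(res.blup_u, index=gr_levels, name="GR_blup")

    return ModelFit(
        spec=spec,
        beta=pd.Series(res.beta, index=colnames),
        anova=anova,
        varcomp=varcomp,
        gr_blups=gr_blups,
        genotype_means=pd.Series(means, index=genotypes, name=spec.response),
        avsed=avsed,
        result=res,
        n_obs=n,
    )


def _prediction_grid(df: pd.DataFrame, genotype, split_root: bool) -> pd.DataFrame:
    reps = sorted(df["replicate"].unique())
    if split_root:
        levels = sorted(df["n_level"].unique())
        sides = sorted(df["side"].unique())
        rows = [
            {"genotype": genotype, "n_level": nl, "replicate": r, "side": s}
            for nl in levels for r in reps for s in sides
        ]
    else:
        rows = [
            {"genotype": genotype, "n_level": "none", "replicate": r, "side": "none"}
            for r in reps
        ]
    return pd.DataFrame(rows)


def _build_design_like(grid: pd.DataFrame, template: pd.DataFrame, split_root: bool):
    """Design matrix for *grid* using the factor levels of *template*."""
    combined = pd.concat(
        [template[["genotype", "n_level", "replicate", "side"]], grid],
        ignore_index=True,
    )
    X, names, terms = _build_design(combined, split_root)
    return X[len(template):], names, terms


# ---------------------------------------------------------------------------
# Heritability

@dataclass(frozen=True)
class VarianceComponents:
    """Genotypic and residual variance with the replication count."""

    sigma2_g: float
    sigma2_e: float
    r: int

    def __post_init__(self):
        if self.r < 1:
            raise ValueError("replication count must be >= 1")


@dataclass(frozen=True)
class HeritabilityResult:
    trait: str
    n_level: str
    vc: VarianceComponents
    h2: float


def heritability(vc: VarianceComponents) -> float:
    """Mean-based heritability ``sigma2_g / (sigma2_g + sigma2_e / r)``.

    Negative component estimates must be clamped to zero upstream; a zero
    genotypic variance gives H^2 = 0 exactly.
    """
    if vc.r <= 0:
        raise ValueError("replication count must be positive")
    g = max(vc.sigma2_g, 0.0)
    e = max(vc.sigma2_e, 0.0)
    if g == 0.0:
        return 0.0
    return g / (g + e / vc.r)


def estimate_heritability(
    table: TraitTable,
    trait: str,
    n_level: Optional[str] = None,
    transform: str = "auto",
) -> HeritabilityResult:
    """Per-stratum heritability of a trait with genotype as random factor.

    Subsets the trait records to *n_level* (``None`` for whole-plant
    traits), fits ``y = mu + R_k (+ S_l) + g_i + e`` by REML with genotype
    random, and plugs the components into the mean-based formula with
    ``r`` = number of distinct replicates observed.
    """
    df = table.subset(trait).dropna(subset=["value"])
    level = "none" if n_level is None else str(n_level)
    if n_level is not None:
        df = df[df["n_level"] == level]
    df = df.reset_index(drop=True)
    if df.empty or df["genotype"].nunique() < 2:
        raise InsufficientDataError(
            f"trait {trait!r}, stratum {level!r}: not enough genotypes"
        )

    do_sqrt = transform == "sqrt" or (transform == "auto" and needs_sqrt(trait))
    y = transform_trait(df["value"].to_numpy(), trait) if do_sqrt \
        else df["value"].to_numpy(float)

    cols = [np.ones((len(df), 1))]
    r_mat, _ = _dummies(df["replicate"], "R")
    if r_mat.shape[1]:
        cols.append(r_mat)
    if df["side"].nunique() > 1:
        s_mat, _ = _dummies(df["side"], "S")
        cols.append(s_mat)
    X = np.hstack(cols)
    g_mat, _ = _dummies(df["genotype"], "G", drop_first=False)

    res = reml_fit(y, X, Z=g_mat, strata=None)
    vc = VarianceComponents(
        sigma2_g=res.sigma2_u if res.sigma2_u is not None else 0.0,
        sigma2_e=res.sigma2_e["all"],
        r=int(df["replicate"].nunique()),
    )
    return HeritabilityResult(trait=trait, n_level=level, vc=vc, h2=heritability(vc))


# ---------------------------------------------------------------------------
# Tukey HSD

def tukey_hsd(q: float, mse: float, n: int) -> float:
    """Honestly significant difference ``q * sqrt(MSE / n)``.

    ``q`` is the studentised-range critical value for the chosen
    significance level and degrees of freedom (supplied by the caller, not
    computed here), ``MSE`` the mean square error and ``n`` the number of
    treatment levels compared.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if q <= 0:
        raise ValueError("q must be positive")
    if mse < 0:
        raise ValueError("MSE must be non-negative")
    return float(q * np.sqrt(mse / n))


def mse_from_avsed(avsed: float, n: int) -> float:
    """Back out the mean square error from the average standard error of a
    difference: ``sed = sqrt(2 MSE / n)`` inverted to ``MSE = n sed^2 / 2``."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if avsed < 0:
        raise ValueError("avsed must be non-negative")
    return float(n * avsed ** 2 / 2.0)


# ---------------------------------------------------------------------------
# BLUP-based diversity summaries

@dataclass
class BlupSummary:
    matrix: pd.DataFrame  # genotype x trait
    correlations: pd.DataFrame
    pca_scores: pd.DataFrame
    pca_loadings: pd.DataFrame
    explained_variance_ratio: np.ndarray
    dropped_traits: List[str]


def blup_summaries(matrix: pd.DataFrame) -> BlupSummary:
    """Correlations and PCA of a genotype x trait effect matrix.

    Traits are centred and unit-scaled; Pearson correlations use
    pairwise-complete genotypes; the PCA is the eigendecomposition of the
    correlation matrix with component signs fixed so the largest-magnitude
    loading of each component is positive.  Zero-variance traits are
    dropped with a warning.
    """
    if matrix.shape[1] < 2 or matrix.shape[0] < 3:
        raise InsufficientDataError("need >= 3 genotypes and >= 2 traits")
    m = matrix.astype(float).copy()
    sd = m.std(ddof=1)
    dropped = sorted(sd.index[(sd == 0) | sd.isna()])
    if dropped:
        warnings.warn(f"zero-variance traits dropped from summaries: {dropped}",
                      stacklevel=2)
        m = m.drop(columns=dropped)
    if m.shape[1] < 2:
        raise InsufficientDataError("fewer than 2 informative traits remain")

    corr = m.corr(method="pearson")  # pairwise complete
    std = (m - m.mean()) / m.std(ddof=1)

    evals, evecs = np.linalg.eigh(corr.to_numpy())
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    evals = np.clip(evals, 0, None)
    for j in range(evecs.shape[1]):
        k = int(np.argmax(np.abs(evecs[:, j])))
        if evecs[k, j] < 0:
            evecs[:, j] = -evecs[:, j]
    pc_names = [f"PC{i + 1}" for i in range(len(evals))]
    loadings = pd.DataFrame(evecs, index=m.columns, columns=pc_names)
    scores = pd.DataFrame(std.to_numpy() @ evecs, index=m.index, columns=pc_names)
    evr = evals / evals.sum() if evals.sum() > 0 else evals

    return BlupSummary(
        matrix=m,
        correlations=corr,
        pca_scores=scores,
        pca_loadings=loadings,
        explained_variance_ratio=evr,
        dropped_traits=dropped,
    )
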