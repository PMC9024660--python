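"""Two-step mixed-effects association between nodal topology and traits.

For each structural resolution gamma, each consensus module and each nodal
metric, a linear mixed model regresses the metric (outcome) on the trait
score, with age, sex and a trait-by-sex interaction as fixed effects,
random intercepts per subject and per scanning group, and a random trait
slope per node ("the module's nodes as random groupings"). The module-level
trait fixed effect is the association of interest; node-level BLUPs of the
random slopes localize it within the module. A second, "robust" step
re-fits after excluding nodes whose conditional residuals fail an
Anderson-Darling normality screen. p-values are Benjamini-Hochberg
FDR-corrected within each (gamma, trait) family, and modules surviving at
two or more resolutions get a cross-gamma model with gamma levels as
repeated measures — the headline estimate.

Conventions: sex is contrast-coded female = -0.5, male = +0.5, so the
trait main effect is the sex-averaged slope and partial per-sex slopes
follow as slope(sex) = beta_trait + code(sex) * beta_interaction. The
trait enters as its standardized Box-Cox score; age is centered. Estimation
is by REML; t statistics use a between-subject Satterthwaite-style
denominator df of (n_subjects - 5), matching the subject-level fixed
design.
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import ConvergenceWarning

logger = logging.getLogger(__name__)

FIXED_FORMULA = "y ~ trait + age_c + sex_code + trait:sex_code"
N_FIXED = 5
SEX_CODE = {"female": -0.5, "male": 0.5}


@dataclass
class ModelSpec:
    """What a single association model is about."""

    metric: str
    trait: str = "ve"
    gamma: float | None = None
    module: int | None = None


@dataclass
class FixedEffect:
    estimate: float
    se: float
    ci_low: float
    ci_high: float
    t: float
    p: float


@dataclass
class AssociationResult:
    """Fixed effects, per-sex partial slopes and node BLUPs of one model."""

    spec: ModelSpec
    beta_trait: FixedEffect
    beta_sex_interaction: FixedEffect
    partial_beta_by_sex: dict[str, float]
    blups: pd.Series
    fixed_effects: pd.DataFrame
    df_resid: int
    n_subjects: int
    n_nodes_used: int
    n_excluded: int = 0
    excluded_nodes: list = field(default_factory=list)
    dropped_terms: list = field(default_factory=list)
    converged: bool = True
    q: float = np.nan

    def __post_init__(self) -> None:
        fe = self.beta_trait
        if np.isfinite([fe.estimate, fe.ci_low, fe.ci_high]).all() and not (
            fe.ci_low <= fe.estimate <= fe.ci_high
        ):
            raise ValueError("confidence interval must bracket the estimate")


# ---------------------------------------------------------------------------
# long-table construction


def build_long_table(
    metric_table: pd.DataFrame,
    cohort: pd.DataFrame,
    gamma: float,
    module_nodes: np.ndarray,
    metric: str,
    trait: str = "ve",
) -> pd.DataFrame:
    """One row per (subject, node-in-module) at one resolution.

    ``metric_table`` is the tidy long table (subject_id, node_id, gamma,
    metric, value); ``cohort`` the scored subject table with ve_t/iu_t.
    Subjects with a missing trait score are excluded (count logged). The
    result has columns y, trait, age_c, sex_code, sex, scan_group,
    subject_id, node_id.
    """
    module_nodes = np.asarray(module_nodes)
    if module_nodes.size == 0:
        raise ValueError("empty module: no nodes to model")
    trait_col = f"{trait}_t"
    sub = metric_table[
        (metric_table["metric"] == metric)
        & (metric_table["gamma"] == gamma)
        & metric_table["node_id"].isin(module_nodes)
    ]
    covars = cohort[["subject_id", "sex", "age", "scan_group", trait_col]].copy()
    complete = covars[trait_col].notna()
    n_dropped = int((~complete).sum())
    if n_dropped:
        logger.info("excluding %d subject(s) with missing %s score", n_dropped, trait)
    covars = covars[complete]
    out = sub.merge(covars, on="subject_id", how="inner")
    out = out.rename(columns={"value": "y", trait_col: "trait"})
    out["age_c"] = out["age"] - out["age"].mean()
    out["sex_code"] = out["sex"].map(SEX_CODE)
    out.attrs["n_subjects_dropped"] = n_dropped
    return out[
        ["subject_id", "node_id", "gamma", "y", "trait", "age_c", "sex_code",
         "sex", "scan_group"]
    ]


# ---------------------------------------------------------------------------
# model fitting


_BLUP_NODE_RE = re.compile(r"nodeslope\[.*\[(?P<node>[^\]]+)\]:trait\]")


def _fit_once(table: pd.DataFrame, vc: dict[str, str]):
    model = smf.mixedlm(
        FIXED_FORMULA,
        data=table,
        groups=np.ones(len(table)),
        vc_formula=vc,
        re_formula="0",
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        warnings.simplefilter("ignore", UserWarning)  # "covariance is singular"
        res = model.fit(reml=True)
        # boundary fits can yield an indefinite Hessian and NaN standard
        # errors under the default optimizer; retry with alternatives
        with np.errstate(invalid="ignore"):
            for method in ("lbfgs", "cg", "powell"):
                if np.isfinite(np.asarray(res.bse_fe)).all():
                    break
                res = model.fit(reml=True, method=method)
    return model, res


def _bad_se(res) -> bool:
    with np.errstate(invalid="ignore"):
        return not np.isfinite(np.asarray(res.bse_fe)).all()


def _vc_weakest_droppable(model, res, droppable: list[str]) -> str | None:
    names = list(model.exog_vc.names)
    candidates = [(res.vcomp[names.index(n)], n) for n in droppable if n in names]
    if not candidates:
        return None
    return min(candidates)[1]


def _is_singular(res) -> bool:
    return (not res.converged) or bool(np.any(res.vcomp < 1e-8)) or _bad_se(res)


def fit_module_model(
    table: pd.DataFrame,
    spec: ModelSpec,
    _extra_vc: dict[str, str] | None = None,
    _drop_order: tuple[str, ...] = ("scangroup",),
) -> AssociationResult:
    """REML fit of the module-level trait association.

    Random structure: subject intercepts, a trait random slope per node,
    and a scanning-group intercept (dropped with a warning when fewer than
    two groups are present). Singular fits (a variance component pinned at
    zero or non-convergence) are re-fit after dropping the weakest
    droppable random term — never the node slope — and flagged in
    ``dropped_terms``.
    """
    n_subjects = table["subject_id"].nunique()
    n_nodes = table["node_id"].nunique()
    if n_nodes < 2:
        raise ValueError("need at least 2 nodes to separate module and node effects")
    if n_subjects < 10:
        raise ValueError(f"need at least 10 subjects, got {n_subjects}")

    vc = {"subject": "0 + C(subject_id)", "nodeslope": "0 + C(node_id):trait"}
    dropped: list[str] = []
    if table["scan_group"].nunique() >= 2:
        vc["scangroup"] = "0 + C(scan_group)"
    else:
        warnings.warn(
            "fewer than 2 scanning groups: group random effect dropped",
            RuntimeWarning, stacklevel=2,
        )
        dropped.append("scangroup")
    if _extra_vc:
        vc.update(_extra_vc)

    model, res = _fit_once(table, vc)
    drop_order = [t for t in _drop_order if t in vc]
    while _is_singular(res) and drop_order:
        weakest = _vc_weakest_droppable(model, res, drop_order)
        if weakest is None:
            break
        vc = {k: v for k, v in vc.items() if k != weakest}
        drop_order.remove(weakest)
        dropped.append(weakest)
        logger.info("singular fit: refitting without random term %r", weakest)
        model, res = _fit_once(table, vc)

    df_resid = max(n_subjects - N_FIXED, 1)
    tcrit = stats.t.ppf(0.975, df_resid)
    with np.errstate(invalid="ignore"):
        bse_fe = pd.Series(np.asarray(res.bse_fe), index=res.fe_params.index)

    def fixed(name: str) -> FixedEffect:
        est = float(res.fe_params[name])
        se = float(bse_fe[name])
        t = est / se if se > 0 else np.nan
        p = float(2 * stats.t.sf(abs(t), df_resid)) if se > 0 else np.nan
        return FixedEffect(est, se, est - tcrit * se, est + tcrit * se, t, p)

    beta = fixed("trait")
    beta_int = fixed("trait:sex_code")
    partial = {
        sex: beta.estimate + code * beta_int.estimate
        for sex, code in SEX_CODE.items()
    }

    re_values = res.random_effects[1.0]
    blups = {}
    for name, value in re_values.items():
        m = _BLUP_NODE_RE.match(name)
        if m:
            blups[m.group("node")] = float(value)
    blup_series = pd.Series(blups, name="blup")
    try:  # restore integer node ids when possible
        blup_series.index = blup_series.index.astype(int)
        blup_series = blup_series.sort_index()
    except (TypeError, ValueError):
        pass

    rows = []
    for name in res.fe_params.index:
        fe = fixed(name)
        rows.append(
            {"term": name, "estimate": fe.estimate, "se": fe.se,
             "ci_low": fe.ci_low, "ci_high": fe.ci_high, "t": fe.t, "p": fe.p}
        )
    fixed_table = pd.DataFrame(rows)
    fixed_table.attrs["fittedvalues"] = res.fittedvalues
    fixed_table.attrs["vcomp"] = dict(zip(model.exog_vc.names, res.vcomp))

    return AssociationResult(
        spec=spec,
        beta_trait=beta,
        beta_sex_interaction=beta_int,
        partial_beta_by_sex=partial,
        blups=blup_series,
        fixed_effects=fixed_table,
        df_resid=df_resid,
        n_subjects=n_subjects,
        n_nodes_used=n_nodes,
        dropped_terms=dropped,
        converged=bool(res.converged),
    )


# ---------------------------------------------------------------------------
# Anderson-Darling residual screen


def anderson_darling_pvalue(x: np.ndarray) -> float:
    """Normality p-value for the Anderson-Darling statistic.

    Mean and variance estimated from the sample ("case 3"); p approximated
    by the standard small-sample-corrected piecewise-exponential formula
    for A*^2 = A^2 (1 + 0.75/n + 2.25/n^2).
    """
    x = np.sort(np.asarray(x, dtype=float))
    n = x.size
    if n < 5:
        return np.nan
    sd = x.std(ddof=1)
    if sd == 0:
        return 0.0
    z = stats.norm.cdf((x - x.mean()) / sd)
    z = np.clip(z, 1e-12, 1 - 1e-12)
    i = np.arange(1, n + 1)
    a2 = -n - np.mean((2 * i - 1) * (np.log(z) + np.log1p(-z[::-1])))
    a2s = a2 * (1 + 0.75 / n + 2.25 / n**2)
    if a2s >= 0.6:
        p = np.exp(1.2937 - 5.709 * a2s + 0.0186 * a2s**2)
    elif a2s >= 0.34:
        p = np.exp(0.9177 - 4.279 * a2s - 1.38 * a2s**2)
    elif a2s >= 0.2:
        p = 1 - np.exp(-8.318 + 42.796 * a2s - 59.938 * a2s**2)
    else:
        p = 1 - np.exp(-13.436 + 101.14 * a2s - 223.73 * a2s**2)
    return float(np.clip(p, 0.0, 1.0))


def residual_screen(
    table: pd.DataFrame,
    spec: ModelSpec,
    alpha_ad: float = 0.05,
) -> tuple[AssociationResult, AssociationResult, list]:
    """Robustness step: refit after dropping non-normal-residual nodes.

    Fits the full model, tests each node's conditional residuals with the
    Anderson-Darling normality test, excludes nodes with p < ``alpha_ad``
    and refits on the remainder. Returns (first_fit, refit, excluded);
    with ``alpha_ad = 0`` (or no offending nodes) the refit is the first
    fit.
    """
    first = fit_module_model(table, spec)
    fitted = pd.Series(
        np.asarray(first.fixed_effects.attrs["fittedvalues"]), index=table.index
    )
    resid = table["y"] - fitted  # conditional residuals (fitted includes BLUPs)
    excluded = []
    if alpha_ad > 0:
        for node, idx in table.groupby("node_id").groups.items():
            p = anderson_darling_pvalue(resid.loc[idx].to_numpy())
            if not np.isnan(p) and p < alpha_ad:
                excluded.append(node)
    if not excluded:
        return first, first, []
    reduced = table[~table["node_id"].isin(excluded)]
    if reduced["node_id"].nunique() < 2:
        raise ValueError(
            "residual screen excluded (almost) all nodes; inspect the module"
        )
    refit = fit_module_model(reduced, spec)
    refit.n_excluded = len(excluded)
    refit.excluded_nodes = list(excluded)
    return first, refit, excluded


# ---------------------------------------------------------------------------
# FDR


def fdr_correct(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# cross-gamma model and ICE curves


def cross_gamma_model(
    tables: list[pd.DataFrame], spec: ModelSpec
) -> AssociationResult:
    """Repeated-measures model pooling all resolutions where a module holds.

    Stacks the per-gamma long tables, adds a random intercept per gamma
    level and nests the node random slopes within gamma. Falls back to the
    single-resolution fit (with a warning) when only one table is given.
    Singular fits drop the gamma-level term first, then the scanning-group
    term, never the node slope.
    """
    if not tables:
        raise ValueError("no tables supplied")
    if len(tables) == 1:
        warnings.warn(
            "module detected at a single resolution: falling back to the "
            "per-gamma model", RuntimeWarning, stacklevel=2,
        )
        return fit_module_model(tables[0], spec)
    stacked = pd.concat(tables, ignore_index=True)
    stacked["node_id"] = (
        stacked["gamma"].astype(str) + ":" + stacked["node_id"].astype(str)
    )
    extra = {"gammalevel": "0 + C(gamma)"}
    return fit_module_model(
        stacked, spec, _extra_vc=extra, _drop_order=("gammalevel", "scangroup")
    )


def ice_curves(
    result: AssociationResult, table: pd.DataFrame, trait_grid: np.ndarray
) -> pd.DataFrame:
    """Individual conditional expectation curves over a trait grid.

    For each subject, the predicted module-average outcome across the trait
    grid at the subject's observed covariates, using the fixed effects plus
    the module-average node slope (BLUP mean is ~0 by shrinkage). Returns a
    long frame (subject_id, trait, predicted); the mean curve slope equals
    the trait fixed effect plus the sex-code-weighted interaction.
    """
    fe = result.fixed_effects.set_index("term")["estimate"]
    grid = np.asarray(trait_grid, dtype=float)
    subjects = table.drop_duplicates("subject_id")[
        ["subject_id", "age_c", "sex_code"]
    ]
    mean_blup = float(result.blups.mean()) if len(result.blups) else 0.0
    rows = []
    for _, s in subjects.iterrows():
        slope = fe["trait"] + fe.get("trait:sex_code", 0.0) * s.sex_code + mean_blup
        base = (
            fe.get("Intercept", 0.0)
            + fe.get("age_c", 0.0) * s.age_c
            + fe.get("sex_code", 0.0) * s.sex_code
        )
        for t in grid:
            rows.append(
                {"subject_id": s.subject_id, "trait": t, "predicted": base + slope * t}
            )
    return pd.DataFrame(rows)
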