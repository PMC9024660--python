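"""Synthetic cohorts with planted structure for end-to-end testing.

Real resting-state data for this kind of analysis are rarely shareable, so
this module generates cohorts whose statistical structure matches what the
downstream pipeline assumes:

* questionnaire items from a two-factor ordinal model (15 odd items load on
  a vicarious-experience factor, 15 even on an intuitive-understanding
  factor; responses are a latent normal thresholded into five equal-width
  categories), calibrated so subscale Cronbach's alpha, the between-subscale
  correlation, and the standardized female-male difference on VE hit
  configured targets;
* connectomes from a planted-partition model, either directly as binary
  adjacencies (mode A) or as block-correlated node time series pushed
  through the real connectome stage (mode B);
* nodal metric tables with a planted linear trait effect in one target
  module, with node-level random slopes, subject and scanning-group random
  intercepts, and an optional trait-by-sex interaction — the generative
  counterpart of the mixed-effects association model.

Everything is deterministic given the configuration seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import optimize, stats

from . import behavior
from .connectome import Connectome, fisher_z_connectome, proportional_threshold

__all__ = [
    "CohortConfig",
    "SubjectRecord",
    "ConfigurationError",
    "generate_cohort",
    "generate_connectome",
    "generate_timeseries",
    "planted_partition_labels",
    "null_metric_table",
    "plant_effect",
    "cohort_frame",
]


class ConfigurationError(ValueError):
    """Invalid simulator configuration."""


@dataclass
class CohortConfig:
    """Study-condition defaults for a simulated cohort.

    The defaults mirror the emulated study: 116 subjects (62 female),
    age 23 +/- 3 years truncated to [18, 35], four scanning groups of
    38/28/22/28, subscale reliabilities 0.92 (VE) and 0.95 (IU), a VE-IU
    correlation of 0.315, a standardized female-male VE difference of 0.90,
    a 418-node connectome, and a planted degree-trait slope of 3.2 per
    standardized (Box-Cox) trait unit in the target module.
    """

    n_subjects: int = 116
    n_nodes: int = 418
    n_modules_planted: int = 8
    p_in: float = 0.4
    p_out: float = 0.05
    trait_corr: float = 0.315
    sex_effect_d: float = 0.90
    female_fraction: float = 62 / 116
    alpha_ve: float = 0.92
    alpha_iu: float = 0.95
    planted_beta: float = 3.2
    planted_beta_sex: float = 0.0
    target_module: int = 0
    target_metric: str = "degree"
    trait: str = "ve"
    subject_sd: float = 1.0
    node_slope_sd: float = 0.5
    group_sd: float = 0.5
    residual_sd: float = 1.0
    n_groups: int = 4
    group_proportions: tuple[float, ...] | None = (38, 28, 22, 28)
    age_mean: float = 23.0
    age_sd: float = 3.0
    age_range: tuple[float, float] = (18.0, 35.0)
    n_timepoints: int = 400
    block_corr_in: float = 0.5
    block_corr_out: float = 0.1
    density: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_subjects, self.n_nodes, self.n_modules_planted) < 1:
            raise ConfigurationError("counts must be >= 1")
        if not (0.0 < self.p_in <= 1.0 and 0.0 <= self.p_out < 1.0):
            raise ConfigurationError("need p_in in (0,1] and p_out in [0,1)")
        if self.p_in <= self.p_out:
            raise ConfigurationError(
                "p_in must exceed p_out for detectable planted structure"
            )
        for name in ("subject_sd", "node_slope_sd", "group_sd", "residual_sd"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        for name in ("alpha_ve", "alpha_iu"):
            a = getattr(self, name)
            if not 0.0 < a < 1.0:
                raise ConfigurationError(
                    f"{name}={a} is unattainable; Cronbach's alpha of a noisy "
                    "factor model must lie in (0, 1)"
                )
        if not -1.0 < self.trait_corr < 1.0:
            raise ConfigurationError("trait_corr must lie in (-1, 1)")
        if not 0.0 <= self.female_fraction <= 1.0:
            raise ConfigurationError("female_fraction must lie in [0, 1]")
        if self.group_proportions is not None and len(self.group_proportions) != self.n_groups:
            raise ConfigurationError("group_proportions length must equal n_groups")
        if not 0 <= self.target_module < self.n_modules_planted:
            raise ConfigurationError("target_module must index a planted module")

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CohortConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        for key in ("group_proportions", "age_range"):
            if raw.get(key) is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class SubjectRecord:
    """One simulated participant."""

    subject_id: str
    sex: str
    age: float
    scan_group: str
    items: np.ndarray
    ve_raw: int = 0
    iu_raw: int = 0
    ve_t: float = np.nan
    iu_t: float = np.nan
    seed: int = field(default=0, repr=False)

    def __post_init__(self) -> None:
        self.items = np.asarray(self.items, dtype=int)
        if self.items.shape != (behavior.N_ITEMS,):
            raise ValueError("items must have length exactly 30")
        if self.sex not in ("female", "male"):
            raise ValueError("sex must be 'female' or 'male'")


# ---------------------------------------------------------------------------
# item-model calibration
#
# Items are parallel within a subscale: latent y = lam * F + eps, eps ~ N(0,1),
# thresholded into 5 categories at -1.5s, -0.5s, 0.5s, 1.5s with s the pooled
# latent item SD (equal-width thresholds). The VE factor carries a sex shift:
# F1 = delta * (female - p) + G1 with (G1, G2) standard bivariate normal with
# correlation rho. Calibration solves (lam1, lam2, rho, delta) so that the
# OBSERVED pooled alphas, subscale-sum correlation, and standardized VE sex
# difference equal their targets, using Gauss-Hermite moments of the
# discretized model (discretization attenuates correlations, the sex mixture
# inflates pooled VE variance; both are accounted for here rather than left
# as bias).

_GH_NODES, _GH_WEIGHTS = np.polynomial.hermite_e.hermegauss(48)
_GH_WEIGHTS = _GH_WEIGHTS / _GH_WEIGHTS.sum()
_K_ITEMS = 15


def _cond_mean_var(f: np.ndarray, lam: float, thresholds: np.ndarray):
    """Mean and variance of the 1..5 response conditional on factor value."""
    q = stats.norm.sf(thresholds[None, :] - lam * f[:, None])  # P(y > tau_t | f)
    m = 1.0 + q.sum(axis=1)
    var = (q * (1 - q)).sum(axis=1)
    for t in range(q.shape[1]):
        for u in range(t + 1, q.shape[1]):
            var += 2 * q[:, u] * (1 - q[:, t])
    return m, var


def _item_moments(lam: float, delta: float, p_f: float, thresholds: np.ndarray):
    """Pooled E[X], Var(X), Cov of two same-factor items, and sex contrast."""
    shifts = np.array([delta * (1 - p_f), -delta * p_f])
    weights = np.array([p_f, 1 - p_f])
    e_x = var_x = cov_xx = 0.0
    mean_by_sex = np.zeros(2)
    within_var = np.zeros(2)
    for s, (shift, w) in enumerate(zip(shifts, weights)):
        m, v = _cond_mean_var(_GH_NODES + shift, lam, thresholds)
        mu = float(_GH_WEIGHTS @ m)
        second = float(_GH_WEIGHTS @ (v + m**2))
        m2 = float(_GH_WEIGHTS @ m**2)
        mean_by_sex[s] = mu
        within_var[s] = second - mu**2
        e_x += w * mu
        var_x += w * second
        cov_xx += w * m2
    var_x -= e_x**2
    cov_xx -= e_x**2
    return e_x, var_x, cov_xx, mean_by_sex, within_var, weights


def _cross_cov(lam1, lam2, rho, delta, p_f, thr1, thr2) -> float:
    """Cov of one VE item with one IU item (over the sex mixture)."""
    f2 = _GH_NODES
    m2, _ = _cond_mean_var(f2, lam2, thr2)
    cov = 0.0
    e1 = e2 = 0.0
    shifts = np.array([delta * (1 - p_f), -delta * p_f])
    weights = np.array([p_f, 1 - p_f])
    for shift, w in zip(shifts, weights):
        # E[m1(F1) m2(F2)] with G1 | G2 ~ N(rho*g2, 1-rho^2)
        resid_sd = np.sqrt(max(1.0 - rho**2, 1e-12))
        g1 = rho * f2[:, None] + resid_sd * _GH_NODES[None, :]
        m1, _ = _cond_mean_var((g1 + shift).ravel(), lam1, thr1)
        m1 = m1.reshape(g1.shape)
        m1_given_g2 = m1 @ _GH_WEIGHTS
        cov += w * float(_GH_WEIGHTS @ (m1_given_g2 * m2))
        e1 += w * float(_GH_WEIGHTS @ m1_given_g2)
        e2 += w * float(_GH_WEIGHTS @ m2)
    return cov - e1 * e2


def _alpha_from(v: float, c: float, k: int = _K_ITEMS) -> float:
    return k * c / (v + (k - 1) * c)


def _thresholds(lam: float, delta: float, p_f: float) -> np.ndarray:
    s = np.sqrt(lam**2 * (1 + delta**2 * p_f * (1 - p_f)) + 1.0)
    return s * np.array([-1.5, -0.5, 0.5, 1.5])


def _calibrate(cfg: CohortConfig) -> dict:
    """Solve for loadings, latent correlation and latent sex shift."""
    p_f = cfg.female_fraction
    # a one-sex cohort cannot carry a sex contrast
    want_d = cfg.sex_effect_d if 0 < p_f < 1 else 0.0

    def loading_resid(params):
        lam1, lam2, delta = params
        thr1 = _thresholds(lam1, delta, p_f)
        thr2 = _thresholds(lam2, 0.0, p_f)
        _, v1, c1, mean_sex, within_var, w = _item_moments(lam1, delta, p_f, thr1)
        _, v2, c2, _, _, _ = _item_moments(lam2, 0.0, p_f, thr2)
        # sum over k items: within-sex var of sum = k*wv + k(k-1)*cov_within
        # within-sex covariance: conditional on sex, F1 ~ N(shift, 1)
        d_item = mean_sex[0] - mean_sex[1]
        k = _K_ITEMS
        cov_within = c1 - (w[0] * mean_sex[0] ** 2 + w[1] * mean_sex[1] ** 2 - (w @ mean_sex) ** 2)
        pooled_within_var = w @ within_var
        sum_var_within = k * pooled_within_var + k * (k - 1) * cov_within
        d_obs = k * d_item / np.sqrt(sum_var_within) if sum_var_within > 0 else 0.0
        return [
            _alpha_from(v1, c1) - cfg.alpha_ve,
            _alpha_from(v2, c2) - cfg.alpha_iu,
            d_obs - want_d,
        ]

    # linear-theory starting point: rbar = a / (k - (k-1) a)
    def lam0(a):
        rbar = a / (_K_ITEMS - (_K_ITEMS - 1) * a)
        return np.sqrt(rbar / (1 - rbar)) * 1.15  # inflate for discretization

    start = [lam0(cfg.alpha_ve), lam0(cfg.alpha_iu), abs(want_d)]
    sol = optimize.root(loading_resid, start, method="hybr", tol=1e-10)
    if not sol.success or np.any(np.asarray(sol.x[:2]) <= 0):
        raise ConfigurationError(
            f"cannot calibrate item model to alpha=({cfg.alpha_ve}, {cfg.alpha_iu}), "
            f"d={want_d}: {sol.message}"
        )
    lam1, lam2, delta = map(float, sol.x)
    thr1 = _thresholds(lam1, delta, p_f)
    thr2 = _thresholds(lam2, 0.0, p_f)
    _, v1, c1, _, _, _ = _item_moments(lam1, delta, p_f, thr1)
    _, v2, c2, _, _, _ = _item_moments(lam2, 0.0, p_f, thr2)
    k = _K_ITEMS
    sum_sd1 = np.sqrt(k * v1 + k * (k - 1) * c1)
    sum_sd2 = np.sqrt(k * v2 + k * (k - 1) * c2)

    def corr_resid(rho):
        c12 = _cross_cov(lam1, lam2, float(rho), delta, p_f, thr1, thr2)
        return k**2 * c12 / (sum_sd1 * sum_sd2) - cfg.trait_corr

    try:
        rho = float(optimize.brentq(corr_resid, -0.999, 0.999, xtol=1e-8))
    except ValueError as exc:
        raise ConfigurationError(
            f"trait_corr={cfg.trait_corr} unattainable under the item model"
        ) from exc
    return {"lam1": lam1, "lam2": lam2, "rho": rho, "delta": delta,
            "thr1": thr1, "thr2": thr2}


_CALIBRATION_CACHE: dict[tuple, dict] = {}


def _calibration(cfg: CohortConfig) -> dict:
    key = (cfg.alpha_ve, cfg.alpha_iu, cfg.trait_corr, cfg.sex_effect_d,
           cfg.female_fraction)
    if key not in _CALIBRATION_CACHE:
        _CALIBRATION_CACHE[key] = _calibrate(cfg)
    return _CALIBRATION_CACHE[key]


# ---------------------------------------------------------------------------
# cohort generation


def _largest_remainder_counts(n: int, proportions: np.ndarray) -> np.ndarray:
    """Integer counts summing to n, proportional to the given weights."""
    target = proportions / proportions.sum() * n
    base = np.floor(target).astype(int)
    short = n - base.sum()
    order = np.argsort(-(target - base))
    base[order[:short]] += 1
    return base


def generate_cohort(config: CohortConfig) -> list[SubjectRecord]:
    """Simulate a scored cohort; deterministic given ``config.seed``.

    Latent trait factors are drawn with the calibrated correlation, the VE
    factor mean is shifted for females, items are generated from the
    thresholded two-factor model, and subscale sums are Box-Cox transformed
    and standardized at the cohort level (stored in ve_t / iu_t).
    """
    cal = _calibration(config)
    ss = np.random.SeedSequence(config.seed)
    rng = np.random.default_rng(ss.spawn(1)[0])
    n = config.n_subjects

    n_female = int(round(config.female_fraction * n))
    sex = np.array(["female"] * n_female + ["male"] * (n - n_female))
    rng.shuffle(sex)
    female = sex == "female"

    lo, hi = config.age_range
    a, b = (lo - config.age_mean) / config.age_sd, (hi - config.age_mean) / config.age_sd
    age = stats.truncnorm.rvs(a, b, loc=config.age_mean, scale=config.age_sd,
                              size=n, random_state=rng).round(1)

    props = np.asarray(config.group_proportions if config.group_proportions is not None
                       else [1.0] * config.n_groups, dtype=float)
    counts = _largest_remainder_counts(n, props)
    groups = np.repeat([f"G{i + 1}" for i in range(config.n_groups)], counts)
    rng.shuffle(groups)

    rho = cal["rho"]
    g = rng.multivariate_normal([0, 0], [[1, rho], [rho, 1]], size=n,
                                method="cholesky")
    p_f = config.female_fraction
    f1 = cal["delta"] * (female.astype(float) - p_f) + g[:, 0]
    f2 = g[:, 1]

    items = np.empty((n, behavior.N_ITEMS), dtype=int)
    for factor, lam, thr, cols in (
        (f1, cal["lam1"], cal["thr1"], np.arange(0, behavior.N_ITEMS, 2)),
        (f2, cal["lam2"], cal["thr2"], np.arange(1, behavior.N_ITEMS, 2)),
    ):
        latent = lam * factor[:, None] + rng.standard_normal((n, _K_ITEMS))
        items[:, cols] = 1 + (latent[:, :, None] > thr[None, None, :]).sum(axis=2)

    subject_seeds = [int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(n + 1)[1:]]
    records = []
    for i in range(n):
        ve, iu = behavior.score_ees(items[i])
        records.append(
            SubjectRecord(
                subject_id=f"S{i + 1:04d}",
                sex=str(sex[i]),
                age=float(age[i]),
                scan_group=str(groups[i]),
                items=items[i],
                ve_raw=ve,
                iu_raw=iu,
                seed=subject_seeds[i],
            )
        )
    # cohort-level Box-Cox + standardization of the trait scores
    for name in ("ve", "iu"):
        raw = np.array([getattr(r, f"{name}_raw") for r in records], dtype=float)
        transformed, _ = behavior.boxcox(raw)
        sd = transformed.std(ddof=1) if len(records) > 1 else 0.0
        if sd > 0:
            transformed = (transformed - transformed.mean()) / sd
        else:
            transformed = transformed - transformed.mean()
        for r, value in zip(records, transformed):
            setattr(r, f"{name}_t", float(value))
    return records


def cohort_frame(records: list[SubjectRecord]) -> pd.DataFrame:
    """One-row-per-subject frame (items expanded to item_01..item_30)."""
    rows = []
    for r in records:
        row = {
            "subject_id": r.subject_id,
            "sex": r.sex,
            "age": r.age,
            "scan_group": r.scan_group,
            "ve_raw": r.ve_raw,
            "iu_raw": r.iu_raw,
            "ve_t": r.ve_t,
            "iu_t": r.iu_t,
        }
        row.update({col: int(v) for col, v in zip(behavior.ITEM_COLUMNS, r.items)})
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# connectomes


def planted_partition_labels(config: CohortConfig) -> np.ndarray:
    """Ground-truth module of each node (remainder goes to the last block)."""
    block = config.n_nodes // config.n_modules_planted
    if block == 0:
        raise ConfigurationError("more planted modules than nodes")
    labels = np.repeat(np.arange(config.n_modules_planted), block)
    return np.concatenate([labels, np.full(config.n_nodes - labels.size,
                                           config.n_modules_planted - 1)])


def generate_connectome(
    config: CohortConfig, subject: SubjectRecord, mode: str = "adjacency"
) -> Connectome:
    """Planted-partition connectome for one subject.

    Mode ``"adjacency"`` draws a binary adjacency directly (edge probability
    ``p_in`` within planted blocks, ``p_out`` between). Mode ``"timeseries"``
    draws block-correlated node time series and pushes them through the real
    Fisher-z + proportional-threshold chain. Reproducible from the subject's
    stored seed.
    """
    rng = np.random.default_rng(np.random.SeedSequence([subject.seed, 7]))
    labels = planted_partition_labels(config)
    if mode == "adjacency":
        same = labels[:, None] == labels[None, :]
        prob = np.where(same, config.p_in, config.p_out)
        u = rng.random((config.n_nodes, config.n_nodes))
        upper = np.triu(u < prob, k=1).astype(float)
        return Connectome(upper + upper.T, kind="binary")
    if mode == "timeseries":
        ts = generate_timeseries(config, subject)
        return proportional_threshold(fisher_z_connectome(ts), density=config.density)
    raise ValueError(f"unknown mode {mode!r}")


def generate_timeseries(config: CohortConfig, subject: SubjectRecord) -> np.ndarray:
    """Node-by-time series from a block-structured covariance."""
    rng = np.random.default_rng(np.random.SeedSequence([subject.seed, 11]))
    labels = planted_partition_labels(config)
    same = labels[:, None] == labels[None, :]
    cov = np.where(same, config.block_corr_in, config.block_corr_out)
    np.fill_diagonal(cov, 1.0)
    chol = np.linalg.cholesky(cov + 1e-10 * np.eye(config.n_nodes))
    return chol @ rng.standard_normal((config.n_nodes, config.n_timepoints))


# ---------------------------------------------------------------------------
# planted trait effects on nodal metrics


def null_metric_table(
    records: list[SubjectRecord],
    config: CohortConfig,
    gammas: tuple[float, ...] = (1.0,),
    metrics: tuple[str, ...] = ("degree",),
    baseline: float = 0.0,
) -> pd.DataFrame:
    """Flat baseline metric table (long format) for pure-model simulations."""
    subj = [r.subject_id for r in records]
    idx = pd.MultiIndex.from_product(
        [subj, range(config.n_nodes), gammas, metrics],
        names=["subject_id", "node_id", "gamma", "metric"],
    )
    out = idx.to_frame(index=False)
    out["value"] = baseline
    return out


def plant_effect(
    metric_table: pd.DataFrame,
    records: list[SubjectRecord],
    config: CohortConfig,
    seed: int | None = None,
) -> pd.DataFrame:
    """Add the generative mixed-model structure to a baseline metric table.

    For rows of the target metric whose node lies in the target planted
    module, the value becomes::

        baseline + (beta + b_node + beta_sex * sex_code) * trait
                 + u_subject + w_group + residual

    with node slopes b ~ N(0, node_slope_sd^2), subject intercepts
    u ~ N(0, subject_sd^2), scanning-group intercepts w ~ N(0, group_sd^2)
    and i.i.d. residuals. Rows outside the target module receive the same
    subject/group/residual terms but no trait term. Sex is coded female =
    -0.5, male = +0.5; the trait is the standardized Box-Cox score named by
    ``config.trait``. With ``planted_beta = 0``, ``planted_beta_sex = 0`` and
    all SDs zero the table is returned unchanged.
    """
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    out = metric_table.copy()
    labels = planted_partition_labels(config)
    by_id = {r.subject_id: r for r in records}

    node_slope = rng.normal(0.0, config.node_slope_sd, size=config.n_nodes)
    u_subj = {r.subject_id: rng.normal(0.0, config.subject_sd) for r in records}
    groups = sorted({r.scan_group for r in records})
    w_group = {gname: rng.normal(0.0, config.group_sd) for gname in groups}

    trait = out["subject_id"].map(
        lambda s: getattr(by_id[s], f"{config.trait}_t")
    ).to_numpy(float)
    sex_code = out["subject_id"].map(
        lambda s: -0.5 if by_id[s].sex == "female" else 0.5
    ).to_numpy(float)
    node = out["node_id"].to_numpy(int)
    in_target = (labels[node] == config.target_module) & (
        out["metric"].to_numpy() == config.target_metric
    )

    slope = config.planted_beta + node_slope[node] + config.planted_beta_sex * sex_code
    effect = np.where(in_target, slope * trait, 0.0)
    effect += out["subject_id"].map(u_subj).to_numpy(float)
    effect += out["subject_id"].map(lambda s: w_group[by_id[s].scan_group]).to_numpy(float)
    effect += rng.normal(0.0, config.residual_sd, size=len(out))
    out["value"] = out["value"].to_numpy(float) + effect
    return out
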