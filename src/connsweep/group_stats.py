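"""Mixed-design group statistics for network summary measures.

The battery mirrors classical split-plot (aov/afex-style) sums of squares,
not REML mixed models:

* an omnibus multivariate test (Pillai's trace) on the (DC, CC, ECC)
  measure vector, with between factor *group*, within factor *network*,
  and *age* as a centered covariate in the between stratum;
* per-measure univariate mixed ANCOVAs with Mauchly's sphericity test and
  Greenhouse-Geisser (GG) df correction, the GG-adjusted p being reported
  when Mauchly's p < .05;
* Tukey-adjusted post hoc group contrasts within each network, gated by a
  policy flag requiring a significant upstream group effect or
  group x network interaction;
* the same machinery, without covariate, for the 3-level connectivity-type
  decomposition ANOVA.

Layout of strata (n subjects, k within levels, p between parameters):
between error df = n - p; within (level x subject) error df = (k-1)(n - p).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2, f as f_dist, studentized_range, t as t_dist

from .atlas import NETWORKS

MEASURES = ("dc", "cc", "ecc")
ALPHA_MAUCHLY = 0.05


class DegenerateDataError(ValueError):
    """Zero error variance: F statistics are undefined."""


class PolicyError(RuntimeError):
    """Post hoc contrasts requested without upstream significance."""


@dataclass(frozen=True)
class EffectTest:
    name: str
    ss: float
    df1: float
    df2: float
    F: float
    p: float
    #: Pillai's trace for multivariate effects, NaN otherwise
    pillai: float = float("nan")


@dataclass(frozen=True)
class SphericityResult:
    W: float
    chi2: float
    df: int
    p: float
    epsilon: float


@dataclass(frozen=True)
class UnivariateResult:
    measure: str
    effects: dict[str, EffectTest]
    sphericity: SphericityResult
    gg_applied: bool
    #: GG-adjusted tests for within effects (same keys)
    effects_gg: dict[str, EffectTest] = field(default_factory=dict)
    #: error mean squares needed by the post hoc pooling
    ms_between: float = float("nan")
    ms_within: float = float("nan")
    df_between: float = float("nan")
    df_within: float = float("nan")

    def reported(self, effect: str) -> EffectTest:
        """The test as reported: GG-adjusted when Mauchly p < .05."""
        if self.gg_applied and effect in self.effects_gg:
            return self.effects_gg[effect]
        return self.effects[effect]


@dataclass(frozen=True)
class OmnibusResult:
    effects: dict[str, EffectTest]


@dataclass(frozen=True)
class ContrastResult:
    level: str
    difference: float          # first group minus second group, adjusted
    se: float
    t: float
    df: float
    p_unadjusted: float
    p_adjusted: float


# ---------------------------------------------------------------------------
# multivariate primitives

def orthonormal_contrasts(k: int) -> np.ndarray:
    """(k-1) x k orthonormal rows spanning the space orthogonal to 1."""
    if k < 2:
        raise ValueError("need at least 2 within levels")
    Q, _ = np.linalg.qr(np.column_stack([np.ones(k), np.eye(k)[:, : k - 1]]))
    return Q[:, 1:].T


def pillai_trace(H: np.ndarray, E: np.ndarray) -> float:
    """V = trace(H (H+E)^-1), rank-reduced when H+E is singular.

    Equals the sum of lambda/(1+lambda) over eigenvalues of E^-1 H.  When
    the DV set is rank-deficient (e.g. duplicated measures) the trace is
    computed on the range of H+E via the pseudo-inverse, so degenerate DV
    sets reduce to the corresponding lower-dimensional test.
    """
    H = np.asarray(H, float)
    E = np.asarray(E, float)
    S = H + E
    if not np.all(np.isfinite(S)):
        raise ValueError("non-finite SSCP matrices")
    evals = np.linalg.eigvalsh(S)
    if evals.max(initial=0.0) <= 0:
        raise DegenerateDataError("H + E is singular: no DV variance")
    return float(np.trace(H @ np.linalg.pinv(S, rcond=1e-12)))


def pillai_f(V: float, p: int, q: int, n_e: float) -> EffectTest:
    """Standard F approximation for Pillai's trace.

    p: number of DVs (effective rank); q: hypothesis df; n_e: error df.
    """
    s = min(p, q)
    m = (abs(p - q) - 1) / 2.0
    nn = (n_e - p - 1) / 2.0
    df1 = s * (2 * m + s + 1)
    df2 = s * (2 * nn + s + 1)
    denom = s - V
    if denom <= 0:
        F = np.inf
    else:
        F = (df2 / df1) * V / denom
    pval = float(f_dist.sf(F, df1, df2)) if np.isfinite(F) else 0.0
    return EffectTest(name="", ss=float("nan"), df1=df1, df2=df2,
                      F=float(F), p=pval, pillai=V)


def sphericity(within_cov: np.ndarray, n_e: int) -> SphericityResult:
    """Mauchly's W and Greenhouse-Geisser epsilon from a k x k covariance.

    The covariance of the k repeated measures is projected onto k-1
    orthonormal contrasts; on that matrix S,
    W = det(S) / (trace(S)/(k-1))^(k-1) and
    epsilon = (sum lambda)^2 / ((k-1) sum lambda^2).
    ``n_e`` is the error df behind the covariance estimate (subjects minus
    between-model parameters); it scales Mauchly's chi-square
    approximation.
    """
    Sig = np.asarray(within_cov, float)
    k = Sig.shape[0]
    if k < 2 or Sig.shape[0] != Sig.shape[1]:
        raise ValueError("within_cov must be k x k with k >= 2")
    C = orthonormal_contrasts(k)
    S = C @ Sig @ C.T
    q = k - 1
    lam = np.linalg.eigvalsh(S)
    lam = np.clip(lam, 0.0, None)
    tr = lam.sum()
    if tr <= 0:
        raise DegenerateDataError("zero within-subject variance")
    eps = float(tr**2 / (q * np.sum(lam**2)))
    eps = float(np.clip(eps, 1.0 / q, 1.0))
    det = float(np.prod(lam))
    W = det / (tr / q) ** q
    if W <= 0:
        import warnings

        warnings.warn("singular contrast covariance: Mauchly W at 0 boundary",
                      stacklevel=2)
        W = 0.0
        stat, pval = np.inf, 0.0
    else:
        factor = n_e - (2 * q**2 + q + 2) / (6.0 * q)
        stat = -factor * np.log(W)
        pval = float(chi2.sf(stat, q * (q + 1) // 2 - 1))
    if q == 1:
        # a single contrast is always spherical
        W, stat, pval, eps = 1.0, 0.0, 1.0, 1.0
    return SphericityResult(W=float(W), chi2=float(stat),
                            df=q * (q + 1) // 2 - 1, p=pval, epsilon=eps)


# ---------------------------------------------------------------------------
# split-plot core

def _between_design(group: np.ndarray, age: np.ndarray | None):
    """Sum-to-zero between design [1, age_c, g] and effect metadata."""
    groups = np.unique(group)
    if len(groups) != 2:
        raise ValueError(f"expected 2 groups, found {list(groups)}")
    g = np.where(group == groups[0], 1.0, -1.0)
    cols = [np.ones(len(g))]
    names = ["intercept"]
    if age is not None:
        cols.append(np.asarray(age, float) - np.mean(age))
        names.append("age")
    cols.append(g)
    names.append("group")
    return np.column_stack(cols), names, tuple(groups)


@dataclass(frozen=True)
class _Strata:
    """Fitted split-plot strata shared by the univariate and multivariate
    tests and the post hoc pooling."""

    X: np.ndarray
    names: list[str]
    groups: tuple[str, str]
    XtX_inv: np.ndarray
    k: int
    n: int
    # between stratum (on subject means, scaled by k)
    beta_b: dict[str, np.ndarray]
    rss_b: dict[str, float]
    # within stratum
    B: dict[str, np.ndarray]            # per measure: p x (k-1)
    E: dict[tuple[str, str], float]     # residual cross-SSCP traces
    E_mat: dict[str, np.ndarray]        # per measure: (k-1) x (k-1)


def _fit_strata(Y: dict[str, np.ndarray], group, age) -> _Strata:
    X, names, groups = _between_design(group, age)
    n, p = X.shape
    if n <= p:
        raise DegenerateDataError("not enough subjects for the between stratum")
    XtX_inv = np.linalg.inv(X.T @ X)
    any_Y = next(iter(Y.values()))
    k = any_Y.shape[1]
    C = orthonormal_contrasts(k)
    beta_b, rss_b, B, E_mat, R = {}, {}, {}, {}, {}
    for m, Ym in Y.items():
        mean_i = Ym.mean(axis=1)
        bb = XtX_inv @ X.T @ mean_i
        beta_b[m] = bb
        rss_b[m] = float(np.sum((mean_i - X @ bb) ** 2)) * k
        Z = Ym @ C.T
        Bm = XtX_inv @ X.T @ Z
        Rm = Z - X @ Bm
        B[m] = Bm
        R[m] = Rm
        E_mat[m] = Rm.T @ Rm
    E = {}
    for a in Y:
        for b in Y:
            E[(a, b)] = float(np.trace(R[a].T @ R[b]))
    return _Strata(X=X, names=names, groups=groups, XtX_inv=XtX_inv, k=k, n=n,
                   beta_b=beta_b, rss_b=rss_b, B=B, E=E, E_mat=E_mat)


def _wide(table: pd.DataFrame, measure: str, within: str,
          levels: tuple[str, ...]):
    """Pivot a long table to subjects x within-levels, with group/age."""
    sub = table[table["measure"] == measure] if "measure" in table else table
    if sub.empty:
        raise ValueError(f"no rows for measure {measure!r}")
    wide = sub.pivot_table(index="participant", columns=within,
                           values="value", aggfunc="first")
    missing = [l for l in levels if l not in wide.columns]
    if missing or wide.isna().any().any():
        raise ValueError(
            f"incomplete participant x {within} crossing (missing: {missing})")
    wide = wide[list(levels)]
    meta = sub.drop_duplicates("participant").set_index("participant")
    meta = meta.loc[wide.index]
    group = meta["group"].to_numpy()
    age = meta["age"].to_numpy(float) if "age" in meta else None
    return wide.to_numpy(float), group, age, list(wide.index)


def _univariate_from_strata(st: _Strata, m: str, measure_label: str,
                            within_name: str) -> UnivariateResult:
    n, p, k = st.n, st.X.shape[1], st.k
    df_b = n - p
    df_w = (k - 1) * df_b
    rss_b = st.rss_b[m]
    trE = st.E[(m, m)]
    if rss_b <= 0 or trE <= 0:
        raise DegenerateDataError(
            "zero error sum of squares: input values are degenerate")
    ms_b = rss_b / df_b
    ms_w = trE / df_w
    effects: dict[str, EffectTest] = {}
    effects_gg: dict[str, EffectTest] = {}
    # between-stratum effects (1 df each)
    for j, name in enumerate(st.names):
        if name == "intercept":
            continue
        ss = float(st.beta_b[m][j] ** 2 / st.XtX_inv[j, j]) * k
        F = ss / ms_b
        effects[name] = EffectTest(name=name, ss=ss, df1=1, df2=df_b, F=F,
                                   p=float(f_dist.sf(F, 1, df_b)))
    # within-stratum effects
    within_map = {"intercept": within_name, "group": f"group:{within_name}",
                  "age": f"age:{within_name}"}
    sph = sphericity_from_sscp(st.E_mat[m], df_b)
    eps = sph.epsilon
    for j, name in enumerate(st.names):
        eff_name = within_map[name]
        eta = st.B[m][j] / np.sqrt(st.XtX_inv[j, j])
        ss = float(eta @ eta)
        F = (ss / (k - 1)) / ms_w
        effects[eff_name] = EffectTest(name=eff_name, ss=ss, df1=k - 1,
                                       df2=df_w, F=F,
                                       p=float(f_dist.sf(F, k - 1, df_w)))
        effects_gg[eff_name] = EffectTest(
            name=eff_name, ss=ss, df1=(k - 1) * eps, df2=df_w * eps, F=F,
            p=float(f_dist.sf(F, (k - 1) * eps, df_w * eps)))
    return UnivariateResult(
        measure=measure_label, effects=effects, sphericity=sph,
        gg_applied=bool(sph.p < ALPHA_MAUCHLY), effects_gg=effects_gg,
        ms_between=ms_b, ms_within=ms_w, df_between=df_b, df_within=df_w)


def sphericity_from_sscp(E_contrast: np.ndarray, n_e: int) -> SphericityResult:
    """Mauchly/GG directly from a contrast-space error SSCP with df n_e."""
    q = E_contrast.shape[0]
    lam = np.clip(np.linalg.eigvalsh(np.asarray(E_contrast, float) / n_e), 0, None)
    tr = lam.sum()
    if tr <= 0:
        raise DegenerateDataError("zero within-subject variance")
    eps = float(np.clip(tr**2 / (q * np.sum(lam**2)), 1.0 / q, 1.0))
    W = float(np.prod(lam) / (tr / q) ** q)
    if q == 1:
        return SphericityResult(W=1.0, chi2=0.0, df=0, p=1.0, epsilon=1.0)
    if W <= 0:
        import warnings

        warnings.warn("singular contrast covariance: Mauchly W at 0 boundary",
                      stacklevel=2)
        return SphericityResult(W=0.0, chi2=float("inf"),
                                df=q * (q + 1) // 2 - 1, p=0.0, epsilon=eps)
    factor = n_e - (2 * q**2 + q + 2) / (6.0 * q)
    stat = -factor * np.log(W)
    pval = float(chi2.sf(stat, q * (q + 1) // 2 - 1))
    return SphericityResult(W=W, chi2=float(stat), df=q * (q + 1) // 2 - 1,
                            p=pval, epsilon=eps)


# ---------------------------------------------------------------------------
# public operations

def mixed_ancova(table: pd.DataFrame, measure: str,
                 within: str = "network",
                 levels: tuple[str, ...] = NETWORKS) -> UnivariateResult:
    """Univariate split-plot ANCOVA for one measure.

    ``table`` is long format with columns participant, group, age,
    ``within`` (factor levels), measure, value.  GG correction is applied
    to the reported within-effect p-values when Mauchly's p < .05.
    """
    Y, group, age, _ = _wide(table, measure, within, levels)
    st = _fit_strata({measure: Y}, group, age)
    return _univariate_from_strata(st, measure, measure, within)


def omnibus_mancova(table: pd.DataFrame,
                    measures: tuple[str, ...] = MEASURES,
                    within: str = "network",
                    levels: tuple[str, ...] = NETWORKS) -> OmnibusResult:
    """Pillai-trace multivariate tests on the measure vector.

    Between effects (group, age) are tested on per-subject measure means
    against the between-stratum error SSCP (df n - p); within effects
    (network, group x network, age x network) pool the orthonormal-contrast
    hypothesis and error cross-products over measures, with error df
    (k-1)(n - p).
    """
    Ys, group, age = {}, None, None
    order = None
    for m in measures:
        Y, group, age, ids = _wide(table, m, within, levels)
        if order is None:
            order = ids
        elif ids != order:
            raise ValueError("participants differ across measures")
        Ys[m] = Y
    # duplicated measure names would collapse the dict; keep unique keys
    keys = []
    for i, m in enumerate(measures):
        key = m if m not in keys else f"{m}#{i}"
        keys.append(key)
        Ys.setdefault(key, Ys[m])
    Ys = {k: Ys[k] for k in keys}
    st = _fit_strata(Ys, group, age)
    n, p, k = st.n, st.X.shape[1], st.k
    nm = len(keys)
    effects: dict[str, EffectTest] = {}
    # between: multivariate on subject means
    M_resid = {}
    for m in keys:
        mean_i = Ys[m].mean(axis=1)
        M_resid[m] = mean_i - st.X @ st.beta_b[m]
    E_b = np.array([[k * float(M_resid[a] @ M_resid[b]) for b in keys]
                    for a in keys])
    for j, name in enumerate(st.names):
        if name == "intercept":
            continue
        eta = np.array([st.beta_b[m][j] / np.sqrt(st.XtX_inv[j, j]) for m in keys])
        eta = eta * np.sqrt(k)
        H = np.outer(eta, eta)
        rank = np.linalg.matrix_rank(H + E_b, tol=1e-10 * np.trace(H + E_b))
        V = pillai_trace(H, E_b)
        res = pillai_f(V, p=rank, q=1, n_e=n - p)
        effects[name] = EffectTest(name=name, ss=float(np.trace(H)),
                                   df1=res.df1, df2=res.df2, F=res.F,
                                   p=res.p, pillai=V)
    # within: pooled over contrast dimensions
    within_map = {"intercept": within, "group": f"group:{within}",
                  "age": f"age:{within}"}
    E_w = np.array([[st.E[(a, b)] for b in keys] for a in keys])
    for j, name in enumerate(st.names):
        eff_name = within_map[name]
        etas = {m: st.B[m][j] / np.sqrt(st.XtX_inv[j, j]) for m in keys}
        H = np.array([[float(etas[a] @ etas[b]) for b in keys] for a in keys])
        rank = np.linalg.matrix_rank(H + E_w, tol=1e-10 * np.trace(H + E_w))
        V = pillai_trace(H, E_w)
        res = pillai_f(V, p=rank, q=k - 1, n_e=(k - 1) * (n - p))
        effects[eff_name] = EffectTest(name=eff_name, ss=float(np.trace(H)),
                                       df1=res.df1, df2=res.df2, F=res.F,
                                       p=res.p, pillai=V)
    return OmnibusResult(effects=effects)


def _tukey_nmeans(family_size: int) -> int:
    """Number of means whose pairwise comparisons equal the family size."""
    m = (1 + np.sqrt(1 + 8 * family_size)) / 2
    return max(2, int(np.ceil(m - 1e-9)))


def posthoc_contrasts(
    table: pd.DataFrame,
    measure: str,
    upstream_significant: bool = True,
    enforce_policy: bool = True,
    within: str = "network",
    levels: tuple[str, ...] = NETWORKS,
) -> list[ContrastResult]:
    """Group contrasts within each within-factor level, Tukey-adjusted.

    The covariate-adjusted group difference in each level is taken from a
    per-level OLS fit; its standard error pools both error strata,

        SE^2 = c * [MS_between + (k-1) MS_within] / k,

    with c the design variance factor of the group difference and a
    Satterthwaite df for the mean-square combination.  The family is the
    set of per-level group contrasts, adjusted with the studentized-range
    distribution (number of means chosen so its pairwise count equals the
    family size); a family of one is returned unadjusted.
    """
    if enforce_policy and not upstream_significant:
        raise PolicyError(
            "post hoc contrasts require a significant upstream group main "
            "effect or group x within-factor interaction")
    Y, group, age, _ = _wide(table, measure, within, levels)
    if len(levels) == 1:
        # family of one: a plain (AN)COVA on the single level
        X, names, _ = _between_design(group, age)
        XtX_inv = np.linalg.inv(X.T @ X)
        jg = names.index("group")
        beta = XtX_inv @ X.T @ Y[:, 0]
        resid = Y[:, 0] - X @ beta
        df = len(group) - X.shape[1]
        se = float(np.sqrt(4.0 * XtX_inv[jg, jg] * resid @ resid / df))
        diff = 2.0 * beta[jg]
        tval = diff / se
        p = float(2 * t_dist.sf(abs(tval), df))
        return [ContrastResult(level=levels[0], difference=float(diff), se=se,
                               t=float(tval), df=float(df), p_unadjusted=p,
                               p_adjusted=p)]
    st = _fit_strata({measure: Y}, group, age)
    uni = _univariate_from_strata(st, measure, measure, within)
    k = st.k
    X, XtX_inv = st.X, st.XtX_inv
    jg = st.names.index("group")
    c = 4.0 * XtX_inv[jg, jg]   # var factor of (group1 - group2) at mean age
    a_part = c * uni.ms_between / k
    b_part = c * (k - 1) * uni.ms_within / k
    var = a_part + b_part
    df = var**2 / (a_part**2 / uni.df_between + b_part**2 / uni.df_within)
    se = float(np.sqrt(var))
    nmeans = _tukey_nmeans(len(levels))
    out = []
    for jlev, level in enumerate(levels):
        beta = XtX_inv @ X.T @ Y[:, jlev]
        diff = 2.0 * beta[jg]
        tval = diff / se
        p_un = float(2 * t_dist.sf(abs(tval), df))
        if len(levels) == 1:
            p_adj = p_un
        else:
            p_adj = float(studentized_range.sf(abs(tval) * np.sqrt(2), nmeans, df))
            p_adj = max(p_adj, p_un)
        out.append(ContrastResult(level=level, difference=float(diff), se=se,
                                  t=float(tval), df=float(df),
                                  p_unadjusted=p_un, p_adjusted=min(p_adj, 1.0)))
    return out


def decomposition_anova(
    table: pd.DataFrame,
    focal: str,
    levels: tuple[str, ...] = ("within", "pair", "rest"),
) -> tuple[UnivariateResult, list[ContrastResult]]:
    """Mixed ANOVA (no covariate) over connectivity types for one focal
    network, plus per-type group contrasts.

    ``table``: long rows (participant, group, focal, partition, value).
    """
    sub = table[table["focal"] == focal].copy()
    if sub.empty:
        raise ValueError(f"no rows for focal network {focal!r}")
    sub = sub.rename(columns={"partition": "connectivity"})
    # no covariate in the decomposition model
    sub = sub.drop(columns=[c for c in ("age", "measure") if c in sub])
    Y, group, _, _ = _wide(sub, measure="", within="connectivity", levels=levels)
    st = _fit_strata({"dc": Y}, group, None)
    uni = _univariate_from_strata(st, "dc", "dc", "connectivity")
    contrasts = posthoc_contrasts(
        sub, "", upstream_significant=True, enforce_policy=False,
        within="connectivity", levels=levels)
    return uni, contrasts
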