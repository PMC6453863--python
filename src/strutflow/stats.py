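"""Statistical stage: univariate comparisons and the three-level mixed model.

The ESS observations form a strict nesting — 5-degree sectors within
cross-sections within scaffolds within animals — and are compared with a
linear mixed model: fixed effects for scaffold type, cross-sectional area and
their interaction; nested random intercepts for animal, scaffold-within-animal
and cross-section-within-scaffold; fitted by maximum likelihood (so candidate
models are comparable by likelihood).

The fitter profiles the fixed effects and the residual variance analytically
and optimizes only the three variance ratios, using per-animal Woodbury
identities on the low-rank random-effect structure; this makes repeated fits
at the full study scale cheap enough for simulation-based calibration.
Fixed-effect tests use Satterthwaite-style degrees of freedom computed by the
delta method on the variance-parameter Hessian (normal approximation as the
fallback).
"""

from __future__ import annotations

from collections import namedtuple
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import optimize, stats as sps
from scipy.linalg import cho_factor, cho_solve

TestResult = namedtuple("TestResult", ["statistic", "pvalue", "kind"])

KIND_MANN_WHITNEY = "mann_whitney"
KIND_KRUSKAL = "kruskal_wallis"
KIND_CHI_SQUARE = "chi_square"
KIND_KS_NORMALITY = "ks_normality"

TERM_TYPE = "scaffold_type"
TERM_CSA = "cross_sectional_area"
TERM_INTERACTION = "interaction"
FULL_MODEL = (TERM_TYPE, TERM_CSA, TERM_INTERACTION)


def compare_univariate(*groups, kind: str) -> TestResult:
    """Two-sided standard tests used for the univariate comparisons.

    ``mann_whitney`` takes two samples, ``kruskal_wallis`` two or more,
    ``chi_square`` a single 2-D contingency table (no continuity correction;
    expected counts below 1 are rejected), ``ks_normality`` one sample tested
    against a normal distribution with the sample's moments.
    """
    if kind == KIND_MANN_WHITNEY:
        if len(groups) != 2:
            raise ValueError("mann_whitney requires exactly two samples")
        a, b = (np.asarray(g, dtype=float) for g in groups)
        if a.size == 0 or b.size == 0:
            raise ValueError("empty group")
        res = sps.mannwhitneyu(a, b, alternative="two-sided",
                               method="asymptotic", use_continuity=False)
        return TestResult(float(res.statistic), float(res.pvalue), kind)
    if kind == KIND_KRUSKAL:
        if len(groups) < 2 or any(len(g) == 0 for g in groups):
            raise ValueError("kruskal_wallis requires >=2 non-empty samples")
        res = sps.kruskal(*groups)
        return TestResult(float(res.statistic), float(res.pvalue), kind)
    if kind == KIND_CHI_SQUARE:
        if len(groups) != 1:
            raise ValueError("chi_square takes a single contingency table")
        table = np.asarray(groups[0], dtype=float)
        if table.ndim != 2 or table.size == 0:
            raise ValueError("contingency table must be 2-D")
        total = table.sum()
        expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / total
        if np.any(expected < 1.0):
            raise ValueError("chi-square invalid: expected cell count < 1")
        res = sps.chi2_contingency(table, correction=False)
        return TestResult(float(res[0]), float(res[1]), kind)
    if kind == KIND_KS_NORMALITY:
        if len(groups) != 1:
            raise ValueError("ks_normality takes a single sample")
        x = np.asarray(groups[0], dtype=float)
        if x.size < 3:
            raise ValueError("need at least 3 observations")
        res = sps.kstest(x, "norm", args=(x.mean(), x.std(ddof=1)))
        return TestResult(float(res.statistic), float(res.pvalue), kind)
    raise ValueError(f"unknown test kind {kind!r}")


# ---------------------------------------------------------------------------
# nested three-level linear mixed model (profiled maximum likelihood)
# ---------------------------------------------------------------------------

@dataclass
class MixedModelResult:
    fixed_effects: pd.DataFrame          # term / estimate / se / stat / df / pvalue
    variance_components: dict            # level -> variance (Pa^2), + residual
    log_likelihood: float
    n_obs: int
    n_params: int                        # fixed + variance parameters
    converged: bool
    singular: list                       # variance components at the boundary
    df_method: str
    fixed_terms: tuple
    data_fingerprint: int
    reml: bool = False

    @property
    def aic(self) -> float:
        return 2.0 * self.n_params - 2.0 * self.log_likelihood

    def coef(self, term: str) -> pd.Series:
        row = self.fixed_effects[self.fixed_effects["term"] == term]
        if row.empty:
            raise KeyError(term)
        return row.iloc[0]


_REQUIRED = ["animal_id", "scaffold_id", "cross_section_id",
             "scaffold_type", "cross_sectional_area", "ess"]


def _check_nesting(df: pd.DataFrame) -> None:
    for child, parent in [("scaffold_id", "animal_id"),
                          ("cross_section_id", "scaffold_id")]:
        n_parents = df.groupby(child)[parent].nunique()
        if (n_parents > 1).any():
            raise ValueError(f"{child} is not nested within {parent}")


def _design_matrix(df: pd.DataFrame, fixed_terms, center_csa: bool):
    terms = ["intercept"]
    cols = [np.ones(len(df))]
    types = np.sort(df["scaffold_type"].unique())
    if TERM_TYPE in fixed_terms:
        if len(types) < 2:
            raise ValueError("need at least two scaffold types")
        ind = (df["scaffold_type"] == types[-1]).to_numpy(float)
        terms.append(f"{TERM_TYPE}[{types[-1]}]")
        cols.append(ind)
    csa = df["cross_sectional_area"].to_numpy(float)
    if center_csa:
        csa = csa - csa.mean()
    if TERM_CSA in fixed_terms:
        terms.append(TERM_CSA + ("_centered" if center_csa else ""))
        cols.append(csa)
    if TERM_INTERACTION in fixed_terms:
        if TERM_TYPE not in fixed_terms or TERM_CSA not in fixed_terms:
            raise ValueError("interaction requires both main effects")
        terms.append(f"{TERM_TYPE}[{types[-1]}]:{TERM_CSA}")
        cols.append(cols[1] * csa)
    return np.column_stack(cols), terms


class _ProfiledML:
    """Profiled ML machinery for the nested random-intercept model.

    Per animal, the random-effect design is U = [1 | scaffold dummies |
    cross-section dummies]; W = I + U diag(gamma_by_kind) U' and all the
    GLS cross-products are corrected through a small (q x q) Woodbury solve.
    All data-dependent cross-products are precomputed once.
    """

    KINDS = ("animal", "scaffold", "cross_section")

    def __init__(self, df: pd.DataFrame, x: np.ndarray, y: np.ndarray):
        self.n = len(df)
        self.p = x.shape[1]
        self.blocks = []
        for _, g in df.groupby("animal_id", sort=True):
            rows = g.index.to_numpy()
            xg, yg = x[rows], y[rows]
            n_g = len(rows)
            u_cols = [np.ones(n_g)]
            kinds = [0]
            for _, sg in g.groupby("scaffold_id", sort=True):
                d = np.zeros(n_g)
                d[np.searchsorted(rows, sg.index.to_numpy())] = 1.0
                u_cols.append(d)
                kinds.append(1)
            for _, cg in g.groupby("cross_section_id", sort=True):
                d = np.zeros(n_g)
                d[np.searchsorted(rows, cg.index.to_numpy())] = 1.0
                u_cols.append(d)
                kinds.append(2)
            u = np.column_stack(u_cols)
            self.blocks.append(dict(
                kinds=np.array(kinds),
                utu=u.T @ u,
                utx=u.T @ xg,
                uty=u.T @ yg,
                xtx=xg.T @ xg,
                xty=xg.T @ yg,
                yty=float(yg @ yg),
            ))

    def gls(self, gamma: np.ndarray):
        """Return (XtWiX, XtWiy, ytWiy, logdetW) for variance ratios gamma."""
        p = self.p
        xtwix = np.zeros((p, p))
        xtwiy = np.zeros(p)
        ytwiy = 0.0
        logdet = 0.0
        for blk in self.blocks:
            d = gamma[blk["kinds"]]
            act = d > 1e-12
            if not act.any():
                xtwix += blk["xtx"]
                xtwiy += blk["xty"]
                ytwiy += blk["yty"]
                continue
            da = d[act]
            m = blk["utu"][np.ix_(act, act)] + np.diag(1.0 / da)
            c, low = cho_factor(m)
            utx = blk["utx"][act]
            uty = blk["uty"][act]
            sx = cho_solve((c, low), utx)
            sy = cho_solve((c, low), uty)
            xtwix += blk["xtx"] - utx.T @ sx
            xtwiy += blk["xty"] - utx.T @ sy
            ytwiy += blk["yty"] - float(uty @ sy)
            logdet += 2.0 * float(np.sum(np.log(np.diag(c)))) + float(np.sum(np.log(da)))
        return xtwix, xtwiy, ytwiy, logdet

    def profile_nll(self, gamma: np.ndarray, reml: bool = False) -> float:
        xtwix, xtwiy, ytwiy, logdet = self.gls(gamma)
        try:
            beta = np.linalg.solve(xtwix, xtwiy)
        except np.linalg.LinAlgError:
            return np.inf
        rss = ytwiy - float(beta @ xtwiy)
        if rss <= 0:
            return np.inf
        if reml:
            nn = self.n - self.p
            sign, logdet_x = np.linalg.slogdet(xtwix)
            if sign <= 0:
                return np.inf
            sigma2 = rss / nn
            return 0.5 * (nn * (np.log(2 * np.pi * sigma2) + 1.0)
                          + logdet + logdet_x)
        sigma2 = rss / self.n
        return 0.5 * (self.n * (np.log(2 * np.pi * sigma2) + 1.0) + logdet)

    def nll_theta(self, theta: np.ndarray, reml: bool = False) -> float:
        """Negative (restricted) log-likelihood in variance parametrization
        theta = (v_animal, v_scaffold, v_cs, sigma2_resid)."""
        v = theta[:3]
        s2 = theta[3]
        if s2 <= 0 or np.any(v < 0):
            return np.inf
        gamma = v / s2
        xtwix, xtwiy, ytwiy, logdet = self.gls(gamma)
        try:
            beta = np.linalg.solve(xtwix, xtwiy)
        except np.linalg.LinAlgError:
            return np.inf
        rss = ytwiy - float(beta @ xtwiy)
        nll = 0.5 * (self.n * np.log(2 * np.pi * s2) + rss / s2 + logdet)
        if reml:
            sign, logdet_x = np.linalg.slogdet(xtwix)
            if sign <= 0:
                return np.inf
            nll += 0.5 * (logdet_x - self.p * np.log(2 * np.pi * s2))
        return nll

    def cov_beta(self, theta: np.ndarray) -> np.ndarray:
        v, s2 = theta[:3], theta[3]
        xtwix, _, _, _ = self.gls(v / s2)
        return s2 * np.linalg.inv(xtwix)


def fit_multilevel(
    records: pd.DataFrame,
    fixed_terms: tuple = FULL_MODEL,
    center_csa: bool = True,
    df_method: str = "satterthwaite",
    n_starts: int = 3,
    reml: bool = True,
) -> MixedModelResult:
    """Fit the nested three-level mixed model by (restricted) maximum
    likelihood.

    ``records`` is the long-format sector table (columns: animal_id,
    scaffold_id, cross_section_id, scaffold_type, cross_sectional_area, ess).
    ``fixed_terms`` selects among scaffold type, CSA and their interaction
    (always with an intercept).  CSA is mean-centered by default so the type
    main effect is evaluated at the mean cross-sectional area.
    ``n_starts`` (1-3) trades robustness of the variance-ratio search for
    speed; simulation studies that fit hundreds of replicates of the same
    well-behaved design can safely use a single start.

    ``reml`` (default) removes the downward small-sample bias of the ML
    variance components, which matters here because the upper levels have few
    clusters (animals, scaffolds); without it the fixed-effect standard
    errors are too small and tests anti-conservative.  Use ``reml=False``
    when models with different fixed effects must be compared by likelihood
    ratio or AIC (see :func:`select_model`).
    """
    missing = [c for c in _REQUIRED if c not in records.columns]
    if missing:
        raise ValueError(f"records missing columns {missing}")
    df = records.reset_index(drop=True)
    _check_nesting(df)
    x, terms = _design_matrix(df, fixed_terms, center_csa)
    y = df["ess"].to_numpy(float)
    ml = _ProfiledML(df, x, y)

    def obj(s):
        return ml.profile_nll(s * s, reml=reml)

    if not 1 <= n_starts <= 3:
        raise ValueError("n_starts must be 1, 2 or 3")
    best = None
    for start in ([0.3, 0.2, 0.2], [1.0, 0.5, 0.5],
                  [0.03, 0.03, 0.03])[:n_starts]:
        res = optimize.minimize(obj, np.sqrt(start), method="Nelder-Mead",
                                options=dict(xatol=1e-6, fatol=1e-9,
                                             maxiter=2000))
        if best is None or res.fun < best.fun:
            best = res
    gamma = best.x ** 2
    converged = bool(best.success or best.fun < np.inf)

    xtwix, xtwiy, ytwiy, _ = ml.gls(gamma)
    beta = np.linalg.solve(xtwix, xtwiy)
    rss = ytwiy - float(beta @ xtwiy)
    sigma2 = rss / (ml.n - ml.p if reml else ml.n)
    loglik = -ml.profile_nll(gamma, reml=reml)
    theta = np.concatenate([gamma * sigma2, [sigma2]])
    cov = ml.cov_beta(theta)
    se = np.sqrt(np.diag(cov))

    singular = [k for k, g in zip(_ProfiledML.KINDS, gamma) if g < 1e-8]

    dfs, used_method = _fixed_effect_dfs(ml, theta, df_method, reml)
    tvals = beta / se
    if np.isfinite(dfs).all():
        pvals = 2.0 * sps.t.sf(np.abs(tvals), dfs)
    else:
        pvals = 2.0 * sps.norm.sf(np.abs(tvals))

    fixed = pd.DataFrame(dict(term=terms, estimate=beta, se=se,
                              stat=tvals, df=dfs, pvalue=pvals))
    vc = {k: float(g * sigma2) for k, g in zip(_ProfiledML.KINDS, gamma)}
    vc["residual"] = float(sigma2)
    fingerprint = hash((ml.n, y.tobytes()))
    return MixedModelResult(
        fixed_effects=fixed,
        variance_components=vc,
        log_likelihood=float(loglik),
        n_obs=ml.n,
        n_params=len(terms) + 4,
        converged=converged,
        singular=singular,
        df_method=used_method,
        fixed_terms=tuple(fixed_terms),
        data_fingerprint=fingerprint,
        reml=reml,
    )


def _fixed_effect_dfs(ml: _ProfiledML, theta: np.ndarray, df_method: str,
                      reml: bool):
    """Satterthwaite-style df by the delta method on the variance-parameter
    Hessian; returns inf (normal approximation) on failure or by request."""
    p = ml.p
    if df_method != "satterthwaite":
        return np.full(p, np.inf), "normal"
    try:
        h = _numeric_hessian(lambda th: ml.nll_theta(th, reml=reml), theta)
        vtheta = np.linalg.inv(h)
        if np.any(np.diag(vtheta) <= 0):
            raise np.linalg.LinAlgError("Hessian not positive definite")
        dfs = np.empty(p)
        for k in range(p):
            grad = _numeric_grad(lambda th: ml.cov_beta(th)[k, k], theta)
            denom = float(grad @ vtheta @ grad)
            var_k = ml.cov_beta(theta)[k, k]
            dfs[k] = max(2.0 * var_k**2 / denom, 1.0) if denom > 0 else np.inf
        return dfs, "satterthwaite"
    except (np.linalg.LinAlgError, FloatingPointError, ValueError):
        return np.full(p, np.inf), "normal"


def _numeric_grad(f, x, rel=1e-4):
    g = np.empty(len(x))
    for i in range(len(x)):
        h = rel * max(abs(x[i]), 1e-8)
        xp, xm = x.copy(), x.copy()
        xp[i] += h
        xm[i] = max(xm[i] - h, 0.0) if i < 3 else xm[i] - h
        g[i] = (f(xp) - f(xm)) / (xp[i] - xm[i])
    return g


def _numeric_hessian(f, x, rel=1e-3):
    n = len(x)
    h = np.empty((n, n))
    steps = [rel * max(abs(xi), 1e-8) for xi in x]
    f0 = f(x)
    for i in range(n):
        for j in range(i, n):
            xi, xj = steps[i], steps[j]
            if i == j:
                xp, xm = x.copy(), x.copy()
                xp[i] += xi
                xm[i] -= xi
                if xm[i] < 0 and i < 3:
                    # one-sided second difference at the boundary
                    x2 = x.copy()
                    x2[i] += 2 * xi
                    h[i, i] = (f(x2) - 2 * f(xp) + f0) / xi**2
                else:
                    h[i, i] = (f(xp) - 2 * f0 + f(xm)) / xi**2
            else:
                xpp, xpm, xmp, xmm = x.copy(), x.copy(), x.copy(), x.copy()
                xpp[i] += xi; xpp[j] += xj
                xpm[i] += xi; xpm[j] -= xj
                xmp[i] -= xi; xmp[j] += xj
                xmm[i] -= xi; xmm[j] -= xj
                if (i < 3 and (xmp[i] < 0 or xmm[i] < 0)) or (j < 3 and (xpm[j] < 0 or xmm[j] < 0)):
                    # fall back to forward differences near the boundary
                    h[i, j] = h[j, i] = (f(xpp) - f(xpm if xpm[j] >= 0 else x)
                                         - f(xmp if xmp[i] >= 0 else x) + f0) / (xi * xj)
                else:
                    h[i, j] = h[j, i] = (f(xpp) - f(xpm) - f(xmp) + f(xmm)) / (4 * xi * xj)
    return h


def select_model(candidates: list) -> dict:
    """Rank ML-fitted candidates and compare nested pairs by likelihood ratio.

    All candidates must be fitted on identical records.  Returns the best
    model (highest log-likelihood, ties broken by fewer parameters), the
    ranking table and the nested likelihood-ratio tests; non-nested pairs are
    compared by AIC only.
    """
    if not candidates:
        raise ValueError("no candidate models")
    if any(m.reml for m in candidates):
        raise ValueError("model selection across fixed-effect structures "
                         "requires ML fits (reml=False)")
    fp = {m.data_fingerprint for m in candidates}
    if len(fp) > 1:
        raise ValueError("candidates were fitted on different records")

    table = pd.DataFrame([
        dict(model="+".join(m.fixed_terms) if m.fixed_terms else "intercept",
             log_likelihood=m.log_likelihood, n_params=m.n_params, aic=m.aic)
        for m in candidates
    ])
    lrt_rows = []
    for i, a in enumerate(candidates):
        for j, b in enumerate(candidates):
            if i >= j:
                continue
            sa, sb = set(a.fixed_terms), set(b.fixed_terms)
            if sa < sb or sb < sa:
                small, big = (a, b) if sa < sb else (b, a)
                stat = 2.0 * (big.log_likelihood - small.log_likelihood)
                ddf = big.n_params - small.n_params
                lrt_rows.append(dict(
                    reduced="+".join(small.fixed_terms),
                    full="+".join(big.fixed_terms),
                    statistic=max(stat, 0.0),
                    df=ddf,
                    pvalue=float(sps.chi2.sf(max(stat, 0.0), ddf)),
                ))
    order = sorted(
        range(len(candidates)),
        key=lambda k: (-candidates[k].log_likelihood, candidates[k].n_params),
    )
    # exact ties in likelihood resolve to the smaller model
    best_idx = order[0]
    for k in order[1:]:
        if abs(candidates[k].log_likelihood
               - candidates[best_idx].log_likelihood) < 1e-6 \
                and candidates[k].n_params < candidates[best_idx].n_params:
            best_idx = k
    return dict(
        best=candidates[best_idx],
        table=table,
        lrt=pd.DataFrame(lrt_rows),
    )
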