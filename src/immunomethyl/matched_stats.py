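"""Matched case-control inference for 1:1 age-matched methylation studies.

The central model is conditional logistic regression for 1:1 matched pairs.
Conditioning on one case per pair reduces the stratum likelihood to a
logistic model on within-pair covariate differences d_i = x_case - x_control:

    l(beta) = sum_i log sigma(d_i' beta)

which this module maximises by Newton iteration with explicit separation
detection. Around it sit the rest of the inference machinery used in such
studies: trapezoid-free AUC with DeLong confidence intervals, Holm
family-wise adjustment, backward variable selection, Harrell's optimism
bootstrap for internal AUC validation, and the small-sample nonparametric
tests (Wilcoxon signed-rank, Mann-Whitney, Jonckheere-Terpstra trend,
Spearman correlation).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit
from statsmodels.stats.multitest import multipletests


# --------------------------------------------------------------------------
# cohort container
# --------------------------------------------------------------------------


@dataclass
class MatchedCohort:
    """1:1 matched case-control samples.

    ``samples`` is indexed by sample_id and must carry ``pair_id`` and a
    boolean ``is_case`` column; covariates (age, bmi, ...) and exposure
    scores may be merged in. Exactly one case and one control per pair, with
    ages within ``age_tolerance`` years.
    """

    samples: pd.DataFrame
    age_tolerance: float = 1.0
    validate: bool = True

    def __post_init__(self) -> None:
        df = self.samples
        if not self.validate:
            return
        for col in ("pair_id", "is_case"):
            if col not in df.columns:
                raise ValueError(f"sample sheet missing column {col!r}")
        if df.index.has_duplicates:
            raise ValueError("duplicate sample ids")
        problems = []
        for pid, grp in df.groupby("pair_id"):
            n_case = int(grp["is_case"].sum())
            if len(grp) != 2 or n_case != 1:
                problems.append(
                    f"pair {pid!r}: {len(grp)} samples, {n_case} cases (need 1+1)"
                )
                continue
            if "age" in grp.columns:
                gap = abs(float(grp["age"].iloc[0]) - float(grp["age"].iloc[1]))
                if gap > self.age_tolerance + 1e-9:
                    problems.append(
                        f"pair {pid!r}: age gap {gap:.2f}y exceeds "
                        f"tolerance {self.age_tolerance}y"
                    )
        if problems:
            raise ValueError("invalid matched cohort: " + "; ".join(problems))

    @property
    def n_pairs(self) -> int:
        return self.samples["pair_id"].nunique()

    def case_control_ids(self) -> pd.DataFrame:
        """One row per pair: case and control sample ids."""
        df = self.samples
        cases = df[df["is_case"]].reset_index().set_index("pair_id")
        ctrls = df[~df["is_case"]].reset_index().set_index("pair_id")
        idcol = df.index.name or "index"
        out = pd.DataFrame(
            {"case": cases[idcol], "control": ctrls[idcol]}
        ).sort_index()
        return out

    def differences(self, data: pd.DataFrame, columns=None) -> pd.DataFrame:
        """Within-pair case-minus-control differences, complete pairs only."""
        cols = list(columns) if columns is not None else list(data.columns)
        ids = self.case_control_ids()
        case = data.reindex(ids["case"])[cols].to_numpy(dtype=float)
        ctrl = data.reindex(ids["control"])[cols].to_numpy(dtype=float)
        d = pd.DataFrame(case - ctrl, index=ids.index, columns=cols)
        return d.dropna(axis=0, how="any")

    def labels(self) -> pd.Series:
        return self.samples["is_case"].astype(bool)

    def subset_pairs(self, pair_ids) -> "MatchedCohort":
        """Resampled cohort: pairs may repeat (bootstrap); ids are re-suffixed.

        Validation is skipped — the source cohort already satisfies the
        pairing invariants and resampling preserves them.
        """
        ids = self.case_control_ids()
        pair_ids = list(pair_ids)
        case_ids = ids.loc[pair_ids, "case"].to_numpy()
        ctrl_ids = ids.loc[pair_ids, "control"].to_numpy()
        order = np.empty(2 * len(pair_ids), dtype=object)
        order[0::2], order[1::2] = case_ids, ctrl_ids
        df = self.samples.loc[order].copy()
        rep = np.repeat(np.arange(len(pair_ids)), 2)
        df["pair_id"] = [f"bs{k}" for k in rep]
        df.index = pd.Index([f"{i}__bs{k}" for k, i in zip(rep, order)])
        return MatchedCohort(df, self.age_tolerance, validate=False)


# --------------------------------------------------------------------------
# conditional logistic regression
# --------------------------------------------------------------------------


@dataclass
class ClogitFit:
    """Fitted 1:1 conditional logistic model."""

    exposures: list[str]
    beta: np.ndarray
    se: np.ndarray
    loglik: float
    n_pairs: int
    converged: bool
    separation: bool
    n_iter: int

    def wald_p(self) -> np.ndarray:
        z = self.beta / self.se
        return 2 * stats.norm.sf(np.abs(z))

    def or_table(self, increment: float = 0.1, conf: float = 0.95) -> pd.DataFrame:
        """Odds ratios per ``increment`` units of each exposure with Wald CI."""
        z = stats.norm.ppf(0.5 + conf / 2)
        est = increment * self.beta
        half = z * increment * self.se
        return pd.DataFrame(
            {
                "beta_hat": self.beta,
                "se": self.se,
                "OR": np.exp(est),
                "CI_low": np.exp(est - half),
                "CI_high": np.exp(est + half),
                "p": self.wald_p(),
            },
            index=self.exposures,
        )


def _conditional_loglik(d: np.ndarray, beta: np.ndarray) -> float:
    # sum_i log sigma(d_i' beta), numerically stable
    eta = d @ beta
    return float(-(np.logaddexp(0.0, -eta)).sum())


def fit_clogit(
    diffs: pd.DataFrame,
    tol: float = 1e-8,
    max_iter: int = 100,
    separation_bound: float = 15.0,
) -> ClogitFit:
    """Maximise the paired conditional likelihood by Newton iteration.

    ``diffs`` holds case-minus-control exposure differences, one row per
    complete pair. Separation (monotone likelihood) is flagged when the
    fitted linear predictors are one-signed and the coefficient exceeds
    ``separation_bound`` per unit-sd covariate; no usable OR exists then.
    """
    d = diffs.to_numpy(dtype=float)
    if d.ndim != 2 or d.shape[0] < 2:
        raise ValueError("need at least 2 complete pairs")
    if not np.any(d != 0):
        raise ValueError("no within-pair variation in exposures")
    n, p = d.shape
    sd = d.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    beta = np.zeros(p)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = d @ beta
        mu = expit(eta)
        grad = d.T @ (1.0 - mu)
        w = mu * (1.0 - mu)
        hess = (d * w[:, None]).T @ d
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            break
        # dampen huge steps (separation makes the Hessian vanish)
        norm = np.max(np.abs(step * sd))
        if norm > 5.0:
            step = step * (5.0 / norm)
        beta = beta + step
        if np.max(np.abs(step * sd)) < tol:
            converged = True
            break
    eta = d @ beta
    scaled = np.abs(beta) * sd
    one_signed = np.all(eta >= -1e-12) or np.all(eta <= 1e-12)
    separation = bool(one_signed and np.any(eta != 0) and scaled.max() > separation_bound)
    mu = expit(eta)
    w = mu * (1.0 - mu)
    hess = (d * w[:, None]).T @ d
    try:
        cov = np.linalg.inv(hess)
        se = np.sqrt(np.diag(cov))
    except np.linalg.LinAlgError:
        se = np.full(p, np.nan)
        separation = True
    if separation:
        converged = False
    return ClogitFit(
        exposures=list(diffs.columns),
        beta=beta,
        se=se,
        loglik=_conditional_loglik(d, beta),
        n_pairs=n,
        converged=converged,
        separation=separation,
        n_iter=it,
    )


# --------------------------------------------------------------------------
# AUC with DeLong confidence interval
# --------------------------------------------------------------------------


def _midrank_placements(cases: np.ndarray, controls: np.ndarray):
    v10 = np.empty(len(cases))
    for i, x in enumerate(cases):
        v10[i] = np.mean((x > controls) + 0.5 * (x == controls))
    v01 = np.empty(len(controls))
    for j, y in enumerate(controls):
        v01[j] = np.mean((cases > y) + 0.5 * (cases == y))
    return v10, v01


def auc(scores_cases, scores_controls, conf: float = 0.95):
    """Mann-Whitney AUC with a DeLong-variance Wald confidence interval.

    AUC = (concordant pairs + 0.5 * ties) / (n_case * n_control). Returns
    (auc, (lo, hi)); the CI is clipped to [0, 1] and collapses to the point
    estimate when all scores tie.
    """
    x = np.asarray(scores_cases, dtype=float)
    y = np.asarray(scores_controls, dtype=float)
    x, y = x[~np.isnan(x)], y[~np.isnan(y)]
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both classes must be non-empty")
    v10, v01 = _midrank_placements(x, y)
    a = float(v10.mean())
    s10 = v10.var(ddof=1) / len(x) if len(x) > 1 else 0.0
    s01 = v01.var(ddof=1) / len(y) if len(y) > 1 else 0.0
    se = float(np.sqrt(s10 + s01))
    z = stats.norm.ppf(0.5 + conf / 2)
    lo, hi = max(0.0, a - z * se), min(1.0, a + z * se)
    return a, (lo, hi)


def auc_from_labels(scores, is_case, conf: float = 0.95):
    scores = np.asarray(scores, dtype=float)
    is_case = np.asarray(is_case, dtype=bool)
    return auc(scores[is_case], scores[~is_case], conf)


# --------------------------------------------------------------------------
# multiplicity
# --------------------------------------------------------------------------


def holm_adjust(pvals) -> np.ndarray:
    """Holm step-down adjusted p-values, in the input order."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="holm")[1]


# --------------------------------------------------------------------------
# association tables, selection, bootstrap validation
# --------------------------------------------------------------------------


def univariable_associations(
    cohort: MatchedCohort,
    scores: pd.DataFrame,
    increment: float = 0.1,
    conf: float = 0.95,
) -> pd.DataFrame:
    """Per-exposure univariable conditional logistic fits plus AUC.

    One Holm family per call (an analysis block, e.g. the nine mdNLRs).
    ORs are reported per ``increment`` exposure units (default 0.1, i.e. a
    10 percentage-point methylation increase for beta-scale exposures).
    """
    rows = []
    labels = cohort.labels()
    for col in scores.columns:
        d = cohort.differences(scores[[col]])
        fit = fit_clogit(d)
        tab = fit.or_table(increment, conf).loc[col]
        s = scores[col]
        a, (lo, hi) = auc_from_labels(
            s.reindex(labels.index), labels.to_numpy()
        )
        rows.append(
            {
                "exposure": col,
                "n_pairs": fit.n_pairs,
                "beta_hat": tab["beta_hat"],
                "OR": tab["OR"] if not fit.separation else np.nan,
                "CI_low": tab["CI_low"] if not fit.separation else np.nan,
                "CI_high": tab["CI_high"] if not fit.separation else np.nan,
                "p": tab["p"],
                "separation": fit.separation,
                "AUC": a,
                "AUC_CI_low": lo,
                "AUC_CI_high": hi,
            }
        )
    out = pd.DataFrame(rows).set_index("exposure")
    out["p_adj"] = holm_adjust(out["p"].to_numpy())
    return out


@dataclass
class ModelFit:
    """Multivariable model after selection and (optionally) bootstrap validation."""

    selected: list[str]
    fit: ClogitFit | None
    trace: list = field(default_factory=list)  # (dropped exposure, its p)
    apparent_auc: float = np.nan
    optimism: float = np.nan
    adjusted_auc: float = np.nan
    n_boot_failed: int = 0


def _linear_predictor(scores: pd.DataFrame, fit: ClogitFit) -> pd.Series:
    return scores[fit.exposures] @ pd.Series(fit.beta, index=fit.exposures)


def backward_select(
    cohort: MatchedCohort,
    scores: pd.DataFrame,
    exposures=None,
    alpha_stay: float = 0.20,
) -> ModelFit:
    """Backward elimination on Wald p-values at ``alpha_stay`` to remain.

    Iteratively refits the multivariable conditional model and drops the
    exposure with the largest p exceeding the threshold (ties: larger p
    first, then lexicographic name). The empty model is allowed.
    """
    current = list(exposures) if exposures is not None else list(scores.columns)
    if not current:
        raise ValueError("need at least one exposure")
    trace: list = []
    fit = None
    while current:
        d = cohort.differences(scores[current])
        fit = fit_clogit(d)
        # separated coefficients have undefined p; treat as 1 so they drop first
        pvals = pd.Series(fit.wald_p(), index=current).fillna(1.0)
        worst = pvals.to_frame("p").reset_index(names="name")
        worst = worst.sort_values(["p", "name"], ascending=[False, True])
        top = worst.iloc[0]
        if top["p"] <= alpha_stay:
            break
        trace.append((top["name"], float(top["p"])))
        current = [c for c in current if c != top["name"]]
        fit = None
    mf = ModelFit(selected=current, fit=fit, trace=trace)
    if fit is not None:
        lp = _linear_predictor(scores, fit)
        labels = cohort.labels()
        mf.apparent_auc = auc_from_labels(lp.reindex(labels.index), labels)[0]
    else:
        mf.apparent_auc = 0.5
    return mf


def bootstrap_adjusted_auc(
    cohort: MatchedCohort,
    scores: pd.DataFrame,
    exposures=None,
    B: int = 200,
    seed: int = 0,
    alpha_stay: float = 0.20,
    max_failure_frac: float = 0.2,
    resampler=None,
) -> ModelFit:
    """Harrell optimism bootstrap of the post-selection AUC.

    The full model-building procedure (backward selection + refit) is
    repeated on ``B`` pair-resampled replicates; optimism is the mean of
    (replicate-sample AUC - original-sample AUC of the replicate model), and
    adjusted AUC = apparent AUC - optimism. The resampling unit is the
    matched pair, preserving the 1:1 structure.

    ``resampler(rng, pair_ids) -> array of pair ids`` can replace the default
    with-replacement draw (useful for deterministic checks).
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    rng = np.random.default_rng(seed)
    base = backward_select(cohort, scores, exposures, alpha_stay)
    labels = cohort.labels()
    pair_ids = cohort.samples["pair_id"].unique()
    optimisms = []
    failed = 0
    for _ in range(B):
        if resampler is None:
            draw = rng.choice(pair_ids, size=len(pair_ids), replace=True)
        else:
            draw = resampler(rng, pair_ids)
        boot = cohort.subset_pairs(draw)
        boot_scores = scores.reindex(
            [i.rsplit("__bs", 1)[0] for i in boot.samples.index]
        )
        boot_scores.index = boot.samples.index
        try:
            mf = backward_select(boot, boot_scores, exposures, alpha_stay)
            if mf.fit is None:
                boot_auc = orig_auc = 0.5
            else:
                lp_b = _linear_predictor(boot_scores, mf.fit)
                boot_auc = auc_from_labels(
                    lp_b.reindex(boot.samples.index), boot.labels()
                )[0]
                lp_o = _linear_predictor(scores, mf.fit)
                orig_auc = auc_from_labels(lp_o.reindex(labels.index), labels)[0]
        except (ValueError, np.linalg.LinAlgError):
            failed += 1
            continue
        optimisms.append(boot_auc - orig_auc)
    if failed > max_failure_frac * B:
        raise RuntimeError(f"{failed}/{B} bootstrap replicates failed")
    base.optimism = float(np.mean(optimisms)) if optimisms else 0.0
    base.adjusted_auc = base.apparent_auc - base.optimism
    base.n_boot_failed = failed
    return base


# --------------------------------------------------------------------------
# nonparametric tests
# --------------------------------------------------------------------------


def wilcoxon_signed_rank(diffs, alternative: str = "two-sided"):
    """Paired Wilcoxon signed-rank test; zeros dropped.

    Exact null enumeration for n <= 25 without ties in |d|, normal
    approximation with tie/continuity correction otherwise.
    """
    d = np.asarray(diffs, dtype=float)
    d = d[~np.isnan(d)]
    d = d[d != 0]
    if d.size == 0:
        raise ValueError("degenerate: all paired differences are zero")
    has_ties = len(np.unique(np.abs(d))) < len(d)
    method = "exact" if (len(d) <= 25 and not has_ties) else "approx"
    res = stats.wilcoxon(
        d, alternative=alternative, method=method, correction=(method == "approx")
    )
    return float(res.statistic), float(res.pvalue)


def mann_whitney(group_a, group_b, alternative: str = "two-sided"):
    """Mann-Whitney U test (exact for small untied samples, else tie-corrected
    normal approximation). Returns (U_a, p); AUC = U_a / (nA * nB)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    res = stats.mannwhitneyu(a, b, alternative=alternative, method="auto")
    return float(res.statistic), float(res.pvalue)


def _jt_statistic(groups) -> float:
    jt = 0.0
    for g, h in combinations(range(len(groups)), 2):
        x, y = groups[g], groups[h]
        jt += float(np.sum(y[None, :] > x[:, None]) + 0.5 * np.sum(y[None, :] == x[:, None]))
    return jt


def jonckheere_terpstra(
    groups,
    alternative: str = "two-sided",
    method: str = "auto",
    n_perm: int = 10_000,
    seed: int = 0,
):
    """Jonckheere-Terpstra trend test across ordered groups.

    JT sums, over ordered group pairs g < h, the count of (x in g, y in h)
    with y > x (ties count one half); large JT indicates an increasing trend.
    The null distribution comes from exact label permutations for total
    n <= 10, from ``n_perm`` seeded random permutations otherwise, or from
    the normal approximation when ``method='normal'``. Returns
    (JT, p, method_used).
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least 2 ordered groups")
    if any(g.size == 0 for g in groups):
        raise ValueError("every group must be non-empty")
    sizes = [g.size for g in groups]
    pooled = np.concatenate(groups)
    N = pooled.size
    jt_obs = _jt_statistic(groups)
    mean_null = sum(
        sizes[g] * sizes[h] for g, h in combinations(range(len(groups)), 2)
    ) / 2.0

    def split(arr):
        out, k = [], 0
        for s in sizes:
            out.append(arr[k : k + s])
            k += s
        return out

    if method == "auto":
        method = "exact" if N <= 10 else "permutation"
    if method == "normal":
        var = (N * N * (2 * N + 3) - sum(s * s * (2 * s + 3) for s in sizes)) / 72.0
        z = (jt_obs - mean_null) / np.sqrt(var)
        if alternative == "two-sided":
            p = 2 * stats.norm.sf(abs(z))
        elif alternative == "increasing":
            p = stats.norm.sf(z)
        else:
            p = stats.norm.cdf(z)
        return jt_obs, float(min(p, 1.0)), "normal"
    if method == "exact":
        # enumerate distinct partitions of the pooled indices into the group
        # sizes (multinomial count, feasible for N <= 10)
        null = []

        def recurse(remaining: tuple, assigned: list) -> None:
            if len(assigned) == len(sizes) - 1:
                null.append(
                    _jt_statistic([pooled[list(ix)] for ix in assigned]
                                  + [pooled[list(remaining)]])
                )
                return
            size = sizes[len(assigned)]
            for pick in combinations(remaining, size):
                rest = tuple(i for i in remaining if i not in pick)
                recurse(rest, assigned + [pick])

        recurse(tuple(range(N)), [])
        null = np.asarray(null)
    else:
        rng = np.random.default_rng(seed)
        null = np.empty(n_perm)
        for i in range(n_perm):
            null[i] = _jt_statistic(split(rng.permutation(pooled)))
    if alternative == "increasing":
        p = float(np.mean(null >= jt_obs - 1e-12))
    elif alternative == "decreasing":
        p = float(np.mean(null <= jt_obs + 1e-12))
    else:
        dev = np.abs(null - mean_null)
        p = float(np.mean(dev >= abs(jt_obs - mean_null) - 1e-12))
    return jt_obs, p, method


def spearman_rho(x, y):
    """Spearman rank correlation (average ranks for ties), t-approximation p."""
    res = stats.spearmanr(x, y, nan_policy="omit")
    return float(res.statistic), float(res.pvalue)
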