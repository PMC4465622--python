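"""Association statistics for ordinal ossification classes.

Treatment effects on the four ordered ossification classes are tested two
ways, as is standard for this kind of categorical skeletal data:

* Pearson chi-square on the group x class contingency table (ordering
  disregarded by construction), and
* a proportional-odds (cumulative logit) ordinal logistic regression with
  a treatment indicator, whose exponentiated coefficient is the common
  odds ratio (OR) of reaching a higher ossification class.

Classes absent from every group are collapsed away before testing (4 -> 3
classes). Small cohorts with near-empty cells can separate the likelihood;
the fit detects this and falls back to a ridge-penalized likelihood with
profile-likelihood confidence intervals, flagged on the result.

The proportional-odds model: with classes k = 1..K and treatment x,

    logit P(Y <= k | x) = alpha_k - beta * x,

so beta > 0 shifts probability mass toward higher classes and
OR = exp(beta). The likelihood is maximized over the monotone cutpoints
alpha and beta on the grouped multinomial counts.

No multiple-testing correction is applied to per-structure tests; reports
carry the number of tests performed so readers can judge.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import expit

from .morphometry import significance_stars
from .ossification import CATEGORIES, OssificationRecord

__all__ = [
    "ContingencyTable",
    "OrdinalFit",
    "collapse_classes",
    "chi_square",
    "fit_ordinal_logistic",
    "odds_ratio_2x2",
    "grouped_contrast",
    "significance_report",
]


@dataclass(frozen=True)
class ContingencyTable:
    """Group x ordered-class counts.

    ``counts`` is indexed by treatment group with columns in ordinal class
    order (a subset of ``absent < early < advanced < over`` after collapse).
    """

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        c = self.counts
        arr = c.to_numpy()
        if (arr < 0).any() or not np.issubdtype(arr.dtype, np.number):
            raise ValueError("counts must be non-negative numbers")
        known = [col for col in c.columns if col in CATEGORIES]
        if len(known) == len(c.columns):
            order = [col for col in CATEGORIES if col in c.columns]
            if list(c.columns) != order:
                raise ValueError(
                    f"columns must follow the ordinal order {order}, got {list(c.columns)}"
                )

    @classmethod
    def from_records(
        cls,
        records: list[OssificationRecord],
        structure: str | None = None,
        conditions: list[str] | None = None,
    ) -> "ContingencyTable":
        recs = [r for r in records if structure is None or r.structure == structure]
        if not recs:
            raise ValueError(f"no records for structure {structure!r}")
        conds = conditions or list(dict.fromkeys(r.condition for r in recs))
        counts = pd.DataFrame(0, index=conds, columns=list(CATEGORIES), dtype=int)
        for r in recs:
            if r.condition in counts.index:
                counts.loc[r.condition, r.category] += 1
        counts.index.name = "group"
        return cls(counts)

    @property
    def groups(self) -> list[str]:
        return list(self.counts.index)

    @property
    def classes(self) -> list[str]:
        return list(self.counts.columns)


def collapse_classes(table: ContingencyTable) -> ContingencyTable:
    """Drop classes with zero total count across all groups (idempotent)."""
    totals = table.counts.sum(axis=0)
    keep = [c for c in table.classes if totals[c] > 0]
    if len(keep) < 2:
        raise ValueError("fewer than 2 populated classes; no association testable")
    return ContingencyTable(table.counts[keep])


def chi_square(table: ContingencyTable) -> dict:
    """Pearson chi-square of independence, no continuity correction.

    Requires populated margins (collapse first); warns when any expected
    cell count is below 5 but still reports the statistic.
    """
    counts = table.counts.to_numpy(dtype=float)
    if counts.shape[0] < 2 or counts.shape[1] < 2:
        raise ValueError("need at least 2 groups and 2 classes")
    if (counts.sum(axis=0) == 0).any() or (counts.sum(axis=1) == 0).any():
        raise ValueError("zero row/column margin; collapse classes first")
    res = stats.chi2_contingency(counts, correction=False)
    n_small = int((res.expected_freq < 5).sum())
    if n_small:
        warnings.warn(
            f"{n_small} expected cell count(s) below 5; chi-square may be unreliable",
            stacklevel=2,
        )
    return {
        "chi2": float(res.statistic),
        "df": int(res.dof),
        "p": float(res.pvalue),
        "expected": res.expected_freq,
        "n_expected_below_5": n_small,
    }


# ---------------------------------------------------------------------------
# Proportional-odds (cumulative logit) fit on grouped counts
# ---------------------------------------------------------------------------


@dataclass
class OrdinalFit:
    beta: float
    or_: float
    ci95: tuple[float, float]
    thresholds: np.ndarray
    p: float
    separation_flag: bool
    converged: bool
    loglik: float
    se: float
    reference_group: str
    treatment_group: str
    betas: dict[str, float] = field(default_factory=dict)
    p_method: str = "wald"


def _cell_probs(alphas: np.ndarray, eta: float) -> np.ndarray:
    """Class probabilities under cumulative logits alpha_k - eta."""
    cum = expit(alphas - eta)
    return np.diff(np.concatenate(([0.0], cum, [1.0])))


def _negll(alphas: np.ndarray, betas: np.ndarray, counts: np.ndarray) -> float:
    # counts: groups x classes; betas[0] = 0 (reference)
    total = 0.0
    for g in range(counts.shape[0]):
        p = np.clip(_cell_probs(alphas, betas[g]), 1e-300, None)
        total -= float(counts[g] @ np.log(p))
    return total


def _unpack(theta: np.ndarray, k: int, n_beta: int) -> tuple[np.ndarray, np.ndarray]:
    # monotone cutpoints via log-difference reparameterization
    raw = theta[: k - 1]
    alphas = np.concatenate(([raw[0]], raw[0] + np.cumsum(np.exp(raw[1:]))))
    betas = np.concatenate(([0.0], theta[k - 1 :]))
    return alphas, betas


def _start(counts: np.ndarray) -> np.ndarray:
    k = counts.shape[1]
    tot = counts.sum(axis=0)
    cum = np.clip(np.cumsum(tot)[:-1] / tot.sum(), 1e-3, 1 - 1e-3)
    alphas = np.log(cum / (1 - cum))
    diffs = np.maximum(np.diff(alphas), 1e-3)
    raw = np.concatenate(([alphas[0]], np.log(diffs)))
    return np.concatenate((raw, np.zeros(counts.shape[0] - 1)))


def _fd_hessian(f, x: np.ndarray, eps: float = 1e-5) -> np.ndarray:
    n = len(x)
    h = np.empty((n, n))
    for i in range(n):
        for j in range(i, n):
            e_i = np.zeros(n)
            e_j = np.zeros(n)
            e_i[i] = eps
            e_j[j] = eps
            h[i, j] = h[j, i] = (
                f(x + e_i + e_j) - f(x + e_i - e_j) - f(x - e_i + e_j) + f(x - e_i - e_j)
            ) / (4 * eps * eps)
    return h


def _minimize(counts: np.ndarray, lam: float) -> tuple[np.ndarray, np.ndarray, float, bool]:
    k = counts.shape[1]
    n_beta = counts.shape[0] - 1

    def objective(theta: np.ndarray) -> float:
        alphas, betas = _unpack(theta, k, n_beta)
        pen = 0.5 * lam * float(betas[1:] @ betas[1:])
        return _negll(alphas, betas, counts) + pen

    res = optimize.minimize(objective, _start(counts), method="Nelder-Mead",
                            options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 20000})
    res = optimize.minimize(objective, res.x, method="BFGS",
                            options={"gtol": 1e-9, "maxiter": 2000})
    alphas, betas = _unpack(res.x, k, n_beta)
    return alphas, betas, float(res.fun), bool(np.isfinite(res.fun))


def _profile_ci(counts: np.ndarray, g_idx: int, beta_hat: float, obj_min: float,
                lam: float, level_drop: float = 1.9207) -> tuple[float, float]:
    """Profile-(penalized-)likelihood CI for one group effect."""
    k = counts.shape[1]
    n_beta = counts.shape[0] - 1

    def profile(beta0: float) -> float:
        # profile out cutpoints and the other betas with beta_{g_idx} fixed
        def obj2(free: np.ndarray) -> float:
            raw = free[: k - 1]
            alphas = np.concatenate(([raw[0]], raw[0] + np.cumsum(np.exp(raw[1:]))))
            other = list(free[k - 1 :])
            betas = [0.0]
            oi = 0
            for g in range(1, counts.shape[0]):
                if g == g_idx:
                    betas.append(beta0)
                else:
                    betas.append(other[oi])
                    oi += 1
            betas = np.asarray(betas)
            pen = 0.5 * lam * float(betas[1:] @ betas[1:])
            return _negll(alphas, betas, counts) + pen

        start = _start(counts)
        free0 = np.concatenate((start[: k - 1], np.zeros(n_beta - 1)))
        r = optimize.minimize(obj2, free0, method="Nelder-Mead",
                              options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 10000})
        return float(r.fun)

    def crossing(beta0: float) -> float:
        return profile(beta0) - obj_min - level_drop

    lo, hi = beta_hat, beta_hat
    step = 0.5
    b = beta_hat - step
    while crossing(b) < 0 and beta_hat - b < 30:
        b -= step
    lo = optimize.brentq(crossing, b, beta_hat, xtol=1e-4) if crossing(b) >= 0 else -np.inf
    b = beta_hat + step
    while crossing(b) < 0 and b - beta_hat < 30:
        b += step
    hi = optimize.brentq(crossing, beta_hat, b, xtol=1e-4) if crossing(b) >= 0 else np.inf
    return float(lo), float(hi)


def fit_ordinal_logistic(
    table: ContingencyTable,
    reference_group: str | None = None,
    p_method: str = "wald",
    separation_beta: float = 8.0,
    ridge_lambda: float = 1.0,
) -> OrdinalFit:
    """Maximum-likelihood proportional-odds fit of treatment vs reference.

    ``beta`` is the common log-odds of a higher ossification class in the
    treatment group; ``or_ = exp(beta)``. Complete/quasi-separation
    (diverging ``beta`` or a singular information matrix) triggers a
    ridge-penalized refit with ``separation_flag=True`` and a
    profile-likelihood CI instead of the Wald interval.
    """
    counts_df = collapse_classes(table).counts
    groups = list(counts_df.index)
    if reference_group is None:
        reference_group = groups[0]
    if reference_group not in groups:
        raise ValueError(f"reference group {reference_group!r} not in table")
    ordered = [reference_group] + [g for g in groups if g != reference_group]
    counts = counts_df.loc[ordered].to_numpy(dtype=float)
    k = counts.shape[1]

    alphas, betas, negll_min, ok = _minimize(counts, lam=0.0)
    separated = (not ok) or bool(np.max(np.abs(betas[1:])) > separation_beta)

    se = np.nan
    cov = None
    if not separated:
        def negll_nat(x: np.ndarray) -> float:
            return _negll(x[: k - 1], np.concatenate(([0.0], x[k - 1 :])), counts)

        x_hat = np.concatenate((alphas, betas[1:]))
        hess = _fd_hessian(negll_nat, x_hat)
        try:
            cov = np.linalg.inv(hess)
            ses = np.sqrt(np.diag(cov)[k - 1 :])
            if not np.all(np.isfinite(ses)):
                separated = True
            else:
                se = float(ses[0])
        except np.linalg.LinAlgError:
            separated = True

    lam = 0.0
    if separated:
        lam = ridge_lambda
        alphas, betas, negll_min, ok = _minimize(counts, lam=lam)
        if not ok:
            raise RuntimeError(
                "ordinal fit failed to converge even with ridge penalty; "
                f"counts=\n{counts_df}"
            )

    beta_hat = float(betas[1])

    if separated:
        ci = _profile_ci(counts, 1, beta_hat, negll_min, lam)
        # Wald p from the penalized curvature as a pragmatic summary
        def obj_nat(x: np.ndarray) -> float:
            b = np.concatenate(([0.0], x[k - 1 :]))
            return _negll(x[: k - 1], b, counts) + 0.5 * lam * float(b[1:] @ b[1:])

        hess = _fd_hessian(obj_nat, np.concatenate((alphas, betas[1:])))
        try:
            se = float(np.sqrt(np.diag(np.linalg.inv(hess))[k - 1]))
        except np.linalg.LinAlgError:
            se = np.nan
    else:
        ci = (beta_hat - 1.959964 * se, beta_hat + 1.959964 * se)

    if p_method == "lr":
        # null fit: shared cutpoints, all betas zero
        null_negll = _minimize_null(counts)
        lr = 2.0 * (null_negll - negll_min)
        df = counts.shape[0] - 1
        p = float(stats.chi2.sf(max(lr, 0.0), df))
    elif np.isfinite(se) and se > 0:
        p = float(2.0 * stats.norm.sf(abs(beta_hat) / se))
    else:
        p = np.nan

    return OrdinalFit(
        beta=beta_hat,
        or_=float(np.exp(beta_hat)),
        ci95=(float(np.exp(ci[0])), float(np.exp(ci[1]))),
        thresholds=alphas.copy(),
        p=p,
        separation_flag=separated,
        converged=ok,
        loglik=-negll_min,
        se=se,
        reference_group=reference_group,
        treatment_group=ordered[1] if len(ordered) > 1 else reference_group,
        betas={g: float(b) for g, b in zip(ordered[1:], betas[1:])},
        p_method=p_method,
    )


def _minimize_null(counts: np.ndarray) -> float:
    k = counts.shape[1]
    tot = counts.sum(axis=0, keepdims=True)

    def obj(raw: np.ndarray) -> float:
        alphas = np.concatenate(([raw[0]], raw[0] + np.cumsum(np.exp(raw[1:]))))
        return _negll(alphas, np.zeros(1), tot)

    start = _start(tot)[: k - 1]
    res = optimize.minimize(obj, start, method="BFGS", options={"gtol": 1e-9})
    return float(res.fun)


def odds_ratio_2x2(
    table: ContingencyTable, haldane: bool = False
) -> dict:
    """Classical 2x2 odds ratio (ad)/(bc) with optional Haldane-Anscombe 0.5
    correction, for dichotomized class comparisons."""
    counts = table.counts.to_numpy(dtype=float)
    if counts.shape != (2, 2):
        raise ValueError(f"need a 2x2 table, got {counts.shape}")
    if haldane or (counts == 0).any():
        counts = counts + 0.5
        corrected = True
    else:
        corrected = False
    a, b = counts[0]
    c, d = counts[1]
    or_ = (a * d) / (b * c)
    se = float(np.sqrt((1 / counts).sum()))
    lo, hi = np.exp(np.log(or_) - 1.959964 * se), np.exp(np.log(or_) + 1.959964 * se)
    return {"or": float(or_), "ci95": (float(lo), float(hi)), "corrected": corrected}


def grouped_contrast(
    table: ContingencyTable,
    pool: list[str],
    vs: str,
    reference_group: str | None = None,
) -> dict:
    """Pool several conditions' counts and contrast them against one group.

    Used for the relative-microgravity design where the hypergravity-exposed
    conditions (3g, 3g>1g, 3g>axe) are pooled against the 1g sample. Counts
    are summed before testing; the reference defaults to ``vs``.
    """
    for g in pool + [vs]:
        if g not in table.groups:
            raise ValueError(f"grouping references unknown condition {g!r}")
    pooled_name = "+".join(pool)
    pooled = table.counts.loc[pool].sum(axis=0)
    two = pd.DataFrame([table.counts.loc[vs], pooled], index=[vs, pooled_name])
    two.index.name = "group"
    two_table = collapse_classes(ContingencyTable(two))
    return {
        "table": two_table,
        "chi_square": chi_square(two_table),
        "ordinal_fit": fit_ordinal_logistic(two_table, reference_group=reference_group or vs),
    }


def significance_report(results: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Annotate a results table (with a ``p`` column) with significance flags.

    Significance is strict (p < alpha). The number of tests performed is
    recorded on ``attrs['n_tests']``; no multiplicity correction is applied.
    """
    out = results.copy()
    if out.empty:
        out["significant"] = pd.Series(dtype=bool)
        out["stars"] = pd.Series(dtype=str)
        out.attrs["n_tests"] = 0
        return out
    out["significant"] = out["p"] < alpha
    out["stars"] = [significance_stars(p) if np.isfinite(p) else "" for p in out["p"]]
    out.attrs["n_tests"] = int(out["p"].notna().sum())
    return out
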