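"""Statistical engines for the audiovisual-integration analysis.

Everything here is implemented directly from the underlying linear-model
algebra — effect-coded least squares with full-versus-reduced residual
sum-of-squares comparisons for the factorial ANOVA, closed-form t and
rank statistics, the Tukey–Kramer studentized-range comparison, and a
random-intercept Gaussian mixed model fit by maximum likelihood with a
one-dimensional profile over the variance ratio. scipy supplies only the
reference distributions (F, t, studentized range) used to convert
statistics to p-values.

The factorial design is 2x2: presence/absence of the auditory component
crossed with presence/absence of the visual component. The
(absent, absent) cell is populated by pre-stimulus baseline-window rates,
so the design is unbalanced by construction; the Type-III-equivalent
effect coding handles that.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats as sps

from .errors import DegenerateDesignError

__all__ = [
    "AnovaResult", "TTestResult", "SpearmanResult", "TukeyResult",
    "MixedModelResult", "two_way_anova", "combined_anova", "one_sample_t",
    "spearman_rho", "tukey_kramer", "mixed_model_fit", "anova_observations",
]

# Relative tolerance below which a sum of squares is treated as exactly zero.
_SS_RTOL = 1e-12


@dataclass
class AnovaResult:
    """2x2 factorial ANOVA with interaction (auditory x visual presence)."""

    F_aud: float
    F_vis: float
    F_int: float
    p_aud: float
    p_vis: float
    p_int: float
    df_num: int
    df_den: int
    ss_table: dict[str, float] = field(default_factory=dict)

    def p_values(self) -> dict[str, float]:
        return {"auditory": self.p_aud, "visual": self.p_vis,
                "interaction": self.p_int}


def _rss(X: np.ndarray, y: np.ndarray) -> float:
    """Residual sum of squares of the least-squares fit of y on X."""
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    return float(r @ r)


def two_way_anova(rates, aud_present, vis_present) -> AnovaResult:
    """Type-III-equivalent 2x2 ANOVA via effect coding and model comparison.

    Parameters
    ----------
    rates : array-like of float
        One observation (a window firing rate) per row.
    aud_present, vis_present : array-like of bool
        Factor levels per observation.

    Each F is the drop in residual sum of squares when that term's
    effect-coded column is removed from the full model, divided by the
    full-model mean squared error; with sum-to-zero coding this matches
    the Type-III test and is well defined for unbalanced cell counts.
    A design with all observations identical reports F = 0, p = 1 for
    every term; nonzero effects over zero residual variance report
    F = +inf, p = 0.
    """
    y = np.asarray(rates, dtype=float)
    a = np.asarray(aud_present, dtype=bool)
    v = np.asarray(vis_present, dtype=bool)
    n = y.size
    if a.size != n or v.size != n:
        raise ValueError("rates, aud_present, vis_present must be equal length")
    for aa in (False, True):
        for vv in (False, True):
            if not np.any((a == aa) & (v == vv)):
                raise DegenerateDesignError(
                    f"empty design cell (auditory={aa}, visual={vv})"
                )
    df_den = n - 4
    if df_den < 1:
        raise DegenerateDesignError(
            f"no residual degrees of freedom (n={n}, 4 cells)"
        )

    ae = np.where(a, 1.0, -1.0)
    ve = np.where(v, 1.0, -1.0)
    ones = np.ones(n)
    X_full = np.column_stack([ones, ae, ve, ae * ve])
    rss_full = _rss(X_full, y)
    tss = float(np.sum((y - y.mean()) ** 2))
    scale = max(tss, 1.0)

    terms = {
        "auditory": np.column_stack([ones, ve, ae * ve]),
        "visual": np.column_stack([ones, ae, ae * ve]),
        "interaction": np.column_stack([ones, ae, ve]),
    }
    ss: dict[str, float] = {}
    F: dict[str, float] = {}
    p: dict[str, float] = {}
    mse = rss_full / df_den
    for name, X_red in terms.items():
        ss_term = max(_rss(X_red, y) - rss_full, 0.0)
        ss[name] = ss_term
        if rss_full <= _SS_RTOL * scale:
            # zero residual variance: identical data => F=0; exact effect => F=inf
            if ss_term <= _SS_RTOL * scale:
                F[name], p[name] = 0.0, 1.0
            else:
                F[name], p[name] = float("inf"), 0.0
        else:
            F[name] = ss_term / mse
            p[name] = float(sps.f.sf(F[name], 1, df_den))
    ss["residual"] = rss_full
    ss["total"] = tss
    return AnovaResult(
        F_aud=F["auditory"], F_vis=F["visual"], F_int=F["interaction"],
        p_aud=p["auditory"], p_vis=p["visual"], p_int=p["interaction"],
        df_num=1, df_den=df_den, ss_table=ss,
    )


def anova_observations(rates: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Assemble factorial observations from a per-trial rate table.

    Response-window rates contribute the three stimulated cells (AV, V, A
    mapped to presence flags); every trial's baseline-window rate populates
    the (absent, absent) cell, so the baseline cell has three times the
    observations of each stimulated cell.
    """
    resp = rates[rates["window_kind"] == "response"]
    base = rates[rates["window_kind"] == "baseline"]
    y = np.concatenate([resp["rate"].to_numpy(float), base["rate"].to_numpy(float)])
    mod = resp["modality"].to_numpy()
    aud = np.concatenate([np.isin(mod, ("AV", "A")), np.zeros(len(base), bool)])
    vis = np.concatenate([np.isin(mod, ("AV", "V")), np.zeros(len(base), bool)])
    return y, aud, vis


def combined_anova(rates: pd.DataFrame) -> AnovaResult:
    """Single factorial ANOVA pooling all stimuli of one neuron.

    Identical engine to :func:`two_way_anova`; all stimuli's trials enter
    as observations of the same 2x2 presence/absence design.
    """
    y, aud, vis = anova_observations(rates)
    return two_way_anova(y, aud, vis)


@dataclass
class TTestResult:
    t: float
    df: int
    p: float


def one_sample_t(values, mu0: float = 0.0) -> TTestResult:
    """Two-sided one-sample t-test of mean(values) against mu0."""
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 2:
        raise DegenerateDesignError(f"one-sample t requires n >= 2, got {n}")
    sd = x.std(ddof=1)
    if sd == 0:
        raise DegenerateDesignError("one-sample t undefined for zero variance")
    t = (x.mean() - mu0) / (sd / np.sqrt(n))
    p = float(2.0 * sps.t.sf(abs(t), n - 1))
    return TTestResult(t=float(t), df=n - 1, p=p)


@dataclass
class SpearmanResult:
    rho: float
    p: float


def _midranks(a: np.ndarray) -> np.ndarray:
    """Ranks 1..n with ties assigned the average of the tied positions."""
    a = np.asarray(a, dtype=float)
    n = a.size
    sorter = np.argsort(a, kind="mergesort")
    inv = np.empty(n, dtype=int)
    inv[sorter] = np.arange(n)
    s = a[sorter]
    new_group = np.r_[True, s[1:] != s[:-1]]
    group = np.cumsum(new_group) - 1
    counts = np.bincount(group)
    ends = np.cumsum(counts)
    starts = ends - counts
    mid = (starts + 1 + ends) / 2.0
    return mid[group][inv]


def spearman_rho(x, y) -> SpearmanResult:
    """Spearman rank correlation: Pearson correlation of mid-ranks.

    Ties receive average ranks; the p-value uses the t approximation with
    n - 2 degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    n = x.size
    if n < 3:
        raise DegenerateDesignError(f"spearman_rho requires n >= 3, got {n}")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise DegenerateDesignError("correlation undefined for a constant vector")
    rx, ry = _midranks(x), _midranks(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    rho = float(rx @ ry / np.sqrt((rx @ rx) * (ry @ ry)))
    rho = max(-1.0, min(1.0, rho))
    if abs(rho) == 1.0:
        p = 0.0
    else:
        t = rho * np.sqrt((n - 2) / (1.0 - rho * rho))
        p = float(2.0 * sps.t.sf(abs(t), n - 2))
    return SpearmanResult(rho=rho, p=p)


@dataclass
class TukeyResult:
    group_a: str
    group_b: str
    mean_diff: float
    q: float
    p_adj: float


def tukey_kramer(groups: list[tuple[str, np.ndarray]]) -> list[TukeyResult]:
    """All-pairs Tukey–Kramer comparison (valid for unequal group sizes).

    q_ij = |mean_i - mean_j| / sqrt(MSE/2 * (1/n_i + 1/n_j)) with MSE the
    pooled within-group variance; the family-wise adjusted p comes from
    the studentized-range distribution with k groups and pooled df.
    """
    k = len(groups)
    if k < 2:
        raise DegenerateDesignError("tukey_kramer requires >= 2 groups")
    arrs = []
    for label, vals in groups:
        v = np.asarray(vals, dtype=float)
        if v.size < 2:
            raise DegenerateDesignError(
                f"group {label!r} has n={v.size} < 2 observations"
            )
        arrs.append((label, v))
    df = sum(v.size - 1 for _, v in arrs)
    mse = sum((v.size - 1) * v.var(ddof=1) for _, v in arrs) / df
    out: list[TukeyResult] = []
    for i in range(k):
        for j in range(i + 1, k):
            la, va = arrs[i]
            lb, vb = arrs[j]
            diff = float(va.mean() - vb.mean())
            if mse == 0:
                q = 0.0 if diff == 0 else float("inf")
                p = 1.0 if diff == 0 else 0.0
            else:
                q = abs(diff) / np.sqrt(mse / 2.0 * (1.0 / va.size + 1.0 / vb.size))
                p = float(np.clip(sps.studentized_range.sf(q, k, df), 0.0, 1.0))
            out.append(TukeyResult(group_a=la, group_b=lb, mean_diff=diff,
                                   q=float(q), p_adj=p))
    return out


@dataclass
class MixedModelResult:
    """Random-intercept Gaussian linear mixed model, fit by ML."""

    terms: list[str]
    beta: np.ndarray
    se: np.ndarray
    t: np.ndarray
    df: int
    p: np.ndarray
    var_neuron: float
    var_resid: float
    loglik: float

    def coef(self, term: str) -> float:
        return float(self.beta[self.terms.index(term)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "factor": self.terms, "beta": self.beta, "se": self.se,
            "t": self.t, "df": self.df, "p": self.p,
        })


def _check_full_rank(X: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify which columns are linearly dependent on the preceding ones
        bad = []
        for j in range(1, X.shape[1]):
            if np.linalg.matrix_rank(X[:, : j + 1]) == np.linalg.matrix_rank(X[:, :j]):
                bad.append(names[j])
        raise DegenerateDesignError(
            f"singular fixed-effects design; collinear columns: {bad}"
        )


def mixed_model_fit(rows: pd.DataFrame,
                    rate_col: str = "rate",
                    var_ratio: float | None = None) -> MixedModelResult:
    """Fit rate ~ auditory + visual + patch + patch:auditory + (1 | neuron).

    Parameters
    ----------
    rows : DataFrame
        Columns ``rate`` (or `rate_col`), ``aud`` and ``vis`` (0/1 presence
        flags), ``patch`` (exactly two labels) and ``neuron_id``.
    var_ratio : float, optional
        Fix the variance ratio var_neuron / var_resid instead of
        profiling it; ``var_ratio=0`` reduces the fit to ordinary least
        squares.

    The model is fit by maximum likelihood, profiling the likelihood over
    the variance ratio theta = var_neuron / var_resid: for fixed theta the
    GLS solution and the residual variance are closed-form (per-neuron
    compound-symmetric covariance inverted by the Woodbury identity), so
    only a one-dimensional optimization remains. Wald t-statistics use
    residual degrees of freedom n_rows - n_fixed.
    """
    req = {rate_col, "aud", "vis", "patch", "neuron_id"}
    missing = req - set(rows.columns)
    if missing:
        raise ValueError(f"mixed_model_fit: missing columns {sorted(missing)}")
    patches = sorted(rows["patch"].unique())
    if len(patches) != 2:
        raise DegenerateDesignError(
            f"mixed model requires exactly 2 patch labels, got {patches}"
        )
    ref, alt = patches
    counts = rows.groupby("neuron_id").size()
    if (counts < 2).any():
        few = list(counts[counts < 2].index)
        raise DegenerateDesignError(f"neurons with < 2 observations: {few}")
    per_patch = rows.drop_duplicates("neuron_id").groupby("patch").size()
    if (per_patch < 2).any() or len(per_patch) < 2:
        raise DegenerateDesignError("need >= 2 neurons in each patch")

    y = rows[rate_col].to_numpy(float)
    aud = rows["aud"].to_numpy(float)
    vis = rows["vis"].to_numpy(float)
    patch = (rows["patch"] == alt).to_numpy(float)
    X = np.column_stack([np.ones(len(y)), aud, vis, patch, patch * aud])
    names = ["intercept", "auditory", "visual", f"patch[{alt}]",
             f"patch[{alt}]:auditory"]
    _check_full_rank(X, names)
    n, p = X.shape

    # per-neuron sufficient statistics for the Woodbury-form GLS
    stats_g = []
    for _, idx in rows.groupby("neuron_id").indices.items():
        Xg, yg = X[idx], y[idx]
        stats_g.append((
            Xg.T @ Xg, Xg.T @ yg, float(yg @ yg),
            Xg.sum(axis=0), float(yg.sum()), len(idx),
        ))

    def profile(theta: float):
        A = np.zeros((p, p))
        b = np.zeros(p)
        yVy = 0.0
        logdet = 0.0
        for XtX, Xty, yty, sx, sy, ng in stats_g:
            c = theta / (1.0 + theta * ng)
            A += XtX - c * np.outer(sx, sx)
            b += Xty - c * sx * sy
            yVy += yty - c * sy * sy
            logdet += np.log1p(theta * ng)
        beta = np.linalg.solve(A, b)
        q = max(yVy - beta @ b, 1e-300)
        sigma2 = q / n
        ll = -0.5 * (n * (np.log(2 * np.pi * sigma2) + 1.0) + logdet)
        return ll, beta, sigma2, A

    def neg_ll(u: float) -> float:
        return -profile(np.exp(u))[0]

    if var_ratio is not None:
        if var_ratio < 0:
            raise ValueError(f"var_ratio must be >= 0, got {var_ratio}")
        theta_hat = float(var_ratio)
        ll_hat, beta, sigma2, A = profile(theta_hat)
    else:
        res = optimize.minimize_scalar(neg_ll, bounds=(-12.0, 12.0),
                                       method="bounded",
                                       options={"xatol": 1e-8})
        theta_hat = float(np.exp(res.x))
        ll_hat, beta, sigma2, A = profile(theta_hat)
        ll0, beta0, sigma2_0, A0 = profile(0.0)
        if ll0 >= ll_hat:  # boundary solution: no between-neuron variance
            theta_hat, ll_hat, beta, sigma2, A = 0.0, ll0, beta0, sigma2_0, A0

    cov = sigma2 * np.linalg.inv(A)
    se = np.sqrt(np.diag(cov))
    t = beta / se
    df = n - p
    pvals = 2.0 * sps.t.sf(np.abs(t), df)
    return MixedModelResult(
        terms=names, beta=beta, se=se, t=t, df=df, p=pvals,
        var_neuron=theta_hat * sigma2, var_resid=sigma2, loglik=ll_hat,
    )
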