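"""Repeated-measures statistical battery for dyadic reaching analyses.

Implements the tests used on the kinematic and rating summaries:

* Shapiro–Wilk normality gate (parametric vs rank-based branch at alpha).
* Wilcoxon signed-rank (paired or one-sample), with the W+ convention
  (sum of positive-difference ranks), exact two-sided p for up to 25
  nonzero differences (tie-aware enumeration) and a tie-corrected normal
  approximation above, and the matched-pairs rank-biserial correlation
  (W+ - W-)/(W+ + W-) as effect size.
* Paired t with Cohen's d (d_z = mean(diff)/sd(diff) by default).
* One- and two-way repeated-measures ANOVA for balanced complete
  within-subject designs, with partial eta squared.
* Mauchly's sphericity test.
* The aligned-rank-transform (ART) procedure: for each effect, the data are
  aligned (residual plus the estimated effect of interest), ranked as a
  whole, and the repeated-measures F-test is run on the aligned ranks.
* Holm step-down and Tukey (studentized-range) post hoc adjustment on
  all-pairs contrasts; post hoc degrees of freedom use the classical
  balanced-design error df (a documented substitute for Kenward-Roger,
  with which they coincide in balanced compound-symmetric designs).
* Spearman rank correlation (exact p for n <= 9 without ties).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy import stats as sps
from scipy.linalg import helmert
from statsmodels.stats.multitest import multipletests

from .errors import DegenerateSampleError, IncompleteDesignError, InvalidArgumentError


@dataclass(frozen=True)
class StatResult:
    test_name: str
    statistic: float
    df: tuple[float, ...]
    p: float
    effect_size: float
    effect_size_type: str
    extras: dict = field(default_factory=dict)

    def __str__(self) -> str:  # compact report line
        dfs = ", ".join(f"{d:g}" for d in self.df)
        return (
            f"{self.test_name}({dfs}) = {self.statistic:.3f}, p = {self.p:.4g}, "
            f"{self.effect_size_type} = {self.effect_size:.3f}"
        )


@dataclass(frozen=True)
class PostHocContrast:
    label: str
    statistic: float
    df: float
    p_raw: float
    p_adjusted: float
    effect_size: float


@dataclass(frozen=True)
class PostHocTable:
    adjustment_method: str  # "holm" | "tukey"
    contrasts: tuple[PostHocContrast, ...]


def partial_eta_sq_from_f(f: float, df1: float, df2: float) -> float:
    """Identity eta_p^2 = F df1 / (F df1 + df2) for a single-error-term F."""
    return f * df1 / (f * df1 + df2)


# ---------------------------------------------------------------------------
# normality gate

def shapiro_wilk(x) -> StatResult:
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 3 or n > 5000:
        raise InvalidArgumentError("Shapiro-Wilk requires 3 <= n <= 5000")
    if np.ptp(x) == 0.0:
        raise DegenerateSampleError("constant sample: normality test undefined")
    w, p = sps.shapiro(x)
    return StatResult("shapiro_wilk_W", float(w), (float(n),), float(p), float(w), "shapiro_W")


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank

def _wilcoxon_exact_two_sided(doubled_ranks: np.ndarray, w2: float) -> float:
    """Exact two-sided p for the signed-rank statistic.

    Works on doubled ranks (integers even with average-rank ties) and
    enumerates the 2^m equiprobable sign assignments by convolution.
    """
    total = int(doubled_ranks.sum())
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for d in doubled_ranks.astype(int):
        shifted = np.zeros_like(counts)
        shifted[d:] = counts[: total + 1 - d]
        counts = 0.5 * (counts + shifted)
    w2i = int(round(w2))
    lower = counts[: w2i + 1].sum()
    upper = counts[w2i:].sum()
    return float(min(1.0, 2.0 * min(lower, upper)))


def wilcoxon_signed_rank(x, y=None, mu: float | None = None) -> StatResult:
    """Signed-rank test on paired differences x - y (or x - mu).

    Zero differences are dropped before ranking; ties get average ranks.
    The reported statistic is W+ (sum of ranks of positive differences);
    effect size is the matched-pairs rank-biserial correlation.
    """
    x = np.asarray(x, dtype=float)
    if y is not None and mu is not None:
        raise InvalidArgumentError("pass either y or mu, not both")
    if y is not None:
        y = np.asarray(y, dtype=float)
        if len(y) != len(x):
            raise InvalidArgumentError("x and y must have equal length")
        d = x - y
    elif mu is not None:
        d = x - mu
    else:
        d = x
    n_pairs = len(d)
    d = d[d != 0.0]
    m = len(d)
    if m == 0:
        raise DegenerateSampleError("all paired differences are zero")
    ranks = sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    w_minus = float(ranks[d < 0].sum())
    total = w_plus + w_minus
    rank_biserial = (w_plus - w_minus) / total

    if m <= 25:
        p = _wilcoxon_exact_two_sided(2.0 * ranks, 2.0 * w_plus)
        method = "exact"
    else:
        mean = m * (m + 1) / 4.0
        _, tie_counts = np.unique(ranks, return_counts=True)
        var = m * (m + 1) * (2 * m + 1) / 24.0 - np.sum(tie_counts**3 - tie_counts) / 48.0
        # continuity correction toward the mean
        z = (w_plus - mean - 0.5 * np.sign(w_plus - mean)) / math.sqrt(var)
        p = float(2.0 * sps.norm.sf(abs(z)))
        method = "normal"
    return StatResult(
        "wilcoxon_W",
        w_plus,
        (float(m),),
        min(1.0, p),
        float(rank_biserial),
        "rank_biserial",
        extras={"n_pairs": n_pairs, "n_zero_dropped": n_pairs - m, "p_method": method},
    )


# ---------------------------------------------------------------------------
# t tests

def paired_t(x, y=None, mu: float = 0.0, d_convention: str = "dz") -> StatResult:
    """Paired t test on x - y (one-sample against mu when y is omitted)."""
    x = np.asarray(x, dtype=float)
    d = x - mu if y is None else x - np.asarray(y, dtype=float)
    n = len(d)
    if n < 2:
        raise InvalidArgumentError("paired t requires n >= 2")
    sd = d.std(ddof=1)
    if sd == 0.0:
        raise DegenerateSampleError("zero-variance differences: t undefined")
    t = d.mean() / (sd / math.sqrt(n))
    p = float(2.0 * sps.t.sf(abs(t), n - 1))
    if d_convention == "dz":
        eff = d.mean() / sd
    elif d_convention == "dav" and y is not None:
        y = np.asarray(y, dtype=float)
        eff = d.mean() / ((x.std(ddof=1) + y.std(ddof=1)) / 2.0)
    else:
        eff = d.mean() / sd
    return StatResult("paired_t", float(t), (float(n - 1),), p, float(eff), "cohen_d_paired")


# ---------------------------------------------------------------------------
# repeated-measures ANOVA

def _check_table(values: np.ndarray, min_levels: int = 2) -> np.ndarray:
    values = np.asarray(values, dtype=float)
    if values.ndim < 2 or any(s < min_levels for s in values.shape[1:]) or values.shape[0] < 2:
        raise IncompleteDesignError("need a complete units x levels table")
    if not np.all(np.isfinite(values)):
        raise IncompleteDesignError("table contains missing cells")
    return values


def rm_anova_oneway(values) -> StatResult:
    """One-way within-subject ANOVA on an (n units x k levels) table."""
    values = _check_table(values)
    if values.ndim != 2:
        raise InvalidArgumentError("one-way ANOVA expects a 2-D table")
    n, k = values.shape
    mu = values.mean()
    m_s = values.mean(axis=1, keepdims=True)
    m_c = values.mean(axis=0, keepdims=True)
    ss_cond = n * np.sum((values.mean(axis=0) - mu) ** 2)
    # residual SS computed directly so it can never go (float-)negative
    ss_err = np.sum((values - m_s - m_c + mu) ** 2)
    df1, df2 = k - 1, (k - 1) * (n - 1)
    ms_err = ss_err / df2
    if ms_err <= 0.0:
        f = 0.0 if ss_cond == 0.0 else math.inf
    else:
        f = (ss_cond / df1) / ms_err
    p = float(sps.f.sf(f, df1, df2)) if np.isfinite(f) else 0.0
    eta = ss_cond / (ss_cond + ss_err) if (ss_cond + ss_err) > 0 else 0.0
    return StatResult(
        "rm_anova_F",
        float(f),
        (float(df1), float(df2)),
        p,
        float(eta),
        "partial_eta_sq",
        extras={"ms_error": float(ms_err), "ss_effect": float(ss_cond), "ss_error": float(ss_err)},
    )


def rm_anova_twoway(values) -> dict[str, StatResult]:
    """Two-way fully within-subject ANOVA on an (n x a x b) table.

    Each effect is tested against its own subject-by-effect interaction
    error term, as is standard for within designs.
    """
    values = _check_table(values)
    if values.ndim != 3:
        raise InvalidArgumentError("two-way ANOVA expects an (n, a, b) table")
    n, a, b = values.shape
    mu = values.mean()
    m_s = values.mean(axis=(1, 2))
    m_a = values.mean(axis=(0, 2))
    m_b = values.mean(axis=(0, 1))
    m_ab = values.mean(axis=0)
    m_sa = values.mean(axis=2)
    m_sb = values.mean(axis=1)

    ss_a = n * b * np.sum((m_a - mu) ** 2)
    ss_b = n * a * np.sum((m_b - mu) ** 2)
    ss_ab = n * np.sum((m_ab - m_a[:, None] - m_b[None, :] + mu) ** 2)
    ss_sa = b * np.sum((m_sa - m_s[:, None] - m_a[None, :] + mu) ** 2)
    ss_sb = a * np.sum((m_sb - m_s[:, None] - m_b[None, :] + mu) ** 2)
    resid = (
        values
        - m_sa[:, :, None]
        - m_sb[:, None, :]
        - m_ab[None, :, :]
        + m_s[:, None, None]
        + m_a[None, :, None]
        + m_b[None, None, :]
        - mu
    )
    ss_sab = np.sum(resid**2)

    out: dict[str, StatResult] = {}
    for name, ss_eff, df1, ss_err, df2 in (
        ("A", ss_a, a - 1, ss_sa, (a - 1) * (n - 1)),
        ("B", ss_b, b - 1, ss_sb, (b - 1) * (n - 1)),
        ("A:B", ss_ab, (a - 1) * (b - 1), ss_sab, (a - 1) * (b - 1) * (n - 1)),
    ):
        ms_err = ss_err / df2
        f = (ss_eff / df1) / ms_err if ms_err > 0 else (0.0 if ss_eff == 0 else math.inf)
        p = float(sps.f.sf(f, df1, df2)) if np.isfinite(f) else 0.0
        eta = ss_eff / (ss_eff + ss_err) if (ss_eff + ss_err) > 0 else 0.0
        out[name] = StatResult(
            "rm_anova_F",
            float(f),
            (float(df1), float(df2)),
            p,
            float(eta),
            "partial_eta_sq",
            extras={"ms_error": float(ms_err)},
        )
    return out


def mauchly_sphericity(values) -> StatResult:
    """Mauchly's test of sphericity for an (n x k) within-subject table."""
    values = _check_table(values)
    n, k = values.shape
    if k < 3:
        raise InvalidArgumentError("sphericity is not applicable for k < 3")
    if n < k:
        raise InvalidArgumentError("Mauchly's test needs n >= k")
    c = helmert(k, full=False)  # (k-1, k) orthonormal contrasts
    t = values @ c.T
    s = np.cov(t, rowvar=False, ddof=1)
    eig = np.linalg.eigvalsh(s)
    if np.any(eig <= 0):
        raise DegenerateSampleError("singular contrast covariance")
    w = float(np.prod(eig) / (eig.mean() ** (k - 1)))
    dfc = k - 1
    df = dfc * (dfc + 1) / 2.0 - 1.0
    factor = 1.0 - (2.0 * dfc**2 + dfc + 2.0) / (6.0 * dfc * (n - 1))
    chi2 = -(n - 1) * factor * math.log(w)
    p = float(sps.chi2.sf(chi2, df))
    return StatResult("mauchly_W", w, (df,), p, w, "mauchly_W", extras={"chi2": float(chi2)})


# ---------------------------------------------------------------------------
# multiplicity

def holm_adjust(pvalues) -> np.ndarray:
    """Holm step-down adjusted p values (monotone, never below raw)."""
    pvalues = np.asarray(pvalues, dtype=float)
    if np.any((pvalues < 0) | (pvalues > 1)):
        raise InvalidArgumentError("p values must lie in [0, 1]")
    if len(pvalues) == 0:
        return pvalues.copy()
    return multipletests(pvalues, method="holm")[1]


# ---------------------------------------------------------------------------
# aligned rank transform

_TWOWAY_EFFECTS = ("A", "B", "A:B")


def art_transform(values, effect: str) -> np.ndarray:
    """Aligned ranks for one effect of a balanced within-subject design.

    The response is aligned by removing every effect other than the one of
    interest (residual w.r.t. the factor-cell means plus the estimated
    effect of interest) and the aligned column is then ranked as a whole
    with average ranks on ties.  Accepts an (n, a) table for one factor
    (effect "A") or an (n, a, b) table (effects "A", "B", "A:B").
    """
    values = _check_table(values)
    mu = values.mean()
    if values.ndim == 2:
        if effect != "A":
            raise InvalidArgumentError("one-factor table has only effect 'A'")
        m_a = values.mean(axis=0)
        aligned = values - m_a[None, :] + (m_a[None, :] - mu)
    elif values.ndim == 3:
        if effect not in _TWOWAY_EFFECTS:
            raise InvalidArgumentError(f"unknown effect {effect!r}")
        m_ab = values.mean(axis=0)
        m_a = values.mean(axis=(0, 2))
        m_b = values.mean(axis=(0, 1))
        resid = values - m_ab[None, :, :]
        if effect == "A":
            est = m_a[None, :, None] - mu
        elif effect == "B":
            est = m_b[None, None, :] - mu
        else:
            est = (m_ab - m_a[:, None] - m_b[None, :] + mu)[None, :, :]
        aligned = resid + est
    else:
        raise InvalidArgumentError("ART supports 1- or 2-factor tables")
    ranks = sps.rankdata(aligned.ravel()).reshape(values.shape)
    return ranks


def art_rm_anova(values, factor_names: tuple[str, ...] | None = None) -> dict[str, StatResult]:
    """Repeated-measures ANOVA on aligned ranks, one aligned model per effect.

    Returns a result per effect; partial eta squared is computed on the
    aligned-rank sums of squares of that effect's own model.
    """
    values = _check_table(values)
    if values.ndim == 2:
        effects = ("A",)
    elif values.ndim == 3:
        effects = _TWOWAY_EFFECTS
    else:
        raise InvalidArgumentError("ART supports 1- or 2-factor tables")
    if factor_names is None:
        factor_names = effects
    out: dict[str, StatResult] = {}
    for effect, name in zip(effects, factor_names):
        ranks = art_transform(values, effect)
        if values.ndim == 2:
            res = rm_anova_oneway(ranks)
        else:
            res = rm_anova_twoway(ranks)[effect]
        out[name] = StatResult(
            "art_rm_anova_F",
            res.statistic,
            res.df,
            res.p,
            res.effect_size,
            "partial_eta_sq",
            extras={**res.extras, "aligned_ranks": ranks},
        )
    return out


# ---------------------------------------------------------------------------
# post hoc contrasts

def holm_posthoc(values, labels: tuple[str, ...] | None = None) -> PostHocTable:
    """All-pairs paired t contrasts with Holm adjustment (df = n - 1)."""
    values = _check_table(values)
    n, k = values.shape
    labels = labels or tuple(f"level{i}" for i in range(k))
    pairs = list(itertools.combinations(range(k), 2))
    results = [paired_t(values[:, i], values[:, j]) for i, j in pairs]
    adj = holm_adjust([r.p for r in results])
    contrasts = tuple(
        PostHocContrast(
            label=f"{labels[i]} - {labels[j]}",
            statistic=r.statistic,
            df=r.df[0],
            p_raw=r.p,
            p_adjusted=float(a),
            effect_size=r.effect_size,
        )
        for (i, j), r, a in zip(pairs, results, adj)
    )
    return PostHocTable("holm", contrasts)


def tukey_posthoc(values, labels: tuple[str, ...] | None = None) -> PostHocTable:
    """All-pairs Tukey (studentized-range) contrasts for a one-way
    within-subject table (typically aligned ranks from ART).

    The error term is the classical repeated-measures MS_error with
    df = (k-1)(n-1); the per-contrast t is q/sqrt(2) and the effect size is
    the model-standardized difference t*sqrt(2/n).
    """
    values = _check_table(values)
    n, k = values.shape
    if k < 2:
        raise InvalidArgumentError("need at least 2 levels for contrasts")
    labels = labels or tuple(f"level{i}" for i in range(k))
    omnibus = rm_anova_oneway(values)
    ms_err = omnibus.extras["ms_error"]
    df_err = omnibus.df[1]
    means = values.mean(axis=0)
    se_q = math.sqrt(ms_err / n)
    contrasts = []
    for i, j in itertools.combinations(range(k), 2):
        diff = means[i] - means[j]
        q = abs(diff) / se_q if se_q > 0 else (0.0 if diff == 0 else math.inf)
        p = float(sps.studentized_range.sf(q, k, df_err)) if np.isfinite(q) else 0.0
        t = math.copysign(q / math.sqrt(2.0), diff) if np.isfinite(q) else math.inf
        contrasts.append(
            PostHocContrast(
                label=f"{labels[i]} - {labels[j]}",
                statistic=t,
                df=df_err,
                p_raw=p,  # studentized-range p is already familywise
                p_adjusted=p,
                effect_size=t * math.sqrt(2.0 / n),
            )
        )
    return PostHocTable("tukey", tuple(contrasts))


# ---------------------------------------------------------------------------
# rank correlation

@lru_cache(maxsize=8)
def _spearman_exact_d2_distribution(n: int) -> tuple[np.ndarray, np.ndarray]:
    """Null distribution of sum of squared rank differences for sample size n."""
    base = np.arange(1, n + 1)
    d2s: dict[int, int] = {}
    for perm in itertools.permutations(base):
        d2 = int(np.sum((np.array(perm) - base) ** 2))
        d2s[d2] = d2s.get(d2, 0) + 1
    keys = np.array(sorted(d2s))
    counts = np.array([d2s[k] for k in keys], dtype=float)
    return keys, counts / counts.sum()


def spearman(x, y) -> StatResult:
    """Spearman rank-order correlation with two-sided p.

    Exact p (enumeration over rank permutations) for n <= 9 without ties;
    otherwise the t approximation on the rank Pearson correlation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 3 or len(y) != n:
        raise InvalidArgumentError("spearman requires two equal samples with n >= 3")
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        raise DegenerateSampleError("constant input: correlation undefined")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    has_ties = len(np.unique(rx)) < n or len(np.unique(ry)) < n
    if n <= 9 and not has_ties:
        d2 = float(np.sum((rx - ry) ** 2))
        keys, probs = _spearman_exact_d2_distribution(n)
        # small d2 <-> large positive rho; two-sided via the mirror tail
        lower = probs[keys <= d2 + 1e-9].sum()
        upper = probs[keys >= d2 - 1e-9].sum()
        p = float(min(1.0, 2.0 * min(lower, upper)))
    else:
        if abs(rho) >= 1.0:
            p = 0.0
        else:
            t = rho * math.sqrt((n - 2) / (1.0 - rho**2))
            p = float(2.0 * sps.t.sf(abs(t), n - 2))
    return StatResult("spearman_rho", rho, (float(n),), p, rho, "spearman_rho")
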