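"""Assumption checks and post-hoc machinery for the wavelet-selection study.

Kolmogorov-Smirnov normality, Levene homogeneity, one-way and two-way ANOVA,
and Duncan's multiple range test.  Duncan's critical values use the special
protection level alpha_p = 1 - (1-alpha)^(p-1) for a span of p ordered means;
the studentized-range quantiles are computed numerically from
``scipy.stats.studentized_range`` (validated against published Duncan tables)
rather than read from hard-coded tables.

Duncan's range test for a span p: R_p = q(1 - alpha_p; p, df) * sqrt(MSE/n_h)
with n_h the harmonic mean group size.  Two ordered means a span p apart are
declared non-significant if their difference is below R_p; non-significant
ranges are merged into homogeneous subsets labelled with letters, with the
standard protection that a range inside a wider non-significant range is
never declared significant.
"""

from __future__ import annotations

from dataclasses import dataclass
import json

import numpy as np
import pandas as pd
from scipy import stats as spstats

__all__ = [
    "AnovaResult",
    "DuncanResult",
    "ZeroVarianceError",
    "ks_normality",
    "levene",
    "anova_oneway",
    "anova_twoway",
    "duncan_mrt",
    "duncan_critical_range",
]


class ZeroVarianceError(ValueError):
    """Within-group variance is zero; the F statistic is undefined."""


@dataclass
class AnovaResult:
    f_statistic: float
    df_num: int
    df_den: int
    p_value: float
    mse: float  # within-group mean square
    group_means: dict[str, float]
    group_sizes: dict[str, int]
    effect: str = "group"

    def to_json(self, **kwargs) -> str:
        return json.dumps(
            {
                "effect": self.effect,
                "F": self.f_statistic,
                "df": [self.df_num, self.df_den],
                "p": self.p_value,
                "mse": self.mse,
                "group_means": self.group_means,
                "group_sizes": self.group_sizes,
            },
            **kwargs,
        )


@dataclass
class DuncanResult:
    means: dict[str, float]  # ordered by descending mean
    letters: dict[str, str]  # homogeneous-subset letters per group
    subsets: list[tuple[str, ...]]  # groups sharing each letter
    critical_ranges: dict[int, float]  # span p -> R_p
    alpha: float
    mse: float
    df_within: int

    def not_different_from(self, group: str) -> set[str]:
        """Groups sharing at least one subset letter with ``group``."""
        mine = set(self.letters[group])
        return {
            g
            for g, ls in self.letters.items()
            if g != group and mine & set(ls)
        }

    def summary(self) -> str:
        lines = [f"Duncan MRT (alpha={self.alpha}, df={self.df_within})"]
        for g, m in self.means.items():
            lines.append(f"  {g:>8s}  mean={m:10.5f}  subset {self.letters[g]}")
        return "\n".join(lines)


def _as_groups(groups) -> dict[str, np.ndarray]:
    if isinstance(groups, dict):
        return {str(k): np.asarray(v, dtype=float) for k, v in groups.items()}
    return {f"g{i}": np.asarray(v, dtype=float) for i, v in enumerate(groups)}


def ks_normality(sample) -> tuple[float, float]:
    """One-sample KS test against a normal with the sample's mean and SD.

    The p-value comes from the asymptotic KS distribution (the parameters
    are estimated from the same sample, so p is approximate; with large n
    the test is still a sharp screen for gross non-normality).
    """
    x = np.asarray(sample, dtype=float)
    if x.size < 5:
        raise ValueError("need at least 5 observations")
    res = spstats.kstest(x, "norm", args=(x.mean(), x.std(ddof=1)))
    return float(res.statistic), float(res.pvalue)


def levene(groups) -> tuple[float, float]:
    """Levene's homoscedasticity test, classic mean-centered form."""
    gs = list(_as_groups(groups).values())
    if len(gs) < 2 or any(g.size < 2 for g in gs):
        raise ValueError("need >= 2 groups with >= 2 observations each")
    res = spstats.levene(*gs, center="mean")
    return float(res.statistic), float(res.pvalue)


def anova_oneway(groups) -> AnovaResult:
    """One-way fixed-effects ANOVA with explicit between/within decomposition."""
    gdict = _as_groups(groups)
    gs = list(gdict.values())
    if len(gs) < 2:
        raise ValueError("need at least two groups")
    ns = np.array([g.size for g in gs])
    if (ns < 1).any() or ns.sum() <= len(gs):
        raise ValueError("total n must exceed the number of groups")
    means = np.array([g.mean() for g in gs])
    grand = np.concatenate(gs).mean()
    ss_between = float(np.sum(ns * (means - grand) ** 2))
    ss_within = float(sum(np.sum((g - g.mean()) ** 2) for g in gs))
    df_num = len(gs) - 1
    df_den = int(ns.sum()) - len(gs)
    if ss_within <= 0.0:
        raise ZeroVarianceError("all within-group variances are zero")
    mse = ss_within / df_den
    f = (ss_between / df_num) / mse
    p = float(spstats.f.sf(f, df_num, df_den))
    return AnovaResult(
        f_statistic=float(f),
        df_num=df_num,
        df_den=df_den,
        p_value=p,
        mse=mse,
        group_means={k: float(v.mean()) for k, v in gdict.items()},
        group_sizes={k: int(v.size) for k, v in gdict.items()},
    )


def anova_twoway(
    values, factor_a, factor_b, interaction: bool = True
) -> dict[str, AnovaResult]:
    """Two-factor ANOVA (Type II sums of squares) via an OLS fit.

    Returns one :class:`AnovaResult` per effect ("A", "B" and, when
    requested and estimable, "A:B").  With a balanced layout Type II
    coincides with the other SS types.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = pd.DataFrame(
        {
            "y": np.asarray(values, dtype=float),
            "A": pd.Categorical([str(a) for a in factor_a]),
            "B": pd.Categorical([str(b) for b in factor_b]),
        }
    )
    cells = df.groupby(["A", "B"], observed=True).size()
    if interaction and (cells < 2).all():
        # no replicates anywhere: the saturated model has zero residual df
        interaction = False
    formula = "y ~ C(A) * C(B)" if interaction else "y ~ C(A) + C(B)"
    fit = smf.ols(formula, data=df).fit()
    if fit.df_resid <= 0:
        raise ValueError("no residual degrees of freedom for the requested model")
    table = sm.stats.anova_lm(fit, typ=2)
    mse = float(table.loc["Residual", "sum_sq"] / table.loc["Residual", "df"])
    df_den = int(table.loc["Residual", "df"])
    out: dict[str, AnovaResult] = {}
    name_map = {"C(A)": "A", "C(B)": "B", "C(A):C(B)": "A:B"}
    for row, effect in name_map.items():
        if row not in table.index:
            continue
        factor = {"A": "A", "B": "B"}.get(effect)
        if factor is not None:
            gm = df.groupby(factor, observed=True)["y"]
            means = {k: float(v) for k, v in gm.mean().items()}
            sizes = {k: int(v) for k, v in gm.size().items()}
        else:
            means, sizes = {}, {}
        out[effect] = AnovaResult(
            f_statistic=float(table.loc[row, "F"]),
            df_num=int(table.loc[row, "df"]),
            df_den=df_den,
            p_value=float(table.loc[row, "PR(>F)"]),
            mse=mse,
            group_means=means,
            group_sizes=sizes,
            effect=effect,
        )
    return out


_Q_CACHE: dict[tuple[float, int, float], float] = {}


def _duncan_q(alpha: float, p: int, df: float) -> float:
    """Studentized-range quantile at Duncan's protection level for span p."""
    key = (round(alpha, 12), p, round(float(df), 6))
    if key not in _Q_CACHE:
        level = (1.0 - alpha) ** (p - 1)
        _Q_CACHE[key] = float(spstats.studentized_range.ppf(level, p, df))
    return _Q_CACHE[key]


def duncan_critical_range(
    p: int, df_within: int, mse: float, n_harmonic: float, alpha: float = 0.05
) -> float:
    """R_p = q(1-(1-alpha)^(p-1); p, df) * sqrt(MSE / n_h)."""
    if df_within <= 0:
        raise ValueError("df_within must be positive")
    return _duncan_q(alpha, p, df_within) * float(np.sqrt(mse / n_harmonic))


def duncan_mrt(
    groups,
    alpha: float = 0.05,
    mse: float | None = None,
    df_within: int | None = None,
) -> DuncanResult:
    """Duncan's multiple range test over the group means.

    ``mse`` and ``df_within`` default to the one-way ANOVA's within-group
    mean square over the same groups (pass them explicitly to reuse an
    already-computed ANOVA).
    """
    gdict = _as_groups(groups)
    if len(gdict) < 2:
        raise ValueError("need at least two groups")
    if mse is None or df_within is None:
        res = anova_oneway(gdict)
        mse = res.mse if mse is None else mse
        df_within = res.df_den if df_within is None else df_within
    if df_within <= 0:
        raise ValueError("df_within must be positive")
    names = sorted(gdict, key=lambda g: (-gdict[g].mean(), g))
    means = np.array([gdict[g].mean() for g in names])
    k = len(names)
    n_h = k / np.sum([1.0 / gdict[g].size for g in names])
    ranges = {
        p: duncan_critical_range(p, df_within, mse, n_h, alpha)
        for p in range(2, k + 1)
    }

    # widest-first sweep: from each position take the widest stretch whose
    # extreme difference is below its span's critical range; inner ranges of
    # a non-significant stretch are protected (never tested)
    nonsig_spans: list[tuple[int, int]] = []
    for i in range(k):
        for j in range(k - 1, i, -1):
            if means[i] - means[j] < ranges[j - i + 1]:
                nonsig_spans.append((i, j))
                break
        else:
            nonsig_spans.append((i, i))
    maximal = [
        (i, j)
        for (i, j) in nonsig_spans
        if not any((a <= i and j <= b) and (a, b) != (i, j) for (a, b) in nonsig_spans)
    ]
    maximal.sort()

    letters = {g: "" for g in names}
    subsets: list[tuple[str, ...]] = []
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    for idx, (i, j) in enumerate(maximal):
        letter = alphabet[idx % len(alphabet)] * (idx // len(alphabet) + 1)
        members = tuple(names[i : j + 1])
        subsets.append(members)
        for g in members:
            letters[g] += letter

    return DuncanResult(
        means={g: float(gdict[g].mean()) for g in names},
        letters=letters,
        subsets=subsets,
        critical_ranges=ranges,
        alpha=alpha,
        mse=float(mse),
        df_within=int(df_within),
    )
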