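"""Split-plot two-way ANOVA, LSD letter displays and Pearson screens.

A split-plot trial randomizes one factor (here fertilization, F) to large
main plots within replicate blocks and the second (irrigation, W) to
subplots inside each main plot.  That creates two error strata: the
Rep x F interaction (error a) tests the main-plot factor, and the residual
(error b) tests the subplot factor and the interaction.  For a balanced
design with r replicates, f main-plot levels and w subplot levels, the
sums of squares partition as

    total = Rep + F + error_a + W + FxW + error_b

with df (rw f - 1) = (r-1) + (f-1) + (r-1)(f-1) + (w-1) + (f-1)(w-1)
+ f(w-1)(r-1).  The partition is computed from cell means directly (not
delegated to a regression routine) so the strata are explicit.

Pairwise mean separation uses Fisher's protected LSD,
``LSD = t(1 - alpha/2, df_e) * sqrt(2 MS_e / n)``, summarized as a compact
letter display by the insert-and-absorb procedure on descending means.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "AnovaTable",
    "LetterDisplay",
    "UnbalancedDesignError",
    "splitplot_anova",
    "lsd_letters",
    "letters_from_nsd",
    "pearson_matrix",
]


class UnbalancedDesignError(ValueError):
    """The factorial layout is incomplete or has unequal cell counts."""


def significance_code(p: float) -> str:
    if np.isnan(p):
        return "na"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


@dataclass
class AnovaTable:
    """Split-plot ANOVA results as a tidy frame plus convenience lookups."""

    table: pd.DataFrame  # rows: Rep, F, Error-a, W, FxW, Error-b, Total
    response: str

    def __getitem__(self, row: str) -> pd.Series:
        return self.table.set_index("source").loc[row]

    @property
    def ms_error_b(self) -> float:
        return float(self["Error-b"]["MS"])

    @property
    def df_error_b(self) -> int:
        return int(self["Error-b"]["df"])

    def p_value(self, source: str) -> float:
        return float(self[source]["p"])


def splitplot_anova(observations: pd.DataFrame, response: str,
                    rep: str = "rep", mainplot: str = "fert_level",
                    subplot: str = "irr_level") -> AnovaTable:
    """Two-way split-plot ANOVA with the stratum-correct denominators.

    ``observations`` must hold a balanced layout: every
    (rep, mainplot, subplot) cell present exactly once.  Zero-fertilizer
    checks (or any extra level) must be excluded by the caller — they are
    rejected here as an unbalanced design rather than silently dropped.
    """
    df = observations
    for col in (rep, mainplot, subplot, response):
        if col not in df.columns:
            raise KeyError(f"observations missing column {col!r}")
    reps = np.sort(df[rep].unique())
    flev = list(pd.unique(df[mainplot]))
    wlev = list(pd.unique(df[subplot]))
    r, f, w = len(reps), len(flev), len(wlev)
    if r < 2:
        raise UnbalancedDesignError("need >= 2 replicates")
    counts = df.groupby([rep, mainplot, subplot]).size()
    if len(counts) != r * f * w or (counts != 1).any():
        raise UnbalancedDesignError(
            f"design is not a balanced {r}x{f}x{w} layout with one "
            "observation per cell")

    y = df.pivot_table(index=[rep, mainplot], columns=subplot,
                       values=response, sort=False)
    grand = df[response].mean()
    n = r * f * w

    m_rep = df.groupby(rep)[response].mean()
    m_f = df.groupby(mainplot)[response].mean()
    m_w = df.groupby(subplot)[response].mean()
    m_rf = df.groupby([rep, mainplot])[response].mean()
    m_fw = df.groupby([mainplot, subplot])[response].mean()

    ss_total = float(((df[response] - grand) ** 2).sum())
    ss_rep = f * w * float(((m_rep - grand) ** 2).sum())
    ss_f = r * w * float(((m_f - grand) ** 2).sum())
    # error a: Rep x F interaction on main-plot means
    dev_rf = (m_rf - grand
              - (m_rep.reindex(m_rf.index.get_level_values(0)).to_numpy() - grand)
              - (m_f.reindex(m_rf.index.get_level_values(1)).to_numpy() - grand))
    ss_ea = w * float((dev_rf ** 2).sum())
    ss_w = r * f * float(((m_w - grand) ** 2).sum())
    dev_fw = (m_fw - grand
              - (m_f.reindex(m_fw.index.get_level_values(0)).to_numpy() - grand)
              - (m_w.reindex(m_fw.index.get_level_values(1)).to_numpy() - grand))
    ss_fw = r * float((dev_fw ** 2).sum())
    ss_eb = ss_total - (ss_rep + ss_f + ss_ea + ss_w + ss_fw)
    ss_eb = max(ss_eb, 0.0)

    df_rep, df_f, df_ea = r - 1, f - 1, (r - 1) * (f - 1)
    df_w, df_fw = w - 1, (f - 1) * (w - 1)
    df_eb = f * (w - 1) * (r - 1)

    def ms(ss, d):
        return ss / d if d > 0 else np.nan

    ms_ea, ms_eb = ms(ss_ea, df_ea), ms(ss_eb, df_eb)

    def ftest(ss, d, ms_err, df_err):
        if d <= 0 or not np.isfinite(ms_err):
            return np.nan, np.nan
        if ms_err <= 0:
            # degenerate noise-free stratum: an exact effect gives F -> inf,
            # a null effect gives F = 0
            return (np.inf, 0.0) if ss > 0 else (0.0, 1.0)
        F = (ss / d) / ms_err
        return F, float(sps.f.sf(F, d, df_err))

    F_rep, p_rep = ftest(ss_rep, df_rep, ms_ea, df_ea)
    F_f, p_f = ftest(ss_f, df_f, ms_ea, df_ea)
    F_w, p_w = ftest(ss_w, df_w, ms_eb, df_eb)
    F_fw, p_fw = ftest(ss_fw, df_fw, ms_eb, df_eb)

    rows = [
        ("Rep", df_rep, ss_rep, ms(ss_rep, df_rep), F_rep, p_rep),
        ("F", df_f, ss_f, ms(ss_f, df_f), F_f, p_f),
        ("Error-a", df_ea, ss_ea, ms_ea, np.nan, np.nan),
        ("W", df_w, ss_w, ms(ss_w, df_w), F_w, p_w),
        ("FxW", df_fw, ss_fw, ms(ss_fw, df_fw), F_fw, p_fw),
        ("Error-b", df_eb, ss_eb, ms_eb, np.nan, np.nan),
        ("Total", n - 1, ss_total, np.nan, np.nan, np.nan),
    ]
    tab = pd.DataFrame(rows, columns=["source", "df", "SS", "MS", "F", "p"])
    tab["sig"] = [significance_code(p) if np.isfinite(p) else ""
                  for p in tab["p"]]
    return AnovaTable(table=tab, response=response)


@dataclass
class LetterDisplay:
    """Compact letter display for a set of treatment means."""

    means: pd.Series          # treatment -> mean, descending
    sds: pd.Series | None
    letters: dict[str, str]   # treatment -> letter string
    lsd: float
    alpha: float

    def annotate(self) -> pd.Series:
        """'mean +/- sd letters' strings, useful for table rendering."""
        out = {}
        for t, m in self.means.items():
            sd = self.sds[t] if self.sds is not None else np.nan
            sd_part = f" ± {sd:.2f}" if np.isfinite(sd) else ""
            out[t] = f"{m:.2f}{sd_part} {self.letters[t]}"
        return pd.Series(out, name="display")


def letters_from_nsd(means: pd.Series, not_different) -> dict[str, str]:
    """Compact letters from a 'not significantly different' predicate.

    ``not_different(a, b)`` is a symmetric predicate on treatment ids.
    Means are sorted descending; maximal runs of mutually-nonsignificant
    means become letter groups ('insert and absorb'), so any two
    treatments sharing a letter are not significantly different and 'a'
    attaches to the highest mean.

    The predicate need not be transitive, so groups are built as maximal
    cliques over contiguous spans of the sorted order (the standard
    procedure for monotone criteria such as a common LSD, where each
    clique IS a contiguous span).
    """
    order = list(means.sort_values(ascending=False).index)
    k = len(order)
    spans: list[tuple[int, int]] = []
    for i in range(k):
        j = i
        while j + 1 < k and all(not_different(order[m], order[j + 1])
                                for m in range(i, j + 1)):
            j += 1
        spans.append((i, j))
    # absorb spans contained in an earlier one
    maximal = []
    for s in spans:
        if not any(o[0] <= s[0] and s[1] <= o[1] and o != s for o in spans):
            if s not in maximal:
                maximal.append(s)
    maximal.sort()
    letters = {t: "" for t in order}
    for idx, (i, j) in enumerate(maximal):
        if idx >= 26:
            raise ValueError("more than 26 letter groups")
        ch = chr(ord("a") + idx)
        for m in range(i, j + 1):
            letters[order[m]] += ch
    return letters


def lsd_letters(cell_means: pd.Series, ms_error: float, df_error: int,
                n_per_mean: int, alpha: float = 0.05,
                sds: pd.Series | None = None) -> LetterDisplay:
    """Fisher's LSD compact letter display for treatment means.

    ``cell_means`` is indexed by treatment id; ``ms_error`` and
    ``df_error`` come from the appropriate ANOVA stratum (error b for
    subplot-level treatment combinations) and ``n_per_mean`` is the number
    of replicates behind each mean.
    """
    if ms_error <= 0:
        raise ValueError("ms_error must be > 0")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if n_per_mean <= 0:
        raise ValueError("n_per_mean must be > 0")
    tcrit = sps.t.ppf(1 - alpha / 2, df_error)
    lsd = float(tcrit * np.sqrt(2.0 * ms_error / n_per_mean))
    means = cell_means.sort_values(ascending=False)

    def nsd(a, b):
        return abs(means[a] - means[b]) <= lsd

    letters = letters_from_nsd(means, nsd)
    return LetterDisplay(means=means, sds=sds, letters=letters,
                         lsd=lsd, alpha=alpha)


def pearson_matrix(table: pd.DataFrame, variables: list[str]) -> pd.DataFrame:
    """All-pairs Pearson correlations with p-values and star codes.

    Returns a tidy frame (var1, var2, r, p, star, n).  A zero-variance
    variable yields NaN r with star ``"undef"`` — flagged, never silently
    zeroed.  Needs >= 3 paired observations per pair.
    """
    rows = []
    for i, a in enumerate(variables):
        for b in variables[i:]:
            x = table[a].to_numpy(dtype=float)
            y = table[b].to_numpy(dtype=float)
            ok = np.isfinite(x) & np.isfinite(y)
            x, y = x[ok], y[ok]
            if len(x) < 3:
                raise ValueError(f"need >= 3 paired observations for ({a}, {b})")
            if a == b:
                r, p = 1.0, 0.0
            elif np.std(x) == 0 or np.std(y) == 0:
                r, p = np.nan, np.nan
            else:
                r, p = sps.pearsonr(x, y)
            star = "undef" if np.isnan(r) else significance_code(p)
            rows.append({"var1": a, "var2": b, "r": r, "p": p,
                         "star": star, "n": len(x)})
            if a != b:
                rows.append({"var1": b, "var2": a, "r": r, "p": p,
                             "star": star, "n": len(x)})
    return pd.DataFrame(rows)
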