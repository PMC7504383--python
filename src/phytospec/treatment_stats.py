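"""Univariate treatment-effect testing on spectra-derived traits.

Per trait: Shapiro-Wilk normality check, one-way (between-subjects) ANOVA,
and Tukey's HSD post-hoc with a compact letter display (groups sharing a
letter are not significantly different).  Unequal group sizes are handled
by the Tukey-Kramer variant.  The classical tests delegate to scipy; the
letter display is computed here by insert-and-absorb over the
non-significance graph.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps


class StatsError(ValueError):
    pass


def shapiro_wilk(values) -> tuple[float, float]:
    """Shapiro-Wilk W statistic and p-value (3 <= n <= 5000)."""
    x = np.asarray(values, dtype=float).ravel()
    if x.size < 3 or x.size > 5000:
        raise StatsError("Shapiro-Wilk requires 3 <= n <= 5000")
    if np.ptp(x) == 0:
        raise StatsError("constant input")
    w, p = sps.shapiro(x)
    return float(w), float(p)


@dataclass
class AnovaResult:
    f_value: float
    p_value: float
    df_between: int
    df_within: int
    group_stats: pd.DataFrame  # index group: n, mean, sd


def _group_arrays(values, groups):
    values = np.asarray(values, dtype=float).ravel()
    groups = np.asarray(groups)
    if values.shape[0] != groups.shape[0]:
        raise StatsError("values and groups lengths differ")
    uniq = np.unique(groups)
    if uniq.size < 2:
        raise StatsError("need at least 2 groups")
    arrays = [values[groups == g] for g in uniq]
    if min(a.size for a in arrays) < 2:
        raise StatsError("singleton group")
    return uniq, arrays


def one_way_anova(values, groups) -> AnovaResult:
    """Classical one-way between-subjects ANOVA."""
    uniq, arrays = _group_arrays(values, groups)
    if all(np.ptp(a) == 0 for a in arrays) and np.ptp(
        np.asarray(values, dtype=float)
    ) != 0:
        raise StatsError("zero within-group variance: F undefined")
    f, p = sps.f_oneway(*arrays)
    n = sum(a.size for a in arrays)
    gs = pd.DataFrame(
        {
            "n": [a.size for a in arrays],
            "mean": [a.mean() for a in arrays],
            "sd": [a.std(ddof=1) for a in arrays],
        },
        index=pd.Index(uniq, name="group"),
    )
    return AnovaResult(
        f_value=float(f), p_value=float(p),
        df_between=len(arrays) - 1, df_within=n - len(arrays),
        group_stats=gs,
    )


@dataclass
class TukeyResult:
    pairwise: pd.DataFrame  # group_a, group_b, diff, p_adj
    letters: dict           # group -> compact letter display
    alpha: float


def _letter_display(groups: list, means: dict, sig_pairs: set) -> dict:
    """Insert-and-absorb compact letter display.

    Start from one set holding all groups; for every significantly
    different pair split the sets containing both; absorb subsets; order
    sets by descending member mean and label them a, b, c, ...
    """
    sets: list[set] = [set(groups)]
    for a, b in sig_pairs:
        new_sets = []
        for s in sets:
            if a in s and b in s:
                new_sets.extend([s - {a}, s - {b}])
            else:
                new_sets.append(s)
        # absorb sets contained in another
        sets = [
            s for s in new_sets
            if s and not any(s < t for t in new_sets)
        ]
        # deduplicate
        uniq: list[set] = []
        for s in sets:
            if s not in uniq:
                uniq.append(s)
        sets = uniq
    sets.sort(key=lambda s: -max(means[g] for g in s))
    labels = "abcdefghijklmnopqrstuvwxyz"
    out = {g: "" for g in groups}
    for i, s in enumerate(sets):
        for g in s:
            out[g] += labels[i]
    return {g: "".join(sorted(v)) for g, v in out.items()}


def tukey_hsd(values, groups, alpha: float = 0.05) -> TukeyResult:
    """Tukey's honestly-significant-difference test with letter display.

    Pairwise p-values come from the studentized-range distribution
    (Tukey-Kramer for unequal group sizes); groups not significantly
    different at ``alpha`` share a letter.
    """
    uniq, arrays = _group_arrays(values, groups)
    res = sps.tukey_hsd(*arrays)
    rows = []
    sig = set()
    means = {g: a.mean() for g, a in zip(uniq, arrays)}
    for i in range(len(uniq)):
        for j in range(i + 1, len(uniq)):
            p = float(res.pvalue[i, j])
            rows.append({
                "group_a": uniq[i], "group_b": uniq[j],
                "diff": means[uniq[i]] - means[uniq[j]],
                "p_adj": p,
            })
            if p < alpha:
                sig.add((uniq[i], uniq[j]))
    letters = _letter_display(list(uniq), means, sig)
    return TukeyResult(pairwise=pd.DataFrame(rows), letters=letters,
                       alpha=alpha)


def treatment_tables(
    trait_table: pd.DataFrame,
    metadata: pd.DataFrame,
    group_col: str = "treatment",
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """ANOVA and Tukey summaries for every trait column.

    Returns ``(anova, tukey)``: one ANOVA row per trait (W/p from
    Shapiro-Wilk on residuals, F, p) and one Tukey row per trait x group
    (mean, sd, letter).
    """
    groups = metadata.loc[trait_table.index, group_col].to_numpy()
    anova_rows, tukey_rows = [], []
    for trait in trait_table.columns:
        vals = trait_table[trait].to_numpy(dtype=float)
        res = one_way_anova(vals, groups)
        resid = vals - res.group_stats["mean"].reindex(groups).to_numpy()
        try:
            _, sw_p = shapiro_wilk(resid)
        except StatsError:
            sw_p = np.nan
        anova_rows.append({
            "trait": trait, "F": res.f_value, "p": res.p_value,
            "shapiro_p": sw_p,
        })
        tk = tukey_hsd(vals, groups, alpha=alpha)
        for g in res.group_stats.index:
            tukey_rows.append({
                "trait": trait, "group": g,
                "mean": res.group_stats.loc[g, "mean"],
                "sd": res.group_stats.loc[g, "sd"],
                "letter": tk.letters[g],
            })
    return (
        pd.DataFrame(anova_rows).set_index("trait"),
        pd.DataFrame(tukey_rows).set_index(["trait", "group"]),
    )
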