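"""Groupwise comparison of daily means: one-way ANOVA, Tukey HSD, letters.

Site/position contrasts of daily mean temperatures are screened with a
one-way ANOVA followed by Tukey's honestly-significant-difference test
(Tukey-Kramer under unequal group sizes) and summarised as a compact letter
display: groups sharing a letter are not separable at the chosen level.
"""

from __future__ import annotations

import string
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multicomp import pairwise_tukeyhsd


@dataclass
class GroupComparison:
    f_stat: float
    p_value: float
    group_means: dict[str, float]
    group_n: dict[str, int]
    tukey_p: dict[frozenset, float]
    letters: dict[str, str]
    alpha: float


def _compact_letters(groups: list[str], sig: set[frozenset]) -> dict[str, str]:
    """Insert-and-absorb compact letter display.

    Columns are sets of mutually non-separated groups; every significant
    pair must end up in no common column, every non-significant pair in at
    least one.
    """
    columns: list[set] = [set(groups)]
    for pair in sig:
        a, b = tuple(pair)
        for col in list(columns):
            if a in col and b in col:
                columns.remove(col)
                ca = col - {b}
                cb = col - {a}
                for c in (ca, cb):
                    if not any(c <= other for other in columns):
                        columns.append(c)
    # drop absorbed columns and order deterministically by best member mean
    columns = [c for c in columns
               if not any(c < other for other in columns)]
    columns.sort(key=lambda c: sorted(groups.index(g) for g in c))
    letters = {g: "" for g in groups}
    for letter, col in zip(string.ascii_lowercase, columns):
        for g in groups:
            if g in col:
                letters[g] += letter
    return letters


def anova_tukey(values, labels, alpha: float = 0.05) -> GroupComparison:
    """One-way ANOVA with Tukey HSD post-hoc and a compact letter display.

    Parameters
    ----------
    values, labels
        Observations (for example daily mean temperatures) and their group
        labels (for example ``"S:open_field"``).
    alpha
        Familywise level for the letter display.
    """
    values = np.asarray(values, dtype=float).ravel()
    labels = np.asarray(labels, dtype=object).ravel()
    keep = np.isfinite(values)
    values, labels = values[keep], labels[keep]
    names = list(dict.fromkeys(labels))  # first-appearance order
    samples = [values[labels == g] for g in names]
    if len(names) < 2:
        raise ValueError("need at least 2 groups")
    for g, s in zip(names, samples):
        if s.size < 2:
            raise ValueError(f"group {g!r} has fewer than 2 observations")
    f_stat, p_value = sps.f_oneway(*samples)
    hsd = pairwise_tukeyhsd(values, labels.astype(str), alpha=alpha)
    tukey_p = {}
    for row in hsd.summary().data[1:]:
        g1, g2, _, padj = row[0], row[1], row[2], float(row[3])
        tukey_p[frozenset((str(g1), str(g2)))] = padj
    sig = {pair for pair, p in tukey_p.items() if p < alpha}
    # order groups by descending mean so letter 'a' tags the warmest block
    means = {g: float(np.mean(s)) for g, s in zip(names, samples)}
    ordered = sorted(names, key=lambda g: -means[g])
    letters = _compact_letters([str(g) for g in ordered], sig)
    return GroupComparison(
        f_stat=float(f_stat),
        p_value=float(p_value),
        group_means=means,
        group_n={g: int(s.size) for g, s in zip(names, samples)},
        tukey_p=tukey_p,
        letters={g: letters[str(g)] for g in names},
        alpha=alpha,
    )
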