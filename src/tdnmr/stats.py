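"""Group comparison: one-way ANOVA, Tukey HSD, compact letter display."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy import stats as sps

__all__ = ["GroupComparison", "group_compare", "compact_letters"]


@dataclass(frozen=True)
class GroupComparison:
    """One-way ANOVA p-value, pairwise Tukey p-values and letter codes.

    Groups sharing a letter are not significantly different at the stated
    confidence level.
    """

    anova_p: float
    letters: dict[str, str]
    pairwise_p: dict[tuple[str, str], float]
    alpha: float
    excluded: tuple[str, ...] = ()


def compact_letters(
    names: list[str],
    means: dict[str, float],
    distinct: dict[tuple[str, str], bool],
) -> dict[str, str]:
    """Compact letter display from a pairwise 'significantly different' map.

    Letters label the maximal cliques of the not-significantly-different
    graph, ordered by descending clique mean, so the group with the
    largest mean carries 'a'.
    """
    g = nx.Graph()
    g.add_nodes_from(names)
    for (a, b), diff in distinct.items():
        if not diff:
            g.add_edge(a, b)
    cliques = list(nx.find_cliques(g))
    cliques.sort(key=lambda c: -max(means[n] for n in c))
    letters: dict[str, list[str]] = {n: [] for n in names}
    for i, clique in enumerate(cliques):
        letter = chr(ord("a") + i) if i < 26 else f"z{i - 25}"
        for n in clique:
            letters[n].append(letter)
    return {n: "".join(sorted(ls)) for n, ls in letters.items()}


def group_compare(values_by_group: dict[str, "np.ndarray"], alpha: float = 0.05) -> GroupComparison:
    """One-way ANOVA plus Tukey HSD letters over replicate groups.

    Groups with fewer than 2 replicates are excluded with a warning.  When
    the within-group variance is numerically zero (noiseless synthetic
    replicates), groups are compared by exact mean equality instead of the
    degenerate studentized-range test.
    """
    groups = {k: np.asarray(v, dtype=float) for k, v in values_by_group.items()}
    excluded = tuple(k for k, v in groups.items() if v.size < 2)
    if excluded:
        warnings.warn(f"excluding single-replicate groups: {excluded}", stacklevel=2)
        groups = {k: v for k, v in groups.items() if v.size >= 2}
    if len(groups) < 2:
        raise ValueError("group comparison requires >= 2 groups with >= 2 replicates")
    names = sorted(groups)
    arrays = [groups[n] for n in names]
    means = {n: float(groups[n].mean()) for n in names}

    pooled_within = float(np.mean([v.var(ddof=1) for v in arrays]))
    scale = max(float(np.mean([np.abs(v).mean() for v in arrays])), 1e-300)
    if pooled_within < (1e-9 * scale) ** 2:
        # degenerate: compare means exactly
        distinct = {}
        pairwise_p = {}
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                same = abs(means[a] - means[b]) <= 1e-9 * scale
                distinct[(a, b)] = not same
                pairwise_p[(a, b)] = 1.0 if same else 0.0
        anova_p = 1.0 if all(not d for d in distinct.values()) else 0.0
    else:
        _, anova_p = sps.f_oneway(*arrays)
        res = sps.tukey_hsd(*arrays)
        pairwise_p = {}
        distinct = {}
        for i, a in enumerate(names):
            for j in range(i + 1, len(names)):
                b = names[j]
                p = float(res.pvalue[i, j])
                pairwise_p[(a, b)] = p
                distinct[(a, b)] = p < alpha
    letters = compact_letters(names, means, distinct)
    return GroupComparison(
        anova_p=float(anova_p), letters=letters,
        pairwise_p=pairwise_p, alpha=alpha, excluded=excluded,
    )
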