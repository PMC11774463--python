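"""Differential and effect-size statistics for motif analyses.

Covers Fisher's exact test on occurrence tables, Bonferroni /
Benjamini-Hochberg adjustment, Cramér's V effect sizes (including the
conditional triangle variant with the 0.21 moderate-effect threshold),
the two-sample two-sided proportion z-test, scaled dense-rank feature
matrices, and per-patient enrichment flags for survival export.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .motif import Motif

__all__ = [
    "fisher_differential", "adjust_pvalues", "cramers_v", "chi2_table",
    "TriangleEffectSize", "triangle_effect_size", "proportion_test",
    "feature_matrix", "enrichment_flags", "MODERATE_EFFECT_SIZE",
]

#: Cramér's V above this is considered a moderate (reportable) effect.
MODERATE_EFFECT_SIZE = 0.21


def fisher_differential(count_a: int, total_a: int, count_b: int, total_b: int
                        ) -> tuple[int, float]:
    """Two-sided Fisher exact test on the 2x2 occurrence table
    ``[[count_a, total_a - count_a], [count_b, total_b - count_b]]``.

    Returns ``(direction, p)`` with direction +1 when condition A has the
    larger occurrence proportion, -1 when smaller, 0 when equal.
    """
    for c, t in ((count_a, total_a), (count_b, total_b)):
        if c < 0 or t <= 0 or c > t:
            raise ValueError("counts must satisfy 0 <= count <= total, total > 0")
    table = [[count_a, total_a - count_a], [count_b, total_b - count_b]]
    _, p = sps.fisher_exact(table, alternative="two-sided")
    pa, pb = float(count_a) / total_a, float(count_b) / total_b
    direction = int(pa > pb) - int(pa < pb)
    return direction, float(p)


def adjust_pvalues(ps: Sequence[float], method: str = "bh") -> np.ndarray:
    """Multiple-testing adjustment (``bonferroni`` or ``bh``), order
    preserved."""
    ps = np.asarray(ps, dtype=float)
    if ps.size == 0:
        return ps
    if np.any((ps < 0) | (ps > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    key = {"bh": "fdr_bh", "bonferroni": "bonferroni"}.get(method)
    if key is None:
        raise ValueError(f"unknown adjustment method {method!r}")
    return multipletests(ps, method=key)[1]


def cramers_v(chi2: float, n: int, k: int = 2) -> float:
    """Effect size ``sqrt(chi2 / (n (k-1)))`` clipped to [0, 1]; ``n`` is
    the number of units in the test, ``k`` the smaller table dimension."""
    if n <= 0:
        raise ValueError("n must be positive")
    if chi2 < 0 or k < 2:
        raise ValueError("need chi2 >= 0 and k >= 2")
    return float(np.clip(np.sqrt(chi2 / (n * (k - 1))), 0.0, 1.0))


def chi2_table(table: np.ndarray, correction: bool = False) -> float:
    """Chi-squared statistic of a contingency table (no continuity
    correction by default)."""
    table = np.asarray(table, dtype=float)
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("degenerate table: zero marginal")
    chi2, _, _, _ = sps.chi2_contingency(table, correction=correction)
    return float(chi2)


@dataclass
class TriangleEffectSize:
    """Conditional Cramér's V for a type triple (A, B, C) over triangles."""

    types: tuple[str, str, str]
    conditional: dict[str, float]   # fixed type -> ES of the other two
    n_fixed: dict[str, int]         # fixed type -> triangles with >=1 such cell
    es: float                       # min of the conditionals
    defined: bool
    significant: bool


def _triangle_label_triples(G: nx.Graph) -> list[tuple[str, str, str]]:
    from .occurrence import triangle_iter
    return [tuple(G.nodes[x]["cell_type"] for x in tri) for tri in triangle_iter(G)]


def triangle_effect_size(G_or_triangles, A: str, B: str, C: str,
                         correction: bool = False) -> TriangleEffectSize:
    """Overall effect size of a size-3 type triple.

    For each fixed type, restrict to the triangles containing at least one
    cell of that type and test independence of the presence of the other
    two types on a 2x2 table; the overall ES is the minimum of the three
    conditional values (so every conditional test must clear the
    moderate-effect threshold for significance).
    """
    if isinstance(G_or_triangles, nx.Graph):
        triples = _triangle_label_triples(G_or_triangles)
    else:
        triples = [tuple(t) for t in G_or_triangles]
    conditional: dict[str, float] = {}
    n_fixed: dict[str, int] = {}
    defined = True
    for fixed, (p1, p2) in ((C, (A, B)), (B, (A, C)), (A, (B, C))):
        sel = [t for t in triples if fixed in t]
        n_fixed[fixed] = len(sel)
        if not sel:
            conditional[fixed] = float("nan")
            defined = False
            continue
        table = np.zeros((2, 2))
        for t in sel:
            has1 = p1 in t
            has2 = p2 in t
            table[1 - has1, 1 - has2] += 1
        try:
            chi2 = chi2_table(table, correction=correction)
            conditional[fixed] = cramers_v(chi2, len(sel), 2)
        except ValueError:
            conditional[fixed] = float("nan")
            defined = False
    es = min(conditional.values()) if defined else float("nan")
    significant = bool(defined and es >= MODERATE_EFFECT_SIZE)
    return TriangleEffectSize(types=(A, B, C), conditional=conditional,
                              n_fixed=n_fixed, es=es, defined=defined,
                              significant=significant)


def proportion_test(x1: int, n1: int, x2: int, n2: int) -> float:
    """Two-sample, two-sided z-test of equal proportions with pooled
    variance.  Degenerate pooled proportions (0 or 1) give p = 1 with a
    warning."""
    for x, n in ((x1, n1), (x2, n2)):
        if n <= 0 or x < 0 or x > n:
            raise ValueError("need 0 <= x <= n and n > 0")
    pooled = (x1 + x2) / (n1 + n2)
    if pooled in (0.0, 1.0):
        warnings.warn("degenerate pooled proportion; p-value undefined, "
                      "returning 1", RuntimeWarning)
        return 1.0
    se = np.sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n2))
    z = (x1 / n1 - x2 / n2) / se
    return float(2 * sps.norm.sf(abs(z)))


def feature_matrix(per_sample_counts: Mapping[object, Mapping[Motif, int]],
                   motifs: Sequence[Motif]) -> pd.DataFrame:
    """Samples x motifs matrix of dense ranks min-max scaled to [0, 1]
    (most abundant motif -> 1); missing motifs count as 0."""
    if not motifs:
        raise ValueError("empty motif list")
    columns = [m.canonical for m in motifs]
    rows = {}
    for sample, counts in per_sample_counts.items():
        vec = np.array([counts.get(m, 0) for m in motifs], dtype=float)
        ranks = sps.rankdata(vec, method="dense")
        span = ranks.max() - 1
        if span == 0:
            warnings.warn(f"sample {sample!r}: all motif counts equal; "
                          "features degenerate to 0", RuntimeWarning)
            rows[sample] = np.zeros(len(motifs))
        else:
            rows[sample] = (ranks - 1) / span
    return pd.DataFrame.from_dict(rows, orient="index", columns=columns)


def enrichment_flags(per_patient_counts: Mapping[object, Mapping[Motif, int]],
                     size: int, top: int = 29) -> pd.DataFrame:
    """Binary patients x motifs matrix: 1 iff the motif (of the given size)
    is among the patient's ``top`` most abundant motifs of that size.

    Ties at the boundary are all included; motifs never observed in a
    patient are never flagged.
    """
    universe: list[Motif] = []
    seen = set()
    for counts in per_patient_counts.values():
        for m in counts:
            if m.k == size and m.canonical not in seen:
                seen.add(m.canonical)
                universe.append(m)
    universe.sort(key=lambda m: m.canonical)
    columns = [m.canonical for m in universe]
    rows = {}
    for patient, counts in per_patient_counts.items():
        vec = np.array([counts.get(m, 0) for m in universe], dtype=float)
        positive = np.sort(vec[vec > 0])[::-1]
        if len(positive) == 0:
            rows[patient] = np.zeros(len(universe), dtype=int)
            continue
        threshold = positive[min(top, len(positive)) - 1]
        rows[patient] = ((vec > 0) & (vec >= threshold)).astype(int)
    return pd.DataFrame.from_dict(rows, orient="index", columns=columns)
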