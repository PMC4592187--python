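"""Per-gene ANOVA, Benjamini-Hochberg FDR and fold-change DEG calling.

Each contrast is a pairwise comparison between two condition cells of the
factorial design (every reported DEG count is attached to one specific
comparison, e.g. combined treatment vs one single stressor). The test is a
one-way fixed-effects ANOVA on log2(expression + pseudocount); the signed
fold change is computed on linear-scale replicate means. A gene is a DEG
when |fold change| >= 2 and BH q <= 0.05 (both thresholds inclusive and
configurable); genes without at least two non-missing replicates on each
side are ``untestable`` and excluded from the BH family.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import DesignSheet, ExpressionTable

__all__ = [
    "AnovaResult",
    "Contrast",
    "anova_gene",
    "bh_fdr",
    "fold_change",
    "call_degs",
    "read_deg_tsv",
    "write_deg_tsv",
]

CALLS = ("up", "down", "not_de", "untestable")

#: Relative tolerance below which the within-group sum of squares is treated
#: as exactly zero (degenerate-variance convention).
_SS_EPS = 1e-12


class AnovaResult(NamedTuple):
    F: float
    p: float
    degenerate: bool  #: within-group variance zero while means differ


@dataclass(frozen=True)
class Contrast:
    """A named pairwise comparison between two condition cells."""

    name: str
    test_condition_id: str
    reference_condition_id: str

    def __post_init__(self) -> None:
        if self.test_condition_id == self.reference_condition_id:
            raise ValueError("test and reference conditions must differ")


def anova_gene(groups: Sequence[Sequence[float]]) -> AnovaResult:
    """One-way fixed-effects ANOVA over >= 2 replicate groups.

    Missing values (NaN) are dropped within each group. If any group retains
    fewer than two values the gene is untestable and ``(nan, nan, False)``
    is returned. Degenerate conventions: all values identical -> ``F = 0,
    p = 1``; zero within-group variance with differing means -> ``p = 0``
    with the ``degenerate`` flag set.
    """
    cleaned = [np.asarray(g, dtype=float) for g in groups]
    cleaned = [g[~np.isnan(g)] for g in cleaned]
    if len(cleaned) < 2:
        raise ValueError("anova_gene needs at least two groups")
    if any(g.size < 2 for g in cleaned):
        return AnovaResult(float("nan"), float("nan"), False)

    all_vals = np.concatenate(cleaned)
    grand = all_vals.mean()
    ssb = sum(g.size * (g.mean() - grand) ** 2 for g in cleaned)
    ssw = sum(float(np.sum((g - g.mean()) ** 2)) for g in cleaned)
    total = ssb + ssw
    if total <= 0.0:
        return AnovaResult(0.0, 1.0, False)
    if ssw <= _SS_EPS * total:
        if ssb <= _SS_EPS * total:
            return AnovaResult(0.0, 1.0, False)
        return AnovaResult(float("inf"), 0.0, True)
    k = len(cleaned)
    n_total = all_vals.size
    F = (ssb / (k - 1)) / (ssw / (n_total - k))
    p = float(stats.f.sf(F, k - 1, n_total - k))
    return AnovaResult(float(F), p, False)


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values; NaN p propagates NaN q.

    ``q_(i) = min_{j >= i} p_(j) * n / j`` clipped at 1, with the family
    size ``n`` counting only the non-missing p-values.
    """
    p = np.asarray(p_values, dtype=float)
    out = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    if not mask.any():
        return out
    vals = p[mask]
    if (vals < 0).any() or (vals > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    out[mask] = multipletests(vals, method="fdr_bh")[1]
    return out


def fold_change(mean_test: float, mean_ref: float) -> float:
    """Signed-ratio fold change on linear means; |fc| >= 1 always.

    ``+mean_test/mean_ref`` when the test mean is at least as large, else
    ``-mean_ref/mean_test``. Zero reference with positive test gives +inf
    (and symmetrically -inf); both zero is untestable (NaN).
    """
    if mean_test < 0 or mean_ref < 0:
        raise ValueError("means must be non-negative")
    if mean_test == 0 and mean_ref == 0:
        return float("nan")
    if mean_ref == 0:
        return float("inf")
    if mean_test == 0:
        return float("-inf")
    if mean_test >= mean_ref:
        return mean_test / mean_ref
    return -mean_ref / mean_test


def _pooled_contrast_p(
    log_groups: list[np.ndarray],
    test_idx: int,
    ref_idx: int,
) -> float:
    """Two-sided p for one pairwise comparison with error pooled over groups.

    Classical protected-contrast test: the within-group mean square is
    pooled across every group with >= 2 values, and the test/reference mean
    difference is referred to a t distribution on the pooled df. With only
    the two contrast groups present this is algebraically identical to the
    two-group one-way ANOVA (F = t^2, same p).
    """
    cleaned = [g[~np.isnan(g)] for g in log_groups]
    ssw = 0.0
    df = 0
    for g in cleaned:
        if g.size >= 2:
            ssw += float(np.sum((g - g.mean()) ** 2))
            df += g.size - 1
    t_grp, r_grp = cleaned[test_idx], cleaned[ref_idx]
    if t_grp.size < 2 or r_grp.size < 2 or df < 1:
        return float("nan")
    diff = t_grp.mean() - r_grp.mean()
    scale = max(abs(t_grp).max(), abs(r_grp).max(), 1.0)
    if ssw <= _SS_EPS * scale**2:
        return 1.0 if abs(diff) <= _SS_EPS * scale else 0.0
    se = np.sqrt((ssw / df) * (1.0 / t_grp.size + 1.0 / r_grp.size))
    return float(2.0 * stats.t.sf(abs(diff) / se, df))


def call_degs(
    expr: ExpressionTable,
    design: DesignSheet,
    contrast: Contrast,
    fc_threshold: float = 2.0,
    q_threshold: float = 0.05,
    pseudocount: float = 1.0,
    error_conditions: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Call DEGs for one pairwise contrast.

    The per-gene test is a one-way fixed-effects ANOVA on
    log2(expression + pseudocount): by default its error term uses the two
    contrast groups only (equivalent to :func:`anova_gene` on those groups);
    passing ``error_conditions`` (e.g. every condition cell at the same time
    point) pools the within-group error across those cells and tests the
    contrast against the pooled mean square, the classical protected
    pairwise comparison within a multi-group ANOVA.

    Returns a DataFrame indexed by gene id with columns ``mean_test``,
    ``mean_ref`` (linear-scale means over non-missing replicates),
    ``fold_change`` (signed ratio), ``p_value``, ``q_value`` (BH over the
    testable genes of this contrast) and ``call`` in
    {up, down, not_de, untestable}.
    """
    def _resolve(cond: str) -> list[str]:
        return [s for s in design.samples(cond) if s in expr.sample_ids]

    test_samples = _resolve(contrast.test_condition_id)
    ref_samples = _resolve(contrast.reference_condition_id)
    if len(test_samples) < 2 or len(ref_samples) < 2:
        raise ValueError(
            f"contrast {contrast.name!r} resolves to <2 samples per side "
            f"(test={len(test_samples)}, ref={len(ref_samples)})"
        )
    if error_conditions is None:
        error_conditions = [contrast.test_condition_id, contrast.reference_condition_id]
    error_conditions = list(error_conditions)
    for cond in (contrast.test_condition_id, contrast.reference_condition_id):
        if cond not in error_conditions:
            error_conditions.append(cond)
    test_idx = error_conditions.index(contrast.test_condition_id)
    ref_idx = error_conditions.index(contrast.reference_condition_id)

    group_arrays = [expr.values[_resolve(c)].to_numpy() for c in error_conditions]
    log_arrays = [np.log2(g + pseudocount) for g in group_arrays]
    tvals = group_arrays[test_idx]
    rvals = group_arrays[ref_idx]
    n_genes = expr.shape[0]
    mean_test = np.full(n_genes, np.nan)
    mean_ref = np.full(n_genes, np.nan)
    fc = np.full(n_genes, np.nan)
    p = np.full(n_genes, np.nan)

    for i in range(n_genes):
        t_ok = tvals[i][~np.isnan(tvals[i])]
        r_ok = rvals[i][~np.isnan(rvals[i])]
        if t_ok.size < 2 or r_ok.size < 2:
            continue
        mean_test[i] = t_ok.mean()
        mean_ref[i] = r_ok.mean()
        fc[i] = fold_change(mean_test[i], mean_ref[i])
        p[i] = _pooled_contrast_p([g[i] for g in log_arrays], test_idx, ref_idx)

    q = bh_fdr(p)
    call = np.full(n_genes, "not_de", dtype=object)
    untestable = np.isnan(p) | np.isnan(fc)
    call[untestable] = "untestable"
    sig = ~untestable & (q <= q_threshold)
    call[sig & (fc >= fc_threshold)] = "up"
    call[sig & (fc <= -fc_threshold)] = "down"

    return pd.DataFrame(
        {
            "mean_test": mean_test,
            "mean_ref": mean_ref,
            "fold_change": fc,
            "p_value": p,
            "q_value": q,
            "call": call,
        },
        index=expr.gene_ids,
    )


def write_deg_tsv(deg: pd.DataFrame, path) -> None:
    deg.to_csv(path, sep="\t", na_rep="NA", index_label="gene_id", lineterminator="\n")


def read_deg_tsv(path) -> pd.DataFrame:
    deg = pd.read_csv(
        path, sep="\t", index_col="gene_id", na_values=["NA"], keep_default_na=False
    )
    for col in ("mean_test", "mean_ref", "fold_change", "p_value", "q_value"):
        deg[col] = deg[col].astype(float)
    return deg
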