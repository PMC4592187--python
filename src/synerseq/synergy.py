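"""Synergy logic: SA-DEG intersection, global synergy, dose and persistence filters.

A *synergistically altered* DEG (SA-DEG) is a gene differentially expressed
in the combined-treatment samples against *each* single-stressor treatment
separately (double-contrast intersection). The global synergy criterion
compares the DEG count of the co-treatment (vs untreated control) with the
theoretical sum of the single-treatment DEG counts: a strict excess flags
synergy at the whole-transcriptome level. Further filters narrow the SA-DEG
set to genes with a monotone dose-response trend (confirmed against the
vehicle control), to genes recovered in an independent dose-response
experiment, and finally to genes whose synergistic perturbation persists at
the late time point — the sustained signature.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SignatureSet",
    "MonotoneResult",
    "call_sa_degs",
    "global_synergy",
    "classify_unique_genes",
    "monotone_dose_filter",
    "intersect_signatures",
    "persistence_filter",
    "dose_response_signature",
    "signed_log2",
]

DE_CALLS = ("up", "down")


@dataclass
class SignatureSet:
    """An ordered gene signature with the provenance of the filters it passed.

    ``table`` is indexed by gene id (sorted) and carries at least a
    ``direction`` column (``up``/``down``); SA-DEG-derived signatures add
    per-contrast fold changes and a ``discordant`` flag for genes whose
    direction disagrees between the two reference contrasts.
    """

    table: pd.DataFrame
    filters_passed: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.table.index.duplicated().any():
            raise ValueError("duplicate gene ids in signature")
        self.table = self.table.sort_index()

    @property
    def genes(self) -> pd.Index:
        return self.table.index

    def __len__(self) -> int:
        return len(self.table)

    def __contains__(self, gene_id) -> bool:
        return gene_id in self.table.index

    def to_frame(self) -> pd.DataFrame:
        out = self.table.copy()
        out["filters_passed"] = ";".join(self.filters_passed)
        return out

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(
            path, sep="\t", na_rep="NA", index_label="gene_id", lineterminator="\n"
        )


def _check_universes(name_a: str, a: pd.DataFrame, name_b: str, b: pd.DataFrame) -> None:
    if not a.index.sort_values().equals(b.index.sort_values()):
        only_a = sorted(set(a.index) - set(b.index))
        only_b = sorted(set(b.index) - set(a.index))
        raise ValueError(
            f"gene universes differ: {len(only_a)} only in {name_a} "
            f"(e.g. {only_a[:5]}), {len(only_b)} only in {name_b} (e.g. {only_b[:5]})"
        )


def call_sa_degs(
    deg_vs_A: pd.DataFrame,
    deg_vs_B: pd.DataFrame,
    filter_name: str = "sa_deg",
) -> SignatureSet:
    """Genes called DE (up or down) against both single-stressor references.

    Both tables must cover the same gene universe and come from the same
    combined-treatment samples contrasted with the two single-stressor
    controls. Genes whose direction disagrees between the two contrasts are
    retained but flagged ``discordant``; their ``direction`` is taken from
    the vs-A contrast.
    """
    _check_universes("deg_vs_A", deg_vs_A, "deg_vs_B", deg_vs_B)
    b = deg_vs_B.loc[deg_vs_A.index]
    both = deg_vs_A["call"].isin(DE_CALLS) & b["call"].isin(DE_CALLS)
    members = deg_vs_A.index[both]
    dir_a = deg_vs_A.loc[members, "call"]
    dir_b = b.loc[members, "call"]
    table = pd.DataFrame(
        {
            "direction": dir_a,
            "discordant": (dir_a != dir_b).to_numpy(),
            "fc_vs_A": deg_vs_A.loc[members, "fold_change"],
            "fc_vs_B": b.loc[members, "fold_change"],
        },
        index=members,
    )
    return SignatureSet(table, [filter_name])


def global_synergy(n_combo: int, n_A: int, n_B: int) -> tuple[int, bool]:
    """Count-vs-theoretical-sum synergy criterion (strict inequality).

    Returns ``(theoretical_sum, synergy_flag)`` where the sum is
    ``n_A + n_B`` and the flag is ``n_combo > n_A + n_B``.
    """
    if min(n_combo, n_A, n_B) < 0:
        raise ValueError("DEG counts must be non-negative")
    theoretical_sum = n_A + n_B
    return theoretical_sum, n_combo > theoretical_sum


def classify_unique_genes(
    sa: SignatureSet,
    deg_combo_vs_ctrl: pd.DataFrame,
    deg_A_vs_ctrl: pd.DataFrame,
    deg_B_vs_ctrl: pd.DataFrame,
) -> tuple[pd.Series, float]:
    """Flag SA-DEGs seen only in the combined treatment vs control.

    A gene is *unique* when it is DE in combo-vs-control but DE in neither
    single-stressor-vs-control contrast. Returns the per-gene boolean flags
    (indexed like the signature) and the unique fraction among SA-DEGs.
    """
    _check_universes("combo_vs_ctrl", deg_combo_vs_ctrl, "A_vs_ctrl", deg_A_vs_ctrl)
    _check_universes("combo_vs_ctrl", deg_combo_vs_ctrl, "B_vs_ctrl", deg_B_vs_ctrl)
    missing = [g for g in sa.genes if g not in deg_combo_vs_ctrl.index]
    if missing:
        raise ValueError(f"signature genes absent from DEG tables: {missing[:10]}")
    genes = sa.genes
    in_combo = deg_combo_vs_ctrl.loc[genes, "call"].isin(DE_CALLS)
    in_a = deg_A_vs_ctrl.loc[genes, "call"].isin(DE_CALLS)
    in_b = deg_B_vs_ctrl.loc[genes, "call"].isin(DE_CALLS)
    unique = in_combo & ~in_a & ~in_b
    frac = float(unique.mean()) if len(genes) else float("nan")
    return unique, frac


def signed_log2(fc: float) -> float:
    """Map a signed-ratio fold change onto a continuous log2 axis.

    ``+r -> log2(r)`` and ``-r -> -log2(r)`` (so +1/-1 both map to 0); this
    removes the discontinuity of the signed-ratio convention at +/-1 so that
    monotone comparisons are meaningful.
    """
    if math.isnan(fc):
        return float("nan")
    if math.isinf(fc):
        return math.copysign(float("inf"), fc)
    if abs(fc) < 1:
        raise ValueError(f"signed-ratio fold change must satisfy |fc| >= 1, got {fc}")
    return math.copysign(math.log2(abs(fc)), fc)


class MonotoneResult(NamedTuple):
    passed: bool
    trend: str | None  #: "increasing" | "decreasing" | "flat" when passed
    reason: str | None  #: failure reason when not passed


def monotone_dose_filter(
    fc_by_dose: Sequence[float],
    top_dose_deg_call: str,
) -> MonotoneResult:
    """Non-strict monotone dose-trend test with a vehicle-control gate.

    ``fc_by_dose`` are signed-ratio fold changes at ascending doses against
    a fixed reference. The gene passes when (a) the signed-log2 fold changes
    are non-strictly monotone in either direction, (b) they do not cross
    sign across doses (the perturbation moves away from baseline
    consistently), and (c) the top-dose condition is itself called DE
    (up/down) against the vehicle control. A missing fold change at any dose
    fails with reason ``"untestable"``.
    """
    fcs = list(fc_by_dose)
    if len(fcs) < 2:
        raise ValueError("need fold changes at >= 2 dose levels")
    if any(f is None or (isinstance(f, float) and math.isnan(f)) for f in fcs):
        return MonotoneResult(False, None, "untestable")
    s = [signed_log2(f) for f in fcs]
    if any(v > 0 for v in s) and any(v < 0 for v in s):
        return MonotoneResult(False, None, "sign_crossing")
    nondec = all(x <= y for x, y in zip(s, s[1:]))
    noninc = all(x >= y for x, y in zip(s, s[1:]))
    if not (nondec or noninc):
        return MonotoneResult(False, None, "non_monotone")
    if top_dose_deg_call not in DE_CALLS:
        return MonotoneResult(False, None, "top_dose_not_de_vs_vehicle")
    if s[0] == s[-1]:
        trend = "flat"
    elif nondec:
        trend = "increasing"
    else:
        trend = "decreasing"
    return MonotoneResult(True, trend, None)


def dose_response_signature(
    deg_by_dose: dict[float, pd.DataFrame],
    deg_top_vs_vehicle: pd.DataFrame,
    filter_name: str = "dose_monotone",
) -> SignatureSet:
    """Derive the dose-responsive gene set from per-dose DEG tables.

    ``deg_by_dose`` maps each ascending stressor-A dose to the DEG table of
    (combo at that dose) vs the B-alone reference; ``deg_top_vs_vehicle`` is
    the top-dose combo contrasted with the non-treated vehicle control.
    Members must be DE vs the B-alone reference at the top dose, show a
    monotone (non-strict, sign-consistent) trend of fold changes across
    doses, and be DE vs the vehicle control at the top dose.
    """
    doses = sorted(deg_by_dose)
    if len(doses) < 2:
        raise ValueError("need DEG tables at >= 2 dose levels")
    top = deg_by_dose[doses[0]]
    for d in doses[1:]:
        _check_universes(f"dose {doses[0]}", top, f"dose {d}", deg_by_dose[d])
    _check_universes("top dose", top, "top vs vehicle", deg_top_vs_vehicle)
    top_tbl = deg_by_dose[doses[-1]]
    candidates = top_tbl.index[top_tbl["call"].isin(DE_CALLS)]

    rows = []
    for g in candidates:
        fcs = [deg_by_dose[d].loc[g, "fold_change"] for d in doses]
        res = monotone_dose_filter(fcs, deg_top_vs_vehicle.loc[g, "call"])
        if res.passed:
            rows.append(
                {
                    "gene_id": g,
                    "direction": top_tbl.loc[g, "call"],
                    "trend": res.trend,
                    **{f"fc_dose_{d:g}": fc for d, fc in zip(doses, fcs)},
                }
            )
    if rows:
        table = pd.DataFrame(rows).set_index("gene_id")
    else:
        table = pd.DataFrame(columns=["direction", "trend"]).rename_axis("gene_id")
    return SignatureSet(table, [filter_name])


def intersect_signatures(a: SignatureSet, b: SignatureSet) -> SignatureSet:
    """Set intersection of two signatures; filter provenance is concatenated.

    Metadata columns are joined from both inputs (suffixed on collision);
    ordering is by gene id. Disjoint inputs yield a valid empty signature.
    """
    common = a.genes.intersection(b.genes).sort_values()
    left = a.table.loc[common]
    right = b.table.loc[common]
    overlap = [c for c in right.columns if c in left.columns]
    merged = left.join(right, lsuffix="", rsuffix="_b") if overlap else left.join(right)
    return SignatureSet(merged, list(a.filters_passed) + list(b.filters_passed))


def persistence_filter(sig_early: SignatureSet, sa_late: SignatureSet) -> SignatureSet:
    """Members of the early signature still SA-DEGs at the late time point.

    The late set must itself be an SA-DEG set (double-contrast definition),
    so a sustained gene is synergistically perturbed against both single
    stressors at both time points.
    """
    keep = sig_early.genes.intersection(sa_late.genes).sort_values()
    table = sig_early.table.loc[keep]
    return SignatureSet(
        table, list(sig_early.filters_passed) + ["persistent_late"]
    )
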