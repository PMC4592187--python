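"""End-to-end workflow: normalize -> NA rule -> DEGs -> synergy filters -> enrichment.

:func:`run_pipeline` executes the full filtering cascade on one expression
matrix covering the factorial design, writes every intermediate artifact to
the output directory and returns a JSON-serializable run report with
per-stage gene counts, the thresholds actually applied, the software
version, a config hash and the seed — enough to audit or re-derive every
count by recounting the written artifacts.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import asdict, dataclass

import pandas as pd
import yaml

from . import __version__
from .diffexpr import Contrast, call_degs, write_deg_tsv
from .enrichment import (
    build_pathway_graph,
    hypergeom_ora,
    read_gmt,
    write_graph_edges_tsv,
)
from .io import (
    DesignSheet,
    apply_single_missing_rule,
    compute_rpkm,
    make_condition_id,
    read_design_tsv,
    read_expression_tsv,
    read_lengths_tsv,
    write_expression_tsv,
)
from .synergy import (
    DE_CALLS,
    call_sa_degs,
    classify_unique_genes,
    dose_response_signature,
    global_synergy,
    intersect_signatures,
    persistence_filter,
)

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "summarize_counts"]


class PipelineError(RuntimeError):
    """A stage failure; the message names the stage and the cause."""


@dataclass
class PipelineConfig:
    """Paths, thresholds and design labels for one pipeline run.

    ``expression`` may be raw counts (``unit="counts"``, requires
    ``lengths``) or precomputed RPKM (``unit="rpkm"``). The early/late time
    labels select the signature and persistence time points; the dose series
    and condition roles (vehicle, A-alone, B-alone, combo) are derived from
    the design sheet.
    """

    expression: str
    design: str
    out_dir: str
    unit: str = "counts"
    lengths: str | None = None
    gmt: str | None = None
    fc_threshold: float = 2.0
    fdr_threshold: float = 0.05
    enrichment_fdr: float = 0.05
    overlap_threshold: float = 0.10
    early_time: int | str = 8
    late_time: int | str = 24
    pseudocount: float = 1.0
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def validate(self) -> None:
        for name in ("expression", "design"):
            path = getattr(self, name)
            if not path or not os.path.exists(path):
                raise PipelineError(f"config: {name} file not found: {path!r}")
        if self.unit == "counts":
            if not self.lengths or not os.path.exists(self.lengths):
                raise PipelineError(
                    f"config: lengths file required for counts input, got {self.lengths!r}"
                )
        elif self.unit != "rpkm":
            raise PipelineError(f"config: unit must be counts or rpkm, got {self.unit!r}")
        if self.gmt is not None and not os.path.exists(self.gmt):
            raise PipelineError(f"config: gmt file not found: {self.gmt!r}")
        for name in ("fc_threshold", "fdr_threshold", "enrichment_fdr", "overlap_threshold"):
            if getattr(self, name) <= 0:
                raise PipelineError(f"config: {name} must be positive")
        if str(self.early_time) == str(self.late_time):
            raise PipelineError("config: early and late time labels must differ")

    def hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _conditions(design: DesignSheet, time) -> dict:
    """Resolve the vehicle / A-alone / B-alone / combo roles at one time point."""
    sub = design.table[design.table["time"].astype(str) == str(time)]
    doses = sorted(sub["doseA"].unique())
    if not doses:
        raise PipelineError(f"no samples at time {time!r}")
    top = doses[-1]
    combo_doses = [d for d in doses if d > 0]
    return {
        "vehicle": make_condition_id(0.0, False, time),
        "A_alone": make_condition_id(top, False, time),
        "B_alone": make_condition_id(0.0, True, time),
        "combo": make_condition_id(top, True, time),
        "combo_by_dose": {d: make_condition_id(d, True, time) for d in combo_doses},
        "top_dose": top,
    }


def summarize_counts(deg_tables: dict) -> pd.DataFrame:
    """Per-(time, condition) DEG tally: up, down and total (= up + down).

    ``deg_tables`` maps ``(time, condition_name)`` to a DEG table. An empty
    mapping gives an empty frame with the summary columns.
    """
    rows = []
    for (time, cond), deg in sorted(deg_tables.items(), key=lambda kv: str(kv[0])):
        n_up = int((deg["call"] == "up").sum())
        n_down = int((deg["call"] == "down").sum())
        rows.append(
            {
                "time": time,
                "condition": cond,
                "n_up": n_up,
                "n_down": n_down,
                "n_de": n_up + n_down,
            }
        )
    return pd.DataFrame(rows, columns=["time", "condition", "n_up", "n_down", "n_de"])


def _n_de(deg: pd.DataFrame) -> int:
    return int(deg["call"].isin(DE_CALLS).sum())


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage in order and return the run report (also written as JSON).

    Stage order: normalize (RPKM if counts) -> single-missing NA rule -> DEG
    calling per contrast -> SA-DEG double intersection (early and late) ->
    global synergy per time point -> unique-gene classification -> monotone
    dose filter -> signature intersection -> persistence filter ->
    enrichment + pathway network (when a GMT collection is configured).
    Every intermediate is written under ``config.out_dir``.
    """
    config.validate()
    os.makedirs(config.out_dir, exist_ok=True)
    out = lambda name: os.path.join(config.out_dir, name)
    fc, q = config.fc_threshold, config.fdr_threshold

    stage = "load"
    try:
        design = read_design_tsv(config.design)
        expr = read_expression_tsv(config.expression, config.unit)
        stage = "normalize"
        if config.unit == "counts":
            lengths = read_lengths_tsv(config.lengths)
            expr = compute_rpkm(expr, lengths, "derive")
        stage = "missing_rule"
        expr = apply_single_missing_rule(expr, design)
        write_expression_tsv(expr, out("rpkm.tsv"))

        stage = "deg_calling"
        deg: dict = {}

        dtab = design.table

        def de(name, test, ref, time):
            # Error term pooled over every condition cell at this time point
            # (protected pairwise contrast within the per-time ANOVA).
            error_conditions = list(
                dict.fromkeys(dtab.loc[dtab["time"].astype(str) == str(time),
                                       "condition_id"])
            )
            table = call_degs(
                expr,
                design,
                Contrast(name, test, ref),
                fc,
                q,
                config.pseudocount,
                error_conditions=error_conditions,
            )
            deg[name] = table
            write_deg_tsv(table, out(f"deg_{name}.tsv"))
            return table

        synergy_rows = []
        vs_ctrl_tables: dict = {}
        all_times = []
        seen = set()
        for t in design.table["time"]:
            if str(t) not in seen:
                seen.add(str(t))
                all_times.append(t)

        for t in all_times:
            roles = _conditions(design, t)
            combo = de(f"combo_vs_ctrl_t{t}", roles["combo"], roles["vehicle"], t)
            a_tab = de(f"A_vs_ctrl_t{t}", roles["A_alone"], roles["vehicle"], t)
            b_tab = de(f"B_vs_ctrl_t{t}", roles["B_alone"], roles["vehicle"], t)
            vs_ctrl_tables[str(t)] = (combo, a_tab, b_tab)
            theoretical, flag = global_synergy(_n_de(combo), _n_de(a_tab), _n_de(b_tab))
            synergy_rows.append(
                {
                    "time": t,
                    "n_deg_combo": _n_de(combo),
                    "n_deg_A": _n_de(a_tab),
                    "n_deg_B": _n_de(b_tab),
                    "n_up_combo": int((combo["call"] == "up").sum()),
                    "n_down_combo": int((combo["call"] == "down").sum()),
                    "theoretical_sum": theoretical,
                    "synergy_flag": bool(flag),
                }
            )

        stage = "sa_degs"
        early, late = config.early_time, config.late_time
        roles_early = _conditions(design, early)
        roles_late = _conditions(design, late)
        sa_sets = {}
        for label, roles in (("early", roles_early), ("late", roles_late)):
            t = early if label == "early" else late
            vs_a = de(f"combo_vs_A_t{t}", roles["combo"], roles["A_alone"], t)
            vs_b = de(f"combo_vs_B_t{t}", roles["combo"], roles["B_alone"], t)
            sa_sets[label] = call_sa_degs(vs_a, vs_b, filter_name=f"sa_deg_t{t}")
            sa_sets[label].write_tsv(out(f"sa_degs_t{t}.tsv"))

        stage = "unique_genes"
        combo, a_tab, b_tab = vs_ctrl_tables[str(early)]
        unique_flags, unique_fraction = classify_unique_genes(
            sa_sets["early"], combo, a_tab, b_tab
        )

        stage = "dose_filter"
        dose_ids = roles_early["combo_by_dose"]
        if len(dose_ids) >= 2:
            deg_by_dose = {}
            for d, cond in dose_ids.items():
                if d == roles_early["top_dose"]:
                    deg_by_dose[d] = deg[f"combo_vs_B_t{early}"]
                    continue
                name = f"combo{d:g}_vs_B_t{early}"
                deg_by_dose[d] = (
                    deg[name] if name in deg else de(name, cond, roles_early["B_alone"], early)
                )
            dose_sig = dose_response_signature(
                deg_by_dose, deg[f"combo_vs_ctrl_t{early}"]
            )
        else:
            dose_sig = None
        if dose_sig is not None:
            dose_sig.write_tsv(out("dose_responsive.tsv"))

        stage = "intersect"
        signature = (
            intersect_signatures(sa_sets["early"], dose_sig)
            if dose_sig is not None
            else sa_sets["early"]
        )
        signature.write_tsv(out("signature.tsv"))

        stage = "persistence"
        sustained = persistence_filter(signature, sa_sets["late"])
        sustained.write_tsv(out("sustained_signature.tsv"))

        # Composition invariant of the filtering cascade.
        assert set(sustained.genes) <= set(signature.genes)
        assert set(signature.genes) <= set(sa_sets["early"].genes)
        if dose_sig is not None:
            assert set(signature.genes) <= set(dose_sig.genes)

        stage = "enrichment"
        enrichment_summary = None
        if config.gmt:
            collection = read_gmt(config.gmt)
            if len(signature):
                records = hypergeom_ora(signature, collection)
                records.to_csv(out("enrichment.tsv"), sep="\t", index=False,
                               lineterminator="\n")
                graph = build_pathway_graph(
                    records,
                    collection,
                    signature,
                    overlap_threshold=config.overlap_threshold,
                    q_threshold=config.enrichment_fdr,
                )
                write_graph_edges_tsv(graph, out("network_edges.tsv"))
                enrichment_summary = {
                    "n_sets": int(len(collection)),
                    "n_enriched": int((records["q_value"] <= config.enrichment_fdr).sum()),
                    "n_graph_nodes": graph.number_of_nodes(),
                    "n_graph_edges": graph.number_of_edges(),
                }

        stage = "report"
        summary = summarize_counts(
            {(n.rsplit("_t", 1)[1], n.rsplit("_t", 1)[0]): tbl for n, tbl in deg.items()}
        )
        summary.to_csv(out("deg_summary.tsv"), sep="\t", index=False, lineterminator="\n")
        report = {
            "version": __version__,
            "config_hash": config.hash(),
            "seed": config.seed,
            "thresholds": {
                "fc": fc,
                "fdr": q,
                "enrichment_fdr": config.enrichment_fdr,
                "overlap": config.overlap_threshold,
                "pseudocount": config.pseudocount,
            },
            "n_genes": int(expr.shape[0]),
            "n_samples": int(expr.shape[1]),
            "deg_counts": {name: _n_de(tbl) for name, tbl in deg.items()},
            "synergy": synergy_rows,
            "sa_deg_counts": {k: len(v) for k, v in sa_sets.items()},
            "unique_fraction_early_sa": unique_fraction,
            "n_dose_responsive": len(dose_sig) if dose_sig is not None else None,
            "n_signature": len(signature),
            "n_sustained": len(sustained),
            "enrichment": enrichment_summary,
        }
        with open(out("report.json"), "w", encoding="utf-8") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
            fh.write("\n")
        return report
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001 - stage provenance on any failure
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
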