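import numpy as np
import pandas as pd
import pytest

import synerseq as ss
from synerseq.diffexpr import Contrast, call_degs


def pooled_call_degs(rpkm, design, test_cond, ref_cond, time, **kw):
    """DEG calling the way the pipeline runs it: error pooled per time point."""
    dtab = design.table
    error_conditions = list(
        dict.fromkeys(dtab.loc[dtab["time"].astype(str) == str(time), "condition_id"])
    )
    contrast = Contrast(f"{test_cond}_vs_{ref_cond}", test_cond, ref_cond)
    return call_degs(rpkm, design, contrast, error_conditions=error_conditions, **kw)


@pytest.fixture(scope="session")
def strong_sim():
    """A small, strongly powered simulation with every gene class planted."""
    config = ss.SimulationConfig(
        n_genes=400,
        seed=3,
        dispersion=0.02,
        frac_null=0.70,
        frac_A_only=0.06,
        frac_B_only=0.06,
        frac_additive=0.06,
        frac_synergistic=0.12,
        interaction_log2fc=2.5,
        frac_persistent=0.4,
    )
    counts, design, lengths, truth = ss.simulate_experiment(config)
    rpkm = ss.apply_single_missing_rule(
        ss.compute_rpkm(counts, lengths, "derive"), design
    )
    return {
        "config": config,
        "counts": counts,
        "design": design,
        "lengths": lengths,
        "truth": truth,
        "rpkm": rpkm,
    }


def make_deg_table(calls: dict, fold_changes: dict | None = None) -> pd.DataFrame:
    """Hand-build a minimal DEG table from {gene: call} (+ optional fc)."""
    genes = list(calls)
    fc = fold_changes or {}
    fc_vals = []
    for g in genes:
        if g in fc:
            fc_vals.append(fc[g])
        elif calls[g] == "up":
            fc_vals.append(3.0)
        elif calls[g] == "down":
            fc_vals.append(-3.0)
        else:
            fc_vals.append(1.1)
    q = [0.01 if calls[g] in ("up", "down") else 0.5 for g in genes]
    return pd.DataFrame(
        {
            "mean_test": 10.0,
            "mean_ref": 5.0,
            "fold_change": fc_vals,
            "p_value": q,
            "q_value": q,
            "call": [calls[g] for g in genes],
        },
        index=pd.Index(genes, name="gene_id"),
    )
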