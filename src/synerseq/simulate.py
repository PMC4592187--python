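"""Negative-binomial count simulator for the two-stressor factorial design.

The generator emulates a study in which cells are dosed with stressor A (a
tumor promoter at several concentrations, 0 = vehicle), optionally exposed
to stressor B (irradiation, on/off), and profiled at several time points
with a fixed number of biological replicates per condition. Genes are
planted in five classes:

``null``
    no treatment effect;
``A_only`` / ``B_only``
    a main effect of one stressor;
``additive``
    both main effects, exactly zero interaction;
``synergistic``
    a pure interaction effect (main effects zero) — expression shifts only
    when both stressors are applied together.

The per-gene mean is log-linear,

    log2 mu[g, s] = baseline[g] + a[g] * f(dose) + b[g] * [B on]
                    + c[g] * f(dose) * [B on] * persist(g, t)

with the scaled-dose link ``f(dose) = dose / max(dose)`` and a persistence
switch that zeroes the interaction at the final time point unless the gene
was planted persistent. Counts are drawn negative-binomial with
``Var = mu + dispersion * mu**2`` (``dispersion`` is the reciprocal of the
NB size parameter; 0 selects Poisson) and scaled by a per-sample
sequencing-depth factor. The matching truth table makes every downstream
filter checkable against a known answer key.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import (
    DesignSheet,
    ExpressionTable,
    read_design_tsv,
    read_expression_tsv,
    read_lengths_tsv,
    write_design_tsv,
    write_expression_tsv,
    write_lengths_tsv,
)

__all__ = [
    "SimulationConfig",
    "SimulationConfigError",
    "simulate_experiment",
    "write_fixture",
    "read_truth_tsv",
    "time_course_config",
    "dose_response_config",
]

CLASS_LABELS = ("null", "A_only", "B_only", "additive", "synergistic")


class SimulationConfigError(ValueError):
    """Raised when a :class:`SimulationConfig` violates its invariants."""


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one simulated factorial experiment.

    Defaults emulate the reference design: 3 biological replicates, time
    points 4/8/24 h, stressor-A doses 0/0.2/0.5/1.0 nM fully crossed with
    the stressor-B flag. ``dispersion`` is the NB overdispersion alpha in
    ``Var = mu + alpha * mu**2`` (reciprocal of the NB size parameter).
    The class fractions leave their complement as null genes.
    """

    n_genes: int = 5000
    n_replicates: int = 3
    times: tuple = (4, 8, 24)
    dosesA: tuple = (0.0, 0.2, 0.5, 1.0)
    baseline_log2_mean_range: tuple = (4.0, 11.0)
    dispersion: float = 0.05
    frac_null: float = 0.82
    frac_A_only: float = 0.05
    frac_B_only: float = 0.05
    frac_additive: float = 0.05
    frac_synergistic: float = 0.03
    effect_log2fc: float = 2.0
    interaction_log2fc: float = 2.0
    frac_persistent: float = 0.3
    library_size_range: tuple = (800_000, 1_200_000)
    gene_length_range: tuple = (300, 10_000)
    missing_replicate_rate: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 1:
            raise SimulationConfigError("n_genes must be >= 1")
        if self.n_replicates < 2:
            raise SimulationConfigError("n_replicates must be >= 2 (ANOVA needs >= 2)")
        if len(self.times) < 1 or len(self.dosesA) < 1:
            raise SimulationConfigError("times and dosesA must be non-empty")
        if list(self.dosesA) != sorted(self.dosesA) or min(self.dosesA) < 0:
            raise SimulationConfigError("dosesA must be non-negative, sorted ascending")
        fracs = (
            self.frac_null,
            self.frac_A_only,
            self.frac_B_only,
            self.frac_additive,
            self.frac_synergistic,
        )
        if any(f < 0 for f in fracs):
            raise SimulationConfigError("class fractions must be non-negative")
        if sum(fracs) > 1 + 1e-9:
            raise SimulationConfigError(f"class fractions sum to {sum(fracs)} > 1")
        for name in ("baseline_log2_mean_range", "library_size_range", "gene_length_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise SimulationConfigError(f"{name}: low {lo} > high {hi}")
        if self.dispersion < 0:
            raise SimulationConfigError("dispersion must be >= 0")
        if not 0 <= self.missing_replicate_rate <= 1:
            raise SimulationConfigError("missing_replicate_rate must be in [0, 1]")
        if not 0 <= self.frac_persistent <= 1:
            raise SimulationConfigError("frac_persistent must be in [0, 1]")
        if self.interaction_log2fc < 0:
            raise SimulationConfigError("interaction_log2fc must be >= 0")


def time_course_config(**overrides) -> SimulationConfig:
    """Config emulating the time-course experiment: vehicle/A/B/A+B at 4, 8, 24 h.

    With 3 replicates this yields 36 samples (2 doses x 2 flags x 3 times x 3).
    """
    base = dict(dosesA=(0.0, 1.0), times=(4, 8, 24))
    base.update(overrides)
    return SimulationConfig(**base)


def dose_response_config(**overrides) -> SimulationConfig:
    """Config emulating the dose-response experiment: dose series at 8 h only."""
    base = dict(dosesA=(0.0, 0.2, 0.5, 1.0), times=(8,))
    base.update(overrides)
    return SimulationConfig(**base)


def _assign_classes(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    n = config.n_genes
    counts = {
        "A_only": int(round(config.frac_A_only * n)),
        "B_only": int(round(config.frac_B_only * n)),
        "additive": int(round(config.frac_additive * n)),
        "synergistic": int(round(config.frac_synergistic * n)),
    }
    if sum(counts.values()) > n:
        raise SimulationConfigError("rounded class counts exceed n_genes")
    labels = np.array(["null"] * n, dtype=object)
    order = rng.permutation(n)
    pos = 0
    for cls, k in counts.items():
        labels[order[pos : pos + k]] = cls
        pos += k
    return labels


def simulate_experiment(
    config: SimulationConfig,
) -> tuple[ExpressionTable, DesignSheet, pd.Series, pd.DataFrame]:
    """Draw one seeded experiment: counts, design, gene lengths and truth table.

    Returns
    -------
    counts : ExpressionTable
        One column per (time x dose x flagB x replicate) cell, minus any
        replicates dropped by ``missing_replicate_rate``.
    design : DesignSheet
        Matching sample sheet.
    lengths : pandas.Series
        Per-gene transcript length in bp.
    truth : pandas.DataFrame
        Per gene: ``class_label``, ``direction`` (+1/-1, 0 for null),
        ``monotone_dose``, ``persistent``, the planted log2 effect sizes
        ``log2_effect_A``, ``log2_effect_B``, ``log2_interaction`` and the
        gene's ``log2_baseline`` expected count.

    Identical configs (including seed) give identical output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    n = config.n_genes
    gene_ids = pd.Index([f"g{i:05d}" for i in range(1, n + 1)], name="gene_id")
    labels = _assign_classes(config, rng)
    direction = np.where(labels == "null", 0, rng.choice([-1, 1], size=n))

    a = np.where(np.isin(labels, ["A_only", "additive"]), direction * config.effect_log2fc, 0.0)
    b = np.where(np.isin(labels, ["B_only", "additive"]), direction * config.effect_log2fc, 0.0)
    c = np.where(labels == "synergistic", direction * config.interaction_log2fc, 0.0)

    syn_idx = np.nonzero(labels == "synergistic")[0]
    persistent = np.zeros(n, dtype=bool)
    if syn_idx.size:
        n_persist = int(round(config.frac_persistent * syn_idx.size))
        persistent[rng.permutation(syn_idx)[:n_persist]] = True
    monotone = np.isin(labels, ["A_only", "additive", "synergistic"])

    baseline = rng.uniform(*config.baseline_log2_mean_range, size=n)
    lengths = pd.Series(
        rng.integers(config.gene_length_range[0], config.gene_length_range[1] + 1, size=n),
        index=gene_ids,
        name="length_bp",
    )

    # Design: full factorial, deterministic sample order.
    rows = []
    for t in config.times:
        for d in config.dosesA:
            for flag in (False, True):
                for rep in range(1, config.n_replicates + 1):
                    rows.append(
                        {
                            "sample_id": f"A{d:g}_B{int(flag)}_t{t}_r{rep}",
                            "doseA": d,
                            "flagB": flag,
                            "time": t,
                            "replicate": rep,
                        }
                    )
    design_df = pd.DataFrame(rows).set_index("sample_id")

    # Whole-sample dropout: each condition may lose one replicate (mirroring a
    # lost library), never going below two replicates.
    if config.missing_replicate_rate > 0 and config.n_replicates > 2:
        keep = np.ones(len(design_df), dtype=bool)
        cond_keys = [
            (t, d, fl)
            for t, d, fl in zip(design_df["time"], design_df["doseA"], design_df["flagB"])
        ]
        seen: dict[tuple, list[int]] = {}
        for i, key in enumerate(cond_keys):
            seen.setdefault(key, []).append(i)
        for key, idxs in seen.items():
            if rng.random() < config.missing_replicate_rate:
                keep[idxs[int(rng.integers(len(idxs)))]] = False
        design_df = design_df.loc[keep]
    design = DesignSheet(design_df)

    max_dose = max(config.dosesA)
    f_dose = np.array(
        [d / max_dose if max_dose > 0 else 0.0 for d in design.table["doseA"]]
    )
    flag = design.table["flagB"].to_numpy().astype(float)
    # Interaction attenuation applies at the final time point of a
    # time-course; a single-time-point experiment has no "late" recovery.
    last_time = config.times[-1] if len(config.times) > 1 else None
    is_last = np.array([t == last_time for t in design.table["time"]], dtype=float)
    # Interaction persistence: 1 at early times; at the final time point only
    # for persistent genes.
    persist_gene = persistent.astype(float)

    log2mu = (
        baseline[:, None]
        + a[:, None] * f_dose[None, :]
        + b[:, None] * flag[None, :]
        + c[:, None]
        * (f_dose * flag)[None, :]
        * ((1 - is_last)[None, :] + is_last[None, :] * persist_gene[:, None])
    )

    lib = rng.integers(
        config.library_size_range[0],
        config.library_size_range[1] + 1,
        size=design.table.shape[0],
    ).astype(float)
    depth = lib / lib.mean()
    mu = np.power(2.0, log2mu) * depth[None, :]

    if config.dispersion <= 1e-12:
        counts = rng.poisson(mu).astype(float)
    else:
        size = 1.0 / config.dispersion  # NB "number of successes" parameter
        p = size / (size + mu)
        counts = rng.negative_binomial(size, p).astype(float)

    counts_table = ExpressionTable(
        pd.DataFrame(counts, index=gene_ids, columns=design.table.index), "counts"
    )
    truth = pd.DataFrame(
        {
            "class_label": labels,
            "direction": direction,
            "monotone_dose": monotone,
            "persistent": persistent,
            "log2_effect_A": a,
            "log2_effect_B": b,
            "log2_interaction": c,
            "log2_baseline": baseline,
        },
        index=gene_ids,
    )
    return counts_table, design, lengths, truth


# ---------------------------------------------------------------------------
# Fixture writing
# ---------------------------------------------------------------------------

FIXTURE_FILES = ("counts.tsv", "design.tsv", "lengths.tsv", "truth.tsv")


def write_fixture(
    counts: ExpressionTable,
    design: DesignSheet,
    lengths: pd.Series,
    truth: pd.DataFrame,
    directory,
    overwrite: bool = False,
) -> dict[str, str]:
    """Write counts/design/lengths/truth as TSVs; returns the file paths.

    Refuses to clobber existing files unless ``overwrite`` is set, and
    refuses to write empty matrices.
    """
    if counts.shape[0] == 0 or counts.shape[1] == 0:
        raise ValueError("refusing to write an empty expression matrix")
    os.makedirs(directory, exist_ok=True)
    paths = {name.split(".")[0]: os.path.join(directory, name) for name in FIXTURE_FILES}
    if not overwrite:
        existing = [p for p in paths.values() if os.path.exists(p)]
        if existing:
            raise FileExistsError(f"fixture files already exist: {existing}")
    write_expression_tsv(counts, paths["counts"])
    write_design_tsv(design, paths["design"])
    write_lengths_tsv(lengths, paths["lengths"])
    out = truth.copy()
    for col in ("monotone_dose", "persistent"):
        out[col] = out[col].astype(int)
    out.to_csv(paths["truth"], sep="\t", index_label="gene_id", lineterminator="\n")
    return paths


def read_truth_tsv(path) -> pd.DataFrame:
    # keep_default_na=False: "null" is a class label, not a missing value
    truth = pd.read_csv(path, sep="\t", index_col="gene_id", keep_default_na=False)
    for col in ("monotone_dose", "persistent"):
        truth[col] = truth[col].astype(bool)
    return truth


def read_fixture(directory) -> tuple[ExpressionTable, DesignSheet, pd.Series, pd.DataFrame]:
    """Read back a fixture directory written by :func:`write_fixture`."""
    counts = read_expression_tsv(os.path.join(directory, "counts.tsv"), "counts")
    design = read_design_tsv(os.path.join(directory, "design.tsv"))
    lengths = read_lengths_tsv(os.path.join(directory, "lengths.tsv"))
    truth = read_truth_tsv(os.path.join(directory, "truth.tsv"))
    return counts, design, lengths, truth
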