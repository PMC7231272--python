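"""Reproducible simulation studies exercising the pipeline end to end.

Each study generates its own synthetic inputs with planted truth (one child
seed per run spawned from a root seed), runs the relevant pipeline stage, and
returns per-run outcomes plus a summary.  The study designs — panel size,
promoter geometry, planting rates, module structure — are the package's
reference operating conditions and are documented in the methods note; tests
and the reproduction script both call these functions so the conditions
cannot drift apart.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .conservation import conservation_matrix
from .enrichment import enrich_report
from .network import build_network, mcode_complexes, select_anchor_cluster
from .qpcr import compare_groups, relative_expression
from .simulate import (ExpressionModule, SimConfig, gen_ct_table,
                       gen_expression_matrix, gen_ortholog_promoters,
                       random_pwm, simulate_enrichment_study, spawn_seeds)

PLANTED_ID = "planted_01"


def default_matrix_panel(n_matrices: int = 20, motif_length: int = 10,
                         panel_seed: int = 101) -> list:
    """One plantable matrix plus ``n_matrices - 1`` random unplanted matrices.

    All matrices are informative 10-mers (peaked Dirichlet columns) so their
    calibrated thresholds land in the discriminating part of the score range.
    """
    panel = [random_pwm(PLANTED_ID, motif_length, seed=panel_seed,
                        total_count=50, concentration=0.2)]
    panel += [random_pwm(f"unplanted_{i:02d}", motif_length,
                         seed=panel_seed + 1000 + i, total_count=50,
                         concentration=0.2) for i in range(n_matrices - 1)]
    return panel


# ---------------------------------------------------------------------------
# TFBS enrichment: recovery and null calibration
# ---------------------------------------------------------------------------

def enrichment_run(seed: int, plant_probability: float = 0.5,
                   reference_plant_probability: float = 0.02,
                   n_targets: int = 200, n_references: int = 5000,
                   promoter_length: int = 1100, n_matrices: int = 20
                   ) -> pd.DataFrame:
    """One full enrichment report: planted targets vs reference promoters."""
    panel = default_matrix_panel(n_matrices)
    cfg = SimConfig(seed=seed, n_target_promoters=n_targets,
                    n_reference_promoters=n_references,
                    promoter_length=promoter_length,
                    plant_probability=plant_probability)
    targets, refs, _, _ = simulate_enrichment_study(
        cfg, panel[0], reference_plant_probability=reference_plant_probability)
    return enrich_report({"cluster": targets.ids}, panel, targets, refs)


@dataclass
class EnrichmentStudy:
    n_runs: int
    planted_called: int          # runs where the planted matrix is significant
    false_calls: int             # significant unplanted (matrix, run) pairs
    unplanted_tests: int

    @property
    def recovery_rate(self) -> float:
        return self.planted_called / self.n_runs

    @property
    def false_call_rate(self) -> float:
        return self.false_calls / self.unplanted_tests


def enrichment_recovery_study(n_runs: int = 100, seed: int = 0, **kwargs
                              ) -> EnrichmentStudy:
    """Planted-motif recovery: targets planted at 0.5, references at 0.02."""
    planted = falses = unplanted = 0
    for s in spawn_seeds(seed, n_runs):
        rep = enrichment_run(s, **kwargs)
        is_planted = rep["matrix_id"] == PLANTED_ID
        planted += int(rep.loc[is_planted, "significant"].any())
        falses += int(rep.loc[~is_planted, "significant"].sum())
        unplanted += int((~is_planted).sum())
    return EnrichmentStudy(n_runs, planted, falses, unplanted)


def enrichment_null_study(n_runs: int = 200, seed: int = 0,
                          plant_probability: float = 0.02,
                          n_references: int = 1000, **kwargs) -> EnrichmentStudy:
    """Null calibration: the motif planted at the same rate in both sets.

    The motif occurs at its genomic reference rate (0.02, the recovery
    study's reference rate) in target and reference promoters alike — the
    cluster is not special.  The full pipeline (whole matrix panel,
    per-cluster FDR) runs each time; the outcome is how often the
    equally-planted matrix is still called significant.
    """
    planted = falses = unplanted = 0
    for s in spawn_seeds(seed, n_runs):
        rep = enrichment_run(s, plant_probability=plant_probability,
                             reference_plant_probability=plant_probability,
                             n_references=n_references, **kwargs)
        is_planted = rep["matrix_id"] == PLANTED_ID
        planted += int(rep.loc[is_planted, "significant"].any())
        falses += int(rep.loc[~is_planted, "significant"].sum())
        unplanted += int((~is_planted).sum())
    return EnrichmentStudy(n_runs, planted, falses, unplanted)


# ---------------------------------------------------------------------------
# Co-expression module recovery
# ---------------------------------------------------------------------------

def module_recovery_run(seed: int, module_size: int = 20, n_background: int = 20,
                        n_samples: int = 12, noise_sd: float = 0.5,
                        min_similarity: float = 0.7) -> tuple[float, float, bool]:
    """Plant two correlated gene modules, recover them with MCODE.

    The module expression programs are orthogonal balanced condition
    contrasts (one stress-vs-control block contrast and one interleaved
    contrast), mirroring the condition structure of the stress/infection
    expression series this pipeline targets.  The +-1 programs have unit
    variance across samples, so with ``noise_sd = 0.5`` the within-module
    correlation is 1 / (1 + 0.25) = 0.8.  Returns the Jaccard index of each
    recovered module against truth and whether the anchor gene (first gene of
    module 1) maps back to its own module.
    """
    if n_samples % 4:
        raise ValueError("n_samples must be a multiple of 4 for balanced contrasts")
    conds = [f"c{j}" for j in range(n_samples)]
    half, quarter = n_samples // 2, n_samples // 4
    e1 = np.array([1.0] * half + [-1.0] * half)
    e2 = np.array(([1.0] * quarter + [-1.0] * quarter) * 2)
    mods = [ExpressionModule(genes=tuple(range(0, module_size)),
                             effects=dict(zip(conds, e1.tolist()))),
            ExpressionModule(genes=tuple(range(module_size, 2 * module_size)),
                             effects=dict(zip(conds, e2.tolist())))]
    expr = gen_expression_matrix(2 * module_size + n_background, conds, mods,
                                 noise_sd=noise_sd, seed=seed)
    graph = build_network(expr, min_similarity=min_similarity)
    complexes = mcode_complexes(graph)
    truths = [set(expr.index[:module_size]),
              set(expr.index[module_size:2 * module_size])]
    jac = []
    for truth in truths:
        jac.append(max((len(truth & set(c.members)) / len(truth | set(c.members))
                        for c in complexes), default=0.0))
    anchor = expr.index[0]
    acx = select_anchor_cluster(complexes, anchor)
    anchor_ok = (acx is not None and
                 len(truths[0] & set(acx.members)) / len(truths[0] | set(acx.members)) >= 0.8)
    return jac[0], jac[1], anchor_ok


def module_recovery_study(n_runs: int = 100, seed: int = 0, **kwargs
                          ) -> tuple[float, float]:
    """Fractions of runs with both Jaccard >= 0.8 and with the anchor recovered."""
    both = anchors = 0
    for s in spawn_seeds(seed, n_runs):
        j1, j2, aok = module_recovery_run(s, **kwargs)
        both += int(min(j1, j2) >= 0.8)
        anchors += int(aok)
    return both / n_runs, anchors / n_runs


# ---------------------------------------------------------------------------
# Cross-species conservation recovery
# ---------------------------------------------------------------------------

SPECIES_7 = ["melanogaster", "simulans", "sechellia", "yakuba", "erecta",
             "ananassae", "virilis"]


def conservation_recovery_run(seed: int, species: list[str] | None = None
                              ) -> tuple[bool, bool, bool]:
    """Plant an all-species motif and a three-species motif; recover the script.

    Emulates a conserved JNK-pathway motif present in every ortholog promoter
    next to a lineage-restricted STAT-like motif confined to a three-species
    clade.  Returns (presence matrix equals script, all-species motif
    positionally conserved, restricted motif not conserved-in-all).
    """
    species = species or SPECIES_7
    s1, s2 = spawn_seeds(seed, 2)
    pwm_all = random_pwm("kay_like", 12, seed=s1, total_count=200, concentration=0.1)
    pwm_clade = random_pwm("stat_like", 12, seed=s2, total_count=200, concentration=0.1)
    thresholds = {p.matrix_id: 0.8 * p.max_score for p in (pwm_all, pwm_clade)}
    block, truth, _ = gen_ortholog_promoters(
        species, [pwm_all, pwm_clade],
        presence={"kay_like": species, "stat_like": species[:3]},
        seed=seed, check_thresholds=thresholds)
    report = conservation_matrix(block, [pwm_all, pwm_clade], thresholds)
    return (bool(report.presence.equals(truth)),
            bool(report.conserved_in_all["kay_like"]),
            not report.conserved_in_all["stat_like"])


def conservation_recovery_study(n_runs: int = 50, seed: int = 0) -> float:
    """Fraction of runs recovering the scripted gain/loss pattern exactly."""
    ok = 0
    for s in spawn_seeds(seed, n_runs):
        match, all_cons, clade_ok = conservation_recovery_run(s)
        ok += int(match and all_cons and clade_ok)
    return ok / n_runs


# ---------------------------------------------------------------------------
# qPCR power
# ---------------------------------------------------------------------------

def qpcr_power_study(n_runs: int = 200, seed: int = 0, fold_change: float = 4.0,
                     ct_noise_sd: float = 0.2, n_replicates: int = 6,
                     alpha: float = 0.01) -> float:
    """Fraction of runs detecting a planted fold change (Mann-Whitney, p < alpha)."""
    detected = 0
    refs = ["ref_a", "ref_b", "ref_c"]
    for s in spawn_seeds(seed, n_runs):
        ct = gen_ct_table(["target"] + refs, ["stress", "control"],
                          {"target": {"stress": fold_change, "control": 1.0}},
                          ct_noise_sd=ct_noise_sd, n_replicates=n_replicates,
                          seed=s, references=refs)
        rel = relative_expression(ct, ["target"], refs)
        cmp_ = compare_groups(rel, "target", "stress", "control", alpha=alpha)
        detected += int(cmp_.significant)
    return detected / n_runs
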