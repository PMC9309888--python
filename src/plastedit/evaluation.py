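"""Seeded recovery and power experiments over the synthetic generator.

These drive the package end to end — generate data with planted truth,
run the corresponding analysis, score the result — and are shared by the
test suite and the acceptance script.
"""

from __future__ import annotations

import numpy as np

from .editing import call_base_conversions
from .phylo import SubstitutionModel, Tree5, optimize_branch_lengths, run_category_contrast
from .simulate import (
    AlignmentSpec,
    SimulationConfig,
    simulate_alignment,
    simulate_genome,
    simulate_pileup,
    simulate_protein_set,
)


def edit_recovery(
    cfg_template: SimulationConfig, n_seeds: int, base_seed: int
) -> dict:
    """Sensitivity/precision of the edit caller on planted conversions.

    Each seed regenerates genome and pileup; a planted site counts as
    recovered when called at the right position with the right conversion.
    """
    seeds = [
        int(s.generate_state(1)[0] % (2**31))
        for s in np.random.SeedSequence(base_seed).spawn(n_seeds)
    ]
    tp = fn = fp = 0
    for seed in seeds:
        cfg = SimulationConfig(**{**cfg_template.__dict__, "seed": seed})
        genome, ann, truth = simulate_genome(cfg)
        pileup, truth = simulate_pileup(genome, ann, cfg, truth)
        called = {
            (s.position, s.conversion)
            for s in call_base_conversions(pileup, genome, ann)
        }
        planted = {(p, c) for p, c, _ in truth.edits}
        tp += len(called & planted)
        fn += len(planted - called)
        fp += len(called - planted)
    return {
        "sensitivity": tp / (tp + fn) if tp + fn else float("nan"),
        "precision": tp / (tp + fp) if tp + fp else float("nan"),
        "n_planted": tp + fn,
        "n_false_positive": fp,
        "n_seeds": n_seeds,
    }


def branch_recovery(
    tree: Tree5,
    model: SubstitutionModel,
    n_sites: int,
    n_replicates: int,
    base_seed: int,
    rel_tol: float = 0.10,
) -> dict:
    """Fraction of replicates recovering every branch within ``rel_tol``."""
    seeds = [
        int(s.generate_state(1)[0] % (2**31))
        for s in np.random.SeedSequence(base_seed).spawn(n_replicates)
    ]
    ok = 0
    rel_errors = []
    for seed in seeds:
        aln = simulate_alignment(tree, model, n_sites, seed=seed)
        fit, _ = optimize_branch_lengths(aln, model, tree.focal_taxon)
        rel = np.abs(fit.branch_lengths - tree.branch_lengths) / tree.branch_lengths
        rel_errors.append(rel)
        ok += bool(np.all(rel < rel_tol))
    return {
        "fraction_within_tol": ok / n_replicates,
        "mean_relative_error": float(np.mean(rel_errors)),
        "n_replicates": n_replicates,
        "n_sites": n_sites,
    }


def contrast_power(
    spec: AlignmentSpec,
    model: SubstitutionModel,
    n_replicates: int,
    alpha: float,
    base_seed: int,
    focal: str = "peDino",
) -> dict:
    """Rejection rate of the category contrast over seeded replicates."""
    seeds = [
        int(s.generate_state(1)[0] % (2**31))
        for s in np.random.SeedSequence(base_seed).spawn(n_replicates)
    ]
    rejections = 0
    pvals = []
    for seed in seeds:
        alns, cats, _ = simulate_protein_set(spec, model, seed=seed)
        res = run_category_contrast(alns, cats, model, focal)
        pvals.append(res.p_two_sided)
        rejections += res.p_two_sided < alpha
    return {
        "rejection_rate": rejections / n_replicates,
        "median_p": float(np.median(pvals)),
        "alpha": alpha,
        "n_replicates": n_replicates,
    }
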