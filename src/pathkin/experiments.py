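"""Reusable simulation experiments: calibration, recovery, power, ranking.

These drive both the acceptance checks and the command-line reproduction
script.  Every experiment takes one integer seed and is fully deterministic
given it; replicate loops share one pedigree (fixed family structure) and
redraw genotypes and phenotypes each time.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .diagnostics import kinship_deviation
from .kernel import estimate_psgrm, make_kernel
from .pedigree import expected_kinship
from .simulate import (
    SimConfig,
    draw_founder_mafs,
    gene_drop,
    simulate_pedigree,
    simulate_phenotype,
)
from .vc import fit_null, fit_pathway, lrt_mixture_p

__all__ = [
    "lrt_replicates",
    "deviation_trend",
    "power_curve",
    "ranking_replicates",
]

# ~600 individuals: 20 families x 3 generations with sibships of 3-6
DEFAULT_FAMILIES = 20
DEFAULT_SIBSHIP = (3, 6)


def _pedigree_setup(rng: np.random.Generator, n_families: int = DEFAULT_FAMILIES):
    cfg = SimConfig(
        n_families=n_families, generations=3, sibship=DEFAULT_SIBSHIP, seed=0
    )
    ped = simulate_pedigree(cfg, rng)
    phi = expected_kinship(ped)
    k_phi = 2.0 * phi.values
    eig = np.linalg.eigh(k_phi)
    return ped, phi, k_phi, eig


def _maf_config(n_variants: int) -> SimConfig:
    # MAF spectrum across rare and common variants, n_variants total
    return SimConfig(
        n_pathways=1, genes_per_pathway=1, variants_per_gene=n_variants, seed=0
    )


def lrt_replicates(
    n_reps: int,
    seed: int,
    h2gp: float = 0.0,
    h2r: float = 0.3,
    n_variants: int = 2000,
    n_families: int = DEFAULT_FAMILIES,
    n_causal: int = 200,
    min_pair_variants: int = 50,
) -> pd.DataFrame:
    """Replicated single-pathway LRTs on gene-dropped data.

    Each replicate gene-drops ``n_variants`` pathway variants, simulates a
    trait with the requested variance fractions (causal variants drawn from
    the pathway when ``h2gp > 0``), estimates the PSGRM, and runs the
    null/pathway fits and the boundary LRT.  Returns one row per replicate
    with columns T, p, h2r_null, h2r_hat, h2gp_hat, n.
    """
    rng = np.random.default_rng(seed)
    ped, phi, k_phi, eig = _pedigree_setup(rng, n_families)
    sim_cfg = SimConfig(
        n_families=n_families, generations=3, sibship=DEFAULT_SIBSHIP,
        h2r=h2r, h2gp=h2gp, causal_pathway=0 if h2gp > 0 else None,
        n_causal=n_causal, seed=0,
    )
    maf_cfg = _maf_config(n_variants)
    rows = []
    for _ in range(n_reps):
        mafs = draw_founder_mafs(maf_cfg, rng)
        g, _ = gene_drop(ped, mafs, rng)
        pheno, _ = simulate_phenotype(ped, g, sim_cfg, rng, phi_kernel=k_phi)
        ids, y, X, names = pheno.design()
        e = estimate_psgrm(g, min_pair_variants=min_pair_variants, fallback=phi)
        e_kernel, _ = make_kernel(e)
        f0 = fit_null(y, X, k_phi, beta_names=names, phi_eig=eig)
        f1 = fit_pathway(y, X, k_phi, e_kernel, beta_names=names, null_fit=f0)
        t, p = lrt_mixture_p(f0.loglik, f1.loglik)
        rows.append(
            {
                "T": t, "p": p, "h2r_null": f0.h2r, "h2r_hat": f1.h2r,
                "h2gp_hat": f1.h2gp, "n": len(y),
            }
        )
    return pd.DataFrame(rows)


def deviation_trend(
    sizes: tuple[int, ...] = (200, 500, 1000, 2000, 3500, 5000),
    seed: int = 0,
    n_families: int = 8,
) -> pd.DataFrame:
    """Mean |PSGRM - pedigree kinship| as the pathway variant count grows."""
    rng = np.random.default_rng(seed)
    ped, phi, _, _ = _pedigree_setup(rng, n_families)
    rows = []
    for m in sizes:
        mafs = draw_founder_mafs(_maf_config(m), rng)
        g, _ = gene_drop(ped, mafs, rng)
        e = estimate_psgrm(g, fallback=phi)
        s = kinship_deviation(e, phi.align(e.ids), n_variants=m)
        all_pairs = (
            s.mean_dev_related * s.n_pairs_related
            + s.mean_dev_unrelated * s.n_pairs_unrelated
        ) / (s.n_pairs_related + s.n_pairs_unrelated)
        rows.append(
            {
                "n_variants": m,
                "mean_dev": all_pairs,
                "mean_dev_related": s.mean_dev_related,
                "mean_dev_unrelated": s.mean_dev_unrelated,
            }
        )
    return pd.DataFrame(rows)


def power_curve(
    h2gps: tuple[float, ...] = (0.0, 0.05, 0.1, 0.2),
    n_reps: int = 50,
    seed: int = 0,
    alpha: float = 0.01,
    n_variants: int = 2000,
) -> pd.DataFrame:
    """Empirical rejection rate of the pathway LRT at each simulated h2gp."""
    rows = []
    for k, h2gp in enumerate(h2gps):
        reps = lrt_replicates(
            n_reps, seed + 1000 * k, h2gp=h2gp, n_variants=n_variants
        )
        rows.append(
            {
                "h2gp": h2gp,
                "power": float((reps["p"] < alpha).mean()),
                "alpha": alpha,
                "n_reps": n_reps,
            }
        )
    return pd.DataFrame(rows)


def ranking_replicates(
    n_reps: int = 50,
    seed: int = 0,
    h2gp: float = 0.15,
    h2r: float = 0.3,
    n_pathways: int = 20,
    genes_per_pathway: int = 4,
    variants_per_gene: int = 25,
    n_causal: int = 60,
    min_pair_variants: int = 50,
) -> pd.DataFrame:
    """Screen ``n_pathways`` pathways per replicate, one carrying the signal.

    The causal pathway is always the first; ranking is by p-value with the
    LRT statistic breaking ties.  Returns per-replicate rows with the rank of
    the causal pathway (1 = first).
    """
    rng = np.random.default_rng(seed)
    ped, phi, k_phi, eig = _pedigree_setup(rng)
    sim_cfg = SimConfig(
        n_families=DEFAULT_FAMILIES, generations=3, sibship=DEFAULT_SIBSHIP,
        n_pathways=n_pathways, genes_per_pathway=genes_per_pathway,
        variants_per_gene=variants_per_gene, h2r=h2r, h2gp=h2gp,
        causal_pathway=0, n_causal=n_causal, seed=0,
    )
    # column blocks per pathway (variants laid out pathway-major)
    block = genes_per_pathway * variants_per_gene
    rows = []
    for _ in range(n_reps):
        mafs = draw_founder_mafs(sim_cfg, rng)
        g, _ = gene_drop(ped, mafs, rng)
        causal_cols = np.arange(block)  # pathway 0 owns the first block
        pheno = _phenotype_on_columns(ped, g, sim_cfg, rng, causal_cols, k_phi)
        ids, y, X, names = pheno.design()
        f0 = fit_null(y, X, k_phi, beta_names=names, phi_eig=eig)
        stats_rows = []
        for pw in range(n_pathways):
            cols = np.arange(pw * block, (pw + 1) * block)
            g_pw = g.take_variants(cols)
            e = estimate_psgrm(
                g_pw, min_pair_variants=min_pair_variants, fallback=phi
            )
            e_kernel, _ = make_kernel(e)
            f1 = fit_pathway(y, X, k_phi, e_kernel, beta_names=names, null_fit=f0)
            t, p = lrt_mixture_p(f0.loglik, f1.loglik)
            stats_rows.append({"pathway": pw, "T": t, "p": p})
        tab = pd.DataFrame(stats_rows).sort_values(
            ["p", "T"], ascending=[True, False], kind="mergesort"
        )
        rank = int(np.flatnonzero(tab["pathway"].to_numpy() == 0)[0]) + 1
        rows.append({"causal_rank": rank, "top_pathway": int(tab.iloc[0]["pathway"])})
    return pd.DataFrame(rows)


def _phenotype_on_columns(ped, g, cfg, rng, causal_cols, k_phi):
    """Phenotype with causal variants restricted to given dosage columns."""
    pheno, _ = simulate_phenotype(
        ped, g, cfg, rng,
        causal_columns=causal_cols if cfg.h2gp > 0 else None,
        phi_kernel=k_phi,
    )
    return pheno
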