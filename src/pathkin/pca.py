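"""Founder-based genetic principal components with projection to relatives.

PCs are computed on founders only (so family structure is not mistaken for
ancestry) from an LD-pruned common-variant subset, then projected to every
genotyped pedigree member through the founder loadings.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .pedigree import Pedigree
from .regions import GenotypeMatrix

logger = logging.getLogger(__name__)

__all__ = ["PCProjection", "ld_prune", "founder_pca", "project"]


def ld_prune(
    g: GenotypeMatrix,
    r2_max: float = 0.1,
    window: int = 100,
    step: int = 25,
    min_maf: float = 0.05,
) -> GenotypeMatrix:
    """Greedy windowed LD pruning on dosage correlations.

    Variants with MAF < ``min_maf`` are excluded up front (pruning on rare
    variants is unstable).  Within each window of ``window`` variants
    (advanced by ``step``), for any remaining pair with squared correlation
    > ``r2_max`` the later variant (by position order) is dropped.
    Deterministic for a given input.
    """
    if not 0 < r2_max <= 1.0:
        raise ValueError(f"r2_max must be in (0, 1], got {r2_max}")
    common = np.flatnonzero(g.maf >= min_maf)
    if common.size == 0:
        raise ValueError(f"no variant with MAF >= {min_maf} to prune")
    g = g.take_variants(common)
    order = np.lexsort((g.variants["pos"].to_numpy(), g.variants["chrom"].to_numpy()))
    d = g.dosages[:, order]
    # mean-impute missing for the correlation computation only
    if np.isnan(d).any():
        col_mean = np.nanmean(d, axis=0)
        nan_r, nan_c = np.where(np.isnan(d))
        d = d.copy()
        d[nan_r, nan_c] = col_mean[nan_c]
    m = d.shape[1]
    keep = np.ones(m, dtype=bool)
    if r2_max < 1.0:
        for w0 in range(0, max(m - 1, 1), step):
            w1 = min(w0 + window, m)
            idx = np.flatnonzero(keep[w0:w1]) + w0
            if idx.size < 2:
                continue
            sub = d[:, idx]
            sd = sub.std(axis=0)
            ok = sd > 0
            sub = (sub[:, ok] - sub[:, ok].mean(axis=0)) / sd[ok]
            idx = idx[ok]
            r = (sub.T @ sub) / sub.shape[0]
            r2 = r * r
            for a in range(len(idx)):
                if not keep[idx[a]]:
                    continue
                hits = np.flatnonzero(r2[a, a + 1:] > r2_max) + a + 1
                keep[idx[hits]] = False
            if w1 == m:
                break
    kept = order[keep]
    return g.take_variants(np.sort(kept))


@dataclasses.dataclass
class PCProjection:
    """Founder PCA result: loadings plus the statistics needed to project."""

    variant_keys: list[tuple]  # (chrom, pos, alt) identifying each variant
    means: np.ndarray  # founder dosage means per variant
    scales: np.ndarray  # founder dosage standard deviations per variant
    loadings: np.ndarray  # variants x k, orthonormal columns
    founder_ids: list[str]
    founder_scores: np.ndarray  # founders x k
    k: int

    def write_scores(self, path: str | Path, ids: Sequence[str], scores: np.ndarray):
        cols = {"iid": list(ids)}
        for j in range(self.k):
            cols[f"pc{j + 1}"] = scores[:, j]
        pd.DataFrame(cols).to_csv(path, sep="\t", index=False)


def _variant_keys(g: GenotypeMatrix) -> list[tuple]:
    return list(
        zip(g.variants["chrom"].astype(str), g.variants["pos"].astype(int),
            g.variants["alt"].astype(str))
    )


def founder_pca(g: GenotypeMatrix, ped: Pedigree, k: int = 5) -> PCProjection:
    """PCA of founder genotypes: center/scale by founder statistics, SVD,
    keep the top ``k`` loading vectors.

    Monomorphic-in-founders variants are dropped.  The sign of each loading
    vector is fixed by forcing its largest-magnitude element positive.
    """
    founder_ids = [i for i in ped.founders if i in set(g.samples)]
    if not founder_ids:
        raise ValueError("no founder has genotypes; cannot anchor the PCA")
    if len(founder_ids) < k + 1:
        raise ValueError(
            f"need >= k+1 = {k + 1} genotyped founders, have {len(founder_ids)}"
        )
    # slice rows directly: keeps the cohort's minor-allele orientation so that
    # projection through the same matrix is consistent
    row_of = {s: r for r, s in enumerate(g.samples)}
    rows = np.array([row_of[i] for i in founder_ids])
    d = g.dosages[rows, :]
    means = np.nanmean(d, axis=0)
    scales = np.nanstd(d, axis=0, ddof=1)
    poly = np.flatnonzero(scales > 0)
    if poly.size < k:
        raise ValueError(
            f"only {poly.size} variant(s) polymorphic in founders; need >= k = {k}"
        )
    if poly.size < d.shape[1]:
        logger.info("dropping %d monomorphic-in-founder variant(s)",
                    d.shape[1] - poly.size)
    d = d[:, poly]
    means = means[poly]
    scales = scales[poly]
    z = (d - means) / scales
    z[np.isnan(z)] = 0.0  # mean imputation after centering
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    k_eff = min(k, len(s))
    loadings = vt[:k_eff].T
    # deterministic sign convention
    for j in range(k_eff):
        i_max = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[i_max, j] < 0:
            loadings[:, j] = -loadings[:, j]
    scores = z @ loadings
    all_keys = _variant_keys(g)
    keys = [all_keys[int(j)] for j in poly]
    return PCProjection(
        variant_keys=keys,
        means=means,
        scales=scales,
        loadings=loadings,
        founder_ids=founder_ids,
        founder_scores=scores,
        k=k_eff,
    )


def project(
    pc: PCProjection, g: GenotypeMatrix, max_missing: float = 0.5
) -> tuple[np.ndarray, np.ndarray]:
    """Project all individuals in ``g`` onto the founder PCs.

    Missing dosages are mean-imputed from founder means (zero after
    centering).  Returns (scores, unreliable flags); individuals missing more
    than ``max_missing`` of the PCA variants are flagged.  Founders reproduce
    their PCA scores exactly.
    """
    key_to_col = {key: j for j, key in enumerate(_variant_keys(g))}
    missing_keys = [key for key in pc.variant_keys if key not in key_to_col]
    if missing_keys:
        raise KeyError(
            f"{len(missing_keys)} PCA variant(s) absent from genotype matrix, "
            f"first: {missing_keys[0]}"
        )
    cols = np.array([key_to_col[key] for key in pc.variant_keys])
    d = g.dosages[:, cols]
    miss = np.isnan(d)
    z = (d - pc.means) / pc.scales
    z[miss] = 0.0
    scores = z @ pc.loadings
    unreliable = miss.mean(axis=1) > max_missing
    return scores, unreliable
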