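"""Empirical pathway-specific kinship (PSGRM) via robust pairwise estimation.

The estimator uses only heterozygote-concordance and opposite-homozygote
counts, so it is invariant to which allele is labelled minor at each variant
and robust to population heterogeneity.  For a pair (i, j) with
N_Aa,Aa = variants where both are heterozygous, N_AA,aa = variants where they
are opposite homozygotes, and N_Aa(i), N_Aa(j) = heterozygote counts of each
individual over the pair's jointly non-missing variants:

  between-family (robust, default):
      phi_hat = 1/2 + [N_Aa,Aa - 2*N_AA,aa - (N_Aa(i) + N_Aa(j))/2]
                / [2 * min(N_Aa(i), N_Aa(j))]
  within-family:
      phi_hat = [N_Aa,Aa - 2*N_AA,aa] / [N_Aa(i) + N_Aa(j)]

Both are exact 0.5 for identical genotype vectors and can be negative for
pairs sharing fewer alleles than random expectation; negatives are retained
(kernel repair is a separate, explicit step).
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np

from .pedigree import KinshipMatrix
from .regions import GenotypeMatrix

logger = logging.getLogger(__name__)

DEFAULT_MIN_PAIR_VARIANTS = 50

__all__ = [
    "PairCounts",
    "pair_counts",
    "robust_kinship",
    "estimate_psgrm",
    "make_kernel",
]


@dataclasses.dataclass
class PairCounts:
    """Sufficient statistics of the robust estimator for all sample pairs.

    All fields are n x n matrices; ``n_het_i[i, j]`` counts heterozygous
    variants of individual i among the (i, j) jointly non-missing variants,
    so it is asymmetric (its transpose is the j count).
    """

    samples: list[str]
    n_het_both: np.ndarray
    n_opp_hom: np.ndarray
    n_het_i: np.ndarray
    n_valid: np.ndarray

    @property
    def n(self) -> int:
        return len(self.samples)


def pair_counts(g: GenotypeMatrix) -> PairCounts:
    """Compute pairwise genotype-concordance counts for all sample pairs.

    Vectorized as indicator-matrix products; float32 accumulation is exact for
    counts below 2**24.
    """
    if g.n_samples < 2 or g.n_variants < 1:
        raise ValueError("pair_counts needs >= 2 samples and >= 1 variant")
    d = g.dosages
    het = (d == 1.0)
    hom0 = (d == 0.0)
    hom2 = (d == 2.0)
    H = het.astype(np.float32)
    A = hom0.astype(np.float32)
    B = hom2.astype(np.float32)
    n_het_both = H @ H.T
    n_opp = A @ B.T
    n_opp = n_opp + n_opp.T
    if np.isnan(d).any():
        M = (~np.isnan(d)).astype(np.float32)
        n_valid = M @ M.T
        n_het_i = H @ M.T
    else:
        m = np.float32(g.n_variants)
        n_valid = np.full((g.n_samples, g.n_samples), m, dtype=np.float32)
        n_het_i = np.broadcast_to(
            H.sum(axis=1)[:, None], n_valid.shape
        ).astype(np.float32)
    return PairCounts(
        samples=list(g.samples),
        n_het_both=np.rint(n_het_both).astype(np.int64),
        n_opp_hom=np.rint(n_opp).astype(np.int64),
        n_het_i=np.rint(n_het_i).astype(np.int64),
        n_valid=np.rint(n_valid).astype(np.int64),
    )


def robust_kinship(
    counts: PairCounts,
    min_pair_variants: int = DEFAULT_MIN_PAIR_VARIANTS,
    fallback: KinshipMatrix | None = None,
    estimator: str = "between",
    diagonal: np.ndarray | float = 0.5,
) -> KinshipMatrix:
    """Estimate the empirical kinship matrix from pairwise counts.

    Pairs with fewer than ``min_pair_variants`` jointly non-missing variants,
    or with no heterozygous variant in either member, are unestimable: they
    take the theoretical kinship from ``fallback`` when given, else 0
    (logged).  The diagonal is not defined by the pairwise estimator and is
    set to ``diagonal`` (0.5 = non-inbred convention; an array allows
    empirical inbreeding).  Raises when every off-diagonal pair is
    unestimable.
    """
    if estimator not in ("between", "within"):
        raise ValueError(f"unknown estimator {estimator!r}")
    n = counts.n
    het_i = counts.n_het_i.astype(float)
    het_j = het_i.T
    num = counts.n_het_both - 2.0 * counts.n_opp_hom
    with np.errstate(divide="ignore", invalid="ignore"):
        if estimator == "between":
            denom = 2.0 * np.minimum(het_i, het_j)
            phi = 0.5 + (num - 0.5 * (het_i + het_j)) / denom
        else:
            denom = het_i + het_j
            phi = num / denom
    estimable = (counts.n_valid >= min_pair_variants) & (denom > 0)
    np.fill_diagonal(estimable, True)
    off = ~estimable
    np.fill_diagonal(off, False)
    n_bad = int(off.sum()) // 2
    if n_bad:
        if n_bad * 2 == n * (n - 1):
            raise ValueError(
                "no estimable pair: use a larger pathway or lower missingness "
                f"(min_pair_variants={min_pair_variants})"
            )
        if fallback is not None:
            fb = fallback.align(counts.samples).values
            phi[off] = fb[off]
            logger.info(
                "%d pair(s) below %d informative variants; imputed theoretical "
                "kinship",
                n_bad,
                min_pair_variants,
            )
        else:
            phi[off] = 0.0
            logger.warning(
                "%d pair(s) below %d informative variants and no theoretical "
                "fallback given; set to 0",
                n_bad,
                min_pair_variants,
            )
    diag = np.full(n, diagonal, dtype=float) if np.isscalar(diagonal) else np.asarray(
        diagonal, dtype=float
    )
    phi[np.diag_indices(n)] = diag
    phi = 0.5 * (phi + phi.T)  # symmetrize away float asymmetry
    return KinshipMatrix(
        list(counts.samples), phi, kind="empirical", counts=counts.n_valid
    )


def empirical_inbreeding_diagonal(g: GenotypeMatrix) -> np.ndarray:
    """Diagonal 0.5*(1+f) with f from observed-vs-expected heterozygosity.

    f_i = 1 - O_het(i) / E_het(i), with E_het(i) = sum over i's non-missing
    variants of 2*p*(1-p); negative f is clipped at 0.
    """
    p = np.where(np.isnan(g.maf), 0.0, g.maf)
    exp_het = 2.0 * p * (1.0 - p)
    obs = (g.dosages == 1.0).astype(float)
    mask = ~np.isnan(g.dosages)
    e = mask @ exp_het
    o = obs.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = 1.0 - o / e
    f = np.clip(np.where(np.isfinite(f), f, 0.0), 0.0, 1.0)
    return 0.5 * (1.0 + f)


def estimate_psgrm(
    g: GenotypeMatrix,
    min_pair_variants: int = DEFAULT_MIN_PAIR_VARIANTS,
    fallback: KinshipMatrix | None = None,
    empirical_inbreeding: bool = False,
) -> KinshipMatrix:
    """Convenience wrapper: counts then robust kinship on one genotype matrix."""
    counts = pair_counts(g)
    diagonal = empirical_inbreeding_diagonal(g) if empirical_inbreeding else 0.5
    return robust_kinship(
        counts, min_pair_variants=min_pair_variants, fallback=fallback,
        diagonal=diagonal,
    )


def make_kernel(
    e: KinshipMatrix, mode: str = "bend"
) -> tuple[np.ndarray, float]:
    """Turn an empirical kinship matrix into the PSD fitting kernel 2E.

    Modes: ``bend`` (default) eigendecomposes 2E, floors eigenvalues at 0,
    reconstructs and restores the original diagonal scale; ``clip`` first sets
    negative off-diagonal kinships to 0, then bends; ``raw`` returns 2E
    unmodified.  Returns (kernel, repair delta) where the delta is the
    Frobenius norm of the change.
    """
    if mode not in ("bend", "clip", "raw"):
        raise ValueError(f"unknown kernel mode {mode!r}")
    k = 2.0 * np.asarray(e.values, dtype=float)
    if not np.allclose(k, k.T, atol=1e-8):
        raise ValueError("kernel input must be symmetric")
    if mode == "raw":
        return k, 0.0
    work = k.copy()
    if mode == "clip":
        off = ~np.eye(len(work), dtype=bool)
        work[off & (work < 0)] = 0.0
    w, v = np.linalg.eigh(0.5 * (work + work.T))
    if w.min() >= -1e-12:
        bent = work
    else:
        bent = (v * np.maximum(w, 0.0)) @ v.T
        # restore the diagonal scale lost by flooring
        d_old = np.diag(work).copy()
        d_new = np.diag(bent).copy()
        ok = d_new > 1e-12
        s = np.ones_like(d_new)
        s[ok] = np.sqrt(np.maximum(d_old[ok], 0.0) / d_new[ok])
        bent = bent * np.outer(s, s)
        bent = 0.5 * (bent + bent.T)
    delta = float(np.linalg.norm(bent - k, "fro"))
    return bent, delta
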