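"""Variance-component models on pedigrees and the pathway boundary LRT.

The phenotypic covariance is Omega = sigma2 * (2*Phi*h2r + 2*E*h2gp + I*e2)
with e2 = 1 - h2r - h2gp; fixed effects enter the mean as X*beta.  For fixed
variance fractions, beta (GLS) and sigma2 are profiled out analytically, so
the ML problem reduces to a 1-D (null) or 2-D simplex (pathway) search.  The
pathway variance fraction h2gp is tested on its boundary: the LRT statistic
is referred to a 50:50 mixture of a chi-square with 1 df and a point mass at
zero.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
import scipy.linalg as sla
from scipy import optimize, stats

from .pedigree import KinshipMatrix

logger = logging.getLogger(__name__)

LRT_TOL = 1e-6
BOUNDARY_TOL = 1e-6
_LOG2PI = float(np.log(2.0 * np.pi))

__all__ = [
    "PhenotypeTable",
    "VCFit",
    "PathwayResult",
    "read_phenotypes",
    "fit_null",
    "fit_pathway",
    "lrt_mixture_p",
    "run_pathway_test",
    "screen_pathways",
]


@dataclasses.dataclass
class PhenotypeTable:
    """Trait + covariates, one row per individual (indexed by id).

    Individuals with a missing trait or any requested covariate are dropped
    listwise (logged) when the design is built.
    """

    df: pd.DataFrame  # must contain columns: iid, trait, and covariates

    def __post_init__(self) -> None:
        if "iid" not in self.df.columns or "trait" not in self.df.columns:
            raise ValueError("phenotype table needs 'iid' and 'trait' columns")
        if self.df["iid"].duplicated().any():
            dup = self.df.loc[self.df["iid"].duplicated(), "iid"].tolist()
            raise ValueError(f"duplicate phenotype rows for: {dup}")

    def design(
        self, covariates: tuple[str, ...] = ("sex", "age", "smoke")
    ) -> tuple[list[str], np.ndarray, np.ndarray, list[str]]:
        """Return (ids, y, X, column names); X includes an intercept."""
        cols = ["trait", *covariates]
        missing_cols = [c for c in cols if c not in self.df.columns]
        if missing_cols:
            raise ValueError(f"phenotype table lacks column(s): {missing_cols}")
        sub = self.df[["iid", *cols]].copy()
        ok = sub[cols].notna().all(axis=1)
        if (~ok).any():
            logger.info(
                "dropping %d individual(s) with missing trait/covariates",
                int((~ok).sum()),
            )
        sub = sub[ok]
        ids = sub["iid"].astype(str).tolist()
        y = sub["trait"].to_numpy(dtype=float)
        X = np.column_stack(
            [np.ones(len(sub))] + [sub[c].to_numpy(dtype=float) for c in covariates]
        )
        return ids, y, X, ["intercept", *covariates]


def read_phenotypes(path) -> PhenotypeTable:
    """Read the tab-delimited phenotype/covariate table (header required)."""
    df = pd.read_csv(path, sep="\t")
    df.columns = [c.lower() for c in df.columns]
    return PhenotypeTable(df)


@dataclasses.dataclass
class VCFit:
    """A fitted variance-component model."""

    loglik: float
    sigma2_total: float
    h2r: float
    h2gp: float
    beta: np.ndarray
    beta_names: list[str]
    converged: bool
    n_iter: int
    n: int
    boundary: dict[str, bool] = dataclasses.field(default_factory=dict)

    @property
    def e2(self) -> float:
        return 1.0 - self.h2r - self.h2gp


def _check_design(X: np.ndarray, names: list[str]) -> None:
    if np.linalg.matrix_rank(X) < X.shape[1]:
        # name the columns involved in collinearity for the error message
        r = np.linalg.qr(X, mode="r")
        bad = [names[j] for j in range(X.shape[1]) if abs(r[j, j]) < 1e-8 * X.shape[0]]
        raise ValueError(f"design matrix is singular; collinear covariates: {bad}")


def _profile_rotated(w: np.ndarray, ybar: np.ndarray, Xbar: np.ndarray):
    """Profiled ML log-likelihood in an eigenbasis with variance weights w."""
    n = len(ybar)
    winv = 1.0 / w
    Xw = Xbar * winv[:, None]
    beta = np.linalg.solve(Xbar.T @ Xw, Xw.T @ ybar)
    r = ybar - Xbar @ beta
    q = float(np.dot(r * winv, r))
    sigma2 = q / n
    ll = -0.5 * (n * _LOG2PI + n + n * np.log(sigma2) + float(np.log(w).sum()))
    return ll, beta, sigma2


def fit_null(
    y: np.ndarray,
    X: np.ndarray,
    k_phi: np.ndarray,
    beta_names: list[str] | None = None,
    xatol: float = 1e-9,
    phi_eig: tuple[np.ndarray, np.ndarray] | None = None,
) -> VCFit:
    """ML fit of the polygenic null model Omega = sigma2*(2*Phi*h2r + I*e2).

    ``k_phi`` is the kernel 2*Phi (must be PSD).  The kernel is
    eigendecomposed once, making each likelihood evaluation O(n * p); a
    precomputed ``phi_eig = (eigenvalues, eigenvectors)`` may be supplied when
    fitting many traits against one pedigree.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n = len(y)
    names = beta_names or [f"b{j}" for j in range(X.shape[1])]
    _check_design(X, names)
    lam, U = phi_eig if phi_eig is not None else np.linalg.eigh(
        np.asarray(k_phi, dtype=float)
    )
    if lam.min() < -1e-8 * max(1.0, lam.max()):
        raise ValueError(
            "kernel 2*Phi is not positive semidefinite; repair with make_kernel"
        )
    lam = np.maximum(lam, 0.0)
    ybar = U.T @ y
    Xbar = U.T @ X

    def nll(h2r: float) -> float:
        w = h2r * lam + (1.0 - h2r)
        if w.min() <= 0:
            return np.inf
        return -_profile_rotated(w, ybar, Xbar)[0]

    res = optimize.minimize_scalar(
        nll, bounds=(0.0, 1.0 - 1e-9), method="bounded",
        options={"xatol": xatol},
    )
    # the bounded Brent never lands exactly on the boundary; compare explicitly
    candidates = [(nll(0.0), 0.0), (res.fun, float(res.x))]
    best_nll, h2r = min(candidates, key=lambda t: t[0])
    w = h2r * lam + (1.0 - h2r)
    ll, beta, sigma2 = _profile_rotated(w, ybar, Xbar)
    return VCFit(
        loglik=ll,
        sigma2_total=sigma2,
        h2r=h2r,
        h2gp=0.0,
        beta=beta,
        beta_names=names,
        converged=bool(res.success),
        n_iter=int(res.nfev),
        n=n,
        boundary={"h2r": h2r <= BOUNDARY_TOL or h2r >= 1.0 - BOUNDARY_TOL},
    )


class _TwoKernelNLL:
    """Negative profiled log-likelihood (and gradient) for the pathway model."""

    def __init__(self, y: np.ndarray, X: np.ndarray, kernels: list[np.ndarray]):
        self.y = y
        self.X = X
        self.kernels = kernels
        self.n = len(y)
        self._Xy = np.column_stack([X, y])
        self._vbuf = np.empty((self.n, self.n))
        self._diag = np.diag_indices(self.n)

    def _build_cov(self, theta: np.ndarray) -> np.ndarray:
        e2 = max(1.0 - float(theta.sum()), 1e-9)
        V = self._vbuf
        np.multiply(self.kernels[0], theta[0], out=V)
        for t, K in zip(theta[1:], self.kernels[1:]):
            if t != 0.0:
                V += t * K
        V[self._diag] += e2
        return V

    def components(self, theta: np.ndarray):
        theta = np.clip(np.asarray(theta, dtype=float), 0.0, 1.0)
        V = self._build_cov(theta)
        try:
            c = sla.cholesky(V, lower=True, check_finite=False)
        except np.linalg.LinAlgError:
            return None
        logdet = 2.0 * float(np.log(np.diag(c)).sum())
        Z = sla.cho_solve((c, True), self._Xy, check_finite=False)
        Xv, yv = Z[:, :-1], Z[:, -1]
        beta = np.linalg.solve(self.X.T @ Xv, self.X.T @ yv)
        r = self.y - self.X @ beta
        u = sla.cho_solve((c, True), r, check_finite=False)
        q = float(r @ u)
        ll = -0.5 * (self.n * _LOG2PI + self.n + self.n * np.log(q / self.n) + logdet)
        return c, beta, u, q, ll

    def value(self, theta: np.ndarray) -> float:
        comp = self.components(theta)
        return np.inf if comp is None else -comp[-1]

    def value_grad(self, theta: np.ndarray):
        comp = self.components(theta)
        if comp is None:
            return np.inf, np.zeros(len(theta))
        c, beta, u, q, ll = comp
        # V^{-1} from its Cholesky factor (dpotri)
        vinv, info = sla.lapack.dpotri(c, lower=True)
        if info != 0:
            return -ll, np.zeros(len(theta))
        vinv = vinv + np.tril(vinv, -1).T
        tr_vinv = float(np.trace(vinv))
        utu = float(u @ u)
        grad = np.empty(len(theta))
        for k, K in enumerate(self.kernels):
            # dV/dtheta_k = K - I because e2 = 1 - sum(theta)
            tr_k = float(np.sum(vinv * K)) - tr_vinv
            quad_k = float(u @ (K @ u)) - utu
            dll = -0.5 * tr_k + 0.5 * self.n * quad_k / q
            grad[k] = -dll
        return -ll, grad


def fit_pathway(
    y: np.ndarray,
    X: np.ndarray,
    k_phi: np.ndarray,
    e_kernel: np.ndarray,
    beta_names: list[str] | None = None,
    null_fit: VCFit | None = None,
    starts: list[tuple[float, float]] | None = None,
    ftol: float = 1e-10,
) -> VCFit:
    """ML fit of Omega = sigma2*(2*Phi*h2r + 2*E*h2gp + I*e2).

    Optimizes (h2r, h2gp) on the simplex {both >= 0, sum <= 1} by SLSQP with
    an analytic gradient of the profiled likelihood, multi-started from the
    null solution and two interior points; returns the best fit.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    names = beta_names or [f"b{j}" for j in range(X.shape[1])]
    _check_design(X, names)
    if null_fit is None:
        null_fit = fit_null(y, X, k_phi, beta_names=names)
    hr0 = null_fit.h2r
    if starts is None:
        starts = [(hr0, 0.0), (hr0 / 2.0, hr0 / 2.0), (0.01, 0.01)]
    nllf = _TwoKernelNLL(y, X, [np.asarray(k_phi, float), np.asarray(e_kernel, float)])
    constraints = [
        {
            "type": "ineq",
            "fun": lambda t: 1.0 - t[0] - t[1],
            "jac": lambda t: np.array([-1.0, -1.0]),
        }
    ]
    best = None
    total_iter = 0
    any_converged = False
    for s in starts:
        s = np.clip(np.asarray(s, dtype=float), 0.0, 1.0)
        if s.sum() > 1.0:
            s = s / (s.sum() + 1e-9)
        res = optimize.minimize(
            nllf.value_grad,
            s,
            jac=True,
            method="SLSQP",
            bounds=[(0.0, 1.0), (0.0, 1.0)],
            constraints=constraints,
            options={"ftol": ftol, "maxiter": 200},
        )
        total_iter += int(res.nit)
        any_converged |= bool(res.success)
        if best is None or res.fun < best.fun:
            best = res
    # the null point is always feasible: never report a worse-than-null optimum
    null_point = np.array([hr0, 0.0])
    null_val = nllf.value(null_point)
    if best is None or null_val < best.fun:
        theta, fun = null_point, null_val
        any_converged = True
    else:
        theta, fun = np.clip(best.x, 0.0, 1.0), float(best.fun)
    comp = nllf.components(theta)
    if comp is None:
        raise FloatingPointError("pathway model covariance not factorizable")
    _, beta, _, q, ll = comp
    h2r, h2gp = float(theta[0]), float(theta[1])
    return VCFit(
        loglik=ll,
        sigma2_total=q / len(y),
        h2r=h2r,
        h2gp=h2gp,
        beta=beta,
        beta_names=names,
        converged=any_converged,
        n_iter=total_iter,
        n=len(y),
        boundary={
            "h2r": h2r <= BOUNDARY_TOL,
            "h2gp": h2gp <= BOUNDARY_TOL,
        },
    )


def lrt_mixture_p(
    loglik_null: float, loglik_alt: float, tol: float = LRT_TOL
) -> tuple[float, float]:
    """Boundary LRT: T = max(0, 2*(ll_alt - ll_null)); p from the 50:50
    mixture of chi2(1) and a point mass at zero (p = 1 at T = 0)."""
    if np.isnan(loglik_null) or np.isnan(loglik_alt):
        raise ValueError("NaN log-likelihood passed to lrt_mixture_p")
    t_raw = 2.0 * (loglik_alt - loglik_null)
    if t_raw < -tol:
        raise ValueError(
            f"alternative log-likelihood below null by {-t_raw:.3g}: refit "
            "the alternative from the null solution"
        )
    t = max(0.0, t_raw)
    if t <= tol:
        return 0.0, 1.0
    return t, float(0.5 * stats.chi2.sf(t, df=1))


def run_pathway_test(
    y: np.ndarray,
    X: np.ndarray,
    k_phi: np.ndarray,
    e_kernel: np.ndarray,
    null_fit: VCFit | None = None,
    beta_names: list[str] | None = None,
) -> tuple[VCFit, VCFit, float, float]:
    """Fit null (reused if given) and pathway models, return both plus (T, p)."""
    if null_fit is None:
        null_fit = fit_null(y, X, k_phi, beta_names=beta_names)
    alt = fit_pathway(
        y, X, k_phi, e_kernel, beta_names=beta_names, null_fit=null_fit
    )
    t, p = lrt_mixture_p(null_fit.loglik, alt.loglik)
    return null_fit, alt, t, p


@dataclasses.dataclass
class PathwayResult:
    pathway: str
    n_genes: int
    n_variants: int
    status: str  # ok | no_genes | no_variants | unestimable | nonconverged | error
    null_fit: VCFit | None = None
    alt_fit: VCFit | None = None
    lrt: float = np.nan
    p: float = np.nan
    repair_delta: float = np.nan


RESULT_COLUMNS = [
    "pathway", "n_genes", "n_variants", "h2r_null", "h2r_alt", "h2gp",
    "loglik_null", "loglik_alt", "lrt", "p", "p_bh", "status",
]


def results_table(results: list[PathwayResult]) -> pd.DataFrame:
    """Tabulate pathway results, sorted by p, with a BH-adjusted column."""
    rows = []
    for r in results:
        rows.append(
            {
                "pathway": r.pathway,
                "n_genes": r.n_genes,
                "n_variants": r.n_variants,
                "h2r_null": r.null_fit.h2r if r.null_fit else np.nan,
                "h2r_alt": r.alt_fit.h2r if r.alt_fit else np.nan,
                "h2gp": r.alt_fit.h2gp if r.alt_fit else np.nan,
                "loglik_null": r.null_fit.loglik if r.null_fit else np.nan,
                "loglik_alt": r.alt_fit.loglik if r.alt_fit else np.nan,
                "lrt": r.lrt,
                "p": r.p,
                "status": r.status,
            }
        )
    df = pd.DataFrame(rows, columns=[c for c in RESULT_COLUMNS if c != "p_bh"])
    df["p_bh"] = np.nan
    ok = df["p"].notna()
    if ok.any():
        from statsmodels.stats.multitest import multipletests

        df.loc[ok, "p_bh"] = multipletests(df.loc[ok, "p"], method="fdr_bh")[1]
    df = df.sort_values(["p", "pathway"], na_position="last", kind="mergesort")
    return df[RESULT_COLUMNS].reset_index(drop=True)


def screen_pathways(
    *,
    ped,
    phenotypes: PhenotypeTable,
    gene_sets: list[tuple[str, list[str]]],
    gene_models,
    genotypes=None,
    vcf_path=None,
    flank: int = 5000,
    max_maf: float | None = None,
    min_pair_variants: int = 50,
    kernel_mode: str = "bend",
    covariates: tuple[str, ...] = ("sex", "age", "smoke"),
    pc_scores: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, list[PathwayResult]]:
    """Run the whole screen: regions -> genotypes -> PSGRM -> kernel -> LRT.

    Exactly one of ``genotypes`` (an in-memory GenotypeMatrix covering all
    variants) or ``vcf_path`` must be given.  Per-pathway failures are
    isolated into status codes; the null model is fitted once and reused.
    """
    from . import kernel as kr
    from . import regions as rg
    from .pedigree import expected_kinship

    if (genotypes is None) == (vcf_path is None):
        raise ValueError("provide exactly one of genotypes= or vcf_path=")

    pheno = phenotypes
    if pc_scores is not None:
        pc_cols = [c for c in pc_scores.columns if c.lower().startswith("pc")]
        merged = pheno.df.merge(
            pc_scores.rename(columns={pc_scores.columns[0]: "iid"}),
            on="iid",
            how="left",
        )
        pheno = PhenotypeTable(merged)
        covariates = tuple(covariates) + tuple(pc_cols)

    ids, y, X, names = pheno.design(covariates)
    in_ped = [i for i in ids if i in ped]
    dropped = sorted(set(ids) - set(in_ped))
    if dropped:
        logger.warning("%d phenotyped individual(s) not in pedigree: %s",
                       len(dropped), ", ".join(dropped[:10]))
        keep = [k for k, i in enumerate(ids) if i in ped]
        ids = [ids[k] for k in keep]
        y, X = y[keep], X[keep]
    phi = expected_kinship(ped).align(ids)
    k_phi = 2.0 * phi.values
    null_fit = fit_null(y, X, k_phi, beta_names=names)

    results: list[PathwayResult] = []
    for pw_name, genes in gene_sets:
        try:
            try:
                regset = rg.build_regions(genes, gene_models, flank=flank, name=pw_name)
            except rg.RegionError:
                results.append(PathwayResult(pw_name, 0, 0, "no_genes"))
                continue
            if vcf_path is not None:
                g = rg.extract_genotypes(vcf_path, regset, samples=ids)
            else:
                g = rg.subset_by_regions(genotypes, regset).take_samples(ids)
            if max_maf is not None and max_maf < 0.5 and not g.is_empty:
                g = rg.maf_filter(g, max_maf)
            if g.is_empty:
                results.append(
                    PathwayResult(pw_name, regset.n_genes, 0, "no_variants")
                )
                continue
            try:
                e = kr.estimate_psgrm(
                    g, min_pair_variants=min_pair_variants, fallback=phi
                )
            except ValueError:
                results.append(
                    PathwayResult(pw_name, regset.n_genes, g.n_variants, "unestimable")
                )
                continue
            e_kernel, delta = kr.make_kernel(e, mode=kernel_mode)
            alt = fit_pathway(
                y, X, k_phi, e_kernel, beta_names=names, null_fit=null_fit
            )
            if not alt.converged:
                results.append(
                    PathwayResult(
                        pw_name, regset.n_genes, g.n_variants, "nonconverged",
                        null_fit=null_fit, alt_fit=alt, repair_delta=delta,
                    )
                )
                continue
            t, p = lrt_mixture_p(null_fit.loglik, alt.loglik)
            results.append(
                PathwayResult(
                    pw_name, regset.n_genes, g.n_variants, "ok",
                    null_fit=null_fit, alt_fit=alt, lrt=t, p=p, repair_delta=delta,
                )
            )
        except Exception:  # per-pathway isolation: never abort the screen
            logger.exception("pathway %s failed", pw_name)
            results.append(PathwayResult(pw_name, 0, 0, "error"))
    return results_table(results), results
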