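"""Evaluation artifacts: kinship-deviation summaries and QQ/inflation stats."""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .pedigree import KinshipMatrix

CHI2_1_MEDIAN = float(stats.chi2.ppf(0.5, df=1))  # 0.4549364...

__all__ = ["DeviationSummary", "QQReport", "kinship_deviation", "genomic_inflation"]


@dataclasses.dataclass
class DeviationSummary:
    """Mean |empirical - theoretical| kinship, stratified by pedigree
    relatedness (related: phi > 0, i.e. same family; unrelated: phi = 0)."""

    pathway: str
    n_variants: int
    mean_dev_related: float
    mean_dev_unrelated: float
    n_pairs_related: int
    n_pairs_unrelated: int
    n_pairs_excluded: int  # unestimable pairs left out of both strata

    def to_row(self) -> dict:
        return dataclasses.asdict(self)


def kinship_deviation(
    e: KinshipMatrix,
    phi: KinshipMatrix,
    pathway: str = "",
    n_variants: int = 0,
    min_pair_variants: int = 0,
) -> DeviationSummary:
    """Compare an empirical kinship matrix against the pedigree expectation.

    Both matrices must cover the same samples in the same order.  Pairs whose
    supporting-variant count (when the empirical matrix carries counts) is
    below ``min_pair_variants`` are excluded and counted.
    """
    if e.ids != phi.ids:
        raise ValueError("sample sets/order differ between empirical and "
                         "theoretical kinship matrices")
    n = e.n
    iu = np.triu_indices(n, k=1)
    dev = np.abs(e.values - phi.values)[iu]
    related = phi.values[iu] > 0
    if e.counts is not None and min_pair_variants > 0:
        estimable = e.counts[iu] >= min_pair_variants
    else:
        estimable = np.ones(dev.shape, dtype=bool)
    rel = related & estimable
    unrel = (~related) & estimable
    return DeviationSummary(
        pathway=pathway,
        n_variants=n_variants,
        mean_dev_related=float(dev[rel].mean()) if rel.any() else np.nan,
        mean_dev_unrelated=float(dev[unrel].mean()) if unrel.any() else np.nan,
        n_pairs_related=int(rel.sum()),
        n_pairs_unrelated=int(unrel.sum()),
        n_pairs_excluded=int((~estimable).sum()),
    )


def deviation_table(summaries: list[DeviationSummary]) -> pd.DataFrame:
    return pd.DataFrame([s.to_row() for s in summaries])


@dataclasses.dataclass
class QQReport:
    observed: np.ndarray  # sorted ascending
    expected: np.ndarray  # uniform order statistics i/(m+1)
    lam: float

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# lambda = {self.lam:.6g}\n")
            fh.write("# lambda computed on the chi2(1) quantile scale; under the\n")
            fh.write("# boundary-mixture null (mass at p = 1) lambda < 1 is expected\n")
            fh.write("expected\tobserved\n")
            for exp_p, obs_p in zip(self.expected, self.observed):
                fh.write(f"{exp_p:.8g}\t{obs_p:.8g}\n")


def genomic_inflation(p_values) -> QQReport:
    """QQ data and the inflation factor lambda for a set of p-values.

    lambda = median(chi2(1) quantile of 1 - p) / median(chi2(1)); expected
    quantiles are uniform order statistics i/(m+1).  Requires >= 10 finite
    p-values, all in (0, 1].
    """
    p = np.asarray(p_values, dtype=float)
    p = p[np.isfinite(p)]
    if p.size < 10:
        raise ValueError(f"need >= 10 finite p-values, got {p.size}")
    if (p <= 0).any() or (p > 1).any():
        bad = p[(p <= 0) | (p > 1)]
        raise ValueError(f"p-values outside (0, 1]: e.g. {bad[:3]}")
    chi = stats.chi2.isf(p, df=1)
    lam = float(np.median(chi) / CHI2_1_MEDIAN)
    obs = np.sort(p)
    exp = np.arange(1, p.size + 1) / (p.size + 1.0)
    return QQReport(observed=obs, expected=exp, lam=lam)
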