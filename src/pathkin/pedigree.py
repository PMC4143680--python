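"""Pedigree parsing and expected (theoretical) kinship matrices.

A pedigree is a directed acyclic graph of individuals; the expected kinship
coefficient phi(i, j) is the probability that a randomly sampled allele from
i and one from j are identical by descent, computed by the classical tabular
recursion over a topological ordering (founders first).
"""

from __future__ import annotations

import dataclasses
from collections import deque
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

MISSING_PARENT = "0"

__all__ = [
    "PedigreeError",
    "Individual",
    "Pedigree",
    "KinshipMatrix",
    "parse_ped",
    "expected_kinship",
]


class PedigreeError(ValueError):
    """Structural problem in a pedigree file or graph."""


@dataclasses.dataclass(frozen=True)
class Individual:
    family: str
    iid: str
    father: str | None  # None = missing/unknown parent
    mother: str | None
    sex: int  # 1 = male, 2 = female, 0 = unknown; not used by kinship

    @property
    def is_founder(self) -> bool:
        return self.father is None and self.mother is None


class Pedigree:
    """Validated pedigree with a topological order (parents before children).

    Half-typed parents (one parent known, the other missing) are treated as
    having a unique unrelated, non-inbred founder in place of the missing
    parent; the recursion simply contributes 0 kinship for that slot.
    """

    def __init__(self, individuals: Iterable[Individual]):
        inds = list(individuals)
        seen: dict[str, Individual] = {}
        for ind in inds:
            if ind.iid in seen:
                raise PedigreeError(f"duplicate individual id: {ind.iid!r}")
            seen[ind.iid] = ind
        for ind in inds:
            for role, pid in (("father", ind.father), ("mother", ind.mother)):
                if pid is not None and pid not in seen:
                    raise PedigreeError(
                        f"{role} {pid!r} of {ind.iid!r} has no pedigree row; "
                        "add the parent or mark it missing ('0')"
                    )
        self.individuals: list[Individual] = inds
        self._by_id = seen
        self._topo_ids = self._topological_order()
        self._topo_index = {iid: k for k, iid in enumerate(self._topo_ids)}

    def _topological_order(self) -> list[str]:
        children: dict[str, list[str]] = {i.iid: [] for i in self.individuals}
        indeg = {i.iid: 0 for i in self.individuals}
        for ind in self.individuals:
            for pid in (ind.father, ind.mother):
                if pid is not None:
                    children[pid].append(ind.iid)
                    indeg[ind.iid] += 1
        order: list[str] = []
        queue = deque(i.iid for i in self.individuals if indeg[i.iid] == 0)
        while queue:
            iid = queue.popleft()
            order.append(iid)
            for c in children[iid]:
                indeg[c] -= 1
                if indeg[c] == 0:
                    queue.append(c)
        if len(order) != len(self.individuals):
            stuck = sorted(iid for iid, d in indeg.items() if d > 0)
            raise PedigreeError(
                f"pedigree contains a cycle involving individual(s): {', '.join(stuck)}"
            )
        return order

    # -- basic accessors ---------------------------------------------------
    def __len__(self) -> int:
        return len(self.individuals)

    def __contains__(self, iid: str) -> bool:
        return iid in self._by_id

    def __getitem__(self, iid: str) -> Individual:
        return self._by_id[iid]

    @property
    def ids(self) -> list[str]:
        """Individual ids in input order."""
        return [i.iid for i in self.individuals]

    @property
    def topological_ids(self) -> list[str]:
        return list(self._topo_ids)

    @property
    def founders(self) -> list[str]:
        return [i.iid for i in self.individuals if i.is_founder]

    @property
    def families(self) -> list[str]:
        out: list[str] = []
        for ind in self.individuals:
            if ind.family not in out:
                out.append(ind.family)
        return out

    def topological_index(self, iid: str) -> int:
        return self._topo_index[iid]

    def write_ped(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for ind in self.individuals:
                fh.write(
                    "\t".join(
                        [
                            ind.family,
                            ind.iid,
                            ind.father or MISSING_PARENT,
                            ind.mother or MISSING_PARENT,
                            str(ind.sex),
                        ]
                    )
                    + "\n"
                )


@dataclasses.dataclass
class KinshipMatrix:
    """Symmetric pairwise kinship coefficients.

    ``kind`` distinguishes the theoretical pedigree matrix (Phi) from the
    empirical, variant-derived one (the PSGRM).  Empirical matrices may carry
    per-pair supporting-variant counts.
    """

    ids: list[str]
    values: np.ndarray
    kind: str  # "theoretical" | "empirical"
    counts: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError(
                f"kinship matrix shape {self.values.shape} does not match {n} ids"
            )
        if not np.allclose(self.values, self.values.T, atol=1e-10, equal_nan=True):
            raise ValueError("kinship matrix is not symmetric")
        if self.kind not in ("theoretical", "empirical"):
            raise ValueError(f"unknown kinship kind: {self.kind!r}")

    @property
    def n(self) -> int:
        return len(self.ids)

    def align(self, ids: Sequence[str]) -> "KinshipMatrix":
        """Reorder/subset to ``ids``; raises on unknown ids."""
        index = {iid: k for k, iid in enumerate(self.ids)}
        missing = [i for i in ids if i not in index]
        if missing:
            raise KeyError(f"ids absent from kinship matrix: {missing}")
        idx = np.array([index[i] for i in ids])
        counts = self.counts[np.ix_(idx, idx)] if self.counts is not None else None
        return KinshipMatrix(list(ids), self.values[np.ix_(idx, idx)], self.kind, counts)

    # -- I/O ---------------------------------------------------------------
    def write_square(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("id\t" + "\t".join(self.ids) + "\n")
            for iid, row in zip(self.ids, self.values):
                fh.write(iid + "\t" + "\t".join(f"{v:.10g}" for v in row) + "\n")

    def write_long(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("id1\tid2\tn_variants\tkinship\n")
            for a in range(self.n):
                for b in range(a, self.n):
                    nv = int(self.counts[a, b]) if self.counts is not None else 0
                    fh.write(
                        f"{self.ids[a]}\t{self.ids[b]}\t{nv}\t{self.values[a, b]:.10g}\n"
                    )

    @classmethod
    def read_square(cls, path: str | Path, kind: str = "theoretical") -> "KinshipMatrix":
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            ids = header[1:]
            rows = []
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                rows.append([float(x) for x in parts[1:]])
        return cls(ids, np.array(rows), kind)


def parse_ped(path: str | Path) -> Pedigree:
    """Parse a whitespace-delimited PED-style file (FID IID PAT MAT SEX ...).

    Missing parents are encoded as ``0``.  Extra columns beyond the first
    five are ignored.
    """
    individuals: list[Individual] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 5:
                raise PedigreeError(
                    f"{path}:{lineno}: expected >= 5 columns (FID IID PAT MAT SEX), "
                    f"got {len(parts)}"
                )
            fid, iid, pat, mat, sex = parts[:5]
            if iid in (pat, mat):
                raise PedigreeError(
                    f"{path}:{lineno}: individual {iid!r} lists itself as a parent "
                    "(cycle)"
                )
            try:
                sex_code = int(sex)
            except ValueError:
                sex_code = 0
            individuals.append(
                Individual(
                    family=fid,
                    iid=iid,
                    father=None if pat == MISSING_PARENT else pat,
                    mother=None if mat == MISSING_PARENT else mat,
                    sex=sex_code,
                )
            )
    return Pedigree(individuals)


def expected_kinship(ped: Pedigree) -> KinshipMatrix:
    """Expected kinship matrix Phi via the tabular recursion.

    Founders are unrelated and non-inbred (phi_ii = 0.5); for a non-founder
    i with parents f and m, phi_ii = 0.5 * (1 + phi(f, m)) and
    phi(i, j) = 0.5 * (phi(f, j) + phi(m, j)) for any j preceding i in
    topological order.  A missing parent contributes 0.
    """
    order = ped.topological_ids
    pos = {iid: k for k, iid in enumerate(order)}
    n = len(order)
    phi = np.zeros((n, n))
    for k, iid in enumerate(order):
        ind = ped[iid]
        f = pos[ind.father] if ind.father is not None else None
        m = pos[ind.mother] if ind.mother is not None else None
        if f is None and m is None:
            phi[k, k] = 0.5
            continue
        row = np.zeros(k)
        if f is not None:
            row += phi[f, :k]
        if m is not None:
            row += phi[m, :k]
        row *= 0.5
        phi[k, :k] = row
        phi[:k, k] = row
        parent_phi = phi[f, m] if (f is not None and m is not None) else 0.0
        phi[k, k] = 0.5 * (1.0 + parent_phi)
    # restore the input order
    idx = np.array([pos[iid] for iid in ped.ids])
    return KinshipMatrix(ped.ids, phi[np.ix_(idx, idx)], kind="theoretical")
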