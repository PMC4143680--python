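"""Gene-set handling: GMT parsing, gene windows, and genotype extraction.

Each gene is mapped to the span of its longest isoform extended by a flank
(default 5 kb) on both genomic sides; all biallelic SNVs falling inside any
window of a pathway are collected once into a minor-allele dosage matrix.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING = np.nan
DEFAULT_FLANK = 5000
MAX_MISSING_RATE = 0.2

__all__ = [
    "GeneModelTable",
    "PathwayRegionSet",
    "GenotypeMatrix",
    "parse_gmt",
    "read_transcript_table",
    "build_regions",
    "extract_genotypes",
    "subset_by_regions",
    "maf_filter",
    "read_vcf",
    "write_regions_bed",
    "read_regions_bed",
]


class RegionError(ValueError):
    pass


def parse_gmt(path: str | Path) -> list[tuple[str, list[str]]]:
    """Parse a GMT file into (pathway name, gene symbols) pairs, in file order.

    GMT lines are tab-delimited: name, description, then one gene per field.
    A gene may appear in multiple pathways.
    """
    out: list[tuple[str, list[str]]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3 or not any(p.strip() for p in parts[2:]):
                raise RegionError(
                    f"{path}:{lineno}: GMT line needs name, description and >= 1 gene"
                )
            name = parts[0].strip()
            genes = [g.strip() for g in parts[2:] if g.strip()]
            out.append((name, genes))
    return out


def _norm_symbol(sym: str) -> str:
    """Case-insensitive match key, version suffix (e.g. ``.2``) stripped."""
    sym = sym.strip()
    if "." in sym:
        head, _, tail = sym.rpartition(".")
        if tail.isdigit():
            sym = head
    return sym.upper()


class GeneModelTable:
    """Transcript table: per gene symbol, isoform spans in 1-based inclusive
    coordinates (columns: gene, transcript, chrom, strand, txStart, txEnd)."""

    REQUIRED = ["gene", "transcript", "chrom", "strand", "txStart", "txEnd"]

    def __init__(self, df: pd.DataFrame):
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise RegionError(f"transcript table missing columns: {missing}")
        df = df.copy()
        if (df["txStart"] > df["txEnd"]).any():
            bad = df.loc[df["txStart"] > df["txEnd"], "transcript"].tolist()
            raise RegionError(f"isoform start > end for transcripts: {bad}")
        df["_key"] = df["gene"].map(_norm_symbol)
        self.df = df

    def lookup(self, symbol: str) -> pd.DataFrame:
        return self.df[self.df["_key"] == _norm_symbol(symbol)]

    def write(self, path: str | Path) -> None:
        self.df[self.REQUIRED].to_csv(path, sep="\t", index=False)


def read_transcript_table(path: str | Path) -> GeneModelTable:
    """Read a tab-delimited transcript table, or BED12 (detected by lack of a
    header); BED coordinates are converted from 0-based half-open."""
    with open(path) as fh:
        first = fh.readline()
    if first.split("\t")[0] == "gene":
        df = pd.read_csv(path, sep="\t")
        return GeneModelTable(df)
    # BED12: chrom, chromStart, chromEnd, name(=transcript|gene), score, strand, ...
    bed = pd.read_csv(path, sep="\t", header=None)
    if bed.shape[1] < 6:
        raise RegionError("BED input needs >= 6 columns (through strand)")
    names = bed[3].astype(str)
    gene = names.str.split("|").str[-1]
    df = pd.DataFrame(
        {
            "gene": gene,
            "transcript": names.str.split("|").str[0],
            "chrom": bed[0].astype(str),
            "strand": bed[5].astype(str),
            "txStart": bed[1].astype(int) + 1,
            "txEnd": bed[2].astype(int),
        }
    )
    return GeneModelTable(df)


@dataclasses.dataclass
class PathwayRegionSet:
    """Per-pathway genomic windows: (gene, chrom, start, end), 1-based inclusive."""

    name: str
    regions: list[tuple[str, str, int, int]]
    flank: int = DEFAULT_FLANK
    missing_genes: list[str] = dataclasses.field(default_factory=list)

    @property
    def n_genes(self) -> int:
        return len(self.regions)

    def write_bed(self, fh) -> None:
        for gene, chrom, start, end in self.regions:
            fh.write(f"{chrom}\t{start - 1}\t{end}\t{gene}\t0\t+\t{self.name}\n")


def build_regions(
    genes: Sequence[str],
    models: GeneModelTable,
    flank: int = DEFAULT_FLANK,
    name: str = "",
    strand_aware: bool = False,
    upstream: int | None = None,
    downstream: int | None = None,
) -> PathwayRegionSet:
    """Map gene symbols to windows around their longest isoform.

    The longest isoform (max end - start + 1; ties broken by lexicographically
    smallest transcript id) is extended by ``flank`` bp on both genomic sides,
    clipped at position 1.  With ``strand_aware`` the ``upstream``/``downstream``
    flanks are applied relative to the strand instead.
    """
    regions: list[tuple[str, str, int, int]] = []
    missing: list[str] = []
    for sym in genes:
        rows = models.lookup(sym)
        if rows.empty:
            missing.append(sym)
            continue
        spans = rows["txEnd"] - rows["txStart"] + 1
        best = rows.assign(_span=spans).sort_values(
            ["_span", "transcript"], ascending=[False, True]
        ).iloc[0]
        if strand_aware:
            up = flank if upstream is None else upstream
            down = flank if downstream is None else downstream
            if best["strand"] == "-":
                up, down = down, up
            start = int(best["txStart"]) - up
            end = int(best["txEnd"]) + down
        else:
            start = int(best["txStart"]) - flank
            end = int(best["txEnd"]) + flank
        regions.append((sym, str(best["chrom"]), max(start, 1), end))
    if missing:
        logger.warning(
            "pathway %s: %d gene symbol(s) not in transcript table: %s",
            name or "<unnamed>",
            len(missing),
            ", ".join(missing),
        )
    if not regions:
        raise RegionError(
            f"pathway {name or '<unnamed>'}: no requested gene resolves in the "
            "transcript table"
        )
    return PathwayRegionSet(name=name, regions=regions, flank=flank, missing_genes=missing)


@dataclasses.dataclass
class GenotypeMatrix:
    """Individuals x variants minor-allele dosage matrix.

    Dosages are 0/1/2 counts of the minor allele (defined within the stored
    sample set) with NaN for missing calls.  ``variants`` carries one row per
    (chrom, pos, alt) with columns: chrom, pos, id, ref, alt, flipped, region.
    """

    samples: list[str]
    variants: pd.DataFrame
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        n, m = len(self.samples), len(self.variants)
        if self.dosages.shape != (n, m):
            raise ValueError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{n} samples x {m} variants"
            )
        vals = self.dosages[~np.isnan(self.dosages)]
        if vals.size and not np.isin(vals, (0.0, 1.0, 2.0)).all():
            raise ValueError("dosages must be 0, 1, 2 or NaN")
        self.variants = self.variants.reset_index(drop=True)
        self._normalize_minor()

    def _normalize_minor(self) -> None:
        if "flipped" not in self.variants.columns:
            self.variants["flipped"] = False
        if self.n_variants == 0:
            return
        with np.errstate(invalid="ignore"):
            af = np.nanmean(self.dosages, axis=0) / 2.0
        flip = af > 0.5
        if flip.any():
            self.dosages[:, flip] = 2.0 - self.dosages[:, flip]
            self.variants.loc[flip, "flipped"] = ~self.variants.loc[
                flip, "flipped"
            ].astype(bool)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def is_empty(self) -> bool:
        return self.n_variants == 0

    @property
    def maf(self) -> np.ndarray:
        """Minor allele frequency per variant over non-missing calls."""
        with np.errstate(invalid="ignore"):
            af = np.nanmean(self.dosages, axis=0) / 2.0
        return np.minimum(af, 1.0 - af)

    def take_variants(self, idx: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            list(self.samples),
            self.variants.iloc[np.asarray(idx)].reset_index(drop=True),
            self.dosages[:, np.asarray(idx)].copy(),
        )

    def take_samples(self, ids: Sequence[str]) -> "GenotypeMatrix":
        index = {s: k for k, s in enumerate(self.samples)}
        missing = [s for s in ids if s not in index]
        if missing:
            raise KeyError(f"samples absent from genotype matrix: {missing}")
        idx = np.array([index[s] for s in ids])
        return GenotypeMatrix(
            list(ids), self.variants.copy(), self.dosages[idx, :].copy()
        )

    @classmethod
    def empty(cls, samples: Sequence[str]) -> "GenotypeMatrix":
        variants = pd.DataFrame(
            columns=["chrom", "pos", "id", "ref", "alt", "flipped", "region"]
        )
        return cls(list(samples), variants, np.zeros((len(samples), 0)))


def _window_lookup(regions: PathwayRegionSet):
    by_chrom: dict[str, list[tuple[int, int, str]]] = {}
    for gene, chrom, start, end in regions.regions:
        by_chrom.setdefault(str(chrom), []).append((start, end, gene))
    return by_chrom


def _containing_gene(by_chrom, chrom: str, pos: int) -> str | None:
    for start, end, gene in by_chrom.get(str(chrom), ()):  # inclusive ends
        if start <= pos <= end:
            return gene
    return None


def extract_genotypes(
    vcf_path: str | Path,
    regions: PathwayRegionSet,
    samples: Sequence[str] | None = None,
    max_missing: float = MAX_MISSING_RATE,
) -> GenotypeMatrix:
    """Extract biallelic SNVs inside any pathway window from a VCF.

    Variants in overlapping gene windows appear once (first containing gene
    is the region label); multi-allelic and non-SNV records are skipped with a
    logged count; variants missing in more than ``max_missing`` of samples are
    dropped.  Returns an empty-matrix sentinel when nothing is found.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(vcf_path), gts012=True)
    vcf_samples = list(vcf.samples)
    if samples is not None:
        offenders = [s for s in samples if s not in vcf_samples]
        if offenders:
            raise KeyError(
                f"samples requested but absent from VCF {vcf_path}: {offenders}"
            )
        vcf = VCF(str(vcf_path), gts012=True, samples=list(samples))
        vcf_samples = list(vcf.samples)

    by_chrom = _window_lookup(regions)
    seen: set[tuple[str, int, str]] = set()
    cols: list[np.ndarray] = []
    meta: list[dict] = []
    n_skipped = 0
    for rec in vcf:
        if len(rec.ALT) != 1 or len(rec.REF) != 1 or len(rec.ALT[0]) != 1:
            n_skipped += 1
            continue
        gene = _containing_gene(by_chrom, rec.CHROM, rec.POS)
        if gene is None:
            continue
        key = (str(rec.CHROM), int(rec.POS), str(rec.ALT[0]))
        if key in seen:
            continue
        seen.add(key)
        gt = rec.gt_types.astype(float)  # 0/1/2 alt dosage, 3 = unknown
        gt[gt == 3] = np.nan
        cols.append(gt)
        meta.append(
            {
                "chrom": str(rec.CHROM),
                "pos": int(rec.POS),
                "id": rec.ID or ".",
                "ref": str(rec.REF),
                "alt": str(rec.ALT[0]),
                "region": gene,
            }
        )
    if n_skipped:
        logger.info(
            "pathway %s: skipped %d multi-allelic/non-SNV record(s)",
            regions.name,
            n_skipped,
        )
    if not cols:
        return GenotypeMatrix.empty(vcf_samples)
    dosages = np.column_stack(cols)
    g = GenotypeMatrix(vcf_samples, pd.DataFrame(meta), dosages)
    return _drop_high_missing(g, max_missing, regions.name)


def _drop_high_missing(g: GenotypeMatrix, max_missing: float, name: str) -> GenotypeMatrix:
    if g.is_empty or not np.isnan(g.dosages).any():
        return g
    rate = np.isnan(g.dosages).mean(axis=0)
    keep = rate <= max_missing
    if not keep.all():
        logger.info(
            "pathway %s: dropped %d variant(s) with missing rate > %.0f%%",
            name,
            int((~keep).sum()),
            100 * max_missing,
        )
    return g.take_variants(np.flatnonzero(keep))


def subset_by_regions(
    g: GenotypeMatrix, regions: PathwayRegionSet, max_missing: float = MAX_MISSING_RATE
) -> GenotypeMatrix:
    """In-memory analogue of :func:`extract_genotypes` for an already-loaded
    genotype matrix (used by the simulation-driven pipeline)."""
    if g.is_empty:
        return g
    by_chrom = _window_lookup(regions)
    keep: list[int] = []
    labels: list[str] = []
    seen: set[tuple[str, int, str]] = set()
    for j, row in g.variants.iterrows():
        gene = _containing_gene(by_chrom, row["chrom"], int(row["pos"]))
        if gene is None:
            continue
        key = (str(row["chrom"]), int(row["pos"]), str(row["alt"]))
        if key in seen:
            continue
        seen.add(key)
        keep.append(j)
        labels.append(gene)
    if not keep:
        return GenotypeMatrix.empty(g.samples)
    out = g.take_variants(np.array(keep))
    out.variants["region"] = labels
    return _drop_high_missing(out, max_missing, regions.name)


def read_vcf(
    vcf_path: str | Path,
    samples: Sequence[str] | None = None,
    max_missing: float = MAX_MISSING_RATE,
) -> GenotypeMatrix:
    """Load every biallelic SNV from a VCF into one GenotypeMatrix."""
    from cyvcf2 import VCF

    vcf = VCF(str(vcf_path), gts012=True)
    if samples is not None:
        offenders = [s for s in samples if s not in vcf.samples]
        if offenders:
            raise KeyError(
                f"samples requested but absent from VCF {vcf_path}: {offenders}"
            )
        vcf = VCF(str(vcf_path), gts012=True, samples=list(samples))
    vcf_samples = list(vcf.samples)
    cols: list[np.ndarray] = []
    meta: list[dict] = []
    for rec in vcf:
        if len(rec.ALT) != 1 or len(rec.REF) != 1 or len(rec.ALT[0]) != 1:
            continue
        gt = rec.gt_types.astype(float)
        gt[gt == 3] = np.nan
        cols.append(gt)
        meta.append(
            {
                "chrom": str(rec.CHROM),
                "pos": int(rec.POS),
                "id": rec.ID or ".",
                "ref": str(rec.REF),
                "alt": str(rec.ALT[0]),
                "region": ".",
            }
        )
    if not cols:
        return GenotypeMatrix.empty(vcf_samples)
    g = GenotypeMatrix(vcf_samples, pd.DataFrame(meta), np.column_stack(cols))
    return _drop_high_missing(g, max_missing, "<all>")


def write_regions_bed(path: str | Path, region_sets: Sequence[PathwayRegionSet]) -> None:
    with open(path, "w") as fh:
        for rs in region_sets:
            rs.write_bed(fh)


def read_regions_bed(path: str | Path) -> list[PathwayRegionSet]:
    """Read windows written by :func:`write_regions_bed` (BED6 + pathway col)."""
    out: dict[str, PathwayRegionSet] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 7:
                raise RegionError(
                    f"{path}:{lineno}: expected 7 columns "
                    "(chrom start end gene score strand pathway)"
                )
            chrom, start, end, gene, _, _, pathway = parts[:7]
            rs = out.setdefault(pathway, PathwayRegionSet(name=pathway, regions=[]))
            rs.regions.append((gene, chrom, int(start) + 1, int(end)))
    return list(out.values())


def maf_filter(g: GenotypeMatrix, max_maf: float) -> GenotypeMatrix:
    """Retain variants with MAF strictly below ``max_maf``."""
    if not 0 < max_maf <= 0.5:
        raise ValueError(f"max_maf must be in (0, 0.5], got {max_maf}")
    if g.is_empty:
        return g
    keep = np.flatnonzero(g.maf < max_maf)
    if keep.size == 0:
        return GenotypeMatrix.empty(g.samples)
    return g.take_variants(keep)
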