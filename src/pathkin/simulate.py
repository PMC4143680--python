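"""Synthetic pedigrees, gene-dropped genotypes, pathways and phenotypes.

Everything the pipeline consumes can be generated here with known truth:
multi-generation families, founder allele frequencies across a MAF spectrum,
Mendelian gene-dropping, synthetic gene/pathway coordinates (emitted as GMT +
transcript table + VCF so the file-based pipeline is exercised end to end),
and phenotypes composed of covariate, polygenic, pathway-specific and
environmental parts.  All randomness flows from one seed.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .pedigree import Individual, Pedigree, expected_kinship
from .regions import GeneModelTable, GenotypeMatrix
from .vc import PhenotypeTable

__all__ = [
    "SimConfig",
    "SimTruth",
    "SimStudy",
    "simulate_pedigree",
    "gene_drop",
    "simulate_phenotype",
    "simulate_study",
    "write_study",
    "write_vcf",
    "write_gmt",
]


@dataclasses.dataclass
class SimConfig:
    n_families: int = 20
    generations: int = 3
    sibship: tuple[int, int] = (2, 5)  # uniform inclusive range
    n_pathways: int = 1
    genes_per_pathway: int = 10
    variants_per_gene: int = 20
    rare_fraction: float = 0.2  # fraction of variants with a rare founder MAF
    rare_maf: tuple[float, float] = (0.001, 0.01)
    common_maf: tuple[float, float] = (0.05, 0.5)
    causal_pathway: int | None = None  # index into pathways, None = no effect
    n_causal: int = 20
    h2r: float = 0.3
    h2gp: float = 0.0
    beta_sex: float = 1.0
    beta_age: float = 0.1
    beta_smoke: float = 0.5
    mu: float = 120.0
    sigma2_total: float = 100.0
    gene_length: int = 2000
    gene_spacing: int = 25000  # > 2 * flank + gene_length: windows never overlap
    ld_blocks: bool = False
    ld_switch_prob: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.h2r < 0 or self.h2gp < 0 or self.h2r + self.h2gp >= 1:
            raise ValueError("need h2r, h2gp >= 0 and h2r + h2gp < 1")
        for field in ("n_families", "generations", "n_pathways",
                      "genes_per_pathway", "variants_per_gene"):
            if getattr(self, field) < 1:
                raise ValueError(f"{field} must be >= 1")
        if self.sibship[0] < 1 or self.sibship[1] < self.sibship[0]:
            raise ValueError(f"bad sibship range {self.sibship}")
        if self.causal_pathway is not None and not (
            0 <= self.causal_pathway < self.n_pathways
        ):
            raise ValueError("causal_pathway out of range")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclasses.dataclass
class SimTruth:
    h2r_target: float
    h2gp_target: float
    h2r_realized: float
    h2gp_realized: float
    causal_variants: list[dict]
    genetic_values: np.ndarray  # per individual: polygenic + pathway part

    def to_json(self) -> dict:
        return {
            "h2r_target": self.h2r_target,
            "h2gp_target": self.h2gp_target,
            "h2r_realized": self.h2r_realized,
            "h2gp_realized": self.h2gp_realized,
            "causal_variants": self.causal_variants,
        }


def simulate_pedigree(cfg: SimConfig, rng: np.random.Generator | None = None) -> Pedigree:
    """Multi-generation families: a founder couple per family, sibships drawn
    from the configured range, and founder spouses marrying in at every
    non-final generation."""
    rng = cfg.rng() if rng is None else rng
    individuals: list[Individual] = []
    lo, hi = cfg.sibship
    for f in range(1, cfg.n_families + 1):
        fam = f"F{f}"
        counter = 0

        def new_id() -> str:
            nonlocal counter
            counter += 1
            return f"{fam}_I{counter}"

        father, mother = new_id(), new_id()
        individuals.append(Individual(fam, father, None, None, 1))
        individuals.append(Individual(fam, mother, None, None, 2))
        couples = [(father, mother)]
        for gen in range(2, cfg.generations + 1):
            next_couples: list[tuple[str, str]] = []
            for pat, mat in couples:
                n_kids = int(rng.integers(lo, hi + 1))
                for _ in range(n_kids):
                    child = new_id()
                    sex = 1 if rng.random() < 0.5 else 2
                    individuals.append(Individual(fam, child, pat, mat, sex))
                    if gen < cfg.generations:
                        spouse = new_id()
                        spouse_sex = 2 if sex == 1 else 1
                        individuals.append(
                            Individual(fam, spouse, None, None, spouse_sex)
                        )
                        if sex == 1:
                            next_couples.append((child, spouse))
                        else:
                            next_couples.append((spouse, child))
            couples = next_couples
    return Pedigree(individuals)


def build_gene_sets(cfg: SimConfig) -> tuple[list[tuple[str, list[str]]], GeneModelTable]:
    """Synthetic pathways and a matching transcript table.

    Pathway ``P<i>`` owns genes ``P<i>G<j>`` laid out on chromosome
    ``chr<i>`` with spacing wide enough that 5 kb windows never overlap.
    """
    sets: list[tuple[str, list[str]]] = []
    rows: list[dict] = []
    for p in range(1, cfg.n_pathways + 1):
        genes = [f"P{p}G{j}" for j in range(1, cfg.genes_per_pathway + 1)]
        sets.append((f"P{p}", genes))
        for j, gene in enumerate(genes):
            start = 100_000 + j * cfg.gene_spacing
            rows.append(
                {
                    "gene": gene,
                    "transcript": f"T_{gene}",
                    "chrom": f"chr{p}",
                    "strand": "+" if j % 2 == 0 else "-",
                    "txStart": start,
                    "txEnd": start + cfg.gene_length - 1,
                }
            )
    return sets, GeneModelTable(pd.DataFrame(rows))


def draw_founder_mafs(cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    m = cfg.n_pathways * cfg.genes_per_pathway * cfg.variants_per_gene
    rare = rng.random(m) < cfg.rare_fraction
    mafs = np.where(
        rare,
        rng.uniform(*cfg.rare_maf, size=m),
        rng.uniform(*cfg.common_maf, size=m),
    )
    return mafs


def _variant_frame(cfg: SimConfig, models: GeneModelTable) -> pd.DataFrame:
    rows: list[dict] = []
    tx = models.df
    for _, g in tx.iterrows():
        span = int(g["txEnd"]) - int(g["txStart"]) + 1
        offsets = np.linspace(0, span - 1, cfg.variants_per_gene).astype(int)
        offsets = np.unique(offsets)
        for k, off in enumerate(offsets):
            rows.append(
                {
                    "chrom": g["chrom"],
                    "pos": int(g["txStart"]) + int(off),
                    "id": f"{g['gene']}_v{k + 1}",
                    "ref": "A",
                    "alt": "G",
                    "region": g["gene"],
                }
            )
    return pd.DataFrame(rows)


def gene_drop(
    ped: Pedigree,
    mafs: np.ndarray,
    rng: np.random.Generator,
    variants: pd.DataFrame | None = None,
    ld_blocks: bool = False,
    ld_switch_prob: float = 0.1,
) -> tuple[GenotypeMatrix, np.ndarray]:
    """Drop unlinked variants through the pedigree.

    Founder haplotype alleles are Bernoulli(MAF); each offspring inherits one
    uniformly chosen allele per parent per variant.  Returns the genotype
    matrix (samples in pedigree input order) and the phased haplotypes as an
    (n, 2, m) 0/1 array of "alt" alleles, for VCF emission.  Optional block-LD
    mode makes adjacent founder alleles copy each other with probability
    1 - ``ld_switch_prob``.
    """
    mafs = np.asarray(mafs, dtype=float)
    m = len(mafs)
    order = ped.topological_ids
    pos = {iid: k for k, iid in enumerate(order)}
    n = len(order)
    haps = np.zeros((n, 2, m), dtype=np.int8)
    for k, iid in enumerate(order):
        ind = ped[iid]
        for h, parent in enumerate((ind.father, ind.mother)):
            if parent is None:
                if ld_blocks:
                    hap = np.empty(m, dtype=np.int8)
                    fresh = rng.random(m) < mafs
                    copy = rng.random(m) >= ld_switch_prob
                    hap[0] = fresh[0]
                    for j in range(1, m):
                        hap[j] = hap[j - 1] if copy[j] else fresh[j]
                    haps[k, h] = hap
                else:
                    haps[k, h] = rng.random(m) < mafs
            else:
                pick = rng.integers(0, 2, size=m)
                src = haps[pos[parent]]
                haps[k, h] = np.where(pick == 0, src[0], src[1])
    dosage = haps.sum(axis=1).astype(float)
    # back to pedigree input order
    idx = np.array([pos[iid] for iid in ped.ids])
    dosage = dosage[idx]
    haps = haps[idx]
    if variants is None:
        variants = pd.DataFrame(
            {
                "chrom": ["chr1"] * m,
                "pos": np.arange(1, m + 1) * 100,
                "id": [f"v{j + 1}" for j in range(m)],
                "ref": ["A"] * m,
                "alt": ["G"] * m,
                "region": ["sim"] * m,
            }
        )
    g = GenotypeMatrix(ped.ids, variants.copy(), dosage)
    return g, haps


def simulate_phenotype(
    ped: Pedigree,
    g: GenotypeMatrix,
    cfg: SimConfig,
    rng: np.random.Generator,
    causal_genes: Sequence[str] | None = None,
    causal_columns: np.ndarray | None = None,
    phi_kernel: np.ndarray | None = None,
) -> tuple[PhenotypeTable, SimTruth]:
    """y = mu + X*beta + polygenic + pathway + noise with known fractions.

    The polygenic part is MVN(0, sigma2*h2r*2Phi) (sampled through the
    eigen square root of 2Phi); the pathway part is a sum of causal-dosage
    effects rescaled so its realized variance fraction equals the target
    h2gp; the noise picks up the remainder.  Sex comes from the pedigree;
    age ~ U(20, 80); smoking ~ Bernoulli(0.3).
    """
    ids = list(g.samples)
    n = len(ids)
    sigma2 = cfg.sigma2_total

    sex = np.array([1.0 if ped[i].sex == 2 else 0.0 for i in ids])
    age = rng.uniform(20.0, 80.0, size=n)
    smoke = (rng.random(n) < 0.3).astype(float)
    fixed = cfg.beta_sex * sex + cfg.beta_age * age + cfg.beta_smoke * smoke

    if phi_kernel is None:
        phi_kernel = 2.0 * expected_kinship(ped).align(ids).values
    g_poly = np.zeros(n)
    if cfg.h2r > 0:
        lam, U = np.linalg.eigh(phi_kernel)
        root = U * np.sqrt(np.maximum(lam, 0.0))
        g_poly = np.sqrt(cfg.h2r * sigma2) * (root @ rng.standard_normal(n))

    g_path = np.zeros(n)
    causal: list[dict] = []
    if cfg.h2gp > 0:
        if causal_columns is not None:
            pool = np.asarray(causal_columns)
        elif causal_genes is not None:
            pool = np.flatnonzero(g.variants["region"].isin(list(causal_genes)))
        else:
            pool = np.arange(g.n_variants)
        d = g.dosages[:, pool]
        usable = pool[np.nanstd(d, axis=0) > 0]
        if usable.size == 0:
            raise ValueError(
                "h2gp > 0 requested but no polymorphic causal variant available"
            )
        n_causal = min(cfg.n_causal, usable.size)
        chosen = np.sort(rng.choice(usable, size=n_causal, replace=False))
        effects = rng.standard_normal(n_causal)
        dc = g.dosages[:, chosen]
        dc = np.where(np.isnan(dc), np.nanmean(dc, axis=0), dc)
        raw = (dc - dc.mean(axis=0)) @ effects
        sd = raw.std()
        if sd == 0:
            raise ValueError("causal pathway effect degenerate (zero variance)")
        scale = np.sqrt(cfg.h2gp * sigma2) / sd
        g_path = raw * scale
        for j, b in zip(chosen, effects):
            row = g.variants.iloc[int(j)]
            causal.append(
                {
                    "chrom": str(row["chrom"]),
                    "pos": int(row["pos"]),
                    "id": str(row["id"]),
                    "effect": float(b * scale),
                }
            )

    e2 = 1.0 - cfg.h2r - cfg.h2gp
    eps = np.sqrt(e2 * sigma2) * rng.standard_normal(n)
    y = cfg.mu + fixed + g_poly + g_path + eps

    truth = SimTruth(
        h2r_target=cfg.h2r,
        h2gp_target=cfg.h2gp,
        h2r_realized=float(g_poly.var() / sigma2),
        h2gp_realized=float(g_path.var() / sigma2),
        causal_variants=causal,
        genetic_values=g_poly + g_path,
    )
    table = PhenotypeTable(
        pd.DataFrame(
            {"iid": ids, "trait": y, "sex": sex, "age": age, "smoke": smoke}
        )
    )
    return table, truth


@dataclasses.dataclass
class SimStudy:
    cfg: SimConfig
    ped: Pedigree
    gene_sets: list[tuple[str, list[str]]]
    gene_models: GeneModelTable
    genotypes: GenotypeMatrix
    haplotypes: np.ndarray
    phenotypes: PhenotypeTable
    truth: SimTruth

    @property
    def causal_pathway_name(self) -> str | None:
        if self.cfg.causal_pathway is None:
            return None
        return self.gene_sets[self.cfg.causal_pathway][0]


def simulate_study(cfg: SimConfig) -> SimStudy:
    """Full synthetic study: pedigree, pathways, genotypes, phenotypes."""
    rng = cfg.rng()
    ped = simulate_pedigree(cfg, rng)
    gene_sets, models = build_gene_sets(cfg)
    mafs = draw_founder_mafs(cfg, rng)
    variants = _variant_frame(cfg, models)
    if len(variants) != len(mafs):  # linspace dedup can shrink tiny genes
        mafs = mafs[: len(variants)]
    g, haps = gene_drop(
        ped, mafs, rng, variants=variants,
        ld_blocks=cfg.ld_blocks, ld_switch_prob=cfg.ld_switch_prob,
    )
    causal_genes = None
    if cfg.causal_pathway is not None and cfg.h2gp > 0:
        causal_genes = gene_sets[cfg.causal_pathway][1]
    pheno, truth = simulate_phenotype(ped, g, cfg, rng, causal_genes=causal_genes)
    return SimStudy(cfg, ped, gene_sets, models, g, haps, pheno, truth)


# ---------------------------------------------------------------------------
# writers (the exact text formats the pipeline consumes)

def write_vcf(
    path: str | Path,
    g: GenotypeMatrix,
    haplotypes: np.ndarray | None = None,
    seed: int | None = None,
) -> None:
    """Write VCF 4.2 with contig headers; phased GTs when haplotypes given,
    otherwise unphased GTs recovered from the (possibly flipped) dosages."""
    chroms = list(dict.fromkeys(g.variants["chrom"].astype(str)))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=pathkin-simulate" +
                 (f" seed={seed}" if seed is not None else "") + "\n")
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(g.samples)
            + "\n"
        )
        flipped = g.variants["flipped"].to_numpy(dtype=bool)
        for j in range(g.n_variants):
            row = g.variants.iloc[j]
            fields = [
                str(row["chrom"]), str(int(row["pos"])), str(row["id"]),
                str(row["ref"]), str(row["alt"]), ".", "PASS", ".", "GT",
            ]
            if haplotypes is not None:
                gts = [f"{haplotypes[i, 0, j]}|{haplotypes[i, 1, j]}"
                       for i in range(g.n_samples)]
            else:
                dos = g.dosages[:, j]
                alt = np.where(np.isnan(dos), np.nan,
                               2.0 - dos if flipped[j] else dos)
                lut = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
                gts = ["./." if np.isnan(a) else lut[a] for a in alt]
            fh.write("\t".join(fields + gts) + "\n")


def write_gmt(path: str | Path, gene_sets: list[tuple[str, list[str]]]) -> None:
    with open(path, "w") as fh:
        for name, genes in gene_sets:
            fh.write("\t".join([name, "synthetic"] + list(genes)) + "\n")


def write_phenotypes(path: str | Path, pheno: PhenotypeTable) -> None:
    pheno.df.to_csv(path, sep="\t", index=False)


def write_study(study: SimStudy, outdir: str | Path) -> dict[str, str]:
    """Write PED/VCF/GMT/transcript/phenotype files plus a truth JSON.

    Returns the map of artifact name -> path.  The seed is recorded in the
    VCF header and in sim_truth.json.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "ped": outdir / "sim.ped",
        "vcf": outdir / "sim.vcf",
        "gmt": outdir / "sim.gmt",
        "genes": outdir / "sim_genes.tsv",
        "pheno": outdir / "sim_pheno.tsv",
        "truth": outdir / "sim_truth.json",
    }
    study.ped.write_ped(paths["ped"])
    write_vcf(paths["vcf"], study.genotypes, study.haplotypes, seed=study.cfg.seed)
    write_gmt(paths["gmt"], study.gene_sets)
    study.gene_models.write(paths["genes"])
    write_phenotypes(paths["pheno"], study.phenotypes)
    truth = study.truth.to_json()
    truth["seed"] = study.cfg.seed
    truth["config"] = dataclasses.asdict(study.cfg)
    with open(paths["truth"], "w") as fh:
        json.dump(truth, fh, indent=2, default=str)
    return {k: str(v) for k, v in paths.items()}
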