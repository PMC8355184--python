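"""Synthetic data generator for the local co-expression pipeline.

Generates gene catalogs, expression matrices with planted co-expression
blocks, genotypes with planted (optionally shared) cis-eQTLs, annotation
tracks with configurable enrichment/depletion around truly co-expressed
pairs, enhancer-gene links, Hi-C-like contact counts with power-law distance
decay, gene-level functional labels, paralog pair lists and multi-trait GWAS
summary statistics.  Truth tables record the planted structure so every
downstream stage can be scored without inspecting generator internals.

The statistical model per stage:

* expression: genes in a block share a standard-normal latent factor with
  loading ``a`` so the nominal within-block pairwise correlation is ``a^2``;
  sample-level confounders are added to all genes with random gene weights.
* genotypes: independent biallelic variants, dosage ~ Binomial(2, MAF) with
  MAF uniform in ``maf_range``; a planted eQTL adds ``beta * dosage`` to its
  target gene(s).  A shared eQTL targets both members of a truth pair with
  the same sign.
* GWAS: null p-values are uniform; lead-eQTL variants can receive mildly
  inflated association statistics (chi-square variance multiplier) and a
  configurable fraction are designated genome-wide-significant hits in a
  configurable number of traits.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import ndtr

from ._seeds import derive_rng
from .genotypes import GenotypeMatrix
from .preprocess import ExpressionMatrix

__all__ = [
    "SimConfig",
    "SyntheticDataset",
    "simulate_genome",
    "simulate_expression",
    "simulate_genotypes_and_eqtls",
    "simulate_tracks",
    "simulate_gwas",
    "simulate_dataset",
    "write_dataset",
]

_NUCS = np.array(list("ACGT"))


@dataclass
class SimConfig:
    """All generator knobs; identical config (incl. seed) gives identical data."""

    n_individuals: int = 300
    n_genes: int = 2000
    n_chromosomes: int = 5
    mean_tss_spacing: int = 100_000
    #: list of (block size, latent loading in [0,1)); blocks are consecutive genes
    block_spec: list = field(default_factory=list)
    confounder_count: int = 0
    confounder_strength: float = 0.0
    maf_range: tuple = (0.05, 0.5)
    eqtl_effect: float = 0.5
    shared_fraction: float = 0.5
    #: candidate cis variants simulated per gene
    variants_per_gene: int = 20
    #: fraction of non-block genes given their own (unshared) eQTL
    egene_fraction: float = 0.0
    #: intervals per Mb for each annotation track
    track_densities: dict = field(
        default_factory=lambda: {"ctcf_sites": 20.0, "ctcf_motifs": 10.0, "tf_motifs": 100.0}
    )
    #: per-track survival probability of intervals near true pairs (1 = neutral)
    track_depletion: dict = field(default_factory=dict)
    enhancers_per_gene: float = 3.0
    #: probability that a true pair's enhancers are shared between members
    enhancer_sharing_rate: float = 0.0
    #: multiplier on the number of enhancers linked to true-pair genes
    enhancer_depletion: float = 1.0
    hic_decay: float = -1.0
    hic_base: float = 100.0
    #: multiplicative Hi-C contact boost for true-pair TSS bin pairs
    hic_boost: float = 1.0
    gwas_traits: int = 5
    #: fraction of shared / other lead-eQTL variants designated GWAS hits
    gwas_shared_hit_rate: float = 0.0
    gwas_other_hit_rate: float = 0.0
    #: number of traits in which a designated hit is genome-wide significant
    gwas_hits_per_variant: int = 2
    #: chi-square variance multipliers for eQTL variants' association stats
    gwas_shared_inflation: float = 1.0
    gwas_other_inflation: float = 1.0
    #: number of GO-like functional terms and per-category labelling rates
    go_terms: int = 50
    go_rate_true: float = 0.0
    go_rate_background: float = 0.02
    #: fraction of true pairs / background cis pairs flagged as paralogs
    paralog_rate_true: float = 0.0
    paralog_rate_background: float = 0.0
    #: exponentiate expression onto a TPM-like positive scale
    tpm_scale: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mean_tss_spacing <= 0:
            raise ValueError("mean_tss_spacing must be positive")
        if self.n_genes < 2 or self.n_chromosomes < 1:
            raise ValueError("need n_genes >= 2 and n_chromosomes >= 1")
        if sum(size for size, _ in self.block_spec) > self.n_genes:
            raise ValueError("block sizes sum beyond n_genes")
        for _, loading in self.block_spec:
            if not 0.0 <= loading < 1.0:
                raise ValueError("block loadings must be in [0, 1)")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")


@dataclass
class SyntheticDataset:
    """Bundle of all generated artifacts plus the truth tables."""

    config: SimConfig
    catalog: pd.DataFrame
    expression: ExpressionMatrix
    confounders: pd.DataFrame
    truth_pairs: pd.DataFrame
    genotypes: GenotypeMatrix
    eqtl_truth: pd.DataFrame
    tracks: dict
    enhancer_links: pd.DataFrame
    hic: pd.DataFrame
    gwas: pd.DataFrame
    go_labels: pd.DataFrame
    paralog_pairs: pd.DataFrame


# ---------------------------------------------------------------------------
# genome


def simulate_genome(config: SimConfig) -> pd.DataFrame:
    """Gene catalog: chrom, strictly increasing TSS per chromosome, strand,
    biotype.  Spacings are exponential with the configured mean, so TSS
    distances are continuous and distance-matching has candidates at every
    scale."""
    rng = derive_rng(config.seed, "genome")
    per_chrom = np.full(config.n_chromosomes, config.n_genes // config.n_chromosomes)
    per_chrom[: config.n_genes % config.n_chromosomes] += 1
    rows = []
    gid = 0
    for c, n_c in enumerate(per_chrom):
        chrom = f"chr{c + 1}"
        gaps = rng.exponential(config.mean_tss_spacing, size=n_c)
        tss = np.maximum(1, np.ceil(np.cumsum(gaps))).astype(np.int64)
        tss = np.maximum.accumulate(tss + np.arange(n_c))  # strictly increasing
        strands = rng.choice(["+", "-"], size=n_c)
        biotypes = rng.choice(["protein_coding", "lincRNA"], size=n_c, p=[0.9, 0.1])
        for j in range(n_c):
            rows.append((f"G{gid:05d}", chrom, int(tss[j]), strands[j], biotypes[j]))
            gid += 1
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "tss", "strand", "biotype"])


# ---------------------------------------------------------------------------
# expression


def _assign_blocks(catalog: pd.DataFrame, config: SimConfig, rng) -> list:
    """Place blocks of consecutive genes, never straddling chromosomes.

    Returns a list of (gene index array, loading).  Block anchors are drawn
    without overlap, scanning chromosomes in random order.
    """
    blocks = []
    used = np.zeros(len(catalog), dtype=bool)
    chrom_groups = {
        c: idx.to_numpy() for c, idx in catalog.groupby("chrom").groups.items()
    }
    max_block = max((size for size, _ in config.block_spec), default=0)
    if max_block and max(len(v) for v in chrom_groups.values()) < max_block:
        raise ValueError("block larger than the gene count of every chromosome")
    # place larger blocks first among the exactly-feasible consecutive runs
    order = sorted(
        rng.permutation(len(config.block_spec)),
        key=lambda bi: -config.block_spec[bi][0],
    )
    chrom_names = sorted(chrom_groups)
    for bi in order:
        size, loading = config.block_spec[bi]
        feasible = []  # (chrom, start offset) pairs where the run is free
        for chrom in chrom_names:
            idx = chrom_groups[chrom]
            if len(idx) < size:
                continue
            free = ~used[idx]
            run = np.convolve(free.astype(int), np.ones(size, dtype=int), "valid")
            feasible.extend((chrom, s) for s in np.where(run == size)[0])
        if not feasible:
            raise ValueError("could not place all blocks without overlap")
        chrom, start = feasible[int(rng.integers(len(feasible)))]
        sel = chrom_groups[chrom][start : start + size]
        used[sel] = True
        blocks.append((sel, float(loading)))
    return blocks


def simulate_expression(
    catalog: pd.DataFrame, config: SimConfig
) -> tuple[ExpressionMatrix, pd.DataFrame, pd.DataFrame]:
    """Raw expression with planted co-expression blocks.

    Returns (expression, truth pair table, confounder table).  The truth
    table lists every within-block pair whose TSSs are < 1 Mb apart with its
    nominal correlation (loading^2).
    """
    if catalog.empty:
        raise ValueError("catalog is empty")
    rng = derive_rng(config.seed, "expression")
    n_genes, n_ind = len(catalog), config.n_individuals
    values = rng.standard_normal((n_genes, n_ind))

    blocks = _assign_blocks(catalog, config, rng)
    truth_rows = []
    for block_id, (sel, loading) in enumerate(blocks):
        factor = rng.standard_normal(n_ind)
        values[sel] = loading * factor + np.sqrt(1 - loading**2) * values[sel]
        tss = catalog["tss"].to_numpy()
        for i in range(len(sel)):
            for j in range(i + 1, len(sel)):
                a, b = sel[i], sel[j]
                if abs(int(tss[a]) - int(tss[b])) < 1_000_000:
                    ga, gb = catalog["gene_id"].iloc[a], catalog["gene_id"].iloc[b]
                    ga, gb = sorted((ga, gb))
                    truth_rows.append((ga, gb, block_id, loading, loading**2))
    truth = pd.DataFrame(
        truth_rows, columns=["gene_a", "gene_b", "block_id", "loading", "expected_r"]
    )

    samples = np.array([f"S{i:04d}" for i in range(n_ind)], dtype=object)
    conf = rng.standard_normal((n_ind, config.confounder_count))
    if config.confounder_count and config.confounder_strength:
        weights = rng.standard_normal((n_genes, config.confounder_count))
        values = values + config.confounder_strength * weights @ conf.T
    confounders = pd.DataFrame(
        conf, index=pd.Index(samples), columns=[f"C{k}" for k in range(config.confounder_count)]
    )
    if config.tpm_scale:
        values = np.exp(values)
    expr = ExpressionMatrix(
        genes=catalog["gene_id"].to_numpy(dtype=object),
        samples=samples,
        values=values,
        state="raw",
    )
    return expr, truth, confounders


# ---------------------------------------------------------------------------
# genotypes and eQTLs


def simulate_genotypes_and_eqtls(
    catalog: pd.DataFrame,
    expr: ExpressionMatrix,
    truth_pairs: pd.DataFrame,
    config: SimConfig,
) -> tuple[GenotypeMatrix, pd.DataFrame, ExpressionMatrix]:
    """Cis variants plus planted eQTL effects added onto the expression.

    Per truth pair, with probability ``shared_fraction`` one cis variant gets
    effect ``eqtl_effect`` on *both* members (same sign, shared=True);
    otherwise on one member only.  A fraction ``egene_fraction`` of the
    remaining genes get an unshared eQTL.  Returns (genotypes, eQTL truth,
    modified expression); expression is modified on its current scale.
    """
    rng = derive_rng(config.seed, "genotypes")
    tss = dict(zip(catalog["gene_id"], catalog["tss"]))
    chrom = dict(zip(catalog["gene_id"], catalog["chrom"]))
    n_ind = expr.n_samples

    var_rows, dosages = [], []
    gene_variants: dict[str, list[int]] = {}
    vid = 0
    lo, hi = config.maf_range
    for gene in catalog["gene_id"]:
        pos0 = tss[gene]
        offsets = rng.integers(-1_000_000, 1_000_000, size=config.variants_per_gene)
        positions = np.maximum(1, pos0 + offsets)
        mafs = rng.uniform(lo, hi, size=config.variants_per_gene)
        idxs = []
        for p, maf in zip(positions, mafs):
            dose = rng.binomial(2, maf, size=n_ind).astype(np.int8)
            ref, alt = rng.choice(4, size=2, replace=False)
            var_rows.append(
                (f"V{vid:06d}", chrom[gene], int(p), _NUCS[ref], _NUCS[alt], float(maf))
            )
            dosages.append(dose)
            idxs.append(vid)
            vid += 1
        gene_variants[gene] = idxs
    variants = pd.DataFrame(
        var_rows, columns=["variant_id", "chrom", "pos", "ref", "alt", "maf"]
    )
    dosages = np.asarray(dosages, dtype=np.int8)
    geno = GenotypeMatrix(variants=variants, samples=expr.samples, dosages=dosages)

    values = expr.values.copy()
    gene_idx = expr.gene_index()
    beta = config.eqtl_effect
    truth_rows = []

    def _add_effect(gene: str, var_i: int, shared: bool, pair_id: int | None) -> None:
        if beta != 0.0:
            values[gene_idx[gene]] += beta * dosages[var_i]
        truth_rows.append(
            (gene, variants["variant_id"].iloc[var_i], beta, shared, pair_id)
        )

    paired_genes: set[str] = set()
    for pid, row in enumerate(truth_pairs.itertuples(index=False)):
        paired_genes |= {row.gene_a, row.gene_b}
        if rng.random() < config.shared_fraction:
            # one variant cis to both genes, same-sign effect on each
            mid_ok = [
                v
                for v in gene_variants[row.gene_a]
                if abs(variants["pos"].iloc[v] - tss[row.gene_b]) < 1_000_000
            ]
            if not mid_ok:
                raise ValueError("no cis variant position available for shared eQTL")
            v = int(rng.choice(mid_ok))
            _add_effect(row.gene_a, v, True, pid)
            _add_effect(row.gene_b, v, True, pid)
        else:
            target = row.gene_a if rng.random() < 0.5 else row.gene_b
            v = int(rng.choice(gene_variants[target]))
            _add_effect(target, v, False, pid)

    if config.egene_fraction > 0:
        for gene in catalog["gene_id"]:
            if gene in paired_genes:
                continue
            if rng.random() < config.egene_fraction:
                v = int(rng.choice(gene_variants[gene]))
                _add_effect(gene, v, False, None)

    eqtl_truth = pd.DataFrame(
        truth_rows, columns=["gene_id", "variant_id", "beta", "shared", "pair_id"]
    )
    expr_out = ExpressionMatrix(
        genes=expr.genes, samples=expr.samples, values=values, state=expr.state
    )
    return geno, eqtl_truth, expr_out


# ---------------------------------------------------------------------------
# annotation tracks


def _chrom_spans(catalog: pd.DataFrame) -> dict:
    spans = {}
    for c, grp in catalog.groupby("chrom"):
        spans[c] = int(grp["tss"].max()) + 1_100_000
    return spans


def _true_pair_regions(catalog: pd.DataFrame, truth_pairs: pd.DataFrame, pad: int = 0):
    """(chrom, lo, hi) spans between (or around) true-pair TSSs."""
    tss = dict(zip(catalog["gene_id"], catalog["tss"]))
    chrom = dict(zip(catalog["gene_id"], catalog["chrom"]))
    regions = []
    for row in truth_pairs.itertuples(index=False):
        a, b = tss[row.gene_a], tss[row.gene_b]
        lo, hi = min(a, b) - pad, max(a, b) + pad
        regions.append((chrom[row.gene_a], lo, hi))
    return regions


def _in_regions(chroms, mids, regions) -> np.ndarray:
    hit = np.zeros(len(mids), dtype=bool)
    for c, lo, hi in regions:
        hit |= (chroms == c) & (mids > lo) & (mids < hi)
    return hit


def simulate_tracks(
    catalog: pd.DataFrame, truth_pairs: pd.DataFrame, config: SimConfig
) -> tuple[dict, pd.DataFrame, pd.DataFrame]:
    """Annotation tracks, enhancer-gene links and Hi-C triplets.

    Tracks are homogeneous-Poisson interval sets per chromosome; per-track
    depletion factors thin intervals lying between true-pair TSSs (CTCF
    tracks) or within +/-50 kb of true-pair TSSs (TF motifs), emulating the
    lower regulatory complexity of co-expressed pairs.  Hi-C counts follow a
    power-law distance decay with an optional contact boost for true pairs.
    """
    if catalog.empty:
        raise ValueError("catalog is empty")
    rng = derive_rng(config.seed, "tracks")
    spans = _chrom_spans(catalog)
    between = _true_pair_regions(catalog, truth_pairs)
    flank_regions = []
    tss_map = dict(zip(catalog["gene_id"], catalog["tss"]))
    chrom_map = dict(zip(catalog["gene_id"], catalog["chrom"]))
    for row in truth_pairs.itertuples(index=False):
        for g in (row.gene_a, row.gene_b):
            flank_regions.append((chrom_map[g], tss_map[g] - 50_000, tss_map[g] + 50_000))

    tf_names = [f"TF{m}" for m in range(20)]
    tracks: dict[str, pd.DataFrame] = {}
    for name, density in config.track_densities.items():
        rows = []
        for c, span in spans.items():
            n = rng.poisson(density * span / 1e6)
            starts = np.sort(rng.integers(0, span, size=n))
            lengths = rng.integers(100, 1000, size=n)
            strands = rng.choice(["+", "-"], size=n)
            if name == "tf_motifs":
                labels = rng.choice(tf_names, size=n)
            elif name == "ctcf_motifs":
                labels = np.full(n, "CTCF")
            else:
                labels = np.full(n, name)
            for s, ln, st, lb in zip(starts, lengths, strands, labels):
                rows.append((c, int(s), int(s + ln), st, lb))
        df = pd.DataFrame(rows, columns=["chrom", "start", "end", "strand", "label"])
        survival = config.track_depletion.get(name, 1.0)
        if survival < 1.0 and len(df):
            mids = ((df["start"] + df["end"]) // 2).to_numpy()
            regions = flank_regions if name == "tf_motifs" else between
            inside = _in_regions(df["chrom"].to_numpy(), mids, regions)
            drop = inside & (rng.random(len(df)) > survival)
            df = df.loc[~drop].reset_index(drop=True)
        tracks[name] = df

    # enhancer-gene links: per gene, Poisson-many enhancers within +/-100 kb;
    # true-pair genes can share enhancers and/or have fewer of them.
    truth_partner: dict[str, str] = {}
    for row in truth_pairs.itertuples(index=False):
        truth_partner.setdefault(row.gene_a, row.gene_b)
        truth_partner.setdefault(row.gene_b, row.gene_a)
    link_rows = []
    eid = 0
    gene_enhancers: dict[str, list[tuple]] = {g: [] for g in catalog["gene_id"]}
    for row in catalog.itertuples(index=False):
        lam = config.enhancers_per_gene
        if row.gene_id in truth_partner:
            lam *= config.enhancer_depletion
        n = rng.poisson(lam)
        for _ in range(n):
            start = max(0, int(row.tss) + int(rng.integers(-100_000, 100_000)))
            gene_enhancers[row.gene_id].append(
                (f"E{eid:06d}", row.chrom, start, start + 500)
            )
            eid += 1
    for row in truth_pairs.itertuples(index=False):
        if config.enhancer_sharing_rate <= 0:
            break
        for enh in gene_enhancers[row.gene_a]:
            if rng.random() < config.enhancer_sharing_rate:
                gene_enhancers[row.gene_b].append(enh)
    for gene, enhs in gene_enhancers.items():
        for e in set(enhs):
            link_rows.append((*e, gene))
    links = pd.DataFrame(
        link_rows, columns=["enhancer_id", "chrom", "start", "end", "gene_id"]
    ).sort_values(["chrom", "start", "enhancer_id"], ignore_index=True)

    # Hi-C: emit triplets for all TSS-bin pairs within 1 Mb plus true-pair bins
    res = 5000
    hic_rows = []
    seen = set()
    for c, grp in catalog.groupby("chrom"):
        bins = np.unique((grp["tss"].to_numpy() // res) * res)
        for i, b1 in enumerate(bins):
            for b2 in bins[i:]:
                if b2 - b1 > 1_000_000:
                    break
                seen.add((c, int(b1), int(b2)))
    for row in truth_pairs.itertuples(index=False):
        b1 = (tss_map[row.gene_a] // res) * res
        b2 = (tss_map[row.gene_b] // res) * res
        key = (chrom_map[row.gene_a], int(min(b1, b2)), int(max(b1, b2)))
        seen.add(key)
    boost_keys = set()
    if config.hic_boost != 1.0:
        for row in truth_pairs.itertuples(index=False):
            b1 = (tss_map[row.gene_a] // res) * res
            b2 = (tss_map[row.gene_b] // res) * res
            boost_keys.add((chrom_map[row.gene_a], int(min(b1, b2)), int(max(b1, b2))))
    for c, b1, b2 in sorted(seen):
        dist_bins = max(1.0, (b2 - b1) / res)
        mean = config.hic_base * dist_bins**config.hic_decay
        if (c, b1, b2) in boost_keys:
            mean *= config.hic_boost
        count = mean * rng.lognormal(0.0, 0.1)
        hic_rows.append((c, b1, b2, count))
    hic = pd.DataFrame(hic_rows, columns=["chrom", "bin1_start", "bin2_start", "count"])
    return tracks, links, hic


# ---------------------------------------------------------------------------
# GWAS


def simulate_gwas(
    variants: pd.DataFrame, eqtl_truth: pd.DataFrame, config: SimConfig
) -> pd.DataFrame:
    """Variant x trait association p-values.

    Non-associated p-values are Uniform(0,1) (via squared standard-normal z
    scores).  Variants that are planted lead-eQTLs get z drawn with variance
    ``gwas_*_inflation`` (shared vs unshared category), which inflates the
    median chi-square (lambda) without flooding the genome-wide-significance
    tail.  Designated hit variants additionally receive p < 5e-8 in
    ``gwas_hits_per_variant`` traits, sampled at the per-category hit rate.
    """
    if variants.empty or config.gwas_traits < 1:
        raise ValueError("need a nonempty variant table and gwas_traits >= 1")
    rng = derive_rng(config.seed, "gwas")
    n_var, n_tr = len(variants), config.gwas_traits
    shared_vars = set(eqtl_truth.loc[eqtl_truth["shared"], "variant_id"])
    other_vars = set(eqtl_truth.loc[~eqtl_truth["shared"], "variant_id"]) - shared_vars

    sd = np.ones(n_var)
    vid = variants["variant_id"].to_numpy()
    is_shared = np.isin(vid, list(shared_vars))
    is_other = np.isin(vid, list(other_vars))
    sd[is_shared] = np.sqrt(config.gwas_shared_inflation)
    sd[is_other] = np.sqrt(config.gwas_other_inflation)

    z = rng.standard_normal((n_var, n_tr)) * sd[:, None]
    pvals = 2.0 * ndtr(-np.abs(z))
    pvals = np.clip(pvals, 1e-300, 1.0)

    hit_rate = np.zeros(n_var)
    hit_rate[is_shared] = config.gwas_shared_hit_rate
    hit_rate[is_other] = config.gwas_other_hit_rate
    carriers = np.where(rng.random(n_var) < hit_rate)[0]
    k_mean = min(config.gwas_hits_per_variant, n_tr)
    for i in carriers:
        # 1 + Binomial keeps the mean at k_mean but lets counts vary
        k = 1 + rng.binomial(n_tr - 1, (k_mean - 1) / max(n_tr - 1, 1))
        traits = rng.choice(n_tr, size=k, replace=False)
        pvals[i, traits] = 10.0 ** rng.uniform(-12, np.log10(5e-8), size=k)

    betas = z * 0.01  # arbitrary effect scale; sign is what downstream uses
    records = pd.DataFrame(
        {
            "variant_id": np.repeat(vid, n_tr),
            "chrom": np.repeat(variants["chrom"].to_numpy(), n_tr),
            "pos": np.repeat(variants["pos"].to_numpy(), n_tr),
            "trait_id": np.tile([f"T{t:02d}" for t in range(n_tr)], n_var),
            "beta": betas.ravel(),
            "pval": pvals.ravel(),
        }
    )
    return records


# ---------------------------------------------------------------------------
# pair annotations


def _simulate_pair_annotations(
    catalog: pd.DataFrame, truth_pairs: pd.DataFrame, config: SimConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """GO-like gene labels and a paralog pair list.

    Block partners are given a common term with probability ``go_rate_true``
    so that truly co-expressed pairs share annotations at an elevated rate;
    every gene additionally draws background terms at ``go_rate_background``
    per term.
    """
    rng = derive_rng(config.seed, "annotations")
    terms = [f"GO:{t:07d}" for t in range(config.go_terms)]
    rows = []
    for gene in catalog["gene_id"]:
        for term in terms:
            if rng.random() < config.go_rate_background:
                rows.append((gene, term))
    for row in truth_pairs.itertuples(index=False):
        if rng.random() < config.go_rate_true:
            term = terms[int(rng.integers(len(terms)))]
            rows.append((row.gene_a, term))
            rows.append((row.gene_b, term))
    go = pd.DataFrame(rows, columns=["gene_id", "go_id"]).drop_duplicates(
        ignore_index=True
    )

    para_rows = []
    for row in truth_pairs.itertuples(index=False):
        if rng.random() < config.paralog_rate_true:
            para_rows.append(tuple(sorted((row.gene_a, row.gene_b))))
    if config.paralog_rate_background > 0:
        genes = catalog["gene_id"].to_numpy()
        n_bg = rng.poisson(config.paralog_rate_background * len(genes))
        for _ in range(n_bg):
            a, b = rng.choice(len(genes), size=2, replace=False)
            para_rows.append(tuple(sorted((genes[a], genes[b]))))
    paralogs = pd.DataFrame(
        sorted(set(para_rows)), columns=["gene_a", "gene_b"]
    )
    return go, paralogs


# ---------------------------------------------------------------------------
# orchestration


def simulate_dataset(config: SimConfig) -> SyntheticDataset:
    """Run every generator stage in order and bundle the outputs."""
    catalog = simulate_genome(config)
    expr, truth_pairs, confounders = simulate_expression(catalog, config)
    geno, eqtl_truth, expr = simulate_genotypes_and_eqtls(
        catalog, expr, truth_pairs, config
    )
    tracks, links, hic = simulate_tracks(catalog, truth_pairs, config)
    gwas = simulate_gwas(geno.variants, eqtl_truth, config)
    go, paralogs = _simulate_pair_annotations(catalog, truth_pairs, config)
    return SyntheticDataset(
        config=config,
        catalog=catalog,
        expression=expr,
        confounders=confounders,
        truth_pairs=truth_pairs,
        genotypes=geno,
        eqtl_truth=eqtl_truth,
        tracks=tracks,
        enhancer_links=links,
        hic=hic,
        gwas=gwas,
        go_labels=go,
        paralog_pairs=paralogs,
    )


def write_dataset(ds: SyntheticDataset, outdir: str | Path) -> None:
    """Write every artifact in its standard plain-text format."""
    from . import io as lio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    lio.write_expression(ds.expression, outdir / "expression.tsv")
    lio.write_catalog_bed(ds.catalog, outdir / "genes.bed")
    lio.write_catalog_gtf(ds.catalog, outdir / "genes.gtf")
    ds.genotypes.write_vcf(outdir / "genotypes.vcf")
    for name, track in ds.tracks.items():
        lio.write_bed_track(track, outdir / f"{name}.bed")
    ds.enhancer_links.to_csv(outdir / "enhancer_links.tsv", sep="\t", index=False)
    ds.hic.to_csv(outdir / "hic.tsv", sep="\t", index=False)
    ds.gwas.to_csv(outdir / "gwas.tsv", sep="\t", index=False)
    ds.go_labels.to_csv(outdir / "go_labels.tsv", sep="\t", index=False)
    ds.paralog_pairs.to_csv(outdir / "paralog_pairs.tsv", sep="\t", index=False)
    ds.truth_pairs.to_csv(outdir / "truth_pairs.tsv", sep="\t", index=False)
    ds.eqtl_truth.to_csv(outdir / "truth_eqtls.tsv", sep="\t", index=False)
    ds.confounders.to_csv(outdir / "confounders.tsv", sep="\t")
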