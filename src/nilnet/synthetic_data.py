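"""Synthetic data with the statistical structure the analysis assumes.

The generator emulates the study design end to end: a 2-pair x 2-allele NIL
layout with unbalanced 2/1/2/2 replication (7 samples), negative-binomial
counts with planted allele-only / NIL-only / interaction / SPE effects, traits
linearly coupled to designated gene subsets over the 4 genotype classes,
promoters with a positionally biased planted motif, and gene->term annotations
with a term enriched in a chosen category.  Ground truth is recorded for
recovery tests.

Categories are assigned by partition (exact configured counts, not coin
flips), and all randomness flows from a single integer seed, so identical
config + seed gives bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data_io import (
    CountMatrix,
    GeneSetAnnotation,
    Motif,
    MotifLibrary,
    Promoter,
    PromoterSet,
    SampleDesign,
    TraitTable,
    GENOTYPE_CLASSES,
    IUPAC,
    study_design,
)

CATEGORIES = ("null", "allele", "nil", "interaction", "spe_f288", "spe_f271")


class ConfigError(ValueError):
    pass


@dataclass
class SimulationConfig:
    """Defaults reproduce the study conditions used throughout the tests."""

    n_genes: int = 2000
    # replicates per genotype class, in canonical class order; the study layout
    layout: tuple[int, int, int, int] = (2, 1, 2, 2)
    # baseline mean counts ~ LogNormal(meanlog, sdlog), natural-log scale;
    # median ~245 counts/gene, matching deep (tens of millions of reads)
    # internode RNA-seq scaled to 2,000 genes
    baseline_meanlog: float = 5.5
    baseline_sdlog: float = 1.5
    dispersion: float = 0.1
    # planted category counts (remainder of n_genes is null)
    n_allele: int = 100
    n_nil: int = 100
    n_interaction: int = 100
    n_spe_f288: int = 7
    n_spe_f271: int = 2
    # log2-scale effect sizes
    allele_log2fc: float = 2.0
    nil_log2fc: float = 2.0
    interaction_log2fc: float = 2.0
    # SPE genes: structural zero in the silent allele class, this floor on the
    # expressed-class baseline mean
    spe_min_mean: float = 50.0
    # library-size factors ~ log-uniform on [0.7, 1.4]
    lib_factor_range: tuple[float, float] = (0.7, 1.4)
    # trait model
    trait_names: tuple[str, ...] = ("IVNDFD", "Hcell/NDF", "Cell/NDF", "ADL/NDF")
    n_coupled: int = 5
    trait_noise_sd: float = 0.05
    # promoter model
    n_promoters: int = 200
    utr_min: int = 10
    utr_max: int = 100
    planted_motif: str = "CATGTG"
    plant_fraction: float = 0.5
    plant_center: float = -50.0
    plant_sd: float = 15.0
    n_decoy_motifs: int = 9
    # annotation model
    enriched_term: str = "GO:PLANTED"
    enriched_category: str = "allele"
    p_in: float = 0.9
    p_out: float = 0.05
    n_background_terms: int = 10
    p_background: float = 0.2
    seed: int = 0

    def __post_init__(self):
        n_planted = (self.n_allele + self.n_nil + self.n_interaction
                     + self.n_spe_f288 + self.n_spe_f271)
        if n_planted > self.n_genes:
            raise ConfigError("planted category counts exceed n_genes")
        if self.dispersion < 0:
            raise ConfigError("dispersion must be >= 0")
        for p in (self.p_in, self.p_out, self.p_background, self.plant_fraction):
            if not 0 <= p <= 1:
                raise ConfigError(f"probability {p} outside [0, 1]")
        if self.spe_min_mean <= 0:
            raise ConfigError("spe_min_mean must be positive")


@dataclass
class TruthTable:
    """Ground-truth labels recorded by the generator."""

    category: dict[str, str] = field(default_factory=dict)
    allele_log2fc: dict[str, float] = field(default_factory=dict)
    class_means: dict[str, np.ndarray] = field(default_factory=dict)  # gene -> (4,)
    trait_coefficients: dict[str, dict[str, float]] = field(default_factory=dict)
    motif_positions: dict[str, dict[str, int]] = field(default_factory=dict)
    annotation_probs: dict[str, tuple[float, float]] = field(default_factory=dict)

    def genes_in_category(self, category: str) -> list[str]:
        return [g for g, c in self.category.items() if c == category]


def _design_from_layout(layout) -> list[SampleDesign]:
    design = []
    for (cls, nrep) in zip(GENOTYPE_CLASSES, layout):
        pair, allele = cls.split("_")
        for rep in range(1, nrep + 1):
            design.append(SampleDesign(f"{pair}_{allele}_r{rep}", int(pair), allele, rep))
    return design


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, phi: float) -> np.ndarray:
    """NB(mean, dispersion phi) with var = mean + phi * mean^2; phi=0 -> Poisson."""
    mean = np.asarray(mean, dtype=float)
    out = np.zeros(mean.shape, dtype=np.int64)
    pos = mean > 0
    if phi == 0:
        out[pos] = rng.poisson(mean[pos])
    else:
        r = 1.0 / phi
        p = r / (r + mean[pos])
        out[pos] = rng.negative_binomial(r, p)
    return out


def class_mean_matrix(config: SimulationConfig, truth: TruthTable) -> np.ndarray:
    """(n_genes, 4) planted class means in canonical class order."""
    genes = list(truth.category)
    return np.vstack([truth.class_means[g] for g in genes])


def simulate_counts(config: SimulationConfig) -> tuple[CountMatrix, list[SampleDesign], TruthTable]:
    """Draw NB counts over the NIL layout with planted category effects.

    Allele-only genes shift the mean by the allele effect identically in both
    pairs; NIL-only genes differ between pairs but not alleles; interaction
    genes carry a pair-specific allele effect; SPE genes are structural zeros
    (mean 0) in every sample of the silent allele class.
    """
    rng = np.random.default_rng(config.seed)
    design = (_design_from_layout(config.layout) if config.layout != (2, 1, 2, 2)
              else study_design())
    n = config.n_genes
    gene_ids = [f"G{i:05d}" for i in range(n)]

    cats = (["allele"] * config.n_allele + ["nil"] * config.n_nil
            + ["interaction"] * config.n_interaction
            + ["spe_f288"] * config.n_spe_f288 + ["spe_f271"] * config.n_spe_f271)
    cats += ["null"] * (n - len(cats))

    baseline = rng.lognormal(config.baseline_meanlog, config.baseline_sdlog, size=n)
    signs = rng.choice([-1.0, 1.0], size=n)
    # interaction genes express their allele effect in one pair only
    int_pair = rng.choice([1, 2], size=n)

    truth = TruthTable()
    class_means = np.zeros((n, 4))
    for i, (gid, cat) in enumerate(zip(gene_ids, cats)):
        mu = np.full(4, baseline[i])
        fc = 0.0
        if cat == "allele":
            fc = signs[i] * config.allele_log2fc
            mu[[1, 3]] *= 2.0 ** fc  # F288 classes
        elif cat == "nil":
            mu[[2, 3]] *= 2.0 ** (signs[i] * config.nil_log2fc)  # pair-2 classes
        elif cat == "interaction":
            j = 1 if int_pair[i] == 1 else 3
            mu[j] *= 2.0 ** (signs[i] * config.interaction_log2fc)
        elif cat == "spe_f288":
            expressed = max(baseline[i], config.spe_min_mean)
            mu[:] = (0.0, expressed, 0.0, expressed)
            fc = np.inf
        elif cat == "spe_f271":
            expressed = max(baseline[i], config.spe_min_mean)
            mu[:] = (expressed, 0.0, expressed, 0.0)
            fc = -np.inf
        class_means[i] = mu
        truth.category[gid] = cat
        truth.allele_log2fc[gid] = fc
        truth.class_means[gid] = mu

    lo, hi = config.lib_factor_range
    factors = np.exp(rng.uniform(np.log(lo), np.log(hi), size=len(design)))
    cls_index = [GENOTYPE_CLASSES.index(d.genotype_class) for d in design]
    counts = np.zeros((n, len(design)), dtype=np.int64)
    for s, (d, ci) in enumerate(zip(design, cls_index)):
        counts[:, s] = _nb_draw(rng, factors[s] * class_means[:, ci], config.dispersion)
    cm = CountMatrix(gene_ids, [d.sample_id for d in design], counts)
    return cm, design, truth


def true_log_expression(truth: TruthTable) -> tuple[list[str], np.ndarray]:
    """Planted class means on the log2 scale (pseudo-count 0.5), genes x 4."""
    genes = list(truth.category)
    mat = np.log2(np.vstack([truth.class_means[g] for g in genes]) + 0.5)
    return genes, mat


def simulate_traits(truth: TruthTable, expr_means: np.ndarray, gene_ids: list[str],
                    config: SimulationConfig) -> TraitTable:
    """Traits = linear combinations of designated genes' class-mean log
    expression + Gaussian noise, over the 4 genotype classes.

    Coupled genes are drawn from the allele-effect category (the only planted
    category whose class profile separates the two allele classes in both
    pairs), so traits genuinely track the introgression.
    """
    rng = np.random.default_rng(config.seed + 1)
    idx = {g: i for i, g in enumerate(gene_ids)}
    pool = [g for g in truth.genes_in_category("allele") if g in idx]
    if not pool:
        pool = [g for g in gene_ids]
    values = np.zeros((4, len(config.trait_names)))
    for t, trait in enumerate(config.trait_names):
        k = min(config.n_coupled, len(pool))
        chosen = list(rng.choice(pool, size=k, replace=False))
        coefs = rng.choice([-1.0, 1.0], size=k)
        truth.trait_coefficients[trait] = dict(zip(chosen, coefs))
        signal = sum(c * expr_means[idx[g]] for g, c in zip(chosen, coefs))
        values[:, t] = signal + rng.normal(0.0, config.trait_noise_sd, size=4)
    for trait, coupling in truth.trait_coefficients.items():
        for g in coupling:
            if g not in truth.category:
                raise ConfigError(f"coupled gene {g!r} absent from truth")
    return TraitTable(list(config.trait_names), values)


def _instantiate_iupac(rng: np.random.Generator, pattern: str) -> str:
    return "".join(rng.choice(list(IUPAC[c])) for c in pattern.upper())


def simulate_promoters(config: SimulationConfig) -> tuple[PromoterSet, MotifLibrary, TruthTable]:
    """I.i.d. uniform ACGT promoters with a positionally biased planted motif.

    The planted motif is inserted (overwriting background) at a position drawn
    from a Gaussian centred at ``plant_center`` in a ``plant_fraction`` of
    promoters; decoy motifs are random k-mers never planted anywhere.
    """
    rng = np.random.default_rng(config.seed + 2)
    motif = config.planted_motif.upper()
    truth = TruthTable()
    truth.motif_positions[motif] = {}
    proms = []
    for i in range(config.n_promoters):
        utr = int(rng.integers(config.utr_min, config.utr_max + 1))
        length = 1000 + utr
        if len(motif) > length:
            raise ConfigError("motif longer than promoter")
        seq = rng.choice(list("ACGT"), size=length)
        if rng.random() < config.plant_fraction:
            pos = int(round(rng.normal(config.plant_center, config.plant_sd)))
            pos = int(np.clip(pos, -1000, utr - len(motif)))
            inst = _instantiate_iupac(rng, motif)
            j = pos + 1000
            seq[j: j + len(motif)] = list(inst)
            truth.motif_positions[motif][f"P{i:04d}"] = pos
        proms.append(Promoter(f"P{i:04d}", "".join(seq), utr))
    motifs = [Motif("planted", motif)]
    k = len(motif)
    seen = {motif}
    while len(motifs) < 1 + config.n_decoy_motifs:
        cand = "".join(rng.choice(list("ACGT"), size=k))
        if cand not in seen:
            seen.add(cand)
            motifs.append(Motif(f"decoy{len(motifs)}", cand))
    return PromoterSet(proms), MotifLibrary(motifs), truth


def simulate_annotations(truth: TruthTable, config: SimulationConfig) -> GeneSetAnnotation:
    """Assign an enriched term to a category's genes with probability p_in and
    to background genes with p_out; background terms are uniform noise."""
    rng = np.random.default_rng(config.seed + 3)
    genes = list(truth.category)
    if not genes:
        raise ConfigError("truth table has no genes")
    target = set(truth.genes_in_category(config.enriched_category))
    gene_terms: dict[str, set[str]] = {g: set() for g in genes}
    for g in genes:
        p = config.p_in if g in target else config.p_out
        if rng.random() < p:
            gene_terms[g].add(config.enriched_term)
        for t in range(config.n_background_terms):
            if rng.random() < config.p_background:
                gene_terms[g].add(f"GO:BG{t:03d}")
    truth.annotation_probs[config.enriched_term] = (config.p_in, config.p_out)
    # every gene stays in the universe; give term-less genes a catch-all
    for g, ts in gene_terms.items():
        if not ts:
            ts.add("GO:OTHER")
    return GeneSetAnnotation(gene_terms)


def write_truth(truth: TruthTable, path) -> None:
    import pandas as pd

    rows = [(g, c, truth.allele_log2fc.get(g, 0.0)) for g, c in truth.category.items()]
    pd.DataFrame(rows, columns=["gene_id", "category", "allele_log2fc"]).to_csv(
        path, sep="\t", index=False
    )
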