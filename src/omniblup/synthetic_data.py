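"""Synthetic inbred-panel bundles: genotypes, expression, phenotypes, annotation.

The generator emulates the statistical structure the prediction models
assume: ~200 fully homozygous lines; biallelic variants with a uniform MAF
spectrum and block LD from a first-order allele-copying process; transcripts
partially under eQTL control (a per-gene genetic variance fraction is hit
exactly by construction); and line-mean phenotypes under variant-additive,
transcript-mediated, mixed, or genome x transcriptome-interaction
architectures with an optional causal GO term. Every output is a pure
function of its configuration and seed.

In the ``mixed`` and ``gxt`` architectures the bundle draws the causal
variants from the eQTLs of the causal transcripts (a shared cis pathway), so
genome and transcriptome carry overlapping trait information — the regime in
which combined-layer models are expected to be redundant with the best
single layer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .data_io import (
    AnnotationMap,
    ExpressionMatrix,
    GenotypeMatrix,
    Panel,
    PhenotypeTable,
    align_layers,
    write_results,
)

ARCHITECTURES = ("variant_additive", "transcript_mediated", "mixed", "gxt")


@dataclass
class SimulationTruth:
    """Ground truth of one simulated phenotype."""

    causal_variants: dict[str, float]
    causal_genes: dict[str, float]
    architecture: str
    h2_target: float
    realized_fractions: dict[str, float]
    causal_term: str | None
    seed: object


@dataclass
class ExpressionTruth:
    """eQTL assignments and realized genetic fractions of simulated expression."""

    eqtl: dict[str, list[tuple[str, float]]]
    genetic_fraction_target: float
    realized_fractions: np.ndarray


@dataclass
class CausalSpec:
    """Which and how many features carry signal in a simulated phenotype."""

    n_causal_variants: int = 100
    n_causal_genes: int = 50
    n_causal_pairs: int = 50
    causal_go_genes: list[str] | None = None
    causal_gene_ids: list[str] | None = None
    causal_variant_ids: list[str] | None = None
    causal_variant_pool: list[str] | None = None
    layer_weights: dict[str, float] | None = None


def simulate_genotypes(
    n_lines: int = 200,
    p_variants: int = 5000,
    maf_range: tuple[float, float] = (0.05, 0.5),
    ld_block_size: int = 20,
    ld_copy_prob: float = 0.9,
    seed=0,
    chrom: str = "2L",
    pos_step: int = 100,
) -> GenotypeMatrix:
    """Fully homozygous dosages in {0, 2} with block LD.

    Within a block, each line's allele at a variant copies its allele at the
    previous variant with probability ``ld_copy_prob``, otherwise it is a
    fresh Bernoulli draw at that variant's allele frequency. Block boundaries
    break the chain, so variants in different blocks are independent.
    """
    if p_variants < 1:
        raise ValueError("p_variants must be >= 1")
    rng = np.random.default_rng(seed)
    freqs = rng.uniform(maf_range[0], maf_range[1], size=p_variants)
    alleles = np.empty((n_lines, p_variants), dtype=np.int8)
    for j in range(p_variants):
        fresh = (rng.random(n_lines) < freqs[j]).astype(np.int8)
        if ld_block_size > 1 and j % ld_block_size != 0:
            copy = rng.random(n_lines) < ld_copy_prob
            alleles[:, j] = np.where(copy, alleles[:, j - 1], fresh)
        else:
            alleles[:, j] = fresh
    variants = pd.DataFrame(
        {
            "id": [f"v{j:06d}" for j in range(p_variants)],
            "chrom": chrom,
            "pos": 1 + pos_step * np.arange(p_variants),
            "ref": "A",
            "alt": "T",
        }
    )
    return GenotypeMatrix(
        line_ids=[f"line_{i:04d}" for i in range(n_lines)],
        dosages=2.0 * alleles,
        variants=variants,
    )


def _orthogonal_noise(rng: np.random.Generator, signal: np.ndarray, target_sd: float) -> np.ndarray:
    """Centered Gaussian noise orthogonalized against the signal, exact sd.

    Removing the sample projection onto the signal makes realized variance
    fractions exact by construction rather than approximate.
    """
    n = len(signal)
    e = rng.standard_normal(n)
    e -= e.mean()
    s = signal - signal.mean()
    ss = float(s @ s)
    if ss > 0:
        e -= (float(e @ s) / ss) * s
    sd = e.std(ddof=1)
    if sd == 0:
        raise RuntimeError("degenerate noise draw")
    return e * (target_sd / sd)


def simulate_expression(
    G: GenotypeMatrix,
    n_genes: int = 2000,
    eqtl_per_gene: int = 5,
    genetic_fraction: float = 0.5,
    seed=0,
    base_mean: float = 3.0,
    base_mean_sd: float = 2.0,
    n_env_factors: int = 20,
    env_factor_fraction: float = 0.5,
) -> tuple[ExpressionMatrix, ExpressionTruth]:
    """log2FPKM-scale transcripts, each a linear function of its eQTLs plus noise.

    The per-gene genetic variance fraction equals ``genetic_fraction``
    exactly (signal and orthogonalized noise are rescaled to target sds).

    The non-genetic component is not independent across genes: a share
    ``env_factor_fraction`` of it loads on ``n_env_factors`` latent line-level
    environmental factors shared by all genes, giving the transcriptome the
    co-expression structure of real RNA-seq panels, where shared
    micro-environment moves many transcripts of a line together.
    """
    if eqtl_per_gene > G.n_variants:
        raise ValueError("eqtl_per_gene exceeds the number of variants")
    if not 0.0 <= genetic_fraction <= 1.0:
        raise ValueError("genetic_fraction must be in [0, 1]")
    if not 0.0 <= env_factor_fraction <= 1.0:
        raise ValueError("env_factor_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n = G.n_lines
    ids = G.variant_ids
    dos_c = G.dosages - G.dosages.mean(axis=0)
    gene_ids = [f"g{j:05d}" for j in range(n_genes)]
    abund = np.empty((n, n_genes))
    eqtl: dict[str, list[tuple[str, float]]] = {}
    realized = np.empty(n_genes)
    factors = (
        rng.standard_normal((n, n_env_factors)) if n_env_factors > 0 else None
    )
    a = env_factor_fraction if n_env_factors > 0 else 0.0
    for j in range(n_genes):
        pick = rng.choice(G.n_variants, size=eqtl_per_gene, replace=False)
        eff = rng.standard_normal(eqtl_per_gene)
        s = dos_c[:, pick] @ eff
        sd_s = s.std(ddof=1)
        if genetic_fraction > 0.0 and sd_s > 0:
            s = s * (np.sqrt(genetic_fraction) / sd_s)
            frac = genetic_fraction
        else:
            s = np.zeros(n)
            frac = 0.0
        if genetic_fraction < 1.0:
            e = np.sqrt(1.0 - a) * rng.standard_normal(n)
            if factors is not None:
                shared = factors @ rng.standard_normal(n_env_factors)
                shared = shared - shared.mean()
                e = e + np.sqrt(a) * shared / shared.std(ddof=1)
            # orthogonalize the whole environmental part against the genetic
            # signal so the realized fraction is exact
            e = e - e.mean()
            if s.std() > 0:
                e -= (float(e @ s) / float(s @ s)) * s
            e *= np.sqrt(1.0 - frac) / e.std(ddof=1)
        else:
            e = np.zeros(n)
        mean_j = rng.normal(base_mean, base_mean_sd)
        abund[:, j] = mean_j + s + e
        eqtl[gene_ids[j]] = [(ids[k], float(w)) for k, w in zip(pick, eff)]
        tot = np.var(s + e, ddof=1)
        realized[j] = float(np.var(s, ddof=1) / tot) if tot > 0 else 0.0
    E = ExpressionMatrix(
        line_ids=list(G.line_ids), abundances=abund, genes=pd.DataFrame({"id": gene_ids})
    )
    return E, ExpressionTruth(
        eqtl=eqtl, genetic_fraction_target=genetic_fraction, realized_fractions=realized
    )


def _standardized_signal(cols: np.ndarray, effects: np.ndarray) -> np.ndarray:
    """Unit-variance linear combination of standardized feature columns."""
    sd = cols.std(axis=0)
    ok = sd > 0
    Z = (cols[:, ok] - cols[:, ok].mean(axis=0)) / sd[ok]
    s = Z @ effects[ok]
    sd_s = s.std(ddof=1)
    if sd_s == 0:
        raise ValueError("degenerate causal signal (all causal features constant)")
    return s / sd_s


def simulate_phenotype(
    G: GenotypeMatrix,
    E: ExpressionMatrix | None,
    architecture: str,
    h2_target: float,
    causal_spec: CausalSpec | None = None,
    seed=0,
    trait: str = "trait",
    expression_truth: ExpressionTruth | None = None,
) -> tuple[PhenotypeTable, SimulationTruth]:
    """Line-mean phenotypes with an exact realized signal fraction.

    Architectures: ``variant_additive`` (dosage effects), ``transcript_mediated``
    (abundance effects), ``mixed`` (both), ``gxt`` (both plus products of a
    standardized causal variant and a standardized causal transcript). In
    ``mixed``/``gxt`` the causal variants default to the causal transcripts'
    eQTLs when ``expression_truth`` is supplied (shared cis pathway).
    """
    if architecture not in ARCHITECTURES:
        raise ValueError(f"unknown architecture {architecture!r}")
    if architecture != "variant_additive" and E is None:
        raise ValueError(f"architecture {architecture!r} requires an expression layer")
    if not 0.0 <= h2_target <= 1.0:
        raise ValueError("h2_target must be in [0, 1]")
    spec = causal_spec or CausalSpec()
    rng = np.random.default_rng(seed)
    n = G.n_lines

    # --- causal genes -------------------------------------------------------
    causal_genes: list[str] = []
    if architecture != "variant_additive":
        if spec.causal_gene_ids is not None:
            causal_genes = list(spec.causal_gene_ids)
        else:
            pool = spec.causal_go_genes if spec.causal_go_genes is not None else E.gene_ids
            pool = sorted(set(pool) & set(E.gene_ids))
            if spec.n_causal_genes > len(pool):
                raise ValueError("n_causal_genes exceeds the causal gene pool")
            causal_genes = sorted(rng.choice(pool, size=spec.n_causal_genes, replace=False))

    # --- causal variants ----------------------------------------------------
    causal_variants: list[str] = []
    if architecture in ("variant_additive", "mixed", "gxt"):
        if spec.causal_variant_ids is not None:
            causal_variants = list(spec.causal_variant_ids)
        else:
            vpool = spec.causal_variant_pool
            if vpool is None and architecture in ("mixed", "gxt") and expression_truth is not None:
                vpool = sorted(
                    {vid for g in causal_genes for vid, _ in expression_truth.eqtl.get(g, [])}
                )
            if vpool is None:
                vpool = G.variant_ids
            n_cv = min(spec.n_causal_variants, len(vpool))
            if n_cv == 0:
                raise ValueError("empty causal variant pool")
            causal_variants = sorted(rng.choice(sorted(vpool), size=n_cv, replace=False))

    vpos = {v: i for i, v in enumerate(G.variant_ids)}
    signals: dict[str, np.ndarray] = {}
    var_effects: dict[str, float] = {}
    gene_effects: dict[str, float] = {}

    if causal_variants:
        cols = G.dosages[:, [vpos[v] for v in causal_variants]]
        eff = rng.standard_normal(len(causal_variants))
        signals["variant"] = _standardized_signal(cols, eff)
        var_effects = dict(zip(causal_variants, map(float, eff)))
    if causal_genes:
        gpos = {g: i for i, g in enumerate(E.gene_ids)}
        cols = E.abundances[:, [gpos[g] for g in causal_genes]]
        eff = rng.standard_normal(len(causal_genes))
        signals["transcript"] = _standardized_signal(cols, eff)
        gene_effects = dict(zip(causal_genes, map(float, eff)))
    if architecture == "gxt":
        gpos = {g: i for i, g in enumerate(E.gene_ids)}
        n_pairs = spec.n_causal_pairs
        pv = rng.choice(causal_variants, size=n_pairs, replace=True)
        pg = rng.choice(causal_genes, size=n_pairs, replace=True)
        prods = np.empty((n, n_pairs))
        for t, (v, g) in enumerate(zip(pv, pg)):
            w = G.dosages[:, vpos[v]]
            z = E.abundances[:, gpos[g]]
            w = (w - w.mean()) / (w.std() if w.std() > 0 else 1.0)
            z = (z - z.mean()) / (z.std() if z.std() > 0 else 1.0)
            prods[:, t] = w * z
        signals["interaction"] = _standardized_signal(prods, rng.standard_normal(n_pairs))

    weights = {
        "variant_additive": {"variant": 1.0},
        "transcript_mediated": {"transcript": 1.0},
        "mixed": {"variant": 1.0, "transcript": 1.0},
        "gxt": {"variant": 1.0, "transcript": 1.0, "interaction": 1.0},
    }[architecture]
    if spec.layer_weights:
        weights = {k: spec.layer_weights.get(k, w) for k, w in weights.items()}

    raw = np.zeros(n)
    for name, w in weights.items():
        raw = raw + w * signals[name]

    realized: dict[str, float] = {}
    if h2_target > 0.0:
        raw = raw - raw.mean()
        scale = np.sqrt(h2_target) / raw.std(ddof=1)
        signal = raw * scale
        noise = (
            _orthogonal_noise(rng, signal, np.sqrt(1.0 - h2_target))
            if h2_target < 1.0
            else np.zeros(n)
        )
        y = signal + noise
        tot = np.var(y, ddof=1)
        realized["signal"] = float(np.var(signal, ddof=1) / tot)
        for name, w in weights.items():
            realized[name] = float(np.var(w * signals[name] * scale, ddof=1) / tot)
    else:
        y = rng.standard_normal(n)
        y = (y - y.mean()) / y.std(ddof=1)
        realized["signal"] = 0.0

    pheno = PhenotypeTable(
        line_ids=list(G.line_ids), traits=pd.DataFrame({trait: y})
    )
    truth = SimulationTruth(
        causal_variants=var_effects,
        causal_genes=gene_effects,
        architecture=architecture,
        h2_target=h2_target,
        realized_fractions=realized,
        causal_term=None,
        seed=seed,
    )
    return pheno, truth


def simulate_annotation(
    gene_ids,
    n_terms: int = 100,
    size_range: tuple[int, int] = (5, 200),
    causal_term: dict | None = None,
    seed=0,
    chrom: str = "2L",
    region_bp: int | None = None,
    gene_span_bp: int = 400,
) -> AnnotationMap:
    """Random overlapping GO terms plus tiled gene spans on a toy chromosome.

    ``causal_term`` is ``{"term_id": ..., "gene_ids": [...]}``; that term
    contains exactly the listed genes.
    """
    gene_ids = [str(g) for g in gene_ids]
    rng = np.random.default_rng(seed)
    lo, hi = size_range
    hi = min(hi, len(gene_ids))
    if lo > len(gene_ids):
        raise ValueError("term size lower bound exceeds the gene universe")

    term_genes: dict[str, list[str]] = {}
    next_i = 1
    if causal_term is not None:
        extra = set(causal_term["gene_ids"]) - set(gene_ids)
        if extra:
            raise ValueError(f"causal term genes not in the universe: {sorted(extra)[:5]}")
        term_genes[str(causal_term["term_id"])] = [str(g) for g in causal_term["gene_ids"]]
    while len(term_genes) < n_terms:
        tid = f"GO:{next_i:07d}"
        next_i += 1
        if tid in term_genes:
            continue
        size = int(rng.integers(lo, hi + 1))
        term_genes[tid] = sorted(rng.choice(gene_ids, size=size, replace=False))

    gene_to_terms: dict[str, set[str]] = {g: set() for g in gene_ids}
    for t, gs in term_genes.items():
        for g in gs:
            gene_to_terms[g].add(t)

    if region_bp is None:
        region_bp = 1000 * len(gene_ids)
    step = max(1, (region_bp - gene_span_bp) // max(1, len(gene_ids) - 1))
    gene_spans = {
        g: (chrom, 1 + j * step, j * step + gene_span_bp) for j, g in enumerate(gene_ids)
    }
    return AnnotationMap(gene_to_terms=gene_to_terms, gene_spans=gene_spans)


# ---------------------------------------------------------------------------
# bundles
# ---------------------------------------------------------------------------

@dataclass
class SimConfig:
    """Full configuration of one synthetic panel bundle."""

    n_lines: int = 200
    p_variants: int = 5000
    n_genes: int = 2000
    n_terms: int = 100
    maf_range: tuple[float, float] = (0.05, 0.5)
    ld_block_size: int = 20
    ld_copy_prob: float = 0.9
    eqtl_per_gene: int = 5
    genetic_fraction: float = 0.5
    architecture: str = "transcript_mediated"
    h2: float = 0.7
    causal: CausalSpec = field(default_factory=CausalSpec)
    term_size_range: tuple[int, int] = (5, 200)
    causal_term_id: str | None = "GO:0000001"
    causal_term_size: int = 100
    trait: str = "trait"


@dataclass
class Bundle:
    genotypes: GenotypeMatrix
    expression: ExpressionMatrix
    phenotypes: PhenotypeTable
    annotation: AnnotationMap
    truth: SimulationTruth
    expression_truth: ExpressionTruth
    config: SimConfig

    def panel(self) -> Panel:
        return align_layers(
            genotypes=self.genotypes,
            expression=self.expression,
            phenotypes=self.phenotypes,
            annotation=self.annotation,
        )


def simulate_bundle(config: SimConfig | None = None, seed: int = 0) -> Bundle:
    """Deterministic multi-layer bundle: a pure function of config + seed."""
    cfg = config or SimConfig()
    G = simulate_genotypes(
        n_lines=cfg.n_lines,
        p_variants=cfg.p_variants,
        maf_range=cfg.maf_range,
        ld_block_size=cfg.ld_block_size,
        ld_copy_prob=cfg.ld_copy_prob,
        seed=[seed, 1],
    )
    E, etruth = simulate_expression(
        G,
        n_genes=cfg.n_genes,
        eqtl_per_gene=cfg.eqtl_per_gene,
        genetic_fraction=cfg.genetic_fraction,
        seed=[seed, 2],
    )

    rng = np.random.default_rng([seed, 3])
    spec = CausalSpec(**{**cfg.causal.__dict__})
    causal_term = None
    if cfg.causal_term_id is not None:
        term_genes = sorted(
            rng.choice(E.gene_ids, size=min(cfg.causal_term_size, cfg.n_genes), replace=False)
        )
        causal_term = {"term_id": cfg.causal_term_id, "gene_ids": term_genes}
        if spec.causal_go_genes is None:
            spec.causal_go_genes = term_genes

    if cfg.architecture != "variant_additive" and spec.causal_gene_ids is None:
        pool = spec.causal_go_genes if spec.causal_go_genes is not None else E.gene_ids
        pool = sorted(set(pool))
        if spec.n_causal_genes > len(pool):
            raise ValueError("n_causal_genes exceeds the causal gene pool")
        spec.causal_gene_ids = sorted(rng.choice(pool, size=spec.n_causal_genes, replace=False))

    ann = simulate_annotation(
        E.gene_ids,
        n_terms=cfg.n_terms,
        size_range=cfg.term_size_range,
        causal_term=causal_term,
        seed=[seed, 4],
        region_bp=100 * cfg.p_variants,
    )
    pheno, truth = simulate_phenotype(
        G,
        E,
        architecture=cfg.architecture,
        h2_target=cfg.h2,
        causal_spec=spec,
        seed=[seed, 5],
        trait=cfg.trait,
        expression_truth=etruth,
    )
    truth.causal_term = cfg.causal_term_id
    return Bundle(
        genotypes=G,
        expression=E,
        phenotypes=pheno,
        annotation=ann,
        truth=truth,
        expression_truth=etruth,
        config=cfg,
    )


def write_bundle(bundle: Bundle, outdir: str | Path, genotype_format: str = "dosage_tsv") -> dict[str, Path]:
    """Emit a bundle as plain-text files (dosage/VCF, TSVs, GFF3, truth JSON)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    G = bundle.genotypes
    if genotype_format == "dosage_tsv":
        df = pd.DataFrame(G.dosages, index=G.line_ids, columns=G.variant_ids)
        paths["genotypes"] = outdir / "genotypes.tsv"
        df.to_csv(paths["genotypes"], sep="\t", na_rep="NA", index_label="line")
        paths["variants"] = outdir / "variants.tsv"
        G.variants.to_csv(paths["variants"], sep="\t", index=False)
    elif genotype_format == "vcf":
        paths["genotypes"] = _write_vcf(G, outdir / "genotypes.vcf")
    else:
        raise ValueError(f"unknown genotype format {genotype_format!r}")

    E = bundle.expression
    paths["expression"] = outdir / "expression.tsv"
    pd.DataFrame(E.abundances, index=E.line_ids, columns=E.gene_ids).to_csv(
        paths["expression"], sep="\t", index_label="line"
    )
    ph = bundle.phenotypes
    paths["phenotypes"] = outdir / "phenotypes.tsv"
    ph.traits.set_axis(ph.line_ids).to_csv(
        paths["phenotypes"], sep="\t", na_rep="NA", index_label="line"
    )
    ann = bundle.annotation
    paths["gene2go"] = outdir / "gene2go.tsv"
    with open(paths["gene2go"], "w") as fh:
        for g in sorted(ann.gene_to_terms):
            for t in sorted(ann.gene_to_terms[g]):
                fh.write(f"{g}\t{t}\n")
    paths["spans"] = outdir / "gene_spans.gff3"
    with open(paths["spans"], "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(ann.gene_spans):
            chrom, start, end = ann.gene_spans[g]
            fh.write(f"{chrom}\tomniblup\tgene\t{start}\t{end}\t.\t+\t.\tID={g}\n")
    paths["truth"] = write_results(bundle.truth, outdir / "truth.json", format="json")
    return paths


def _write_vcf(G: GenotypeMatrix, path: Path) -> Path:
    gt = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        chroms = pd.unique(G.variants["chrom"])
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(G.line_ids) + "\n")
        for j, row in G.variants.iterrows():
            calls = [
                gt.get(d, "./.") if not np.isnan(d) else "./."
                for d in G.dosages[:, j]
            ]
            fh.write(
                f"{row['chrom']}\t{row['pos']}\t{row['id']}\t{row['ref']}\t{row['alt']}"
                f"\t.\tPASS\t.\tGT\t" + "\t".join(calls) + "\n"
            )
    return path
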