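"""Synthetic fixtures: a toy gene catalog, tissue-structured expression,
an annotation DAG and PPI tables with planted co-functional modules.

The generator plants modules of genes that are simultaneously co-annotated
(shared ontology terms, pathways, interactions) and co-expressed within
tissues, so the association the classifier must learn — correlated
expression and shared annotation — is genuinely present. Module membership
drives both signals; `module_coexpression_rho` sets the target within-module
within-tissue correlation of log-scale expression and `noise_sd` the
residual noise. Protein sequences are generated independently of mRNA
sequences: the pipeline treats them as separate feature sources and never
translates.

Each planted module is annotated under its own term chain (its own root), so
after true-path propagation co-annotation stays within modules instead of
pooling every annotated gene under one giant retained root term. NOT
annotations are planted on internal chain terms so inverse propagation is
exercised.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .catalog import AMINO_ACIDS, MRNA_ALPHABET, GeneCatalog, IsoformRecord
from .exceptions import ConfigurationError
from .expression import ExpressionMatrix
from .labels import AnnotationRecord, OntologyDAG, PPIRecord

DEFAULT_TISSUES = ("heart", "liver", "kidney", "brain")


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic fixture.

    Defaults describe a desk-scale cohort: 200 genes, half single-isoform,
    4 tissues with 10 samples each (tissues below 10 samples are not worth
    correlating), 8 planted modules of 10 single-isoform genes (plus 2
    multi-isoform members), strong within-module correlation.
    """

    n_genes: int = 200
    max_isoforms_per_gene: int = 3
    single_isoform_fraction: float = 0.5
    tissues: tuple[str, ...] = DEFAULT_TISSUES
    samples_per_tissue: int = 10
    n_terms: int = 40
    dag_depth: int = 3
    not_annotation_count: int = 8
    planted_module_count: int = 8
    module_single_genes: int = 10
    module_multi_genes: int = 2
    module_coexpression_rho: float = 0.9
    module_tissue_shift: float = 0.0
    tissue_groups: tuple[tuple[str, ...], ...] = ()
    noise_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ConfigurationError("n_genes must be >= 1")
        if self.max_isoforms_per_gene < 1:
            raise ConfigurationError("max_isoforms_per_gene must be >= 1")
        if not 0.0 <= self.single_isoform_fraction <= 1.0:
            raise ConfigurationError(
                "single_isoform_fraction must lie in [0, 1]"
            )
        if self.samples_per_tissue < 2:
            raise ConfigurationError(
                "samples_per_tissue must be >= 2 (correlation over one "
                "sample is undefined)"
            )
        if not self.tissues:
            raise ConfigurationError("tissues must be nonempty")
        if len(set(self.tissues)) != len(self.tissues):
            raise ConfigurationError("tissues must be unique")
        if self.single_isoform_fraction * self.n_genes < 4:
            raise ConfigurationError(
                "single_isoform_fraction * n_genes must be >= 4 so positive "
                "pairs exist"
            )
        if self.dag_depth < 1:
            raise ConfigurationError("dag_depth must be >= 1")
        if self.n_terms < self.dag_depth:
            raise ConfigurationError("n_terms must be >= dag_depth")
        if not 0.0 < self.module_coexpression_rho <= 1.0:
            raise ConfigurationError(
                "module_coexpression_rho must lie in (0, 1]"
            )
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be nonnegative")
        if self.planted_module_count < 1:
            raise ConfigurationError("planted_module_count must be >= 1")
        grouped = [t for group in self.tissue_groups for t in group]
        if len(grouped) != len(set(grouped)):
            raise ConfigurationError("tissue_groups must be disjoint")
        unknown = set(grouped) - set(self.tissues)
        if unknown:
            raise ConfigurationError(
                f"tissue_groups name unknown tissues: {sorted(unknown)}"
            )

    def tissue_group_of(self, tissue: str) -> tuple[str, ...]:
        """The similarity group a tissue belongs to (singleton by default)."""
        for group in self.tissue_groups:
            if tissue in group:
                return tuple(group)
        return (tissue,)

    @property
    def n_single(self) -> int:
        return int(round(self.single_isoform_fraction * self.n_genes))


def _random_sequence(rng: np.random.Generator, alphabet: str, length: int) -> str:
    return "".join(rng.choice(list(alphabet), size=length))


def simulate_catalog(config: SimulationConfig) -> GeneCatalog:
    """Random gene catalog; deterministic for a fixed seed.

    The first ``n_single`` genes are single-isoform (they seed the positive
    label universe); the rest draw 2..max isoforms. Protein length is at
    least 60 residues, comfortably above the 30-residue load filter.
    """
    rng = np.random.default_rng(config.seed)
    records: list[IsoformRecord] = []
    width = max(4, len(str(config.n_genes)))
    for g in range(config.n_genes):
        gene_id = f"G{g + 1:0{width}d}"
        if g < config.n_single:
            n_iso = 1
        elif config.max_isoforms_per_gene == 1:
            n_iso = 1
        else:
            n_iso = int(rng.integers(2, config.max_isoforms_per_gene + 1))
        for j in range(n_iso):
            mrna = _random_sequence(
                rng, MRNA_ALPHABET, int(rng.integers(300, 901))
            )
            protein = _random_sequence(
                rng, AMINO_ACIDS, int(rng.integers(60, 301))
            )
            records.append(
                IsoformRecord(f"{gene_id}.{j + 1}", gene_id, mrna, protein)
            )
    return GeneCatalog(records)


@dataclass
class PlantedModules:
    """Which genes belong to which planted module (single/multi split)."""

    single: dict[int, list[str]] = field(default_factory=dict)
    multi: dict[int, list[str]] = field(default_factory=dict)

    def genes(self, module: int) -> list[str]:
        return self.single.get(module, []) + self.multi.get(module, [])

    def module_of(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for m in self.single:
            for g in self.genes(m):
                out[g] = m
        return out


def plant_modules(catalog: GeneCatalog, config: SimulationConfig) -> PlantedModules:
    """Deterministic module assignment used by expression AND annotations.

    Modules draw disjoint blocks of single-isoform genes (positives need
    co-annotated single-isoform genes) plus a few multi-isoform genes, which
    enrich the negative side. Module sizes shrink if the catalog is small.
    """
    single = catalog.single_isoform_genes()
    multi = [g for g in catalog.gene_ids if g not in set(single)]
    modules = PlantedModules()
    # prefer fewer full-size modules: undersized modules fall below the
    # downstream [10, 1000] term-size filter and produce no labels at all
    n_mod = min(
        config.planted_module_count,
        max(1, len(single) // config.module_single_genes),
    )
    per_single = min(config.module_single_genes, len(single) // n_mod)
    per_multi = min(config.module_multi_genes, len(multi) // n_mod)
    for m in range(n_mod):
        block = single[m * per_single: (m + 1) * per_single]
        if len(block) < 2:
            break
        modules.single[m] = block
        modules.multi[m] = multi[m * per_multi: (m + 1) * per_multi]
    return modules


def simulate_expression(
    catalog: GeneCatalog,
    config: SimulationConfig,
    modules: PlantedModules | None = None,
) -> ExpressionMatrix:
    """FPKM-scale expression with planted tissue-specific module correlation.

    Every module prefers one tissue (or one declared tissue group, e.g. the
    three brain regions). On the log2 scale, a member's expression in sample
    s is ``mu_i + a * u_{m,s} + noise_sd * eps`` where the shared module
    factor u ~ N(module_tissue_shift, 1) exists only in samples of the
    preferred tissue(s) and is absent (0) elsewhere: members co-vary with
    correlation rho inside the preferred tissue and are uncorrelated in the
    others. A nonzero ``module_tissue_shift`` additionally raises member
    median expression in the preferred tissue(s) (used when emulating
    tissue-enriched expression profiles; tissue specificity itself lives in
    the correlation structure, which is what the pair features measure, so
    the shift defaults to 0). With noise_sd = 0
    members track u exactly (correlation 1 in the preferred tissue);
    ``a = noise_sd * sqrt(rho / (1 - rho))`` otherwise. Pooling all samples
    shows attenuated correlation for module pairs, so the organism-wide
    feature stays informative. FPKM = 2**x - 1, floored at 0.
    """
    if len(catalog) == 0:
        raise ConfigurationError("catalog is empty")
    if modules is None:
        modules = plant_modules(catalog, config)
    rng = np.random.default_rng(config.seed + 1)
    module_of = modules.module_of()
    tissues = config.tissues
    samples = [
        f"{t}_s{j + 1}" for t in tissues for j in range(config.samples_per_tissue)
    ]
    sample_tissue = {s: s.rsplit("_s", 1)[0] for s in samples}
    rho = config.module_coexpression_rho
    if config.noise_sd == 0.0 or rho >= 1.0:
        coupling, noise = 1.0, 0.0 if config.noise_sd == 0.0 else config.noise_sd
        if rho >= 1.0:
            noise = 0.0
    else:
        coupling = config.noise_sd * np.sqrt(rho / (1.0 - rho))
        noise = config.noise_sd

    isoforms = catalog.isoform_ids
    base = {iso: 6.0 + rng.normal(0.0, 0.5) for iso in isoforms}
    n_modules = max(modules.single.keys(), default=-1) + 1
    preferred = {
        m: config.tissue_group_of(tissues[m % len(tissues)])
        for m in range(n_modules)
    }

    log_expr = np.zeros((len(isoforms), len(samples)))
    for sj, sample in enumerate(samples):
        tissue = sample_tissue[sample]
        factor = {
            m: rng.normal(config.module_tissue_shift, 1.0)
            if tissue in preferred[m] else 0.0
            for m in range(n_modules)
        }
        for ii, iso in enumerate(isoforms):
            gene = catalog.gene_of(iso)
            m = module_of.get(gene)
            if m is None:
                x = base[iso] + rng.normal(0.0, 1.0)
            elif tissue in preferred[m]:
                x = base[iso] + coupling * factor[m] + (
                    rng.normal(0.0, noise) if noise > 0 else 0.0
                )
            else:
                # marginal variance matches the preferred tissue so only the
                # correlation structure, not the spread, is tissue-specific
                x = base[iso] + rng.normal(
                    0.0, float(np.hypot(coupling, noise))
                )
            log_expr[ii, sj] = x
    fpkm = np.maximum(np.exp2(log_expr) - 1.0, 0.0)
    values = pd.DataFrame(fpkm, index=isoforms, columns=samples)
    return ExpressionMatrix(
        values=values, sample_tissue=sample_tissue, tissues=tuple(tissues)
    )


@dataclass
class SyntheticAnnotations:
    dag: OntologyDAG
    dag_edges: list[tuple[str, str, str]]  # (child, parent, relation)
    annotations: list[AnnotationRecord]
    pathways: list[AnnotationRecord]
    ppi: list[PPIRecord]
    modules: PlantedModules


def simulate_annotations(
    catalog: GeneCatalog,
    config: SimulationConfig,
    modules: PlantedModules | None = None,
) -> SyntheticAnnotations:
    """Ontology DAG + annotations (incl. NOT records), pathways and PPIs.

    Each module gets its own term chain of length ``dag_depth`` (leaf up to
    a module-private root); module genes are annotated at the leaf with
    experimental evidence codes and reach the chain by propagation. Distractor
    terms (some with excluded IEA/NAS/ND annotations) pad the ontology to
    ``n_terms``. Exactly ``not_annotation_count`` NOT records are planted on
    internal chain terms, naming genes outside the module. One pathway per
    even-indexed module and within-module PPI edges (plus records each PPI
    filter rejects) complete the label sources.
    """
    if modules is None:
        modules = plant_modules(catalog, config)
    rng = np.random.default_rng(config.seed + 2)
    depth = config.dag_depth
    module_ids = sorted(modules.single)
    edges: list[tuple[str, str, str]] = []
    terms: list[str] = []
    leaf_of: dict[int, str] = {}
    internal_of: dict[int, str] = {}
    for m in module_ids:
        chain = [f"T{m:02d}_{lvl}" for lvl in range(depth)]  # root .. leaf
        terms.extend(chain)
        for child, parent in zip(chain[1:], chain[:-1]):
            relation = "part_of" if (m + len(child)) % 5 == 0 else "is_a"
            edges.append((child, parent, relation))
        leaf_of[m] = chain[-1]
        internal_of[m] = chain[-2] if depth >= 2 else chain[-1]
    di = 0
    while len(terms) < config.n_terms:
        terms.append(f"TD{di:02d}")
        di += 1
    dag = OntologyDAG([(c, p) for c, p, _ in edges], terms=terms)

    annotations: list[AnnotationRecord] = []
    evidence_cycle = ("EXP", "IDA", "IMP")
    for m in module_ids:
        for i, gene in enumerate(sorted(modules.genes(m))):
            annotations.append(
                AnnotationRecord(
                    gene, leaf_of[m], "positive",
                    evidence_cycle[i % len(evidence_cycle)], "ontology",
                )
            )
    # distractor annotations carrying excluded evidence codes
    distractor_terms = [t for t in terms if t.startswith("TD")]
    excluded_cycle = ("IEA", "NAS", "ND")
    for i, term in enumerate(distractor_terms):
        gene = catalog.gene_ids[int(rng.integers(0, catalog.n_genes()))]
        annotations.append(
            AnnotationRecord(
                gene, term, "positive", excluded_cycle[i % 3], "ontology"
            )
        )

    module_gene_set = set(modules.module_of())
    # NOT genes prefer multi-isoform genes outside the module: the negative
    # side of the gold standard is not restricted to single-isoform genes.
    outside = sorted(
        (g for g in catalog.gene_ids if g not in module_gene_set),
        key=lambda g: (-len(catalog.isoforms_of(g)), g),
    )
    not_records: list[AnnotationRecord] = []
    for i in range(config.not_annotation_count):
        m = module_ids[i % len(module_ids)]
        pool = outside if outside else catalog.gene_ids
        gene = pool[i % len(pool)]
        not_records.append(
            AnnotationRecord(gene, internal_of[m], "NOT", "IDA", "ontology")
        )
    annotations.extend(not_records)

    pathways: list[AnnotationRecord] = []
    for m in module_ids[::2]:
        for gene in modules.genes(m):
            pathways.append(
                AnnotationRecord(gene, f"PWY{m:02d}", "positive", "NA", "pathway")
            )

    ppi: list[PPIRecord] = []
    sources = ("intact", "biogrid", "apid", "iid", "mentha")
    for m in module_ids:
        genes = modules.single[m]
        for i in range(len(genes) - 1):
            ppi.append(
                PPIRecord(
                    genes[i], genes[i + 1], sources[i % len(sources)],
                    evidence_count=2, score=0.9,
                )
            )
    if len(catalog.gene_ids) >= 4:
        g = catalog.gene_ids
        ppi.extend(
            [
                PPIRecord(g[0], g[1], "apid", evidence_count=1),  # dropped
                PPIRecord(g[0], g[2], "mentha", score=0.1),  # dropped
                PPIRecord(g[1], g[3], "iid", orthology_only=True),  # dropped
                PPIRecord(g[2], g[3], "intact", taxon_b="human"),  # dropped
            ]
        )
    return SyntheticAnnotations(
        dag=dag,
        dag_edges=edges,
        annotations=annotations,
        pathways=pathways,
        ppi=ppi,
        modules=modules,
    )
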