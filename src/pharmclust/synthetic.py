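"""Synthetic paired cell-line panels with known ground truth.

Emulates two pharmacogenomic studies profiling the same cell lines on
partially overlapping gene panels: planted co-expression modules whose
genes share a cluster-specific mean pattern, decoy genes of pure noise,
an interaction graph whose high-score communities coincide with the
planted modules, drug-response tables with cluster-shifted effects and
study-specific missingness (a quarter of IC50s unavailable in one study
and nearly half in the other, as is typical of dose-response fits that
do not reach 50% inhibition), and a binary mutation matrix with
cluster-enriched genes.

Every generator is a pure function of (config, seed); the truth bundle
records which structure was planted so recovery can be scored.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import (
    CellLineClustering,
    DrugResponseTable,
    ExpressionMatrix,
    InteractionGraph,
    MutationMatrix,
    ValidationError,
)

__all__ = [
    "GeneratorConfig", "TruthBundle",
    "generate_paired_expression", "generate_interaction_graph",
    "generate_drug_responses", "generate_mutations", "generate_bundle",
    "write_bundle",
]


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the synthetic study, with defaults mirroring the emulated
    panels at desk scale.

    ``module_shift`` is in units of ``noise_sd``; ``missing_fraction_a`` /
    ``_b`` reproduce the 25% / 45% IC50 drop-out of the two studies;
    ``drug_effect_size`` is the planted cluster shift in units of
    ``drug_noise_sd``.
    """

    n_genes: int = 2000          # genes carrying planted module structure
    n_decoy_genes: int = 500     # pure-noise genes
    n_samples: int = 300
    n_modules: int = 5
    n_clusters: int = 8
    module_shift: float = 3.0
    noise_sd: float = 1.0
    batch_shift_sd: float = 0.5
    gene_panel_overlap: float = 0.9
    n_drugs: int = 15
    drug_noise_sd: float = 1.0
    drug_effect_size: float = 2.0
    missing_fraction_a: float = 0.25
    missing_fraction_b: float = 0.45
    n_tissues: int = 24
    n_mutation_genes: int = 8
    mutation_base_rate: float = 0.1
    mutation_odds_multiplier: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_genes", "n_decoy_genes", "n_samples", "n_modules",
                     "n_clusters", "n_drugs", "n_tissues", "n_mutation_genes"):
            if getattr(self, name) < 0 or (name not in
                    ("n_decoy_genes",) and getattr(self, name) == 0):
                raise ValidationError(f"{name} must be positive")
        if self.n_modules > self.n_genes:
            raise ValidationError("n_modules cannot exceed n_genes")
        for name in ("gene_panel_overlap", "missing_fraction_a",
                     "missing_fraction_b"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} = {v} outside [0, 1]")
        if self.mutation_odds_multiplier < 1.0:
            raise ValidationError(
                "mutation_odds_multiplier must be >= 1 (enrichment only)"
            )
        b = max(1, math.ceil(math.log2(self.n_clusters)))
        # b binary code bits plus a parity bit: without the parity bit two
        # clusters could share all but one module pattern
        if self.n_modules < b + 1:
            raise ValidationError(
                f"n_modules = {self.n_modules} too small to give "
                f"{self.n_clusters} clusters distinct module patterns"
            )


@dataclass
class TruthBundle:
    """Everything that was planted, for scoring recovery."""

    config: GeneratorConfig
    gene_module: dict            # gene -> module id (decoys absent)
    modules: dict                # module id -> list of genes
    decoy_genes: list
    clusters: CellLineClustering
    tissue_labels: dict          # sample -> tissue label
    drug_effects: dict           # drug -> {"cluster", "shift", "phenotype"}
    mutation_effects: dict       # gene -> {"cluster", "odds_multiplier"}
    pattern: np.ndarray = field(default=None, repr=False)  # modules x clusters

    def to_json(self) -> str:
        payload = {
            "config": dataclasses.asdict(self.config),
            "gene_module": self.gene_module,
            "modules": {m: sorted(g) for m, g in self.modules.items()},
            "decoy_genes": sorted(self.decoy_genes),
            "clusters": dict(zip(self.clusters.sample_ids, self.clusters.labels)),
            "tissue_labels": self.tissue_labels,
            "drug_effects": self.drug_effects,
            "mutation_effects": self.mutation_effects,
            "pattern": self.pattern.tolist() if self.pattern is not None else None,
        }
        return json.dumps(payload, indent=1, sort_keys=True)


def _cluster_patterns(n_modules: int, n_clusters: int) -> np.ndarray:
    """+-1 module patterns per cluster with pairwise Hamming distance >= 2.

    Clusters are encoded in binary, extended with an overall parity bit
    and then cyclic repeats of the base bits, so any two clusters differ
    in at least two modules and module-space separation never collapses.
    """
    b = max(1, math.ceil(math.log2(n_clusters)))
    if n_modules < b + 1:
        raise ValueError(
            f"need at least {b + 1} modules for {n_clusters} clusters"
        )
    patterns = np.empty((n_modules, n_clusters))
    for c in range(n_clusters):
        bits = [(c >> i) & 1 for i in range(b)]
        code = list(bits) + [sum(bits) % 2]
        j = 0
        while len(code) < n_modules:  # complements keep module rows distinct
            code.append(1 - bits[j % b])
            j += 1
        patterns[:, c] = [2 * v - 1 for v in code[:n_modules]]
    return patterns


def generate_paired_expression(
    config: GeneratorConfig,
) -> tuple[ExpressionMatrix, ExpressionMatrix, TruthBundle]:
    """Two noisy replicate expression datasets with planted structure.

    Module genes inherit their module's cluster-specific mean shift;
    decoys are pure noise.  Dataset B shares the planted means but has
    independent noise, a per-gene batch offset, and its own gene panel
    overlapping dataset A's by ``gene_panel_overlap``.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    genes = [f"G{i:05d}" for i in range(cfg.n_genes)]
    decoys = [f"D{i:05d}" for i in range(cfg.n_decoy_genes)]
    all_genes = genes + decoys
    samples = [f"CL{i:04d}" for i in range(cfg.n_samples)]

    # planted partitions
    module_of = {g: f"M{(i % cfg.n_modules) + 1}" for i, g in enumerate(genes)}
    modules: dict[str, list[str]] = {}
    for g, m in module_of.items():
        modules.setdefault(m, []).append(g)
    cluster_idx = rng.integers(0, cfg.n_clusters, size=cfg.n_samples)
    clusters = CellLineClustering(
        sample_ids=tuple(samples),
        labels=tuple(f"K{c + 1}" for c in cluster_idx),
    )
    tissue_idx = rng.integers(0, cfg.n_tissues, size=cfg.n_samples)
    tissues = {s: f"T{t + 1}" for s, t in zip(samples, tissue_idx)}

    pattern = _cluster_patterns(cfg.n_modules, cfg.n_clusters)
    module_ids = sorted(modules, key=lambda m: int(m[1:]))
    mod_index = {m: i for i, m in enumerate(module_ids)}

    baseline = rng.normal(7.0, 1.0, size=len(all_genes))
    mean = np.tile(baseline[:, None], (1, cfg.n_samples))
    shift = cfg.module_shift * cfg.noise_sd
    for gi, g in enumerate(genes):
        mi = mod_index[module_of[g]]
        mean[gi] += shift * pattern[mi, cluster_idx]

    noise_a = rng.normal(0.0, cfg.noise_sd, size=mean.shape)
    noise_b = rng.normal(0.0, cfg.noise_sd, size=mean.shape)
    batch = rng.normal(0.0, cfg.batch_shift_sd, size=(len(all_genes), 1))
    mat_a = mean + noise_a
    mat_b = mean + batch + noise_b

    # overlapping gene panels: shared core plus study-exclusive tails
    n_total = len(all_genes)
    perm = rng.permutation(n_total)
    n_shared = int(round(cfg.gene_panel_overlap * n_total))
    shared = perm[:n_shared]
    tail = perm[n_shared:]
    only_a, only_b = tail[: len(tail) // 2], tail[len(tail) // 2:]
    idx_a = np.sort(np.concatenate([shared, only_a]).astype(int))
    idx_b = np.sort(np.concatenate([shared, only_b]).astype(int))

    names = np.array(all_genes)
    expr_a = ExpressionMatrix(pd.DataFrame(
        mat_a[idx_a], index=names[idx_a], columns=samples
    ))
    expr_b = ExpressionMatrix(pd.DataFrame(
        mat_b[idx_b], index=names[idx_b], columns=samples
    ))

    # plant drug effects: each drug shifts one cluster, alternating sign
    drug_effects = {}
    for d in range(cfg.n_drugs):
        cluster = f"K{(d % cfg.n_clusters) + 1}"
        phenotype = "sensitive" if d % 2 == 0 else "resistant"
        drug_effects[f"drug{d + 1:02d}"] = {
            "cluster": cluster,
            "shift": cfg.drug_effect_size if phenotype == "sensitive"
            else -cfg.drug_effect_size,
            "phenotype": phenotype,
        }
    mutation_effects = {
        f"MUT{m + 1}": {
            "cluster": f"K{(m % cfg.n_clusters) + 1}",
            "odds_multiplier": cfg.mutation_odds_multiplier,
        }
        for m in range(cfg.n_mutation_genes)
    }

    truth = TruthBundle(
        config=cfg,
        gene_module=module_of,
        modules=modules,
        decoy_genes=decoys,
        clusters=clusters,
        tissue_labels=tissues,
        drug_effects=drug_effects,
        mutation_effects=mutation_effects,
        pattern=pattern,
    )
    return expr_a, expr_b, truth


def generate_interaction_graph(
    truth: TruthBundle,
    within_score: float = 0.9,
    within_degree: float = 10.0,
    cross_rate: float = 0.001,
    seed: int | None = None,
) -> InteractionGraph:
    """Scored gene-gene edges whose strong communities are the modules.

    Within each planted module, random pairs are connected with scores in
    [within_score, 1] at an expected degree of ``within_degree``; across
    modules and to decoys, sparse edges carry scores below the 0.7
    pruning threshold.
    """
    if not truth.modules:
        raise ValueError("truth bundle has no modules")
    rng = np.random.default_rng(truth.config.seed + 1 if seed is None else seed)
    triples: list[tuple[str, str, float]] = []
    seen: set[frozenset] = set()
    lo, hi = within_score, min(1.0, within_score + 0.05)

    for module_genes in truth.modules.values():
        g = sorted(module_genes)
        n = len(g)
        if n < 2:
            continue
        p = min(1.0, within_degree / max(n - 1, 1))
        # ring backbone keeps every module gene connected, extra random edges
        for i in range(n):
            a, b = g[i], g[(i + 1) % n]
            key = frozenset((a, b))
            if key not in seen:
                seen.add(key)
                triples.append((a, b, float(rng.uniform(lo, hi))))
        n_extra = rng.binomial(n * (n - 1) // 2, p)
        for _ in range(n_extra):
            i, j = rng.choice(n, size=2, replace=False)
            key = frozenset((g[i], g[j]))
            if key not in seen:
                seen.add(key)
                triples.append((g[i], g[j], float(rng.uniform(lo, hi))))

    all_genes = sorted(truth.gene_module) + sorted(truth.decoy_genes)
    n_all = len(all_genes)
    n_cross = rng.binomial(n_all * (n_all - 1) // 2, cross_rate)
    for _ in range(n_cross):
        i, j = rng.choice(n_all, size=2, replace=False)
        key = frozenset((all_genes[i], all_genes[j]))
        if key not in seen:
            seen.add(key)
            triples.append((all_genes[i], all_genes[j],
                            float(rng.uniform(0.1, 0.65))))
    return InteractionGraph.from_edge_list(triples)


def generate_drug_responses(
    truth: TruthBundle, seed: int | None = None
) -> tuple[DrugResponseTable, DrugResponseTable]:
    """Paired IC50 tables sharing planted cluster effects.

    Responses are drawn on the -log10(M) sensitivity scale (baseline per
    drug around 6, i.e. 1 uM) and converted back to micromolar IC50s;
    positive planted shifts make the affected cluster more sensitive.
    Each study masks its own fraction of entries as missing.
    """
    cfg = truth.config
    rng = np.random.default_rng(cfg.seed + 2 if seed is None else seed)
    samples = list(truth.clusters.sample_ids)
    label = dict(zip(truth.clusters.sample_ids, truth.clusters.labels))
    known = set(truth.clusters.cluster_labels())
    drugs = sorted(truth.drug_effects)

    base = rng.normal(6.0, 0.5, size=len(drugs))
    tables = []
    for miss_frac in (cfg.missing_fraction_a, cfg.missing_fraction_b):
        mat = np.empty((len(drugs), len(samples)))
        for di, d in enumerate(drugs):
            eff = truth.drug_effects[d]
            if eff["cluster"] not in known:
                raise ValueError(
                    f"drug {d} references unknown cluster {eff['cluster']!r}"
                )
            shift = eff["shift"] * cfg.drug_noise_sd
            for si, s in enumerate(samples):
                mu = base[di] + (shift if label[s] == eff["cluster"] else 0.0)
                mat[di, si] = mu + rng.normal(0.0, cfg.drug_noise_sd)
        ic50_um = 10.0 ** (6.0 - mat)  # invert -log10(M), expressed in uM
        mask = rng.random(mat.shape) < miss_frac
        ic50_um[mask] = np.nan
        tables.append(DrugResponseTable(
            values=pd.DataFrame(ic50_um, index=drugs, columns=samples),
            metric="ic50_uM",
            orientation="high_is_resistant",
        ))
    return tables[0], tables[1]


def generate_mutations(
    truth: TruthBundle, seed: int | None = None
) -> MutationMatrix:
    """Binary mutation calls with cluster-enriched genes.

    Background mutation probability is the configured base rate; for an
    enriched (gene, cluster) pair the odds are multiplied, matching the
    one-sided direction of the downstream Fisher test.
    """
    cfg = truth.config
    rng = np.random.default_rng(cfg.seed + 3 if seed is None else seed)
    samples = list(truth.clusters.sample_ids)
    label = dict(zip(truth.clusters.sample_ids, truth.clusters.labels))
    genes = sorted(truth.mutation_effects)
    p0 = cfg.mutation_base_rate
    odds0 = p0 / (1.0 - p0) if p0 < 1 else np.inf
    mat = np.zeros((len(genes), len(samples)), dtype=int)
    for gi, g in enumerate(genes):
        eff = truth.mutation_effects[g]
        mult = eff["odds_multiplier"]
        if mult < 1.0:
            raise ValueError("odds multiplier must be >= 1 (enrichment only)")
        odds = odds0 * mult
        p1 = odds / (1.0 + odds) if np.isfinite(odds) else 1.0
        for si, s in enumerate(samples):
            p = p1 if label[s] == eff["cluster"] else p0
            mat[gi, si] = int(rng.random() < p)
    return MutationMatrix(pd.DataFrame(mat, index=genes, columns=samples))


def generate_bundle(config: GeneratorConfig):
    """All inputs of one paired study: expression, graph, drugs, mutations."""
    expr_a, expr_b, truth = generate_paired_expression(config)
    graph = generate_interaction_graph(truth)
    drugs_a, drugs_b = generate_drug_responses(truth)
    mutations = generate_mutations(truth)
    return {
        "expression_a": expr_a,
        "expression_b": expr_b,
        "graph": graph,
        "drugs_a": drugs_a,
        "drugs_b": drugs_b,
        "mutations": mutations,
        "truth": truth,
    }


def write_bundle(bundle: dict, out_dir: str | Path) -> dict:
    """Serialize a generated bundle to the pipeline's file formats."""
    from . import io as pio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression_a": out / "expression_a.tsv",
        "expression_b": out / "expression_b.tsv",
        "graph": out / "interactions.tsv",
        "drugs_a": out / "drugs_a.tsv",
        "drugs_b": out / "drugs_b.tsv",
        "mutations": out / "mutations.tsv",
        "tissues": out / "tissues.tsv",
        "truth": out / "truth.json",
    }
    pio.save_expression_matrix(bundle["expression_a"], paths["expression_a"])
    pio.save_expression_matrix(bundle["expression_b"], paths["expression_b"])
    pio.save_interaction_graph(bundle["graph"], paths["graph"])
    pio.save_drug_response(bundle["drugs_a"], paths["drugs_a"])
    pio.save_drug_response(bundle["drugs_b"], paths["drugs_b"])
    pio.save_mutation_matrix(bundle["mutations"], paths["mutations"])
    truth = bundle["truth"]
    pd.DataFrame({
        "sample_id": list(truth.tissue_labels),
        "tissue": list(truth.tissue_labels.values()),
    }).to_csv(paths["tissues"], sep="\t", index=False)
    paths["truth"].write_text(truth.to_json(), encoding="utf-8")
    return {k: str(v) for k, v in paths.items()}
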