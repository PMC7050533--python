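"""Synthetic benchmark corpora with planted target-phenotype truth.

The generator follows the same two-layer generative chain the method
assumes: compound descriptors d are i.i.d. standard normal; each
protein's binary activity is Bernoulli(sigma(w.d + b)) with a sparse
compound-side weight vector shared within the protein's family (so the
family-level interaction model is well-specified) and a per-protein
bias; each phenotype depends on a small planted set S_p of relevant
targets through Bernoulli(sigma(sum_{k in S_p} v t_k + c)) evaluated at
the TRUE binary activities.  Only a random fraction of compound-protein
pairs is "measured" into the interaction table, so hybrid profiles must
fall back on stage-1 predictions for the rest — emulating the sparse
coverage of real bioactivity databases.

Everything is reproducible bit-for-bit from (parameters, seed), and the
planted truth is returned so selection output can be scored for
precision/recall against S_p.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import (
    PROTEIN_FAMILIES,
    DescriptorMatrix,
    InteractionTable,
    PhenotypeTable,
    ProteinPanel,
    write_descriptor_matrix,
    write_interaction_table,
    write_phenotype_table,
)

__all__ = [
    "BenchmarkParams",
    "SyntheticTruth",
    "Benchmark",
    "generate_benchmark",
    "recovery_score",
    "write_benchmark",
]


@dataclass
class BenchmarkParams:
    """Generator settings.  Defaults define the standard benchmark:
    2000 compounds, a 20-protein panel over the six families, 10
    phenotypes each driven by 3 relevant targets with effect weight 3.
    """

    n_compounds: int = 2000
    n_compound_features: int = 32
    n_protein_features: int = 32
    n_proteins: int = 20
    n_phenotypes: int = 10
    relevant_per_phenotype: int = 3
    phenotype_effect: float = 3.0
    phenotype_bias: float | None = None  # None -> -effect * n_relevant / 2 (centred)
    cpi_weight_norm: float = 3.0
    cpi_weight_nonzeros: int = 5
    cpi_bias_mean: float = -1.0
    cpi_bias_sd: float = 0.25
    measured_fraction: float = 0.5
    label_flip_rate: float = 0.0
    equicorrelation: float = 0.0
    families: tuple[str, ...] = PROTEIN_FAMILIES

    def __post_init__(self) -> None:
        if self.n_compounds < 1 or self.n_proteins < 1:
            raise ValueError("need at least one compound and one protein")
        if self.relevant_per_phenotype > self.n_proteins:
            raise ValueError("relevant_per_phenotype cannot exceed the panel size")
        if self.cpi_weight_nonzeros > self.n_compound_features:
            raise ValueError("cpi_weight_nonzeros cannot exceed n_compound_features")
        if not 0 <= self.measured_fraction <= 1:
            raise ValueError("measured_fraction must lie in [0, 1]")
        if not 0 <= self.label_flip_rate < 1:
            raise ValueError("label_flip_rate must lie in [0, 1)")
        if not 0 <= self.equicorrelation < 1:
            raise ValueError("equicorrelation must lie in [0, 1)")


@dataclass
class SyntheticTruth:
    """The planted ground truth behind one generated corpus."""

    protein_weights: dict[str, np.ndarray]  # compound-side generating weights
    protein_biases: dict[str, float]
    phenotype_targets: dict[str, tuple[str, ...]]  # S_p per phenotype
    phenotype_effects: dict[str, float]
    phenotype_biases: dict[str, float]
    true_activities: pd.DataFrame  # compounds x proteins, the true binary t
    params: BenchmarkParams
    seed: int


@dataclass
class Benchmark:
    compounds: DescriptorMatrix
    panel: ProteinPanel
    interactions: InteractionTable
    phenotypes: PhenotypeTable
    truth: SyntheticTruth


def _sigmoid(z: np.ndarray) -> np.ndarray:
    from scipy.special import expit

    return expit(z)


def generate_benchmark(
    params: BenchmarkParams | None = None, seed: int = 0
) -> Benchmark:
    """Draw one benchmark corpus; identical (params, seed) give
    bit-identical output."""
    params = params or BenchmarkParams()
    rng = np.random.default_rng(seed)
    n, D = params.n_compounds, params.n_compound_features
    K, Dp = params.n_proteins, params.n_protein_features

    compound_ids = [f"C{i:05d}" for i in range(n)]
    protein_ids = [f"P{k:03d}" for k in range(K)]
    phenotype_ids = [f"AID{j:03d}" for j in range(params.n_phenotypes)]

    Xc = rng.standard_normal((n, D))
    if params.equicorrelation > 0:
        rho = params.equicorrelation
        common = rng.standard_normal((n, 1))
        Xc = np.sqrt(1 - rho) * Xc + np.sqrt(rho) * common
    Xp = rng.standard_normal((K, Dp))

    compounds = DescriptorMatrix(
        entity_ids=compound_ids,
        feature_names=[f"d{j}" for j in range(D)],
        values=Xc,
    )
    prot_desc = DescriptorMatrix(
        entity_ids=protein_ids,
        feature_names=[f"q{j}" for j in range(Dp)],
        values=Xp,
    )
    families = {p: params.families[k % len(params.families)] for k, p in enumerate(protein_ids)}
    panel = ProteinPanel(protein_ids=protein_ids, families=families, descriptors=prot_desc)

    # family-shared sparse compound-side weights, per-protein bias
    fam_weights: dict[str, np.ndarray] = {}
    for fam in dict.fromkeys(families.values()):
        w = np.zeros(D)
        support = rng.choice(D, size=params.cpi_weight_nonzeros, replace=False)
        vals = rng.standard_normal(params.cpi_weight_nonzeros)
        vals *= params.cpi_weight_norm / max(np.linalg.norm(vals), 1e-12)
        w[support] = vals
        fam_weights[fam] = w
    protein_weights = {p: fam_weights[families[p]] for p in protein_ids}
    protein_biases = {
        p: float(rng.normal(params.cpi_bias_mean, params.cpi_bias_sd))
        for p in protein_ids
    }

    W = np.column_stack([protein_weights[p] for p in protein_ids])  # D x K
    b = np.array([protein_biases[p] for p in protein_ids])
    t_true = (rng.random((n, K)) < _sigmoid(Xc @ W + b)).astype(int)
    if params.label_flip_rate > 0:
        flips = rng.random((n, K)) < params.label_flip_rate
        t_true = np.where(flips, 1 - t_true, t_true)

    measured = rng.random((n, K)) < params.measured_fraction
    ci, pi = np.nonzero(measured)
    inter = pd.DataFrame(
        dict(
            compound_id=[compound_ids[i] for i in ci],
            protein_id=[protein_ids[k] for k in pi],
            label=t_true[ci, pi],
        )
    )
    interactions = InteractionTable(inter)

    pheno_targets: dict[str, tuple[str, ...]] = {}
    pheno_bias: dict[str, float] = {}
    pheno_rows = []
    for aid in phenotype_ids:
        S = rng.choice(K, size=params.relevant_per_phenotype, replace=False)
        S = np.sort(S)
        pheno_targets[aid] = tuple(protein_ids[k] for k in S)
        c = (
            params.phenotype_bias
            if params.phenotype_bias is not None
            else -params.phenotype_effect * params.relevant_per_phenotype / 2.0
        )
        pheno_bias[aid] = float(c)
        logits = params.phenotype_effect * t_true[:, S].sum(axis=1) + c
        p = (rng.random(n) < _sigmoid(logits)).astype(int)
        pheno_rows.append(
            pd.DataFrame(
                dict(compound_id=compound_ids, phenotype_id=aid, label=p)
            )
        )
    phenotypes = PhenotypeTable(pd.concat(pheno_rows, ignore_index=True))

    truth = SyntheticTruth(
        protein_weights=protein_weights,
        protein_biases=protein_biases,
        phenotype_targets=pheno_targets,
        phenotype_effects={aid: params.phenotype_effect for aid in phenotype_ids},
        phenotype_biases=pheno_bias,
        true_activities=pd.DataFrame(t_true, index=compound_ids, columns=protein_ids),
        params=params,
        seed=seed,
    )
    return Benchmark(compounds, panel, interactions, phenotypes, truth)


def recovery_score(
    selected, truth: SyntheticTruth, phenotype_id: str
) -> tuple[float, float]:
    """Precision and recall of a selected protein set against the
    planted relevant set S_p.

    An empty selection scores precision 0 when S_p is non-empty
    (conservative) and (1, 1) when S_p is empty too.
    """
    if phenotype_id not in truth.phenotype_targets:
        raise KeyError(f"unknown phenotype {phenotype_id!r}")
    S = set(truth.phenotype_targets[phenotype_id])
    sel = set(selected)
    if not sel:
        return (1.0, 1.0) if not S else (0.0, 0.0)
    hits = len(sel & S)
    precision = hits / len(sel)
    recall = 1.0 if not S else hits / len(S)
    return (precision, recall)


def write_benchmark(benchmark: Benchmark, out_dir: str | Path) -> dict[str, Path]:
    """Persist all tables plus the truth file and a parameters manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "compounds": out / "compound_descriptors.tsv",
        "proteins": out / "protein_descriptors.tsv",
        "panel": out / "protein_panel.tsv",
        "interactions": out / "interactions.tsv",
        "phenotypes": out / "phenotypes.tsv",
        "truth": out / "truth.json",
        "manifest": out / "params.json",
    }
    write_descriptor_matrix(benchmark.compounds, paths["compounds"])
    write_descriptor_matrix(benchmark.panel.descriptors, paths["proteins"])
    pd.DataFrame(
        dict(
            protein_id=benchmark.panel.protein_ids,
            family=[benchmark.panel.families[p] for p in benchmark.panel.protein_ids],
        )
    ).to_csv(paths["panel"], sep="\t", index=False)
    write_interaction_table(benchmark.interactions, paths["interactions"])
    write_phenotype_table(benchmark.phenotypes, paths["phenotypes"])

    truth = benchmark.truth
    truth_payload = {
        "protein_weights": {p: w.tolist() for p, w in truth.protein_weights.items()},
        "protein_biases": truth.protein_biases,
        "phenotype_targets": {a: list(s) for a, s in truth.phenotype_targets.items()},
        "phenotype_effects": truth.phenotype_effects,
        "phenotype_biases": truth.phenotype_biases,
        "seed": truth.seed,
    }
    paths["truth"].write_text(json.dumps(truth_payload, indent=1), encoding="utf-8")
    paths["manifest"].write_text(
        json.dumps(dataclasses.asdict(truth.params), indent=1), encoding="utf-8"
    )
    return paths
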