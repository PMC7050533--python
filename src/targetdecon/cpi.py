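"""Stage 1: compound-protein interaction (CPI) models and target profiles.

Follows the chemogenomics-based virtual screening (CGBVS) scheme: one
classifier per protein family is trained on the concatenation of a
compound descriptor vector and a protein descriptor vector, so unseen
(compound, protein) pairs within the family can be scored.  Applying
the family models across a fixed protein panel turns each compound into
a *target profile* — the per-protein interaction activities (known
binary labels, predicted probabilities, or a hybrid) that stage 2
consumes as features.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from ._glm import TrainingConfig, fit_with_c_selection
from .io import DescriptorMatrix, InteractionTable, LogisticModel, ProteinPanel

__all__ = [
    "TrainingConfig",
    "TargetProfileSet",
    "PROFILE_MODES",
    "train_cpi_model",
    "train_family_models",
    "predict_interaction",
    "build_target_profiles",
    "write_profiles",
    "read_profiles",
]

PROFILE_MODES = ("binary_known", "predicted_prob", "predicted_binary", "hybrid")


@dataclass
class TargetProfileSet:
    """Per-compound activity vectors over an ordered protein panel.

    ``values[i, k]`` is compound i's activity for panel protein k: a
    known binary label, a predicted probability (the expectation of the
    binary activity under the stage-1 model), or a mixture, depending
    on ``mode``.  All entries lie in [0, 1].
    """

    compound_ids: list[str]
    protein_ids: list[str]
    values: np.ndarray
    mode: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.compound_ids), len(self.protein_ids)):
            raise ValueError("profile matrix shape mismatch")
        if self.mode not in PROFILE_MODES:
            raise ValueError(f"mode must be one of {PROFILE_MODES}")
        if self.values.size and (self.values.min() < 0 or self.values.max() > 1):
            raise ValueError("profile values must lie in [0, 1]")
        if self.mode in ("binary_known", "predicted_binary"):
            if not np.isin(self.values, (0.0, 1.0)).all():
                raise ValueError(f"mode {self.mode} requires values in {{0, 1}}")
        self._index = {c: i for i, c in enumerate(self.compound_ids)}

    def profile(self, compound_id: str) -> np.ndarray:
        return self.values[self._index[compound_id]]

    def subset_compounds(self, compound_ids) -> "TargetProfileSet":
        idx = [self._index[c] for c in compound_ids]
        return TargetProfileSet(
            list(compound_ids), list(self.protein_ids), self.values[idx], self.mode
        )

    def subset_proteins(self, protein_ids) -> "TargetProfileSet":
        pidx = {p: k for k, p in enumerate(self.protein_ids)}
        cols = [pidx[p] for p in protein_ids]
        return TargetProfileSet(
            list(self.compound_ids), list(protein_ids), self.values[:, cols], self.mode
        )


def _pair_design(
    interactions: InteractionTable,
    compound_desc: DescriptorMatrix,
    protein_desc: DescriptorMatrix,
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Concatenated [compound descriptor ; protein descriptor] design matrix."""
    recs = interactions.records
    Xc = compound_desc.rows(recs["compound_id"].tolist())
    Xp = protein_desc.rows(recs["protein_id"].tolist())
    X = np.hstack([Xc, Xp])
    y = recs["label"].to_numpy(dtype=int)
    names = [f"cmp:{f}" for f in compound_desc.feature_names] + [
        f"prt:{f}" for f in protein_desc.feature_names
    ]
    return X, y, names


def train_cpi_model(
    interactions: InteractionTable,
    compound_desc: DescriptorMatrix,
    protein_desc: DescriptorMatrix,
    config: TrainingConfig,
    family: str | None = None,
    panel: ProteinPanel | None = None,
) -> tuple[LogisticModel, pd.DataFrame]:
    """Train one CPI classifier on concatenated compound+protein descriptors.

    If ``family`` and ``panel`` are given, the interaction table is
    first restricted to that family's proteins.  The penalty C is chosen
    by ``config.cv_folds``-fold cross-validated AUC over
    ``config.c_grid`` (ties toward the smallest C) and the returned
    model is refit on all the family's data at that C.  The per-C CV
    report accompanies the model.
    """
    if family is not None:
        if panel is None:
            raise ValueError("family filtering requires a panel")
        interactions = interactions.subset_proteins(panel.proteins_in_family(family))
    if len(interactions) == 0:
        raise ValueError(f"no interaction records for family {family!r}")
    labels = interactions.records["label"]
    if labels.nunique() < 2:
        raise ValueError(
            f"family {family!r} has a single interaction class; cannot train"
        )
    X, y, names = _pair_design(interactions, compound_desc, protein_desc)
    return fit_with_c_selection(X, y, names, config)


def train_family_models(
    interactions: InteractionTable,
    panel: ProteinPanel,
    compound_desc: DescriptorMatrix,
    protein_desc: DescriptorMatrix,
    config: TrainingConfig,
) -> tuple[dict[str, LogisticModel], dict[str, pd.DataFrame]]:
    """Train one CPI model per protein family (or per protein when
    ``config.per_protein``), keyed by family name (or protein id)."""
    models: dict[str, LogisticModel] = {}
    reports: dict[str, pd.DataFrame] = {}
    if config.per_protein:
        for pid in panel.protein_ids:
            sub = interactions.subset_proteins([pid])
            models[pid], reports[pid] = train_cpi_model(
                sub, compound_desc, protein_desc, config
            )
    else:
        for fam in panel.family_names:
            models[fam], reports[fam] = train_cpi_model(
                interactions, compound_desc, protein_desc, config, family=fam, panel=panel
            )
    return models, reports


def predict_interaction(
    model: LogisticModel, compound_vec: np.ndarray, protein_vec: np.ndarray
) -> float:
    """sigma(w.[compound;protein] + b) after the stored standardization."""
    x = np.concatenate(
        [np.asarray(compound_vec, dtype=float), np.asarray(protein_vec, dtype=float)]
    )
    if x.shape[0] != model.n_features:
        raise ValueError(
            f"concatenated vector has {x.shape[0]} features, "
            f"model expects {model.n_features}"
        )
    return float(model.predict_proba(x[None, :])[0])


def _model_for_protein(
    models: dict[str, LogisticModel], panel: ProteinPanel, protein_id: str
) -> LogisticModel:
    fam = panel.family_of(protein_id)
    if protein_id in models:
        return models[protein_id]
    if fam in models:
        return models[fam]
    raise KeyError(f"no model for protein {protein_id!r} (family {fam!r})")


def build_target_profiles(
    models: dict[str, LogisticModel] | None,
    panel: ProteinPanel,
    compounds: DescriptorMatrix,
    known: InteractionTable | None,
    mode: str,
    compound_ids: list[str] | None = None,
) -> TargetProfileSet:
    """Assemble per-compound target profiles over the panel.

    Modes: ``binary_known`` uses known labels with unmeasured pairs
    encoded 0; ``predicted_prob`` scores every pair with its protein's
    family model; ``predicted_binary`` thresholds those probabilities at
    0.5; ``hybrid`` takes the known label where measured and the
    prediction elsewhere.  Each protein is scored only by its own
    family's model (or its own model under per-protein training); panel
    order defines the profile coordinate order.
    """
    if mode not in PROFILE_MODES:
        raise ValueError(f"mode must be one of {PROFILE_MODES}")
    if compound_ids is None:
        if mode == "binary_known":
            if known is None:
                raise ValueError("binary_known mode requires known interactions")
            compound_ids = known.compound_ids
        else:
            compound_ids = list(compounds.entity_ids)
    K = panel.size
    n = len(compound_ids)
    values = np.zeros((n, K))

    if mode != "binary_known":
        if models is None:
            raise ValueError(f"mode {mode!r} requires trained models")
        missing = [c for c in compound_ids if c not in compounds]
        if missing:
            raise KeyError(f"compounds without descriptors: {missing[:10]}")
        Xc = compounds.rows(compound_ids)
        if panel.descriptors is None:
            raise ValueError("prediction modes require panel protein descriptors")
        for k, pid in enumerate(panel.protein_ids):
            model = _model_for_protein(models, panel, pid)
            xp = panel.descriptors.row(pid)
            X = np.hstack([Xc, np.tile(xp, (n, 1))])
            values[:, k] = model.predict_proba(X)
        if mode == "predicted_binary":
            values = (values > 0.5).astype(float)

    if mode in ("binary_known", "hybrid") and known is not None:
        cidx = {c: i for i, c in enumerate(compound_ids)}
        pidx = {p: k for k, p in enumerate(panel.protein_ids)}
        for (c, p), lab in known.pair_labels().items():
            if c in cidx and p in pidx:
                values[cidx[c], pidx[p]] = float(lab)

    return TargetProfileSet(list(compound_ids), list(panel.protein_ids), values, mode)


# ---------------------------------------------------------------------------
# persistence: delimited matrix + sidecar metadata


def write_profiles(profiles: TargetProfileSet, path: str | Path) -> None:
    """Write profiles as a delimited matrix (rows = compounds, columns =
    panel proteins) with the mode in a sidecar ``.meta.json`` file."""
    path = Path(path)
    df = pd.DataFrame(
        profiles.values, index=profiles.compound_ids, columns=profiles.protein_ids
    )
    df.index.name = "compound_id"
    df.to_csv(path, sep="\t", float_format="%.17g")
    meta = {"mode": profiles.mode, "n_compounds": len(profiles.compound_ids)}
    path.with_suffix(path.suffix + ".meta.json").write_text(
        json.dumps(meta, indent=1), encoding="utf-8"
    )


def read_profiles(path: str | Path) -> TargetProfileSet:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col="compound_id")
    meta_path = path.with_suffix(path.suffix + ".meta.json")
    mode = "predicted_prob"
    if meta_path.exists():
        mode = json.loads(meta_path.read_text(encoding="utf-8"))["mode"]
    return TargetProfileSet(
        compound_ids=[str(c) for c in df.index],
        protein_ids=[str(p) for p in df.columns],
        values=df.to_numpy(dtype=float),
        mode=mode,
    )
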