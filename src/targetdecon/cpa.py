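"""Stage 2: phenotype classifiers over target profiles.

The probabilistic picture is a two-layer chain: a compound's descriptor
vector d determines per-target Bernoulli activities t_k through
independent logistic models, and the phenotype label p depends on the
binary target vector t through a second logistic model with weights v
and bias c.  The exact phenotype probability given d marginalizes over
all 2^K target configurations,

    P(p=1 | d) = sum_t sigma(v.t + c) * prod_k m_k^{t_k} (1-m_k)^{1-t_k},

with m_k = E[t_k | d]; this is exponential in K, so the working model
is the mean-field approximation sigma(v.m + c) — the second-stage model
evaluated at the expectation profile.  Training the mean-field model on
(profile, label) pairs minimizes the cross-entropy, equivalently the
KL divergence to the empirical label distribution up to the constant
label entropy.  The exact marginalization is retained as a small-K
oracle for validating the approximation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._glm import TrainingConfig, fit_with_c_selection
from .cpi import TargetProfileSet
from .io import LogisticModel, PhenotypeTable

__all__ = [
    "PhenotypeModel",
    "train_cpa_model",
    "predict_phenotype_meanfield",
    "predict_phenotype_exact",
    "phenotype_prediction_table",
]

#: Largest panel for which the exact 2^K marginalization is attempted.
EXACT_K_CAP = 20


@dataclass
class PhenotypeModel:
    """A logistic phenotype classifier whose features are panel proteins."""

    model: LogisticModel
    phenotype_id: str

    @property
    def protein_ids(self) -> list[str]:
        return self.model.feature_order

    @property
    def weights(self) -> np.ndarray:
        return self.model.weights

    @property
    def bias(self) -> float:
        return self.model.bias


def train_cpa_model(
    profiles: TargetProfileSet,
    phenotypes: PhenotypeTable,
    phenotype_id: str,
    config: TrainingConfig | None = None,
) -> tuple[PhenotypeModel, pd.DataFrame]:
    """Train the phenotype classifier on (target profile, label) pairs.

    This is the supervised mean-field training: the input is the profile
    (binary activities or their expectations, already in [0, 1]) and the
    label is the phenotype outcome.  Profiles are not re-standardized by
    default; pass a config with ``standardize=True`` to override.  C is
    chosen by cross-validated AUC, ties toward the smallest C.
    """
    if config is None:
        config = TrainingConfig(standardize=False)
    labels = phenotypes.labels_for(phenotype_id)
    have_profile = [c for c in labels.index if c in profiles._index]
    labels = labels.loc[have_profile]
    if labels.nunique() < 2:
        raise ValueError(
            f"phenotype {phenotype_id!r} has a single class among profiled compounds"
        )
    X = profiles.subset_compounds(list(labels.index)).values
    y = labels.to_numpy(dtype=int)
    model, report = fit_with_c_selection(X, y, list(profiles.protein_ids), config)
    return PhenotypeModel(model=model, phenotype_id=str(phenotype_id)), report


def _check_aligned(model: PhenotypeModel, profile) -> np.ndarray:
    if isinstance(profile, TargetProfileSet):
        if profile.protein_ids != model.protein_ids:
            raise ValueError("profile panel order does not match model feature order")
        return profile.values
    arr = np.atleast_2d(np.asarray(profile, dtype=float))
    if arr.shape[1] != len(model.protein_ids):
        raise ValueError(
            f"profile has {arr.shape[1]} coordinates, model expects "
            f"{len(model.protein_ids)}"
        )
    return arr


def predict_phenotype_meanfield(model: PhenotypeModel, profile) -> float | np.ndarray:
    """Mean-field phenotype probability sigma(v.t_bar + c).

    ``profile`` is one expectation vector (or a TargetProfileSet /
    stacked array, in which case a vector of probabilities is returned).
    """
    arr = _check_aligned(model, profile)
    out = model.model.predict_proba(arr)
    return float(out[0]) if arr.shape[0] == 1 and np.ndim(profile) == 1 else out


def predict_phenotype_exact(
    model: PhenotypeModel, marginals, k_cap: int = EXACT_K_CAP
) -> float:
    """Exact phenotype probability by summing over all 2^K target states.

    Treats the target coordinates as independent Bernoulli(marginal_k)
    given the compound and computes
    sum_t sigma(v.t + c) * prod_k marginal_k^{t_k} (1-marginal_k)^{1-t_k}.
    Exponential in K; refuses panels larger than ``k_cap`` (use the
    mean-field prediction instead).
    """
    m = np.asarray(marginals, dtype=float).ravel()
    K = len(model.protein_ids)
    if m.shape[0] != K:
        raise ValueError(f"expected {K} marginals, got {m.shape[0]}")
    if np.any((m < 0) | (m > 1)):
        raise ValueError("marginals must lie in [0, 1]")
    if K > k_cap:
        raise ValueError(
            f"exact marginalization over 2^{K} states exceeds the K<={k_cap} cap; "
            "use predict_phenotype_meanfield"
        )
    v, c = model.weights, model.bias
    total = 0.0
    n_states = 1 << K
    block = 1 << 16
    for start in range(0, n_states, block):
        codes = np.arange(start, min(start + block, n_states), dtype=np.int64)
        # bit k of each code -> t_k
        states = (codes[:, None] >> np.arange(K)) & 1
        probs = np.prod(np.where(states == 1, m, 1.0 - m), axis=1)
        from scipy.special import expit

        sig = expit(states @ v + c)
        total += float(probs @ sig)
    return total


def phenotype_prediction_table(
    models: list[PhenotypeModel], profiles: TargetProfileSet
) -> pd.DataFrame:
    """Mean-field scores for every (compound, phenotype) pair as a long
    table with columns compound_id, phenotype_id, score."""
    frames = []
    for pm in models:
        scores = pm.model.predict_proba(_check_aligned(pm, profiles))
        frames.append(
            pd.DataFrame(
                dict(
                    compound_id=profiles.compound_ids,
                    phenotype_id=pm.phenotype_id,
                    score=scores,
                )
            )
        )
    return pd.concat(frames, ignore_index=True)
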