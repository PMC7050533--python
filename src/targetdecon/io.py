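"""Tabular data model, file readers/writers and activity-threshold labelling.

All tables are delimited text (comma or tab, header mandatory, UTF-8).
Bioactivity measurements (Ki / EC50 / IC50 with a unit) are converted to
micromolar and binarized against a potency threshold: a pair is *active*
iff its most potent measurement is strictly below the threshold
(default 30 uM).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "DescriptorMatrix",
    "ProteinPanel",
    "InteractionTable",
    "PhenotypeTable",
    "LogisticModel",
    "PROTEIN_FAMILIES",
    "read_interaction_table",
    "read_phenotype_table",
    "read_descriptor_matrix",
    "write_descriptor_matrix",
    "save_model",
    "load_model",
    "to_micromolar",
]

#: The six target-protein families the interaction corpora are organised by.
PROTEIN_FAMILIES = (
    "GPCR",
    "kinase",
    "ion channel",
    "transporter",
    "nuclear receptor",
    "protease",
)

# Multiplicative factors taking a value in the given unit to micromolar.
_UNIT_TO_UM = {
    "m": 1e6,
    "mm": 1e3,
    "um": 1.0,
    "μm": 1.0,  # μM
    "µm": 1.0,  # µM (micro sign)
    "nm": 1e-3,
    "pm": 1e-6,
}

_ASSAY_TYPES = ("Ki", "EC50", "IC50")


def to_micromolar(value: float, unit: str) -> float:
    """Convert an affinity value in *unit* to micromolar.

    Raises ``ValueError`` for an unrecognised unit.
    """
    factor = _UNIT_TO_UM.get(str(unit).strip().lower())
    if factor is None:
        raise ValueError(f"unknown concentration unit: {unit!r}")
    return float(value) * factor


@dataclass
class DescriptorMatrix:
    """A dense real-valued entities x features table with string ids.

    Rows are compounds or proteins, columns are descriptor features
    (e.g. physicochemical descriptors or fingerprint bits). Values are
    unitless; ids must be unique and all entries finite.
    """

    entity_ids: list[str]
    feature_names: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("descriptor values must be a 2-D matrix")
        if len(self.entity_ids) != len(set(self.entity_ids)):
            dupes = {i for i in self.entity_ids if self.entity_ids.count(i) > 1}
            raise ValueError(f"duplicate entity ids: {sorted(dupes)[:5]}")
        if self.values.shape != (len(self.entity_ids), len(self.feature_names)):
            raise ValueError(
                f"shape mismatch: values {self.values.shape} vs "
                f"{len(self.entity_ids)} ids x {len(self.feature_names)} features"
            )
        if self.values.shape[1] < 1:
            raise ValueError("descriptor matrix needs at least one feature column")
        if not np.all(np.isfinite(self.values)):
            r, c = np.argwhere(~np.isfinite(self.values))[0]
            raise ValueError(
                f"non-finite descriptor value at id {self.entity_ids[r]!r}, "
                f"feature {self.feature_names[c]!r}"
            )
        self._index = {e: i for i, e in enumerate(self.entity_ids)}

    @property
    def n_entities(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def row(self, entity_id: str) -> np.ndarray:
        try:
            return self.values[self._index[entity_id]]
        except KeyError:
            raise KeyError(f"no descriptor row for id {entity_id!r}") from None

    def rows(self, entity_ids: Sequence[str]) -> np.ndarray:
        missing = [e for e in entity_ids if e not in self._index]
        if missing:
            raise KeyError(f"no descriptor rows for ids {missing[:10]}")
        idx = [self._index[e] for e in entity_ids]
        return self.values[idx]

    def __contains__(self, entity_id: str) -> bool:
        return entity_id in self._index


@dataclass
class ProteinPanel:
    """An ordered protein panel with one family label per protein.

    The order of ``protein_ids`` defines the coordinate order of every
    target profile and of phenotype-model weight vectors; it is persisted
    with any model that consumes profiles.
    """

    protein_ids: list[str]
    families: dict[str, str]
    descriptors: DescriptorMatrix | None = None

    def __post_init__(self) -> None:
        if len(self.protein_ids) != len(set(self.protein_ids)):
            raise ValueError("duplicate protein ids in panel")
        missing = [p for p in self.protein_ids if p not in self.families]
        if missing:
            raise ValueError(f"proteins without family label: {missing[:10]}")
        if self.descriptors is not None:
            absent = [p for p in self.protein_ids if p not in self.descriptors]
            if absent:
                raise ValueError(f"panel proteins without descriptors: {absent[:10]}")

    @property
    def size(self) -> int:
        return len(self.protein_ids)

    def family_of(self, protein_id: str) -> str:
        return self.families[protein_id]

    def proteins_in_family(self, family: str) -> list[str]:
        return [p for p in self.protein_ids if self.families[p] == family]

    @property
    def family_names(self) -> list[str]:
        seen: list[str] = []
        for p in self.protein_ids:
            f = self.families[p]
            if f not in seen:
                seen.append(f)
        return seen


@dataclass
class InteractionTable:
    """Binary compound-protein interaction records with provenance.

    ``records`` has columns compound_id, protein_id, label (1 active /
    0 inactive) and, when derived from affinities, value_uM, unit, type.
    One row per (compound, protein) pair.
    """

    records: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"compound_id", "protein_id", "label"}
        if not required.issubset(self.records.columns):
            raise ValueError(f"interaction table needs columns {sorted(required)}")
        if self.records.duplicated(["compound_id", "protein_id"]).any():
            raise ValueError("duplicate (compound, protein) pairs after resolution")
        labels = set(self.records["label"].unique())
        if not labels <= {0, 1}:
            raise ValueError(f"labels must be binary, got {sorted(labels)}")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def compound_ids(self) -> list[str]:
        return list(pd.unique(self.records["compound_id"]))

    def subset_proteins(self, protein_ids: Sequence[str]) -> "InteractionTable":
        keep = self.records["protein_id"].isin(set(protein_ids))
        return InteractionTable(self.records[keep].reset_index(drop=True))

    def pair_labels(self) -> dict[tuple[str, str], int]:
        return {
            (c, p): int(l)
            for c, p, l in zip(
                self.records["compound_id"],
                self.records["protein_id"],
                self.records["label"],
            )
        }


@dataclass
class PhenotypeTable:
    """Binary compound-phenotype association records."""

    records: pd.DataFrame
    metadata: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        required = {"compound_id", "phenotype_id", "label"}
        if not required.issubset(self.records.columns):
            raise ValueError(f"phenotype table needs columns {sorted(required)}")
        if self.records.duplicated(["compound_id", "phenotype_id"]).any():
            raise ValueError("duplicate (compound, phenotype) pairs")
        labels = set(self.records["label"].unique())
        if not labels <= {0, 1}:
            raise ValueError(f"labels must be binary, got {sorted(labels)}")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def phenotype_ids(self) -> list[str]:
        return list(pd.unique(self.records["phenotype_id"]))

    def labels_for(self, phenotype_id: str) -> pd.Series:
        """compound_id -> 0/1 label for one phenotype."""
        sub = self.records[self.records["phenotype_id"] == phenotype_id]
        if sub.empty:
            raise KeyError(f"unknown phenotype {phenotype_id!r}")
        return sub.set_index("compound_id")["label"].astype(int)


@dataclass
class LogisticModel:
    """A fitted linear logistic model: p = sigma(w . x_std + b).

    ``feature_order`` names the coordinates of ``weights``; inputs must
    be aligned to it.  When ``mean``/``scale`` are present, inputs are
    z-scaled with those (training-data) statistics before the dot
    product, so the stored weights live on the standardized scale.
    """

    weights: np.ndarray
    bias: float
    reg_type: str
    penalty_C: float
    feature_order: list[str]
    mean: np.ndarray | None = None
    scale: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape != (len(self.feature_order),):
            raise ValueError("weight length must equal feature_order length")
        if self.reg_type not in ("l1", "l2"):
            raise ValueError(f"reg_type must be 'l1' or 'l2', got {self.reg_type!r}")
        if not self.penalty_C > 0:
            raise ValueError("penalty_C must be positive")
        for a in ("mean", "scale"):
            v = getattr(self, a)
            if v is not None:
                v = np.asarray(v, dtype=float)
                if v.shape != self.weights.shape:
                    raise ValueError(f"{a} length must equal weight length")
                setattr(self, a, v)

    @property
    def n_features(self) -> int:
        return len(self.feature_order)

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_features:
            raise ValueError(
                f"input has {X.shape[1]} features, model expects {self.n_features}"
            )
        if self.mean is not None:
            X = (X - self.mean) / self.scale
        return X @ self.weights + self.bias

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """sigma(w.x + b) for each row, values in (0, 1)."""
        from scipy.special import expit

        return expit(self.decision_function(X))

    def weight_by_feature(self) -> dict[str, float]:
        return dict(zip(self.feature_order, self.weights.tolist()))


# ---------------------------------------------------------------------------
# readers / writers


def _read_delimited(path: str | Path) -> pd.DataFrame:
    """Read a comma- or tab-delimited table with a mandatory header."""
    return pd.read_csv(path, sep=None, engine="python", dtype=str, encoding="utf-8")


def read_interaction_table(
    path: str | Path, affinity_threshold_uM: float = 30.0
) -> InteractionTable:
    """Read and binarize a compound-protein activity table.

    Each row carries either a precomputed binary ``label`` or a measured
    affinity (``value``, ``unit``, ``type``).  Affinities are converted
    to micromolar and labelled active (1) iff strictly below
    ``affinity_threshold_uM``; a value equal to the threshold is
    inactive.  Duplicate (compound, protein) pairs are resolved by the
    most potent (minimum micromolar) measurement.  Rows with an unknown
    unit are rejected with a logged warning; a row with neither label
    nor value is a hard error naming its line number.
    """
    df = _read_delimited(path)
    for col in ("compound_id", "protein_id"):
        if col not in df.columns:
            raise ValueError(f"interaction table missing required column {col!r}")
    has_label = "label" in df.columns
    has_value = "value" in df.columns

    rows = []
    for i, rec in df.iterrows():
        line_no = i + 2  # header is line 1
        label = rec.get("label") if has_label else None
        value = rec.get("value") if has_value else None
        if label is not None and not _is_missing(label):
            lab = int(float(label))
            if lab not in (0, 1):
                raise ValueError(f"line {line_no}: label must be 0 or 1, got {label!r}")
            rows.append(
                dict(
                    compound_id=rec["compound_id"],
                    protein_id=rec["protein_id"],
                    label=lab,
                    value_uM=math.nan,
                    unit="",
                    type="",
                )
            )
        elif value is not None and not _is_missing(value):
            unit = rec.get("unit", "")
            atype = rec.get("type", "")
            try:
                v_um = to_micromolar(float(value), unit)
            except ValueError as exc:
                logger.warning("line %d rejected: %s", line_no, exc)
                continue
            rows.append(
                dict(
                    compound_id=rec["compound_id"],
                    protein_id=rec["protein_id"],
                    label=int(v_um < affinity_threshold_uM),
                    value_uM=v_um,
                    unit=str(unit),
                    type=str(atype),
                )
            )
        else:
            raise ValueError(
                f"line {line_no}: row has neither a binary label nor an affinity value"
            )

    out = pd.DataFrame(
        rows, columns=["compound_id", "protein_id", "label", "value_uM", "unit", "type"]
    )
    out = _resolve_duplicates(out)
    return InteractionTable(out)


def _is_missing(x) -> bool:
    return x is None or (isinstance(x, float) and math.isnan(x)) or str(x).strip() == ""


def _resolve_duplicates(df: pd.DataFrame) -> pd.DataFrame:
    """Keep the most potent measurement per (compound, protein) pair.

    Measured rows (finite value_uM) beat label-only rows; among measured
    rows the minimum micromolar value wins; among label-only duplicates
    an active label wins.  The result is sorted canonically so that two
    reads of row-shuffled copies of the same table are identical.
    """

    def pick(group: pd.DataFrame) -> pd.Series:
        measured = group[np.isfinite(group["value_uM"])]
        if not measured.empty:
            return measured.loc[measured["value_uM"].idxmin()]
        return group.loc[group["label"].idxmax()]

    resolved = (
        df.groupby(["compound_id", "protein_id"], sort=True, group_keys=False)
        .apply(pick, include_groups=False)
        .reset_index()
    )
    cols = ["compound_id", "protein_id", "label", "value_uM", "unit", "type"]
    resolved = resolved[cols]
    resolved["label"] = resolved["label"].astype(int)
    return resolved.reset_index(drop=True)


def read_phenotype_table(path: str | Path) -> PhenotypeTable:
    """Read a compound-phenotype association table (compound_id, phenotype_id, label)."""
    df = _read_delimited(path)
    for col in ("compound_id", "phenotype_id", "label"):
        if col not in df.columns:
            raise ValueError(f"phenotype table missing required column {col!r}")
    df = df.copy()
    df["label"] = df["label"].astype(float).astype(int)
    df = df.sort_values(["phenotype_id", "compound_id"]).reset_index(drop=True)
    return PhenotypeTable(df[["compound_id", "phenotype_id", "label"]])


def write_interaction_table(table: InteractionTable, path: str | Path) -> None:
    table.records.to_csv(path, sep="\t", index=False)


def write_phenotype_table(table: PhenotypeTable, path: str | Path) -> None:
    table.records.to_csv(path, sep="\t", index=False)


def read_descriptor_matrix(path: str | Path) -> DescriptorMatrix:
    """Read a delimited numeric table whose first column is the entity id."""
    df = pd.read_csv(path, sep=None, engine="python", encoding="utf-8")
    id_col = df.columns[0]
    ids = df[id_col].astype(str).tolist()
    if len(ids) != len(set(ids)):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate ids in descriptor table: {dupes[:5]}")
    feats = [str(c) for c in df.columns[1:]]
    try:
        values = df[df.columns[1:]].astype(float).to_numpy()
    except (TypeError, ValueError) as exc:
        raise ValueError(f"non-numeric descriptor cell: {exc}") from exc
    if not np.all(np.isfinite(values)):
        r, c = np.argwhere(~np.isfinite(values))[0]
        raise ValueError(
            f"non-finite value at id {ids[r]!r}, feature {feats[c]!r}"
        )
    return DescriptorMatrix(entity_ids=ids, feature_names=feats, values=values)


def write_descriptor_matrix(matrix: DescriptorMatrix, path: str | Path) -> None:
    df = pd.DataFrame(matrix.values, columns=matrix.feature_names)
    df.insert(0, "id", matrix.entity_ids)
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# model serialization (text JSON; floats round-trip exactly via repr)

_MODEL_FORMAT = "targetdecon-logistic-model"


def save_model(model: LogisticModel, path: str | Path, **extra) -> None:
    """Serialize a model to structured text (JSON). Extra key/values
    (e.g. phenotype_id) are stored alongside and returned by load_model."""
    payload = {
        "format": _MODEL_FORMAT,
        "reg_type": model.reg_type,
        "penalty_C": model.penalty_C,
        "bias": model.bias,
        "feature_order": list(model.feature_order),
        "weights": model.weights.tolist(),
        "mean": None if model.mean is None else model.mean.tolist(),
        "scale": None if model.scale is None else model.scale.tolist(),
    }
    overlap = set(payload) & set(extra)
    if overlap:
        raise ValueError(f"extra keys shadow model fields: {sorted(overlap)}")
    payload.update(extra)
    Path(path).write_text(json.dumps(payload, indent=1), encoding="utf-8")


def load_model(path: str | Path) -> tuple[LogisticModel, dict]:
    """Load a model saved by :func:`save_model`.

    Returns ``(model, extra)`` where ``extra`` holds any additional
    key/values stored at save time.  A corrupted or foreign file raises
    ``ValueError`` rather than yielding a silent default.
    """
    try:
        payload = json.loads(Path(path).read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise ValueError(f"cannot parse model file {path}: {exc}") from exc
    if not isinstance(payload, dict) or payload.get("format") != _MODEL_FORMAT:
        raise ValueError(f"{path} is not a serialized logistic model")
    core = {
        "weights",
        "bias",
        "reg_type",
        "penalty_C",
        "feature_order",
        "mean",
        "scale",
        "format",
    }
    model = LogisticModel(
        weights=np.asarray(payload["weights"], dtype=float),
        bias=float(payload["bias"]),
        reg_type=payload["reg_type"],
        penalty_C=float(payload["penalty_C"]),
        feature_order=[str(f) for f in payload["feature_order"]],
        mean=None if payload["mean"] is None else np.asarray(payload["mean"]),
        scale=None if payload["scale"] is None else np.asarray(payload["scale"]),
    )
    extra = {k: v for k, v in payload.items() if k not in core}
    return model, extra
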