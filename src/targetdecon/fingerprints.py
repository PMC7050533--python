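"""Open-source compound descriptors from SMILES (optional RDKit path).

Where precomputed physicochemical descriptor tables are unavailable,
compounds listed in a ``SMILES<TAB>id`` file can be featurized with
Morgan (ECFP-like) count fingerprints folded to a fixed width.  Proteins
have no analogous substitute here; protein descriptor tables must be
supplied precomputed.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .io import DescriptorMatrix

__all__ = ["read_smiles_file", "morgan_descriptors"]


def read_smiles_file(path: str | Path) -> list[tuple[str, str]]:
    """Parse a file of one ``SMILES<TAB>id`` pair per line."""
    pairs = []
    for i, line in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ValueError(f"line {i}: expected 'SMILES<TAB>id', got {line!r}")
        pairs.append((parts[0], parts[1]))
    return pairs


def morgan_descriptors(
    smiles_ids: list[tuple[str, str]], n_bits: int = 1024, radius: int = 2
) -> DescriptorMatrix:
    """Morgan count fingerprints as a compound DescriptorMatrix.

    Requires RDKit; raises ImportError with guidance if it is missing,
    and ValueError on an unparsable SMILES.
    """
    try:
        from rdkit import Chem
        from rdkit.Chem import rdFingerprintGenerator
    except ImportError as exc:  # pragma: no cover - environment dependent
        raise ImportError(
            "RDKit is required for SMILES featurization; install the 'chem' extra"
        ) from exc

    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    rows, ids = [], []
    for smiles, cid in smiles_ids:
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            raise ValueError(f"unparsable SMILES for id {cid!r}: {smiles!r}")
        fp = gen.GetCountFingerprintAsNumPy(mol)
        rows.append(np.asarray(fp, dtype=float))
        ids.append(cid)
    return DescriptorMatrix(
        entity_ids=ids,
        feature_names=[f"fp{j}" for j in range(n_bits)],
        values=np.vstack(rows),
    )
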