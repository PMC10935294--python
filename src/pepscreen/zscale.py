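"""Peptide encoding with the five z-scale amino-acid descriptors.

The z-scales are principal-component scores summarising amino-acid
physicochemical properties: z1 lipophilicity, z2 steric/spatial, z3 charge,
z4/z5 electronic properties (electronegativity, heat of formation,
electrophilicity, hardness).  A peptide of n residues is encoded as the
position-major concatenation of its per-residue 5-vectors, giving a 5n
descriptor vector — the standard layout for length-stratified z-scale QSAR.

The descriptor table ships as a versioned data file (``data/zscales.csv``),
not as constants in code.
"""
from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .proteolysis import STANDARD_AA

ZSCALE_FILE = Path(__file__).parent / "data" / "zscales.csv"
Z_COLUMNS = ["z1", "z2", "z3", "z4", "z5"]


def load_zscale_table(path: str | Path = ZSCALE_FILE) -> pd.DataFrame:
    """Load the z-scale table, indexed by one-letter residue code."""
    table = pd.read_csv(path, comment="#").set_index("residue")
    if set(table.index) != STANDARD_AA:
        raise ValueError(
            f"z-scale table {path} must cover exactly the 20 standard residues"
        )
    if list(table.columns) != Z_COLUMNS or not np.isfinite(table.values).all():
        raise ValueError(f"z-scale table {path} malformed")
    return table


_TABLE = load_zscale_table()
_VECTORS = {aa: _TABLE.loc[aa].to_numpy(float) for aa in _TABLE.index}


def encode_residue(aa: str) -> np.ndarray:
    """The (z1..z5) descriptor 5-vector of a single residue."""
    try:
        return _VECTORS[aa].copy()
    except KeyError:
        raise KeyError(
            f"unknown residue {aa!r}: not in the 20-letter standard alphabet"
        ) from None


def encode_peptide(sequence: str) -> np.ndarray:
    """Concatenated per-position descriptor vector (length 5n) of a peptide."""
    if not sequence:
        raise ValueError("cannot encode an empty peptide")
    return np.concatenate([encode_residue(aa) for aa in sequence])


def encode_peptides(sequences: Sequence[str]) -> np.ndarray:
    """Descriptor matrix (len(sequences) × 5n) for equal-length peptides."""
    lengths = {len(s) for s in sequences}
    if len(lengths) != 1:
        raise ValueError(f"peptides must share one length, got lengths {sorted(lengths)}")
    return np.vstack([encode_peptide(s) for s in sequences])


def dump_zscale_table(path: str | Path) -> None:
    """Re-serialize the packaged table (byte-identical: all values carry 2 dp)."""
    _TABLE.reset_index().to_csv(path, index=False, float_format="%.2f")
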