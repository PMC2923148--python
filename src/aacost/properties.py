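"""Per-residue property tables: atomic composition, weight, tRNA gene counts.

The bundled table covers the 20 standard amino acids with carbon, nitrogen
and sulphur atom counts of the free amino acid, molecular weight (Da) and
the *S. cerevisiae* genomic tRNA gene copy number decoding each residue.
"""
from __future__ import annotations

import importlib.resources

import pandas as pd

RESIDUES_1 = list("ARNDCQEGHILKMFPSTWYV")
#: 3-letter codes in the same order as :data:`RESIDUES_1`.
RESIDUES_3 = [
    "ala", "arg", "asn", "asp", "cys", "gln", "glu", "gly", "his", "ile",
    "leu", "lys", "met", "phe", "pro", "ser", "thr", "trp", "tyr", "val",
]
ONE_TO_THREE = dict(zip(RESIDUES_1, RESIDUES_3))
THREE_TO_ONE = {v: k for k, v in ONE_TO_THREE.items()}


class AminoAcidPropertyTable:
    """Immutable per-residue property table indexed by 1-letter code.

    Columns: ``three``, ``carbon``, ``nitrogen``, ``sulphur``,
    ``mol_weight``, ``trna_genes``.
    """

    def __init__(self, frame: pd.DataFrame):
        frame = frame.copy()
        if set(frame.index) != set(RESIDUES_1):
            raise ValueError("property table must cover exactly the 20 standard residues")
        for col in ("carbon", "nitrogen", "sulphur", "trna_genes"):
            if (frame[col] < 0).any():
                raise ValueError(f"negative values in column {col!r}")
        if (frame["mol_weight"] <= 0).any():
            raise ValueError("molecular weights must be positive")
        sulphur_bearing = set(frame.index[frame["sulphur"] > 0])
        if sulphur_bearing != {"C", "M"}:
            raise ValueError(
                "cysteine and methionine (and only they) must carry one sulphur atom"
            )
        if not (frame.loc[["C", "M"], "sulphur"] == 1).all():
            raise ValueError("cys and met must each carry exactly one sulphur atom")
        self._frame = frame

    @property
    def frame(self) -> pd.DataFrame:
        return self._frame.copy()

    def column(self, name: str) -> pd.Series:
        """One property across residues, indexed by 1-letter code."""
        return self._frame[name].copy()

    def value(self, residue: str, name: str) -> float:
        """Property ``name`` for ``residue`` (1- or 3-letter code)."""
        key = THREE_TO_ONE.get(residue.lower(), residue.upper())
        return self._frame.at[key, name]

    def __repr__(self) -> str:  # pragma: no cover
        return f"AminoAcidPropertyTable({len(self._frame)} residues)"


def load_properties() -> AminoAcidPropertyTable:
    """Load the bundled amino acid property table."""
    with importlib.resources.files("aacost.data").joinpath("aa_properties.tsv").open() as fh:
        frame = pd.read_csv(fh, sep="\t", comment="#")
    frame = frame.rename(columns={"one": "residue"}).set_index("residue")
    return AminoAcidPropertyTable(frame)
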