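"""Stoichiometric model container and I/O (tabular dialect and SBML subset).

A model is the matrix S (metabolites x reactions) with per-reaction flux
bounds, plus the annotations the cost pipeline needs: which column is the
biomass reaction, which metabolite each of the 20 amino acids corresponds to
in that column, and which exchange reactions supply glucose, ammonium and
sulphate.  Exchange reactions follow the standard convention in which a
negative flux imports the metabolite (the single stoichiometric coefficient
is negative); models using the opposite convention are handled through the
sign of that coefficient.
"""
from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .properties import RESIDUES_3

NUTRIENTS = ("glucose", "ammonium", "sulphate")

#: Synonyms used to resolve amino acid metabolites in biomass reactions.
#: Keys are 3-letter residue codes; values match normalized metabolite ids
#: (lower case, compartment suffix and ``M_`` prefix stripped).
AMINO_ACID_SYNONYMS: dict[str, set[str]] = {}
_FULL_NAMES = {
    "ala": "alanine", "arg": "arginine", "asn": "asparagine",
    "asp": "aspartate", "cys": "cysteine", "gln": "glutamine",
    "glu": "glutamate", "gly": "glycine", "his": "histidine",
    "ile": "isoleucine", "leu": "leucine", "lys": "lysine",
    "met": "methionine", "phe": "phenylalanine", "pro": "proline",
    "ser": "serine", "thr": "threonine", "trp": "tryptophan",
    "tyr": "tyrosine", "val": "valine",
}
for _code, _name in _FULL_NAMES.items():
    AMINO_ACID_SYNONYMS[_code] = {
        _code, f"{_code}__l", f"{_code}_l", f"l_{_code}", f"aa_{_code}",
        _name, f"l_{_name}", _name.replace("ate", "ic_acid"),
    }

NUTRIENT_SYNONYMS = {
    "glucose": {"glc", "glc__d", "glc_d", "d_glucose", "glucose", "glcd"},
    "ammonium": {"nh4", "nh3", "ammonium", "ammonia"},
    "sulphate": {"so4", "sulphate", "sulfate", "slf"},
}

_BIOMASS_PATTERN = re.compile(r"biomass|growth", re.IGNORECASE)
_COMPARTMENT_SUFFIX = re.compile(r"(?:\[[a-z]\]|__\d+__[a-z]__\d+__|_[a-z])$")


class ModelValidationError(ValueError):
    """The model violates a structural invariant."""


def normalize_metabolite_id(met_id: str) -> str:
    """Lower-case a metabolite id and strip ``M_`` prefix and compartment tag.

    ``"M_ala__L_c"`` and ``"L-alanine[c]"`` both normalize to a form matched
    by the residue synonym table.
    """
    s = met_id.strip().lower().replace("-", "_").replace(" ", "_")
    if s.startswith("m_"):
        s = s[2:]
    s = _COMPARTMENT_SUFFIX.sub("", s)
    return s


@dataclass
class StoichiometricModel:
    """Genome-scale (or toy) metabolic model for flux balance analysis.

    ``S`` has one row per metabolite and one column per reaction; a negative
    coefficient means the metabolite is consumed by the reaction, positive
    that it is produced.  Bounds are in mmol gDW^-1 h^-1.
    """

    metabolite_ids: list[str]
    reaction_ids: list[str]
    S: np.ndarray
    lower_bounds: np.ndarray
    upper_bounds: np.ndarray
    biomass_reaction: str
    amino_acid_map: dict[str, str] = field(default_factory=dict)
    nutrient_exchanges: dict[str, str] = field(default_factory=dict)
    uptake_sign: int = -1

    def __post_init__(self):
        self.S = np.asarray(self.S, dtype=float)
        self.lower_bounds = np.asarray(self.lower_bounds, dtype=float)
        self.upper_bounds = np.asarray(self.upper_bounds, dtype=float)
        self.validate()

    # -- indexing helpers -------------------------------------------------
    def metabolite_index(self, met_id: str) -> int:
        try:
            return self.metabolite_ids.index(met_id)
        except ValueError:
            raise KeyError(f"unknown metabolite {met_id!r}") from None

    def reaction_index(self, rxn_id: str) -> int:
        try:
            return self.reaction_ids.index(rxn_id)
        except ValueError:
            raise KeyError(f"unknown reaction {rxn_id!r}") from None

    @property
    def n_metabolites(self) -> int:
        return len(self.metabolite_ids)

    @property
    def n_reactions(self) -> int:
        return len(self.reaction_ids)

    def copy(self) -> "StoichiometricModel":
        return replace(
            self,
            metabolite_ids=list(self.metabolite_ids),
            reaction_ids=list(self.reaction_ids),
            S=self.S.copy(),
            lower_bounds=self.lower_bounds.copy(),
            upper_bounds=self.upper_bounds.copy(),
            amino_acid_map=dict(self.amino_acid_map),
            nutrient_exchanges=dict(self.nutrient_exchanges),
        )

    def exchange_coefficient(self, rxn_id: str) -> float:
        """Stoichiometric coefficient of the single metabolite an exchange touches."""
        col = self.S[:, self.reaction_index(rxn_id)]
        nz = np.flatnonzero(col)
        if len(nz) != 1:
            raise ModelValidationError(
                f"exchange reaction {rxn_id!r} touches {len(nz)} metabolites, expected 1"
            )
        return float(col[nz[0]])

    def validate(self) -> None:
        m, n = self.S.shape
        if m != len(self.metabolite_ids):
            raise ModelValidationError(
                f"S has {m} rows but {len(self.metabolite_ids)} metabolite ids"
            )
        if n != len(self.reaction_ids):
            raise ModelValidationError(
                f"S has {n} columns but {len(self.reaction_ids)} reaction ids"
            )
        if len(self.lower_bounds) != n or len(self.upper_bounds) != n:
            raise ModelValidationError("bound vectors must match the reaction count")
        if np.any(self.lower_bounds > self.upper_bounds):
            bad = [self.reaction_ids[i]
                   for i in np.flatnonzero(self.lower_bounds > self.upper_bounds)]
            raise ModelValidationError(f"lower bound exceeds upper bound for {bad}")
        if self.biomass_reaction not in self.reaction_ids:
            raise ModelValidationError(
                f"biomass reaction {self.biomass_reaction!r} not in model"
            )
        j = self.reaction_index(self.biomass_reaction)
        for residue, met in self.amino_acid_map.items():
            if residue not in RESIDUES_3:
                raise ModelValidationError(f"unknown residue code {residue!r}")
            i = self.metabolite_index(met)
            if self.S[i, j] >= 0:
                raise ModelValidationError(
                    f"biomass column does not consume {met!r} (residue {residue})"
                )
        for nutrient, rxn in self.nutrient_exchanges.items():
            if nutrient not in NUTRIENTS:
                raise ModelValidationError(f"unknown nutrient {nutrient!r}")
            self.exchange_coefficient(rxn)  # raises unless exactly one metabolite


def get_biomass_coefficient(model: StoichiometricModel, residue: str) -> float:
    """Consumption magnitude x of ``residue`` in the biomass reaction (mmol/gDW)."""
    residue = residue.lower()
    if residue not in model.amino_acid_map:
        raise KeyError(f"residue {residue!r} is not mapped in this model")
    i = model.metabolite_index(model.amino_acid_map[residue])
    j = model.reaction_index(model.biomass_reaction)
    return abs(float(model.S[i, j]))


# ---------------------------------------------------------------------------
# annotation resolution


def _detect_biomass(reaction_ids: list[str]) -> str | None:
    hits = [r for r in reaction_ids if _BIOMASS_PATTERN.search(r)]
    if not hits:
        return None
    if len(hits) > 1:
        hits.sort(key=len)
        warnings.warn(
            f"multiple biomass-like reactions {hits}; using {hits[0]!r}",
            stacklevel=3,
        )
    return hits[0]


def _resolve_amino_acids(
    metabolite_ids: list[str], S: np.ndarray, biomass_j: int
) -> dict[str, str]:
    consumed = {
        metabolite_ids[i]: normalize_metabolite_id(metabolite_ids[i])
        for i in np.flatnonzero(S[:, biomass_j] < 0)
    }
    mapping: dict[str, str] = {}
    for residue in RESIDUES_3:
        syn = AMINO_ACID_SYNONYMS[residue]
        matches = [mid for mid, norm in consumed.items() if norm in syn]
        if matches:
            mapping[residue] = sorted(matches)[0]
    return mapping


def _resolve_nutrients(model_mets: list[str], S: np.ndarray,
                       reaction_ids: list[str]) -> dict[str, str]:
    mapping: dict[str, str] = {}
    for j, rxn in enumerate(reaction_ids):
        nz = np.flatnonzero(S[:, j])
        if len(nz) != 1:
            continue
        norm = normalize_metabolite_id(model_mets[nz[0]])
        for nutrient, syns in NUTRIENT_SYNONYMS.items():
            if norm in syns and nutrient not in mapping:
                mapping[nutrient] = rxn
    return mapping


def _annotate(metabolite_ids, reaction_ids, S, lb, ub, *,
              biomass_reaction=None, amino_acid_map=None,
              nutrient_exchanges=None) -> StoichiometricModel:
    if biomass_reaction is None:
        biomass_reaction = _detect_biomass(reaction_ids)
        if biomass_reaction is None:
            raise ModelValidationError(
                "no reaction id matches the biomass pattern and no override was given"
            )
    j = reaction_ids.index(biomass_reaction)
    if amino_acid_map is None:
        amino_acid_map = _resolve_amino_acids(metabolite_ids, S, j)
        if not amino_acid_map:
            raise ModelValidationError(
                "no amino acid metabolite could be resolved in the biomass reaction"
            )
        missing = [r for r in RESIDUES_3 if r not in amino_acid_map]
        if missing:
            warnings.warn(
                f"only {len(amino_acid_map)}/20 amino acids mapped; missing: {missing}",
                stacklevel=3,
            )
    if nutrient_exchanges is None:
        nutrient_exchanges = _resolve_nutrients(metabolite_ids, S, reaction_ids)
    return StoichiometricModel(
        metabolite_ids=metabolite_ids, reaction_ids=reaction_ids, S=S,
        lower_bounds=lb, upper_bounds=ub, biomass_reaction=biomass_reaction,
        amino_acid_map=amino_acid_map, nutrient_exchanges=nutrient_exchanges,
    )


# ---------------------------------------------------------------------------
# tabular dialect


def _load_tabular(path, **overrides) -> StoichiometricModel:
    sections: dict[str, list[list[str]]] = {}
    current = None
    with open(path) as fh:
        for raw in fh:
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            if line.startswith("[") and line.endswith("]"):
                current = line[1:-1]
                sections[current] = []
                continue
            if current is None:
                raise ValueError(f"{path}: data before any section header")
            sections[current].append(line.split("\t"))
    for required in ("metabolites", "reactions", "stoichiometry"):
        if required not in sections:
            raise ValueError(f"{path}: missing [{required}] section")

    metabolite_ids = [row[0] for row in sections["metabolites"]]
    reaction_ids = [row[0] for row in sections["reactions"]]
    lb = np.array([float(row[1]) for row in sections["reactions"]])
    ub = np.array([float(row[2]) for row in sections["reactions"]])
    S = np.zeros((len(metabolite_ids), len(reaction_ids)))
    met_pos = {m: i for i, m in enumerate(metabolite_ids)}
    rxn_pos = {r: j for j, r in enumerate(reaction_ids)}
    for met, rxn, coeff in sections["stoichiometry"]:
        S[met_pos[met], rxn_pos[rxn]] = float(coeff)

    ann: dict[str, str] = {}
    aa_map: dict[str, str] = {}
    nut_map: dict[str, str] = {}
    for row in sections.get("annotations", []):
        key = row[0]
        if key == "amino_acid":
            aa_map[row[1]] = row[2]
        elif key == "nutrient":
            nut_map[row[1]] = row[2]
        else:
            ann[key] = row[1]
    overrides.setdefault("biomass_reaction", ann.get("biomass_reaction"))
    if aa_map:
        overrides.setdefault("amino_acid_map", aa_map)
    if nut_map:
        overrides.setdefault("nutrient_exchanges", nut_map)
    return _annotate(metabolite_ids, reaction_ids, S, lb, ub, **overrides)


def _write_tabular(model: StoichiometricModel, path) -> None:
    lines = ["[metabolites]"]
    lines.extend(model.metabolite_ids)
    lines.append("[reactions]")
    for rxn, lo, hi in zip(model.reaction_ids, model.lower_bounds, model.upper_bounds):
        lines.append(f"{rxn}\t{float(lo)!r}\t{float(hi)!r}")
    lines.append("[stoichiometry]")
    rows, cols = np.nonzero(model.S)
    for i, j in zip(rows, cols):
        lines.append(
            f"{model.metabolite_ids[i]}\t{model.reaction_ids[j]}\t{float(model.S[i, j])!r}"
        )
    lines.append("[annotations]")
    lines.append(f"biomass_reaction\t{model.biomass_reaction}")
    for residue in sorted(model.amino_acid_map):
        lines.append(f"amino_acid\t{residue}\t{model.amino_acid_map[residue]}")
    for nutrient in sorted(model.nutrient_exchanges):
        lines.append(f"nutrient\t{nutrient}\t{model.nutrient_exchanges[nutrient]}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# SBML subset (species, reactions, stoichiometry, fbc flux bounds)


def _load_sbml(path, **overrides) -> StoichiometricModel:
    import libsbml

    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getModel() is None or doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        raise ValueError(f"{path}: SBML parse failure")
    sbml_model = doc.getModel()
    fbc = sbml_model.getPlugin("fbc")

    metabolite_ids = [sbml_model.getSpecies(i).getId()
                      for i in range(sbml_model.getNumSpecies())
                      if not sbml_model.getSpecies(i).getBoundaryCondition()]
    met_pos = {m: i for i, m in enumerate(metabolite_ids)}
    n = sbml_model.getNumReactions()
    reaction_ids = []
    S = np.zeros((len(metabolite_ids), n))
    lb = np.full(n, -1000.0)
    ub = np.full(n, 1000.0)
    for j in range(n):
        rxn = sbml_model.getReaction(j)
        reaction_ids.append(rxn.getId())
        for k in range(rxn.getNumReactants()):
            ref = rxn.getReactant(k)
            if ref.getSpecies() in met_pos:
                S[met_pos[ref.getSpecies()], j] -= ref.getStoichiometry()
        for k in range(rxn.getNumProducts()):
            ref = rxn.getProduct(k)
            if ref.getSpecies() in met_pos:
                S[met_pos[ref.getSpecies()], j] += ref.getStoichiometry()
        rfbc = rxn.getPlugin("fbc")
        if rfbc is not None:
            for getter, arr in ((rfbc.getLowerFluxBound, lb),
                                (rfbc.getUpperFluxBound, ub)):
                pid = getter()
                if pid:
                    param = sbml_model.getParameter(pid)
                    if param is not None:
                        arr[j] = param.getValue()
        elif not rxn.getReversible():
            lb[j] = 0.0
    return _annotate(metabolite_ids, reaction_ids, S, lb, ub, **overrides)


def _write_sbml(model: StoichiometricModel, path) -> None:
    import libsbml

    ns = libsbml.SBMLNamespaces(3, 1, "fbc", 2)
    doc = libsbml.SBMLDocument(ns)
    doc.setPackageRequired("fbc", False)
    sbml_model = doc.createModel()
    sbml_model.setId("model")
    sbml_model.getPlugin("fbc").setStrict(False)
    comp = sbml_model.createCompartment()
    comp.setId("c")
    comp.setConstant(True)
    for met in model.metabolite_ids:
        sp = sbml_model.createSpecies()
        sp.setId(met)
        sp.setCompartment("c")
        sp.setHasOnlySubstanceUnits(False)
        sp.setBoundaryCondition(False)
        sp.setConstant(False)
    bound_params: dict[float, str] = {}

    def bound_param(value: float) -> str:
        if value not in bound_params:
            pid = f"fb_{len(bound_params)}"
            param = sbml_model.createParameter()
            param.setId(pid)
            param.setValue(value)
            param.setConstant(True)
            bound_params[value] = pid
        return bound_params[value]

    for j, rxn_id in enumerate(model.reaction_ids):
        rxn = sbml_model.createReaction()
        rxn.setId(rxn_id)
        rxn.setFast(False)
        rxn.setReversible(bool(model.lower_bounds[j] < 0))
        col = model.S[:, j]
        for i in np.flatnonzero(col):
            ref = rxn.createReactant() if col[i] < 0 else rxn.createProduct()
            ref.setSpecies(model.metabolite_ids[i])
            ref.setStoichiometry(abs(float(col[i])))
            ref.setConstant(True)
        rfbc = rxn.getPlugin("fbc")
        rfbc.setLowerFluxBound(bound_param(float(model.lower_bounds[j])))
        rfbc.setUpperFluxBound(bound_param(float(model.upper_bounds[j])))
    if libsbml.writeSBMLToFile(doc, str(path)) != 1:
        raise OSError(f"could not write SBML to {path}")


# ---------------------------------------------------------------------------
# public API

_DIALECTS = {"tabular", "sbml"}


def _infer_dialect(path) -> str:
    s = str(path).lower()
    return "sbml" if s.endswith((".xml", ".sbml")) else "tabular"


def load_model(path, dialect: str | None = None, *, biomass_reaction=None,
               amino_acid_map=None, nutrient_exchanges=None) -> StoichiometricModel:
    """Load and validate a model from ``path``.

    ``dialect`` is ``"sbml"`` or ``"tabular"`` (inferred from the extension
    when omitted).  The biomass reaction is auto-detected by id pattern
    unless ``biomass_reaction`` is given; amino acid metabolites and nutrient
    exchanges are resolved through the synonym tables unless explicit maps
    are passed.
    """
    dialect = dialect or _infer_dialect(path)
    if dialect not in _DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}")
    loader = _load_sbml if dialect == "sbml" else _load_tabular
    overrides = {k: v for k, v in (
        ("biomass_reaction", biomass_reaction),
        ("amino_acid_map", amino_acid_map),
        ("nutrient_exchanges", nutrient_exchanges),
    ) if v is not None}
    return loader(path, **overrides)


def write_model(model: StoichiometricModel, path, dialect: str | None = None) -> None:
    """Write ``model`` so that :func:`load_model` reproduces it."""
    if model.n_reactions == 0:
        raise ValueError("refusing to write a model with no reactions")
    model.validate()
    dialect = dialect or _infer_dialect(path)
    if dialect not in _DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}")
    (_write_sbml if dialect == "sbml" else _write_tabular)(model, path)
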