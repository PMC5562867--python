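"""Model readers and writers.

Three formats are supported:

* a documented TSV dialect — one reaction per row with columns
  ``id, equation, lower_bound, upper_bound, gene_rule, subsystem``, where
  the equation uses ``-->`` (irreversible) or ``<=>`` (reversible) and
  compartment-suffixed metabolite tokens (``2 na[u] + glc[u] --> ...``);
* SBML Level 3 with the FBC package (bounds, objective, gene rules),
  serialized through the COBRA toolbox's SBML layer;
* the COBRA .mat structure (fields rxns, mets, S, lb, ub, grRules, genes);
  other fields are ignored with a warning.

TSV carries stoichiometry, bounds, gene rules and subsystems only;
metabolite formulas and names do not round-trip through it.
"""

from __future__ import annotations

import re
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import sparse

from .model import (
    Compartment,
    CompartmentSide,
    GeneRule,
    MetabolicModel,
    Metabolite,
    Reaction,
)


class ModelParseError(ValueError):
    pass


# ----------------------------------------------------------------------
# TSV dialect
# ----------------------------------------------------------------------

_ARROWS = ("<=>", "-->", "->")
_MET_TOKEN = re.compile(r"^(?:(\d+(?:\.\d+)?(?:[eE][+-]?\d+)?)\s+)?(\S+)$")
_SUFFIX = re.compile(r"^(.*)\[([a-z])\]$")

TSV_COLUMNS = ["id", "equation", "lower_bound", "upper_bound",
               "gene_rule", "subsystem"]


def _format_side(terms: list[tuple[str, float]]) -> str:
    parts = []
    for met, coeff in terms:
        if abs(coeff - 1.0) < 1e-12:
            parts.append(met)
        else:
            parts.append(f"{coeff:.10g} {met}")
    return " + ".join(parts)


def equation_string(rxn: Reaction) -> str:
    subs = [(m, -c) for m, c in rxn.stoichiometry.items() if c < 0]
    prods = [(m, c) for m, c in rxn.stoichiometry.items() if c > 0]
    arrow = "<=>" if rxn.reversible else "-->"
    return f"{_format_side(subs)} {arrow} {_format_side(prods)}".strip()


def parse_equation(equation: str) -> tuple[dict[str, float], bool]:
    """Parse an equation string into (stoichiometry, reversible)."""
    arrow = next((a for a in _ARROWS if a in equation), None)
    if arrow is None:
        raise ModelParseError(f"no reaction arrow in equation {equation!r}")
    left, right = equation.split(arrow, 1)
    stoich: dict[str, float] = {}
    for side_text, sign in ((left, -1.0), (right, 1.0)):
        side_text = side_text.strip()
        if not side_text:
            continue
        for term in side_text.split(" + "):
            term = term.strip()
            if not term:
                continue
            m = _MET_TOKEN.match(term)
            if not m:
                raise ModelParseError(f"malformed term {term!r} in {equation!r}")
            coeff = float(m.group(1)) if m.group(1) else 1.0
            met = m.group(2)
            stoich[met] = stoich.get(met, 0.0) + sign * coeff
    stoich = {m: c for m, c in stoich.items() if c != 0.0}
    return stoich, arrow == "<=>"


_SIDE_BY_SUFFIX = {
    "u": CompartmentSide.APICAL_LUMEN,
    "e": CompartmentSide.BASOLATERAL_EXTRACELLULAR,
}

_COMPARTMENT_NAMES = {
    "c": "cytosol", "n": "nucleus", "m": "mitochondrion", "x": "peroxisome",
    "g": "Golgi", "r": "endoplasmic reticulum", "u": "intestinal lumen",
    "e": "extracellular",
}


def _register_metabolites(model: MetabolicModel, stoich: dict[str, float]) -> None:
    for met_id in stoich:
        if met_id in model.metabolites:
            continue
        m = _SUFFIX.match(met_id)
        base, comp = (m.group(1), m.group(2)) if m else (met_id, "c")
        if comp not in model.compartments:
            model.add_compartment(Compartment(
                comp, _COMPARTMENT_NAMES.get(comp, comp),
                _SIDE_BY_SUFFIX.get(comp, CompartmentSide.INTRACELLULAR)))
        model.add_metabolite(Metabolite(met_id, base, comp, base))


def write_tsv(model: MetabolicModel, path: str | Path) -> None:
    rows = []
    for rxn in model.reactions.values():
        rows.append({
            "id": rxn.id,
            "equation": equation_string(rxn),
            "lower_bound": rxn.lower_bound,
            "upper_bound": rxn.upper_bound,
            "gene_rule": rxn.gene_rule.expression,
            "subsystem": rxn.subsystem,
        })
    pd.DataFrame(rows, columns=TSV_COLUMNS).to_csv(path, sep="\t", index=False)


def read_tsv(path: str | Path, model_id: str | None = None) -> MetabolicModel:
    try:
        df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    except Exception as exc:
        raise ModelParseError(f"{path}: cannot read TSV ({exc})") from exc
    missing = [c for c in TSV_COLUMNS[:4] if c not in df.columns]
    if missing:
        raise ModelParseError(f"{path}: missing columns {missing}")

    model = MetabolicModel(model_id or Path(path).stem)
    for line_no, row in enumerate(df.itertuples(index=False), start=2):
        try:
            stoich, _rev = parse_equation(row.equation)
            _register_metabolites(model, stoich)
            rxn = Reaction(
                row.id, stoich,
                float(row.lower_bound), float(row.upper_bound),
                GeneRule(getattr(row, "gene_rule", "") or ""),
                getattr(row, "subsystem", "") or "",
                is_exchange=len(stoich) == 1,
            )
            model.add_reaction(rxn)
        except (ValueError, KeyError) as exc:
            raise ModelParseError(
                f"{path}: line {line_no} (reaction {row.id!r}): {exc}") from exc
    return model


# ----------------------------------------------------------------------
# cobra interoperability + SBML
# ----------------------------------------------------------------------


def to_cobra(model: MetabolicModel):
    """Convert to a cobra.Model (used for SBML serialization and as an
    independent solver route in cross-validation)."""
    import cobra

    cm = cobra.Model(model.id)
    mets = {}
    for met in model.metabolites.values():
        m = cobra.Metabolite(
            _sanitize(met.id), name=met.name or met.base_id,
            compartment=met.compartment, formula=met.formula)
        mets[met.id] = m
    cm.add_metabolites(list(mets.values()))
    for rxn in model.reactions.values():
        r = cobra.Reaction(_sanitize(rxn.id), name=rxn.name or rxn.id,
                           subsystem=rxn.subsystem)
        cm.add_reactions([r])
        r.add_metabolites({mets[m]: c for m, c in rxn.stoichiometry.items()})
        r.lower_bound = rxn.lower_bound
        r.upper_bound = rxn.upper_bound
        if not rxn.gene_rule.is_empty():
            r.gene_reaction_rule = rxn.gene_rule.expression
    if model.objective is not None:
        obj_rxn, direction = model.objective
        cm.objective = cm.reactions.get_by_id(_sanitize(obj_rxn))
        cm.objective_direction = ("max" if direction.value == "maximize"
                                  else "min")
    return cm


def _sanitize(token: str) -> str:
    # SBML ids cannot contain brackets; use the COBRA _x suffix style
    return token.replace("[", "_").replace("]", "")


def _unsanitize_met(token: str) -> str:
    m = re.match(r"^(.*)_([a-z])$", token)
    return f"{m.group(1)}[{m.group(2)}]" if m else token


def from_cobra(cm) -> MetabolicModel:
    from .model import Direction

    model = MetabolicModel(cm.id or "model")
    for comp_id, comp_name in (cm.compartments or {}).items():
        model.add_compartment(Compartment(
            comp_id, comp_name or comp_id,
            _SIDE_BY_SUFFIX.get(comp_id, CompartmentSide.INTRACELLULAR)))
    for met in cm.metabolites:
        comp = met.compartment or "c"
        if comp not in model.compartments:
            model.add_compartment(Compartment(
                comp, comp, _SIDE_BY_SUFFIX.get(comp, CompartmentSide.INTRACELLULAR)))
        mid = _unsanitize_met(met.id)
        model.add_metabolite(Metabolite(mid, mid.rsplit("[", 1)[0], comp,
                                        met.name or "", met.formula))
    for rxn in cm.reactions:
        stoich = {_unsanitize_met(m.id): c for m, c in rxn.metabolites.items()}
        model.add_reaction(Reaction(
            rxn.id, stoich, rxn.lower_bound, rxn.upper_bound,
            GeneRule(rxn.gene_reaction_rule or ""), rxn.subsystem or "",
            is_exchange=len(stoich) == 1, name=rxn.name or ""))
    return model


def write_sbml(model: MetabolicModel, path: str | Path) -> None:
    from cobra.io import write_sbml_model

    write_sbml_model(to_cobra(model), str(path))


def read_sbml(path: str | Path) -> MetabolicModel:
    from cobra.io import read_sbml_model

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cm = read_sbml_model(str(path))
    except Exception as exc:
        raise ModelParseError(f"{path}: cannot parse SBML ({exc})") from exc
    return from_cobra(cm)


# ----------------------------------------------------------------------
# COBRA .mat structure
# ----------------------------------------------------------------------


def _mat_cell_to_list(arr) -> list[str]:
    out = []
    for item in np.ravel(arr):
        while isinstance(item, np.ndarray):
            item = item[0] if item.size else ""
        out.append(str(item) if item is not None else "")
    return out


def read_mat(path: str | Path, model_id: str | None = None) -> MetabolicModel:
    """Read a COBRA-toolbox .mat model (rxns, mets, S, lb, ub, grRules).

    Only the listed fields are interpreted; any other struct fields are
    ignored with a warning.
    """
    from scipy.io import loadmat

    try:
        raw = loadmat(str(path), simplify_cells=False)
    except Exception as exc:
        raise ModelParseError(f"{path}: cannot read .mat file ({exc})") from exc

    struct_names = [k for k in raw if not k.startswith("__")]
    if not struct_names:
        raise ModelParseError(f"{path}: no model struct found")
    struct = raw[struct_names[0]]
    # loadmat returns a 1x1 structured (record) array; unwrap to the record
    while isinstance(struct, np.ndarray) and struct.size == 1 and (
            struct.dtype == object or struct.dtype.names):
        if struct.dtype.names and struct.shape == ():
            break
        struct = struct.flat[0]

    fields = struct.dtype.names or ()
    needed = {"rxns", "mets", "S", "lb", "ub"}
    missing = needed - set(fields)
    if missing:
        raise ModelParseError(f"{path}: missing COBRA fields {sorted(missing)}")
    known = needed | {"grRules", "genes", "rxnNames", "metNames", "subSystems"}
    extra = set(fields) - known
    if extra:
        warnings.warn(f"{path}: ignoring unsupported .mat fields {sorted(extra)}")

    rxn_ids = _mat_cell_to_list(struct["rxns"])
    met_ids = _mat_cell_to_list(struct["mets"])
    S = sparse.csc_matrix(struct["S"][0, 0] if isinstance(struct["S"], np.ndarray)
                          and struct["S"].dtype == object else struct["S"])
    lb = np.ravel(struct["lb"]).astype(float)
    ub = np.ravel(struct["ub"]).astype(float)
    gr_rules = (_mat_cell_to_list(struct["grRules"]) if "grRules" in fields
                else [""] * len(rxn_ids))
    genes = _mat_cell_to_list(struct["genes"]) if "genes" in fields else []

    if S.shape != (len(met_ids), len(rxn_ids)):
        raise ModelParseError(
            f"{path}: S shape {S.shape} inconsistent with "
            f"{len(met_ids)} mets x {len(rxn_ids)} rxns")

    model = MetabolicModel(model_id or Path(path).stem)
    for mid in met_ids:
        m = _SUFFIX.match(mid)
        base, comp = (m.group(1), m.group(2)) if m else (mid, "c")
        if comp not in model.compartments:
            model.add_compartment(Compartment(
                comp, _COMPARTMENT_NAMES.get(comp, comp),
                _SIDE_BY_SUFFIX.get(comp, CompartmentSide.INTRACELLULAR)))
        model.add_metabolite(Metabolite(mid, base, comp, base))
    for j, rid in enumerate(rxn_ids):
        col = S.getcol(j).tocoo()
        stoich = {met_ids[i]: float(v) for i, v in zip(col.row, col.data)}
        model.add_reaction(Reaction(
            rid, stoich, float(lb[j]), float(ub[j]),
            GeneRule(gr_rules[j] if gr_rules[j] not in ("", "[]") else ""),
            is_exchange=len(stoich) == 1))
    model.annotations["genes"] = genes
    model.annotations["counts"] = model_counts(model)
    return model


def model_counts(model: MetabolicModel) -> dict[str, int]:
    """Reaction/metabolite/gene counts as logged on model load."""
    genes: set[str] = set(model.annotations.get("genes", []))
    if not genes:
        for rxn in model.reactions.values():
            genes |= rxn.gene_rule.genes
    unique_bases = {m.base_id for m in model.metabolites.values()}
    return {
        "reactions": model.n_reactions,
        "metabolites": model.n_metabolites,
        "unique_metabolites": len(unique_bases),
        "genes": len(genes),
    }


def read_model(path: str | Path, format: str | None = None) -> MetabolicModel:
    """Dispatch on format ('sbml' | 'tsv' | 'mat'; inferred from suffix)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format or {".xml": "sbml", ".sbml": "sbml", ".tsv": "tsv",
                     ".mat": "mat"}.get(path.suffix.lower())
    if fmt == "sbml":
        return read_sbml(path)
    if fmt == "tsv":
        return read_tsv(path)
    if fmt == "mat":
        return read_mat(path)
    raise ModelParseError(f"cannot infer model format for {path}")
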