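"""Reading and writing genome-scale metabolic models.

A model here is a light container: metabolites with compartments, reactions
with reversibility and side membership, and gene-reaction associations.
Boolean gene-protein-reaction (GPR) structure is deliberately flattened to
gene membership: downstream copy-number analysis counts genes per isoenzyme
group and never evaluates complexes.

Both the legacy encoding of gene associations (``GENE_ASSOCIATION`` lines in
the reaction notes, as used by older BiGG/BioModels exports) and the SBML
``fbc`` package (gene products referenced from reactions) are supported; the
dialect is auto-detected and can be forced.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, replace

import libsbml

__all__ = [
    "Metabolite",
    "Reaction",
    "MetabolicModel",
    "CURRENCY_METABOLITES",
    "read_sbml_model",
    "write_sbml_model",
    "strip_currency_metabolites",
    "count_gene_associated_reactions",
    "model_summary",
]

#: The thirteen ubiquitous cofactors removed before edge construction, as
#: compartment-independent base names.  Keys are canonical names; values are
#: accepted synonyms (matched case-insensitively against metabolite names and
#: compartment-stripped ids).
CURRENCY_METABOLITES: dict[str, tuple[str, ...]] = {
    "H+": ("h", "h+", "proton"),
    "H2O": ("h2o", "water"),
    "ATP": ("atp",),
    "ADP": ("adp",),
    "Pi": ("pi", "phosphate", "orthophosphate"),
    "PPi": ("ppi", "diphosphate", "pyrophosphate"),
    "Na+": ("na1", "na+", "na", "sodium"),
    "CoA": ("coa", "coenzyme a", "co-enzyme a"),
    "O2": ("o2", "oxygen"),
    "NAD+": ("nad", "nad+"),
    "NADH": ("nadh",),
    "NADP+": ("nadp", "nadp+"),
    "NADPH": ("nadph",),
}


class SBMLParseError(ValueError):
    """Raised when an SBML document cannot be read or fails validation."""


@dataclass(frozen=True)
class Metabolite:
    id: str
    name: str
    compartment: str


@dataclass
class Reaction:
    id: str
    reversible: bool
    reactants: set[str] = field(default_factory=set)
    products: set[str] = field(default_factory=set)
    genes: set[str] = field(default_factory=set)
    #: set when currency removal emptied both sides; the reaction is retained
    #: so reaction counts stay stable, but it can contribute no edges
    emptied_by_currency_removal: bool = False


@dataclass
class MetabolicModel:
    id: str
    metabolites: list[Metabolite]
    reactions: list[Reaction]
    genes: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        seen: set[str] = set()
        for m in self.metabolites:
            if m.id in seen:
                raise SBMLParseError(f"duplicate metabolite id {m.id!r}")
            seen.add(m.id)
        for r in self.reactions:
            for mid in r.reactants | r.products:
                if mid not in seen:
                    raise SBMLParseError(
                        f"reaction {r.id!r} references undeclared species {mid!r}"
                    )
        self.genes |= {g for r in self.reactions for g in r.genes}

    @property
    def metabolite_ids(self) -> set[str]:
        return {m.id for m in self.metabolites}

    def reactions_by_id(self) -> dict[str, Reaction]:
        return {r.id: r for r in self.reactions}


_GPR_NOTE_RE = re.compile(
    r"GENE[ _]?ASSOCIATION\s*:\s*([^<\n]*)", re.IGNORECASE
)
# tokens that are boolean operators, not gene ids
_GPR_SPLIT_RE = re.compile(r"[()\s,]+")


def _flatten_gpr(gpr: str) -> set[str]:
    """Flatten a boolean GPR string to the set of gene ids it mentions."""
    tokens = [t for t in _GPR_SPLIT_RE.split(gpr) if t]
    return {t for t in tokens if t.lower() not in {"and", "or", "none", ""}}


def _genes_from_notes(reaction: libsbml.Reaction) -> set[str] | None:
    if not reaction.isSetNotes():
        return None
    notes = reaction.getNotesString()
    m = _GPR_NOTE_RE.search(notes)
    if m is None:
        return None
    return _flatten_gpr(m.group(1))


def _genes_from_fbc(reaction: libsbml.Reaction) -> set[str] | None:
    rplug = reaction.getPlugin("fbc")
    if rplug is None:
        return None
    gpa = rplug.getGeneProductAssociation()
    if gpa is None:
        return None
    genes: set[str] = set()

    def walk(assoc: libsbml.FbcAssociation) -> None:
        if assoc is None:
            return
        if assoc.isFbcAnd() or assoc.isFbcOr():
            for i in range(assoc.getNumAssociations()):
                walk(assoc.getAssociation(i))
        elif assoc.isGeneProductRef():
            genes.add(assoc.getGeneProduct())

    walk(gpa.getAssociation())
    return genes


def read_sbml_model(path: str, gpr_dialect: str = "auto") -> MetabolicModel:
    """Read an SBML (Level 2 or 3) metabolic model.

    Parameters
    ----------
    path
        Path to the SBML file.
    gpr_dialect
        ``"auto"`` (default) tries fbc gene products first, then legacy
        ``GENE_ASSOCIATION`` notes; ``"fbc"`` or ``"notes"`` force one.

    Returns
    -------
    MetabolicModel
        With boolean GPR strings flattened to gene-id sets.
    """
    if gpr_dialect not in {"auto", "fbc", "notes"}:
        raise ValueError(f"unknown gpr_dialect {gpr_dialect!r}")
    doc = libsbml.readSBMLFromFile(path)
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        err = doc.getError(0)
        raise SBMLParseError(
            f"invalid SBML in {path}: {err.getMessage().strip()} "
            f"(line {err.getLine()})"
        )
    sm = doc.getModel()
    if sm is None:
        raise SBMLParseError(f"{path} contains no SBML model element")

    metabolites = [
        Metabolite(
            id=sp.getId(),
            name=sp.getName() or sp.getId(),
            compartment=sp.getCompartment() or "default",
        )
        for sp in (sm.getSpecies(i) for i in range(sm.getNumSpecies()))
    ]

    reactions: list[Reaction] = []
    for i in range(sm.getNumReactions()):
        sr = sm.getReaction(i)
        genes: set[str] | None = None
        if gpr_dialect in ("auto", "fbc"):
            genes = _genes_from_fbc(sr)
        if genes is None and gpr_dialect in ("auto", "notes"):
            genes = _genes_from_notes(sr)
        reactions.append(
            Reaction(
                id=sr.getId(),
                reversible=bool(sr.getReversible()),
                reactants={
                    sr.getReactant(j).getSpecies()
                    for j in range(sr.getNumReactants())
                },
                products={
                    sr.getProduct(j).getSpecies()
                    for j in range(sr.getNumProducts())
                },
                genes=genes or set(),
            )
        )

    declared: set[str] = set()
    mplug = sm.getPlugin("fbc")
    if mplug is not None:
        declared = {
            mplug.getGeneProduct(i).getId()
            for i in range(mplug.getNumGeneProducts())
        }
    return MetabolicModel(
        id=sm.getId() or "model",
        metabolites=metabolites,
        reactions=reactions,
        genes=declared,
    )


def write_sbml_model(model: MetabolicModel, path: str) -> None:
    """Write a model as SBML Level 3 with legacy notes-field GPR strings."""
    doc = libsbml.SBMLDocument(3, 2)
    sm = doc.createModel()
    sm.setId(model.id)
    for comp in sorted({m.compartment for m in model.metabolites}):
        c = sm.createCompartment()
        c.setId(comp)
        c.setConstant(True)
    for m in model.metabolites:
        sp = sm.createSpecies()
        sp.setId(m.id)
        sp.setName(m.name)
        sp.setCompartment(m.compartment)
        sp.setHasOnlySubstanceUnits(False)
        sp.setBoundaryCondition(False)
        sp.setConstant(False)
    for r in model.reactions:
        sr = sm.createReaction()
        sr.setId(r.id)
        sr.setReversible(r.reversible)
        for mid in sorted(r.reactants):
            ref = sr.createReactant()
            ref.setSpecies(mid)
            ref.setConstant(True)
        for mid in sorted(r.products):
            ref = sr.createProduct()
            ref.setSpecies(mid)
            ref.setConstant(True)
        if r.genes:
            gpr = " or ".join(sorted(r.genes))
            sr.setNotes(
                f"<body xmlns='http://www.w3.org/1999/xhtml'>"
                f"<p>GENE_ASSOCIATION: {gpr}</p></body>"
            )
    libsbml.writeSBMLToFile(doc, path)


def _base_name_keys(met: Metabolite) -> set[str]:
    """Candidate compartment-independent keys for currency matching."""
    keys = {met.name.strip().lower()}
    mid = met.id.lower()
    # SBML dialects suffix compartments differently: M_atp_c, atp_c, atp[c]
    mid = re.sub(r"^[ms]_", "", mid)
    mid = re.sub(r"\[[a-z0-9]+\]$", "", mid)
    keys.add(mid)
    keys.add(re.sub(r"_[a-z0-9]{1,2}$", "", mid))
    # names like "ATP(4-)" or "ATP [cytosol]"
    name = met.name.strip().lower()
    keys.add(re.sub(r"\s*[\[(].*?[\])]\s*$", "", name))
    return {k for k in keys if k}


def strip_currency_metabolites(
    model: MetabolicModel,
    currency: dict[str, tuple[str, ...]] | set[str] | None = None,
) -> MetabolicModel:
    """Remove currency metabolites, in every compartment they occur.

    The default list is the thirteen ubiquitous cofactors (H+, H2O, ATP, ADP,
    Pi, PPi, Na+, CoA, O2, NAD+, NADH, NADP+, NADPH).  Matching is by
    compartment-stripped base name or synonym, case-insensitive.  Reactions
    whose two sides both become empty are kept but flagged.  Idempotent.
    """
    if currency is None:
        currency = CURRENCY_METABOLITES
    if isinstance(currency, dict):
        synonyms = {s.lower() for names in currency.values() for s in names}
        synonyms |= {k.lower() for k in currency}
    else:
        synonyms = {s.lower() for s in currency}

    drop = {
        m.id for m in model.metabolites if _base_name_keys(m) & synonyms
    }
    metabolites = [m for m in model.metabolites if m.id not in drop]
    reactions = []
    for r in model.reactions:
        reactants = r.reactants - drop
        products = r.products - drop
        reactions.append(
            replace(
                r,
                reactants=reactants,
                products=products,
                emptied_by_currency_removal=(
                    r.emptied_by_currency_removal
                    or (not reactants and not products and bool(r.reactants | r.products))
                ),
            )
        )
    return MetabolicModel(
        id=model.id,
        metabolites=metabolites,
        reactions=reactions,
        genes=set(model.genes),
    )


def count_gene_associated_reactions(model: MetabolicModel) -> int:
    """Number of reactions associated with at least one gene."""
    return sum(1 for r in model.reactions if r.genes)


def model_summary(model: MetabolicModel) -> dict:
    """JSON-serialisable summary of model dimensions."""
    return {
        "model_id": model.id,
        "n_metabolites": len(model.metabolites),
        "n_reactions": len(model.reactions),
        "n_genes": len(model.genes),
        "n_gene_associated_reactions": count_gene_associated_reactions(model),
        "n_compartments": len({m.compartment for m in model.metabolites}),
        "n_reversible": sum(1 for r in model.reactions if r.reversible),
    }


def summary_json(model: MetabolicModel) -> str:
    return json.dumps(model_summary(model), indent=2, sort_keys=True)
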