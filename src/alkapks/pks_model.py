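"""Rule-based simulator of a modular, partially reductive type-I polyketide
synthase ("PKS alk") that assembles the acyl chains of plant alkamides.

The model is an assembly line: an acetyl (C2) starter is elongated by
successive modules, each performing a decarboxylative Claisen condensation
with a malonyl-derived C2 extender and then tailoring the new beta-keto
group.  A module carrying KR+DH only (a "gamma" module) leaves an
alpha,beta double bond in the chain; a module carrying KR+DH+ER (a "delta"
module) reduces it again.  The dehydratase geometry rule is context
dependent: the new Delta-2 bond is *cis* (Z) when the previous module left
a *trans* (E) Delta-2 bond unreduced, and *trans* (E) otherwise.  Carbons
are numbered from the thioester carbonyl carbon C1, so the bond locant
"Delta n" denotes the bond between Cn and Cn+1; the headline product is
the affinin chain C10-2E,6Z,8E.

Besides forward simulation the module offers systematic chain naming
(``name_chain``/``parse_chain``), offloading to free acids or N-alkyl
amides with isomeric SMILES rendering, and retrobiosynthetic enumeration
of module architectures that produce a target chain
(``infer_architecture``).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

__all__ = [
    "PksModelError",
    "InvalidExtenderError",
    "InvalidStateError",
    "UnsupportedModuleError",
    "IncompleteTailoringError",
    "ChainParseError",
    "InfeasibleTargetError",
    "DoubleBond",
    "AcylChain",
    "ModuleSpec",
    "AssemblySpec",
    "ModuleRecord",
    "AssemblyTrace",
    "ProductStructure",
    "condense",
    "reduce_keto",
    "dehydrate",
    "enoyl_reduce",
    "run_module",
    "simulate_assembly",
    "offload",
    "name_chain",
    "parse_chain",
    "chain_smiles",
    "canonical_smiles",
    "infer_architecture",
    "AMINE_SMILES",
    "GAMMA",
    "DELTA",
]


class PksModelError(Exception):
    """Base class for assembly-line modelling errors."""


class InvalidExtenderError(PksModelError):
    pass


class InvalidStateError(PksModelError):
    """Operation applied to a chain in the wrong beta-carbon state."""


class UnsupportedModuleError(PksModelError):
    """Module domain set with undefined tailoring behaviour."""


class IncompleteTailoringError(PksModelError):
    """Offloading attempted on a chain that is not fully tailored."""


class ChainParseError(PksModelError):
    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


class InfeasibleTargetError(PksModelError):
    pass


SATURATED = "saturated"
KETO = "keto"
HYDROXYL = "hydroxyl"
_BETA_STATES = (SATURATED, KETO, HYDROXYL)

E = "E"
Z = "Z"


@dataclass(frozen=True, order=True)
class DoubleBond:
    """A C=C bond at locant ``position`` (between C_position and C_position+1,
    numbering from the carbonyl carbon C1) with geometry E (trans) or Z (cis)."""

    position: int
    geometry: str

    def __post_init__(self):
        if self.position < 2:
            raise ValueError(f"bond locant must be >= 2, got {self.position}")
        if self.geometry not in (E, Z):
            raise ValueError(f"geometry must be 'E' or 'Z', got {self.geometry!r}")

    def __str__(self) -> str:
        return f"{self.position}{self.geometry}"


@dataclass(frozen=True)
class AcylChain:
    """A linear acyl chain tethered (conceptually) as a thioester.

    ``beta_state`` tracks the transient state of C3 within a module cycle:
    ``keto`` right after condensation, ``hydroxyl`` after ketoreduction and
    ``saturated`` once tailoring is complete (a Delta-2 bond may remain).
    """

    n_carbons: int
    bonds: tuple[DoubleBond, ...] = ()
    beta_state: str = SATURATED

    def __post_init__(self):
        if self.n_carbons < 2:
            raise ValueError(f"chain needs >= 2 carbons, got {self.n_carbons}")
        if self.beta_state not in _BETA_STATES:
            raise ValueError(f"unknown beta_state {self.beta_state!r}")
        bonds = tuple(sorted(self.bonds))
        object.__setattr__(self, "bonds", bonds)
        positions = [b.position for b in bonds]
        if len(set(positions)) != len(positions):
            raise ValueError(f"duplicate bond locants in {positions}")
        for p, q in zip(positions, positions[1:]):
            if q - p < 2:
                raise ValueError(f"cumulated double bonds at {p} and {q}")
        if positions and positions[-1] > self.n_carbons - 1:
            raise ValueError(
                f"bond locant {positions[-1]} beyond C{self.n_carbons} chain"
            )

    def bond_at(self, position: int) -> Optional[DoubleBond]:
        for b in self.bonds:
            if b.position == position:
                return b
        return None

    def __str__(self) -> str:
        return name_chain(self)


# --- chain naming ---------------------------------------------------------

def name_chain(chain: AcylChain) -> str:
    """Systematic descriptor, e.g. ``C10-2E,6Z,8E``; ``C4`` when saturated."""
    head = f"C{chain.n_carbons}"
    if not chain.bonds:
        return head
    return head + "-" + ",".join(str(b) for b in chain.bonds)


def parse_chain(descriptor: str) -> AcylChain:
    """Parse a ``C<n>[-<loc><E|Z>,...]`` descriptor back into an AcylChain.

    Raises :class:`ChainParseError` with the offending character position.
    """
    s = descriptor.strip()
    if not s.startswith("C"):
        raise ChainParseError("descriptor must start with 'C'", 0)
    i = 1
    j = i
    while j < len(s) and s[j].isdigit():
        j += 1
    if j == i:
        raise ChainParseError("expected carbon count after 'C'", i)
    n = int(s[i:j])
    if j == len(s):
        return AcylChain(n_carbons=n)
    if s[j] != "-":
        raise ChainParseError(f"expected '-' before bond list, got {s[j]!r}", j)
    if j + 1 == len(s):
        raise ChainParseError("empty bond list after '-'", j)
    bonds = []
    k = j + 1
    while k < len(s):
        m = k
        while m < len(s) and s[m].isdigit():
            m += 1
        if m == k:
            raise ChainParseError("expected bond locant", k)
        pos = int(s[k:m])
        if m >= len(s) or s[m] not in (E, Z):
            raise ChainParseError("expected geometry 'E' or 'Z'", m)
        try:
            bonds.append(DoubleBond(pos, s[m]))
        except ValueError as exc:
            raise ChainParseError(str(exc), k) from exc
        k = m + 1
        if k < len(s):
            if s[k] != ",":
                raise ChainParseError(f"expected ',' between bonds, got {s[k]!r}", k)
            k += 1
            if k == len(s):
                raise ChainParseError("trailing ',' in bond list", k - 1)
    try:
        return AcylChain(n_carbons=n, bonds=tuple(bonds))
    except ValueError as exc:
        raise ChainParseError(str(exc), len(s) - 1) from exc


# --- elementary domain chemistry -----------------------------------------

def condense(chain: AcylChain, extender_carbons: int = 2) -> AcylChain:
    """Decarboxylative Claisen condensation with a malonyl-derived extender.

    The growing chain is attacked at its thioester carbon, so every carbon
    (and hence every bond locant) shifts up by ``extender_carbons`` and the
    new beta carbon carries a keto group.
    """
    if extender_carbons <= 0 or extender_carbons % 2 != 0:
        raise InvalidExtenderError(
            f"extender must contribute a positive even carbon count, "
            f"got {extender_carbons}"
        )
    if chain.beta_state != SATURATED:
        raise InvalidStateError(
            f"cannot condense onto a chain with beta_state={chain.beta_state!r}; "
            "the previous module left it untailored"
        )
    shifted = tuple(
        DoubleBond(b.position + extender_carbons, b.geometry) for b in chain.bonds
    )
    return AcylChain(
        n_carbons=chain.n_carbons + extender_carbons,
        bonds=shifted,
        beta_state=KETO,
    )


def reduce_keto(chain: AcylChain) -> AcylChain:
    """KR step: beta-keto -> beta-hydroxyl; double bonds untouched."""
    if chain.beta_state != KETO:
        raise InvalidStateError(
            f"ketoreduction requires beta_state='keto', got {chain.beta_state!r}"
        )
    return replace(chain, beta_state=HYDROXYL)


def dehydrate(
    chain: AcylChain, prev_retained_delta2_geometry: Optional[str] = None
) -> AcylChain:
    """DH step: eliminate the beta-hydroxyl to a Delta-2 double bond.

    Geometry follows the context rule: Z when the previous module retained
    an E Delta-2 bond (now shifted to Delta-4), otherwise E — including the
    first module and the module after a delta (fully reducing) module.
    """
    if chain.beta_state != HYDROXYL:
        raise InvalidStateError(
            f"dehydration requires beta_state='hydroxyl', got {chain.beta_state!r}"
        )
    if chain.bond_at(2) is not None:
        raise InvalidStateError("chain already carries a Delta-2 bond")
    geometry = Z if prev_retained_delta2_geometry == E else E
    return AcylChain(
        n_carbons=chain.n_carbons,
        bonds=chain.bonds + (DoubleBond(2, geometry),),
        beta_state=SATURATED,
    )


def enoyl_reduce(chain: AcylChain) -> AcylChain:
    """ER step: saturate the alpha,beta (Delta-2) double bond."""
    bond = chain.bond_at(2)
    if bond is None:
        raise InvalidStateError("no Delta-2 bond to reduce")
    remaining = tuple(b for b in chain.bonds if b.position != 2)
    return replace(chain, bonds=remaining)


# --- modules and assemblies ----------------------------------------------

CORE_DOMAINS = frozenset({"KS", "AT", "ACP"})
_KNOWN_DOMAINS = frozenset({"KS", "AT", "ACP", "KR", "DH", "ER", "TE"})

GAMMA = "gamma"
DELTA = "delta"

#: GO molecular-function terms conventionally attached to each domain.
DEFAULT_GO_TERMS: Mapping[str, str] = {
    "KS": "GO:0016740",
    "AT": "GO:0016740",
    "ACP": "GO:0016740",
    "KR": "GO:0016491",
    "ER": "GO:0016491",
    "DH": "GO:0016740",
    "TE": "GO:0016744",
}


@dataclass(frozen=True)
class ModuleSpec:
    """One extension module: the obligatory KS/AT/ACP core plus an optional
    reductive loop (KR, DH, ER).  ``module_class`` is 'gamma' for KR+DH,
    'delta' for KR+DH+ER, and None for any other reductive combination."""

    name: str
    domains: frozenset[str]
    go_terms: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self):
        domains = frozenset(self.domains)
        object.__setattr__(self, "domains", domains)
        unknown = domains - _KNOWN_DOMAINS
        if unknown:
            raise ValueError(f"unknown domain labels: {sorted(unknown)}")
        if not CORE_DOMAINS <= domains:
            raise ValueError(
                f"extension module {self.name!r} must carry KS, AT and ACP; "
                f"got {sorted(domains)}"
            )

    @property
    def module_class(self) -> Optional[str]:
        reductive = self.domains & {"KR", "DH", "ER"}
        if reductive == {"KR", "DH"}:
            return GAMMA
        if reductive == {"KR", "DH", "ER"}:
            return DELTA
        return None

    @classmethod
    def gamma(cls, name: str) -> "ModuleSpec":
        return cls(name=name, domains=CORE_DOMAINS | {"KR", "DH"})

    @classmethod
    def delta(cls, name: str) -> "ModuleSpec":
        return cls(name=name, domains=CORE_DOMAINS | {"KR", "DH", "ER"})

    @classmethod
    def from_class(cls, module_class: str, name: str) -> "ModuleSpec":
        if module_class == GAMMA:
            return cls.gamma(name)
        if module_class == DELTA:
            return cls.delta(name)
        raise ValueError(f"unknown module class {module_class!r}")


@dataclass(frozen=True)
class AssemblySpec:
    """A full assembly line: starter, extender, ordered modules, offloading."""

    modules: tuple[ModuleSpec, ...]
    starter_carbons: int = 2
    extender_carbons: int = 2
    te_present: bool = True
    amine: Optional[str] = None

    def __post_init__(self):
        object.__setattr__(self, "modules", tuple(self.modules))
        if not self.modules:
            raise ValueError("an assembly needs at least one module")
        if self.starter_carbons < 2:
            raise ValueError("starter must contribute >= 2 carbons")

    @property
    def product_carbons(self) -> int:
        return self.starter_carbons + self.extender_carbons * len(self.modules)

    @classmethod
    def from_classes(
        cls, classes: Sequence[str], name_prefix: str = "M", **kwargs
    ) -> "AssemblySpec":
        modules = tuple(
            ModuleSpec.from_class(c, f"{name_prefix}{i + 1}")
            for i, c in enumerate(classes)
        )
        return cls(modules=modules, **kwargs)


@dataclass(frozen=True)
class ModuleRecord:
    module_name: str
    after_condensation: AcylChain
    after_tailoring: AcylChain


@dataclass(frozen=True)
class AssemblyTrace:
    records: tuple[ModuleRecord, ...]

    def intermediates(self) -> list[AcylChain]:
        return [r.after_tailoring for r in self.records]

    def render(self) -> str:
        lines = []
        for r in self.records:
            lines.append(
                f"{r.module_name}: condense -> {name_chain(r.after_condensation)}"
                f" [beta-keto]; tailored -> {name_chain(r.after_tailoring)}"
                f" [{r.after_tailoring.beta_state}]"
            )
        return "\n".join(lines)


def run_module(
    chain: AcylChain,
    module: ModuleSpec,
    prev_retained: Optional[str] = None,
    extender_carbons: int = 2,
    allow_extended: bool = False,
) -> tuple[AcylChain, Optional[str]]:
    """Apply one module cycle: condensation, then the module's reductive loop.

    Returns the tailored chain and the geometry of the Delta-2 bond this
    module leaves unreduced (None for delta modules), which threads the DH
    geometry rule to the next module.
    """
    reductive = module.domains & {"KR", "DH", "ER"}
    if "DH" in reductive and "KR" not in reductive:
        raise UnsupportedModuleError(
            f"module {module.name!r} carries DH without KR"
        )
    if "ER" in reductive and "DH" not in reductive:
        raise UnsupportedModuleError(
            f"module {module.name!r} carries ER without DH"
        )
    if module.module_class is None and not allow_extended:
        raise UnsupportedModuleError(
            f"module {module.name!r} with reductive domains {sorted(reductive)} "
            "is neither gamma (KR+DH) nor delta (KR+DH+ER); downstream "
            "behaviour of partially tailored chains is undefined "
            "(pass allow_extended=True to accept it)"
        )
    chain = condense(chain, extender_carbons)
    if "KR" in reductive:
        chain = reduce_keto(chain)
    if "DH" in reductive:
        chain = dehydrate(chain, prev_retained)
    if "ER" in reductive:
        chain = enoyl_reduce(chain)
    retained = chain.bond_at(2)
    return chain, (retained.geometry if retained is not None else None)


#: SMILES fragments for the amine tokens accepted at offloading; the N is
#: the attachment point.
AMINE_SMILES: Mapping[str, str] = {
    "isobutylamine": "NCC(C)C",
    "2-methylbutylamine": "NCC(C)CC",
}

#: Trivial names for products the field knows by name.
_COMMON_NAMES: Mapping[tuple[str, str], str] = {
    ("C10-2E,6Z,8E", "isobutylamine"): "affinin",
}


@dataclass(frozen=True)
class ProductStructure:
    """An offloaded product: the acyl chain plus its linkage and rendering.

    ``name`` is the systematic chain descriptor (round-trips through
    :func:`parse_chain`); ``common_name`` is the trivial name when one
    exists (e.g. affinin for the N-isobutyl amide of C10-2E,6Z,8E).
    """

    chain: AcylChain
    linkage: str  # thioester | free-acid | amide
    amine: Optional[str] = None
    name: str = ""
    smiles: Optional[str] = None
    common_name: Optional[str] = None

    def __post_init__(self):
        if self.linkage not in ("thioester", "free-acid", "amide"):
            raise ValueError(f"unknown linkage {self.linkage!r}")
        if self.linkage == "amide" and self.amine is None:
            raise ValueError("amide linkage requires an amine token")
        if not self.name:
            object.__setattr__(self, "name", name_chain(self.chain))


def chain_smiles(chain: AcylChain, linkage: str, amine: Optional[str] = None) -> str:
    """Render an isomeric SMILES with explicit ``/``/``\\`` bond geometry.

    Carbons are written C1 -> Cn; directional single-bond marks are placed
    on the bonds flanking each C=C so that E maps to *trans* and Z to *cis*.
    """
    doubles = {b.position: b.geometry for b in chain.bonds}
    symbols: dict[int, str] = {}
    flip = {"/": "\\", "\\": "/"}
    for p in sorted(doubles):
        inc = symbols.setdefault(p - 1, "/")
        if p + 1 <= chain.n_carbons - 1:
            symbols[p + 1] = inc if doubles[p] == E else flip[inc]
    if linkage == "free-acid":
        head = "OC(=O)"
    elif linkage == "amide":
        if amine not in AMINE_SMILES:
            raise ValueError(f"no SMILES fragment for amine {amine!r}")
        head = f"O=C({AMINE_SMILES[amine]})"
    else:
        raise ValueError(f"cannot render linkage {linkage!r}")
    parts = [head]
    for i in range(2, chain.n_carbons + 1):
        bond_pos = i - 1
        if bond_pos in doubles:
            parts.append("=C")
        else:
            parts.append(symbols.get(bond_pos, "") + "C")
    return "".join(parts)


def canonical_smiles(smiles: str) -> str:
    """Canonical isomeric SMILES via RDKit; raises on invalid input."""
    from rdkit import Chem

    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"RDKit could not parse SMILES {smiles!r}")
    return Chem.MolToSmiles(mol)


def offload(chain: AcylChain, amine: Optional[str] = None) -> ProductStructure:
    """TE offloading: hydrolysis to the free acid, or aminolysis to the
    N-alkyl amide when an amine token is supplied."""
    if chain.beta_state != SATURATED:
        raise IncompleteTailoringError(
            f"cannot offload a chain with beta_state={chain.beta_state!r}"
        )
    linkage = "amide" if amine is not None else "free-acid"
    name = name_chain(chain)
    smiles = canonical_smiles(chain_smiles(chain, linkage, amine))
    common = _COMMON_NAMES.get((name, amine)) if amine else None
    return ProductStructure(
        chain=chain,
        linkage=linkage,
        amine=amine,
        name=name,
        smiles=smiles,
        common_name=common,
    )


def simulate_assembly(spec: AssemblySpec) -> tuple[ProductStructure, AssemblyTrace]:
    """Fold the modules over the starter, threading the retained Delta-2
    geometry, then offload (TE) or leave the chain as a thioester."""
    chain = AcylChain(n_carbons=spec.starter_carbons)
    retained: Optional[str] = None
    records = []
    for module in spec.modules:
        after_cond = condense(chain, spec.extender_carbons)
        chain, retained = run_module(
            chain, module, retained, spec.extender_carbons
        )
        records.append(ModuleRecord(module.name, after_cond, chain))
    trace = AssemblyTrace(records=tuple(records))
    if spec.te_present:
        product = offload(chain, spec.amine)
    else:
        product = ProductStructure(chain=chain, linkage="thioester")
    return product, trace


def infer_architecture(
    target: AcylChain,
    starter_carbons: int = 2,
    allowed_classes: Iterable[str] = (GAMMA, DELTA),
    extender_carbons: int = 2,
) -> list[tuple[str, ...]]:
    """Retrobiosynthesis by exhaustive forward search.

    Enumerates every module-class sequence of the length dictated by the
    carbon arithmetic and keeps those whose forward simulation reproduces
    the target chain (carbon count, bond locants and geometries).
    """
    classes = sorted(set(allowed_classes))
    delta_c = target.n_carbons - starter_carbons
    if delta_c <= 0 or delta_c % extender_carbons != 0:
        raise InfeasibleTargetError(
            f"target C{target.n_carbons} unreachable from a C{starter_carbons} "
            f"starter with C{extender_carbons} extenders"
        )
    n_modules = delta_c // extender_carbons
    goal = replace(target, beta_state=SATURATED)
    hits = []
    for seq in itertools.product(classes, repeat=n_modules):
        spec = AssemblySpec.from_classes(
            seq,
            starter_carbons=starter_carbons,
            extender_carbons=extender_carbons,
            te_present=False,
        )
        product, _ = simulate_assembly(spec)
        if product.chain == goal:
            hits.append(seq)
    return hits
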