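"""Module specs, chain extension, ring closure and tailoring arithmetic.

The chain model is unit-based: each elongation contributes one
:class:`KetideUnit` holding the alpha substituent and the processing
state of its beta carbon. Carbon numbering follows the macrolide
convention — C1 is the (lactone) carbonyl carbon, numbers increase
toward the starter, alpha-methyl branches are unnumbered substituents.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .mass_tools import MolecularFormula
from .specificity_rules import ATCall, DHCall, KRCall, KSCall

__all__ = [
    "AssemblyError",
    "ModuleFlags",
    "ModuleSpec",
    "ModuleCalls",
    "AssemblyLayout",
    "KetideUnit",
    "Backbone",
    "TailoringStep",
    "dehydration",
    "epoxidation",
    "glycosylation",
    "CARBAMOYL_DEOXYHEXOSE_DELTA",
    "build_modules",
    "extend_chain",
    "close_rings",
    "apply_tailoring",
    "aglycone_formula",
]

STARTER_CARBONS = {"propionyl": 3, "acetyl": 2}


class AssemblyError(ValueError):
    pass


@dataclass(frozen=True)
class ModuleFlags:
    iterative: int = 1  # number of elongations this module performs
    at_borrowed_from: int | str | None = None
    ks_gatekeeper_override: str | None = None  # forced extender class
    olefin_shift: bool = False


@dataclass(frozen=True)
class ModuleCalls:
    """Per-module classifier output, the raw material for a ModuleSpec."""

    index: int | str
    ks: KSCall
    at: ATCall | None = None
    dh: DHCall | None = None
    er: bool = False
    kr: KRCall | None = None
    t_present: bool = True
    te_present: bool = False


@dataclass(frozen=True)
class ModuleSpec:
    index: int | str
    ks: KSCall
    at: ATCall
    dh: DHCall | None
    er: bool
    kr: KRCall | None
    t_present: bool
    te_present: bool
    flags: ModuleFlags = field(default_factory=ModuleFlags)

    @property
    def is_loading(self) -> bool:
        return self.ks.role == "loading"


@dataclass(frozen=True)
class TailoringStep:
    kind: str  # dehydration | epoxidation | glycosylation
    site: tuple[int, ...]
    formula_delta: dict[str, int]


#: glycosyl residue delta: carbamoylated deoxyhexose net of condensation water
CARBAMOYL_DEOXYHEXOSE_DELTA = {"C": 7, "H": 11, "N": 1, "O": 5}


def dehydration(hydroxyl_carbon: int) -> TailoringStep:
    """Eliminate the hydroxyl at *hydroxyl_carbon* toward the next carbon."""
    return TailoringStep("dehydration", (hydroxyl_carbon, hydroxyl_carbon + 1), {"H": -2, "O": -1})


def epoxidation(carbon_a: int, carbon_b: int) -> TailoringStep:
    return TailoringStep("epoxidation", (carbon_a, carbon_b), {"O": 1})


def glycosylation(site_carbon: int, residue_delta: dict[str, int] | None = None) -> TailoringStep:
    return TailoringStep(
        "glycosylation", (site_carbon,), dict(residue_delta or CARBAMOYL_DEOXYHEXOSE_DELTA)
    )


@dataclass(frozen=True)
class AssemblyLayout:
    """Assembly-line configuration not derivable from the sequences."""

    iterative: dict = field(default_factory=dict)  # index -> elongation count
    at_borrowed_from: dict = field(default_factory=dict)  # index -> donor index
    ks_gatekeeper_override: dict = field(default_factory=dict)  # index -> extender
    olefin_shift: tuple = ()  # module indices whose enoyl product is shifted (cis)
    lactone_oxygen_carbon: int | None = None
    hemiketal: tuple[int, int] | None = None  # (ketone carbon, hydroxyl carbon)
    tailoring: tuple[TailoringStep, ...] = ()


@dataclass(frozen=True)
class KetideUnit:
    unit_index: int  # 1-based from the starter
    alpha_substituent: str  # H | methyl
    beta_state: str  # ketone | hydroxyl | enoyl | shifted_enoyl | methylene
    stereo_label: str = "none"  # A | B | none, set only for hydroxyl
    geometry: str = "none"  # E | Z | none, set only for (shifted) enoyl
    source_module: int | str = ""

    def __post_init__(self) -> None:
        if (self.stereo_label != "none") != (self.beta_state == "hydroxyl"):
            raise AssemblyError(
                f"unit {self.unit_index}: stereo label is set iff beta state is hydroxyl"
            )
        if (self.geometry != "none") != (self.beta_state in ("enoyl", "shifted_enoyl")):
            raise AssemblyError(
                f"unit {self.unit_index}: geometry is set iff beta state is an enoyl"
            )


@dataclass(frozen=True)
class Backbone:
    starter: str  # propionyl | acetyl | other
    units: tuple[KetideUnit, ...]
    lactone_ring: tuple = ()
    hemiketal_ring: tuple = ()
    exchangeable_oxygen_carbons: tuple[int, ...] = ()
    annotations: dict = field(default_factory=dict)

    # -- carbon bookkeeping -------------------------------------------
    @property
    def n_units(self) -> int:
        return len(self.units)

    @property
    def starter_carbons(self) -> int:
        return STARTER_CARBONS.get(self.starter, 2)

    @property
    def chain_carbons(self) -> int:
        return self.starter_carbons + 2 * self.n_units

    @property
    def carbon_numbering(self) -> dict[tuple, int]:
        """(unit_index, role) -> main-chain carbon number, C1 = carbonyl."""
        u = self.n_units
        numbering: dict[tuple, int] = {}
        for unit in self.units:
            j = unit.unit_index
            numbering[(j, "carbonyl")] = 2 * (u - j) + 1
            numbering[(j, "alpha")] = 2 * (u - j) + 2
        for s in range(1, self.starter_carbons + 1):
            numbering[("starter", s)] = 2 * u + s
        return numbering

    def beta_carbon(self, unit: KetideUnit) -> int:
        """Chain number of the carbon processed by *unit*'s KR/DH/ER."""
        return 2 * (self.n_units - unit.unit_index) + 3

    def carbon_states(self) -> dict[int, str]:
        """Beta-processing state keyed by main-chain carbon number."""
        return {self.beta_carbon(unit): unit.beta_state for unit in self.units}

    def double_bonds(self) -> set[tuple[int, int]]:
        """(lower, higher) carbon pairs joined by a C=C bond."""
        bonds = set()
        for unit in self.units:
            if unit.beta_state in ("enoyl", "shifted_enoyl"):
                beta = self.beta_carbon(unit)
                bonds.add((beta - 1, beta))
        return bonds

    def methyl_count(self) -> int:
        return sum(1 for unit in self.units if unit.alpha_substituent == "methyl")


def _effective_extender(spec: ModuleSpec, by_index: dict) -> str:
    """Extender unit actually used, honoring gatekeeping and AT borrowing."""
    if spec.flags.ks_gatekeeper_override:
        return spec.flags.ks_gatekeeper_override
    if spec.at.specificity in ("methylmalonyl", "malonyl"):
        return spec.at.specificity
    donor_index = spec.flags.at_borrowed_from
    if donor_index is None:
        raise AssemblyError(
            f"module {spec.index}: AT is {spec.at.specificity} and no borrowing "
            "source is configured; a layout decision is required"
        )
    donor = by_index.get(donor_index)
    if donor is None:
        raise AssemblyError(f"module {spec.index}: borrowing source {donor_index} not found")
    return _effective_extender(donor, by_index)


def build_modules(calls: list[ModuleCalls], layout: AssemblyLayout) -> list[ModuleSpec]:
    """Merge classifier calls with the layout into validated ModuleSpecs."""
    te_indices = [c.index for c in calls if c.te_present]
    if len(te_indices) != 1:
        raise AssemblyError(f"exactly one TE required, found {len(te_indices)}")
    if calls[-1].index != te_indices[0]:
        raise AssemblyError("TE must sit on the final module")

    specs = []
    for call in calls:
        if call.at is None:
            raise AssemblyError(f"module {call.index}: no AT call")
        flags = ModuleFlags(
            iterative=layout.iterative.get(call.index, 1),
            at_borrowed_from=layout.at_borrowed_from.get(call.index),
            ks_gatekeeper_override=layout.ks_gatekeeper_override.get(call.index),
            olefin_shift=call.index in layout.olefin_shift,
        )
        specs.append(
            ModuleSpec(
                index=call.index,
                ks=call.ks,
                at=call.at,
                dh=call.dh,
                er=call.er,
                kr=call.kr,
                t_present=call.t_present,
                te_present=call.te_present,
                flags=flags,
            )
        )

    by_index = {s.index: s for s in specs}
    final = specs[-1]
    if final.at.specificity in ("inactive", "unclassified"):
        # raises when no borrowing source is configured
        _effective_extender(final, by_index)
    return specs


def _beta_state(spec: ModuleSpec) -> tuple[str, str, str]:
    """(beta_state, stereo_label, geometry) from the module's reductive loop."""
    kr = spec.kr
    kr_active = kr is not None and kr.stereotype in ("A", "B1", "B2", "B_unsubtyped")
    dh_active = spec.dh is not None and spec.dh.status == "active"

    if not kr_active:
        if dh_active:
            raise AssemblyError(
                f"module {spec.index}: active DH atop absent/inactive KR — nothing to dehydrate"
            )
        return ("ketone", "none", "none")
    stereo = "A" if kr.stereotype == "A" else "B"
    if not dh_active:
        return ("hydroxyl", stereo, "none")
    if spec.er:
        return ("methylene", "none", "none")
    if spec.flags.olefin_shift:
        return ("shifted_enoyl", "none", "Z")
    return ("enoyl", "none", "E" if stereo == "B" else "Z")


def extend_chain(modules: list[ModuleSpec], options: dict | None = None) -> Backbone:
    """Run the assembly line and return the unclosed (linear) backbone.

    ``options["olefin_shift_path"]`` selects the bookkeeping for shifted
    double bonds: path 1 records a PKS-assisted shift on the flagged
    module, path 2 records a post-assembly electrocyclization route. The
    two paths yield identical final unit states and formula and differ
    only in the intermediate annotations they attach.
    """
    options = options or {}
    path = int(options.get("olefin_shift_path", 1))
    if path not in (1, 2):
        raise AssemblyError(f"olefin_shift_path must be 1 or 2, got {path}")

    by_index = {s.index: s for s in modules}
    extension_modules = [s for s in modules if not s.is_loading]

    if modules and modules[0].is_loading:
        loader = modules[0]
        starter = {"methylmalonyl": "propionyl", "malonyl": "acetyl"}.get(
            loader.at.specificity, "other"
        )
    else:
        starter = "acetyl"

    units = []
    intermediates = []
    j = 0
    for spec in extension_modules:
        extender = _effective_extender(spec, by_index)
        alpha = "methyl" if extender == "methylmalonyl" else "H"
        state, stereo, geometry = _beta_state(spec)
        for _ in range(max(1, spec.flags.iterative)):
            j += 1
            units.append(
                KetideUnit(
                    unit_index=j,
                    alpha_substituent=alpha,
                    beta_state=state,
                    stereo_label=stereo,
                    geometry=geometry,
                    source_module=spec.index,
                )
            )
        if spec.flags.olefin_shift:
            if path == 1:
                intermediates.append(
                    f"module {spec.index}: alpha,beta-enoyl isomerized on the "
                    "assembly line (PKS-assisted shift) before the next transfer"
                )
            else:
                intermediates.append(
                    f"module {spec.index}: alpha,beta-enoyl retained; triene formed, "
                    "6pi-electrocyclization plus water addition after release"
                )
    return Backbone(
        starter=starter,
        units=tuple(units),
        annotations={"olefin_shift_path": path, "intermediates": tuple(intermediates)},
    )


def close_rings(
    backbone: Backbone,
    lactone_oxygen_carbon: int,
    hemiketal: tuple[int, int] | None = None,
) -> Backbone:
    """Close the macrolactone and, optionally, the hemiketal ring.

    The lactone ring runs C1..C(lactone_oxygen_carbon) plus the ester
    oxygen. A requested hemiketal turns the named beta-ketone carbon into
    a hemiketal carbon bearing one exchangeable hydroxyl — recorded as
    the labeled-oxygen slot.
    """
    states = backbone.carbon_states()
    if not 1 <= lactone_oxygen_carbon <= backbone.chain_carbons:
        raise AssemblyError(f"no chain carbon {lactone_oxygen_carbon}")
    if states.get(lactone_oxygen_carbon) != "hydroxyl":
        raise AssemblyError(
            f"carbon C{lactone_oxygen_carbon} does not bear a hydroxyl; cannot lactonize"
        )
    lactone_ring = tuple(range(1, lactone_oxygen_carbon + 1)) + ("O_ester",)

    hemiketal_ring: tuple = ()
    exchangeable: tuple[int, ...] = ()
    if hemiketal is not None:
        ketone_carbon, hydroxyl_carbon = hemiketal
        if states.get(ketone_carbon) != "ketone":
            raise AssemblyError(f"carbon C{ketone_carbon} does not bear a ketone")
        if states.get(hydroxyl_carbon) != "hydroxyl":
            raise AssemblyError(f"carbon C{hydroxyl_carbon} does not bear a hydroxyl")
        lo, hi = sorted((ketone_carbon, hydroxyl_carbon))
        hemiketal_ring = tuple(range(lo, hi + 1)) + ("O_hemiketal",)
        exchangeable = (ketone_carbon,)
    return replace(
        backbone,
        lactone_ring=lactone_ring,
        hemiketal_ring=hemiketal_ring,
        exchangeable_oxygen_carbons=exchangeable,
    )


def aglycone_formula(backbone: Backbone) -> MolecularFormula:
    """Molecular formula of the (closed or linear) assembly-line product.

    Counted from the unit states: oxygens are the two carboxyl/ester
    oxygens plus one per ketone and hydroxyl; each C=C or C=O above the
    carboxyl removes one H2 from the saturated-chain baseline. Ring
    closures (lactone, hemiketal) are mass-neutral except for the
    lactonization water.
    """
    n_c = backbone.chain_carbons + backbone.methyl_count()
    n_ketone = sum(1 for u in backbone.units if u.beta_state == "ketone")
    n_hydroxyl = sum(1 for u in backbone.units if u.beta_state == "hydroxyl")
    n_enoyl = sum(1 for u in backbone.units if u.beta_state in ("enoyl", "shifted_enoyl"))
    dbe = 1 + n_ketone + n_enoyl  # carboxyl C=O plus chain unsaturation
    n_h = 2 * n_c + 2 - 2 * dbe
    n_o = 2 + n_ketone + n_hydroxyl
    if backbone.lactone_ring:
        n_h -= 2
        n_o -= 1
    return MolecularFormula({"C": n_c, "H": n_h, "O": n_o})


def apply_tailoring(backbone: Backbone, steps: list[TailoringStep]) -> MolecularFormula:
    """Total formula after tailoring: aglycone formula plus step deltas.

    Deltas commute in the total; site validation is sequential, so an
    epoxidation is only legal once some prior step (or the backbone)
    provides a double bond at its site.
    """
    states = backbone.carbon_states()
    bonds = set(backbone.double_bonds())
    formula = aglycone_formula(backbone)
    occupied = set(backbone.exchangeable_oxygen_carbons)
    if backbone.lactone_ring:
        states[backbone.lactone_ring[-2]] = "esterified"
    for carbon in occupied:
        states[carbon] = "hemiketal"

    for step in steps:
        if any(c > backbone.chain_carbons or c < 1 for c in step.site):
            raise AssemblyError(f"{step.kind}: site {step.site} outside the chain")
        if step.kind == "dehydration":
            site = step.site[0]
            if states.get(site) != "hydroxyl":
                raise AssemblyError(f"dehydration at C{site}: no hydroxyl present")
            states[site] = "dehydrated"
            bonds.add(tuple(sorted(step.site[:2])))
        elif step.kind == "epoxidation":
            pair = tuple(sorted(step.site[:2]))
            if pair not in bonds:
                raise AssemblyError(
                    f"epoxidation at C{pair[0]}-C{pair[1]}: no double bond at this site "
                    "after prior steps"
                )
            bonds.remove(pair)
        elif step.kind == "glycosylation":
            site = step.site[0]
            if states.get(site) != "hydroxyl":
                raise AssemblyError(f"glycosylation at C{site}: no hydroxyl present")
            states[site] = "glycosylated"
        else:
            raise AssemblyError(f"unknown tailoring step kind {step.kind!r}")
        formula = formula.add_delta(step.formula_delta)
    return formula
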