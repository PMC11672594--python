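"""Packaged iru-like assembly-line fixture and end-to-end pipeline.

The fixture encodes the published per-module motif calls for the
irumamycin assembly line: eight methylmalonyl-motif AT domains (LM,
M1-M5, M9, M10), four malonyl (M6, M7, M8, M11), one inactive (M12);
KR stereotypes B2 for M2/M4, B1 elsewhere in the B set, A for M7;
dehydratase-dead modules M5, M10 and M12. Module M8 carries a
ketosynthase gatekeeping override and M12 elongates with malonyl
borrowed from AT11. Ring-closure carbons and the module-to-protein
split of the early proteins are configuration, not sequence-derived,
and are marked provisional where the source leaves them open.
"""

from __future__ import annotations

from dataclasses import dataclass

from .assembly_model import (
    AssemblyLayout,
    Backbone,
    ModuleCalls,
    ModuleSpec,
    TailoringStep,
    aglycone_formula,
    apply_tailoring,
    build_modules,
    close_rings,
    dehydration,
    epoxidation,
    extend_chain,
    glycosylation,
)
from .domain_scanner import RawModule, scan_assembly_line, segment_modules
from .mass_tools import MolecularFormula
from .specificity_rules import classify_hit
from .synthetic_data import KRTruth, ModuleTruth, SyntheticBundle, TruthTable, generate

__all__ = [
    "IRU_SEED",
    "iru_truth_table",
    "iru_layout",
    "iru_bundle",
    "calls_from_segmentation",
    "DecodeResult",
    "decode",
    "decode_iru",
]

IRU_SEED = 42

_B1 = lambda motif: KRTruth("B1", motif)  # noqa: E731
_B2 = lambda motif: KRTruth("B2", motif)  # noqa: E731

_FULL = ("KS", "AT", "DH", "KR", "T")
_REDUCING = ("KS", "AT", "DH", "ER", "KR", "T")


def iru_truth_table() -> TruthTable:
    modules = (
        ModuleTruth("LM", ("KS", "AT", "T"), at_class="methylmalonyl", ks_residue="Q"),
        ModuleTruth(1, _REDUCING, "methylmalonyl", _B1("LDD"), "active"),
        ModuleTruth(2, ("KS", "AT", "KR", "T"), "methylmalonyl", _B2("LDD")),
        ModuleTruth(3, ("KS", "AT", "KR", "T"), "methylmalonyl", _B1("LDD")),
        ModuleTruth(4, ("KS", "AT", "KR", "T"), "methylmalonyl", _B2("LDD")),
        ModuleTruth(5, _FULL, "methylmalonyl", _B1("LDD"), "inactive_yxy"),
        ModuleTruth(6, _FULL, "malonyl", _B1("IDD"), "active"),
        ModuleTruth(7, _FULL, "malonyl", KRTruth("A"), "active"),
        ModuleTruth(8, _REDUCING, "malonyl", _B1("IDD"), "active"),
        ModuleTruth(9, _FULL, "methylmalonyl", _B1("VDD"), "active"),
        ModuleTruth(10, _FULL, "methylmalonyl", _B1("LDD"), "inactive_yxy"),
        ModuleTruth(11, _FULL, "malonyl", _B1("LDD"), "active"),
        ModuleTruth(12, ("KS", "AT", "DH", "T", "TE"), "inactive", None, "inactive_yxy"),
    )
    # final protein carries M11+M12+TE, the one before ends at T10; the
    # earlier distribution is provisional configuration
    partition = (("LM", 1, 2), (3, 4), (5, 6), (7, 8), (9, 10), (11, 12))
    return TruthTable(modules=modules, partition=partition, protein_prefix="iruPKS")


def iru_layout() -> AssemblyLayout:
    return AssemblyLayout(
        at_borrowed_from={12: 11},
        ks_gatekeeper_override={8: "malonyl"},
        olefin_shift=(11,),
        lactone_oxygen_carbon=19,
        hemiketal=(3, 7),  # C3 ketone + C7 hydroxyl -> six-membered ring (provisional carbons)
        tailoring=(
            dehydration(23),
            epoxidation(23, 24),
            glycosylation(17),
        ),
    )


def iru_bundle(seed: int = IRU_SEED) -> SyntheticBundle:
    return generate(iru_truth_table(), seed)


def calls_from_segmentation(raw_modules: list[RawModule]) -> list[ModuleCalls]:
    """Classify every hit of every grammar grouping into ModuleCalls.

    The first grouping whose KS carries the loading residue is indexed
    ``LM``; the remaining groupings are numbered 1..n in line order.
    """
    calls = []
    next_index = 1
    for raw in raw_modules:
        by_kind = {}
        for hit in raw.hits:
            if hit.kind in ("KS", "AT", "DH", "KR"):
                by_kind[hit.kind] = classify_hit(hit.kind, hit.windows)
        ks = by_kind.get("KS")
        if ks is None:
            continue  # orphan grouping, reported by the segmenter
        if ks.role == "loading" and not calls:
            index: int | str = "LM"
        else:
            index = next_index
            next_index += 1
        calls.append(
            ModuleCalls(
                index=index,
                ks=ks,
                at=by_kind.get("AT"),
                dh=by_kind.get("DH"),
                er=any(h.kind == "ER" for h in raw.hits),
                kr=by_kind.get("KR"),
                t_present=any(h.kind == "T" for h in raw.hits),
                te_present=any(h.kind == "TE" for h in raw.hits),
            )
        )
    return calls


@dataclass(frozen=True)
class DecodeResult:
    modules: tuple[ModuleSpec, ...]
    backbone: Backbone
    aglycone: MolecularFormula
    product: MolecularFormula  # tailored, glycosylated, unlabeled
    labeled_product: MolecularFormula  # one heavy oxygen at the hemiketal slot

    @property
    def lactone_ring_size(self) -> int:
        return len(self.backbone.lactone_ring)

    @property
    def hemiketal_ring_size(self) -> int:
        return len(self.backbone.hemiketal_ring)


def decode(proteins, layout: AssemblyLayout, olefin_shift_path: int = 1) -> DecodeResult:
    """Full pipeline: scan -> segment -> classify -> assemble -> tailor."""
    hits = scan_assembly_line(list(proteins))
    raw_modules = segment_modules(hits)
    calls = calls_from_segmentation(raw_modules)
    modules = build_modules(calls, layout)
    backbone = extend_chain(modules, {"olefin_shift_path": olefin_shift_path})
    backbone = close_rings(backbone, layout.lactone_oxygen_carbon, layout.hemiketal)
    aglycone = aglycone_formula(backbone)
    product = apply_tailoring(backbone, list(layout.tailoring))
    labeled = product.relabel_oxygen(len(backbone.exchangeable_oxygen_carbons))
    return DecodeResult(
        modules=tuple(modules),
        backbone=backbone,
        aglycone=aglycone,
        product=product,
        labeled_product=labeled,
    )


def decode_iru(seed: int = IRU_SEED, olefin_shift_path: int = 1) -> DecodeResult:
    bundle = iru_bundle(seed)
    return decode(bundle.proteins, iru_layout(), olefin_shift_path)
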