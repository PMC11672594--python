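"""Generate synthetic multi-protein PKS assembly lines with known truth.

Scaffolds are shuffled low-complexity filler drawn from a reduced
alphabet that cannot spell any anchor pattern, with a screening pass
that resamples a protein if an anchor arises by chance across a
junction. This guarantees that every scanner hit corresponds to an
embedded domain, making the truth table a brute-force oracle for the
scanner and classifiers.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import _patterns
from .domain_scanner import DEFAULT_MODELS, EXPECTED_SPACINGS, ProteinRecord

__all__ = [
    "KRTruth",
    "ModuleTruth",
    "TruthTable",
    "SyntheticBundle",
    "instantiate_motif",
    "generate",
    "corrupt",
    "MUTATIONS",
]

GENERATOR_VERSION = "1"

#: filler alphabet: no G/W/F/H/M/P/C/Y, so no anchor pattern can occur in filler
FILLER_ALPHABET = "ADEIKLNQRSTV"

#: default residue span of one embedded domain block (lead + core + tail)
DOMAIN_LENGTHS = {"KS": 420, "AT": 300, "DH": 280, "ER": 300, "KR": 450, "T": 80, "TE": 260}
DOMAIN_LEAD = 15  # filler residues before anchor 1 inside a block
LINKER_LENGTH = 12  # filler between domains of one module
MODULE_GAP = 30  # filler between modules
PROTEIN_PAD = 25  # filler at each protein terminus


class SyntheticDataError(ValueError):
    pass


@dataclass(frozen=True)
class KRTruth:
    stereotype: str  # A | B1 | B2
    catalytic_motif: str = ""  # LDD / IDD / VDD for B types


@dataclass(frozen=True)
class ModuleTruth:
    index: int | str  # "LM" or 1..n
    domains: tuple[str, ...]
    at_class: str = "methylmalonyl"  # methylmalonyl | malonyl | inactive
    kr: KRTruth | None = None
    dh_variant: str | None = None  # active | inactive_yxy | ei
    ks_residue: str = "C"

    def expected_calls(self) -> dict[str, str]:
        """Ground-truth classifier outcomes for this module."""
        expected = {
            "KS": "loading" if self.ks_residue == "Q" else "extension",
            "AT": self.at_class,
        }
        if "KR" in self.domains and self.kr is not None:
            expected["KR"] = self.kr.stereotype
        if "DH" in self.domains and self.dh_variant is not None:
            expected["DH"] = "inactive" if self.dh_variant == "inactive_yxy" else "active"
        return expected


@dataclass(frozen=True)
class TruthTable:
    modules: tuple[ModuleTruth, ...]
    partition: tuple[tuple, ...]  # module indices per protein, in line order
    mutation_rate: float = 0.0
    protein_prefix: str = "synpks"

    def __post_init__(self) -> None:
        indices = [m.index for m in self.modules]
        covered = [i for group in self.partition for i in group]
        if sorted(map(str, indices)) != sorted(map(str, covered)):
            raise SyntheticDataError("protein partition must cover every module exactly once")
        for module in self.modules:
            if "KS" in module.domains and "AT" in module.domains:
                continue
            if "KS" in module.domains or "AT" in module.domains:
                raise SyntheticDataError(
                    f"module {module.index}: a module's KS and AT must stay together"
                )

    def module(self, index) -> ModuleTruth:
        for m in self.modules:
            if m.index == index:
                return m
        raise KeyError(index)


@dataclass(frozen=True)
class SyntheticBundle:
    proteins: tuple[ProteinRecord, ...]
    truth: TruthTable
    seed: int
    generator_version: str = GENERATOR_VERSION
    #: (module index, domain kind, window name) -> (protein_id, start, end) 1-based
    window_index: dict = field(default_factory=dict)
    #: (module index, domain kind) -> (protein_id, start, end) 1-based
    domain_index: dict = field(default_factory=dict)


def instantiate_motif(pattern: str, rng) -> str:
    """Concrete window satisfying *pattern*; wildcard draws avoid residues
    that could complete a competing classification motif."""
    return _patterns.instantiate(pattern, rng)


# -- window content per domain kind -----------------------------------------

def _at_windows(at_class: str, rng) -> dict[str, str]:
    if at_class == "methylmalonyl":
        return {
            "motif_I": instantiate_motif("xVDVxQ", rng),
            "motif_II": "GHSQGE",
            "motif_III": instantiate_motif("xxSH", rng),
        }
    if at_class == "malonyl":
        return {
            "motif_I": instantiate_motif("xTxYTQ", rng),
            "motif_II": instantiate_motif("GHSI(V)GE", rng),
            "motif_III": instantiate_motif("xAFN", rng),
        }
    if at_class == "inactive":
        # catalytic serine replaced by glycine; flanking motifs degenerate
        return {
            "motif_I": instantiate_motif("xxxxxx", rng),
            "motif_II": "GHGQGE",
            "motif_III": instantiate_motif("xxxx", rng),
        }
    raise SyntheticDataError(f"unknown AT class {at_class!r}")


def _kr_windows(kr: KRTruth | None, rng) -> dict[str, str]:
    if kr is None or kr.stereotype == "A":
        return {
            "catalytic_motif": instantiate_motif("xxx", rng),
            "subtype_window": instantiate_motif("xxx", rng),
            "a_type_window": instantiate_motif("WxxxxQ", rng),
        }
    subtype_pattern = {"B1": "YxA", "B2": "YxP"}[kr.stereotype]
    return {
        "catalytic_motif": kr.catalytic_motif,
        "subtype_window": instantiate_motif(subtype_pattern, rng),
        "a_type_window": instantiate_motif("xxxxxx", rng),
    }


def _dh_windows(variant: str | None, rng) -> dict[str, str]:
    variant = variant or "active"
    if variant == "active":
        return {
            "catalytic_motif": instantiate_motif("HxxxxxxxxP", rng),
            "yxy_window": instantiate_motif("YxY", rng),
            "second_motif": instantiate_motif("DxxxQ(H)", rng),
        }
    if variant == "inactive_yxy":
        return {
            "catalytic_motif": instantiate_motif("HxxxxxxxxP", rng),
            "yxy_window": instantiate_motif("xxY", rng),  # tyrosine lost
            "second_motif": instantiate_motif("DxxxQ(H)", rng),
        }
    if variant == "ei":
        return {
            "catalytic_motif": instantiate_motif("HxxxxxxxxL(V)", rng),
            "yxy_window": instantiate_motif("YxY", rng),
            "second_motif": instantiate_motif("DxxxV(L)", rng),
        }
    raise SyntheticDataError(f"unknown DH variant {variant!r}")


def _domain_windows(kind: str, module: ModuleTruth, rng) -> dict[str, str]:
    if kind == "KS":
        return {"active_site": "DTA" + module.ks_residue + "SSS"}
    if kind == "AT":
        return _at_windows(module.at_class, rng)
    if kind == "KR":
        return _kr_windows(module.kr, rng)
    if kind == "DH":
        return _dh_windows(module.dh_variant, rng)
    return {}


def _filler(rng, n: int) -> str:
    return "".join(
        FILLER_ALPHABET[i] for i in rng.integers(len(FILLER_ALPHABET), size=n)
    )


def _build_domain_block(kind: str, module: ModuleTruth, rng):
    """Returns (sequence, anchor1_offset, window offsets, span) for one domain."""
    model = DEFAULT_MODELS[kind]
    length = DOMAIN_LENGTHS[kind]
    block = list(_filler(rng, length))

    a1 = DOMAIN_LEAD
    anchor_offsets = [a1]
    for spacing in EXPECTED_SPACINGS[kind]:
        anchor_offsets.append(anchor_offsets[-1] + spacing)
    for pattern, offset in zip(model.anchor_patterns, anchor_offsets):
        text = instantiate_motif(pattern, rng)
        block[offset : offset + len(text)] = text

    windows = {}
    content = _domain_windows(kind, module, rng)
    for name, (anchor_index, offset, win_len) in model.windows.items():
        text = content[name]
        if len(text) != win_len:
            raise SyntheticDataError(f"{kind}.{name}: content {text!r} is not {win_len} long")
        w0 = anchor_offsets[anchor_index] + offset
        block[w0 : w0 + win_len] = text
        windows[name] = (w0, w0 + win_len - 1)
    return "".join(block), a1, windows, model.span


def _assemble_protein(protein_id: str, module_indices, truth: TruthTable, rng):
    """One protein string plus the window/domain coordinate maps."""
    parts = [_filler(rng, PROTEIN_PAD)]
    pos = PROTEIN_PAD  # 0-based length so far
    window_index = {}
    domain_index = {}
    for k, idx in enumerate(module_indices):
        module = truth.module(idx)
        if k:
            parts.append(_filler(rng, MODULE_GAP))
            pos += MODULE_GAP
        for d, kind in enumerate(module.domains):
            if d:
                parts.append(_filler(rng, LINKER_LENGTH))
                pos += LINKER_LENGTH
            block, a1, windows, span = _build_domain_block(kind, module, rng)
            anchor_start = pos + a1 + 1  # 1-based
            domain_index[(idx, kind)] = (protein_id, anchor_start, anchor_start + span - 1)
            for name, (w0, w1) in windows.items():
                window_index[(idx, kind, name)] = (protein_id, pos + w0 + 1, pos + w1 + 1)
            parts.append(block)
            pos += len(block)
    parts.append(_filler(rng, PROTEIN_PAD))
    return "".join(parts), window_index, domain_index


def _intended_anchor_starts(domain_index, protein_id: str) -> dict[str, set[int]]:
    intended: dict[str, set[int]] = {}
    for (idx, kind), (pid, start, _end) in domain_index.items():
        if pid != protein_id:
            continue
        model = DEFAULT_MODELS[kind]
        offsets = [0]
        for spacing in EXPECTED_SPACINGS[kind]:
            offsets.append(offsets[-1] + spacing)
        for pattern, off in zip(model.anchor_patterns, offsets):
            intended.setdefault(pattern, set()).add(start - 1 + off)
    return intended


def _screen(sequence: str, intended: dict[str, set[int]]) -> bool:
    """True when every anchor-pattern occurrence is an intended embedding."""
    patterns = {p for model in DEFAULT_MODELS.values() for p in model.anchor_patterns}
    for pattern in patterns:
        allowed = intended.get(pattern, set())
        if any(s not in allowed for s in _patterns.find_all(pattern, sequence)):
            return False
    return True


def _mutate_scaffold(sequence: str, protected: list[tuple[int, int]], rate: float, rng) -> str:
    if rate <= 0:
        return sequence
    shielded = np.zeros(len(sequence), dtype=bool)
    for start, end in protected:  # 1-based inclusive
        shielded[start - 1 : end] = True
    out = list(sequence)
    hits = rng.random(len(sequence)) < rate
    for i in np.nonzero(hits & ~shielded)[0]:
        out[i] = FILLER_ALPHABET[rng.integers(len(FILLER_ALPHABET))]
    return "".join(out)


def generate(truth: TruthTable, seed: int) -> SyntheticBundle:
    """Deterministically instantiate *truth* into proteins with coordinates."""
    rng = np.random.default_rng(seed)
    proteins = []
    window_index = {}
    domain_index = {}
    for order, module_indices in enumerate(truth.partition, start=1):
        protein_id = f"{truth.protein_prefix}_{order}"
        for attempt in range(50):
            sequence, wins, doms = _assemble_protein(protein_id, module_indices, truth, rng)
            protected = [(s, e) for (_pid, s, e) in wins.values()]
            sequence = _mutate_scaffold(sequence, protected, truth.mutation_rate, rng)
            if _screen(sequence, _intended_anchor_starts(doms, protein_id)):
                break
        else:
            raise SyntheticDataError(f"{protein_id}: could not build a clean scaffold")
        proteins.append(ProteinRecord(id=protein_id, order_index=order, sequence=sequence))
        window_index.update(wins)
        domain_index.update(doms)
    return SyntheticBundle(
        proteins=tuple(proteins),
        truth=truth,
        seed=seed,
        window_index=window_index,
        domain_index=domain_index,
    )


# -- targeted corruption -----------------------------------------------------

def _mut_at_serine(window: str) -> str:
    return window[:2] + "G" + window[3:]


def _mut_ks_to_loading(window: str) -> str:
    return window[:3] + "Q" + window[4:]


def _mut_dh_yxy(window: str) -> str:
    return "A" + window[1:]


MUTATIONS = {
    # name: (domain kind, window name, text mutation, truth field update)
    "at_serine_to_glycine": ("AT", "motif_II", _mut_at_serine, {"at_class": "inactive"}),
    "ks_cys_to_gln": ("KS", "active_site", _mut_ks_to_loading, {"ks_residue": "Q"}),
    "dh_break_yxy": ("DH", "yxy_window", _mut_dh_yxy, {"dh_variant": "inactive_yxy"}),
}


def corrupt(bundle: SyntheticBundle, operations: list[tuple], seed: int = 0) -> SyntheticBundle:
    """Apply named window mutations; returns a bundle with updated truth.

    *operations* is a list of ``(module_index, mutation_name)``. Exactly
    the targeted windows change; the truth table is updated to the
    implied new ground truth.
    """
    sequences = {p.id: list(p.sequence) for p in bundle.proteins}
    modules = {m.index: m for m in bundle.truth.modules}
    for module_index, name in operations:
        try:
            kind, window_name, mutate, truth_update = MUTATIONS[name]
        except KeyError:
            raise SyntheticDataError(
                f"unknown mutation {name!r}; known: {sorted(MUTATIONS)}"
            ) from None
        key = (module_index, kind, window_name)
        if key not in bundle.window_index:
            raise SyntheticDataError(f"no window {window_name!r} on module {module_index} {kind}")
        protein_id, start, end = bundle.window_index[key]
        seq = sequences[protein_id]
        original = "".join(seq[start - 1 : end])
        seq[start - 1 : end] = mutate(original)
        modules[module_index] = replace(modules[module_index], **truth_update)

    proteins = tuple(
        replace(p, sequence="".join(sequences[p.id])) for p in bundle.proteins
    )
    truth = replace(bundle.truth, modules=tuple(modules[m.index] for m in bundle.truth.modules))
    return replace(bundle, proteins=proteins, truth=truth)
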