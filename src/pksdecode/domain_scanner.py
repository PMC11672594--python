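"""Locate PKS domains in assembly-line proteins by anchored motif scanning.

Detection is deliberately anchor-based rather than profile-HMM-based: each
domain kind is described by one or two short anchor patterns with an
allowed spacing interval, plus classification windows at fixed offsets
from the first anchor. This keeps the scanner free of external model
files and makes every hit exactly reproducible from the sequence.

Coordinates are 1-based inclusive throughout, the protein residue
convention; re-slicing ``sequence[start-1:end]`` reproduces the matched
region.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace

from . import _patterns

__all__ = [
    "ProteinRecord",
    "DomainModel",
    "DomainHit",
    "RawModule",
    "DEFAULT_MODELS",
    "MODULE_GRAMMAR",
    "read_fasta",
    "scan_domains",
    "scan_assembly_line",
    "segment_modules",
]

log = logging.getLogger(__name__)

VALID_RESIDUES = set(_patterns.AMINO_ACIDS) | {"X"}

#: canonical within-module domain order for cis-AT PKS
MODULE_GRAMMAR = re.compile(r"^KS AT( DH( ER)?)?( KR)? T( TE)?$")

_KIND_RANK = {k: i for i, k in enumerate(["KS", "AT", "DH", "ER", "KR", "T", "TE"])}


class FastaError(ValueError):
    pass


@dataclass(frozen=True)
class ProteinRecord:
    """One assembly-line protein, ordered by its position in the line."""

    id: str
    order_index: int
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise FastaError(f"record {self.id!r}: empty sequence")
        for pos, res in enumerate(self.sequence, start=1):
            if res not in VALID_RESIDUES:
                raise FastaError(
                    f"record {self.id!r}: invalid residue {res!r} at position {pos}"
                )


@dataclass(frozen=True)
class DomainModel:
    """Anchored degenerate-pattern model of one domain kind.

    ``windows`` maps a window name to ``(anchor_index, offset, length)``:
    the window starts *offset* residues after the start of that anchor.
    ``spacing_ranges[i]`` bounds the start-to-start distance between
    anchors ``i`` and ``i+1``.
    """

    kind: str
    anchor_patterns: tuple[str, ...]
    spacing_ranges: tuple[tuple[int, int], ...] = ()
    windows: dict[str, tuple[int, int, int]] = field(default_factory=dict)
    span: int = 0  # residues from anchor-1 start covered by the model

    def __post_init__(self) -> None:
        if not self.anchor_patterns:
            raise ValueError(f"{self.kind}: at least one anchor pattern required")
        if len(self.spacing_ranges) != len(self.anchor_patterns) - 1:
            raise ValueError(f"{self.kind}: need one spacing range per anchor gap")
        for lo, hi in self.spacing_ranges:
            if hi <= lo:
                raise ValueError(f"{self.kind}: spacing interval ({lo}, {hi}) has no width")


@dataclass(frozen=True)
class DomainHit:
    """A located domain with its extracted classification windows."""

    protein_id: str
    kind: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    windows: dict[str, str] = field(default_factory=dict)
    protein_order: int = 0


def _spacing(expected: int, slack: float = 0.30) -> tuple[int, int]:
    return (int(expected * (1 - slack)), int(expected * (1 + slack)) + 1)


#: anchor-start to anchor-start distances in the packaged synthetic reference
EXPECTED_SPACINGS: dict[str, tuple[int, ...]] = {
    "KS": (300,),
    "AT": (220,),
    "DH": (160,),
    "ER": (120,),
    "KR": (260,),
    "T": (),
    "TE": (150,),
}

#: geometry of the packaged synthetic reference; spacing slack is +/-30%
DEFAULT_MODELS: dict[str, DomainModel] = {
    "KS": DomainModel(
        kind="KS",
        anchor_patterns=("EPIAIVGM", "HGTGT"),
        spacing_ranges=(_spacing(300),),
        windows={"active_site": (0, 160, 7)},
        span=305,
    ),
    "AT": DomainModel(
        kind="AT",
        anchor_patterns=("GQGAQW", "WNEVFA"),
        spacing_ranges=(_spacing(220),),
        windows={"motif_I": (0, 40, 6), "motif_II": (0, 90, 6), "motif_III": (0, 140, 4)},
        span=226,
    ),
    "DH": DomainModel(
        kind="DH",
        anchor_patterns=("FPHAVG", "MGTRED"),
        spacing_ranges=(_spacing(160),),
        windows={
            "catalytic_motif": (0, 30, 10),
            "yxy_window": (0, 70, 3),
            "second_motif": (0, 100, 5),
        },
        span=166,
    ),
    "ER": DomainModel(
        kind="ER",
        anchor_patterns=("GGVGMA", "AQLFRE"),
        spacing_ranges=(_spacing(120),),
        span=126,
    ),
    "KR": DomainModel(
        kind="KR",
        anchor_patterns=("TGGTGA", "LERDWY"),
        spacing_ranges=(_spacing(260),),
        windows={
            "catalytic_motif": (0, 120, 3),
            "subtype_window": (0, 150, 3),
            "a_type_window": (0, 180, 6),
        },
        span=266,
    ),
    "T": DomainModel(kind="T", anchor_patterns=("GLDSLG",), span=6),
    "TE": DomainModel(
        kind="TE",
        anchor_patterns=("GWSAGG", "HFDALL"),
        spacing_ranges=(_spacing(150),),
        span=156,
    ),
}


def read_fasta(path) -> list[ProteinRecord]:
    """Read amino-acid FASTA into ordered :class:`ProteinRecord` objects."""
    from Bio import SeqIO

    records = []
    for idx, rec in enumerate(SeqIO.parse(str(path), "fasta"), start=1):
        records.append(ProteinRecord(id=rec.id, order_index=idx, sequence=str(rec.seq).upper()))
    if not records:
        raise FastaError(f"no FASTA records in {path}")
    return records


def _candidates(sequence: str, model: DomainModel) -> list[DomainHit]:
    """All placements of *model* on *sequence*, leftmost-first."""
    out = []
    for a1 in _patterns.find_all(model.anchor_patterns[0], sequence):
        anchor_starts = [a1]
        ok = True
        for i, pattern in enumerate(model.anchor_patterns[1:]):
            lo, hi = model.spacing_ranges[i]
            prev = anchor_starts[-1]
            plen = _patterns.pattern_length(pattern)
            window_hits = [
                s
                for s in _patterns.find_all(pattern, sequence[prev : prev + hi + plen])
                if lo <= s <= hi
            ]
            if not window_hits:
                ok = False
                break
            anchor_starts.append(prev + window_hits[0])
        if not ok:
            continue
        windows = {}
        end0 = anchor_starts[-1] + _patterns.pattern_length(model.anchor_patterns[-1]) - 1
        for name, (anchor_index, offset, length) in model.windows.items():
            w0 = anchor_starts[anchor_index] + offset
            if w0 + length > len(sequence):
                ok = False
                break
            windows[name] = sequence[w0 : w0 + length]
            end0 = max(end0, w0 + length - 1)
        if not ok:
            continue
        out.append(
            DomainHit(protein_id="", kind=model.kind, start=a1 + 1, end=end0 + 1, windows=windows)
        )
    return out


def scan_domains(protein: ProteinRecord, models: list[DomainModel] | dict | None = None) -> list[DomainHit]:
    """Locate every domain of every model on one protein.

    Overlapping candidate placements are resolved by earliest start, then
    longest match. A protein yielding neither a KS nor an AT placement is
    reported with a warning-level diagnostic and an empty result.
    """
    if models is None:
        models = DEFAULT_MODELS
    model_list = list(models.values()) if isinstance(models, dict) else list(models)

    candidates: list[DomainHit] = []
    for model in model_list:
        candidates.extend(_candidates(protein.sequence, model))
    candidates.sort(key=lambda h: (h.start, -h.end))

    hits: list[DomainHit] = []
    occupied_until = 0
    for cand in candidates:
        if cand.start > occupied_until:
            hits.append(
                replace(cand, protein_id=protein.id, protein_order=protein.order_index)
            )
            occupied_until = cand.end
    scanned_kinds = {m.kind for m in model_list}
    if {"KS", "AT"} <= scanned_kinds and not any(h.kind in ("KS", "AT") for h in hits):
        log.warning(
            "protein %s: no KS or AT anchors found; returning no hits", protein.id
        )
    return hits


def scan_assembly_line(
    proteins: list[ProteinRecord], models=None
) -> list[DomainHit]:
    """Scan each protein and return hits ordered along the assembly line."""
    hits = []
    for protein in sorted(proteins, key=lambda p: p.order_index):
        hits.extend(scan_domains(protein, models))
    return hits


@dataclass(frozen=True)
class RawModule:
    """A grammar-delimited grouping of consecutive domain hits."""

    hits: tuple[DomainHit, ...]
    ambiguous: bool = False
    diagnostics: tuple[str, ...] = ()

    @property
    def kinds(self) -> tuple[str, ...]:
        return tuple(h.kind for h in self.hits)


def segment_modules(hits: list[DomainHit], grammar: re.Pattern[str] = MODULE_GRAMMAR) -> list[RawModule]:
    """Group ordered hits into modules at KS boundaries.

    Every hit lands in exactly one module; a KS always opens a new module
    so a KS-AT pair is never split. Groupings that violate the canonical
    cis-AT grammar are still returned, flagged ambiguous, with
    diagnostics naming the offending kinds.
    """
    ordered = sorted(hits, key=lambda h: (h.protein_order, h.start))
    groups: list[list[DomainHit]] = []
    orphans: list[DomainHit] = []
    for hit in ordered:
        if hit.kind == "KS":
            groups.append([hit])
        elif groups:
            groups[-1].append(hit)
        else:
            orphans.append(hit)

    modules: list[RawModule] = []
    if orphans:
        modules.append(
            RawModule(
                hits=tuple(orphans),
                ambiguous=True,
                diagnostics=(
                    "hits before the first KS: " + ", ".join(h.kind for h in orphans),
                ),
            )
        )
    for group in groups:
        kinds = " ".join(h.kind for h in group)
        diagnostics = []
        if not grammar.match(kinds):
            diagnostics.append(f"domain order {kinds!r} violates module grammar")
        modules.append(
            RawModule(hits=tuple(group), ambiguous=bool(diagnostics), diagnostics=tuple(diagnostics))
        )
    for module in modules:
        if module.ambiguous:
            log.warning("ambiguous module grouping: %s", "; ".join(module.diagnostics))
    return modules
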