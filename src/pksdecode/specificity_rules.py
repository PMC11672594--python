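"""Classify PKS catalytic domains from their extracted active-site windows.

The rules are deliberately literal translations of the published motif
diagnostics for cis-AT assembly lines:

* AT extender choice from motifs I-III around the catalytic serine
  (methylmalonyl: ``xVDVxQ / GHSQGE / xxSH``; malonyl:
  ``xTxYTQ / GHSI(V)GE / xAFN``); a ``GH[not-S]`` motif II marks a dead
  domain.
* KR stereotype from the LDD-family catalytic motif (B; ``YxP`` -> B2,
  ``YxA`` -> B1) or the ``WxxxxQ`` window (A).
* DH activity from the ``HxxxxxxxxP`` catalytic motif plus an intact
  ``YxY`` window; an ``HxxxxxxxxL/V`` terminus or a ``DxxxV/L`` second
  motif flags an enoyl-isomerase candidate.
* KS role from the single active-site residue (Q -> loading, C -> extension).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from . import _patterns

__all__ = [
    "ATCall",
    "KRCall",
    "DHCall",
    "KSCall",
    "classify_at",
    "classify_kr",
    "classify_dh",
    "classify_ks",
    "classify_hit",
    "AT_METHYLMALONYL",
    "AT_MALONYL",
    "KR_B_MOTIFS",
]

AT_METHYLMALONYL = ("xVDVxQ", "GHSQGE", "xxSH")
AT_MALONYL = ("xTxYTQ", "GHSI(V)GE", "xAFN")
KR_B_MOTIFS = ("LDD", "IDD", "VDD")
KR_A_PATTERN = "WxxxxQ"
KR_B2_PATTERN = "YxP"
KR_B1_PATTERN = "YxA"
DH_ACTIVE_PATTERN = "HxxxxxxxxP"
DH_EI_PATTERNS = ("HxxxxxxxxL", "HxxxxxxxxV")
DH_YXY_PATTERN = "YxY"
DH_SECOND_PATTERN = "DxxxQ(H)"
DH_SECOND_EI_PATTERN = "DxxxV(L)"


class WindowError(ValueError):
    """A classification window is missing or shorter than its pattern."""


def _require(window: str, name: str, length: int) -> None:
    if window is None or len(window) < length:
        raise WindowError(f"window {name!r} shorter than its {length}-residue pattern: {window!r}")


@dataclass(frozen=True)
class ATCall:
    specificity: str  # methylmalonyl | malonyl | inactive | unclassified
    evidence: dict = field(default_factory=dict)


@dataclass(frozen=True)
class KRCall:
    stereotype: str  # A | B1 | B2 | B_unsubtyped | absent
    catalytic_motif: str = ""
    conflict: bool = False
    evidence: dict = field(default_factory=dict)


@dataclass(frozen=True)
class DHCall:
    status: str  # active | inactive | absent
    ei_candidate: bool = False
    evidence: dict = field(default_factory=dict)


@dataclass(frozen=True)
class KSCall:
    role: str  # extension | loading
    active_site_residue: str = ""
    warning: str | None = None


def classify_at(motif_I: str, motif_II: str, motif_III: str) -> ATCall:
    """Call extender-unit specificity from the three AT motifs.

    Motif II carries the catalytic serine, so it is weighted double when
    the three motifs disagree; full-pattern matches take precedence, then
    a GH-context serine loss means *inactive*, then the weighted majority.
    """
    for name, window, patterns in (
        ("motif_I", motif_I, (AT_METHYLMALONYL[0], AT_MALONYL[0])),
        ("motif_II", motif_II, (AT_METHYLMALONYL[1], AT_MALONYL[1])),
        ("motif_III", motif_III, (AT_METHYLMALONYL[2], AT_MALONYL[2])),
    ):
        _require(window, name, max(_patterns.pattern_length(p) for p in patterns))

    windows = (motif_I, motif_II, motif_III)
    mmal_hits = [_patterns.matches(p, w) for p, w in zip(AT_METHYLMALONYL, windows)]
    mal_hits = [_patterns.matches(p, w) for p, w in zip(AT_MALONYL, windows)]
    evidence = {
        "motif_I": motif_I,
        "motif_II": motif_II,
        "motif_III": motif_III,
        "methylmalonyl_matches": sum(mmal_hits),
        "malonyl_matches": sum(mal_hits),
    }

    serine_lost = motif_II[:2] == "GH" and motif_II[2] != "S"
    if all(mmal_hits):
        return ATCall("methylmalonyl", {**evidence, "rule": "all three methylmalonyl motifs"})
    if all(mal_hits):
        return ATCall("malonyl", {**evidence, "rule": "all three malonyl motifs"})
    if serine_lost:
        return ATCall("inactive", {**evidence, "rule": f"catalytic serine replaced by {motif_II[2]}"})
    # motif II dominates (it holds the catalytic serine), then majority
    if mmal_hits[1] != mal_hits[1]:
        winner = "methylmalonyl" if mmal_hits[1] else "malonyl"
        return ATCall(winner, {**evidence, "rule": "weighted majority (motif II dominates)"})
    mmal_score = mmal_hits[0] + mmal_hits[2]
    mal_score = mal_hits[0] + mal_hits[2]
    if mmal_score > mal_score:
        return ATCall("methylmalonyl", {**evidence, "rule": "weighted majority"})
    if mal_score > mmal_score:
        return ATCall("malonyl", {**evidence, "rule": "weighted majority"})
    return ATCall("unclassified", {**evidence, "rule": "no rule fired"})


def classify_kr(catalytic_motif: str, subtype_window: str, a_type_window: str) -> KRCall:
    _require(catalytic_motif, "catalytic_motif", 3)
    _require(subtype_window, "subtype_window", 3)
    _require(a_type_window, "a_type_window", 6)

    is_b = catalytic_motif[:3] in KR_B_MOTIFS
    is_a = _patterns.matches(KR_A_PATTERN, a_type_window[:6])
    evidence = {
        "catalytic_motif": catalytic_motif,
        "subtype_window": subtype_window,
        "a_type_window": a_type_window,
    }
    if is_b:
        if _patterns.matches(KR_B2_PATTERN, subtype_window[:3]):
            subtype = "B2"
        elif _patterns.matches(KR_B1_PATTERN, subtype_window[:3]):
            subtype = "B1"
        else:
            subtype = "B_unsubtyped"
        # contradictory evidence is reported, never silent
        return KRCall(subtype, catalytic_motif[:3], conflict=is_a, evidence=evidence)
    if is_a:
        return KRCall("A", catalytic_motif[:3], evidence=evidence)
    return KRCall(
        "absent",
        catalytic_motif[:3],
        evidence={**evidence, "note": "no diagnostic motif; treated as non-functional"},
    )


def classify_dh(catalytic_motif: str, yxy_window: str, second_motif: str) -> DHCall:
    _require(catalytic_motif, "catalytic_motif", 10)
    _require(yxy_window, "yxy_window", 3)
    _require(second_motif, "second_motif", 5)

    cat = catalytic_motif[:10]
    has_his = cat[0] == "H"
    terminal = cat[9]
    yxy_intact = _patterns.matches(DH_YXY_PATTERN, yxy_window[:3])
    ei = has_his and (
        any(_patterns.matches(p, cat) for p in DH_EI_PATTERNS)
        or _patterns.matches(DH_SECOND_EI_PATTERN, second_motif[:5])
    )
    active = has_his and terminal in "PLV" and yxy_intact
    return DHCall(
        status="active" if active else "inactive",
        ei_candidate=ei,
        evidence={
            "catalytic_motif": cat,
            "yxy_window": yxy_window[:3],
            "second_motif": second_motif[:5],
            "histidine": has_his,
            "yxy_intact": yxy_intact,
        },
    )


def classify_ks(active_site_residue: str) -> KSCall:
    if not active_site_residue:
        raise WindowError("empty KS active-site residue")
    residue = active_site_residue[0]
    if residue == "Q":
        return KSCall("loading", residue)
    if residue == "C":
        return KSCall("extension", residue)
    return KSCall("extension", residue, warning=f"unexpected active-site residue {residue!r}")


def classify_hit(kind: str, windows: dict[str, str]):
    """Dispatch a scanner hit's windows to the matching classifier."""
    if kind == "AT":
        return classify_at(windows["motif_I"], windows["motif_II"], windows["motif_III"])
    if kind == "KR":
        return classify_kr(windows["catalytic_motif"], windows["subtype_window"], windows["a_type_window"])
    if kind == "DH":
        return classify_dh(windows["catalytic_motif"], windows["yxy_window"], windows["second_motif"])
    if kind == "KS":
        return classify_ks(windows["active_site"][3])
    raise KeyError(f"no classifier for domain kind {kind!r}")
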