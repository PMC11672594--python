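"""Monoisotopic mass, adduct m/z and exchange-labeling isotopologue arithmetic.

Conventions
-----------
* Masses are monoisotopic throughout; the natural-abundance isotope
  envelope (e.g. the 13C ladder) is out of scope.
* Cation adduct deltas subtract one electron mass (proton = 1.00728 Da
  convention), applied uniformly to every supported adduct.
* A heavy-oxygen label is tracked as its own formula slot ``[18O]`` so a
  formula can carry both common and labeled oxygen.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field

__all__ = [
    "MolecularFormula",
    "AdductSpec",
    "IsotopologuePattern",
    "ADDUCTS",
    "monoisotopic_mass",
    "adduct_mz",
    "exchange_pattern",
    "compare_peaklists",
    "O18_SHIFT",
]

# CODATA / AME monoisotopic masses (Da)
ISOTOPE_MASS: dict[str, float] = {
    "H": 1.00782503207,
    "C": 12.0,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "[18O]": 17.9991610,
    "Na": 22.9897692809,
    "P": 30.97376163,
    "S": 31.97207100,
    "K": 38.96370668,
    "Cl": 34.96885268,
}

ELECTRON_MASS = 0.000548579909

#: mass gained when one common oxygen is exchanged for a heavy one
O18_SHIFT = ISOTOPE_MASS["[18O]"] - ISOTOPE_MASS["O"]

_FORMULA_TOKEN = re.compile(r"(\[18O\]|[A-Z][a-z]?)(\d*)")


class FormulaError(ValueError):
    pass


@dataclass(frozen=True)
class MolecularFormula:
    """Element/isotope -> non-negative count, labeled oxygen kept separate."""

    counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean = {k: int(v) for k, v in self.counts.items() if v}
        for key, value in clean.items():
            if key not in ISOTOPE_MASS:
                raise FormulaError(f"unknown element symbol {key!r}")
            if value < 0:
                raise FormulaError(f"negative count for {key}: {value}")
        object.__setattr__(self, "counts", clean)

    # -- construction -------------------------------------------------
    @classmethod
    def parse(cls, text: str) -> "MolecularFormula":
        """Parse Hill-order text such as ``C41H65NO12`` or ``C41H65NO11[18O]``."""
        counts: dict[str, int] = {}
        pos = 0
        while pos < len(text):
            m = _FORMULA_TOKEN.match(text, pos)
            if m is None or not m.group(1):
                raise FormulaError(f"cannot parse formula {text!r} at index {pos}")
            sym, num = m.group(1), m.group(2)
            counts[sym] = counts.get(sym, 0) + (int(num) if num else 1)
            pos = m.end()
        if not counts:
            raise FormulaError("empty formula")
        return cls(counts)

    # -- arithmetic ----------------------------------------------------
    def __add__(self, other: "MolecularFormula") -> "MolecularFormula":
        merged = dict(self.counts)
        for k, v in other.counts.items():
            merged[k] = merged.get(k, 0) + v
        return MolecularFormula(merged)

    def add_delta(self, delta: dict[str, int]) -> "MolecularFormula":
        """Apply a signed element-count delta (raises if any count goes negative)."""
        merged = dict(self.counts)
        for k, v in delta.items():
            merged[k] = merged.get(k, 0) + v
        return MolecularFormula(merged)

    def relabel_oxygen(self, n_labels: int) -> "MolecularFormula":
        """Move *n_labels* common oxygens into the heavy-oxygen slot."""
        if n_labels > self.counts.get("O", 0):
            raise FormulaError("not enough oxygen to label")
        return self.add_delta({"O": -n_labels, "[18O]": n_labels})

    def __getitem__(self, key: str) -> int:
        return self.counts.get(key, 0)

    @property
    def oxygen_total(self) -> int:
        return self["O"] + self["[18O]"]

    def hill(self) -> str:
        """Hill-order text (C, H, then alphabetical; label slot appended)."""
        parts = []
        for sym in ("C", "H"):
            n = self[sym]
            if n:
                parts.append(sym + (str(n) if n > 1 else ""))
        rest = sorted(k for k in self.counts if k not in ("C", "H", "[18O]"))
        for sym in rest:
            n = self[sym]
            parts.append(sym + (str(n) if n > 1 else ""))
        if self["[18O]"]:
            n = self["[18O]"]
            parts.append("[18O]" + (str(n) if n > 1 else ""))
        return "".join(parts)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.hill()


@dataclass(frozen=True)
class AdductSpec:
    """A singly charged cation adduct."""

    name: str
    mass_delta: float
    charge: int = 1


def _cation(symbols: dict[str, int]) -> float:
    return sum(ISOTOPE_MASS[s] * n for s, n in symbols.items()) - ELECTRON_MASS


ADDUCTS: dict[str, AdductSpec] = {
    "[M+H]+": AdductSpec("[M+H]+", _cation({"H": 1})),
    "[M+NH4]+": AdductSpec("[M+NH4]+", _cation({"N": 1, "H": 4})),
    "[M+Na]+": AdductSpec("[M+Na]+", _cation({"Na": 1})),
}
# short aliases accepted by the CLI
ADDUCTS.update({"H": ADDUCTS["[M+H]+"], "NH4": ADDUCTS["[M+NH4]+"], "Na": ADDUCTS["[M+Na]+"]})


def monoisotopic_mass(formula: MolecularFormula) -> float:
    """Neutral monoisotopic mass in Da; labeled slots use the heavy mass."""
    return sum(ISOTOPE_MASS[sym] * n for sym, n in formula.counts.items())


def adduct_mz(formula: MolecularFormula, adduct: AdductSpec | str) -> float:
    if isinstance(adduct, str):
        try:
            adduct = ADDUCTS[adduct]
        except KeyError:
            raise KeyError(
                f"unsupported adduct {adduct!r}; supported: "
                + ", ".join(sorted(k for k in ADDUCTS if k.startswith("[")))
            ) from None
    if adduct.charge != 1:
        raise ValueError("only singly charged adducts are supported")
    return (monoisotopic_mass(formula) + adduct.mass_delta) / adduct.charge


@dataclass(frozen=True)
class IsotopologuePattern:
    """Binomial heavy-atom pattern: (j, m/z, abundance) ordered by j."""

    entries: tuple[tuple[int, float, float], ...]
    enrichment: float
    exchangeable_slots: int

    def abundances(self) -> list[float]:
        return [a for _, _, a in self.entries]

    def mz_values(self) -> list[float]:
        return [m for _, m, _ in self.entries]


def exchange_pattern(
    formula: MolecularFormula,
    k: int,
    p: float,
    adduct: AdductSpec | str = "[M+NH4]+",
) -> IsotopologuePattern:
    """Isotopologue pattern for *k* exchangeable oxygens at enrichment *p*.

    Abundance of the ``j``-heavy species is ``C(k, j) p^j (1-p)^(k-j)``;
    consecutive entries are spaced by the 18O-16O mass difference on the
    chosen adduct. The input formula is taken as fully unlabeled.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"enrichment must lie in [0, 1], got {p}")
    if not 0 <= k <= formula.oxygen_total:
        raise ValueError(f"exchangeable slots {k} outside [0, oxygen count]")
    base = adduct_mz(formula, adduct)
    entries = tuple(
        (j, base + j * O18_SHIFT, math.comb(k, j) * p**j * (1.0 - p) ** (k - j))
        for j in range(k + 1)
    )
    return IsotopologuePattern(entries=entries, enrichment=p, exchangeable_slots=k)


@dataclass(frozen=True)
class PeakMatch:
    predicted_mz: float
    observed_mz: float | None
    predicted_abundance: float
    observed_intensity: float | None
    mz_error: float | None


@dataclass(frozen=True)
class MatchReport:
    matches: tuple[PeakMatch, ...]
    unmatched_observed: tuple[tuple[float, float], ...]
    tolerance: float

    @property
    def n_matched(self) -> int:
        return sum(1 for m in self.matches if m.observed_mz is not None)

    def intensity_ratio_deviations(self) -> list[float]:
        """|observed share - predicted abundance| over the matched peaks."""
        matched = [m for m in self.matches if m.observed_intensity is not None]
        total = sum(m.observed_intensity for m in matched)
        if not matched or total == 0:
            return []
        return [abs(m.observed_intensity / total - m.predicted_abundance) for m in matched]


def compare_peaklists(
    predicted: IsotopologuePattern,
    observed: list[tuple[float, float]],
    tolerance: float = 0.05,
) -> MatchReport:
    """Greedy nearest-m/z matching of a predicted pattern to observed peaks."""
    if not observed:
        raise ValueError("observed peak list is empty")
    remaining = list(observed)
    matches = []
    for j, mz, abundance in predicted.entries:
        best = None
        for peak in remaining:
            d = abs(peak[0] - mz)
            if d <= tolerance and (best is None or d < abs(best[0] - mz)):
                best = peak
        if best is None:
            matches.append(PeakMatch(mz, None, abundance, None, None))
        else:
            remaining.remove(best)
            matches.append(PeakMatch(mz, best[0], abundance, best[1], best[0] - mz))
    return MatchReport(
        matches=tuple(matches),
        unmatched_observed=tuple(remaining),
        tolerance=tolerance,
    )
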