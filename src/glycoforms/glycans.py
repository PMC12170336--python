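"""Glycan composition vocabulary: parsing, monoisotopic mass, class assignment
and database-level plausibility filtering.

A glycan *composition* is a multiset of monosaccharide (and small-modification)
residues; no linkage or branching information is modeled.  Compositions are
written in the open-search annotation dialect ``HexNAc(2)Hex(5)Fuc(1)``.

Classification is hierarchical: the first matching rule wins, so a glycan that
is both sialylated and fucosylated belongs to the sialylated class.  N- and
O-linked glycans use separate hierarchies (mannose processing only applies to
N-glycans; O-GlcNAc and sulfation only appear in the O hierarchy).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, fields

import pandas as pd

__all__ = [
    "GlycanComposition",
    "GlycanParseError",
    "RESIDUE_MASSES",
    "N_CLASSES",
    "O_CLASSES",
    "parse_composition",
    "glycan_mass",
    "classify_n",
    "classify_o",
    "filter_database",
    "read_glycan_list",
    "classification_table",
]

#: Monoisotopic residue masses in Da (residue = monosaccharide minus water,
#: i.e. the mass added to a peptide by incorporating the unit).
RESIDUE_MASSES = {
    "hexnac": 203.07937,
    "hex": 162.05282,
    "fuc": 146.05791,
    "neuac": 291.09542,
    "neugc": 307.09033,
    "phospho": 79.96633,
    "sulfo": 79.95682,
}

# Parse-time token names; dHex is a common synonym for fucose in search exports.
_TOKEN_TO_FIELD = {
    "hexnac": "hexnac",
    "hex": "hex",
    "fuc": "fuc",
    "dhex": "fuc",
    "neuac": "neuac",
    "neugc": "neugc",
    "phospho": "phospho",
    "sulfo": "sulfo",
}

# Canonical spellings used when formatting.
_FIELD_TO_TOKEN = {
    "hexnac": "HexNAc",
    "hex": "Hex",
    "fuc": "Fuc",
    "neuac": "NeuAc",
    "neugc": "NeuGc",
    "phospho": "Phospho",
    "sulfo": "Sulfo",
}

N_CLASSES = (
    "phospho",
    "sialylated",
    "fucosylated",
    "high_mannose",
    "paucimannose",
    "small",
    "complex_hybrid",
)

O_CLASSES = (
    "o_phospho",
    "o_sialylated",
    "o_fucosylated",
    "o_sulfated",
    "o_glcnac",
    "o_hexose",
    "o_hybrid",
)


class GlycanParseError(ValueError):
    """Raised when a composition string cannot be interpreted."""


@dataclass(frozen=True, order=True)
class GlycanComposition:
    """Residue counts of one glycan composition (all non-negative ints)."""

    hexnac: int = 0
    hex: int = 0
    fuc: int = 0
    neuac: int = 0
    neugc: int = 0
    phospho: int = 0
    sulfo: int = 0

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not isinstance(v, int) or v < 0:
                raise ValueError(f"residue count {f.name}={v!r} must be a non-negative int")

    @property
    def total(self) -> int:
        return self.hexnac + self.hex + self.fuc + self.neuac + self.neugc + self.phospho + self.sulfo

    @property
    def is_empty(self) -> bool:
        return self.total == 0

    @property
    def mass(self) -> float:
        return glycan_mass(self)

    def __str__(self) -> str:
        return "".join(
            f"{_FIELD_TO_TOKEN[f.name]}({getattr(self, f.name)})"
            for f in fields(self)
            if getattr(self, f.name) > 0
        )


_TOKEN_RE = re.compile(r"([A-Za-z]+)\((\d+)\)")


def parse_composition(text: str) -> GlycanComposition:
    """Parse a ``Name(count)`` token string into a :class:`GlycanComposition`.

    Recognized names (case-insensitive): HexNAc, Hex, Fuc (synonym dHex),
    NeuAc, NeuGc, Phospho, Sulfo.  Counts of repeated tokens accumulate.
    Raises :class:`GlycanParseError` on an empty string, an unknown residue
    name, or leftover characters.
    """
    if not isinstance(text, str) or not text.strip():
        raise GlycanParseError("empty composition string")
    text = text.strip()
    counts: dict[str, int] = {}
    pos = 0
    for m in _TOKEN_RE.finditer(text):
        if m.start() != pos:
            raise GlycanParseError(f"unparseable segment {text[pos:m.start()]!r} in {text!r}")
        name = m.group(1).lower()
        if name not in _TOKEN_TO_FIELD:
            raise GlycanParseError(f"unknown residue name {m.group(1)!r} in {text!r}")
        field = _TOKEN_TO_FIELD[name]
        counts[field] = counts.get(field, 0) + int(m.group(2))
        pos = m.end()
    if pos != len(text):
        raise GlycanParseError(f"unparseable segment {text[pos:]!r} in {text!r}")
    return GlycanComposition(**counts)


def glycan_mass(c: GlycanComposition) -> float:
    """Monoisotopic mass (Da): sum of residue counts times residue masses."""
    return sum(getattr(c, k) * m for k, m in RESIDUE_MASSES.items())


def classify_n(c: GlycanComposition) -> str:
    """Assign the N-glycan class of a composition (hierarchical, first match).

    Order: phospho > sialylated > fucosylated > high_mannose (HexNAc(2) core
    with 4-12 Hex, nothing else) > paucimannose (HexNAc(2) core with 1-3 Hex)
    > small (fewer than three HexNAc, nothing else) > complex_hybrid.
    """
    if c.is_empty:
        raise ValueError("cannot classify an empty composition")
    if c.phospho > 0:
        return "phospho"
    if c.neuac + c.neugc > 0:
        return "sialylated"
    if c.fuc > 0:
        return "fucosylated"
    # from here on fuc = neuac = neugc = phospho = 0
    if c.hexnac == 2 and 4 <= c.hex <= 12 and c.sulfo == 0:
        return "high_mannose"
    if c.hexnac == 2 and 1 <= c.hex <= 3 and c.sulfo == 0:
        return "paucimannose"
    if c.hexnac < 3 and c.hex == 0 and c.sulfo == 0:
        return "small"
    return "complex_hybrid"


def classify_o(c: GlycanComposition) -> str:
    """Assign the O-glycan class of a composition (hierarchical, first match).

    Order: o_phospho > o_sialylated > o_fucosylated > o_sulfated > o_glcnac
    (a single HexNAc, nothing else) > o_hexose (fewer than three HexNAc and at
    least one Hex, nothing else) > o_hybrid.
    """
    if c.is_empty:
        raise ValueError("cannot classify an empty composition")
    if c.phospho > 0:
        return "o_phospho"
    if c.neuac + c.neugc > 0:
        return "o_sialylated"
    if c.fuc > 0:
        return "o_fucosylated"
    if c.sulfo > 0:
        return "o_sulfated"
    if c.hexnac == 1 and c.hex == 0:
        return "o_glcnac"
    if c.hexnac < 3 and c.hex >= 1:
        return "o_hexose"
    return "o_hybrid"


def _rule_flags(c: GlycanComposition) -> tuple[bool, bool, bool]:
    sialic = c.neuac + c.neugc
    r1 = c.hexnac <= 2 * c.hex + 1
    # hex/2 evaluated as a real number; the sialic-acid total and fucose are
    # each bounded independently.
    bound = c.hex / 2 + 1
    r2 = sialic <= bound and c.fuc <= bound
    r3 = sialic + c.fuc <= 5
    return r1, r2, r3


def filter_database(entries: list[GlycanComposition]) -> pd.DataFrame:
    """Apply the three N-glycan-database plausibility rules to compositions.

    Rules (a composition is retained iff all three hold):

    1. ``HexNAc <= 2*Hex + 1``
    2. ``NeuAc+NeuGc <= Hex/2 + 1`` and ``Fuc <= Hex/2 + 1``
    3. ``NeuAc+NeuGc+Fuc <= 5``

    Returns a frame with one row per *unique* composition, columns
    ``composition`` (string), ``rule1_pass .. rule3_pass`` and ``retained``.
    """
    seen: dict[GlycanComposition, None] = {}
    for c in entries:
        seen.setdefault(c, None)
    rows = []
    for c in seen:
        r1, r2, r3 = _rule_flags(c)
        rows.append(
            {
                "composition": str(c),
                "rule1_pass": r1,
                "rule2_pass": r2,
                "rule3_pass": r3,
                "retained": r1 and r2 and r3,
            }
        )
    return pd.DataFrame(
        rows, columns=["composition", "rule1_pass", "rule2_pass", "rule3_pass", "retained"]
    )


def read_glycan_list(path) -> list[GlycanComposition]:
    """Read a glycan database file: one composition string per line.

    A tab-separated variant with extra columns (e.g. a mass column) is
    accepted; only the first field is parsed.  Blank lines and ``#`` comments
    are ignored.
    """
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            out.append(parse_composition(line.split("\t")[0]))
    return out


def classification_table(entries: list[GlycanComposition], mode: str) -> pd.DataFrame:
    """Tabulate composition, mode, class, mass and database-rule flags."""
    if mode not in ("N", "O"):
        raise ValueError(f"mode must be 'N' or 'O', got {mode!r}")
    classify = classify_n if mode == "N" else classify_o
    rows = []
    for c in entries:
        r1, r2, r3 = _rule_flags(c)
        rows.append(
            {
                "composition": str(c),
                "mode": mode,
                "glycan_class": classify(c),
                "mass": glycan_mass(c),
                "rule1_pass": r1,
                "rule2_pass": r2,
                "rule3_pass": r3,
            }
        )
    return pd.DataFrame(rows)
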