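"""Construct definitions: coil/linker libraries, parser, and bead-chain builder.

A designed polypeptide is an ordered list of coiled-coil (CC) "sticker"
segments joined by flexible "spacer" linkers.  Constructs are written in a
compact string grammar mirroring the naming used for the designs themselves:

* repeat groups: ``(S1h-S3h)3`` expands to ``S1h-S3h-S1h-S3h-S1h-S3h``
* runs: ``(S2h)3(S4h)3`` expands to three S2h coils followed by three S4h
* orientation strings: ``APPAPAPPAP`` — each letter is one homodimeric coil,
  ``A`` = antiparallel (APHh3), ``P`` = parallel (GCNh3)
* linker suffix: ``-gs`` (8 residues, default) or ``-gs40`` (40 residues)
* fluorescent-tag prefixes (``Cit-``, ``BFP-``) are accepted and dropped —
  tags are not part of the coarse-grained model.

The coil library covers the heterodimeric Sh set (3 heptads), the
heterodimeric Pf set (4 heptads) and the two homodimeric 3-heptad coils with
opposite pairing orientation.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field

import numpy as np

RESIDUES_PER_HEPTAD = 7

__all__ = [
    "CoilType",
    "LinkerType",
    "ConstructSpec",
    "BeadChain",
    "SystemSpec",
    "PanelEntry",
    "COIL_LIBRARY",
    "LINKER_LIBRARY",
    "ConstructParseError",
    "parse_construct",
    "render_construct",
    "build_chain",
    "design_panel",
]


class ConstructParseError(ValueError):
    """Raised when a construct string cannot be parsed."""


@dataclass(frozen=True)
class CoilType:
    """A coiled-coil sticker segment type.

    Parameters
    ----------
    name : str
        Identifier, e.g. ``"S1h"``.
    heptads : int
        Number of 7-residue heptad repeats (2--4 for the designs modelled).
    partners : frozenset[str]
        Names of coil types this coil dimerizes with.  Heterodimeric coils
        have exactly one partner; homodimeric coils list themselves.
    orientation : dict[str, str]
        Per-partner dimer orientation, ``"parallel"`` or ``"antiparallel"``.
    set_id : str
        Design set: ``"Sh"``, ``"Pf"`` or ``"homo"``.
    """

    name: str
    heptads: int
    partners: frozenset
    orientation: dict
    set_id: str

    @property
    def residues(self) -> int:
        return RESIDUES_PER_HEPTAD * self.heptads

    @property
    def homodimeric(self) -> bool:
        return self.name in self.partners


@dataclass(frozen=True)
class LinkerType:
    """A flexible spacer segment type (Gly/Ser-rich linker)."""

    name: str
    residues: int

    def __post_init__(self):
        if self.residues < 1:
            raise ValueError("linker must have at least one residue")


def _coil(name, heptads, partner, orient, set_id):
    return CoilType(
        name=name,
        heptads=heptads,
        partners=frozenset({partner}),
        orientation={partner: orient},
        set_id=set_id,
    )


#: Heterodimeric Sh set (3 heptads, parallel pairing: S1h–S2h, S3h–S4h),
#: heterodimeric Pf set (4 heptads, parallel: P5f–P6f, P13f–P14f) and the two
#: homodimeric 3-heptad coils: APHh3 pairs antiparallel, GCNh3 parallel.
COIL_LIBRARY: dict[str, CoilType] = {
    c.name: c
    for c in [
        _coil("S1h", 3, "S2h", "parallel", "Sh"),
        _coil("S2h", 3, "S1h", "parallel", "Sh"),
        _coil("S3h", 3, "S4h", "parallel", "Sh"),
        _coil("S4h", 3, "S3h", "parallel", "Sh"),
        _coil("P5f", 4, "P6f", "parallel", "Pf"),
        _coil("P6f", 4, "P5f", "parallel", "Pf"),
        _coil("P13f", 4, "P14f", "parallel", "Pf"),
        _coil("P14f", 4, "P13f", "parallel", "Pf"),
        _coil("APHh3", 3, "APHh3", "antiparallel", "homo"),
        _coil("GCNh3", 3, "GCNh3", "parallel", "homo"),
    ]
}

LINKER_LIBRARY: dict[str, LinkerType] = {
    "gs": LinkerType("gs", 8),
    "gs40": LinkerType("gs40", 40),
}

#: Orientation-letter aliases used in single-chain designs.
ORIENTATION_LETTERS = {"A": "APHh3", "P": "GCNh3"}

#: Fluorescent-protein tag prefixes accepted (and dropped) by the parser.
TAG_PREFIXES = ("Cit-", "BFP-", "mCitrine-", "mCit-")


@dataclass(frozen=True)
class ConstructSpec:
    """A parsed polypeptide design: ordered coil and linker segments.

    ``segments`` is an ordered list of ``("coil", name)`` / ``("linker",
    name)`` tuples; consecutive coils are separated by exactly one linker.
    """

    name: str
    segments: tuple

    def __post_init__(self):
        classes = [c for c, _ in self.segments]
        if "coil" not in classes:
            raise ValueError("construct needs at least one coil segment")
        for a, b in zip(classes, classes[1:]):
            if a == b:
                raise ValueError("coil and linker segments must alternate")

    @property
    def coil_names(self) -> tuple:
        return tuple(n for c, n in self.segments if c == "coil")

    @property
    def coil_count(self) -> int:
        return len(self.coil_names)

    @property
    def linker_names(self) -> tuple:
        return tuple(n for c, n in self.segments if c == "linker")

    @property
    def arrangement(self) -> str:
        return "-".join(self.coil_names)

    @property
    def n_residues(self) -> int:
        total = 0
        for cls, nm in self.segments:
            total += (
                COIL_LIBRARY[nm].residues if cls == "coil" else LINKER_LIBRARY[nm].residues
            )
        return total


_GROUP_RE = re.compile(r"^\(([^()]+)\)(\d*)")
_TOKEN_RE = re.compile(r"^[A-Za-z][A-Za-z0-9]*")


def _expand_token(token: str) -> list[str]:
    """Map a bare token to a list of coil names (A/P strings expand per letter)."""
    if token in COIL_LIBRARY:
        return [token]
    if token and all(ch in ORIENTATION_LETTERS for ch in token):
        return [ORIENTATION_LETTERS[ch] for ch in token]
    raise ConstructParseError(f"unknown coil token {token!r}")


def parse_construct(spec_string: str) -> ConstructSpec:
    """Parse a construct string into a :class:`ConstructSpec`.

    Examples
    --------
    >>> parse_construct("Cit-(S1h-S3h)3-gs").coil_count
    6
    >>> parse_construct("APPAPAPPAP-gs").coil_count
    10
    """
    s = spec_string.strip()
    if not s:
        raise ConstructParseError("empty construct string")
    original = s
    for tag in TAG_PREFIXES:
        if s.startswith(tag):
            s = s[len(tag):]
            break
    linker = "gs"
    if s.endswith("-gs40"):
        linker, s = "gs40", s[:-5]
    elif s.endswith("-gs"):
        s = s[:-3]
    if s.count("(") != s.count(")"):
        raise ConstructParseError(f"unbalanced parentheses in {original!r}")
    if not s:
        raise ConstructParseError(f"no coil segments in {original!r}")

    coils: list[str] = []
    pos = 0
    while pos < len(s):
        if s[pos] == "-":
            pos += 1
            continue
        if s[pos] == "(":
            m = _GROUP_RE.match(s[pos:])
            if m is None:
                raise ConstructParseError(f"malformed group at {s[pos:]!r}")
            inner, count = m.group(1), int(m.group(2) or "1")
            unit: list[str] = []
            for tok in inner.split("-"):
                unit.extend(_expand_token(tok))
            coils.extend(unit * count)
            pos += m.end()
        else:
            m = _TOKEN_RE.match(s[pos:])
            if m is None:
                raise ConstructParseError(f"unexpected character {s[pos]!r} in {original!r}")
            coils.extend(_expand_token(m.group(0)))
            pos += m.end()

    if not coils:
        raise ConstructParseError(f"no coil segments in {original!r}")

    segments: list[tuple] = []
    for i, c in enumerate(coils):
        if i:
            segments.append(("linker", linker))
        segments.append(("coil", c))
    return ConstructSpec(name=original, segments=tuple(segments))


def render_construct(spec: ConstructSpec) -> str:
    """Canonical string form: expanded arrangement plus linker suffix.

    Homodimer-only constructs render as orientation-letter strings
    (``APPAPAPPAP-gs``); all others as hyphen-joined coil names.
    """
    linkers = set(spec.linker_names) or {"gs"}
    if len(linkers) > 1:
        raise ValueError("mixed-linker constructs have no single-suffix canonical form")
    suffix = linkers.pop()
    names = spec.coil_names
    letter_map = {v: k for k, v in ORIENTATION_LETTERS.items()}
    if all(n in letter_map for n in names):
        body = "".join(letter_map[n] for n in names)
    else:
        body = "-".join(names)
    return f"{body}-{suffix}"


def canonical_form(spec_string: str) -> str:
    """Canonical form of a construct string (parse then render)."""
    return render_construct(parse_construct(spec_string))


@dataclass
class BeadChain:
    """One-bead-per-residue (C-alpha) topology of a single construct.

    Arrays are indexed by bead; coil beads carry a 1-based registry index
    numbered N→C within their segment, linker beads carry registry 0.
    """

    spec: ConstructSpec
    segment_ordinal: np.ndarray  # int, per bead
    segment_class: np.ndarray  # "coil" | "linker", per bead
    segment_name: np.ndarray  # coil type or linker name, per bead
    registry: np.ndarray  # 1..L within coil, 0 for linker

    @property
    def n_beads(self) -> int:
        return len(self.registry)

    def to_json(self) -> str:
        return json.dumps(
            {
                "construct": self.spec.name,
                "arrangement": self.spec.arrangement,
                "n_beads": self.n_beads,
                "segment_ordinal": self.segment_ordinal.tolist(),
                "segment_class": self.segment_class.tolist(),
                "segment_name": self.segment_name.tolist(),
                "registry": self.registry.tolist(),
            }
        )


def build_chain(spec: ConstructSpec) -> BeadChain:
    """Build the per-bead topology for one construct.

    Each residue becomes one bead; coil beads are numbered 1..7*heptads
    (N-terminus first), linker beads carry registry 0.
    """
    ordinals, classes, names, regs = [], [], [], []
    for ordinal, (cls, nm) in enumerate(spec.segments):
        if cls == "coil":
            n = COIL_LIBRARY[nm].residues
            regs.extend(range(1, n + 1))
        else:
            n = LINKER_LIBRARY[nm].residues
            regs.extend([0] * n)
        ordinals.extend([ordinal] * n)
        classes.extend([cls] * n)
        names.extend([nm] * n)
    return BeadChain(
        spec=spec,
        segment_ordinal=np.asarray(ordinals, dtype=np.int64),
        segment_class=np.asarray(classes, dtype=object),
        segment_name=np.asarray(names, dtype=object),
        registry=np.asarray(regs, dtype=np.int64),
    )


@dataclass
class SystemSpec:
    """A simulated system: constructs with copy numbers, box, temperature, seed.

    Box lengths are in nm (orthorhombic, periodic); temperature in K on the
    model's own scale (see the calibration utilities in :mod:`ccphase.slab`).
    """

    components: list  # list of (ConstructSpec, copy_number)
    box: tuple = (15.0, 15.0, 15.0)
    temperature: float = 310.0
    seed: int = 0

    def __post_init__(self):
        for _, copies in self.components:
            if copies < 1:
                raise ValueError("copy_number must be >= 1")
        if any(b <= 0 for b in self.box):
            raise ValueError("box lengths must be positive")


@dataclass(frozen=True)
class PanelEntry:
    """One design combination with its experimentally observed phase label.

    ``expected`` uses the closed vocabulary {condensate, dimer, diffuse}.
    ``strict`` marks entries where the sub-label (dimer vs diffuse) is itself
    established; for the rest agreement is judged on condensate vs not.
    """

    key: str
    constructs: tuple  # construct strings, one per component
    expected: str
    strict: bool
    note: str

    @property
    def expected_condensate(self) -> bool:
        return self.expected == "condensate"


def design_panel() -> list[PanelEntry]:
    """The full panel of simulated design combinations with observed outcomes.

    Covers the two-component 3-heptad pairs (mismatched vs matched
    arrangement), the 4-heptad pair, the single-chain orientation-patterned
    designs, and the third-chain inhibition (blind-challenge) combinations.
    """
    E = PanelEntry
    return [
        E(
            "mixed_3h_pair",
            ("Cit-(S1h-S3h)3-gs", "BFP-(S2h)3(S4h)3-gs"),
            "condensate",
            True,
            "alternating + clustered 3-heptad pair; condensate (Fig. 3b/e)",
        ),
        E(
            "matched_3h_pair",
            ("Cit-(S1h-S3h)3-gs", "BFP-(S2h-S4h)3-gs"),
            "dimer",
            True,
            "same sequential arrangement; dimer-poisoned, no condensate (Fig. 3f/g)",
        ),
        E(
            "mixed_4h_pair",
            ("Cit-(P5f-P13f)3-gs", "BFP-(P6f)3(P14f)3-gs"),
            "condensate",
            True,
            "4-heptad pair; condensate, largely immobile (Fig. 3h/j)",
        ),
        E(
            "appap",
            ("Cit-APPAP-gs",),
            "diffuse",
            False,
            "5-segment orientation-patterned single chain; no condensate (Fig. 4b/e)",
        ),
        E(
            "pppppp_aaaa",
            ("Cit-PPPPPPAAAA-gs",),
            "diffuse",
            False,
            "segregated arrangement; no condensate (Fig. 4c/f)",
        ),
        E(
            "appapappap",
            ("Cit-APPAPAPPAP-gs",),
            "condensate",
            True,
            "10-segment orientation-patterned single chain; condensate (Fig. 4d/g)",
        ),
        E(
            "blind_poisoned_triple",
            ("Cit-(S1h-S3h)3-gs", "BFP-(S2h)3(S4h)3-gs", "Cit-(S1h)4-gs"),
            "dimer",
            False,
            "blind challenge a: (S1h)4 occupies S2h cluster; no condensate",
        ),
        E(
            "blind_s_pair",
            ("Cit-(S1h-S3h)3-gs", "BFP-(S2h)4-gs"),
            "condensate",
            True,
            "blind challenge b: alternating vs run-of-4; condensate",
        ),
        E(
            "blind_p_pair",
            ("Cit-(P5f-P13f)3-gs", "BFP-(P6f)4-gs"),
            "condensate",
            True,
            "blind challenge c: condensate",
        ),
        E(
            "blind_p_poisoned_pair",
            ("BFP-(P6f)3(P14f)3-gs", "Cit-(P5f)4-gs"),
            "dimer",
            False,
            "blind challenge d: (P5f)4 saturates the P6f cluster; no condensate",
        ),
        E(
            "blind_p_triple",
            ("Cit-(P5f-P13f)3-gs", "Cit-(P5f)4-gs", "BFP-(P6f)4-gs"),
            "dimer",
            False,
            "blind challenge e: short chains dimerize, long chain excluded; no condensate",
        ),
    ]
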