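"""Parsing and structural bookkeeping for stapled-peptide sequences.

Stapled peptides in an MDM2/p53 SAR library are written in a compact
hyphen-delimited notation, e.g.::

    Ac-LTF[R8]EYWQL[Cba][S5]SAA-amide
    Ac-K(N3)-(βA)-LTF[R8]EYWAQ[Cba][S5]SAA-amide

Single uppercase letters are the natural L-amino acids; bracketed tokens
are non-natural residues (the olefinic staple anchors ``R8`` and ``S5``,
``Aib``, ``Cba``) or modified residues (``[D-X]`` for a D-amino acid,
``[NMe-X]`` for an N-methylated one).  Leading hyphen-separated tokens
before the residue body are N-terminal caps (``Ac``, ``K(N3)``, ``(βA)``);
the trailing token is the C-terminal cap (``amide``).

Residue positions are 1-based and follow the library table convention:
the printed columns 1-11 plus the C-terminal S-A-A tail at positions
12-14.  Caps are unnumbered.  A hydrocarbon staple spans i to i+7, so a
valid stapled sequence carries exactly one ``R8`` and one ``S5`` seven
positions apart.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Optional, Sequence

__all__ = [
    "Residue",
    "Peptide",
    "PeptideParseError",
    "StapleTopologyError",
    "parse_sequence",
    "render_sequence",
    "residue_count",
    "classify_position",
    "INTERFACIAL_POSITIONS",
]

#: Positions making direct contact with the MDM2 binding cleft
#: (Phe3, Trp7, Cba10 occupy the Phe19/Trp23/Leu26 sub-pockets of p53).
INTERFACIAL_POSITIONS: tuple[int, ...] = (3, 7, 10)

_NATURAL = set("ACDEFGHIKLMNPQRSTVWY")
_ACHIRAL_NATURAL = {"G"}
#: non-natural residue tokens registered as opaque identities
_SPECIAL = {
    "Aib": dict(chirality="achiral", note="alpha-aminoisobutyric acid, alpha-methylated helix inducer"),
    "Cba": dict(chirality="L", note="cyclobutylalanine, Leu26-pocket hydrophobe"),
    "R8": dict(chirality="L", note="(R)-2-(7-octenyl)alanine staple anchor", anchor=True),
    "S5": dict(chirality="L", note="(S)-2-(4-pentenyl)alanine staple anchor", anchor=True),
    "K(N3)": dict(chirality="L", note="azido-lysine"),
}
_STAPLE_ANCHORS = ("R8", "S5")
_STAPLE_SPACING = 7

#: cap vocabulary; True marks amino-acid-like caps counted by
#: ``residue_count(include_caps=True)``
_N_CAPS = {"Ac": False, "K(N3)": True, "(βA)": True, "βA": True, "(bA)": True}
_C_CAPS = {"amide", "NH2"}


class PeptideParseError(ValueError):
    """Raised when a notation string cannot be tokenized."""


class StapleTopologyError(ValueError):
    """Raised when staple anchors are absent, unpaired, or not i/i+7."""


@dataclass(frozen=True)
class Residue:
    """One position of a peptide.

    ``code`` is the base token (``L``, ``Cba``, ``R8``...); chirality and
    N-methylation are carried separately so ``[D-F]`` and ``F`` share a code.
    """

    code: str
    chirality: Literal["L", "D", "achiral"] = "L"
    n_methylated: bool = False
    is_staple_anchor: bool = False
    sidechain_note: str = ""

    def __post_init__(self) -> None:
        if self.chirality not in ("L", "D", "achiral"):
            raise ValueError(f"invalid chirality {self.chirality!r}")
        if self.code in ("G", "Aib") and self.chirality != "achiral":
            raise ValueError(f"{self.code} must be achiral")

    @property
    def token(self) -> str:
        """Canonical notation token (with D-/NMe- prefixes, no brackets)."""
        t = self.code
        if self.chirality == "D":
            t = f"D-{t}"
        if self.n_methylated:
            t = f"NMe-{t}"
        return t


@dataclass(frozen=True)
class Peptide:
    """A parsed peptide: caps, ordered residues, optional staple."""

    name: str
    residues: tuple[Residue, ...]
    n_cap: tuple[str, ...] = ("Ac",)
    c_cap: str = "amide"
    staple_pair: Optional[tuple[int, int]] = None

    def __post_init__(self) -> None:
        if self.staple_pair is not None:
            i, j = self.staple_pair
            if j - i != _STAPLE_SPACING:
                raise StapleTopologyError(
                    f"staple anchors at {i}/{j}: spacing {j - i}, expected {_STAPLE_SPACING}"
                )
            for pos in (i, j):
                if not self.residues[pos - 1].is_staple_anchor:
                    raise StapleTopologyError(f"position {pos} is not a staple anchor")

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def is_stapled(self) -> bool:
        return self.staple_pair is not None

    def render(self) -> str:
        return render_sequence(self)


def _make_residue(token: str, position: int) -> Residue:
    chirality = "L"
    n_methylated = False
    base = token
    if base.startswith("NMe-") or base.startswith("Nme-"):
        n_methylated = True
        base = base[4:]
    if base.startswith("D-"):
        chirality = "D"
        base = base[2:]
    if base in _SPECIAL:
        info = _SPECIAL[base]
        if chirality == "D" and info["chirality"] == "achiral":
            raise PeptideParseError(
                f"token {token!r} at position {position}: D flag on achiral residue"
            )
        return Residue(
            code=base,
            chirality="D" if chirality == "D" else info["chirality"],
            n_methylated=n_methylated,
            is_staple_anchor=bool(info.get("anchor")),
            sidechain_note=info["note"],
        )
    if base in _NATURAL:
        if base in _ACHIRAL_NATURAL:
            if chirality == "D":
                raise PeptideParseError(
                    f"token {token!r} at position {position}: D flag on achiral residue"
                )
            chirality = "achiral"
        return Residue(code=base, chirality=chirality, n_methylated=n_methylated)
    raise PeptideParseError(f"unknown residue token {token!r} at position {position}")


def _split_top_level(notation: str) -> list[str]:
    """Split on '-' outside brackets/parentheses."""
    segments: list[str] = []
    depth = 0
    current: list[str] = []
    for ch in notation:
        if ch in "[(":
            depth += 1
        elif ch in "])":
            depth -= 1
            if depth < 0:
                raise PeptideParseError(f"unbalanced bracket in {notation!r}")
        if ch == "-" and depth == 0:
            segments.append("".join(current))
            current = []
        else:
            current.append(ch)
    if depth != 0:
        raise PeptideParseError(f"unbalanced bracket in {notation!r}")
    segments.append("".join(current))
    return segments


def _tokenize_body(body: str) -> list[str]:
    tokens: list[str] = []
    i = 0
    while i < len(body):
        ch = body[i]
        if ch == "[":
            j = body.index("]", i)
            tokens.append(body[i + 1 : j])
            i = j + 1
        elif ch.isalpha() and ch.isupper():
            tokens.append(ch)
            i += 1
        else:
            raise PeptideParseError(
                f"unexpected character {ch!r} at body offset {i} in {body!r}"
            )
    return tokens


def parse_sequence(notation: str, name: str = "") -> Peptide:
    """Parse a hyphen-delimited peptide notation into a :class:`Peptide`.

    >>> p = parse_sequence("Ac-LTF[R8]EYWQL[Cba][S5]SAA-amide")
    >>> len(p), p.staple_pair
    (14, (4, 11))

    Raises :class:`PeptideParseError` for empty input or unknown tokens
    (the error names the token and position) and
    :class:`StapleTopologyError` when staple anchors are unpaired or not
    spaced i/i+7.
    """
    if not notation or not notation.strip():
        raise PeptideParseError("empty notation")
    segments = _split_top_level(notation.strip())
    if len(segments) < 2:
        raise PeptideParseError(f"notation {notation!r} lacks hyphen-delimited caps")
    c_cap = segments[-1]
    if c_cap not in _C_CAPS:
        raise PeptideParseError(f"unknown C-terminal cap {c_cap!r}")
    n_cap: list[str] = []
    body_idx = None
    for idx, seg in enumerate(segments[:-1]):
        if seg in _N_CAPS:
            # canonicalize βA spelling
            n_cap.append("(βA)" if seg in ("βA", "(βA)", "(bA)") else seg)
        else:
            body_idx = idx
            break
    if body_idx is None or body_idx != len(segments) - 2:
        raise PeptideParseError(
            f"could not locate a single residue body in {notation!r}"
        )
    tokens = _tokenize_body(segments[body_idx])
    if not tokens:
        raise PeptideParseError(f"empty residue body in {notation!r}")
    residues = tuple(_make_residue(t, i + 1) for i, t in enumerate(tokens))

    anchors = [i + 1 for i, r in enumerate(residues) if r.is_staple_anchor]
    staple_pair: Optional[tuple[int, int]] = None
    if anchors:
        if len(anchors) != 2:
            raise StapleTopologyError(
                f"expected 0 or 2 staple anchors, found {len(anchors)} at {anchors}"
            )
        staple_pair = (anchors[0], anchors[1])  # spacing checked in Peptide

    return Peptide(
        name=name,
        residues=residues,
        n_cap=tuple(n_cap),
        c_cap="amide",
        staple_pair=staple_pair,
    )


def render_sequence(p: Peptide) -> str:
    """Render a :class:`Peptide` back to canonical notation.

    ``parse_sequence(render_sequence(p))`` is the identity on the parsed
    structure for every library row.
    """
    parts = list(p.n_cap)
    body = []
    for r in p.residues:
        tok = r.token
        body.append(tok if len(tok) == 1 else f"[{tok}]")
    parts.append("".join(body))
    parts.append(p.c_cap)
    return "-".join(parts)


def residue_count(p: Peptide, include_caps: bool = False) -> int:
    """Number of residues; the MRE-per-residue denominator for CD analysis.

    With ``include_caps=True``, amino-acid-like N-terminal cap tokens
    (azido-lysine, β-alanine) are counted too; acetyl and amide are not.
    """
    n = len(p.residues)
    if include_caps:
        n += sum(1 for cap in p.n_cap if _N_CAPS.get(cap, False))
    return n


def classify_position(
    p: Peptide,
    position: int,
    interfacial: Sequence[int] = INTERFACIAL_POSITIONS,
) -> str:
    """Classify a 1-based position as ``staple``, ``interfacial`` or
    ``non-interfacial``.

    The default interfacial set {3, 7, 10} holds the three hot-spot
    residues (Phe3, Trp7, Cba10) whose Ala substitution costs 10- to
    100-fold in MDM2 affinity; staple positions come from the peptide's
    own ``staple_pair``.
    """
    if not 1 <= position <= len(p):
        raise IndexError(f"position {position} out of range 1..{len(p)}")
    if p.staple_pair is not None and position in p.staple_pair:
        return "staple"
    if position in interfacial:
        return "interfacial"
    return "non-interfacial"
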