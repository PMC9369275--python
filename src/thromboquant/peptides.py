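"""Peptide sequence arithmetic for the flow-assay inhibitor peptides.

Parses the shorthand peptide notation used for the GPR56 tethered-ligand
mimic (pGRP, ``TYFAVLM``) and the CIB1-blocking integrin-αIIb cytoplasmic
peptides (pCIB and its mutated variant pCIBm), and reproduces the sequence
arithmetic that can be recomputed from the sequences alone: length,
substitution count between variants, and theoretical monoisotopic mass.

Masses are computed from a residue table of monoisotopic masses (sum of the
residue masses plus one water for the free linear peptide).  Printed
"theoretical monoisotopic" masses in peptide-synthesis reports conventionally
drop the decimal fraction rather than rounding, so :func:`integer_mass`
truncates; see docs/methods.md.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from enum import Enum
from typing import Dict

__all__ = [
    "PeptideSequence",
    "PeptideParseError",
    "NTerminalMod",
    "CTerminal",
    "MONOISOTOPIC_RESIDUE_MASS",
    "WATER_MONO",
    "ACETYL_MONO",
    "AMIDE_MONO_DELTA",
    "parse_peptide",
    "monoisotopic_mass",
    "integer_mass",
    "count_mutations",
    "PGRP",
    "PCIB",
    "PCIB_M",
]

# Monoisotopic residue masses (Da): the mass each amino acid contributes once
# condensed into a chain, i.e. the free amino acid minus one water.
# Values are exact atomic-composition sums over NIST isotope masses
# (C 12, H 1.00782503, N 14.00307401, O 15.99491462, S 31.97207117).
MONOISOTOPIC_RESIDUE_MASS: Dict[str, float] = {
    "G": 57.02146372,  # C2H3NO
    "A": 71.03711378,  # C3H5NO
    "S": 87.03202840,  # C3H5NO2
    "P": 97.05276384,  # C5H7NO
    "V": 99.06841391,  # C5H9NO
    "T": 101.04767846,  # C4H7NO2
    "C": 103.00918447,  # C3H5NOS
    "L": 113.08406397,  # C6H11NO
    "I": 113.08406397,  # C6H11NO
    "N": 114.04292744,  # C4H6N2O2
    "D": 115.02694302,  # C4H5NO3
    "Q": 128.05857750,  # C5H8N2O2
    "K": 128.09496301,  # C6H12N2O
    "E": 129.04259308,  # C5H7NO3
    "M": 131.04048460,  # C5H9NOS
    "H": 137.05891185,  # C6H7N3O
    "F": 147.06841391,  # C9H9NO
    "R": 156.10111102,  # C6H12N4O
    "Y": 163.06332853,  # C9H9NO2
    "W": 186.07931294,  # C11H10N2O
}

WATER_MONO = 18.01056468  # H2O
ACETYL_MONO = 42.01056468  # +C2H2O on the N-terminus
AMIDE_MONO_DELTA = -0.98401558  # C-terminal OH -> NH2 (−O +NH)


class NTerminalMod(str, Enum):
    FREE = "free"
    ACETYL = "acetyl"


class CTerminal(str, Enum):
    FREE_ACID = "free-acid"
    AMIDE = "amide"


class PeptideParseError(ValueError):
    """Raised for notation that cannot be interpreted as a peptide."""


@dataclass(frozen=True)
class PeptideSequence:
    """A linear peptide: one-letter residues plus terminal chemistry."""

    residues: str
    n_terminal_mod: NTerminalMod = NTerminalMod.FREE
    c_terminal: CTerminal = CTerminal.FREE_ACID

    def __post_init__(self) -> None:
        if not self.residues:
            raise PeptideParseError("empty peptide sequence")
        for i, aa in enumerate(self.residues):
            if aa not in MONOISOTOPIC_RESIDUE_MASS:
                raise PeptideParseError(
                    f"unknown residue {aa!r} at position {i + 1}"
                )

    def __len__(self) -> int:
        return len(self.residues)


_NTERM_PREFIXES = {"ACE-": NTerminalMod.ACETYL, "AC-": NTerminalMod.ACETYL}
_CTERM_SUFFIXES = {"-OH": CTerminal.FREE_ACID, "-NH2": CTerminal.AMIDE}


def parse_peptide(text: str) -> PeptideSequence:
    """Parse peptide notation such as ``Ace-LVLAMWKVGFF...-OH``.

    ``Ace-``/``Ac-`` prefixes mark N-terminal acetylation; ``-OH`` and
    ``-NH2`` suffixes mark a free-acid or amidated C-terminus.  Whitespace
    inside the sequence (a typographic artifact of printed sequences) is
    ignored, and parsing is case-insensitive.
    """
    if not isinstance(text, str) or not text.strip():
        raise PeptideParseError("empty peptide string")
    s = re.sub(r"\s+", "", text).upper()

    n_mod = NTerminalMod.FREE
    for prefix, mod in _NTERM_PREFIXES.items():
        if s.startswith(prefix):
            n_mod = mod
            s = s[len(prefix):]
            break
    c_term = CTerminal.FREE_ACID
    for suffix, term in _CTERM_SUFFIXES.items():
        if s.endswith(suffix):
            c_term = term
            s = s[: -len(suffix)]
            break
    return PeptideSequence(residues=s, n_terminal_mod=n_mod, c_terminal=c_term)


def monoisotopic_mass(p: PeptideSequence, include_mods: bool = False) -> float:
    """Theoretical monoisotopic mass in Da.

    The base value is the residue-mass sum plus one water, i.e. the linear
    peptide with free N- and C-termini.  With ``include_mods`` the terminal
    chemistry carried by the sequence (acetylation, C-terminal amide) is
    added; printed theoretical masses for these peptides correspond to the
    unmodified linear chain, so the default is off.
    """
    mass = sum(MONOISOTOPIC_RESIDUE_MASS[aa] for aa in p.residues) + WATER_MONO
    if include_mods:
        if p.n_terminal_mod is NTerminalMod.ACETYL:
            mass += ACETYL_MONO
        if p.c_terminal is CTerminal.AMIDE:
            mass += AMIDE_MONO_DELTA
    return mass


def integer_mass(p: PeptideSequence, include_mods: bool = False) -> int:
    """Mass truncated to integer daltons, the convention of printed values.

    Synthesis reports quote e.g. "3102 Da" for a peptide of monoisotopic mass
    3102.56 Da: the decimal fraction is dropped, not rounded.
    """
    return math.floor(monoisotopic_mass(p, include_mods=include_mods))


def count_mutations(a: PeptideSequence, b: PeptideSequence) -> int:
    """Hamming distance between two equal-length peptides."""
    if len(a) != len(b):
        raise ValueError(
            f"sequences differ in length ({len(a)} vs {len(b)}); "
            "mutation count requires equal lengths"
        )
    return sum(x != y for x, y in zip(a.residues, b.residues))


# The study's peptides, as printed (the internal space in pCIB is typographic).
PGRP = parse_peptide("TYFAVLM")
PCIB = parse_peptide("Ace-LVLAMWKVGFFKRNRPP LEEDDEEGQ-OH")
PCIB_M = parse_peptide("Ace-LVRKMWQVGFYKRNRYPLEEDDEEGQ-OH")
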