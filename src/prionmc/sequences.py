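"""Capped peptide sequences of the prion hydrophobic domain.

The package models the murine prion protein fragments spanning residues
109-122 and 106-126 (human numbering), each blocked with an N-terminal
acetyl and a C-terminal amide group, together with their A117V variants
associated with Gerstmann-Straussler-Scheinker disease.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

#: The 20 standard one-letter amino-acid codes.
STANDARD_RESIDUES = set("ACDEFGHIKLMNPQRSTVWY")

#: Built-in peptides: label -> (one-letter sequence, human number of position 1).
BUILTIN_PEPTIDES: dict[str, tuple[str, int]] = {
    "109-122": ("LKHVAGAAAAGAVV", 109),
    "109-122_A117V": ("LKHVAGAAVAGAVV", 109),
    "106-126": ("KTNLKHVAGAAAAGAVVGGLG", 106),
    "106-126_A117V": ("KTNLKHVAGAAVAGAVVGGLG", 106),
}

_CAPPED_RE = re.compile(r"^Acetyl-([A-Za-z]*)-NH2$")


@dataclass(frozen=True)
class PeptideSequence:
    """An acetyl/amide-capped peptide in human prion numbering.

    ``numbering_offset`` maps chain position 1 to the human residue number
    (109 for the 14-mer fragments, 106 for the 21-mers), so e.g. the A117V
    substitution site is position ``117 - offset + 1``.
    """

    residues: str
    label: str = ""
    numbering_offset: int = 109
    n_term_cap: bool = True
    c_term_cap: bool = True

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError("empty peptide sequence")
        bad = set(self.residues) - STANDARD_RESIDUES
        if bad:
            raise ValueError(f"unknown residue letter(s): {sorted(bad)}")
        if not (self.n_term_cap and self.c_term_cap):
            raise ValueError("peptides must carry both acetyl and amide caps")

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def residue_numbers(self) -> list[int]:
        """Human residue numbers, one per position."""
        return [self.numbering_offset + i for i in range(len(self.residues))]

    def human_number(self, position: int) -> int:
        """Human number of 1-based chain position."""
        if not 1 <= position <= len(self):
            raise IndexError(f"position {position} outside 1..{len(self)}")
        return self.numbering_offset + position - 1

    def position_of(self, human_number: int) -> int:
        """1-based chain position of a human residue number."""
        pos = human_number - self.numbering_offset + 1
        if not 1 <= pos <= len(self):
            raise IndexError(f"residue {human_number} not in this peptide")
        return pos

    def residue_at(self, human_number: int) -> str:
        return self.residues[self.position_of(human_number) - 1]


def parse_sequence(text: str, label: str = "", numbering_offset: int | None = None) -> PeptideSequence:
    """Parse an ``Acetyl-<one letter codes>-NH2`` string.

    The caps are mandatory: the peptides this package studies are always
    acetylated and amidated, and uncapped termini would change both the
    hydrogen-bonding pattern and the charge state.
    """
    m = _CAPPED_RE.match(text.strip())
    if m is None:
        raise ValueError(
            f"sequence {text!r} does not match 'Acetyl-<residues>-NH2' (caps are required)"
        )
    residues = m.group(1).upper()
    if numbering_offset is None:
        # 21-mers are the 106-126 fragments, 14-mers the 109-122 ones.
        numbering_offset = 106 if len(residues) == 21 else 109
    return PeptideSequence(residues, label=label, numbering_offset=numbering_offset)


def get_peptide(name: str) -> PeptideSequence:
    """Look up one of the built-in peptides by label (e.g. ``"109-122_A117V"``)."""
    key = name.replace(" ", "_")
    if key not in BUILTIN_PEPTIDES:
        raise KeyError(f"unknown peptide {name!r}; known: {sorted(BUILTIN_PEPTIDES)}")
    seq, offset = BUILTIN_PEPTIDES[key]
    return PeptideSequence(seq, label=key, numbering_offset=offset)
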