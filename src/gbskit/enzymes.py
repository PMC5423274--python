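"""Restriction enzyme definitions and IUPAC recognition-site handling.

Enzyme biology lives in data, not code: the module ships the three enzymes
used in common reduced-representation protocols (ApeKI for single digests,
PstI + MspI for double digests) and accepts arbitrary user-defined enzymes
as long as their recognition site is palindromic under IUPAC degeneracy
(non-palindromic sites would require scanning both strands, which this
package does not do and rejects at parse time).
"""

from __future__ import annotations

from dataclasses import dataclass

# IUPAC nucleotide codes -> set of concrete bases
IUPAC: dict[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"), "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"), "W": frozenset("AT"),
    "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"), "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def iupac_complement(code: str) -> str:
    """Complement of an IUPAC string (degenerate codes map to their complement sets)."""
    return code.translate(_COMPLEMENT)


def reverse_complement(seq: str) -> str:
    return iupac_complement(seq)[::-1]


@dataclass(frozen=True)
class RestrictionEnzyme:
    """A restriction enzyme with a (possibly degenerate) recognition site.

    Parameters
    ----------
    name : str
        Enzyme name, e.g. ``"ApeKI"``.
    recognition : str
        IUPAC recognition sequence on the top strand, e.g. ``"GCWGC"``.
    cut_offset : int
        Cut position in bases from the start of the recognition site on the
        top strand (0 <= cut_offset <= len(recognition)).
    """

    name: str
    recognition: str
    cut_offset: int

    def __post_init__(self) -> None:
        if not self.recognition:
            raise ValueError(f"{self.name}: empty recognition sequence")
        rec = self.recognition.upper()
        bad = set(rec) - set(IUPAC)
        if bad:
            raise ValueError(f"{self.name}: invalid IUPAC code(s) {sorted(bad)}")
        object.__setattr__(self, "recognition", rec)
        if not (0 <= self.cut_offset <= len(rec)):
            raise ValueError(
                f"{self.name}: cut_offset {self.cut_offset} outside recognition "
                f"site of length {len(rec)}"
            )
        if reverse_complement(rec) != rec:
            raise ValueError(
                f"{self.name}: recognition site {rec} is not palindromic under "
                "IUPAC degeneracy; only palindromic enzymes are supported "
                "(top-strand scanning)"
            )

    @property
    def site_length(self) -> int:
        return len(self.recognition)

    def matches_at(self, sequence: str, pos: int) -> bool:
        """True if the recognition site matches ``sequence`` at ``pos``."""
        site = self.recognition
        if pos < 0 or pos + len(site) > len(sequence):
            return False
        return all(sequence[pos + i] in IUPAC[c] for i, c in enumerate(site))


# Default enzymes (standard REBASE recognition sites; '^' marks the cut).
APEKI = RestrictionEnzyme("ApeKI", "GCWGC", 1)      # G^CWGC
PSTI = RestrictionEnzyme("PstI", "CTGCAG", 5)       # CTGCA^G
MSPI = RestrictionEnzyme("MspI", "CCGG", 1)         # C^CGG

DEFAULT_ENZYMES: dict[str, RestrictionEnzyme] = {
    e.name: e for e in (APEKI, PSTI, MSPI)
}


def get_enzyme(name: str) -> RestrictionEnzyme:
    try:
        return DEFAULT_ENZYMES[name]
    except KeyError:
        raise KeyError(
            f"unknown enzyme {name!r}; known: {sorted(DEFAULT_ENZYMES)}"
        ) from None
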