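"""Tryptic cleavage-conformity classification of peptides.

Trypsin cleaves C-terminal to lysine (K) and arginine (R).  A peptide
observed in a bottom-up experiment therefore has two cleavage sites, one
at each terminus, and each site either conforms to tryptic specificity
or not.  A peptide whose one terminus conforms while the other does not
("semi-tryptic") is the signature of a truncation product: a fully
tryptic peptide that was shortened from one end, most plausibly by
endo-/exo-proteases acting on the protein before or during sample
preparation.  Counting the intensity carried by such peptides is the
basis of the proteome-integrity scoring in :mod:`proteopin.pin_core`.
"""

from __future__ import annotations

import enum

__all__ = ["CleavageClass", "classify_cleavage", "TERMINUS", "VALID_RESIDUES"]

#: Sentinel flanking "residue" marking a protein terminus.  A peptide that
#: starts at the protein N-terminus (or ends at the C-terminus) has no
#: cleavage site there, so the terminus conforms by definition.
TERMINUS = "-"

#: The 20 canonical amino acids plus selenocysteine (U).
VALID_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWYU")


class CleavageClass(enum.Enum):
    """Tryptic conformity of a peptide's two termini.

    The two SEMI values record *which* terminus is non-conforming; for
    integrity scoring they collapse into a single "semi-tryptic"
    category (see :meth:`is_semi_tryptic`).
    """

    FULLY_TRYPTIC = "full"
    SEMI_TRYPTIC_NTERM_NONCONFORMING = "semi_n"
    SEMI_TRYPTIC_CTERM_NONCONFORMING = "semi_c"
    NON_TRYPTIC = "non"

    @property
    def is_semi_tryptic(self) -> bool:
        return self in (
            CleavageClass.SEMI_TRYPTIC_NTERM_NONCONFORMING,
            CleavageClass.SEMI_TRYPTIC_CTERM_NONCONFORMING,
        )

    @classmethod
    def from_label(cls, label: str) -> "CleavageClass":
        """Parse a short label (``full``/``semi_n``/``semi_c``/``non``)."""
        try:
            return cls(label.strip().lower())
        except ValueError:
            raise ValueError(f"unknown cleavage label {label!r}") from None


def _check_residues(sequence: str) -> None:
    bad = set(sequence) - VALID_RESIDUES
    if bad:
        raise ValueError(
            f"sequence {sequence!r} contains non-amino-acid characters: "
            f"{''.join(sorted(bad))}"
        )


def classify_cleavage(
    sequence: str,
    preceding: str,
    following: str,
    proline_rule: bool = False,
) -> CleavageClass:
    """Classify a peptide's tryptic conformity from its flanking residues.

    Parameters
    ----------
    sequence
        Uppercase amino-acid sequence of the peptide.
    preceding
        Residue immediately N-terminal of the peptide in its protein, or
        :data:`TERMINUS` if the peptide starts at the protein N-terminus.
    following
        Residue immediately C-terminal of the peptide, or :data:`TERMINUS`
        if the peptide ends at the protein C-terminus.
    proline_rule
        If True, cleavage before a proline is considered blocked — on
        *either* side of the peptide (the classical trypsin convention;
        off by default because semi-tryptic search engines typically do
        not enforce it).

    Returns
    -------
    CleavageClass
        FULLY_TRYPTIC when both termini conform; one of the SEMI values
        when exactly one conforms; NON_TRYPTIC when neither does.
    """
    if not sequence:
        raise ValueError("peptide sequence must be non-empty")
    sequence = sequence.upper()
    _check_residues(sequence)
    for flank, side in ((preceding, "preceding"), (following, "following")):
        if flank != TERMINUS and (len(flank) != 1 or flank.upper() not in VALID_RESIDUES):
            raise ValueError(f"{side} flank {flank!r} is not a residue or {TERMINUS!r}")

    preceding = preceding.upper() if preceding != TERMINUS else TERMINUS
    following = following.upper() if following != TERMINUS else TERMINUS

    n_conforms = preceding == TERMINUS or (
        preceding in "KR" and not (proline_rule and sequence[0] == "P")
    )
    c_conforms = following == TERMINUS or (
        sequence[-1] in "KR" and not (proline_rule and following == "P")
    )

    if n_conforms and c_conforms:
        return CleavageClass.FULLY_TRYPTIC
    if c_conforms:
        return CleavageClass.SEMI_TRYPTIC_NTERM_NONCONFORMING
    if n_conforms:
        return CleavageClass.SEMI_TRYPTIC_CTERM_NONCONFORMING
    return CleavageClass.NON_TRYPTIC
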