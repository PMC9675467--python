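"""Low-level nucleotide utilities: IUPAC matching and reverse complement.

Coordinates throughout the package are 0-based, half-open. Sequences are
plain Python strings over the unambiguous DNA alphabet; IUPAC ambiguity
codes are legal in PAM motifs but rejected in reference sequences.
"""

from __future__ import annotations

IUPAC = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")

DNA_BASES = frozenset("ACGT")


def revcomp(seq: str) -> str:
    """Reverse complement of an unambiguous DNA string."""
    return seq.translate(_COMPLEMENT)[::-1]


def validate_dna(seq: str, *, what: str = "sequence") -> str:
    """Upper-case ``seq`` and reject any non-ACGT character."""
    up = seq.upper()
    bad = set(up) - DNA_BASES
    if bad:
        raise ValueError(
            f"{what} contains non-ACGT characters: {sorted(bad)!r} "
            "(IUPAC ambiguity codes are not expanded in references)"
        )
    return up


def validate_motif(motif: str) -> str:
    """Upper-case an IUPAC motif and reject unknown codes."""
    up = motif.upper()
    bad = set(up) - set(IUPAC)
    if bad:
        raise ValueError(f"motif contains non-IUPAC characters: {sorted(bad)!r}")
    if len(up) < 2:
        raise ValueError("PAM motif must be at least 2 nt long")
    return up


def matches_motif(window: str, motif: str) -> bool:
    """True iff every base of ``window`` is allowed by the IUPAC ``motif``.

    Case-insensitive; ``window`` and ``motif`` must have equal length.
    """
    if len(window) != len(motif):
        return False
    return all(b.upper() in IUPAC[m] for b, m in zip(window, motif.upper()))
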