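"""Single source of truth for the bundled motif catalog geometry.

The tables below drive three things: the vendored catalog data files
(written once by ``scripts/build_reference_data.py``), the synthetic
fixture generators, and the self-consistency checks performed when the
catalog is loaded.

Consensus pattern syntax: plain amino-acid letters are fixed, ``x`` is a
wildcard, and ``(A/B)`` marks an alternative position.  ``Aa1``, ``Ta1``
and ``G`` are the optional extended motifs (A-domain start, T-domain
first helix, and the conserved-glycine loop motif between A5 and A6).
"""

from __future__ import annotations

import re

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

# domain_type -> ordered list of (motif_id, consensus_pattern, optional)
MOTIF_TABLE: dict[str, list[tuple[str, str, bool]]] = {
    "C": [
        ("C1", "SxAQxR(L/M)(W/Y)xL", False),
        ("C2", "RHExLRTxF", False),
        ("C3", "MHHxISDG(W/V)S", False),
        ("C4", "YxD(F/Y)AVW", False),
        ("C5", "(I/V)GxFVNT(Q/L)(C/A)xR", False),
        ("C6", "(H/N)QD(Y/V)PFE", False),
        ("C7", "RDxSRNPL", False),
    ],
    "A": [
        ("Aa1", "PxxxAV", True),
        ("A1", "L(T/S)YxEL", False),
        ("A2", "LKAGxAYL(V/L)P(L/I)D", False),
        ("A3", "LAYxxYTSG(S/T)TGxPKG", False),
        ("A4", "FDxS", False),
        ("A5", "NxYGPTE", False),
        ("G", "(I/V)P(I/L)G(K/R)P(I/L)", True),
        ("A6", "GELxIxGxG(V/L)(A/E)RGYL", False),
        ("A7", "Y(R/K)TGDL", False),
        ("A8", "GRxDxQVKIRGxRIELGEIE", False),
        ("A9", "LPxYM(I/V)P", False),
        ("A10", "NGK(V/L)DR", False),
    ],
    "T": [
        ("Ta1", "ExxxxxxxxxL", True),
        ("T1", "(L/F)GG(D/H)S(I/L)", False),
    ],
    "E": [
        ("E1", "PIQxWF", False),
        ("E2", "HHxISDG(W/V)S", False),
        ("E3", "DxLLxAxG", False),
        ("E4", "EGHGRE", False),
        ("E5", "RTVGWFTxxYP(V/L)", False),
        ("E6", "PxxGxGYG", False),
        ("E7", "FNYLG(Q/R)", False),
    ],
    "TE": [
        ("TE1", "G(W/Y)SAG", False),
    ],
    "ACP": [
        ("ACP1", "xGxDSL", False),
    ],
}

# Subtype-specific consensus overrides for C-domain motifs.
# (domain_type, subtype, motif_id) -> consensus
MOTIF_OVERRIDES: dict[tuple[str, str, str], str] = {
    ("C", "Cyc", "C3"): "DxxxxDGxSx",
    ("C", "LCL-A", "C3"): "SHxxxDxx(T/S)x",
}

# domain_type -> ([(motif_id, gap_before)], trailing_pad).  ``gap_before``
# is the number of unconstrained residues preceding the motif; the first
# entry's gap is the leading pad of the domain.
DOMAIN_LAYOUTS: dict[str, tuple[list[tuple[str, int]], int]] = {
    "C": ([("C1", 20), ("C2", 30), ("C3", 40), ("C4", 50),
           ("C5", 65), ("C6", 45), ("C7", 60)], 40),
    "A": ([("Aa1", 5), ("A1", 9), ("A2", 28), ("A3", 70), ("A4", 25),
           ("A5", 76), ("G", 17), ("A6", 19), ("A7", 28), ("A8", 20),
           ("A9", 35), ("A10", 18)], 30),
    "T": ([("Ta1", 5), ("T1", 7)], 50),
    "E": ([("E1", 12), ("E2", 25), ("E3", 30), ("E4", 40),
           ("E5", 35), ("E6", 40), ("E7", 25)], 20),
    "TE": ([("TE1", 55)], 150),
    "ACP": ([("ACP1", 35)], 35),
}

# Default linker lengths between consecutive domains when fixture
# pathways are concatenated (keyed by adjacent domain types).
MODULE_LINKERS: dict[tuple[str, str], int] = {
    ("C", "A"): 74,
    ("A", "T"): 10,
    ("T", "C"): 30,
    ("T", "E"): 5,
    ("T", "TE"): 5,
    ("E", "C"): 10,
    ("ACP", "C"): 30,
}

# Ten binding-pocket code positions of the A domain, expressed relative
# to the layout above: either an offset inside a motif or an offset into
# the gap that follows a motif (1-based in both cases).
CODE_POSITION_SPEC: list[tuple[str, str, int]] = [
    ("s1", "in:A4", 2),
    ("s2", "after:A4", 8),
    ("s3", "after:A4", 20),
    ("s4", "after:A4", 30),
    ("s5", "after:A4", 40),
    ("s6", "after:A4", 50),
    ("s7", "after:A4", 58),
    ("s8", "after:A4", 66),
    ("s9", "after:A4", 72),
    ("s10", "in:A10", 3),
]

# The five binding-pocket loops, as (left anchor, right anchor).  Anchors
# are motif ids (span boundaries are used) or code-position ids (single
# residues).  ``G`` here means the central glycine of the G motif.
LOOP_DEFS: list[tuple[str, str, str]] = [
    ("A3-A4", "A3", "A4"),
    ("A4-S4", "A4", "s4"),
    ("S4-S6", "s4", "s6"),
    ("S6-A5", "s6", "A5"),
    ("A5-G", "A5", "Gc"),
]

# Offset (1-based) of the conserved central glycine inside the G motif.
G_MOTIF_CENTER = 4

# Anchored intermotif boundary convention: a segment that ends at the
# keyed motif instead ends just before the anchor residue inside that
# motif (value = extra residues gained over the span convention, i.e.
# anchor offset - 1).  Example: the region before C1 ends before the
# conserved Q, the 4th consensus position of C1.
INTERMOTIF_ANCHOR_EXTENSIONS: dict[str, int] = {"C1": 3}

# The 18 condensation-superfamily subtype models of the default panel.
SUBTYPE_IDS = [
    "CT", "CT-DCL", "CT-A", "LCL-A", "FUM14", "SgcC5", "Cglyc", "Dual",
    "Starter", "Cyc", "X", "I", "PS", "bL", "modAA", "Hybrid", "LCL", "DCL",
]

_TOKEN_RE = re.compile(r"\(([A-Z](?:/[A-Z])+)\)|([A-Zx])")


def parse_consensus(pattern: str) -> list[frozenset[str] | None]:
    """Expand a consensus pattern into one position per element.

    Returns, per position, the allowed residue set, or ``None`` for a
    wildcard.
    """
    out: list[frozenset[str] | None] = []
    pos = 0
    for m in _TOKEN_RE.finditer(pattern):
        if m.start() != pos:
            raise ValueError(f"malformed consensus pattern: {pattern!r}")
        pos = m.end()
        if m.group(1):
            out.append(frozenset(m.group(1).split("/")))
        elif m.group(2) == "x":
            out.append(None)
        else:
            out.append(frozenset(m.group(2)))
    if pos != len(pattern):
        raise ValueError(f"malformed consensus pattern: {pattern!r}")
    return out


def consensus_length(pattern: str) -> int:
    return len(parse_consensus(pattern))


def matches_consensus(seq: str, pattern: str) -> bool:
    positions = parse_consensus(pattern)
    if len(seq) != len(positions):
        return False
    return all(allowed is None or aa in allowed
               for aa, allowed in zip(seq, positions))
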