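"""Minimal germline segment tables and codon utilities for the repertoire simulator.

The segment anchors below are synthetic approximations of human TRA/TRB CDR3
boundaries (conserved cysteine end of the V segment, FGXG-proximal end of the J
segment).  They exist so that simulated CDR3s carry realistic germline-derived
prefixes/suffixes and V/J gene names; they are not IMGT reference sequences.
"""
from __future__ import annotations

import numpy as np
from Bio.Data import CodonTable
from Bio.Seq import Seq

_STANDARD = CodonTable.unambiguous_dna_by_id[1]

#: amino acid -> tuple of synonymous codons (standard nuclear code)
AA_TO_CODONS: dict[str, tuple[str, ...]] = {}
for _codon, _aa in _STANDARD.forward_table.items():
    AA_TO_CODONS.setdefault(_aa, []).append(_codon)  # type: ignore[arg-type]
AA_TO_CODONS = {aa: tuple(sorted(c)) for aa, c in AA_TO_CODONS.items()}

#: the 20 standard residues (sorted for deterministic indexing)
AMINO_ACIDS: tuple[str, ...] = tuple(sorted(AA_TO_CODONS))

# (gene name, CDR3 anchor prefix) -- beta V segments
TRBV_SEGMENTS: tuple[tuple[str, str], ...] = (
    ("TRBV28", "CASS"),
    ("TRBV27", "CASS"),
    ("TRBV19", "CASS"),
    ("TRBV9", "CASS"),
    ("TRBV5-1", "CASS"),
    ("TRBV6-5", "CASS"),
    ("TRBV7-9", "CASS"),
    ("TRBV12-3", "CASS"),
    ("TRBV11-2", "CASS"),
    ("TRBV20-1", "CSAR"),
    ("TRBV29-1", "CSVE"),
    ("TRBV30", "CAWS"),
)

# (gene name, CDR3 anchor suffix) -- beta J segments
TRBJ_SEGMENTS: tuple[tuple[str, str], ...] = (
    ("TRBJ1-1", "NTEAFF"),
    ("TRBJ1-2", "YGYTF"),
    ("TRBJ1-5", "QPQHF"),
    ("TRBJ2-1", "NEQFF"),
    ("TRBJ2-2", "TGELFF"),
    ("TRBJ2-3", "DTQYF"),
    ("TRBJ2-7", "SYEQYF"),
)

TRAV_SEGMENTS: tuple[tuple[str, str], ...] = (
    ("TRAV1-2", "CAV"),
    ("TRAV8-2", "CVVS"),
    ("TRAV12-1", "CVVN"),
    ("TRAV27", "CAG"),
    ("TRAV29", "CAAS"),
    ("TRAV13-1", "CAAS"),
    ("TRAV19", "CALSE"),
    ("TRAV38-1", "CAFM"),
)

TRAJ_SEGMENTS: tuple[tuple[str, str], ...] = (
    ("TRAJ33", "NYQLIW"),
    ("TRAJ42", "SQGNLIF"),
    ("TRAJ49", "GNQFYF"),
    ("TRAJ45", "ADGLTF"),
    ("TRAJ23", "GGKLIF"),
    ("TRAJ37", "SSNTGKLIF"),
)

TRBD_GENES: tuple[str, ...] = ("TRBD1", "TRBD2")


def back_translate(aa: str, rng: np.random.Generator) -> str:
    """Back-translate an amino-acid string with uniformly random synonymous codons."""
    return "".join(AA_TO_CODONS[a][rng.integers(len(AA_TO_CODONS[a]))] for a in aa)


def translate(nt: str) -> str:
    """Translate a nucleotide string (length divisible by 3) to amino acids."""
    return str(Seq(nt).translate())


def segment_weights(
    segments: tuple[tuple[str, str], ...], usage: dict[str, float] | None
) -> np.ndarray:
    """Normalized sampling weights over a segment table.

    ``usage`` maps gene names to nonnegative weights; unnamed genes get weight 1.
    ``None`` means uniform usage.
    """
    if usage is None:
        w = np.ones(len(segments))
    else:
        w = np.array([float(usage.get(name, 1.0)) for name, _ in segments])
    if (w < 0).any() or w.sum() <= 0:
        raise ValueError("segment usage weights must be nonnegative and normalizable")
    return w / w.sum()
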