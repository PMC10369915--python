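"""Shared fixtures: tiny libraries, codon encoding, mass-action oracle."""

from __future__ import annotations

import numpy as np
import pytest

from sh2screen import PeptideEntry, PeptideLibrary

# one codon per amino acid (standard table), for writing synthetic FASTQ
CODON = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT",
    "G": "GGT", "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTG",
    "M": "ATG", "N": "AAT", "P": "CCG", "Q": "CAA", "R": "CGT",
    "S": "TCT", "T": "ACT", "V": "GTT", "W": "TGG", "Y": "TAT",
}


def encode(peptide: str) -> str:
    return "".join(CODON[aa] for aa in peptide)


def write_fastq(path, reads):
    with open(path, "w") as fh:
        for i, read in enumerate(reads):
            fh.write(f"@read{i}\n{read}\n+\n{'I' * len(read)}\n")


@pytest.fixture
def tiny_library() -> PeptideLibrary:
    """Two phosphosites and one tyrosine-free control, length 9."""
    return PeptideLibrary(
        name="tiny",
        entries=(
            PeptideEntry("p1", "AVDYGELDF", "wildtype_site", phospho_index=3),
            PeptideEntry("p2", "GHEYAALKP", "wildtype_site", phospho_index=3),
            PeptideEntry("c1", "ASDFGHKLM", "tyr_free_control"),
        ),
        peptide_length=9,
    )


def two_peptide_library() -> PeptideLibrary:
    """Controls-free pair for closed-form selection checks."""
    return PeptideLibrary(
        name="pair",
        entries=(
            PeptideEntry("A", "AAYAA", "wildtype_site", phospho_index=2),
            PeptideEntry("B", "GGYGG", "wildtype_site", phospho_index=2),
        ),
        peptide_length=5,
        require_controls=False,
    )


def mass_action_oracle(R, L, I, Kd, Ki, n_iter=20000, damp=0.5):
    """Damped fixed-point iteration on the two binding equations.

    Independent of the closed-form cubic: repeatedly updates the free
    ligand concentrations from free receptor and vice versa until the
    mass-action equilibrium is self-consistent.
    """
    R, L, I, Kd, Ki = np.broadcast_arrays(
        *(np.asarray(x, dtype=float) for x in (R, L, I, Kd, Ki))
    )
    Rf = R.astype(float).copy()
    for _ in range(n_iter):
        Lf = L / (1.0 + Rf / Kd)
        If = I / (1.0 + Rf / Ki)
        Rf = (1.0 - damp) * Rf + damp * R / (1.0 + Lf / Kd + If / Ki)
    return Rf
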