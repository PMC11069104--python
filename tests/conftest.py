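"""Shared fixtures: in-text structures and seeded synthetic corpora."""

import pytest

from glyre import SyntheticGlycanSpec, generate_corpus

# sialyl Lewis x, the classic cell-adhesion motif (Unicode dialect)
SLEX_UNICODE = "Neu5Acα2-3Galβ1-4(Fucα1-3)GlcNAc"
SLEX = "Neu5Aca2-3Galb1-4(Fuca1-3)GlcNAc"

# disialylated biantennary N-glycan with a2-6 caps on both arms
BIANT = ("Neu5Aca2-6Galb1-4GlcNAcb1-2Mana1-6"
         "(Neu5Aca2-6Galb1-4GlcNAcb1-2Mana1-3)"
         "Manb1-4GlcNAcb1-4GlcNAc")

# three tandem LacNAc units on a GalNAc reducing end
POLY_LACNAC = "Galb1-4GlcNAcb1-3Galb1-4GlcNAcb1-3Galb1-4GlcNAcb1-3GalNAc"

# a core-1 O-glycan: no N-glycan core anywhere
O_GLYCAN = "Galb1-3GalNAc"


@pytest.fixture(scope="session")
def small_corpus():
    """50 seeded random glycans, at most 8 residues each."""
    return generate_corpus(SyntheticGlycanSpec(max_residues=8, seed=424), 50)


@pytest.fixture(scope="session")
def tiny_corpus():
    """20 seeded random glycans, at most 6 residues (for slower sweeps)."""
    return generate_corpus(SyntheticGlycanSpec(max_residues=6, seed=77), 20)
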