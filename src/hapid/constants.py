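"""Physical constants for peptide mass arithmetic.

Monoisotopic residue masses come from pyteomics; the proton mass and the
averagine isotope spacing are the standard values used by search engines
for ppm-tolerance precursor filters with isotope-error windows.
"""

from pyteomics import mass as _pmass

#: Monoisotopic residue masses (Da), the 20 standard amino acids.
MONO_RESIDUE: dict[str, float] = {
    aa: _pmass.std_aa_mass[aa] for aa in "ACDEFGHIKLMNPQRSTVWY"
}

#: Mass of one water molecule (Da), added once per peptide.
WATER: float = _pmass.calculate_mass(formula="H2O")

#: Proton mass (Da) for charge-state arithmetic.
PROTON: float = 1.007276

#: Spacing between isotope peaks (Da), used for isotope-error correction.
ISOTOPE_SPACING: float = 1.00335

#: Residues accepted in database sequences. X is an unknown residue: it is
#: legal in a database but peptides containing it have no defined mass.
VALID_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWYX")

#: Default fixed modification: carbamidomethylation of cysteine.
CARBAMIDOMETHYL: float = 57.02146

#: Default variable modification: oxidation of methionine.
OXIDATION: float = 15.99491
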