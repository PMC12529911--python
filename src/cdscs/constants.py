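"""Physical constants and unit conversions used across the package."""

#: Hartree -> kcal/mol conversion used for all benchmark I/O.
HARTREE_TO_KCAL = 627.509474

#: Angstrom -> bohr (CODATA 2018).
ANGSTROM_TO_BOHR = 1.8897259886

#: Average of the subset mean absolute reference energies |dE|avg over the
#: 55 GMTKN55 subsets; the numerator of the WTMAD2 weight (kcal/mol).
WTMAD2_REFERENCE_KCAL = 56.84

#: Default multireference screen on the largest single-orbital nondynamic
#: term max_i n_i(1 - n_i); species above it are flagged.
IND_MAX_THRESHOLD = 0.030

#: Nuclear charges for the elements the built-in engine supports.
NUCLEAR_CHARGE = {"H": 1, "He": 2, "Li": 3, "Be": 4, "B": 5, "C": 6,
                  "N": 7, "O": 8, "F": 9, "Ne": 10}
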