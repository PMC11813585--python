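"""Unit conventions used throughout the package.

Everything in the model is expressed in a single, fixed unit system:

====================  =========================================
quantity              unit
====================  =========================================
concentrations        nM (nanomolar), for mRNA, protein, tRNA,
                      DNA and chloramphenicol alike
time                  h (hours); all rates are per hour
protein length        amino acids (aa)
elongation rate       aa/h
cell protein mass M   aa, expressed on the same per-cell
                      concentration scale as proteins (i.e. the
                      sum of n_j * p_j over the proteome is M)
====================  =========================================

Conversion between concentrations and discrete molecule counts (used only
by the stochastic simulator) goes through :data:`MOLECULES_PER_NM`, the
number of molecules corresponding to 1 nM in an E. coli-sized cell volume
of roughly 1 fL (1 nM * 1 fL * Avogadro ~= 0.6 molecules).
"""

#: molecules per cell corresponding to a 1 nM concentration (~1 fL cell).
MOLECULES_PER_NM = 0.6022

def nm_to_count(conc_nm: float, volume_factor: float = MOLECULES_PER_NM) -> float:
    """Convert a concentration in nM to a molecule count (not rounded)."""
    return conc_nm * volume_factor

def count_to_nm(count: float, volume_factor: float = MOLECULES_PER_NM) -> float:
    """Convert a molecule count back to a concentration in nM."""
    return count / volume_factor
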