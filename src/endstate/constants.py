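"""Physical constants and shared defaults (kcal/mol, Å, e, K units throughout)."""

#: Boltzmann constant, kcal/(mol·K)
KB = 0.0019872041

#: Coulomb prefactor, kcal·Å/(mol·e²)
COULOMB_CONSTANT = 332.0637

#: Default analysis temperature, K
DEFAULT_TEMPERATURE = 300.0

#: Water-probe radius for solvent-accessible surface area, Å
DEFAULT_PROBE_RADIUS = 1.4

#: Default quadrature points per atom for numerical SASA
DEFAULT_SASA_POINTS = 960

#: Surface-tension coefficient for the non-polar solvation term, kcal/(mol·Å²)
DEFAULT_GAMMA = 0.005

#: Offset for the non-polar solvation term, kcal/mol
DEFAULT_BETA = 0.0

#: Solvent dielectric for the generalized-Born polar term
DEFAULT_EPS_SOLVENT = 80.0
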