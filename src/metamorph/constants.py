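"""Physical constants and shared defaults.

All energies are kJ/mol, lengths nm, temperatures K throughout the package.
"""

#: Boltzmann constant in kJ/(mol K)
KB = 0.0083144621

#: Default absolute temperature (physiological conditions), K
DEFAULT_TEMPERATURE_K = 310.0

#: Default number of essential (non-Gaussian) modes retained
DEFAULT_N_ESSENTIAL = 6

#: Default number of grid bins per essential dimension
DEFAULT_BINS_PER_DIM = 10

#: Default minimum frame count for a grid cell to count as populated
DEFAULT_MIN_COUNT = 1
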