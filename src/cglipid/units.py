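"""Unit system and physical constants.

Canonical internal units: angstrom (A), femtosecond (fs), atomic mass unit
(amu), kcal/mol (energy).  Forces are kcal/mol/A.  Conversions happen only at
I/O boundaries; the core never guesses units.
"""

# Boltzmann constant, kcal/mol/K
KB = 0.001987204259

# Acceleration conversion: (kcal/mol/A) / amu -> A/fs^2.
# 1 kcal (thermochemical) = 4184 J and amu * N_A = 1 g/mol exactly, which
# makes this factor exact.
FORCE_TO_ACC = 4.184e-4

# Kinetic-energy conversion: amu * (A/fs)^2 -> kcal/mol
VSQ_TO_ENERGY = 1.0 / FORCE_TO_ACC

NM_TO_ANGSTROM = 10.0
PS_TO_FS = 1000.0


def kinetic_energy(velocities, masses):
    """Kinetic energy in kcal/mol from velocities (A/fs) and masses (amu)."""
    import numpy as np

    v2 = np.sum(velocities**2, axis=-1)
    return 0.5 * float(np.sum(masses * v2)) * VSQ_TO_ENERGY


def kinetic_temperature(velocities, masses):
    """Instantaneous kinetic temperature (K), 3N degrees of freedom."""
    n = velocities.shape[0]
    return 2.0 * kinetic_energy(velocities, masses) / (3.0 * n * KB)
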