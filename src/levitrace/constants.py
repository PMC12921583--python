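"""Physical constants and material defaults shared across the package.

All quantities are SI unless a unit suffix says otherwise. Gas and material
values are configurable at every call site that uses them; the module-level
values are the package defaults.
"""

from scipy import constants as _sc

#: Boltzmann constant (J/K)
KB = _sc.k
#: Vacuum permittivity (F/m)
EPS0 = _sc.epsilon_0
#: Speed of light (m/s)
C_LIGHT = _sc.c
#: Atomic mass unit (kg)
AMU = _sc.atomic_mass

#: Dynamic viscosity of air (Pa*s) at room temperature
ETA_AIR = 1.81e-5
#: Effective diameter of an air molecule (m), kinetic-theory value
D_AIR = 0.372e-9

#: Density of amorphous (fumed) silica nanoparticles (kg/m^3)
RHO_SILICA = 1850.0
#: Relative permittivity of silica at 1550 nm (n = 1.444)
EPS_SILICA = 2.085

#: Trapping-laser wavelength (m)
WAVELENGTH = 1550e-9

#: mbar -> Pa
MBAR_TO_PA = 100.0

#: Default environment temperature (K): thermal equilibrium assumption
T_ENV = 300.0
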