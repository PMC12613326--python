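"""Unit conversions and mathematical constants (atomic units internally).

All internal quantities are in Hartree atomic units: hartree for energy,
bohr for length, electron masses for mass, hbar/hartree for time.
"""

import math

#: Atomic time units per femtosecond.
FS_TO_AU = 41.341374575751

#: Electron masses per unified atomic mass unit.
AMU_TO_ME = 1822.888486209

#: Electronvolts per hartree.
HARTREE_TO_EV = 27.211386245988

#: Wavenumbers (cm^-1) per hartree.
HARTREE_TO_CM = 219474.6313632

#: Average of |cos(theta)| over a uniform angle, (1/2pi) * int_0^2pi |cos| dtheta.
#: Used to trade the unknown projection angle between the trajectory velocity
#: and a force/momentum difference vector for an isotropic average.
ANGLE_AVG_ABS_COS = 2.0 / math.pi


def fs_to_au(t_fs: float) -> float:
    return t_fs * FS_TO_AU


def au_to_fs(t_au: float) -> float:
    return t_au / FS_TO_AU


def amu_to_me(m_amu: float) -> float:
    return m_amu * AMU_TO_ME


def ev_to_hartree(e_ev: float) -> float:
    return e_ev / HARTREE_TO_EV


def hartree_to_ev(e_h: float) -> float:
    return e_h * HARTREE_TO_EV
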