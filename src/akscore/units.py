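"""Affinity unit conversions.

Binding affinities come in two interchangeable representations: pK units
(pKi/pKd, the negative decadic log of the inhibition/dissociation constant)
and the binding free energy in kcal/mol, related by dG = -ln(10) * R * T * pK.
Labels are stored in pK and converted once to kcal/mol for training.
"""

from __future__ import annotations

import numpy as np

__all__ = ["R_KCAL", "T_STANDARD", "pk_to_kcal", "kcal_to_pk"]

#: gas constant, kcal / (mol K)
R_KCAL = 1.987204259e-3
#: standard temperature, K
T_STANDARD = 298.15


def pk_to_kcal(pk, temperature: float = T_STANDARD):
    """Convert pKi/pKd to a binding free energy in kcal/mol (negative for
    favorable binding)."""
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    return -np.log(10.0) * R_KCAL * temperature * np.asarray(pk)


def kcal_to_pk(kcal, temperature: float = T_STANDARD):
    """Inverse of :func:`pk_to_kcal`."""
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    return np.asarray(kcal) / (-np.log(10.0) * R_KCAL * temperature)
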