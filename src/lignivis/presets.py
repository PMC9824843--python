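"""Reference study conditions for the two lignosulphonate samples.

The package's worked examples and round-trip tests revolve around two
lignosulphonate (LS) feedstocks methylolated at 280 g/L, pH 9.6, with a
formaldehyde-to-LS solids mass ratio of 0.17 over 5 h:

* ``SLS`` — spray-dried softwood sodium lignosulphonate (guaiacyl-rich,
  more reactive ring positions), run at 60 degC.
* ``HLS`` — hardwood spent sulfite liquor (syringyl-rich, more blocked
  positions, and showing a formaldehyde-consuming secondary reaction),
  run at 50 and 60 degC.

The kinetic parameter sets and initial concentrations below are the fitted
values for those runs; the phenolic hydroxyl contents and LS contents are
the corresponding UV characterization results.
"""

from __future__ import annotations

from dataclasses import dataclass

from .kinetics import InitialConditions, KineticParams
from .phenolics import PhenolicOHContent

__all__ = [
    "StudyConditions",
    "SLS_60",
    "HLS_50",
    "HLS_60",
    "HLS_OH_CONTENT",
    "SLS_OH_CONTENT",
    "HLS_LS_CONTENT_PCT",
    "SLS_LS_CONTENT_PCT",
    "LS_MEDIUM_CONC_G_L",
]


@dataclass(frozen=True)
class StudyConditions:
    """A named methylolation run: kinetic parameters plus initial charge."""

    name: str
    params: KineticParams
    init: InitialConditions


SLS_60 = StudyConditions(
    name="SLS_60",
    params=KineticParams(k1=1.53, k2=0.0, f_nonreactive=0.71, temperature_C=60),
    init=InitialConditions(F0=0.59, POH0=0.36),
)

HLS_50 = StudyConditions(
    name="HLS_50",
    params=KineticParams(k1=2.02, k2=0.06, f_nonreactive=0.86, temperature_C=50),
    init=InitialConditions(F0=0.79, POH0=0.38),
)

HLS_60 = StudyConditions(
    name="HLS_60",
    params=KineticParams(k1=1.32, k2=0.14, f_nonreactive=0.79, temperature_C=60),
    init=InitialConditions(F0=0.79, POH0=0.38),
)

# UV characterization: phenolic OH contents as mass % on a dry-LS basis.
HLS_OH_CONTENT = PhenolicOHContent(oh_I_II=1.76, oh_III_IV=0.93)
SLS_OH_CONTENT = PhenolicOHContent(oh_I_II=1.37, oh_III_IV=0.86)

# LS content of the raw samples, mass % (as-received basis).
HLS_LS_CONTENT_PCT = 33.5
SLS_LS_CONTENT_PCT = 72.0

# LS concentration in the reaction medium, g/L.
LS_MEDIUM_CONC_G_L = 280.0
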