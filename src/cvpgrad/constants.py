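"""Physical constants and unit conventions.

Internal units throughout the package:

====================  =========
quantity              unit
====================  =========
gradient amplitude    mT/m
time                  microseconds (us)
distance              mm (slice positions), m only where stated
frequency             Hz (fields), kHz (spectra)
k-space               1/m
====================  =========

Time stamps refer to sample centers; all indexing is 0-based.
"""

#: Gyromagnetic ratio of 1H over 2*pi, in MHz/T.
GAMMA_OVER_2PI_MHZ_PER_T = 42.577

#: Larmor frequency offset in Hz produced by 1 mT/m at 1 mm off-center:
#: 42.577e6 Hz/T * 1e-3 T/m * 1e-3 m.
HZ_PER_MTM_MM = GAMMA_OVER_2PI_MHZ_PER_T

#: Phase in rad accrued per unit gradient moment (mT/m * us) at 1 mm:
#: 2*pi * HZ_PER_MTM_MM * 1e-6.
import math

RAD_PER_MTM_US_MM = 2.0 * math.pi * HZ_PER_MTM_MM * 1e-6

#: k-space advance in 1/m per unit gradient moment (mT/m * us).
K_PER_MTM_US = GAMMA_OVER_2PI_MHZ_PER_T * 1e-3
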