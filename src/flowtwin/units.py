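"""Package-wide unit conventions and conversion constants.

All quantities are expressed in a single fixed unit system:

===========  ==========
quantity     unit
===========  ==========
volume       mL
time         s
pressure     mmHg
flow         mL/s
area         cm^2
elastance    mmHg/mL
resistance   mmHg*s/mL
compliance   mL/mmHg
inertance    mmHg*s^2/mL
density      g/mL
velocity     cm/s
===========  ==========

The only place unit juggling is required is the convective valve term
rho/(2*ELCo^2) * Q*|Q|, whose natural value comes out in CGS dynamic-pressure
units (g cm^-1 s^-2, i.e. barye) once flows in mL/s and areas in cm^2 are
inserted.  Conversion to mmHg uses the composite factor 0.06/133.322:
1 mmHg = 1333.22 barye and the remaining 0.06/10 absorbs the cm/mL scaling
of the squared-flow term.  The factor is applied verbatim wherever the
convective gradient is evaluated.
"""

#: converts rho/(2*ELCo^2)*Q^2 (rho in g/mL, ELCo in cm^2, Q in mL/s) to mmHg
CONVECTIVE_MMHG = 0.06 / 133.322

#: default blood density, g/mL
RHO_BLOOD = 1.06

#: significance threshold used throughout the variability statistics
P_SIGNIFICANT = 0.05
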