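"""Physical constants (SI units, CODATA 2018)."""

EPS0 = 8.8541878128e-12  # vacuum permittivity, F/m
MU0 = 1.25663706212e-6   # vacuum permeability, H/m
C0 = 299792458.0         # speed of light in vacuum, m/s
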