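"""Physical constants and unit conventions.

The package works in a single internal unit system chosen so that the gas
constant is numerically identical in mechanical and thermal units:

* temperature  : K
* pressure     : MPa
* mass density : g/cm3
* molar volume : cm3/mol

since 1 MPa * 1 cm3 = 1 J, ``R_GAS`` below serves both as
8.31446 J/(mol K) and 8.31446 MPa cm3/(mol K).
"""

#: Gas constant, J/(mol K) == MPa cm3/(mol K).
R_GAS = 8.31446

#: Molar volume of an ideal gas at standard temperature and pressure
#: (0 degC, 1 atm), cm3(STP)/mol.
V_STP = 22414.0

#: Conversion factor from MPa to bar.
MPA_TO_BAR = 10.0

#: Reference pressure (MPa) used for "unpenetrated polymer" densities:
#: 1 bar, the low-pressure end of the sorption isotherms.
P_REFERENCE = 0.1
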