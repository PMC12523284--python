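"""Evaluate the maize/air constitutive closures at storage conditions.

Prints the specific heat and conductivity correlations, the vapor
diffusivity, and the sorption-isotherm state (equilibrium RH and the
vapor-pressure partials sigma, omega) at 14% wet-basis moisture, 25 degC.
"""

from grainfield import (dry_from_wet_basis, isotherm_vapor_partials,
                        specific_heat_maize, thermal_conductivity_maize,
                        vapor_diffusivity)

M_wb = 14.0                       # wet-basis moisture, %
Wg = dry_from_wet_basis(M_wb)     # dry-basis fraction
T_C, T_K = 25.0, 298.15

print(f"cb({M_wb}% w.b.)   = {specific_heat_maize(M_wb):.4f} kJ/(kg degC)")
print(f"kb({T_C} degC)  = {thermal_conductivity_maize(T_C):.5f} W/(m K)")
d = vapor_diffusivity(T_K)
print(f"Dv({T_K} K) = {d.Dv:.3e} m^2/s   Deff = {d.Deff:.3e} m^2/s")
c = isotherm_vapor_partials(T_K, Wg)
print(f"equilibrium RH  = {100 * c.rh:.2f} %")
print(f"sigma (dp/dWg)  = {c.sigma:.1f} Pa      omega (dp/dT) = {c.omega:.2f} Pa/K")
print(f"DM = Deff*sigma = {c.DM:.3e}   DT = Deff*omega = {c.DT:.3e}")
# ~70% interstitial RH at 14% w.b. maize and a 2.6e-5 m^2/s free-air
# vapor diffusivity are the textbook magnitudes for these conditions.
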