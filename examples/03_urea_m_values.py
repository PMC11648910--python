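"""Urea m-values of folding states and transition states.

Builds the urea-titration series of four-state networks (free energies
exactly linear in urea), converts populations and microscopic rates into
free energies relative to the folded state, and extracts each m-value as
minus the slope versus urea concentration.
"""

from foldcest import synthetic
from foldcest.thermo import m_value_profile

points = synthetic.urea_series()
print(f"{len(points)} urea points at T = {points[0].temperature:.2f} K\n")

print(f"{'target':9s} {'m (kJ/mol/M)':>13s} {'intercept (kJ/mol)':>19s}")
for fit in m_value_profile(points):
    print(f"{fit.target:9s} {fit.m_value:13.3f} {fit.intercept:19.2f}")

# m > 0: the state exposes more surface to solvent than F (U most,
# the U->I1 transition state in between, I2 indistinguishable from F).
# Intercepts are the 0 M free energies relative to F and depend on the
# chosen anchor; the slopes do not.
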