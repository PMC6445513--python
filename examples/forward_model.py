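"""Build theoretical fringe templates and derive JKR contact quantities.

A 10 um hydrogel probe indenting the coverslip by 0.2 um produces a flat
dark contact core surrounded by compressing fringes; from the contact
radius and the probe's elastic constants the adhesion energy follows.
"""

from ricmfringe import (
    OpticalConfig,
    TemplateParams,
    adhesion_energy,
    contact_radius,
    generate_template,
)

config = OpticalConfig()  # 0.067 um/px, 530 nm, INA 0.67, n 1.332, theta pi
params = TemplateParams(d=-0.2, p=10.0, dec=2.0)
template = generate_template(params, config)

r_c = contact_radius(params.d, params.p)
w_adh = adhesion_energy(r_c, params.p, e_modulus=4e4, poisson=0.5)

print(f"template radius       : {config.r_max} px = {config.r_max * config.u:.2f} um")
print(f"contact radius        : {r_c:.3f} um ({r_c / config.u:.1f} px of flat dark core)")
print(f"template at r=1 px    : {template.values[0]:+.4f}  (cos(theta) = -1 in the core)")
print(f"first bright fringe   : r = {template.values.argmax() + 1} px, value {template.values.max():+.3f}")
print(f"adhesion energy (JKR) : {w_adh:.3e} J/m^2 for E = 40 kPa, v = 0.5")
# The contact core is uniformly dark (intensity -1 before decay); fringes
# start right past r_c and their spacing shrinks outward because the
# sphere-coverslip gap opens ever faster with radius.
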