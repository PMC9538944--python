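"""Extrapolate a whole-body biotransformation rate constant from CL_int.

Takes the mean fresh-cell carp clearance of methoxychlor (0.287 mL/h/1e6
cells), scales it to the whole liver, applies the binding correction and the
well-stirred liver model, and divides by the apparent volume of distribution.
"""

from fishbcf import extrapolate_kb, get_chemical, get_species

phys = get_species("carp_study")     # 44.6 g, 21 degC, 9.57 % lipid, liver 0.0174
chem = get_chemical("MXC")           # log Kow 5.08
est = extrapolate_kb(clint=0.287, phys=phys, chem=chem)

print(f"CL_in vivo,int : {est.cl_in_vivo_int:8.2f} L/d/kg   (liver scaling)")
print(f"fu             : {est.fu:8.4f}          (binding correction)")
print(f"Q_H            : {est.q_h:8.2f} L/d/kg   (hepatic blood flow)")
print(f"CL_H           : {est.cl_h:8.3f} L/d/kg   (well-stirred liver)")
print(f"V_D            : {est.v_d:8.2f} L/kg     (apparent volume of distribution)")
print(f"kB             : {est.kb:8.4f} 1/d")
# kB is the first-order whole-body biotransformation rate constant implied by
# the in vitro assay; it feeds the mass-balance BCF prediction as one of the
# elimination terms.
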