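# fishbcf

Tools for assessing chemical bioaccumulation in fish from in vitro
biotransformation data.  The package implements the computational chain that
links a hepatocyte substrate-depletion assay to an in vivo bioconcentration
factor (BCF), for rainbow trout (*Oncorhynchus mykiss*) and common carp
(*Cyprinus carpio*):

1. **In vitro intrinsic clearance** (`fishbcf.depletion`).  First-order
   depletion of a test chemical in a hepatocyte suspension is fitted by
   ordinary least squares on log₁₀-transformed concentrations versus time,
   k = −ln(10) · slope (1/h), and normalised to cell number:
   CL_int = k / (2 × 10⁶ cells/mL), in mL/h/10⁶ cells.  Includes the
   dead-cell (heat-inactivated) abiotic-loss QC (≤ 5 % of the live rate) and
   an iterative trailing-point drop to restrict fits to the log-linear
   portion of the curve.

2. **In vitro–in vivo extrapolation** (`fishbcf.ivive`).  CL_int is scaled to
   the whole liver (hepatocellularity 510 × 10⁶ cells/g, liver fraction
   0.015 trout / 0.0174 carp), corrected for differential binding
   (f_u = f_u,blood / f_u,incubation from log K_OW QSARs, or f_u = 1), passed
   through the well-stirred liver model
   CL_H = Q_H f_u CL_int / (Q_H + f_u CL_int), and divided by an apparent
   volume of distribution V_D = lipid · K_OW / P_BW to give the whole-body
   biotransformation rate constant k_B (1/d).

3. **Mass-balance BCF prediction** (`fishbcf.massbalance`).  Gill uptake k₁,
   respiratory elimination k₂, fecal egestion k_E and growth dilution k_G
   from allometric/temperature correlations;
   BCF = k₁ / (k₂ + k_E + k_G + k_B).

4. **In vivo study evaluation** (`fishbcf.tg305`).  OECD TG 305
   aqueous-exposure studies: time-weighted average water concentration,
   steady-state BCF (mean fish concentration on plateau days / TWA),
   exponential depuration fit C_f = C_f,0 e^(−k_T t), and the in vivo
   biotransformation estimate k_B = k_T − (k₂ + k_E + k_G).

5. **Synthetic studies** (`fishbcf.simulate`).  Generators for depletion runs
   and full uptake/depuration studies with known ground truth, used by the
   parameter-recovery test suite.

Packaged parameter sets (`fishbcf.params`) cover the study fish
(carp: 44.6 g, 21 °C, 9.57 % lipid, 77 % O₂ saturation; trout: 18.5 g, 12 °C,
9.08 % lipid, 91 %), a 10 g/15 °C/5 % lipid reference trout, and the test
chemicals methoxychlor (MXC, log K_OW 5.08) and benzo[a]pyrene (BaP, 5.99).

## Worked example

```python
from fishbcf import extrapolate_kb, get_chemical, get_species

phys = get_species("carp_study")   # 44.6 g, 21 °C, 9.57 % lipid
chem = get_chemical("MXC")         # log Kow 5.08
est = extrapolate_kb(clint=0.287, phys=phys, chem=chem)
```

prints (see `examples/02_ivive_kb.py`):

```
CL_in vivo,int :    61.12 L/d/kg   (liver scaling)
fu             :   0.0102          (binding correction)
Q_H            :    32.06 L/d/kg   (hepatic blood flow)
CL_H           :    0.614 L/d/kg   (well-stirred liver)
V_D            :    14.06 L/kg     (apparent volume of distribution)
kB             :   0.0437 1/d
```

The mean carp clearance of methoxychlor (0.287 mL/h/10⁶ cells) becomes a
whole-liver intrinsic clearance of 61 L/d/kg; heavy binding (f_u ≈ 0.01)
makes the liver far from flow-limited (CL_H ≈ 0.6 vs Q_H ≈ 32 L/d/kg), and
relative to the large lipid-driven distribution volume this corresponds to a
whole-body biotransformation rate of ≈ 0.044 1/d — enough to cut the
predicted BCF roughly in half (see `examples/03_bcf_prediction.py`).

The other example scripts cover fitting a simulated depletion assay
(`examples/01_...`), the four-case BCF table (`03`), and a full simulated
TG 305 evaluation including the in vivo k_B back-calculation (`04`).
A thin CLI exposes the same stages
(`fishbcf clint|ivive|bcf|tg305|simulate|reproduce --help`).

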