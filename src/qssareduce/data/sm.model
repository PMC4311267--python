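# Simplified two-feedback NF-kB / IkBa / A20 oscillator, 10 dynamic variables.
# Concentrations in uM, time and rate constants in seconds; k24 (TR) is the
# TNFa stimulus switch, driven as a time signal or fixed as a number.
# Initial conditions are the published rest state of the parent 14-variable
# model (equilibrated without stimulus, with v = total IKK and r = k1*k3).
label = SM

[variables]
p = 3.81e-3      # cytoplasmic NF-kB
q = 1.58e-2      # cytoplasmic IkBa
r = 9.79e-3      # nuclear NF-kB
s = 5.44e-3      # nuclear IkBa
u = 2.07e-5      # IkBa transcript
v = 0.08         # neutral IKK
w = 0.0          # active IKK
x = 6.46e-6      # A20 transcript
y = 7.19e-4      # A20 protein
z = 0.0          # nuclear (p-IkBa o NF-kB) complex

[parameters]
k1 = 3.3               # kv, nuclear/cytoplasmic volume ratio
k2 = 0.08 uM           # total IKK (conserved in the parent model)
k3 = 0.08 uM           # total NF-kB (conserved in the parent model)
k4 = 0.5 1/(uM*s)      # ka1a, IkBa-NF-kB association
k5 = 1.4e-7 1/(uM*s)   # c1a, IkBa transcription
k6 = 0.5 1/s           # c2a, IkBa translation
k7 = 0.0003 1/s        # c3a, IkBa transcript decay
k8 = 0.0005 1/s        # c4a, IkBa protein decay
k9 = 1.4e-7 1/(uM*s)   # c1, A20 transcription
k10 = 0.5 1/s          # c2, A20 translation
k11 = 0.00048 1/s      # c3, A20 transcript decay
k12 = 0.0045 1/s       # c4, A20 protein decay
k13 = 0.00067 1/s      # ki3a, IkBa nuclear import
k14 = 3.35e-4 1/s      # ke3a, IkBa nuclear export
k15 = 0.0026 1/s       # ki1, NF-kB nuclear import
k16 = 0.000052 1/s     # ke1, NF-kB nuclear export
k17 = 0.074 1/s        # kc1a, IKK-mediated IkBa phosphorylation
k18 = 0.37 1/s         # kc2a, complex phosphorylation
k19 = 0.1 1/s          # kt2a, complex-borne NF-kB release
k20 = 0.0006 1/s       # kp, IKK recycling
k21 = 0.0018 uM        # kbA20, A20 inhibition threshold
k22 = 0.004 1/s        # ka, IKK activation
k23 = 0.003 1/s        # ki, IKK inactivation
k = 0.065 uM           # Hill threshold of NF-kB-driven transcription
h = 2                  # Hill coefficient

[inputs]
k24 = 0                # TR, TNFa stimulus switch (0 off / 1 saturating)

[equations]
p' = k19*z - k4*q*p - k15*p + k16*r
q' = -k4*q*p + k6*u - k8*q - k13*q + k14*s - k17*w*q
r' = k15*k1*p - k4*s*r - k16*k1*r
s' = k13*k1*q - k4*s*r - k8*s - k14*k1*s
u' = k5*r**h/(r**h + k**h) - k7*u
v' = k20*k21/(k21 + k24*y)*(k2 - v) - k24*k22*v
w' = k24*k22*v - k23*w
x' = k9*r**h/(r**h + k**h) - k11*x
y' = k10*x - k12*y
z' = k18*w*(k3 - p - r/k1) - k19*z
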