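# Six-variable minimal model derived with respect to the pulse-entrained
# representative solution (z, p, y, w eliminated at zeroth order; the neutral
# IKK form v stays dynamic because it is slow between pulses).
# The nuclear-IkBa equation uses k13*k1*q, as in the ten-variable system the
# elimination leaves untouched; the published transcription of this model
# prints k13*k1*pbar there instead, almost certainly a typo -- see the
# companion "-printed" fixture for the verbatim variant.
label = *z0p0y0w0

[variables]
q = 1.58e-2      # cytoplasmic IkBa
r = 9.79e-3      # nuclear NF-kB
s = 5.44e-3      # nuclear IkBa
u = 2.07e-5      # IkBa transcript
v = 0.08         # neutral IKK
x = 6.46e-6      # A20 transcript

[parameters]
k1 = 3.3
k2 = 0.08 uM
k3 = 0.08 uM
k4 = 0.5 1/(uM*s)
k5 = 1.4e-7 1/(uM*s)
k6 = 0.5 1/s
k7 = 0.0003 1/s
k8 = 0.0005 1/s
k9 = 1.4e-7 1/(uM*s)
k10 = 0.5 1/s
k11 = 0.00048 1/s
k12 = 0.0045 1/s
k13 = 0.00067 1/s
k14 = 3.35e-4 1/s
k15 = 0.0026 1/s
k16 = 0.000052 1/s
k17 = 0.074 1/s
k18 = 0.37 1/s
k19 = 0.1 1/s
k20 = 0.0006 1/s
k21 = 0.0018 uM
k22 = 0.004 1/s
k23 = 0.003 1/s
k = 0.065 uM
h = 2

[inputs]
k24 = 0

[defs]
wbar = k24*k22*v/k23
ybar = k10*x/k12
pbar = (k16*r*k1 + k18*wbar*k3*k1 - k18*wbar*r)/(k1*(k4*q + k15 + k18*wbar))

[equations]
q' = -k4*q*pbar + k6*u - k8*q - k13*q + k14*s - k17*wbar*q
r' = k15*k1*pbar - k4*s*r - k16*k1*r
s' = k13*k1*q - k4*s*r - k8*s - k14*k1*s
u' = k5*r**h/(r**h + k**h) - k7*u
v' = k20*k21/(k21 + k24*ybar)*(k2 - v) - k24*k22*v
x' = k9*r**h/(r**h + k**h) - k11*x
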