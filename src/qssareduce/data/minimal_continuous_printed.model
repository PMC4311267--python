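# Four-variable minimal model for continuous stimulation, transcribed with
# the literal published closed forms (constants A and B(x) as printed).
# The published A/B bookkeeping is internally inconsistent with a direct
# derivation from the ten-variable system (placement of ki = k23 across the
# terms of B, and the NF-kB total k3 where the IKK total k2 is expected --
# the two totals are numerically equal, 0.08 uM); this fixture preserves the
# printed form verbatim for comparison.  The algorithmically derived variant
# is built by the reduction pipeline itself.
label = z0p0y0v0s0w1-printed

[variables]
q = 1.58e-2      # cytoplasmic IkBa
r = 9.79e-3      # nuclear NF-kB
u = 2.07e-5      # IkBa transcript
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
Aconst = k24*k22*k20*k21*k12*k3
Bx = k20*k21*k12 + k24*k22*k21*k12 + k24**2*k22*k10*k23*x
wbar = Aconst/Bx + k24**2*k22*k10*Aconst*(k9*r**h/(r**h + k**h) - k11*x)/Bx**2
sbar = k1*k13*q/(k4*r + k1*k14 + k8)
pbar = (k16*r + k18*wbar*(k3 - r/k1))/(k4*q + k15 + k18*wbar)

[equations]
q' = -k4*q*pbar + k6*u - k8*q - k13*q + k14*sbar - k17*wbar*q
r' = k15*k1*pbar - k4*sbar*r - k16*k1*r
u' = k5*r**h/(r**h + k**h) - k7*u
x' = k9*r**h/(r**h + k**h) - k11*x
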