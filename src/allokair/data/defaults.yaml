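# Default kinetic parameter set.
# Measured values come from stopped-flow quench kinetics of the beta2AR /
# Gs-peptide SPASM sensor; the remainder are package conventions chosen to
# satisfy the printed constraints (see docs/methods.md).
k_on_G:        {value: 0.01, unit: "1/(uM*s)"}   # shared association rate; 0.3/30 ≈ 0.006/0.75 µM⁻¹s⁻¹ within ~25%
k_off_weak:    {value: 0.3, unit: "1/s"}         # measured HR'G (weak-state) off-rate
k_off_strong:  {value: 0.006, unit: "1/s"}       # measured HR*G (strong-state) off-rate
k_act_f:       {value: 0.002, unit: "1/s"}       # spontaneous HR' -> HR*; satisfies the ≤0.007 s⁻¹ bound
k_act_r:       {value: 0.002, unit: "1/s"}       # spontaneous HR* -> HR'
k_actG_f:      {value: 0.002, unit: "1/s"}       # G-bound forward interconversion; ≤0.007 s⁻¹ bound
# k_actG_r derived from cycle closure K_actG = alpha * K_act
K_E:           {value: 100.0, unit: "uM"}        # weak effector binding (K_E >> K_D/alpha)
k_on_E:        {value: 0.01, unit: "1/(uM*s)"}
gamma_E:       {value: 100.0, unit: "dimensionless"}  # gamma*k_act = 0.2 s⁻¹, within the 0.1–0.7 s⁻¹ catalyzed range
k_on_N:        {value: 1.0, unit: "1/(uM*s)"}    # fast nanobody capture of free receptor
k_off_N:       {value: 0.0, unit: "1/s"}         # high-affinity capture treated as irreversible
k_ns:          {value: 0.046209812037329684, unit: "1/s"}  # ln2/15: nonspecific decay, t1/2 = 15 s
C_eff:         {value: 10.0, unit: "uM"}         # effective tethered-peptide concentration (SPASM geometry)
R_total:       {value: 0.1, unit: "uM"}
G_total:       {value: 30.0, unit: "uM"}         # bio-Spep concentration in the sequestration assay
E_total:       {value: 0.0, unit: "uM"}
N_total:       {value: 0.0, unit: "uM"}
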