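"""From raw assay reads to Kp,uu,brain.

Builds one compound's transwell, dialysis and in vivo measurements and walks
them through the full calculation chain.
"""

from kpuubrain.assays import (
    BindingMeasurement,
    BrainPenetrationRecord,
    Matrix,
    TransportAssay,
    apparent_permeability,
    efflux_ratio,
    fraction_unbound_brain,
    fraction_unbound_plasma,
    kpuu_brain,
    steady_state_check,
)

# Transwell: 1-h receiver concentrations in a MDCK-MDR1 monolayer, 2 uM donor.
ab = TransportAssay(times_s=(3600.0,), receiver_concentrations_um=(0.08,),
                    v_r=0.25, c0=2.0)   # A->B accumulates basolaterally
ba = TransportAssay(times_s=(3600.0,), receiver_concentrations_um=(1.07,),
                    v_r=0.075, c0=2.0)  # B->A accumulates apically
papp_ab = apparent_permeability(ab)
papp_ba = apparent_permeability(ba)
er = efflux_ratio(papp_ba, papp_ab)
print(f"Papp A->B = {papp_ab:.3e} cm/s, B->A = {papp_ba:.3e} cm/s")
print(f"efflux ratio = {er:.2f}  (> 2 flags an MDR1 substrate)")

# Equilibrium dialysis: plasma directly, brain in 20% homogenate (D = 5).
fu_plasma = fraction_unbound_plasma(
    BindingMeasurement(c_buffer=0.12, c_matrix=0.80, matrix=Matrix.PLASMA))
fu_brain = fraction_unbound_brain(fu_prime=0.35, dilution_factor=5.0)
print(f"fu,plasma = {fu_plasma.value:.3f}, fu,brain = {fu_brain:.4f} "
      "(dilution-corrected from fu' = 0.35)")

# In vivo concentrations at the later sampling time.
kpuu = kpuu_brain(BrainPenetrationRecord(
    fu_plasma=fu_plasma.value, fu_brain=fu_brain,
    c_plasma=1.8, c_brain=0.9))
ok, fold = steady_state_check(kpuu_early=kpuu * 1.3, kpuu_late=kpuu)
print(f"Kp,uu,brain = {kpuu:.3f}  (steady-state 2-fold check: "
      f"{'pass' if ok else 'fail'}, fold difference {fold:.2f})")
print("Kp,uu < 1 indicates net efflux keeps unbound brain levels below plasma.")
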