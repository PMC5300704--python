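"""Estimate the work the secretion apparatus does per insertion.

With drag zeta = kT/D per monomer, pushing n = 12 close-packed residents a
distance s = 56 nm costs W = n*kT*v*s/D — a few kT to a few tens of kT
depending on how fast the insertion happens, i.e. a few ATP at most.
"""

from flagrow import EnergeticsQuery, drag_coefficient, injection_work

D = 5000.0  # best-fit diffusion coefficient, nm^2/s
print(f"drag per monomer: zeta = {drag_coefficient(D):.2e} kT.s/nm^2")

for push_time in (0.1, 0.6):
    q = EnergeticsQuery.from_push_time(n=12, push_time_s=push_time, s_nm=56.0, D=D)
    w_kt, w_atp = injection_work(q)
    print(f"insertion in {push_time} s (v = {q.v_nm_per_s:.0f} nm/s): "
          f"W = {w_kt:.1f} kT = {w_atp:.2f} ATP")
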