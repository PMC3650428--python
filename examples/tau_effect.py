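"""The tau effect: the quicker interval feels spatially shorter.

Three taps at 0 cm, 3 cm and a variable third position define two
spatial intervals. When both temporal intervals are 0.5 s the point of
subjective equality (PSE) sits veridically at 6 cm; as the second
temporal interval shrinks, the third tap must move progressively
farther to feel equally spaced.
"""

from saltation import ObserverParams, tau_effect_pse

params = ObserverParams.from_tau(0.10)

print("t2 (s)   PSE x3 (cm)   implied l2/l1")
for t2 in (0.5, 0.35, 0.25, 0.175, 0.125):
    x3 = tau_effect_pse(l1=3.0, t1=0.5, t2=t2, params=params, mode="pairwise")
    print(f"{t2:5.3f}   {x3:8.3f}      {(x3 - 3.0) / 3.0:6.3f}")
# at t2 = t1 the PSE is 6 cm (equal actual spacing); shorter t2 demands
# an ever longer second interval to be perceived as equal
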