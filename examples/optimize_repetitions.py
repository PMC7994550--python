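"""How many repetitions are needed for a target inter-session reliability?

Averaging the K sides x L repetitions of a session shrinks the side,
interaction and residual variance by 1/K and 1/(K*L) but cannot reduce the
session variance itself, so the average-measures ICCk(session) rises with
L toward a ceiling set by the subject and session variances alone.
"""

from ppticc import (VarianceComponents, icc_two_component, icck_session,
                    minimal_repetitions, repetition_curve)

components = VarianceComponents(grand_mean=50.0, sigma2_subj=222.28,
                                sigma2_sess=4.83, sigma2_side=9.72,
                                sigma2_sss=34.63, sigma2_reps=45.77)

print("ICCk(session) averaging over K=2 sides and L repetitions:")
for L, res in repetition_curve(components, k_avg=2, l_range=range(1, 11)):
    print(f"  L={L:>2d}: {res.value:.3f}")

ceiling = icc_two_component(components.sigma2_subj, components.sigma2_sess)
print(f"\nceiling as K,L -> infinity: {ceiling:.3f}")

for threshold in (0.85, 0.88, 0.95):
    L = minimal_repetitions(components, k_avg=2, threshold=threshold)
    txt = "unreachable" if L is None else f"L = {L}"
    print(f"smallest L with ICCk >= {threshold:.2f}: {txt}")
print("\nTwo repetitions per side already clear 0.85 — more than about ten "
      "buys almost nothing, and 0.95 is unreachable because the session "
      "variance itself cannot be averaged away.")
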