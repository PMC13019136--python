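"""Residual privacy risk of the released perturbed slice.

Simulates a contiguous common-SNP slice with realistic haplotype
sharing (coalescent model), releases the LDP-perturbed member matrix,
and mounts the min-Hamming-distance membership-inference attack with a
threshold calibrated to a 5% false-positive rate.
"""

import fedprint as fp

members, controls = fp.sample_haplotype_panel(
    n_members=1500, n_controls=300, n_loci=100, seed=9
)
print(f"panel: {members.n_samples} members, {controls.n_samples} "
      f"population-matched non-members, {members.n_loci} SNPs")

for eps in (0.5, 1.0, 3.0):
    res = fp.mi_attack_power(
        members, controls, eps, n_case=25, n_ctrl=25, reps=50, fpr=0.05, seed=1
    )
    print(f"eps={eps:>3}: attack power {res.mean_power:.3f} "
          f"(95% CI {res.ci_low:.3f}-{res.ci_high:.3f})")

print("power near the 5% false-positive floor means the attacker gains")
print("almost nothing from the release; power grows with the privacy budget.")
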