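"""Free-ratio model: an independent dN/dS ratio on every branch.

Not a formal test of selection, but the per-branch dN, dS and omega
summarize the relative strength of purifying selection across lineages.
dN and dS follow the mutational-opportunity convention (substitutions per
nonsynonymous/synonymous site).
"""

from codonsel import free_ratio, make_study_like_fixture, simulate_alignment

spec = make_study_like_fixture("m0-purifying", seed=3)
spec.n_sites = 500
aln, _ = simulate_alignment(spec)
print(f"data simulated with omega = {spec.theta['omega']} on every branch\n")

rates, _ = free_ratio(aln, spec.tree, seed=0)
print(f"{'branch':12s} {'t':>7s} {'dN':>8s} {'dS':>8s} {'omega':>7s}")
for r in rates:
    print(f"{r.branch:12s} {r.t:7.3f} {r.dN:8.4f} {r.dS:8.4f} {r.omega:7.3f}")

omegas = sorted(r.omega for r in rates)
print(f"\nmedian branch omega = {omegas[len(omegas) // 2]:.3f} — all "
      "branches hover near the generating value, with per-branch noise "
      "largest on the shortest branches.")
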