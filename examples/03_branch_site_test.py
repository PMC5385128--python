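"""Branch-site test of positive selection on a foreground lineage.

Data are simulated with ~10% of sites evolving at omega = 5 on the
labeled foreground clade only. The test compares branch-site model A
(omega2 >= 1 free on the foreground) against the null (omega2 = 1) with a
1-df likelihood-ratio test, and reports the sites assigned to the
positively selected classes by empirical Bayes.
"""

import numpy as np

from codonsel import branch_site_test, make_study_like_fixture, simulate_alignment

spec = make_study_like_fixture("branchsite-positive", seed=77)
spec.n_sites = 400
aln, truth = simulate_alignment(spec)

result, posteriors = branch_site_test(aln, spec.tree, restarts=2, seed=0)
print(f"lnL alternative = {result.lnL_alt:.2f}")
print(f"lnL null        = {result.lnL_null:.2f}")
print(f"LRT = {result.lrt:.2f}, df = {result.df}, p = {result.pvalue:.3g}")
print(f"foreground omega2-hat = {result.fit_alt.theta['omega2']:.2f} (truth 5)")

top = np.argsort(posteriors.posteriors)[::-1][:5]
print("\ntop-5 sites by posterior of positive selection:")
for s in top:
    truly = "yes" if truth.site_class[s] in (2, 3) else "no"
    print(f"  site {s + 1:3d}  posterior {posteriors.posteriors[s]:.3f}  "
          f"(simulated in a selected class: {truly})")
print(
    "\np < 0.05 rejects the null of no positive selection on the "
    "foreground; high-posterior sites are the candidates for the "
    "selected residues."
)
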