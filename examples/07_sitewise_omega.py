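"""Site-wise omega: a per-site maximum-likelihood dN/dS scan.

With kappa and branch lengths fixed from the one-ratio fit, each codon
site gets its own omega estimate and a likelihood-ratio statistic against
neutrality (omega = 1) — the per-site view used to pinpoint which
residues drive a gene-level signal.
"""

from codonsel import fit, make_study_like_fixture, simulate_alignment, sitewise_omega

spec = make_study_like_fixture("cmc-divergent", seed=100)
spec.n_sites = 150
aln, truth = simulate_alignment(spec)

m0 = fit(aln, spec.tree, "M0", restarts=1, seed=0)
df = sitewise_omega(aln, spec.tree, m0_fit=m0)

top = df.nlargest(5, "omega")
print("five sites with the highest omega-hat:")
for _, row in top.iterrows():
    s = int(row["site"]) - 1
    cls = int(truth.site_class[s])
    print(f"  site {int(row['site']):3d}  omega {row['omega']:8.2f}  "
          f"LRT vs omega=1 {row['LRT_vs_neutral']:6.2f}  "
          f"(simulated class {cls})")

frac_low = (df["omega"] < 0.5).mean()
print(f"\n{100 * frac_low:.0f}% of sites estimate omega < 0.5 — the "
      "purifying majority. Note the scan pools all branches, so sites "
      "that are divergent only on the small foreground clade (class 2) "
      "blend toward their background ratio here; the clade-model test, "
      "not this scan, is the tool that separates the partitions.")
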